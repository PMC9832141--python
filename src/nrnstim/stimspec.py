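"""Stimulus specifications: distributions, modules, tags, sessions.

A *module* is one input mechanism — a current step (``istep``), a two-state
kinetic synapse (``synaptic``, difference-of-exponentials conductance with
rise tau1, decay tau2 and reversal E), or a ``custom`` NMODL point process
carried as an opaque payload.  A *tag* groups modules that share locations
and activation times (e.g. AMPA + NMDA at the same synapse), with an input
count, compartment limits, a location distribution anchored at a chosen
segment, and a timing rule (onset + inter-stimulus interval).  A *session*
bundles morphology path, modules, tags, run count and seed, and persists as
JSON.

Units are user-facing: synaptic weights in nS, currents in nA, times in ms,
distances in um.  Conversion to NEURON's uS happens only in codegen.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Any

from .morphology import Compartment, Morphology, SegmentRef

__all__ = [
    "DistributionKind",
    "DistributionSpec",
    "StimulusModule",
    "LocationSpec",
    "TimingSpec",
    "StimulusTag",
    "Session",
    "SessionLoadError",
    "validate_session",
    "save_session",
    "load_session",
    "load_defaults",
    "merge_defaults",
    "point_process_name",
]

SCHEMA_VERSION = 1

SINGLE = "single"
MULTIPLE_UNIFORM = "multiple_uniform"
MULTIPLE_POISSON = "multiple_poisson"
DistributionKind = (SINGLE, MULTIPLE_UNIFORM, MULTIPLE_POISSON)


class SessionLoadError(ValueError):
    """Session/defaults JSON is malformed or violates the schema."""


@dataclass(frozen=True)
class DistributionSpec:
    """How a quantity varies across inputs.

    ``single`` is the constant ``mean``; ``multiple_uniform`` the symmetric
    uniform with that mean and sd; ``multiple_poisson`` a scaled Poisson
    c*K with lambda = mean^2/sd^2, c = sd^2/mean, matching both moments.
    """

    kind: str = SINGLE
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in DistributionKind:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class StimulusModule:
    kind: str  # istep | synaptic | custom
    name: str
    weight: DistributionSpec  # nS (synaptic/custom) or nA (istep)
    E: float | None = None  # mV, synaptic only
    tau1: float | None = None  # ms rise, synaptic only
    tau2: float | None = None  # ms decay, synaptic only
    duration: float | None = None  # ms, istep only
    mod_source: str | None = None  # opaque NMODL text, custom only


@dataclass(frozen=True)
class LocationSpec:
    anchor: SegmentRef
    distribution: DistributionSpec = field(default_factory=DistributionSpec)


@dataclass(frozen=True)
class TimingSpec:
    onset: float = 0.0  # ms delay before the first input
    interval: DistributionSpec = field(default_factory=DistributionSpec)


@dataclass(frozen=True)
class StimulusTag:
    name: str
    module_names: tuple[str, ...]
    n_inputs: int
    allowed_compartments: frozenset[Compartment]
    location: LocationSpec
    timing: TimingSpec
    color: str = ""  # inert display label, carried for GUI compatibility

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_names", tuple(self.module_names))
        object.__setattr__(
            self,
            "allowed_compartments",
            frozenset(Compartment(c) for c in self.allowed_compartments),
        )


@dataclass(frozen=True)
class Session:
    swc_path: str
    modules: tuple[StimulusModule, ...] = ()
    tags: tuple[StimulusTag, ...] = ()
    n_runs: int = 1
    seed: int | None = None
    output_path: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        object.__setattr__(self, "tags", tuple(self.tags))

    def module(self, name: str) -> StimulusModule:
        for mod in self.modules:
            if mod.name == name:
                return mod
        raise KeyError(name)


_POINT_PROCESS_RE = re.compile(r"\bPOINT_PROCESS\s+(\w+)")


def point_process_name(mod_source: str) -> str | None:
    """Name declared by the NEURON block's POINT_PROCESS statement, if any."""
    m = _POINT_PROCESS_RE.search(mod_source)
    return m.group(1) if m else None


def validate_session(s: Session, m: Morphology) -> list[str]:
    """All constraint violations in ``s`` against morphology ``m``.

    Empty list iff the session is generatable.  Pure: inputs are not
    mutated and repeated calls agree.
    """
    errors: list[str] = []
    names = [mod.name for mod in s.modules]
    for n in names:
        if names.count(n) > 1:
            errors.append(f"module name {n!r} is not unique")
    for mod in s.modules:
        if mod.kind not in ("istep", "synaptic", "custom"):
            errors.append(f"module {mod.name!r}: unknown kind {mod.kind!r}")
        if mod.kind == "synaptic":
            if mod.tau1 is None or mod.tau2 is None or mod.E is None:
                errors.append(f"module {mod.name!r}: synaptic requires tau1, tau2, E")
            elif not (0 < mod.tau1 < mod.tau2):
                errors.append(
                    f"module {mod.name!r}: 0 < tau1 < tau2 violated "
                    f"(tau1={mod.tau1}, tau2={mod.tau2})"
                )
        if mod.kind == "istep" and (mod.duration is None or mod.duration <= 0):
            errors.append(f"module {mod.name!r}: istep requires duration > 0")
        if mod.kind == "custom":
            if not mod.mod_source:
                errors.append(f"module {mod.name!r}: custom requires mod_source")
            else:
                pp = point_process_name(mod.mod_source)
                if pp is None:
                    errors.append(
                        f"module {mod.name!r}: mod_source has no POINT_PROCESS"
                    )
        errors.extend(
            f"module {mod.name!r}: weight {msg}"
            for msg in _check_distribution(mod.weight)
        )
    if s.n_runs < 1:
        errors.append(f"n_runs must be >= 1, got {s.n_runs}")
    for tag in s.tags:
        if tag.n_inputs < 1:
            errors.append(f"tag {tag.name!r}: n_inputs must be >= 1")
        if not tag.module_names:
            errors.append(f"tag {tag.name!r}: references no modules")
        for name in tag.module_names:
            if name not in names:
                errors.append(f"tag {tag.name!r}: unknown module {name!r}")
        if not tag.allowed_compartments:
            errors.append(f"tag {tag.name!r}: allowed_compartments is empty")
        for comp in tag.allowed_compartments:
            if not m.sections[comp]:
                errors.append(
                    f"tag {tag.name!r}: morphology has no {comp.value} sections"
                )
        try:
            m.point_of_ref(tag.location.anchor)
        except LookupError as exc:
            errors.append(f"tag {tag.name!r}: anchor invalid ({exc})")
        errors.extend(
            f"tag {tag.name!r}: location {msg}"
            for msg in _check_distribution(tag.location.distribution)
        )
        if tag.timing.onset < 0:
            errors.append(f"tag {tag.name!r}: onset must be >= 0")
        errors.extend(
            f"tag {tag.name!r}: interval {msg}"
            for msg in _check_distribution(tag.timing.interval)
        )
    return errors


def _check_distribution(spec: DistributionSpec) -> list[str]:
    out = []
    if spec.kind == MULTIPLE_POISSON and spec.sd > 0 and spec.mean <= 0:
        out.append("mean > 0 required for multiple_poisson")
    return out


# ---------------------------------------------------------------------------
# JSON persistence


def _dist_to_dict(d: DistributionSpec) -> dict:
    return {"kind": d.kind, "mean": d.mean, "sd": d.sd}


def _dist_from_dict(d: dict, where: str) -> DistributionSpec:
    try:
        return DistributionSpec(kind=d["kind"], mean=d["mean"], sd=d["sd"])
    except (KeyError, TypeError, ValueError) as exc:
        raise SessionLoadError(f"{where}: invalid distribution ({exc})") from None


def _ref_to_dict(r: SegmentRef) -> dict:
    return {"compartment": r.compartment.value, "index": r.index, "position": r.position}


def _ref_from_dict(d: dict, where: str) -> SegmentRef:
    try:
        return SegmentRef(Compartment(d["compartment"]), d["index"], d.get("position", 0.5))
    except (KeyError, TypeError, ValueError) as exc:
        raise SessionLoadError(f"{where}: invalid segment reference ({exc})") from None


def session_to_dict(s: Session) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "swc_path": s.swc_path,
        "n_runs": s.n_runs,
        "seed": s.seed,
        "output_path": s.output_path,
        "modules": [
            {
                "kind": mod.kind,
                "name": mod.name,
                "weight": _dist_to_dict(mod.weight),
                "E": mod.E,
                "tau1": mod.tau1,
                "tau2": mod.tau2,
                "duration": mod.duration,
                "mod_source": mod.mod_source,
            }
            for mod in s.modules
        ],
        "tags": [
            {
                "name": t.name,
                "module_names": list(t.module_names),
                "n_inputs": t.n_inputs,
                "allowed_compartments": sorted(c.value for c in t.allowed_compartments),
                "location": {
                    "anchor": _ref_to_dict(t.location.anchor),
                    "distribution": _dist_to_dict(t.location.distribution),
                },
                "timing": {
                    "onset": t.timing.onset,
                    "interval": _dist_to_dict(t.timing.interval),
                },
                "color": t.color,
            }
            for t in s.tags
        ],
    }


def save_session(s: Session) -> str:
    return json.dumps(session_to_dict(s), indent=2, sort_keys=True) + "\n"


_KNOWN_SESSION_KEYS = {
    "schema_version", "swc_path", "n_runs", "seed", "output_path",
    "modules", "tags",
}


def load_session(text: str, warnings: list[str] | None = None) -> Session:
    """Parse session JSON.  Unknown keys are tolerated with a warning."""
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SessionLoadError(f"not valid JSON: {exc}") from None
    if not isinstance(data, dict):
        raise SessionLoadError("session JSON must be an object")
    extra = set(data) - _KNOWN_SESSION_KEYS
    if extra and warnings is not None:
        warnings.append(f"ignoring unknown session keys: {sorted(extra)}")
    missing = {"swc_path"} - set(data)
    if missing:
        raise SessionLoadError(f"missing required keys: {sorted(missing)}")
    try:
        modules = tuple(
            StimulusModule(
                kind=md["kind"],
                name=md["name"],
                weight=_dist_from_dict(md["weight"], f"module {md.get('name')}"),
                E=md.get("E"),
                tau1=md.get("tau1"),
                tau2=md.get("tau2"),
                duration=md.get("duration"),
                mod_source=md.get("mod_source"),
            )
            for md in data.get("modules", [])
        )
        tags = tuple(
            StimulusTag(
                name=td["name"],
                module_names=tuple(td["module_names"]),
                n_inputs=td["n_inputs"],
                allowed_compartments=frozenset(
                    Compartment(c) for c in td["allowed_compartments"]
                ),
                location=LocationSpec(
                    anchor=_ref_from_dict(
                        td["location"]["anchor"], f"tag {td.get('name')}"
                    ),
                    distribution=_dist_from_dict(
                        td["location"]["distribution"], f"tag {td.get('name')}"
                    ),
                ),
                timing=TimingSpec(
                    onset=td["timing"]["onset"],
                    interval=_dist_from_dict(
                        td["timing"]["interval"], f"tag {td.get('name')}"
                    ),
                ),
                color=td.get("color", ""),
            )
            for td in data.get("tags", [])
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, SessionLoadError):
            raise
        raise SessionLoadError(f"invalid session structure: {exc!r}") from None
    return Session(
        swc_path=data["swc_path"],
        modules=modules,
        tags=tags,
        n_runs=data.get("n_runs", 1),
        seed=data.get("seed"),
        output_path=data.get("output_path", "."),
    )


# ---------------------------------------------------------------------------
# Defaults ("partial session") files

_DEFAULT_KEYS = {
    "onset", "interval_mean", "interval_sd",
    "tau1", "tau2", "E", "duration",
    "n_runs", "seed", "output_path",
}


def load_defaults(text: str, warnings: list[str] | None = None) -> dict[str, Any]:
    """Parse a defaults file: a flat JSON object of parameter overrides.

    Recognized keys: onset, interval_mean, interval_sd (timing of all tags);
    tau1, tau2, E (synaptic modules); duration (istep modules); n_runs,
    seed, output_path (session).  Only the keys present take effect.
    """
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SessionLoadError(f"not valid JSON: {exc}") from None
    if not isinstance(data, dict):
        raise SessionLoadError("defaults JSON must be an object")
    extra = set(data) - _DEFAULT_KEYS
    if extra and warnings is not None:
        warnings.append(f"ignoring unknown defaults keys: {sorted(extra)}")
    return {k: v for k, v in data.items() if k in _DEFAULT_KEYS}


def merge_defaults(s: Session, defaults: dict[str, Any]) -> Session:
    """Apply a defaults dict to a session; only present keys override."""
    modules = []
    for mod in s.modules:
        if mod.kind == "synaptic":
            mod = replace(
                mod,
                tau1=defaults.get("tau1", mod.tau1),
                tau2=defaults.get("tau2", mod.tau2),
                E=defaults.get("E", mod.E),
            )
        elif mod.kind == "istep":
            mod = replace(mod, duration=defaults.get("duration", mod.duration))
        modules.append(mod)
    tags = []
    for tag in s.tags:
        timing = tag.timing
        if "onset" in defaults:
            timing = replace(timing, onset=defaults["onset"])
        if "interval_mean" in defaults or "interval_sd" in defaults:
            interval = replace(
                timing.interval,
                mean=defaults.get("interval_mean", timing.interval.mean),
                sd=defaults.get("interval_sd", timing.interval.sd),
            )
            timing = replace(timing, interval=interval)
        tags.append(replace(tag, timing=timing))
    return replace(
        s,
        modules=tuple(modules),
        tags=tuple(tags),
        n_runs=defaults.get("n_runs", s.n_runs),
        seed=defaults.get("seed", s.seed),
        output_path=defaults.get("output_path", s.output_path),
    )
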
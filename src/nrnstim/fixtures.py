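"""Synthetic SWC morphologies and canned sessions for testing and demos.

Straight cables with uniform point spacing make distance oracles closed
form: the k-th stick point lies exactly k*spacing um from the soma.  The
session presets encode the published single-input and 100-input
configurations (AMPA kinetics tau1=0.7/tau2=2 ms, E=0 mV, 1 nS and 7.5 pS
weights; GABA_A kinetics tau1=0.5/tau2=7 ms, E=-75 mV, 330 pS; onset
200 ms) against a 300 um ball-and-stick cable so the whole pipeline runs
with no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .morphology import Compartment, Morphology, SegmentRef, parse_swc
from .stimspec import (
    MULTIPLE_POISSON,
    SINGLE,
    DistributionSpec,
    LocationSpec,
    Session,
    StimulusModule,
    StimulusTag,
    TimingSpec,
)

__all__ = [
    "FixtureSpec",
    "make_swc",
    "make_session",
    "materialize_preset",
    "PRESETS",
    "PRESET_FIXTURE",
]


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # ball_and_stick | y_tree | random_tree
    n_points: int = 20  # points per branch
    spacing: float = 10.0  # um between successive points
    radius: float = 1.0  # neurite radius, um
    soma_radius: float = 10.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


def _line(pid, type_code, x, y, z, radius, parent):
    return f"{pid} {type_code} {x:.6g} {y:.6g} {z:.6g} {radius:.6g} {parent}"


def make_swc(spec: FixtureSpec) -> str:
    """SWC text for the requested fixture; deterministic in (spec, seed)."""
    lines = ["# synthetic fixture morphology"]
    lines.append(_line(1, 1, 0, 0, 0, spec.soma_radius, -1))
    if spec.kind == "ball_and_stick":
        for k in range(1, spec.n_points + 1):
            lines.append(_line(k + 1, 4, 0, k * spec.spacing, 0, spec.radius, k))
    elif spec.kind == "y_tree":
        n = spec.n_points
        # trunk straight up; daughter A continues sequentially at +45 deg,
        # daughter B re-attaches at the trunk tip with an id gap (the one
        # branch point by construction).
        for k in range(1, n + 1):
            lines.append(_line(k + 1, 4, 0, k * spec.spacing, 0, spec.radius, k))
        tip_id = n + 1
        tip_y = n * spec.spacing
        step = spec.spacing / np.sqrt(2)
        for k in range(1, n + 1):
            lines.append(
                _line(tip_id + k, 4, k * step, tip_y + k * step, 0, spec.radius,
                      tip_id + k - 1)
            )
        for k in range(1, n + 1):
            pid = tip_id + n + k
            parent = tip_id if k == 1 else pid - 1
            lines.append(
                _line(pid, 4, -k * step, tip_y + k * step, 0, spec.radius, parent)
            )
    elif spec.kind == "random_tree":
        rng = np.random.default_rng(spec.seed)
        next_id = 2
        # a few primary neurites of random type, random-walk directions,
        # occasional bifurcations; parents always precede children.
        tips: list[tuple[int, np.ndarray, np.ndarray, int]] = []
        for type_code in rng.choice([2, 3, 4], size=3, replace=True):
            theta = rng.uniform(0, 2 * np.pi)
            tips.append(
                (1, np.zeros(3), np.array([np.cos(theta), np.sin(theta), 0.0]),
                 int(type_code))
            )
        budget = spec.n_points * 3
        while tips and budget > 0:
            parent_id, pos, direction, type_code = tips.pop(
                int(rng.integers(len(tips)))
            )
            theta = rng.normal(0, 0.3)
            c, s = np.cos(theta), np.sin(theta)
            direction = np.array(
                [c * direction[0] - s * direction[1],
                 s * direction[0] + c * direction[1], 0.0]
            )
            pos = pos + direction * spec.spacing
            lines.append(
                _line(next_id, type_code, pos[0], pos[1], pos[2], spec.radius,
                      parent_id)
            )
            budget -= 1
            tips.append((next_id, pos, direction, type_code))
            if rng.random() < 0.1:  # bifurcate
                tips.append((next_id, pos, -direction, type_code))
            next_id += 1
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Session presets

# 300 um apical cable at 1 um spacing: anchor index 199 sits 200 um out.
PRESET_FIXTURE = FixtureSpec(kind="ball_and_stick", n_points=300, spacing=1.0)
_ANCHOR_200UM = SegmentRef(Compartment.apical, 199)

_AMPA = dict(kind="synaptic", E=0.0, tau1=0.7, tau2=2.0)
_GABA = dict(kind="synaptic", E=-75.0, tau1=0.5, tau2=7.0)

PRESETS = ("fig3_single", "fig3_poisson100", "fig4_subthreshold", "fig5_gaba")


def make_session(preset: str, swc_path: str = "fixture.swc") -> Session:
    """A canned session encoding one of the published test configurations."""
    single = DistributionSpec(SINGLE, 0.0, 0.0)
    timing = TimingSpec(onset=200.0, interval=DistributionSpec(SINGLE, 0.0, 0.0))
    if preset == "fig3_single":
        module = StimulusModule(
            name="AMPA", weight=DistributionSpec(SINGLE, 1.0, 0.0), **_AMPA
        )
        tag = StimulusTag(
            name="Distal", module_names=("AMPA",), n_inputs=1,
            allowed_compartments=frozenset({Compartment.apical}),
            location=LocationSpec(anchor=_ANCHOR_200UM, distribution=single),
            timing=timing, color="red",
        )
    elif preset == "fig3_poisson100":
        module = StimulusModule(
            name="AMPA", weight=DistributionSpec(SINGLE, 1.0, 0.0), **_AMPA
        )
        tag = StimulusTag(
            name="Distal", module_names=("AMPA",), n_inputs=100,
            allowed_compartments=frozenset({Compartment.apical}),
            location=LocationSpec(
                anchor=_ANCHOR_200UM,
                distribution=DistributionSpec(MULTIPLE_POISSON, 200.0, 50.0),
            ),
            timing=timing, color="red",
        )
    elif preset == "fig4_subthreshold":
        module = StimulusModule(
            name="AMPA", weight=DistributionSpec(SINGLE, 0.0075, 0.0), **_AMPA
        )
        tag = StimulusTag(
            name="Distal", module_names=("AMPA",), n_inputs=1,
            allowed_compartments=frozenset({Compartment.apical}),
            location=LocationSpec(anchor=_ANCHOR_200UM, distribution=single),
            timing=timing, color="red",
        )
    elif preset == "fig5_gaba":
        module = StimulusModule(
            name="GABA", weight=DistributionSpec(SINGLE, 0.33, 0.0), **_GABA
        )
        tag = StimulusTag(
            name="Distal", module_names=("GABA",), n_inputs=1,
            allowed_compartments=frozenset({Compartment.apical}),
            location=LocationSpec(anchor=_ANCHOR_200UM, distribution=single),
            timing=timing, color="blue",
        )
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    return Session(
        swc_path=swc_path, modules=(module,), tags=(tag,), n_runs=1, seed=1,
    )


def materialize_preset(preset: str, directory: str | Path) -> tuple[Session, Morphology]:
    """Write the preset's fixture SWC under ``directory`` and return the
    session (with swc_path pointing at it) plus the parsed morphology."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    swc_path = directory / f"{preset}.swc"
    text = make_swc(PRESET_FIXTURE)
    swc_path.write_text(text)
    return make_session(preset, str(swc_path)), parse_swc(text)
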
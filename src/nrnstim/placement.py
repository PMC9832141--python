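"""Realize a session into concrete input ensembles.

Weights, locations and activation times are drawn independently per stimulus
tag.  Locations are chosen by drawing a target Euclidean distance from the
tag's anchor segment and picking the allowed segment whose distance is
nearest (ties broken uniformly at random).  Times accumulate onset +
inter-stimulus intervals.  Randomness comes from per-(run, tag, role)
substreams of one master seed, so adding a tag or module never perturbs the
draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .morphology import Morphology, SegmentRef, euclidean_distance
from .stimspec import (
    MULTIPLE_POISSON,
    MULTIPLE_UNIFORM,
    SINGLE,
    DistributionSpec,
    Session,
    StimulusTag,
    validate_session,
)

__all__ = [
    "PlacedInput",
    "PlacedEnsemble",
    "GenerationError",
    "draw_value",
    "place_locations",
    "place_times",
    "realize",
]

_MAX_RESAMPLE = 1000
_ROLE = {"location": 0, "time": 1, "weight": 2}


class GenerationError(RuntimeError):
    """Ensemble realization failed (empty candidates, resample budget, ...)."""


@dataclass(frozen=True)
class PlacedInput:
    tag_name: str
    input_index: int
    segment: SegmentRef
    time: float  # ms
    weights: dict[str, float]  # module name -> drawn weight (nS or nA)


@dataclass(frozen=True)
class PlacedEnsemble:
    run_index: int
    inputs: tuple[PlacedInput, ...]
    seed: int


def substream(seed: int, run_index: int, tag_name: str, role: str,
              module_name: str = "") -> np.random.Generator:
    """Independent, reproducible RNG for one (run, tag, role[, module])."""
    key = (
        seed & 0x7FFFFFFF,
        run_index,
        zlib.crc32(tag_name.encode()),
        _ROLE[role],
        zlib.crc32(module_name.encode()),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def draw_value(
    spec: DistributionSpec,
    rng: np.random.Generator,
    poisson_mode: str = "scaled",
) -> float:
    """One draw from a distribution spec.

    single -> the mean exactly.  multiple_uniform -> uniform on
    [mean - sqrt(3)*sd, mean + sqrt(3)*sd] (the unique symmetric uniform with
    those moments); negative draws are resampled, up to 1000 attempts.
    multiple_poisson -> c*K with K ~ Poisson(mean^2/sd^2), c = sd^2/mean, so
    both requested moments are matched; ``poisson_mode="natural"`` instead
    ignores sd and draws Poisson(mean) directly.
    """
    if spec.kind == SINGLE or spec.sd == 0:
        return float(spec.mean)
    if spec.kind == MULTIPLE_UNIFORM:
        half = np.sqrt(3.0) * spec.sd
        for _ in range(_MAX_RESAMPLE):
            v = rng.uniform(spec.mean - half, spec.mean + half)
            if v >= 0:
                return float(v)
        raise GenerationError(
            f"could not draw a non-negative value from {spec} "
            f"after {_MAX_RESAMPLE} attempts"
        )
    if spec.kind == MULTIPLE_POISSON:
        if poisson_mode == "natural":
            return float(rng.poisson(spec.mean))
        lam = spec.mean**2 / spec.sd**2
        c = spec.sd**2 / spec.mean
        return float(c * rng.poisson(lam))
    raise ValueError(f"unknown distribution kind {spec.kind!r}")


def place_locations(
    tag: StimulusTag,
    m: Morphology,
    rng: np.random.Generator,
    poisson_mode: str = "scaled",
) -> list[SegmentRef]:
    """Segment for each of the tag's inputs.

    ``single`` repeats the anchor.  Otherwise each input draws a target
    distance from the anchor and takes the nearest-by-|distance - target|
    segment among the allowed compartments; ties break uniformly at random.
    Positions along sections are fixed at 0.5.
    """
    anchor = SegmentRef(tag.location.anchor.compartment, tag.location.anchor.index)
    if tag.location.distribution.kind == SINGLE:
        return [anchor] * tag.n_inputs
    candidates = list(m.iter_refs(tag.allowed_compartments))
    if not candidates:
        raise GenerationError(
            f"tag {tag.name!r}: no segments in allowed compartments "
            f"{sorted(c.value for c in tag.allowed_compartments)}"
        )
    dists = np.array([euclidean_distance(m, anchor, c) for c in candidates])
    out: list[SegmentRef] = []
    for _ in range(tag.n_inputs):
        target = draw_value(tag.location.distribution, rng, poisson_mode)
        gaps = np.abs(dists - target)
        best = gaps.min()
        ties = np.flatnonzero(gaps == best)
        pick = ties[0] if len(ties) == 1 else ties[rng.integers(len(ties))]
        out.append(candidates[pick])
    return out


def place_times(
    tag: StimulusTag,
    rng: np.random.Generator,
    poisson_mode: str = "scaled",
) -> list[float]:
    """Activation time for each input: onset, then cumulative intervals."""
    times = [float(tag.timing.onset)]
    for _ in range(tag.n_inputs - 1):
        times.append(times[-1] + draw_value(tag.timing.interval, rng, poisson_mode))
    return times


def realize(
    s: Session,
    m: Morphology,
    run_index: int = 0,
    poisson_mode: str = "scaled",
) -> PlacedEnsemble:
    """Draw one complete ensemble for one run of the session.

    Per tag there is one shared location list and one shared time list, so
    all modules of a tag land at the same segments and fire at the same
    times; each (module, input) pair draws its weight independently.
    """
    errors = validate_session(s, m)
    if errors:
        raise GenerationError("session is not generatable: " + "; ".join(errors))
    seed = s.seed if s.seed is not None else 0
    inputs: list[PlacedInput] = []
    for tag in s.tags:
        rng_loc = substream(seed, run_index, tag.name, "location")
        rng_time = substream(seed, run_index, tag.name, "time")
        segments = place_locations(tag, m, rng_loc, poisson_mode)
        times = place_times(tag, rng_time, poisson_mode)
        weight_draws: dict[str, list[float]] = {}
        for name in tag.module_names:
            rng_w = substream(seed, run_index, tag.name, "weight", name)
            spec = s.module(name).weight
            weight_draws[name] = [
                draw_value(spec, rng_w, poisson_mode) for _ in range(tag.n_inputs)
            ]
        for i in range(tag.n_inputs):
            inputs.append(
                PlacedInput(
                    tag_name=tag.name,
                    input_index=i,
                    segment=segments[i],
                    time=times[i],
                    weights={name: weight_draws[name][i] for name in tag.module_names},
                )
            )
    return PlacedEnsemble(run_index=run_index, inputs=tuple(inputs), seed=seed)
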
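"""Stochastic draws, segment selection, timing, and ensemble realization."""

from dataclasses import replace

import numpy as np
import pytest

from nrnstim.morphology import Compartment, SegmentRef
from nrnstim.placement import (
    GenerationError,
    draw_value,
    place_locations,
    place_times,
    realize,
    substream,
)
from nrnstim.fixtures import make_session
from nrnstim.stimspec import (
    MULTIPLE_POISSON,
    MULTIPLE_UNIFORM,
    SINGLE,
    DistributionSpec,
    LocationSpec,
    StimulusModule,
    TimingSpec,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestDrawValue:
    def test_single_returns_mean_exactly(self):
        spec = DistributionSpec(SINGLE, 1.0, 0.0)
        assert all(draw_value(spec, _rng()) == 1.0 for _ in range(10))

    @pytest.mark.parametrize("kind", [SINGLE, MULTIPLE_UNIFORM, MULTIPLE_POISSON])
    def test_zero_sd_degenerates_to_constant(self, kind):
        spec = DistributionSpec(kind, 7.0, 0.0)
        assert draw_value(spec, _rng()) == 7.0

    def test_scaled_poisson_moments(self):
        # oracle: c*K with K ~ Poisson(lambda), lambda = mean^2/sd^2 = 25,
        # c = sd^2/mean = 0.4, so E = c*lambda = 10, SD = c*sqrt(lambda) = 2
        spec = DistributionSpec(MULTIPLE_POISSON, 10.0, 2.0)
        rng = _rng(1)
        draws = np.array([draw_value(spec, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(10.0, abs=0.05)
        assert draws.std() == pytest.approx(2.0, abs=0.05)
        # support is the lattice 0.4 * integers
        assert np.allclose(draws / 0.4, np.round(draws / 0.4))

    def test_uniform_moments_and_support(self):
        spec = DistributionSpec(MULTIPLE_UNIFORM, 50.0, 10.0)
        rng = _rng(2)
        draws = np.array([draw_value(spec, rng) for _ in range(100_000)])
        half = np.sqrt(3.0) * 10.0
        assert draws.min() >= 50.0 - half and draws.max() <= 50.0 + half
        assert draws.mean() == pytest.approx(50.0, abs=3 * 10 / np.sqrt(1e5))
        assert draws.std() == pytest.approx(10.0, abs=0.15)

    def test_uniform_negative_draws_resampled_not_clamped(self):
        # mean < sqrt(3)*sd: the raw support dips below zero
        spec = DistributionSpec(MULTIPLE_UNIFORM, 1.0, 2.0)
        rng = _rng(3)
        draws = np.array([draw_value(spec, rng) for _ in range(20_000)])
        assert draws.min() >= 0.0
        assert (draws == 0.0).sum() == 0  # clamping would pile mass at zero

    def test_natural_poisson_mode_ignores_sd(self):
        spec = DistributionSpec(MULTIPLE_POISSON, 10.0, 2.0)
        rng = _rng(4)
        draws = np.array(
            [draw_value(spec, rng, poisson_mode="natural") for _ in range(50_000)]
        )
        assert draws.std() == pytest.approx(np.sqrt(10.0), abs=0.1)
        assert np.allclose(draws, np.round(draws))


class TestPlaceLocations:
    def test_single_repeats_anchor(self, preset):
        s, m = preset("fig3_single")
        tag = replace(s.tags[0], n_inputs=5)
        refs = place_locations(tag, m, _rng())
        assert refs == [SegmentRef(Compartment.apical, 199)] * 5

    def test_zero_mean_zero_sd_selects_anchor(self, preset):
        s, m = preset("fig3_single")
        tag = replace(
            s.tags[0],
            n_inputs=20,
            location=LocationSpec(
                anchor=SegmentRef(Compartment.apical, 42),
                distribution=DistributionSpec(MULTIPLE_UNIFORM, 0.0, 0.0),
            ),
        )
        refs = place_locations(tag, m, _rng())
        assert all(r.index == 42 for r in refs)

    def test_mean_selected_distance_recovers_target(self, long_cable, preset):
        # 1 um point spacing: nearest-segment quantization error < 1 um
        s, _ = preset("fig3_single")
        tag = replace(
            s.tags[0],
            n_inputs=10_000,
            location=LocationSpec(
                anchor=SegmentRef(Compartment.soma, 0),
                distribution=DistributionSpec(MULTIPLE_UNIFORM, 50.0, 10.0),
            ),
        )
        refs = place_locations(tag, long_cable, _rng(5))
        from nrnstim.morphology import euclidean_distance

        anchor = SegmentRef(Compartment.soma, 0)
        dists = [euclidean_distance(long_cable, anchor, r) for r in refs]
        assert np.mean(dists) == pytest.approx(50.0, abs=1.0)

    def test_confinement_to_allowed_compartments(self, preset):
        s, m = preset("fig3_poisson100")
        refs = place_locations(s.tags[0], m, _rng(6))
        assert all(r.compartment == Compartment.apical for r in refs)

    def test_empty_candidate_set_raises(self, preset):
        s, m = preset("fig3_single")
        tag = replace(
            s.tags[0],
            allowed_compartments=frozenset({Compartment.axon}),
            location=LocationSpec(
                anchor=s.tags[0].location.anchor,
                distribution=DistributionSpec(MULTIPLE_UNIFORM, 50.0, 10.0),
            ),
        )
        with pytest.raises(GenerationError, match="axon"):
            place_locations(tag, m, _rng())


class TestPlaceTimes:
    def test_simultaneous_when_interval_zero(self, preset):
        s, _ = preset("fig3_single")
        tag = replace(s.tags[0], n_inputs=3)
        assert place_times(tag, _rng()) == [200.0, 200.0, 200.0]

    def test_constant_interval_cumulative_sum(self, preset):
        s, _ = preset("fig3_single")
        tag = replace(
            s.tags[0],
            n_inputs=3,
            timing=TimingSpec(onset=200.0,
                              interval=DistributionSpec(SINGLE, 5.0, 0.0)),
        )
        assert place_times(tag, _rng()) == [200.0, 205.0, 210.0]

    def test_poisson_interval_mean_recovered(self, preset):
        s, _ = preset("fig3_single")
        tag = replace(
            s.tags[0],
            n_inputs=10_000,
            timing=TimingSpec(
                onset=0.0, interval=DistributionSpec(MULTIPLE_POISSON, 10.0, 3.0)
            ),
        )
        times = np.array(place_times(tag, _rng(7)))
        assert np.diff(times).mean() == pytest.approx(10.0, abs=0.1)

    def test_times_non_decreasing(self, preset):
        s, _ = preset("fig3_single")
        tag = replace(
            s.tags[0],
            n_inputs=500,
            timing=TimingSpec(
                onset=10.0, interval=DistributionSpec(MULTIPLE_UNIFORM, 2.0, 1.5)
            ),
        )
        times = place_times(tag, _rng(8))
        assert all(b >= a for a, b in zip(times, times[1:]))


class TestRealize:
    def _two_module_session(self, preset):
        s, m = preset("fig3_poisson100")
        nmda = StimulusModule(
            kind="synaptic", name="NMDA",
            weight=DistributionSpec(MULTIPLE_UNIFORM, 0.5, 0.1),
            E=0.0, tau1=2.0, tau2=50.0,
        )
        tag = replace(s.tags[0], module_names=("AMPA", "NMDA"), n_inputs=10)
        return replace(s, modules=s.modules + (nmda,), tags=(tag,)), m

    def test_co_localization_of_tagged_modules(self, preset):
        s, m = self._two_module_session(preset)
        ensemble = realize(s, m)
        for inp in ensemble.inputs:
            assert set(inp.weights) == {"AMPA", "NMDA"}
        # one shared segment and time per input index is structural:
        # each PlacedInput carries a single segment/time for all its modules
        assert len(ensemble.inputs) == 10

    def test_determinism(self, preset):
        s, m = preset("fig3_poisson100")
        assert realize(s, m, run_index=0) == realize(s, m, run_index=0)

    def test_distinct_runs_differ(self, preset):
        s, m = preset("fig3_poisson100")
        e0, e1 = realize(s, m, run_index=0), realize(s, m, run_index=1)
        assert [i.segment for i in e0.inputs] != [i.segment for i in e1.inputs]

    def test_tag_substreams_independent(self, preset):
        # changing tag A's spec leaves tag B's realized values unchanged
        s, m = preset("fig3_poisson100")
        tag_b = replace(
            s.tags[0], name="B",
            location=LocationSpec(
                anchor=SegmentRef(Compartment.apical, 99),
                distribution=DistributionSpec(MULTIPLE_UNIFORM, 100.0, 20.0),
            ),
        )
        s2 = replace(s, tags=(s.tags[0], tag_b))
        tag_a_mod = replace(
            s.tags[0],
            location=LocationSpec(
                anchor=s.tags[0].location.anchor,
                distribution=DistributionSpec(MULTIPLE_POISSON, 120.0, 30.0),
            ),
        )
        s3 = replace(s, tags=(tag_a_mod, tag_b))
        b_of = lambda e: [i for i in e.inputs if i.tag_name == "B"]
        assert b_of(realize(s2, m)) == b_of(realize(s3, m))

    def test_invalid_session_rejected(self, preset):
        s, m = preset("fig3_single")
        bad = replace(s, tags=(replace(s.tags[0], module_names=("missing",)),))
        with pytest.raises(GenerationError):
            realize(bad, m)

    def test_compartment_confinement_invariant(self, preset):
        s, m = preset("fig3_poisson100")
        for inp in realize(s, m).inputs:
            assert inp.segment.compartment in s.tags[0].allowed_compartments
            assert inp.time >= s.tags[0].timing.onset


def test_substreams_reproducible_and_role_separated():
    a = substream(1, 0, "tag", "location").random(5)
    b = substream(1, 0, "tag", "location").random(5)
    c = substream(1, 0, "tag", "time").random(5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
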
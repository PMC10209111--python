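import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from layerphys.datatypes import EventTable, Unit
from layerphys.spikes import (
    WindowSpec,
    align_spikes,
    burst_probability,
    classify_burst_regime,
    isi_cdf,
    mean_rate,
    modulation_index,
    parse_burst_events,
    population_median_cdf,
    pressure_derivative,
    response_probability,
)
from conftest import make_aligned


def _events(onsets, condition="L", duration=5.0):
    import pandas as pd

    return EventTable(
        pd.DataFrame(
            {"condition": condition, "onset_s": onsets, "duration_s": duration}
        )
    )


class TestAlignment:
    def test_boundary_spikes_follow_half_open_convention(self):
        unit = Unit("u", [8.6, 10.0, 10.5, 11.99, 12.0])
        al = align_spikes(unit, _events([10.0]), "L")
        # spike at onset: excluded from baseline and in the delay gap
        assert 0.0 not in al.baseline[0]
        # spike at onset+0.5 opens the response window; 12.0 is past its end
        np.testing.assert_allclose(al.response[0], [0.5, 1.99])
        np.testing.assert_allclose(al.baseline[0], [-1.4])

    def test_silent_unit_gives_empty_trials(self):
        unit = Unit("u", [])
        al = align_spikes(unit, _events(np.arange(40) * 100.0), "L")
        assert al.n_trials == 40
        assert all(t.size == 0 for t in al.response)

    def test_missing_condition_raises(self):
        with pytest.raises(ValueError, match="no events"):
            align_spikes(Unit("u", [1.0]), _events([0.0], "M"), "ML")

    def test_every_spike_in_trial_span_assigned_to_one_window(self, rng):
        """Window partition: baseline + gap + response + post covers a trial."""
        win = WindowSpec()
        onset = 50.0
        t = np.sort(rng.uniform(onset - win.baseline_dur_s, onset + 5.0, 400))
        unit = Unit("u", t)
        al = align_spikes(unit, _events([onset]), "L", win)
        n_base = al.baseline[0].size
        n_resp = al.response[0].size
        n_gap = np.sum((t >= onset) & (t < onset + win.response_start))
        n_post = np.sum(t >= onset + win.response_end)
        assert n_base + n_gap + n_resp + n_post == t.size


class TestRates:
    def test_mean_rate_is_count_over_duration(self):
        al = make_aligned([[0.6, 0.7, 0.8]] * 3)
        assert mean_rate(al, "response") == pytest.approx(2.0)

    def test_all_empty_is_zero(self):
        assert mean_rate(make_aligned([[]] * 5), "response") == 0.0

    def test_zero_trials_raise(self):
        with pytest.raises(ValueError):
            mean_rate(make_aligned([]), "response")

    def test_poisson_rate_recovered_within_3_sigma(self, rng):
        lam = 5.0 * 1.5  # 5 Hz over the 1.5 s window
        counts = rng.poisson(lam, 200)
        trials = [np.sort(rng.uniform(0.5, 2.0, c)) for c in counts]
        r = mean_rate(make_aligned(trials), "response")
        sigma = np.sqrt(lam / 200) / 1.5
        assert abs(r - 5.0) < 3 * sigma


class TestModulationIndex:
    @pytest.mark.parametrize(
        "rs,rb,expected", [(6, 2, 0.5), (0, 2, -1.0), (2, 0, 1.0)]
    )
    def test_formula(self, rs, rb, expected):
        assert modulation_index(rs, rb) == pytest.approx(expected)

    def test_degenerate_undefined(self):
        assert np.isnan(modulation_index(0.0, 0.0))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(-1.0, 2.0)

    @given(
        st.floats(0.001, 100.0), st.floats(0.001, 100.0)
    )
    def test_antisymmetry(self, a, b):
        assert modulation_index(a, b) == pytest.approx(-modulation_index(b, a))


class TestResponseProbability:
    def test_fraction_of_trials_with_spikes(self):
        trials = [[0.7]] * 7 + [[]] * 3
        assert response_probability(make_aligned(trials)) == pytest.approx(0.7)

    def test_all_empty_is_zero(self):
        assert response_probability(make_aligned([[]] * 4)) == 0.0

    def test_matches_poisson_closed_form(self, rng):
        lam = 1.2
        counts = rng.poisson(lam, 500)
        trials = [np.sort(rng.uniform(0.5, 2.0, c)) for c in counts]
        rp = response_probability(make_aligned(trials))
        expected = 1 - np.exp(-lam)
        sigma = np.sqrt(expected * (1 - expected) / 500)
        assert abs(rp - expected) < 3 * sigma

    def test_monotone_in_rate(self, rng):
        rps = []
        for rate in (1.0, 3.0, 8.0):
            counts = rng.poisson(rate * 1.5, 400)
            rps.append(
                response_probability(
                    make_aligned([np.full(c, 0.7) for c in counts])
                )
            )
        assert rps[0] < rps[1] < rps[2]


def brute_force_burst_parser(times_s, cutoff_ms=5.0):
    """Independent reference: explicit scan merging sub-cutoff ISIs."""
    events = []
    current = []
    for i, t in enumerate(times_s):
        if current and (t - times_s[current[-1]]) * 1000.0 < cutoff_ms:
            current.append(i)
        else:
            if current:
                events.append(("burst" if len(current) > 1 else "single", current))
            current = [i]
    if current:
        events.append(("burst" if len(current) > 1 else "single", current))
    return events


class TestBurstParsing:
    def test_hand_enumerated_events(self):
        times = np.array([0, 2, 4, 104, 107, 307]) / 1000.0
        events = parse_burst_events(times)
        kinds = [k for k, _ in events]
        sizes = [g.size for _, g in events]
        assert kinds == ["burst", "burst", "single"]
        assert sizes == [3, 2, 1]

    def test_single_spike_and_all_bursting(self):
        assert [k for k, _ in parse_burst_events(np.array([0.5]))] == ["single"]
        dense = np.arange(6) * 0.001
        assert [k for k, _ in parse_burst_events(dense)] == ["burst"]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            parse_burst_events(np.array([0.2, 0.1]))

    def test_matches_reference_parser_on_random_trains(self, rng):
        for _ in range(100):
            n = rng.integers(0, 30)
            t = np.sort(rng.uniform(0, 0.2, n))
            got = [(k, list(g)) for k, g in parse_burst_events(t)]
            assert got == brute_force_burst_parser(t)


class TestBurstProbability:
    def test_hand_enumerated_bp(self):
        trial = (np.array([0, 2, 4, 104, 107, 307]) / 1000.0) + 0.6
        assert burst_probability(make_aligned([trial])) == pytest.approx(2 / 3)

    def test_tonic_poisson_has_low_bp(self, rng):
        trials = [np.sort(rng.uniform(0.5, 2.0, rng.poisson(7.5))) for _ in range(500)]
        assert burst_probability(make_aligned(trials)) < 0.05

    def test_planted_burst_probability_recovered(self, rng):
        # events at 5 Hz; half expand into 2.5 ms-ISI bursts
        trials = []
        for _ in range(500):
            ev = np.sort(rng.uniform(0.5, 2.0, rng.poisson(7.5)))
            extra = ev[rng.uniform(size=ev.size) < 0.5] + 0.0025
            trials.append(np.sort(np.concatenate([ev, extra])))
        assert burst_probability(make_aligned(trials)) == pytest.approx(0.5, abs=0.05)

    def test_no_events_is_nan(self):
        assert np.isnan(burst_probability(make_aligned([[]] * 3)))

    def test_unit_ranking_stable_between_cutoffs(self, rng):
        """BP ranking preserved when the cutoff moves from 5 to 10 ms."""
        bp5, bp10 = [], []
        for bp in np.linspace(0.0, 0.6, 30):
            trials = []
            for _ in range(60):
                ev = np.sort(rng.uniform(0.5, 2.0, rng.poisson(9)))
                extra = ev[rng.uniform(size=ev.size) < bp] + 0.0025
                trials.append(np.sort(np.concatenate([ev, extra])))
            al = make_aligned(trials)
            bp5.append(burst_probability(al, 5.0))
            bp10.append(burst_probability(al, 10.0))
        rho = spearmanr(bp5, bp10).statistic
        assert rho >= 0.9


class TestBurstRegime:
    @pytest.mark.parametrize("bp,label", [(0.11, "bursty"), (0.1, "tonic"), (0.0, "tonic")])
    def test_strict_threshold(self, bp, label):
        assert classify_burst_regime(bp) == label

    def test_undefined_bp_raises(self):
        with pytest.raises(ValueError):
            classify_burst_regime(float("nan"))


class TestIsiCdf:
    def test_constant_isi_step(self):
        trial = 0.6 + np.arange(5) * 0.01
        cdf = isi_cdf(make_aligned([trial]))
        assert cdf[8] == 0.0  # 9 ms bin
        assert cdf[9] == 1.0  # 10 ms bin

    def test_median_of_identical_units_is_either(self):
        trial = 0.6 + np.arange(5) * 0.01
        c = isi_cdf(make_aligned([trial]))
        np.testing.assert_array_equal(population_median_cdf([c, c.copy()]), c)

    def test_exponential_isis_within_dkw_band(self, rng):
        lam = 50.0  # 1/s => mean ISI 20 ms
        n = 10_000
        isis = rng.exponential(1 / lam, n)
        times = 0.5 + np.cumsum(isis)
        cdf = isi_cdf(make_aligned([times], window=WindowSpec(0.5, 1e9, 1.5)))
        edges_s = np.arange(1, 501) / 1000.0
        theory = 1 - np.exp(-lam * edges_s)
        eps = np.sqrt(np.log(2 / 0.001) / (2 * n))  # DKW at alpha=0.001
        assert np.max(np.abs(cdf - theory)) < eps

    def test_unit_without_isis_is_excluded(self):
        assert isi_cdf(make_aligned([[0.7]])) is None
        with pytest.raises(ValueError):
            population_median_cdf([None])


class TestPressureDerivative:
    def test_constant_trace_gives_zeros(self):
        np.testing.assert_allclose(pressure_derivative(np.full(10, 3.0)), 0.0)

    def test_linear_ramp_gives_slope(self):
        d = pressure_derivative(np.arange(10) * 2.5, dt_s=0.5)
        np.testing.assert_allclose(d, 5.0)

    def test_sine_derivative_is_cosine_within_dt_squared(self):
        dt = 0.001
        t = np.arange(0, 1, dt)
        d = pressure_derivative(np.sin(2 * np.pi * t), dt_s=dt)
        interior = slice(1, -1)
        err = np.abs(d[interior] - 2 * np.pi * np.cos(2 * np.pi * t)[interior])
        assert err.max() < (2 * np.pi) ** 3 * dt**2  # Taylor bound

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            pressure_derivative(np.array([1.0]))
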
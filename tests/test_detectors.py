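"""Unit tests for the periodogram and the three rhythm detectors."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import circasense as cs
from circasense.detectors import _jtk_machine


def dft_oracle(x):
    """Brute-force DFT intensities |X_k|^2 / n for k = 0..n-1."""
    n = len(x)
    out = []
    for k in range(n):
        re = sum(x[t] * math.cos(-2 * math.pi * k * t / n) for t in range(n))
        im = sum(x[t] * math.sin(-2 * math.pi * k * t / n) for t in range(n))
        out.append((re * re + im * im) / n)
    return np.array(out)


class TestPeriodogram:
    def test_pure_cosine_peaks_at_its_period(self, design):
        y = np.cos(2 * np.pi * design.times / 24.0)
        spec = cs.periodogram(y, 4.0)
        periods = [p for p, _ in spec]
        assert periods == pytest.approx([48.0, 24.0, 16.0, 12.0, 9.6])
        assert max(spec, key=lambda pi: pi[1])[0] == 24.0

    def test_constant_series_has_zero_spectrum(self):
        spec = cs.periodogram(np.full(12, 3.3), 4.0)
        assert all(i == pytest.approx(0.0, abs=1e-20) for _, i in spec)

    @given(seed=st.integers(0, 5_000))
    def test_matches_dft_oracle_and_parseval(self, seed):
        x = np.random.default_rng(seed).normal(size=12)
        xc = x - x.mean()
        oracle = dft_oracle(xc)
        spec = cs.periodogram(x, 4.0)
        for k, (_, intensity) in enumerate(spec, start=1):
            assert intensity == pytest.approx(oracle[k], abs=1e-9)
        # Parseval: retained ordinates plus the Nyquist term account for n/2 * variance
        total = sum(i for _, i in spec) + oracle[6] / 2.0
        assert total == pytest.approx(12.0 / 2.0 * xc.var(), abs=1e-9)


class TestFisherG:
    def test_single_pure_tone_gives_vanishing_p(self, design):
        y = np.cos(2 * np.pi * design.times / 24.0)
        res = cs.fisher_g_test(y, 4.0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 1e-12
        assert res.period_h == 24.0

    def test_constant_series_not_analyzable(self):
        assert cs.fisher_g_test(np.zeros(12), 4.0).status == "zero_variance"

    def test_closed_form_matches_gaussian_monte_carlo_oracle(self, rng):
        # direct oracle: tail frequencies of G over white-noise draws
        from circasense.detectors import _fisher_batch

        g, _, _ = _fisher_batch(rng.normal(size=(50_000, 12)), 4.0)
        for gq in (0.4, 0.5, 0.6, 0.7):
            emp = float(np.mean(g >= gq))
            se = np.sqrt(emp * (1 - emp) / len(g))
            assert abs(emp - cs.fisher_g_p_value(gq, 5)) <= 4 * se

    def test_null_rejection_rate_close_to_alpha(self, rng):
        X = rng.normal(size=(500, 12))
        ps = np.array([cs.fisher_g_test(x, 4.0).p_value for x in X])
        assert 0.02 <= np.mean(ps < 0.05) <= 0.09


class TestJTKReferences:
    def test_lattice_periods_and_phase_counts(self, design, band):
        refs = cs.jtk_reference_set(design, band, phase_step_h=4.0)
        assert sorted({r.period_h for r in refs}) == [20.0, 24.0, 28.0]
        assert sum(r.period_h == 24.0 for r in refs) == 6
        assert sum(r.period_h == 20.0 for r in refs) == 5
        assert sum(r.period_h == 28.0 for r in refs) == 7

    def test_half_period_shift_reverses_ranks(self, design, band):
        refs = {
            (r.period_h, r.phase_h): np.asarray(r.ranks)
            for r in cs.jtk_reference_set(design, band, 4.0)
        }
        r0, r12 = refs[(24.0, 0.0)], refs[(24.0, 12.0)]
        assert np.allclose(r12, len(r0) + 1 - r0)


class TestKendallExact:
    def test_perfect_concordance_tiefree(self):
        ref = np.arange(1, 7, dtype=float)
        tau, p = cs.kendall_tau_exact_p(np.arange(6, dtype=float), ref)
        assert tau == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 720.0)

    def test_perfect_reversal_has_tail_one(self):
        ref = np.arange(1, 7, dtype=float)
        tau, p = cs.kendall_tau_exact_p(np.arange(6, 0, -1, dtype=float), ref)
        assert tau == pytest.approx(-1.0)
        assert p == pytest.approx(1.0)

    def test_null_matches_enumeration_with_tied_reference(self):
        ref = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])
        i, j = np.triu_indices(6, k=1)
        rsign = np.sign(ref[j] - ref[i])
        p_pairs = int(np.count_nonzero(rsign))
        s_values = [
            int(np.sum(np.sign(np.array(perm)[j] - np.array(perm)[i]) * rsign))
            for perm in itertools.permutations(range(6))
        ]
        enum_counts = np.bincount([(s + p_pairs) // 2 for s in s_values])
        counts, total = cs.jtk_null_distribution((1, 1, 1, 1, 2))
        # enumeration over 720 orderings = exact counts x within-tie-group orderings
        assert list(enum_counts) == [c * math.factorial(2) for c in counts]
        # and the reported tail probability agrees with the enumeration tail
        for perm in itertools.islice(itertools.permutations(range(6)), 0, 720, 71):
            x = np.array(perm, dtype=float)
            _, p = cs.kendall_tau_exact_p(x, ref)
            s_obs = int(np.sum(np.sign(x[j] - x[i]) * rsign))
            assert p == pytest.approx(np.mean([s >= s_obs for s in s_values]), abs=1e-12)


class TestJTKCycle:
    def test_recovers_planted_phase_and_period(self, design):
        y = np.cos(2 * np.pi * (design.times - 12.0) / 24.0)
        res = cs.jtk_cycle(y, design)
        assert (res.period_h, res.phase_h) == (24.0, 12.0)

    def test_negated_series_lands_in_antiphase(self, design):
        y = -np.cos(2 * np.pi * (design.times - 12.0) / 24.0)
        assert cs.jtk_cycle(y, design).phase_h == 0.0

    def test_bonferroni_family_counts_antiphase_once(self, design, band):
        machine = _jtk_machine(design, band, 4.0)
        assert len(machine.refs) == 18
        assert machine.family_size == 15  # period 24 contributes 3 reversal pairs

    def test_constant_series_not_analyzable(self, design):
        assert cs.jtk_cycle(np.ones(12), design).status == "zero_variance"


class TestCosopt:
    @pytest.mark.parametrize("period", [20.0, 22.0, 24.0, 26.0, 28.0])
    def test_noiseless_period_recovery_within_grid_step(self, design, period):
        y = np.cos(2 * np.pi * (design.times - 3.0) / period)
        res = cs.cosopt(y, design, n_surrogates=99, seed=0)
        assert abs(res.period_h - period) <= 0.2 + 1e-9

    def test_perfect_fit_gets_minimal_permutation_p(self, design):
        y = np.cos(2 * np.pi * design.times / 24.0)
        res = cs.cosopt(y, design, n_surrogates=199, seed=5)
        assert res.p_value == pytest.approx(1.0 / 200.0)
        assert res.statistic == pytest.approx(1.0)
        assert res.amplitude == pytest.approx(1.0)
        assert res.phase_h == pytest.approx(0.0, abs=1e-6)

    def test_surrogate_floor_enforced(self, design):
        with pytest.raises(cs.ConfigurationError):
            cs.cosopt(np.random.default_rng(0).normal(size=12), design, n_surrogates=10)


class TestInvariances:
    @given(seed=st.integers(0, 2_000), shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_shift_invariance_and_positive_scaling(self, design, seed, shift, scale):
        x = np.random.default_rng(seed).normal(size=12)
        f0 = cs.fisher_g_test(x, 4.0)
        f1 = cs.fisher_g_test(scale * x + shift, 4.0)
        assert f1.p_value == pytest.approx(f0.p_value, rel=1e-9)
        j0 = cs.jtk_cycle(x, design)
        j1 = cs.jtk_cycle(scale * x + shift, design)
        assert j1.p_value == pytest.approx(j0.p_value, rel=1e-9)
        assert 0 <= f0.p_value <= 1 and 0 <= j0.p_value <= 1

    def test_cosopt_shift_invariance(self, design):
        x = np.random.default_rng(7).normal(size=12)
        r0 = cs.cosopt(x, design, n_surrogates=99, seed=3)
        r1 = cs.cosopt(x + 11.0, design, n_surrogates=99, seed=3)
        assert r1.p_value == r0.p_value and r1.statistic == pytest.approx(r0.statistic)


class TestRunAllDetectors:
    def _prepared(self, seed=5, n_sense=4, n_antisense=2):
        study = cs.simulate_dataset(
            cs.SimulationConfig(
                seed=seed, n_sense=n_sense, n_antisense=n_antisense,
                expressed_fraction_sense=1.0, expressed_fraction_antisense=1.0,
            )
        )
        prep, _ = cs.prepare_dataset(study.dataset)
        return prep

    def test_three_rows_per_probe(self):
        prep = self._prepared()
        res = cs.run_all_detectors(prep, settings=cs.DetectorSettings(n_surrogates=99))
        assert len(res) == 3 * len(prep)
        assert set(res["method"]) == {"cosopt", "jtk", "fisher_g"}

    def test_deterministic_and_order_independent(self):
        prep = self._prepared()
        settings = cs.DetectorSettings(seed=9, n_surrogates=99)
        a = cs.run_all_detectors(prep, settings=settings)
        b = cs.run_all_detectors(prep, settings=settings)
        assert a.equals(b)
        shuffled = prep.subset(list(reversed(prep.timecourses)))
        c = cs.run_all_detectors(shuffled, settings=settings)
        key = ["probe_id", "direction", "method"]
        a_sorted = a.sort_values(key).reset_index(drop=True)
        c_sorted = c.sort_values(key).reset_index(drop=True)
        assert a_sorted.equals(c_sorted)

    def test_not_analyzable_probe_gets_marker_rows(self, design):
        flat = cs.ProbeTimeCourse(
            "pflat", "sflat", "sense",
            np.zeros((2, 12)), np.ones((2, 12), dtype=bool),
        )
        live = cs.ProbeTimeCourse(
            "plive", "slive", "sense",
            np.random.default_rng(1).normal(size=(2, 12)), np.ones((2, 12), dtype=bool),
        )
        ds = cs.ExpressionDataset(design, timecourses=[flat, live])
        prep, _ = cs.prepare_dataset(ds)
        res = cs.run_all_detectors(prep, settings=cs.DetectorSettings(n_surrogates=99))
        flat_rows = res[res["probe_id"] == "pflat"]
        assert len(flat_rows) == 3
        assert (flat_rows["status"] == "zero_variance").all()
        assert flat_rows["p_value"].isna().all()
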
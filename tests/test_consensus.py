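"""Consensus calling, phase binning, summaries and Venn set identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import circasense as cs
from circasense.consensus import PHASE_BIN_LABELS, VENN_REGIONS
from circasense.errors import IntegrityError
from circasense.timecourse_io import DirectionSummary


def results_frame(rows):
    """Detector-table rows: (probe, method, p, period, phase, status)."""
    return pd.DataFrame(
        [
            {
                "probe_id": probe, "direction": "sense", "method": method,
                "p_value": p, "statistic": 0.5, "period_h": period,
                "phase_h": phase, "amplitude": np.nan, "status": status,
            }
            for probe, method, p, period, phase, status in rows
        ]
    )


def simple_probe(p_cos, p_jtk, p_fis, probe="p1", period=24.0, fisher_period=24.0):
    return results_frame(
        [
            (probe, "cosopt", p_cos, period, 6.0, "ok"),
            (probe, "jtk", p_jtk, period, 8.0, "ok"),
            (probe, "fisher_g", p_fis, fisher_period, np.nan, "ok"),
        ]
    )


class TestConsensusCall:
    @pytest.mark.parametrize(
        "pvals,expected",
        [((0.04, 0.04, 0.20), True), ((0.04, 0.20, 0.20), False), ((0.04, 0.04, 0.04), True)],
    )
    def test_two_of_three_rule(self, pvals, expected):
        calls = cs.consensus_call(simple_probe(*pvals))
        assert bool(calls.iloc[0]["circadian"]) is expected
        if pvals == (0.04, 0.04, 0.04):
            assert calls.iloc[0]["n_methods"] == 3

    def test_out_of_band_period_does_not_count(self):
        # fisher significant but peaking at 48 h: not a circadian vote
        calls = cs.consensus_call(simple_probe(0.04, 0.2, 0.001, fisher_period=48.0))
        assert not calls.iloc[0]["circadian"]
        assert not calls.iloc[0]["rhythmic_fisher"]

    def test_period_and_phase_copied_even_when_subthreshold(self):
        calls = cs.consensus_call(simple_probe(0.50, 0.01, 0.01, period=26.0))
        row = calls.iloc[0]
        assert row["circadian"] and row["period_h"] == 26.0 and row["phase_h"] == 8.0

    def test_not_analyzable_method_counts_as_nonrhythmic(self):
        res = results_frame(
            [
                ("p1", "cosopt", 0.01, 24.0, 6.0, "ok"),
                ("p1", "jtk", 0.01, 24.0, 8.0, "ok"),
                ("p1", "fisher_g", np.nan, np.nan, np.nan, "zero_variance"),
            ]
        )
        row = cs.consensus_call(res).iloc[0]
        assert row["circadian"] and not row["rhythmic_fisher"]
        assert np.isnan(row["p_fisher"])

    def test_duplicate_rows_rejected(self):
        res = pd.concat([simple_probe(0.01, 0.01, 0.01)] * 2, ignore_index=True)
        with pytest.raises(IntegrityError):
            cs.consensus_call(res)

    @given(alpha1=st.floats(0.001, 0.2), alpha2=st.floats(0.001, 0.2), seed=st.integers(0, 500))
    def test_circadian_count_monotone_in_alpha(self, alpha1, alpha2, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(12):
            for method in ("cosopt", "jtk", "fisher_g"):
                rows.append((f"p{i}", method, rng.uniform(0, 0.25), 24.0, 6.0, "ok"))
        res = results_frame(rows)
        lo, hi = sorted((alpha1, alpha2))
        n_lo = cs.consensus_call(res, alpha=lo)["circadian"].sum()
        n_hi = cs.consensus_call(res, alpha=hi)["circadian"].sum()
        assert n_lo <= n_hi


class TestBinPhase:
    @pytest.mark.parametrize(
        "phase,label", [(12.0, "ZT12"), (23.1, "ZT0"), (2.0, "ZT4"), (0.0, "ZT0"), (21.9, "ZT20")]
    )
    def test_examples_and_boundary_rule(self, phase, label):
        assert cs.bin_phase(phase) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bin_phase(24.0)

    @given(phase=st.floats(0, 24, exclude_max=True))
    def test_every_phase_gets_exactly_one_nearby_bin(self, phase):
        label = cs.bin_phase(phase)
        center = float(label[2:])
        assert label in PHASE_BIN_LABELS
        assert cs.circ_distance(phase, center) <= 2.0 + 1e-9


class TestSummaries:
    def test_percentages_and_bin_histogram(self):
        calls = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(4)],
                "direction": ["sense"] * 3 + ["antisense"],
                "circadian": [True, True, False, False],
                "rhythmic_cosopt": [True, True, False, False],
                "rhythmic_jtk": [True, False, False, False],
                "rhythmic_fisher": [True, True, True, False],
                "period_h": [24.0, 26.0, np.nan, np.nan],
                "phase_h": [12.0, 4.0, np.nan, np.nan],
                "phase_bin": ["ZT12", "ZT4", None, None],
            }
        )
        fs = cs.FilterSummary(
            sense=DirectionSummary("sense", 5, 4, 3),
            antisense=DirectionSummary("antisense", 3, 1, 1),
        )
        summary = cs.summarize_rhythmicity(calls, fs)
        s = summary["sense"]
        assert (s.n_circadian, s.pct_circadian) == (2, 66.7)
        assert s.per_method_counts == {"cosopt": 2, "jtk": 1, "fisher_g": 3}
        assert s.per_method_pct["fisher_g"] == 100.0
        assert s.period_mean_h == pytest.approx(25.0)
        assert s.phase_bin_fractions["ZT12"] == 0.5
        assert sum(s.phase_bin_fractions.values()) == pytest.approx(1.0)
        frame = cs.summary_to_frame(summary)
        assert set(frame["direction"]) == {"sense", "antisense"}


class TestVenn:
    def _random_results(self, seed, n=40):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            for method in ("cosopt", "jtk", "fisher_g"):
                rows.append((f"p{i}", method, rng.uniform(0, 0.15), 24.0, 6.0, "ok"))
        return results_frame(rows)

    def test_identical_sets_fill_only_triple_region(self):
        rows = []
        for i in range(5):
            for method in ("cosopt", "jtk", "fisher_g"):
                rows.append((f"p{i}", method, 0.01, 24.0, 6.0, "ok"))
        counts = cs.venn_counts(results_frame(rows))["sense"]
        assert counts["all_three"] == 5
        assert sum(counts[r] for r in VENN_REGIONS if r != "all_three") == 0

    def test_disjoint_sets_fill_only_singletons(self):
        rows = []
        for i, method in enumerate(("cosopt", "jtk", "fisher_g")):
            for j, m2 in enumerate(("cosopt", "jtk", "fisher_g")):
                rows.append((f"p{i}", m2, 0.01 if m2 == method else 0.9, 24.0, 6.0, "ok"))
        counts = cs.venn_counts(results_frame(rows))["sense"]
        assert (counts["cosopt_only"], counts["jtk_only"], counts["fisher_only"]) == (1, 1, 1)
        assert counts["all_three"] == 0

    @given(seed=st.integers(0, 1_000))
    def test_inclusion_exclusion_and_consensus_identity(self, seed):
        res = self._random_results(seed)
        counts = cs.venn_counts(res)["sense"]
        calls = cs.consensus_call(res)
        # brute-force set algebra oracle
        sets = {
            m: set(calls[calls[col]]["probe_id"])
            for m, col in [
                ("cosopt", "rhythmic_cosopt"), ("jtk", "rhythmic_jtk"), ("fisher", "rhythmic_fisher"),
            ]
        }
        assert counts["cosopt_only"] + counts["cosopt_jtk"] + counts["cosopt_fisher"] + counts[
            "all_three"
        ] == len(sets["cosopt"])
        assert counts["jtk_only"] + counts["cosopt_jtk"] + counts["jtk_fisher"] + counts[
            "all_three"
        ] == len(sets["jtk"])
        assert counts["fisher_only"] + counts["cosopt_fisher"] + counts["jtk_fisher"] + counts[
            "all_three"
        ] == len(sets["fisher"])
        n_consensus = counts["cosopt_jtk"] + counts["cosopt_fisher"] + counts["jtk_fisher"] + counts["all_three"]
        assert n_consensus == int(calls["circadian"].sum())
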
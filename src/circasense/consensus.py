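"""Consensus circadian calls from the three detectors, with summaries.

A detector counts a probe rhythmic when its p-value is below alpha *and*
its reported period (when it reports one) lies inside the circadian band.
A probe is circadian when at least ``min_methods`` (default 2 of 3)
detectors agree.  The consensus period comes from COSOPT and the phase from
JTK, reported even when that single method was sub-threshold; phases of
circadian probes are binned into six 4-h groups centred on
ZT0, ZT4, ..., ZT20 (a phase on a bin boundary goes to the later bin).

Raw per-probe p-values at alpha are used without a cross-probe correction,
matching the source convention; pass the rhythm-call frame through an FDR
step yourself if you want one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DIRECTIONS
from .detectors import METHODS, PeriodBand
from .errors import IntegrityError
from .timecourse_io import FilterSummary
from .utils import percentage, round_half_up

PHASE_BIN_CENTERS = (0, 4, 8, 12, 16, 20)
PHASE_BIN_LABELS = tuple(f"ZT{c}" for c in PHASE_BIN_CENTERS)


def bin_phase(phase_h: float) -> str:
    """Assign a ZT phase to the nearest of six 4 h bins (boundary -> later bin)."""
    if not (0.0 <= phase_h < 24.0):
        raise ValueError(f"phase_h must lie in [0, 24), got {phase_h}")
    idx = int(((phase_h + 2.0) % 24.0) // 4.0)
    return PHASE_BIN_LABELS[idx]


def consensus_call(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_methods: int = 2,
    band: PeriodBand = PeriodBand(),
) -> pd.DataFrame:
    """Combine detector rows into one rhythm call per (probe, direction).

    Output columns: probe_id, direction, p_cosopt, p_jtk, p_fisher,
    rhythmic_cosopt/jtk/fisher, n_methods, circadian, period_h (COSOPT),
    phase_h (JTK), phase_bin.
    """
    if results.duplicated(["probe_id", "direction", "method"]).any():
        dupes = results[results.duplicated(["probe_id", "direction", "method"])]
        raise IntegrityError(
            f"duplicate detector rows, e.g. {dupes.iloc[0][['probe_id', 'direction', 'method']].tolist()}"
        )
    calls = []
    for (probe_id, direction), grp in results.groupby(["probe_id", "direction"], sort=False):
        by_method = {row["method"]: row for _, row in grp.iterrows()}
        rhythmic = {}
        pvals = {}
        for method in METHODS:
            row = by_method.get(method)
            if row is None or row["status"] != "ok" or not np.isfinite(row["p_value"]):
                rhythmic[method] = False
                pvals[method] = np.nan
                continue
            pvals[method] = float(row["p_value"])
            in_band = (
                bool(band.contains(row["period_h"]))
                if np.isfinite(row.get("period_h", np.nan))
                else True
            )
            rhythmic[method] = (pvals[method] < alpha) and in_band
        n_methods = sum(rhythmic.values())
        circadian = n_methods >= min_methods

        cos_row = by_method.get("cosopt")
        jtk_row = by_method.get("jtk")
        period = (
            float(cos_row["period_h"])
            if cos_row is not None and cos_row["status"] == "ok"
            else np.nan
        )
        phase = (
            float(jtk_row["phase_h"])
            if jtk_row is not None and jtk_row["status"] == "ok"
            else np.nan
        )
        phase_bin = bin_phase(phase) if circadian and np.isfinite(phase) else None
        calls.append(
            {
                "probe_id": probe_id,
                "direction": direction,
                "p_cosopt": pvals["cosopt"],
                "p_jtk": pvals["jtk"],
                "p_fisher": pvals["fisher_g"],
                "rhythmic_cosopt": rhythmic["cosopt"],
                "rhythmic_jtk": rhythmic["jtk"],
                "rhythmic_fisher": rhythmic["fisher_g"],
                "n_methods": n_methods,
                "circadian": circadian,
                "period_h": period,
                "phase_h": phase,
                "phase_bin": phase_bin,
            }
        )
    return pd.DataFrame(calls)


@dataclass(frozen=True)
class DirectionRhythmSummary:
    """Counts-table row for one direction (layout of the printed summary)."""

    direction: str
    n_probes: int
    n_expressed: int
    pct_expressed: float
    n_circadian: int
    pct_circadian: float  # of expressed probes
    per_method_counts: dict
    per_method_pct: dict
    period_mean_h: float
    period_sd_h: float
    phase_bin_fractions: dict


def summarize_rhythmicity(
    calls: pd.DataFrame, filter_summary: FilterSummary
) -> dict[str, DirectionRhythmSummary]:
    """Per-direction rhythmicity summary with half-up 1-decimal percentages.

    Circadian percentages are relative to probes passing the expression
    filter; period mean/sd and the phase-bin histogram cover circadian
    probes only.
    """
    out = {}
    for direction in DIRECTIONS:
        fs = filter_summary.for_direction(direction)
        sub = calls[calls["direction"] == direction]
        n_circ = int(sub["circadian"].sum())
        method_cols = {
            "cosopt": "rhythmic_cosopt",
            "jtk": "rhythmic_jtk",
            "fisher_g": "rhythmic_fisher",
        }
        counts = {m: int(sub[c].sum()) for m, c in method_cols.items()}
        pcts = {m: percentage(counts[m], fs.n_expressed_filter) for m in counts}
        circ = sub[sub["circadian"]]
        periods = circ["period_h"].dropna()
        bins = {label: 0 for label in PHASE_BIN_LABELS}
        for label in circ["phase_bin"].dropna():
            bins[label] += 1
        total_binned = sum(bins.values())
        bin_fracs = {
            label: (bins[label] / total_binned if total_binned else 0.0) for label in bins
        }
        out[direction] = DirectionRhythmSummary(
            direction=direction,
            n_probes=fs.n_probes,
            n_expressed=fs.n_expressed_filter,
            pct_expressed=fs.pct_expressed_filter,
            n_circadian=n_circ,
            pct_circadian=percentage(n_circ, fs.n_expressed_filter),
            per_method_counts=counts,
            per_method_pct=pcts,
            period_mean_h=round_half_up(float(periods.mean()), 2) if len(periods) else float("nan"),
            period_sd_h=round_half_up(float(periods.std(ddof=1)), 2) if len(periods) > 1 else float("nan"),
            phase_bin_fractions=bin_fracs,
        )
    return out


def summary_to_frame(summary: dict[str, DirectionRhythmSummary]) -> pd.DataFrame:
    rows = []
    for direction, s in summary.items():
        rows.append(
            {
                "direction": direction,
                "n_probes": s.n_probes,
                "n_expressed": s.n_expressed,
                "pct_expressed": s.pct_expressed,
                "n_circadian": s.n_circadian,
                "pct_circadian": s.pct_circadian,
                **{f"n_{m}": s.per_method_counts[m] for m in METHODS},
                **{f"pct_{m}": s.per_method_pct[m] for m in METHODS},
                "period_mean_h": s.period_mean_h,
                "period_sd_h": s.period_sd_h,
            }
        )
    return pd.DataFrame(rows)


VENN_REGIONS = (
    "cosopt_only",
    "jtk_only",
    "fisher_only",
    "cosopt_jtk",
    "cosopt_fisher",
    "jtk_fisher",
    "all_three",
)


def venn_counts(
    results: pd.DataFrame, alpha: float = 0.05, band: PeriodBand = PeriodBand()
) -> dict[str, dict[str, int]]:
    """Counts of the 7 intersection regions of the per-method rhythmic sets,
    per direction."""
    calls = consensus_call(results, alpha=alpha, min_methods=2, band=band)
    out = {}
    for direction in DIRECTIONS:
        sub = calls[calls["direction"] == direction]
        c = sub["rhythmic_cosopt"].to_numpy()
        j = sub["rhythmic_jtk"].to_numpy()
        f = sub["rhythmic_fisher"].to_numpy()
        out[direction] = {
            "cosopt_only": int((c & ~j & ~f).sum()),
            "jtk_only": int((~c & j & ~f).sum()),
            "fisher_only": int((~c & ~j & f).sum()),
            "cosopt_jtk": int((c & j & ~f).sum()),
            "cosopt_fisher": int((c & ~j & f).sum()),
            "jtk_fisher": int((~c & j & f).sum()),
            "all_three": int((c & j & f).sum()),
        }
    return out
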
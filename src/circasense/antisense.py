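"""Sense/antisense (SS/AS) pair correlation analysis.

Natural antisense transcripts can be co-regulated with their sense cognate,
regulated in antiphase, or controlled independently.  For every gene model
with both directions retained after the expression filter, Spearman's rank
correlation (rho) between the merged SS and AS time courses classifies the
pair: rho strictly above the threshold (0.56 by default, the fixed critical
bound used for 12-point series) is a significant positive correlation,
strictly below -threshold a negative one, anything else uncorrelated.
|rho| exactly at the threshold is uncorrelated.

When both members are circadian, the circular lag between their JTK phases
is reported (unsigned, in [0, 12] h; an antiphase pair sits near 12 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .circular import circ_distance
from .dataset import ExpressionDataset

DEFAULT_RHO_THRESHOLD = 0.56

CLASSIFICATIONS = ("positive", "negative", "uncorrelated")


def spearman_rho(x, y) -> float:
    """Spearman's rho with average ranks for ties.

    Raises ValueError on length mismatch or fewer than 3 points; returns
    NaN for a zero-variance vector (not-analyzable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(spearmanr(x, y).statistic)


def classify_pair(rho: float, threshold: float = DEFAULT_RHO_THRESHOLD) -> str:
    """positive iff rho > threshold, negative iff rho < -threshold, else uncorrelated."""
    if not (-1.0 - 1e-12 <= rho <= 1.0 + 1e-12):
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    if rho > threshold:
        return "positive"
    if rho < -threshold:
        return "negative"
    return "uncorrelated"


@dataclass(frozen=True)
class PairSummary:
    """Classification fractions over all pairs and the either-circadian subset."""

    n_pairs: int
    fractions: dict
    n_either_circadian: int
    fractions_either_circadian: dict
    rho_histogram: pd.DataFrame = field(repr=False)


def pair_analysis(
    ds: ExpressionDataset,
    calls: pd.DataFrame,
    threshold: float = DEFAULT_RHO_THRESHOLD,
) -> tuple[pd.DataFrame, PairSummary]:
    """Correlate and classify every SS/AS pair present in a filtered dataset.

    Pairs are gene models (sas_id) with both directions retained.  Returns
    a per-pair frame (sas_id, rho, n_points, classification,
    either_circadian, phase_lag_h) and a summary with classification
    fractions over all pairs and over the subset where at least one member
    is circadian, plus a rho histogram at bin width 0.1 over [-1, 1].
    """
    sense = {tc.sas_id: tc for tc in ds.by_direction("sense")}
    anti = {tc.sas_id: tc for tc in ds.by_direction("antisense")}
    shared = sorted(set(sense) & set(anti))

    call_idx = {}
    for _, row in calls.iterrows():
        call_idx[(row["probe_id"], row["direction"])] = row

    rows = []
    for sas_id in shared:
        ss, as_ = sense[sas_id], anti[sas_id]
        rho = spearman_rho(ss.values, as_.values)
        ss_call = call_idx.get((ss.probe_id, "sense"))
        as_call = call_idx.get((as_.probe_id, "antisense"))
        ss_circ = bool(ss_call["circadian"]) if ss_call is not None else False
        as_circ = bool(as_call["circadian"]) if as_call is not None else False
        lag = np.nan
        if ss_circ and as_circ:
            ph_s, ph_a = float(ss_call["phase_h"]), float(as_call["phase_h"])
            if np.isfinite(ph_s) and np.isfinite(ph_a):
                lag = float(circ_distance(ph_a, ph_s))
        rows.append(
            {
                "sas_id": sas_id,
                "rho": rho,
                "n_points": int(len(ss.values)),
                "classification": classify_pair(rho, threshold) if np.isfinite(rho) else "not_analyzable",
                "either_circadian": ss_circ or as_circ,
                "phase_lag_h": lag,
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=["sas_id", "rho", "n_points", "classification", "either_circadian", "phase_lag_h"],
    )

    def fractions(frame: pd.DataFrame) -> dict:
        n = len(frame)
        return {
            c: (float((frame["classification"] == c).sum()) / n if n else 0.0)
            for c in CLASSIFICATIONS
        }

    either = pairs[pairs["either_circadian"]] if len(pairs) else pairs
    edges = np.round(np.arange(-1.0, 1.0 + 0.05, 0.1), 10)
    counts, _ = np.histogram(pairs["rho"].dropna(), bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    summary = PairSummary(
        n_pairs=len(pairs),
        fractions=fractions(pairs),
        n_either_circadian=len(either),
        fractions_either_circadian=fractions(either),
        rho_histogram=hist,
    )
    return pairs, summary
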
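"""Functional-category phase summaries and hypergeometric term enrichment.

Each probe carries one of ~30 functional categories.  Two views are
provided:

* phase summaries — for each category, the circular median +/- MAD of the
  JTK phases of its circadian probes (MAD = median circular distance to the
  median, so half the probes lie within one MAD of the median).  When the
  2 h circular phase histogram of a category splits into two occupied arcs
  separated by empty gaps of at least ``bimodality_gap_h`` on both sides,
  the category is reported as bimodal with a separate median +/- MAD per
  mode (larger mode first).

* term enrichment — upper-tail hypergeometric test of each category's
  frequency in a study set (e.g. circadian probes) against a background
  (e.g. all expressed probes), Bonferroni-corrected over the categories
  tested.  Unannotated probes fall into an "Unknown" category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .circular import circ_distance, circular_mad, circular_median

UNKNOWN_CATEGORY = "Unknown"
DEFAULT_BIMODALITY_GAP_H = 8.0
_HIST_BIN_H = 2.0


def phase_median_mad(phases: Iterable[float]) -> tuple[float, float]:
    """Circular median (0.1 h grid) and circular MAD of a set of ZT phases."""
    phases = np.asarray(list(phases), dtype=float)
    if phases.size == 0:
        raise ValueError("phase_median_mad of an empty list")
    median = circular_median(phases)
    return median, circular_mad(phases, median)


@dataclass(frozen=True)
class CategoryPhaseSummary:
    """Phase summary for one functional category."""

    category: str
    n_rhythmic: int
    n_total: int
    phase_median_h: Optional[float]
    phase_mad_h: Optional[float]
    n_modes: int
    secondary_median_h: Optional[float] = None
    secondary_mad_h: Optional[float] = None


def _split_modes(phases: np.ndarray, gap_h: float) -> list[np.ndarray]:
    """Split phases into occupied arcs of the 2 h circular histogram.

    Returns one array per contiguous occupied arc; a two-arc split counts
    as bimodal only when both separating gaps are >= gap_h.
    """
    n_bins = int(round(24.0 / _HIST_BIN_H))
    bins = (phases // _HIST_BIN_H).astype(int) % n_bins
    occupied = np.zeros(n_bins, dtype=bool)
    occupied[bins] = True
    if occupied.all():
        return [phases]
    # rotate so position 0 is empty, then find contiguous occupied runs
    start = int(np.argmin(occupied))
    order = [(start + k) % n_bins for k in range(n_bins)]
    arcs: list[list[int]] = []
    current: list[int] = []
    for b in order:
        if occupied[b]:
            current.append(b)
        elif current:
            arcs.append(current)
            current = []
    if current:
        arcs.append(current)
    if len(arcs) != 2:
        return [phases]
    # circular gaps between the two arcs, in hours
    empties = n_bins - sum(len(a) for a in arcs)
    gap1_bins = (arcs[1][0] - arcs[0][-1] - 1) % n_bins
    gap2_bins = empties - gap1_bins
    if min(gap1_bins, gap2_bins) * _HIST_BIN_H < gap_h:
        return [phases]
    groups = [phases[np.isin(bins, arc)] for arc in arcs]
    groups.sort(key=lambda g: (-len(g), circular_median(g)))
    return groups


def summarize_categories(
    calls: pd.DataFrame,
    annot: Mapping[str, str],
    bimodality_gap_h: float = DEFAULT_BIMODALITY_GAP_H,
) -> list[CategoryPhaseSummary]:
    """Per-category circadian counts and phase medians (one or two modes).

    ``calls`` is a rhythm-call frame (any direction mix); ``annot`` maps
    probe_id to its single category.  Categories with zero circadian probes
    keep their counts but carry no phase summary.
    """
    categories = sorted(set(annot.values()))
    out = []
    for category in categories:
        members = calls[calls["probe_id"].map(lambda p: annot.get(p) == category)]
        n_total = len(members)
        circ = members[members["circadian"]]
        phases = circ["phase_h"].dropna().to_numpy(dtype=float) % 24.0
        n_rhythmic = int(members["circadian"].sum())
        if phases.size == 0:
            out.append(
                CategoryPhaseSummary(category, n_rhythmic, n_total, None, None, 0)
            )
            continue
        groups = _split_modes(phases, bimodality_gap_h)
        med, mad = phase_median_mad(groups[0])
        if len(groups) == 2:
            med2, mad2 = phase_median_mad(groups[1])
            out.append(
                CategoryPhaseSummary(
                    category, n_rhythmic, n_total, med, mad, 2, med2, mad2
                )
            )
        else:
            out.append(CategoryPhaseSummary(category, n_rhythmic, n_total, med, mad, 1))
    return out


def category_summary_frame(summaries: list[CategoryPhaseSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": s.category,
                "n_rhythmic": s.n_rhythmic,
                "n_total": s.n_total,
                "phase_median_h": s.phase_median_h,
                "phase_mad_h": s.phase_mad_h,
                "n_modes": s.n_modes,
                "secondary_median_h": s.secondary_median_h,
                "secondary_mad_h": s.secondary_mad_h,
            }
            for s in summaries
        ]
    )


def hypergeometric_enrichment(
    study_set: Iterable[str],
    background: Iterable[str],
    annot: Mapping[str, str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of categories in a study set.

    For a category with K background members, k of which are in the study
    set of size n drawn from a background of size N,
    p_raw = P(X >= k), X ~ Hypergeometric(N, K, n); p_bonferroni multiplies
    by the number of categories tested (clipped at 1).  Rows sorted by p_raw.
    """
    study = set(study_set)
    bg = set(background)
    if not study <= bg:
        extra = sorted(study - bg)[:3]
        raise ValueError(f"study set is not contained in background (e.g. {extra})")
    cat_of = {p: annot.get(p, UNKNOWN_CATEGORY) for p in bg}
    categories = sorted(set(cat_of.values()))
    N, n = len(bg), len(study)
    rows = []
    for category in categories:
        members = {p for p, c in cat_of.items() if c == category}
        K = len(members)
        k = len(members & study)
        p_raw = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": category, "k": k, "n": n, "K": K, "N": N, "p_raw": p_raw})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * len(categories))
    return df.sort_values("p_raw", kind="stable").reset_index(drop=True)
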
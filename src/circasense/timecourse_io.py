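"""Reading, writing, expression calling and normalization of time courses.

The on-disk format is a TSV with one row per (probe, direction, replicate):

    probe_id  sas_id  direction  rep  flag_t0..flag_t<T>  value_t0..value_t<T>

where the time suffixes follow the sampling design (t0, t4, ... for 4 h
sampling).  Flags mark time points whose signal was distinguishable from
local background ("expressed"); they are produced upstream (or by the
synthetic generator) and consumed as-is.

The analysis convention mirrors the source study: replicates are merged by
arithmetic mean (majority-expressed flags, ties expressed), probes expressed
in at least 10 of 12 time points are retained, and retained series are
Z-score normalized (population standard deviation) before rhythm detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DIRECTIONS, ExpressionDataset, ProbeTimeCourse, SamplingDesign
from .errors import FormatError, IntegrityError
from .utils import percentage

DEFAULT_MIN_TIMEPOINTS = 10


def _time_labels(design: SamplingDesign) -> list[str]:
    return [f"t{int(round(t))}" for t in design.times - design.start_zt_h]


def _columns(design: SamplingDesign) -> tuple[list[str], list[str]]:
    labels = _time_labels(design)
    return [f"flag_{s}" for s in labels], [f"value_{s}" for s in labels]


def read_expression_table(path, design: SamplingDesign) -> ExpressionDataset:
    """Read an expression TSV into an :class:`ExpressionDataset`.

    Raises :class:`FormatError` for missing columns or non-numeric cells
    (naming the offending cell and line) and :class:`IntegrityError` for
    duplicate (probe_id, direction, rep) rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    flag_cols, value_cols = _columns(design)
    required = ["probe_id", "sas_id", "direction", "rep"] + flag_cols + value_cols
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    seen_rows: set[tuple[str, str, str]] = set()
    groups: dict[tuple[str, str], dict] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after the header
        direction = row["direction"]
        if direction not in DIRECTIONS:
            raise FormatError(
                f"{path} line {line_no}: direction must be one of {DIRECTIONS}"
            )
        key = (row["probe_id"], direction, row["rep"])
        if key in seen_rows:
            raise IntegrityError(
                f"{path} line {line_no}: duplicate (probe_id, direction, rep) {key}"
            )
        seen_rows.add(key)

        values = np.empty(design.n_timepoints)
        for j, col in enumerate(value_cols):
            try:
                values[j] = float(row[col])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path} line {line_no}, column {col}: "
                    f"non-numeric value {row[col]!r}"
                ) from None
        flags = np.empty(design.n_timepoints, dtype=bool)
        for j, col in enumerate(flag_cols):
            cell = str(row[col]).strip().lower()
            if cell in ("1", "true", "t"):
                flags[j] = True
            elif cell in ("0", "false", "f"):
                flags[j] = False
            else:
                raise FormatError(
                    f"{path} line {line_no}, column {col}: non-boolean flag {row[col]!r}"
                )

        g = groups.setdefault(
            (row["probe_id"], direction),
            {"sas_id": row["sas_id"], "values": [], "flags": []},
        )
        if g["sas_id"] != row["sas_id"]:
            raise IntegrityError(
                f"{path} line {line_no}: probe {row['probe_id']} maps to two sas_ids"
            )
        g["values"].append(values)
        g["flags"].append(flags)

    timecourses = [
        ProbeTimeCourse(
            probe_id=probe_id,
            sas_id=g["sas_id"],
            direction=direction,
            replicate_values=np.vstack(g["values"]),
            replicate_flags=np.vstack(g["flags"]),
        )
        for (probe_id, direction), g in groups.items()
    ]
    return ExpressionDataset(design=design, timecourses=timecourses)


def write_expression_table(ds: ExpressionDataset, path) -> None:
    """Write a dataset back to the TSV schema of :func:`read_expression_table`."""
    flag_cols, value_cols = _columns(ds.design)
    rows = []
    for tc in ds:
        for r in range(tc.n_replicates):
            row: dict = {
                "probe_id": tc.probe_id,
                "sas_id": tc.sas_id,
                "direction": tc.direction,
                "rep": r + 1,
            }
            row.update({c: int(v) for c, v in zip(flag_cols, tc.replicate_flags[r])})
            row.update(
                {c: repr(float(v)) for c, v in zip(value_cols, tc.replicate_values[r])}
            )
            rows.append(row)
    cols = ["probe_id", "sas_id", "direction", "rep"] + flag_cols + value_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def merge_replicates(tc: ProbeTimeCourse, method: str = "mean") -> ProbeTimeCourse:
    """Combine replicate rows into one series.

    Values are averaged per time point; a time point is flagged expressed
    when a majority of replicates flag it (ties count as expressed, the
    permissive rule for dye-swap duplicates).
    """
    if method != "mean":
        raise ValueError(f"unknown merge method {method!r}")
    if tc.replicate_values.shape[0] == 0:
        raise ValueError(f"probe {tc.probe_id}: no replicates to merge")
    values = tc.replicate_values.mean(axis=0)
    n_rep = tc.n_replicates
    flags = tc.replicate_flags.sum(axis=0) * 2 >= n_rep
    return tc.with_(values=values, expressed_flags=flags)


def call_expressed(tc: ProbeTimeCourse, min_timepoints: int = DEFAULT_MIN_TIMEPOINTS) -> bool:
    """A merged probe is expressed when flagged in >= ``min_timepoints`` arrays."""
    if tc.expressed_flags is None:
        raise ValueError(f"probe {tc.probe_id}: merge replicates before calling expression")
    return int(tc.expressed_flags.sum()) >= min_timepoints


def zscore_normalize(tc: ProbeTimeCourse) -> ProbeTimeCourse:
    """Z-score a merged series to mean 0, population sd 1.

    Zero-variance series cannot be normalized; they are returned unchanged
    with ``analyzable=False`` and ``status='zero_variance'`` so batch runs
    report rather than raise.
    """
    if tc.values is None:
        raise ValueError(f"probe {tc.probe_id}: merge replicates before normalizing")
    sd = float(np.std(tc.values))
    if sd == 0.0:
        return tc.with_(analyzable=False, status="zero_variance")
    z = (tc.values - tc.values.mean()) / sd
    return tc.with_(values=z)


@dataclass(frozen=True)
class DirectionSummary:
    direction: str
    n_probes: int
    n_expressed_ge1: int
    n_expressed_filter: int

    @property
    def pct_expressed_ge1(self) -> float:
        return percentage(self.n_expressed_ge1, self.n_probes)

    @property
    def pct_expressed_filter(self) -> float:
        return percentage(self.n_expressed_filter, self.n_probes)


@dataclass(frozen=True)
class FilterSummary:
    """Per-direction expression-filter bookkeeping (layout of a counts table)."""

    sense: DirectionSummary
    antisense: DirectionSummary

    def for_direction(self, direction: str) -> DirectionSummary:
        return getattr(self, direction)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in (self.sense, self.antisense):
            rows.append(
                {
                    "direction": d.direction,
                    "n_probes": d.n_probes,
                    "n_expressed_ge1": d.n_expressed_ge1,
                    "n_expressed_filter": d.n_expressed_filter,
                    "pct": d.pct_expressed_filter,
                }
            )
        return pd.DataFrame(rows)


def filter_dataset(
    ds: ExpressionDataset, min_timepoints: int = DEFAULT_MIN_TIMEPOINTS
) -> tuple[ExpressionDataset, FilterSummary]:
    """Retain probes passing the expression call; summarize per direction.

    Retained time courses are passed through unchanged (filtering alters
    membership only).
    """
    kept = []
    stats = {d: {"n": 0, "ge1": 0, "pass": 0} for d in DIRECTIONS}
    for tc in ds:
        if tc.expressed_flags is None:
            raise ValueError("merge replicates before filtering")
        s = stats[tc.direction]
        s["n"] += 1
        if tc.expressed_flags.any():
            s["ge1"] += 1
        if call_expressed(tc, min_timepoints):
            s["pass"] += 1
            kept.append(tc)
    summary = FilterSummary(
        sense=DirectionSummary(
            "sense", stats["sense"]["n"], stats["sense"]["ge1"], stats["sense"]["pass"]
        ),
        antisense=DirectionSummary(
            "antisense",
            stats["antisense"]["n"],
            stats["antisense"]["ge1"],
            stats["antisense"]["pass"],
        ),
    )
    return ds.subset(kept), summary


def prepare_dataset(
    ds: ExpressionDataset, min_timepoints: int = DEFAULT_MIN_TIMEPOINTS
) -> tuple[ExpressionDataset, FilterSummary]:
    """Merge replicates, apply the expression filter, and Z-score.

    Convenience wrapper giving the standard preprocessing order
    (merge -> filter -> normalize); zero-variance survivors stay in the
    dataset flagged not-analyzable.
    """
    merged = ds.subset([merge_replicates(tc) for tc in ds])
    filtered, summary = filter_dataset(merged, min_timepoints)
    normalized = filtered.subset([zscore_normalize(tc) for tc in filtered])
    return normalized, summary
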
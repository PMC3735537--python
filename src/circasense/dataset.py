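"""Core containers: sampling design, probe time courses and expression datasets.

The experimental unit is a probe-level time course sampled on a regular grid
(by default 12 points, one every 4 h over 48 h of constant light, the first
sample at subjective dawn, ZT0).  Each gene model (SAS) can carry up to two
probes, one per transcriptional direction: ``sense`` (SS) and ``antisense``
(AS).  Replicate hybridizations are stored row-wise until merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

from .errors import ConfigurationError, IntegrityError

DIRECTIONS = ("sense", "antisense")


@dataclass(frozen=True)
class SamplingDesign:
    """Regular sampling grid for a circadian time course.

    Sample times are ``t = start_zt_h + k * interval_h`` for
    ``k = 0 .. n_timepoints - 1``, in hours of zeitgeber time.
    """

    n_timepoints: int = 12
    interval_h: float = 4.0
    start_zt_h: float = 0.0

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise ConfigurationError("need at least 4 time points")
        if self.interval_h <= 0:
            raise ConfigurationError("interval_h must be positive")

    @property
    def duration_h(self) -> float:
        return self.n_timepoints * self.interval_h

    @property
    def times(self) -> np.ndarray:
        return self.start_zt_h + self.interval_h * np.arange(self.n_timepoints)


@dataclass
class ProbeTimeCourse:
    """One probe's direction-resolved trajectory with expressed flags.

    ``replicate_values``/``replicate_flags`` hold the raw replicate rows
    (n_replicates x n_timepoints); ``values``/``expressed_flags`` are filled
    by :func:`circasense.timecourse_io.merge_replicates`.  ``analyzable``
    is cleared (with ``status`` set) for series that cannot be normalized,
    e.g. zero variance.
    """

    probe_id: str
    sas_id: str
    direction: str
    replicate_values: np.ndarray
    replicate_flags: np.ndarray
    values: Optional[np.ndarray] = None
    expressed_flags: Optional[np.ndarray] = None
    analyzable: bool = True
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise IntegrityError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        self.replicate_values = np.atleast_2d(np.asarray(self.replicate_values, dtype=float))
        self.replicate_flags = np.atleast_2d(np.asarray(self.replicate_flags, dtype=bool))
        if self.replicate_values.shape != self.replicate_flags.shape:
            raise IntegrityError(
                f"probe {self.probe_id}: replicate value/flag shapes differ"
            )
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
        if self.expressed_flags is not None:
            self.expressed_flags = np.asarray(self.expressed_flags, dtype=bool)

    @property
    def n_replicates(self) -> int:
        return self.replicate_values.shape[0]

    def with_(self, **changes) -> "ProbeTimeCourse":
        return replace(self, **changes)

    def equals(self, other: "ProbeTimeCourse") -> bool:
        if (self.probe_id, self.sas_id, self.direction) != (
            other.probe_id,
            other.sas_id,
            other.direction,
        ):
            return False
        return bool(
            np.allclose(self.replicate_values, other.replicate_values)
            and np.array_equal(self.replicate_flags, other.replicate_flags)
        )


@dataclass
class ExpressionDataset:
    """A collection of probe time courses sharing one sampling design."""

    design: SamplingDesign
    species_label: str = "unlabelled"
    timecourses: list[ProbeTimeCourse] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        seen_sas: set[tuple[str, str]] = set()
        for tc in self.timecourses:
            key = (tc.probe_id, tc.direction)
            if key in seen:
                raise IntegrityError(f"duplicate probe {key}")
            seen.add(key)
            skey = (tc.sas_id, tc.direction)
            if skey in seen_sas:
                raise IntegrityError(f"two probes map to the same (sas_id, direction) {skey}")
            seen_sas.add(skey)
            n = self.design.n_timepoints
            if tc.replicate_values.shape[1] != n:
                raise IntegrityError(
                    f"probe {tc.probe_id}: {tc.replicate_values.shape[1]} columns, "
                    f"design has {n} time points"
                )

    def __len__(self) -> int:
        return len(self.timecourses)

    def __iter__(self) -> Iterator[ProbeTimeCourse]:
        return iter(self.timecourses)

    def get(self, probe_id: str, direction: str) -> ProbeTimeCourse:
        for tc in self.timecourses:
            if tc.probe_id == probe_id and tc.direction == direction:
                return tc
        raise KeyError((probe_id, direction))

    def by_direction(self, direction: str) -> list[ProbeTimeCourse]:
        return [tc for tc in self.timecourses if tc.direction == direction]

    def equals(self, other: "ExpressionDataset") -> bool:
        if self.design != other.design or len(self) != len(other):
            return False
        mine = {(tc.probe_id, tc.direction): tc for tc in self.timecourses}
        theirs = {(tc.probe_id, tc.direction): tc for tc in other.timecourses}
        if mine.keys() != theirs.keys():
            return False
        return all(mine[k].equals(theirs[k]) for k in mine)

    def subset(self, keep: Iterable[ProbeTimeCourse]) -> "ExpressionDataset":
        return ExpressionDataset(self.design, self.species_label, list(keep))
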
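"""Ground-truth-labelled synthetic expression datasets.

The generator emulates the statistical structure of a two-channel circadian
oligoarray experiment: 12 time points every 4 h under constant light, two
dye-swap replicates per time point, ~70% of sense probes and ~10% of
antisense probes expressed, a rhythmic subpopulation with periods from a
truncated normal on [20, 28] h and phases concentrated at ZT12 (sense) and
ZT4 (antisense), and sense/antisense pairs coupled in same-phase,
antiphase, lagged, independent-rhythm or arrhythmic-antisense modes.

Rhythmic probes are ``amplitude * cos(2*pi*(t - phase)/period)`` plus
i.i.d. Gaussian noise per replicate and time point, on the normalized
log-ratio scale the detectors consume; arrhythmic probes are pure noise.
The signal-to-noise ratio is ``amplitude / noise_sd`` (3 at the defaults).

Antisense coupling: when the sense partner is rhythmic the drawn pair mode
drives the antisense rhythm (same phase, +12 h, +lag_h, an independent
rhythm, or none); when the sense partner is arrhythmic the coupled modes
are unavailable and the antisense is independently rhythmic with
``rhythmic_fraction_antisense``.

Everything is reproducible from the config seed, and each probe draws from
its own content-keyed stream, so output is independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .circular import circ_distance
from .dataset import ExpressionDataset, ProbeTimeCourse, SamplingDesign
from .errors import ConfigurationError, IntegrityError
from .orthologs import OrthologCatalogue
from .utils import probe_rng

PAIR_MODES = ("same_phase", "antiphase", "lagged", "independent", "as_arrhythmic")

# defaults emulate the observed phase histograms: sense peaks at ZT12
# (~29% of circadian probes), antisense at ZT4 (~28%)
SENSE_PHASE_WEIGHTS = (0.12, 0.12, 0.14, 0.29, 0.18, 0.15)
ANTISENSE_PHASE_WEIGHTS = (0.14, 0.28, 0.14, 0.12, 0.16, 0.16)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_sense: int = 1000
    n_antisense: int = 500
    design: SamplingDesign = field(default_factory=SamplingDesign)
    rhythmic_fraction_sense: float = 0.32
    rhythmic_fraction_antisense: float = 0.22
    period_mean_h: float = 24.5
    period_sd_h: float = 2.5
    period_bounds: tuple[float, float] = (20.0, 28.0)
    phase_bin_weights_sense: tuple[float, ...] = SENSE_PHASE_WEIGHTS
    phase_bin_weights_antisense: tuple[float, ...] = ANTISENSE_PHASE_WEIGHTS
    amplitude: float = 1.0
    noise_sd: float = 1.0 / 3.0
    expressed_fraction_sense: float = 0.70
    expressed_fraction_antisense: float = 0.10
    background_flag_rate: float = 0.15
    flag_dropout: float = 0.05
    n_replicates: int = 2
    pair_mode_weights: tuple[float, ...] = (0.20, 0.10, 0.10, 0.10, 0.50)
    lag_h: float = 4.0
    n_categories: int = 30
    category_phase_concentration: Optional[float] = None
    species_label: str = "synthetic"

    def __post_init__(self) -> None:
        probs = (
            self.rhythmic_fraction_sense,
            self.rhythmic_fraction_antisense,
            self.expressed_fraction_sense,
            self.expressed_fraction_antisense,
            self.background_flag_rate,
            self.flag_dropout,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all fractions must lie in [0, 1]")
        for weights, n in (
            (self.phase_bin_weights_sense, 6),
            (self.phase_bin_weights_antisense, 6),
            (self.pair_mode_weights, len(PAIR_MODES)),
        ):
            if len(weights) != n or any(w < 0 for w in weights) or sum(weights) == 0:
                raise ConfigurationError(
                    "weights must be non-negative, not all zero, with the expected length"
                )
        lo, hi = self.period_bounds
        if not (0 < lo < hi):
            raise ConfigurationError("period_bounds must satisfy 0 < lo < hi")
        if self.n_replicates < 1 or self.n_antisense > self.n_sense:
            raise ConfigurationError("need n_replicates >= 1 and n_antisense <= n_sense")


@dataclass
class SimulatedStudy:
    """A simulated dataset plus its ground truth and companion fixtures."""

    dataset: ExpressionDataset
    truth: pd.DataFrame
    catalogue: OrthologCatalogue
    annotation: dict


def _draw_period(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    if cfg.period_sd_h == 0:
        return float(cfg.period_mean_h)
    lo, hi = cfg.period_bounds
    for _ in range(10_000):  # rejection sampling from the truncated normal
        p = rng.normal(cfg.period_mean_h, cfg.period_sd_h)
        if lo <= p <= hi:
            return float(p)
    return float(np.clip(cfg.period_mean_h, lo, hi))


def _draw_phase(weights, rng: np.random.Generator) -> float:
    w = np.asarray(weights, dtype=float)
    center = 4.0 * rng.choice(6, p=w / w.sum())
    return float((center + rng.uniform(-2.0, 2.0)) % 24.0)


def _make_values(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    period: Optional[float],
    phase: Optional[float],
) -> np.ndarray:
    t = cfg.design.times
    signal = (
        cfg.amplitude * np.cos(2.0 * np.pi * (t - phase) / period)
        if period is not None
        else np.zeros_like(t)
    )
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_replicates, len(t)))
    return signal[None, :] + noise


def _make_flags(cfg: SimulationConfig, rng: np.random.Generator, expressed: bool) -> np.ndarray:
    shape = (cfg.n_replicates, cfg.design.n_timepoints)
    if expressed:
        return rng.random(shape) >= cfg.flag_dropout
    return rng.random(shape) < cfg.background_flag_rate


def simulate_dataset(config: SimulationConfig) -> SimulatedStudy:
    """Generate an expression dataset with per-probe planted ground truth.

    Returns the dataset (raw replicate rows, ready for
    :func:`circasense.timecourse_io.prepare_dataset`), a truth table
    (probe_id, direction, sas_id, expressed, rhythmic, period_h, phase_h,
    pair_mode, category, cluster_id), an ortholog catalogue with one cluster
    per gene model and a probe map for this dataset, and a probe-to-category
    annotation.
    """
    cfg = config
    seed = cfg.seed
    timecourses: list[ProbeTimeCourse] = []
    truth_rows: list[dict] = []
    annotation: dict[str, str] = {}
    clusters: dict[str, set] = {}
    probe_map: dict[str, str] = {}

    if cfg.category_phase_concentration is not None:
        category_base_phase = {
            i: 24.0 * i / cfg.n_categories for i in range(cfg.n_categories)
        }
    else:
        category_base_phase = None

    sense_info: dict[str, dict] = {}
    for i in range(cfg.n_sense):
        sas_id = f"SAS{i:05d}"
        probe_id = f"SP{i:05d}"
        cluster_id = f"OC{i:05d}"
        rng = probe_rng(seed, probe_id, "sense")
        cat_idx = int(rng.integers(cfg.n_categories))
        category = f"cat_{cat_idx + 1:02d}"
        expressed = rng.random() < cfg.expressed_fraction_sense
        rhythmic = expressed and rng.random() < cfg.rhythmic_fraction_sense
        period = phase = None
        if rhythmic:
            period = _draw_period(cfg, rng)
            if category_base_phase is not None:
                phase = float(
                    rng.normal(category_base_phase[cat_idx], cfg.category_phase_concentration)
                    % 24.0
                )
            else:
                phase = _draw_phase(cfg.phase_bin_weights_sense, rng)
        values = _make_values(cfg, rng, period, phase)
        flags = _make_flags(cfg, rng, expressed)
        timecourses.append(
            ProbeTimeCourse(probe_id, sas_id, "sense", values, flags)
        )
        sense_info[sas_id] = {"rhythmic": rhythmic, "period": period, "phase": phase}
        annotation[probe_id] = category
        clusters[cluster_id] = {(cfg.species_label, sas_id)}
        probe_map[probe_id] = sas_id
        truth_rows.append(
            {
                "probe_id": probe_id, "direction": "sense", "sas_id": sas_id,
                "expressed": expressed, "rhythmic": rhythmic,
                "period_h": period if period is not None else np.nan,
                "phase_h": phase if phase is not None else np.nan,
                "pair_mode": None, "category": category, "cluster_id": cluster_id,
            }
        )

    mode_w = np.asarray(cfg.pair_mode_weights, dtype=float)
    mode_w = mode_w / mode_w.sum()
    for i in range(cfg.n_antisense):
        sas_id = f"SAS{i:05d}"
        probe_id = f"AP{i:05d}"
        rng = probe_rng(seed, probe_id, "antisense")
        expressed = rng.random() < cfg.expressed_fraction_antisense
        ss = sense_info[sas_id]
        if ss["rhythmic"]:
            mode = PAIR_MODES[int(rng.choice(len(PAIR_MODES), p=mode_w))]
        else:
            mode = "independent" if rng.random() < cfg.rhythmic_fraction_antisense else "as_arrhythmic"
        period = phase = None
        if mode == "same_phase":
            period, phase = ss["period"], ss["phase"]
        elif mode == "antiphase":
            period, phase = ss["period"], (ss["phase"] + 12.0) % 24.0
        elif mode == "lagged":
            period, phase = ss["period"], (ss["phase"] + cfg.lag_h) % 24.0
        elif mode == "independent":
            period = _draw_period(cfg, rng)
            phase = _draw_phase(cfg.phase_bin_weights_antisense, rng)
        values = _make_values(cfg, rng, period, phase)
        flags = _make_flags(cfg, rng, expressed)
        timecourses.append(
            ProbeTimeCourse(probe_id, sas_id, "antisense", values, flags)
        )
        sense_probe = f"SP{i:05d}"
        annotation[probe_id] = annotation[sense_probe]
        probe_map[probe_id] = sas_id
        truth_rows.append(
            {
                "probe_id": probe_id, "direction": "antisense", "sas_id": sas_id,
                "expressed": expressed, "rhythmic": period is not None,
                "period_h": period if period is not None else np.nan,
                "phase_h": phase if phase is not None else np.nan,
                "pair_mode": mode, "category": annotation[probe_id],
                "cluster_id": f"OC{i:05d}",
            }
        )

    dataset = ExpressionDataset(
        design=cfg.design, species_label=cfg.species_label, timecourses=timecourses
    )
    catalogue = OrthologCatalogue(clusters=clusters)
    catalogue.add_probe_map(cfg.species_label, probe_map)
    truth = pd.DataFrame(truth_rows)
    return SimulatedStudy(dataset, truth, catalogue, annotation)


def evaluate_against_truth(
    calls: pd.DataFrame,
    pair_table: Optional[pd.DataFrame],
    truth: pd.DataFrame,
) -> dict:
    """Score rhythm calls (and optionally pair classifications) against truth.

    Returns a dict with per-method and consensus sensitivity / false-positive
    rate (over probes present in both tables), COSOPT period RMSE and JTK
    circular phase RMSE over truly rhythmic probes, and (when a pair table
    is given) a pair-mode x classification confusion table.
    """
    merged = calls.merge(
        truth, on=["probe_id", "direction"], how="left", suffixes=("", "_truth")
    )
    if merged["rhythmic"].isna().any():
        missing = merged[merged["rhythmic"].isna()]["probe_id"].iloc[0]
        raise IntegrityError(f"probe {missing} has calls but no ground truth")

    is_rhythmic = merged["rhythmic"].astype(bool).to_numpy()
    metrics: dict = {"n_scored": int(len(merged))}
    flag_cols = {
        "cosopt": "rhythmic_cosopt",
        "jtk": "rhythmic_jtk",
        "fisher_g": "rhythmic_fisher",
        "consensus": "circadian",
    }
    for name, col in flag_cols.items():
        called = merged[col].astype(bool).to_numpy()
        n_pos, n_neg = int(is_rhythmic.sum()), int((~is_rhythmic).sum())
        metrics[f"sensitivity_{name}"] = (
            float(called[is_rhythmic].mean()) if n_pos else float("nan")
        )
        metrics[f"fpr_{name}"] = (
            float(called[~is_rhythmic].mean()) if n_neg else float("nan")
        )

    rhythmic = merged[is_rhythmic]
    period_err = (rhythmic["period_h"] - rhythmic["period_h_truth"]).dropna()
    metrics["period_rmse_h"] = (
        float(np.sqrt(np.mean(period_err**2))) if len(period_err) else float("nan")
    )
    ok_phase = rhythmic.dropna(subset=["phase_h", "phase_h_truth"])
    if len(ok_phase):
        d = circ_distance(ok_phase["phase_h"], ok_phase["phase_h_truth"])
        metrics["phase_rmse_h"] = float(np.sqrt(np.mean(d**2)))
    else:
        metrics["phase_rmse_h"] = float("nan")

    if pair_table is not None and len(pair_table):
        as_truth = truth[truth["direction"] == "antisense"][["sas_id", "pair_mode"]]
        pt = pair_table.merge(as_truth, on="sas_id", how="left")
        metrics["pair_confusion"] = pd.crosstab(pt["pair_mode"], pt["classification"])
    return metrics
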
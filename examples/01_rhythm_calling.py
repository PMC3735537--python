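"""Consensus rhythm calling on a simulated circadian time-course experiment.

Simulates a 1,000-probe sense channel (12 samples, one every 4 h over 48 h,
two replicates, ~70% expressed, 32% of expressed rhythmic at SNR 3), runs
the three detectors, calls probes circadian when at least two agree inside
the 20-28 h band, and scores the calls against the planted truth.
"""

import circasense as cs

cfg = cs.SimulationConfig(seed=42, n_sense=1000, n_antisense=0)
study = cs.simulate_dataset(cfg)

prepared, filt = cs.prepare_dataset(study.dataset)
s = filt.sense
print(f"expressed (>=10 of 12 arrays): {s.n_expressed_filter}/{s.n_probes} "
      f"({s.pct_expressed_filter}%)")

results = cs.run_all_detectors(
    prepared, settings=cs.DetectorSettings(seed=1, n_surrogates=199)
)
calls = cs.consensus_call(results, alpha=0.05)
summary = cs.summarize_rhythmicity(calls, filt)["sense"]
print(f"circadian (>=2 of 3 detectors): {summary.n_circadian} "
      f"({summary.pct_circadian}% of expressed)")
print(f"per-method counts: {summary.per_method_counts}")
print(f"COSOPT period over circadian probes: "
      f"{summary.period_mean_h} +/- {summary.period_sd_h} h (mean +/- sd)")
print(f"phase-bin fractions: "
      f"{ {k: round(v, 2) for k, v in summary.phase_bin_fractions.items()} }")

venn = cs.venn_counts(results)["sense"]
print(f"detector agreement (Venn regions): {venn}")

metrics = cs.evaluate_against_truth(calls, None, study.truth)
print(f"vs planted truth: consensus sensitivity {metrics['sensitivity_consensus']:.3f}, "
      f"false-positive rate {metrics['fpr_consensus']:.3f}")
print(f"COSOPT period RMSE {metrics['period_rmse_h']:.2f} h, "
      f"JTK circular phase RMSE {metrics['phase_rmse_h']:.2f} h")
# Sensitivity near 1 and FPR well below alpha mean the 2-of-3 consensus
# recovers the planted rhythms without inflating the false-call rate.
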
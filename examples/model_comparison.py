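"""Laplace model comparison on a small synthetic cohort.

Runs the full pipeline (simulate -> fit -> compare) for three tactile-
paradigm participants and prints per-model Laplace evidences and the
group-level evidence ratio of the causal model over a bias-only baseline.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from bcisa.pipeline import RunConfig, run_compare, run_fit, run_simulate

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(
        experiment="exp1", seed=11, n_participants=3, n_trials=120,
        n_restarts=3, out_dir=tmp,
    )
    data = run_simulate(cfg)
    fits = run_fit(cfg, data)
    summary_path = run_compare(cfg, data, fits)

    table = pd.read_csv(Path(tmp) / "exp1_model_comparison.csv")
    print(table[["participant_id", "model", "lap"]].to_string(index=False))

    summary = json.loads(summary_path.read_text())
    blk = summary["causal_vs_bias"]
    print(f"\nmean dLAP (causal - bias): {blk['mean_delta_lap']:.2f} "
          f"+- {blk['sem']:.2f}")
    print(f"group evidence ratio exp(sum dLAP): {blk['group_ratio']:.3g}")
    print(f"mean KL goodness of fit: {summary['kl_mean']:.4f} nats")

print(
    "\nA positive mean dLAP means the causal-inference model explains the\n"
    "condition-dependent detection rates better than an idiosyncratic\n"
    "response bias, even after the Laplace Occam penalty for its 7 free\n"
    "parameters."
)
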
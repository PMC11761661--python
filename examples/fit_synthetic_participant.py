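"""Fit one synthetic participant and compare recovered to true parameters.

Simulates a tactile-paradigm participant at known ground truth (binomial
detection counts at model-derived rates), fits the seven free parameters
by multi-start Powell, and prints true vs. recovered noise width.
"""

from bcisa import fit_participant_exp1, sample_ground_truth, simulate_participant
from bcisa.tactile import MOVEMENT_TRIAL_TYPES, detection_probability

gt = sample_ground_truth("exp1", seed=7, n_trials=200)
data = simulate_participant(gt)

print("condition            trials  detections  empirical rate")
for tt in MOVEMENT_TRIAL_TYPES:
    n, k = data.counts[tt]
    print(f"{tt:20s} {n:6d}  {k:10d}  {k / n:14.3f}")

fit = fit_participant_exp1(data, seed=1, n_restarts=3)
print(f"\nbest cost {fit.best_cost:.4f} after {fit.n_function_evals} evaluations")
print(f"true sigma {gt.params.sigma:.2f}, recovered sigma {fit.best_params.sigma:.2f}")
print("model detection probabilities at the fit:")
for tt in MOVEMENT_TRIAL_TYPES:
    print(f"  {tt:20s} {detection_probability(tt, fit.best_params):.3f}")
print(
    "\nThe fitted detection probabilities track the empirical rates; the\n"
    "noise width is identified mainly by the congruent/incongruent contrast."
)
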
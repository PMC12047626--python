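"""Parameter-recovery study: how well does the pipeline recover a known
model from simulated behavior?

Simulates a 10-participant study, fits it, and scores the recovered
group means, correlations and SvM curve against the ground truth (both
renormalized to the common scale anchor).
"""

import numpy as np

from grtmeta import StudyConfig, recovery_harness

config = StudyConfig(n_participants=10, trials_per_condition=200, seed=31)
report = recovery_harness(config, n_restarts=10, fit_seed=2)

print(f"group-mean RMSE:            {report['group_mean_rmse']:.4f}")
print(f"max |correlation error|:    {report['rho_max_abs_error']:.4f}")
print(f"max |SvM curve error|:      {report['curve_max_abs_error']:.4f} "
      f"(over L in [0.5, 5])")
print(f"variance accounted for:     {report['pct_variance']:.2f}%")
print("correlation errors by stimulus:",
      np.round(report["rho_errors"], 4))
# Mean RMSE well below the between-stimulus separation and correlation
# errors well inside +/-0.1 indicate the design (200 trials/condition)
# identifies the model comfortably at this sample size.
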
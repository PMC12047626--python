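"""Figure panels: the fitted decision space and the SvM curve with band.

Writes svm_panels.png into the current directory.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from grtmeta import StudyConfig, bootstrap_svm_band, build_svm_curve, fit_grt_wind, generate_study
from grtmeta.io import aggregate_counts
from grtmeta.plotting import plot_decision_space, plot_svm_curve

config = StudyConfig(n_participants=4, trials_per_condition=150, seed=3)
trials, _ = generate_study(config)
tables = aggregate_counts(trials, judgment="TOT")
fitted = fit_grt_wind(tables, n_restarts=10, seed=1)
curve = build_svm_curve(fitted, n_points=61, metad_starts=4)
band = bootstrap_svm_band(
    fitted, tables, n_boot=30, seed=7, restarts_per_refit=5,
    L_grid=np.geomspace(0.3, 8, 31),
)

fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5))
plot_decision_space(fitted, ax=ax1)
plot_svm_curve(curve, band=band, ax=ax2)
fig.tight_layout()
fig.savefig("svm_panels.png", dpi=150)
print("wrote svm_panels.png")
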
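"""Simulate a two-dose PK study and recover free/total profiles through RED.

Generates one-compartment total-plasma time courses for 1 and 3 mg/kg dose
groups, pushes every time point through dialysis, prep, quantification and
mass balance, and prints the recovered peak concentrations.
"""

import numpy as np

from redquant import REDGeometry, StudyDesign, fractionate_table, generate_study, simulate_pk_profile
from redquant.pipeline import fit_batch_curves, quantify_samples

design = StudyDesign(n_runs=1)
for dose in design.dose_groups:
    prof = simulate_pk_profile(dose, design, seed=11, cv_lognormal=0.0)
    peak = prof.groupby("time_min")["total_ng_ml"].mean().max()
    print(f"dose {dose:g} mg/kg: noiseless peak total {peak:7.1f} ng/mL")

bundle = generate_study(design=design, seed=11, components=("qc_runs",),
                        include_pk=True, n_animals=2)
curves, _ = fit_batch_curves(bundle.manifest, bundle.peaks)
measured = quantify_samples(bundle.manifest, bundle.peaks, curves)
study = measured[measured["sample_type"] == "study"]
fractions = fractionate_table(
    study[["specimen_id", "compartment", "analyzed_ng_ml"]], REDGeometry()
)
merged = fractions.merge(bundle.truth, on="specimen_id")
post = merged[merged["true_total_ng_ml"] > 0]
err = 100 * np.median(
    (post["total_ng_ml"] - post["true_total_ng_ml"]).abs() / post["true_total_ng_ml"]
)
print(f"median recovery error of analyzed totals across {len(post)} samples: {err:.2f}%")
print(f"median free/total ratio: {(post['free_ng_ml']/post['total_ng_ml']).median():.3f}")
# Doses scale the profile linearly; the analysis pipeline recovers each
# sampled total to within instrument noise, and the free/total ratio
# reflects the configured binding plus the dialysis volume shift.
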
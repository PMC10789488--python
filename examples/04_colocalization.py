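"""Core analysis: co-localization of patient alterations with template maps.

Generates a cohort whose patients lose signal where template 1 is
dense, z-scores each patient against the controls, correlates the
regional z-maps with every template (Fisher-z Spearman), and tests the
per-template mean coefficient with a group-label permutation test plus
BH-FDR. Also prints the ROC discrimination of patients vs leave-one-out
control profiles.
"""

from neurocoloc.coloc import (
    coloc_group_test,
    coloc_profiles,
    coloc_roc,
    loo_control_zscores,
    regional_data_matrix,
    zscore_vs_controls,
)
import pandas as pd

from neurocoloc.simulate import (
    SyntheticConfig,
    generate_atlas,
    generate_cohort,
    generate_template_maps,
)

atlas = generate_atlas((14, 14, 14), 60, seed=1)
templates = generate_template_maps(atlas, 5, smoothness=1.5, seed=2)
config = SyntheticConfig(
    grid_shape=(14, 14, 14), n_regions=60, n_templates=5,
    n_patients=24, n_controls=12,
    planted_template_index=1, effect_size_beta=0.1, noise_sd=1.0, seed=3,
)
subjects, maps, truth = generate_cohort(atlas, templates, config)

data = regional_data_matrix(maps, atlas)
patients = data[(subjects.group == "patient").to_numpy()].reset_index(drop=True)
controls = data[(subjects.group == "control").to_numpy()].reset_index(drop=True)

result = coloc_group_test(
    patients, controls, templates.regional, n_perm=2000, seed=4
)
print(result.table.round(4).to_string(index=False))

control_profiles = coloc_profiles(loo_control_zscores(controls), templates.regional)
roc = coloc_roc(result.profiles, control_profiles)
print()
print(roc.table.round(3).to_string(index=False))

print(
    "\nThe planted template (index 1) shows a negative mean r - patients lost "
    "signal where its density is high - with a permutation p at the test's "
    "resolution, and its profile separates patients from controls (AUC)."
)
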
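"""Gene-expression association and donor stability of regional profiles.

Generates a 6-donor expression set in which gene_coupled follows the
spatial layout of a template map while gene_free does not, then runs
the donor-averaged association of patient z-maps with each gene and the
gene differential stability (mean pairwise inter-donor Fisher-z
Spearman).
"""

import pandas as pd

from neurocoloc.coloc import regional_data_matrix, zscore_vs_controls
from neurocoloc.mrna import gene_coloc_table, gene_stability_table
from neurocoloc.simulate import (
    SyntheticConfig,
    generate_atlas,
    generate_cohort,
    generate_donors,
    generate_template_maps,
)

atlas = generate_atlas((14, 14, 14), 60, seed=1)
templates = generate_template_maps(atlas, 3, smoothness=1.5, seed=2)
config = SyntheticConfig(
    grid_shape=(14, 14, 14), n_regions=60, n_templates=3,
    n_patients=20, n_controls=10,
    planted_template_index=0, effect_size_beta=0.6, noise_sd=1.0, seed=3,
)
subjects, maps, _ = generate_cohort(atlas, templates, config)

donors = generate_donors(
    atlas, ["gene_coupled", "gene_free"],
    coupling_template=templates.regional.iloc[:, 0],
    inter_donor_rho=0.5, n_donors=6, seed=4,
    coupled_genes=["gene_coupled"],
)

data = regional_data_matrix(maps, atlas)
patients = data[(subjects.group == "patient").to_numpy()].reset_index(drop=True)
controls = data[(subjects.group == "control").to_numpy()].reset_index(drop=True)
zmaps = pd.DataFrame(
    [zscore_vs_controls(patients.iloc[i], controls) for i in range(len(patients))]
)

print(gene_coloc_table(zmaps, donors, ["gene_coupled", "gene_free"]).round(4).to_string(index=False))
print()
print(gene_stability_table(donors, ["gene_coupled", "gene_free"]).round(3).to_string(index=False))
print(
    "\ngene_coupled tracks the planted template, so patient z-maps correlate "
    "negatively with its expression (Bonferroni-significant one-sample t); "
    "both genes share the donor latent, so stability_z sits near "
    "atanh(0.5) = 0.55."
)
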
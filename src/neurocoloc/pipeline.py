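"""End-to-end orchestration of the synthetic co-localization study.

Sequences the full analysis chain on a generated dataset: simulate ->
confound regression -> group contrast -> co-localization (functional,
structural, and total-GMV-controlled variants) -> ROC -> variance
explained -> clinical associations -> site check -> mRNA association.
All result tables are written as TSV with a run log recording the seeds
and settings; identical config + seed reproduces identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imaging import extract_regional_means, regress_confounds_images
from .simulate import (
    SyntheticConfig,
    generate_atlas,
    generate_clinical,
    generate_cohort,
    generate_donors,
    generate_gm_probability,
    generate_template_maps,
)
from .contrast import permutation_cluster_inference
from .coloc import (
    coloc_group_test,
    coloc_profiles,
    coloc_roc,
    loo_control_zscores,
    regional_data_matrix,
    zscore_vs_controls,
)
from .structural import clinical_association, site_homogeneity_test, variance_explained
from .mrna import gene_coloc_table, gene_stability_table, template_gene_coloc

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Settings of one pipeline run; the numeric defaults are the study's."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_perm_cluster: int = 1000
    n_perm_coloc: int = 10000
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    fdr_q: float = 0.05
    adjust_gm: bool = True
    control_total_gmv: bool = True
    clinical_target_rho: float = 0.4
    n_genes: int = 6
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        own = {f for f in cls.__dataclass_fields__ if f != "synthetic"}
        synth = SyntheticConfig.from_mapping(mapping)
        return cls(synthetic=synth, **{k: v for k, v in mapping.items() if k in own})


def _write(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic study; returns the result tables.

    Writes every table to ``outdir`` along with ``run_log.json`` and a
    ``manifest.txt`` of completed stages (retained on failure so partial
    output is inspectable).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: list[str] = []
    seeds = {
        "master": config.seed,
        "atlas": config.seed,
        "templates": config.seed + 1,
        "falff_cohort": config.synthetic.seed,
        "gmv_cohort": config.synthetic.seed + 1000003,
        "contrast": config.seed + 2,
        "coloc": config.seed + 3,
        "coloc_gmv": config.seed + 4,
        "coloc_gmvctrl": config.seed + 5,
        "clinical": config.seed + 6,
        "donors": config.seed + 7,
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # pragma: no cover - error path
                _finish(outdir, config, seeds, manifest, failed=name)
                raise StageError(name, exc) from exc
            manifest.append(name)

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        syn = config.synthetic
        atlas = generate_atlas(syn.grid_shape, syn.n_regions, seeds["atlas"])
        templates = generate_template_maps(
            atlas,
            syn.n_templates,
            smoothness=syn.template_smoothness,
            seed=seeds["templates"],
            max_pairwise_rho=syn.template_rho_cap,
        )
        gm_rv = extract_regional_means(generate_gm_probability(atlas), atlas)
        subjects, falff_maps, truth = generate_cohort(atlas, templates, syn)
        gmv_cfg = SyntheticConfig(
            **{
                **asdict(syn),
                "effect_size_beta": 0.0,
                "seed": seeds["gmv_cohort"],
                "confound_effects": {**syn.confound_effects, "tiv": 0.3},
            }
        )
        _, gmv_maps, _ = generate_cohort(atlas, templates, gmv_cfg)
        state.update(
            atlas=atlas,
            templates=templates,
            gm_rv=gm_rv,
            subjects=subjects,
            falff_maps=falff_maps,
            gmv_maps=gmv_maps,
        )
        results["ground_truth"] = pd.DataFrame([truth])
        _write(results["ground_truth"], outdir / "ground_truth.tsv")
        subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False, lineterminator="\n")

    @stage("confound_regression")
    def _confounds():
        covs = ["age", "sex", "site"] if config.synthetic.n_sites > 1 else ["age", "sex"]
        state["falff_clean"] = regress_confounds_images(
            state["falff_maps"], state["subjects"], covs
        )
        state["gmv_clean"] = regress_confounds_images(
            state["gmv_maps"], state["subjects"], covs + ["tiv"]
        )
        state["covariates"] = covs

    @stage("contrast")
    def _contrast():
        results["clusters_falff"] = permutation_cluster_inference(
            state["falff_clean"],
            state["subjects"],
            state["covariates"],
            contrast="control>patient",
            n_perm=config.n_perm_cluster,
            voxel_p=config.voxel_p,
            cluster_p=config.cluster_p,
            seed=seeds["contrast"],
        )
        _write(results["clusters_falff"], outdir / "clusters_falff.tsv")

    @stage("coloc_falff")
    def _coloc():
        subjects = state["subjects"]
        data = regional_data_matrix(state["falff_clean"], state["atlas"])
        is_pat = (subjects["group"] == "patient").to_numpy()
        state["falff_pat"] = data[is_pat].reset_index(drop=True)
        state["falff_ctl"] = data[~is_pat].reset_index(drop=True)
        res = coloc_group_test(
            state["falff_pat"],
            state["falff_ctl"],
            state["templates"].regional,
            gm_rv=state["gm_rv"],
            adjust_gm=config.adjust_gm,
            n_perm=config.n_perm_coloc,
            seed=seeds["coloc"],
            fdr_q=config.fdr_q,
        )
        state["coloc_falff"] = res
        results["coloc_falff"] = res.table
        _write(res.table, outdir / "coloc_falff.tsv")
        prof = res.profiles.copy()
        prof.insert(0, "subject", subjects.loc[is_pat, "id"].to_numpy())
        _write(prof, outdir / "profiles_falff.tsv")

    @stage("coloc_gmv")
    def _coloc_gmv():
        subjects = state["subjects"]
        data = regional_data_matrix(state["gmv_clean"], state["atlas"])
        is_pat = (subjects["group"] == "patient").to_numpy()
        res = coloc_group_test(
            data[is_pat].reset_index(drop=True),
            data[~is_pat].reset_index(drop=True),
            state["templates"].regional,
            gm_rv=state["gm_rv"],
            adjust_gm=config.adjust_gm,
            n_perm=config.n_perm_coloc,
            seed=seeds["coloc_gmv"],
            fdr_q=config.fdr_q,
        )
        state["coloc_gmv"] = res
        results["coloc_gmv"] = res.table
        _write(res.table, outdir / "coloc_gmv.tsv")

    @stage("coloc_total_gmv_controlled")
    def _coloc_ctrl():
        if not config.control_total_gmv:
            return
        subjects = state["subjects"].copy()
        subjects["total_gmv"] = [
            float(np.nansum(m.data)) for m in state["gmv_maps"]
        ]
        cleaned = regress_confounds_images(
            state["falff_maps"], subjects, state["covariates"] + ["total_gmv"]
        )
        data = regional_data_matrix(cleaned, state["atlas"])
        is_pat = (subjects["group"] == "patient").to_numpy()
        res = coloc_group_test(
            data[is_pat].reset_index(drop=True),
            data[~is_pat].reset_index(drop=True),
            state["templates"].regional,
            gm_rv=state["gm_rv"],
            adjust_gm=config.adjust_gm,
            n_perm=config.n_perm_coloc,
            seed=seeds["coloc_gmvctrl"],
            fdr_q=config.fdr_q,
        )
        results["coloc_falff_totalgmv"] = res.table
        _write(res.table, outdir / "coloc_falff_totalgmv.tsv")

    @stage("roc")
    def _roc():
        loo_z = loo_control_zscores(state["falff_ctl"])
        ctl_prof = coloc_profiles(
            loo_z,
            state["templates"].regional,
            gm_rv=state["gm_rv"],
            adjust_gm=config.adjust_gm,
        )
        roc = coloc_roc(state["coloc_falff"].profiles, ctl_prof)
        results["roc"] = roc.table
        _write(roc.table, outdir / "roc.tsv")

    @stage("variance_explained")
    def _varexp():
        rhos, fraction = variance_explained(
            state["coloc_falff"].profiles, state["coloc_gmv"].profiles
        )
        results["variance_explained"] = pd.DataFrame(
            {"median_rho_sq": [fraction], "n_patients": [len(rhos)]}
        )
        _write(results["variance_explained"], outdir / "variance_explained.tsv")

    @stage("clinical")
    def _clinical():
        syn = config.synthetic
        planted = syn.planted_template_index or 0
        profiles = state["coloc_falff"].profiles
        strength = profiles.iloc[:, planted].to_numpy(float)
        subjects = generate_clinical(
            state["subjects"], strength, config.clinical_target_rho, seeds["clinical"]
        )
        state["subjects_clinical"] = subjects
        sig = results["coloc_falff"].loc[results["coloc_falff"]["significant"], "template"]
        tested = profiles[sig] if len(sig) else profiles
        table = clinical_association(tested, subjects, ["clinical_score"], fdr_q=config.fdr_q)
        results["clinical"] = table
        _write(table, outdir / "clinical.tsv")
        h, df, p = site_homogeneity_test(
            profiles.iloc[:, planted].set_axis(
                subjects.index[subjects["group"] == "patient"]
            ),
            subjects,
        )
        results["site_homogeneity"] = pd.DataFrame({"H": [h], "df": [df], "p": [p]})
        _write(results["site_homogeneity"], outdir / "site_homogeneity.tsv")

    @stage("mrna")
    def _mrna():
        syn = config.synthetic
        planted = syn.planted_template_index or 0
        genes = [f"gene_{i:03d}" for i in range(config.n_genes)]
        donors = generate_donors(
            state["atlas"],
            genes,
            coupling_template=state["templates"].regional.iloc[:, planted],
            inter_donor_rho=syn.inter_donor_rho,
            n_donors=syn.n_donors,
            seed=seeds["donors"],
            coupled_genes=[genes[0]],
        )
        is_pat = (state["subjects"]["group"] == "patient").to_numpy()
        zmaps = pd.DataFrame(
            [
                zscore_vs_controls(state["falff_pat"].iloc[i], state["falff_ctl"])
                for i in range(len(state["falff_pat"]))
            ]
        )
        results["mrna_gene_coloc"] = gene_coloc_table(zmaps, donors, genes)
        _write(results["mrna_gene_coloc"], outdir / "mrna_gene_coloc.tsv")
        sig = results["coloc_falff"].loc[results["coloc_falff"]["significant"], "template"]
        tested = list(sig) if len(sig) else [state["templates"].names[planted]]
        rows = [
            {
                "template": tname,
                "gene": gene,
                "mean_z": template_gene_coloc(
                    state["templates"].regional[tname], donors, gene
                ),
            }
            for tname in tested
            for gene in genes
        ]
        results["mrna_template_coloc"] = pd.DataFrame(rows)
        _write(results["mrna_template_coloc"], outdir / "mrna_template_coloc.tsv")
        results["gene_stability"] = gene_stability_table(donors, genes)
        _write(results["gene_stability"], outdir / "gene_stability.tsv")

    _finish(outdir, config, seeds, manifest, failed=None)
    return results


def _finish(outdir: Path, config: PipelineConfig, seeds: dict, manifest: list, failed):
    log = {
        "version": __version__,
        "config": {**asdict(config), "synthetic": asdict(config.synthetic)},
        "seeds": seeds,
        "stages_completed": list(manifest),
        "failed_stage": failed,
    }
    log["config"]["synthetic"]["grid_shape"] = list(config.synthetic.grid_shape)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    (outdir / "manifest.txt").write_text("\n".join(manifest) + "\n")
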
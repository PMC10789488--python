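"""Synthetic study generator with known ground truth.

Every input the pipeline consumes can be generated here: a connected
gray-matter parcellation, smooth nonnegative template density maps, a
two-group cohort of subject maps with a planted co-localization effect,
band-limited BOLD series, multi-donor regional expression tables, and
clinical scores coupled to the planted effect strength.

The planted model mirrors the directional hypothesis the pipeline is
built to detect: patients lose signal preferentially in regions where
the planted template's density is high, i.e.

    control map = baseline + covariate effects + noise
    patient map = baseline - beta * planted template + covariate effects + noise

so patient-vs-control z-maps correlate *negatively* with the planted
template. Cohort demographics default to the reference study
population: 52 patients (age ~ N(61.5, 10.0^2), 38 m / 14 f) and
22 controls (age ~ N(63.6, 11.9^2), 9 m / 13 f).

Every generator is deterministic given its seed; ground truth is
returned (and serialized) beside the outputs so recovery tests never
re-derive it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import Atlas, ScalarMap, extract_regional_means
from .falff import TimeSeriesSet, FrequencyBand, DEFAULT_BAND
from .mrna import DonorExpressionSet
from .stats import spearman_rho, fisher_z, fisher_z_inv

__all__ = [
    "SyntheticConfig",
    "TemplateMapSet",
    "GenerationError",
    "generate_atlas",
    "generate_gm_probability",
    "generate_template_maps",
    "generate_cohort",
    "generate_bold",
    "generate_donors",
    "generate_clinical",
    "calibrate_effect_size",
]


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its constraints."""


# Reference-cohort demographic defaults (patients / controls).
PATIENT_AGE = (61.5, 10.0)
CONTROL_AGE = (63.6, 11.9)
PATIENT_FEMALE_FRAC = 14 / 52
CONTROL_FEMALE_FRAC = 13 / 22


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic study.

    ``effect_size_beta`` is in map units per unit of (standardized)
    template density; its sign sets the direction of the patient change
    (positive beta = patient signal reduced where density is high).
    ``confound_effects`` maps covariate names (age, sex, site, tiv) to
    spatial effect amplitudes in map units per SD of the covariate.
    ``inter_donor_rho`` is the population Spearman correlation between
    any two donors' regional expression profiles.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_regions: int = 74
    n_templates: int = 11
    n_patients: int = 52
    n_controls: int = 22
    planted_template_index: int | None = 0
    effect_size_beta: float = 0.0
    noise_sd: float = 1.0
    confound_effects: dict = field(default_factory=dict)
    inter_donor_rho: float = 0.5
    n_donors: int = 6
    n_sites: int = 3
    template_smoothness: float = 2.0
    template_rho_cap: float = 0.3
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if len(self.grid_shape) != 3 or any(v <= 0 for v in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        for name in ("n_regions", "n_templates", "n_patients", "n_controls", "n_donors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.planted_template_index is not None and not (
            0 <= self.planted_template_index < self.n_templates
        ):
            raise ValueError("planted_template_index must be < n_templates")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.inter_donor_rho < 1):
            raise ValueError("inter_donor_rho must lie in [0, 1)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SyntheticConfig":
        fields = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in mapping.items() if k in fields})


def _ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Connected 'brain-like' mask: a centered ellipsoid covering ~half the box."""
    coords = np.indices(grid_shape, dtype=float)
    center = (np.asarray(grid_shape, float) - 1) / 2
    semi = np.maximum(np.asarray(grid_shape, float) / 2 - 0.5, 0.75)
    r2 = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def generate_atlas(grid_shape, n_regions: int, seed: int) -> Atlas:
    """Partition a connected gray-matter mask into ``n_regions`` parcels.

    Regions are nearest-seed (Voronoi) cells around randomly chosen
    in-mask voxels, so every label is nonempty and the labels exactly
    partition the mask. Deterministic in ``seed``.
    """
    grid_shape = tuple(int(v) for v in grid_shape)
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    mask = _ellipsoid_mask(grid_shape)
    in_mask = np.argwhere(mask)
    if n_regions > len(in_mask):
        raise ValueError(
            f"n_regions = {n_regions} exceeds the {len(in_mask)} in-mask voxels"
        )
    rng = np.random.default_rng(seed)
    centers = in_mask[rng.choice(len(in_mask), size=n_regions, replace=False)]
    d2 = ((in_mask[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assignment = d2.argmin(axis=1) + 1
    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[tuple(in_mask.T)] = assignment
    table = pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "name": [f"region_{i:03d}" for i in range(1, n_regions + 1)],
        }
    )
    return Atlas(labels, table)


def generate_gm_probability(atlas: Atlas, smoothness: float = 1.5) -> ScalarMap:
    """Synthetic gray-matter probability map: the smoothed atlas mask.

    Values are in [0, 1], highest deep inside the mask — the covariate
    used when co-localization adjusts for local GM probability.
    """
    prob = ndimage.gaussian_filter(atlas.mask.astype(float), smoothness)
    data = np.where(atlas.mask, np.clip(prob, 0.0, 1.0), np.nan)
    return ScalarMap(data, atlas.affine)


@dataclass
class TemplateMapSet:
    """Smooth nonnegative density maps plus their regional means."""

    maps: list[ScalarMap]
    regional: pd.DataFrame  # regions x templates
    names: list[str]

    def __len__(self) -> int:
        return len(self.maps)


def generate_template_maps(
    atlas: Atlas,
    n_templates: int,
    smoothness: float = 2.0,
    seed: int = 0,
    max_pairwise_rho: float = 0.3,
    max_retries: int = 200,
) -> TemplateMapSet:
    """Generate template density maps with bounded mutual correlation.

    Each template is Gaussian-smoothed white noise, shifted to be
    nonnegative (density-like) inside the mask. Candidate templates are
    rejected until the regional means of every accepted pair satisfy
    ``|Spearman rho| <= max_pairwise_rho``, so a co-localization effect
    planted on one template is attributable to that template alone.
    ``smoothness = 0`` yields voxel-wise independent noise maps.
    """
    rng = np.random.default_rng(seed)
    mask = atlas.mask
    accepted_maps: list[ScalarMap] = []
    accepted_regional: list[np.ndarray] = []
    tries = 0
    while len(accepted_maps) < n_templates:
        if tries > max_retries + n_templates:
            raise GenerationError(
                f"could not generate {n_templates} templates with pairwise "
                f"|rho| <= {max_pairwise_rho} after {tries} attempts"
            )
        tries += 1
        noise = rng.standard_normal(atlas.labels.shape)
        if smoothness > 0:
            noise = ndimage.gaussian_filter(noise, smoothness)
        data = np.where(mask, noise - noise[mask].min(), np.nan)
        candidate = ScalarMap(data, atlas.affine)
        regional = extract_regional_means(candidate, atlas).to_numpy()
        if any(
            abs(spearman_rho(regional, prev)) > max_pairwise_rho
            for prev in accepted_regional
        ):
            continue
        accepted_maps.append(candidate)
        accepted_regional.append(regional)
    names = [f"template_{i:02d}" for i in range(n_templates)]
    regional = pd.DataFrame(
        np.column_stack(accepted_regional),
        index=pd.Index(atlas.region_ids, name="region_id"),
        columns=names,
    )
    return TemplateMapSet(accepted_maps, regional, names)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _draw_demographics(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients + config.n_controls
    group = ["patient"] * config.n_patients + ["control"] * config.n_controls
    age = np.concatenate(
        [
            rng.normal(*PATIENT_AGE, size=config.n_patients),
            rng.normal(*CONTROL_AGE, size=config.n_controls),
        ]
    )
    female = np.concatenate(
        [
            rng.random(config.n_patients) < PATIENT_FEMALE_FRAC,
            rng.random(config.n_controls) < CONTROL_FEMALE_FRAC,
        ]
    )
    site = rng.integers(0, config.n_sites, size=n)
    tiv = rng.normal(1450.0, 130.0, size=n)
    return pd.DataFrame(
        {
            "id": [f"sub-{i:03d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": np.where(female, "f", "m"),
            "site": [f"site{s}" for s in site],
            "tiv": tiv,
        }
    )


def generate_cohort(
    atlas: Atlas,
    templates: TemplateMapSet,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, list[ScalarMap], dict]:
    """Generate subject maps with an optional planted template effect.

    Returns ``(subject_table, maps, ground_truth)``. The ground-truth
    dict records the planted template index and effect size so recovery
    tests never re-derive them.
    """
    if config.n_templates != len(templates):
        raise ValueError("config.n_templates does not match the template set")
    rng = np.random.default_rng(config.seed)
    mask = atlas.mask
    subjects = _draw_demographics(config, rng)

    baseline = ndimage.gaussian_filter(rng.standard_normal(atlas.labels.shape), 2.0)
    baseline = baseline - baseline[mask].min() + 1.0

    planted = np.zeros(atlas.labels.shape)
    if config.planted_template_index is not None and config.effect_size_beta != 0.0:
        tmpl = templates.maps[config.planted_template_index].data
        vals = np.where(mask, tmpl, 0.0)
        vals[mask] = _standardize(vals[mask])
        planted = vals

    # per-covariate fixed smooth spatial patterns for confound effects
    effect_patterns = {}
    for name in sorted(config.confound_effects):
        pat = ndimage.gaussian_filter(rng.standard_normal(atlas.labels.shape), 2.0)
        pat[mask] = _standardize(pat[mask])
        effect_patterns[name] = pat

    covariate_values = {}
    if config.confound_effects:
        covariate_values["age"] = _standardize(subjects["age"].to_numpy(float))
        covariate_values["sex"] = _standardize((subjects["sex"] == "f").to_numpy(float))
        site_codes = pd.Categorical(subjects["site"]).codes
        covariate_values["site"] = _standardize(site_codes.astype(float))
        covariate_values["tiv"] = _standardize(subjects["tiv"].to_numpy(float))

    maps = []
    for i in range(len(subjects)):
        data = baseline.copy()
        if subjects.loc[i, "group"] == "patient":
            data = data - config.effect_size_beta * planted
        for name, coef in config.confound_effects.items():
            data = data + coef * covariate_values[name][i] * effect_patterns[name]
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
        maps.append(ScalarMap(np.where(mask, data, np.nan), atlas.affine))

    ground_truth = {
        "planted_template_index": config.planted_template_index,
        "effect_size_beta": config.effect_size_beta,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return subjects, maps, ground_truth


def generate_bold(
    n_voxels: int,
    n_volumes: int,
    tr_seconds: float,
    band_power_fraction: float,
    seed: int,
    band: FrequencyBand = DEFAULT_BAND,
) -> TimeSeriesSet:
    """Band-limited BOLD-like series with a prescribed in-band power share.

    Series are synthesized in the frequency domain: each positive DFT
    bin receives an independent complex-Gaussian coefficient whose
    variance is split so the expected spectral power fraction inside
    ``band`` equals ``band_power_fraction``. Synthetic 6-parameter
    motion (random walk) and WM/CSF mean signals are attached for
    nuisance-regression tests.
    """
    if n_volumes < 16:
        raise ValueError("need at least 16 volumes")
    if not (0 <= band_power_fraction <= 1):
        raise ValueError("band_power_fraction must lie in [0, 1]")
    band.validate_for_tr(tr_seconds)
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_volumes, d=tr_seconds)
    positive = freqs > 0
    in_band = positive & (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)
    out_band = positive & ~in_band
    n_in, n_out = int(in_band.sum()), int(out_band.sum())
    if n_in == 0:
        raise ValueError("band contains no DFT frequency for this TR / duration")
    weights = np.zeros(freqs.size)
    if band_power_fraction > 0:
        weights[in_band] = math.sqrt(band_power_fraction / n_in)
    if band_power_fraction < 1 and n_out > 0:
        weights[out_band] = math.sqrt((1 - band_power_fraction) / n_out)
    coeff = (
        rng.standard_normal((n_voxels, freqs.size))
        + 1j * rng.standard_normal((n_voxels, freqs.size))
    ) * weights
    series = np.fft.irfft(coeff, n=n_volumes, axis=1) * n_volumes
    motion6 = np.cumsum(rng.normal(0.0, 0.02, size=(n_volumes, 6)), axis=0)
    wm = rng.standard_normal(n_volumes)
    csf = rng.standard_normal(n_volumes)
    return TimeSeriesSet(series, tr_seconds, motion6=motion6, wm_signal=wm, csf_signal=csf)


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: Pearson rho giving Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_donors(
    atlas: Atlas | int,
    gene_names: list[str],
    coupling_template: pd.Series | None = None,
    inter_donor_rho: float = 0.5,
    n_donors: int = 6,
    seed: int = 0,
    coupled_genes: list[str] | None = None,
) -> DonorExpressionSet:
    """Multi-donor regional expression with a shared latent pattern.

    Each gene has a latent regional profile; donor profiles are
    ``sqrt(rho_p) * latent + sqrt(1 - rho_p) * donor noise`` on the
    Gaussian scale, with ``rho_p`` chosen so the *population Spearman*
    correlation between any two donors equals ``inter_donor_rho``.
    If ``coupling_template`` is given, the latent pattern of the genes
    in ``coupled_genes`` (default: all genes) is the normal-scores
    transform of the template's regional values, coupling expression to
    that template's spatial layout.
    """
    if not (0 <= inter_donor_rho < 1):
        raise ValueError("inter_donor_rho must lie in [0, 1)")
    region_ids = (
        atlas.region_ids if isinstance(atlas, Atlas) else np.arange(1, int(atlas) + 1)
    )
    n_regions = len(region_ids)
    rng = np.random.default_rng(seed)
    rho_p = _spearman_to_pearson(inter_donor_rho)
    if coupling_template is not None:
        from scipy.stats import norm

        ranks = coupling_template.rank().to_numpy(float)
        template_latent = norm.ppf((ranks - 0.5) / len(ranks))
    coupled = set(coupled_genes if coupled_genes is not None else gene_names)
    frames = {}
    for donor_idx in range(n_donors):
        donor_vals = np.empty((n_regions, len(gene_names)))
        frames[f"donor{donor_idx}"] = donor_vals
    for g, gene in enumerate(gene_names):
        if coupling_template is not None and gene in coupled:
            latent = template_latent
        else:
            latent = rng.standard_normal(n_regions)
        for donor_idx in range(n_donors):
            eps = rng.standard_normal(n_regions)
            frames[f"donor{donor_idx}"][:, g] = (
                math.sqrt(rho_p) * latent + math.sqrt(1 - rho_p) * eps
            )
    blocks = []
    for donor, vals in frames.items():
        frame = pd.DataFrame(vals, columns=gene_names)
        frame.insert(0, "region_id", region_ids)
        frame.insert(0, "donor", donor)
        blocks.append(frame)
    data = pd.concat(blocks, ignore_index=True).set_index(["donor", "region_id"])
    return DonorExpressionSet(data)


def generate_clinical(
    subject_table: pd.DataFrame,
    coloc_strengths: np.ndarray,
    target_rho: float,
    seed: int,
    score_name: str = "clinical_score",
) -> pd.DataFrame:
    """Append a clinical score with a prescribed Spearman link to effect strength.

    The score is generated through a Gaussian copula on the normal
    scores of ``coloc_strengths`` so the *population* Spearman
    correlation equals ``target_rho``; controls receive NaN (scores are
    patient instruments). ``target_rho = +/-1`` reproduces the strengths'
    ranks exactly.
    """
    if abs(target_rho) > 1:
        raise ValueError("|target_rho| must be <= 1")
    patients = subject_table["group"] == "patient"
    strengths = np.asarray(coloc_strengths, dtype=float)
    if strengths.size != int(patients.sum()):
        raise ValueError(
            f"need one strength per patient: got {strengths.size}, "
            f"expected {int(patients.sum())}"
        )
    rng = np.random.default_rng(seed)
    from scipy.stats import rankdata, norm

    normal_scores = norm.ppf((rankdata(strengths) - 0.5) / strengths.size)
    if abs(target_rho) == 1:
        latent = np.sign(target_rho) * normal_scores
    else:
        rho_p = _spearman_to_pearson(target_rho)
        latent = rho_p * normal_scores + math.sqrt(1 - rho_p**2) * rng.standard_normal(
            strengths.size
        )
    out = subject_table.copy()
    out[score_name] = np.nan
    out.loc[patients, score_name] = latent
    return out


def calibrate_effect_size(
    atlas: Atlas,
    templates: TemplateMapSet,
    config: SyntheticConfig,
    target_mean_rho: float = -0.2,
    n_reps: int = 100,
    seed: int = 12345,
    beta_bracket: tuple[float, float] = (0.0, 4.0),
) -> tuple[float, dict]:
    """Monte-Carlo calibration of the planted effect size.

    Finds the ``beta`` for which the population mean patient
    co-localization Spearman rho with the planted template equals
    ``target_mean_rho`` (mean taken as the back-transformed mean Fisher
    z over patients and replicates). Uses common random numbers across
    candidate betas so the objective is a deterministic, monotone
    function of beta, solved by bisection. Returns the calibrated beta
    and a log dict recording the evaluations.
    """
    from .coloc import zscore_vs_controls, regional_data_matrix
    from scipy.optimize import brentq

    planted = config.planted_template_index
    if planted is None:
        raise ValueError("config has no planted template")
    template_rv = templates.regional.iloc[:, planted]
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)
    evaluations = []

    def mean_rho(beta: float) -> float:
        zs = []
        for rs in rep_seeds:
            cfg = SyntheticConfig(
                **{
                    **asdict(config),
                    "effect_size_beta": float(beta),
                    "seed": int(rs),
                }
            )
            subjects, maps, _ = generate_cohort(atlas, templates, cfg)
            data = regional_data_matrix(maps, atlas)
            pat = data[subjects["group"] == "patient"]
            ctl = data[subjects["group"] == "control"]
            mu, sd = ctl.mean(axis=0), ctl.std(axis=0, ddof=1)
            for i in range(len(pat)):
                z = (pat.iloc[i] - mu) / sd
                zs.append(fisher_z(spearman_rho(z.to_numpy(), template_rv.to_numpy())))
        value = float(fisher_z_inv(np.mean(zs)))
        evaluations.append({"beta": float(beta), "mean_rho": value})
        return value

    lo, hi = beta_bracket
    f_lo = mean_rho(lo) - target_mean_rho
    f_hi = mean_rho(hi) - target_mean_rho
    if f_lo * f_hi > 0:
        raise GenerationError(
            f"target mean rho {target_mean_rho} not bracketed by beta in {beta_bracket}"
        )
    beta = brentq(lambda b: mean_rho(b) - target_mean_rho, lo, hi, xtol=1e-3, rtol=1e-3)
    log = {
        "target_mean_rho": target_mean_rho,
        "n_reps": n_reps,
        "seed": seed,
        "evaluations": evaluations,
        "beta": float(beta),
    }
    return float(beta), log
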
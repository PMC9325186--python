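"""Synthetic two-cohort TMT study generator with known ground truth.

Emulates the statistical structure of a paired Barrett's-esophagus (BE) vs
adjacent-normal (ADJ) biopsy study quantified by isobaric labelling, plus
non-BE healthy controls, so the full analysis chain (normalization, paired
moderated-t, signature selection, clustering classification, GSEA, kinase
enrichment) can be exercised and validated without any external download.

Generative model, per feature f on the log2 scale:

    value = b_f + patient_effect + class_effect + technical_noise

* baseline ``b_f ~ Normal(24, 2)`` (raw intensity = 2**value);
* ``patient_effect ~ Normal(0, sigma_feature)`` drawn per (feature, patient)
  and shared by both biopsies of a patient -- it cancels in the paired
  contrast, which is exactly why the paired design helps;
* for a planted differential feature with true effect ``beta`` (random sign,
  magnitude uniform over ``effect_size_range``), the class effect is
  ``compression_factor * beta`` in BE and ``0`` in ADJ.  The single
  multiplicative ``compression_factor`` models TMT ratio compression;
* NONBE (healthy-control) samples carry a field-effect offset on the same
  differential features: ``nonbe_effect_scale * compression_factor * |beta|``
  with an independent random sign per feature.  Adjacent mucosa from BE
  patients differs from truly normal squamous tissue, but along its own
  molecular direction rather than a rescaled copy of the BE axis -- the
  independent signs keep the three class profiles non-collinear, which is
  what makes them separable by correlation clustering and gives the
  ADJ-vs-NONBE contrast real signal;
* technical noise ``~ Normal(0, sigma_f)`` per cell, where the per-feature
  noise variance is drawn from a scaled inverse-chi-square prior
  ``sigma_f^2 ~ sigma_noise^2 * variance_prior_df / chisq(variance_prior_df)``
  -- the variance heterogeneity across peptide features that empirical-Bayes
  moderation exists to handle (``variance_prior_df = inf`` recovers a single
  shared ``sigma_noise``);
* each cell is independently missing with probability
  ``logistic(missing_alpha - missing_beta * value)`` (lower-abundance
  features drop out more often);
* phosphosite localization probabilities follow a mixture: with probability
  ``loc_prob_true_mix`` uniform on (0.7, 1.0], else uniform on (0, 0.7).

Both cohorts share the planted biology (true effects, gene sets, kinases)
but have independent patients and noise, which is what makes cross-cohort
validation of a discovery-cohort signature meaningful.

All randomness flows from ``SimConfig.seed`` through named generators; the
same seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ConfigError
from .io_formats import (
    FeatureRecord,
    GeneSetCollection,
    IntensityMatrix,
    KinaseSubstrateMap,
    SampleDesign,
    canonical_site_id,
    validate_design,
)

_TMT_CHANNELS = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131N", "131C"]


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Cohort sizes default to the emulated study design: a discovery plex with
    3 BE patients (paired BE+ADJ biopsies) and 2 non-BE controls, and a
    validation plex with 2 BE patients and 3 controls; each control patient
    contributes two NONBE biopsies so every plex holds 10 specimens.
    """

    n_patients_be_discovery: int = 3
    n_patients_be_validation: int = 2
    n_patients_nonbe_discovery: int = 2
    n_patients_nonbe_validation: int = 3
    n_proteins: int = 6000
    n_phosphosites: int = 6000
    frac_differential: float = 0.01
    effect_size_range: tuple[float, float] = (2.2, 3.2)
    compression_factor: float = 0.7
    nonbe_effect_scale: float = 0.6
    sigma_feature: float = 0.3
    sigma_noise: float = 0.25
    variance_prior_df: float = 8.0
    missing_alpha: float = 3.0
    missing_beta: float = 0.3
    loc_prob_true_mix: float = 0.85
    n_genesets: int = 50
    geneset_size_range: tuple[int, int] = (10, 40)
    n_planted_sets: int = 3
    n_kinases: int = 20
    substrates_per_kinase: int = 10
    n_active_kinases: int = 3
    transcript_effect_correlation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        pos_ints = {
            "n_patients_be_discovery": self.n_patients_be_discovery,
            "n_patients_be_validation": self.n_patients_be_validation,
            "n_proteins": self.n_proteins,
            "n_phosphosites": self.n_phosphosites,
        }
        for name, v in pos_ints.items():
            if int(v) < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v}")
        if self.n_patients_nonbe_discovery < 0 or self.n_patients_nonbe_validation < 0:
            raise ConfigError("control patient counts must be non-negative")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ConfigError("frac_differential must lie in [0, 1]")
        lo, hi = self.effect_size_range
        if not (0 < lo <= hi):
            raise ConfigError("effect_size_range must satisfy 0 < low <= high")
        if not 0 < self.compression_factor <= 1:
            raise ConfigError("compression_factor must lie in (0, 1]")
        if self.sigma_feature < 0 or self.sigma_noise < 0:
            raise ConfigError("sigma_feature and sigma_noise must be non-negative")
        if not self.variance_prior_df > 0:
            raise ConfigError("variance_prior_df must be positive (may be inf)")
        if not 0.0 <= self.loc_prob_true_mix <= 1.0:
            raise ConfigError("loc_prob_true_mix must lie in [0, 1]")
        if not -1.0 <= self.transcript_effect_correlation <= 1.0:
            raise ConfigError("transcript_effect_correlation must lie in [-1, 1]")
        if self.n_planted_sets > 0 and self.frac_differential * self.n_proteins < 1:
            raise ConfigError(
                "planted gene sets requested but frac_differential * n_proteins < 1"
            )
        if self.geneset_size_range[0] < 1 or self.geneset_size_range[0] > self.geneset_size_range[1]:
            raise ConfigError("geneset_size_range must satisfy 1 <= low <= high")
        if self.geneset_size_range[1] > self.n_proteins:
            raise ConfigError("largest gene set exceeds the gene universe")
        if self.n_planted_sets > self.n_genesets:
            raise ConfigError("n_planted_sets exceeds n_genesets")
        if self.n_active_kinases > self.n_kinases:
            raise ConfigError("n_active_kinases exceeds n_kinases")
        if self.n_active_kinases > 0 and self.frac_differential * self.n_phosphosites < 1:
            raise ConfigError(
                "active kinases requested but frac_differential * n_phosphosites < 1"
            )


@dataclass
class GroundTruth:
    """Planted signal: what a correct analysis should recover."""

    differential_features: dict[str, float] = field(default_factory=dict)
    planted_sets: dict[str, int] = field(default_factory=dict)  # name -> +1/-1
    active_kinases: dict[str, int] = field(default_factory=dict)  # kinase -> +1/-1
    transcript_effects: dict[str, float] = field(default_factory=dict)
    gene_universe: list[str] = field(default_factory=list)


def _build_design(cfg: SimConfig) -> list[SampleDesign]:
    design: list[SampleDesign] = []
    for cohort, n_be, n_nonbe in (
        ("discovery", cfg.n_patients_be_discovery, cfg.n_patients_nonbe_discovery),
        ("validation", cfg.n_patients_be_validation, cfg.n_patients_nonbe_validation),
    ):
        tag = "D" if cohort == "discovery" else "V"
        n_samples = 2 * (n_be + n_nonbe)
        if n_samples > len(_TMT_CHANNELS):
            raise ConfigError(
                f"{cohort} cohort needs {n_samples} channels; a TMT plex has at most "
                f"{len(_TMT_CHANNELS)}"
            )
        chan = iter(_TMT_CHANNELS)
        for i in range(n_be):
            patient = f"{tag}BE{i + 1:02d}"
            design.append(SampleDesign(f"{patient}_BE", patient, "BE", cohort, next(chan)))
            design.append(SampleDesign(f"{patient}_ADJ", patient, "ADJ", cohort, next(chan)))
        for i in range(n_nonbe):
            patient = f"{tag}NB{i + 1:02d}"
            for rep in (1, 2):  # control patients contribute two normal biopsies
                design.append(
                    SampleDesign(f"{patient}_N{rep}", patient, "NONBE", cohort, next(chan))
                )
    validate_design(design)
    return design


def _simulate_matrix(
    features: list[FeatureRecord],
    be_effects: np.ndarray,
    nonbe_effects: np.ndarray,
    design: list[SampleDesign],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> IntensityMatrix:
    n_feat = len(features)
    samples = [d.sample_id for d in design]
    baseline = rng.normal(24.0, 2.0, size=n_feat)
    patients = sorted({d.patient_id for d in design})
    pat_idx = {p: i for i, p in enumerate(patients)}
    pat_eff = rng.normal(0.0, cfg.sigma_feature, size=(n_feat, len(patients)))
    # per-feature technical noise SD: scaled inverse-chi-square heterogeneity
    if np.isfinite(cfg.variance_prior_df):
        d0 = cfg.variance_prior_df
        sigma_f = cfg.sigma_noise * np.sqrt(d0 / rng.chisquare(d0, size=n_feat))
    else:
        sigma_f = np.full(n_feat, cfg.sigma_noise)
    class_eff = {
        "BE": be_effects,
        "ADJ": np.zeros(n_feat),
        "NONBE": nonbe_effects,
    }
    values = np.empty((n_feat, len(design)))
    for j, d in enumerate(design):
        noise = rng.normal(0.0, 1.0, size=n_feat) * sigma_f if cfg.sigma_noise > 0 else 0.0
        values[:, j] = baseline + pat_eff[:, pat_idx[d.patient_id]] + class_eff[d.tissue_class] + noise
    p_missing = expit(cfg.missing_alpha - cfg.missing_beta * values)
    mask = rng.random(values.shape) < p_missing
    raw = np.power(2.0, values)
    raw[mask] = np.nan
    return IntensityMatrix(features, samples, raw, scale="raw")


def simulate_dataset(
    config: SimConfig,
) -> tuple[
    IntensityMatrix,
    IntensityMatrix,
    list[SampleDesign],
    GeneSetCollection,
    KinaseSubstrateMap,
    GroundTruth,
]:
    """Generate (proteome, phospho, design, genesets, ksmap, truth).

    Planted differential features, gene sets and kinases are recorded in the
    returned :class:`GroundTruth`; cohorts share the planted biology but have
    independent patients and noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"GENE{i:04d}" for i in range(cfg.n_proteins)]

    # --- proteome features and planted effects ---
    prot_features = [FeatureRecord(g, g, "protein") for g in genes]
    n_diff_prot = int(round(cfg.frac_differential * cfg.n_proteins))
    diff_prot_idx = rng.choice(cfg.n_proteins, size=n_diff_prot, replace=False)
    prot_effects = np.zeros(cfg.n_proteins)
    signs = rng.choice([-1.0, 1.0], size=n_diff_prot)
    mags = rng.uniform(*cfg.effect_size_range, size=n_diff_prot)
    prot_effects[diff_prot_idx] = signs * mags

    # --- phosphosite features (unique gene/residue/position triples) ---
    residues = np.array(["S", "T", "Y"])
    seen: set[tuple[str, str, int]] = set()
    site_meta: list[tuple[str, str, int]] = []
    while len(site_meta) < cfg.n_phosphosites:
        g = genes[int(rng.integers(cfg.n_proteins))]
        res = str(residues[int(rng.choice(3, p=[0.80, 0.15, 0.05]))])
        pos = int(rng.integers(1, 1000))
        key = (g, res, pos)
        if key not in seen:
            seen.add(key)
            site_meta.append(key)
    loc_true = rng.random(cfg.n_phosphosites) < cfg.loc_prob_true_mix
    loc_prob = np.where(
        loc_true,
        rng.uniform(0.7, 1.0, size=cfg.n_phosphosites),
        rng.uniform(0.0, 0.7, size=cfg.n_phosphosites),
    )
    phos_features = [
        FeatureRecord(
            canonical_site_id(g, res, pos),
            g,
            "phosphosite",
            site_residue=res,
            site_position=pos,
            localization_prob=float(p),
        )
        for (g, res, pos), p in zip(site_meta, loc_prob)
    ]
    n_diff_phos = int(round(cfg.frac_differential * cfg.n_phosphosites))
    diff_phos_idx = rng.choice(cfg.n_phosphosites, size=n_diff_phos, replace=False)
    phos_effects = np.zeros(cfg.n_phosphosites)
    signs_p = rng.choice([-1.0, 1.0], size=n_diff_phos)
    mags_p = rng.uniform(*cfg.effect_size_range, size=n_diff_phos)
    phos_effects[diff_phos_idx] = signs_p * mags_p

    # --- design and matrices ---
    # NONBE offsets: same magnitude scale as the (compressed) BE effects but
    # independent signs, so the healthy-vs-adjacent axis is not collinear
    # with the BE-vs-adjacent axis
    c = cfg.compression_factor
    prot_nonbe = (
        cfg.nonbe_effect_scale * c * np.abs(prot_effects)
        * rng.choice([-1.0, 1.0], size=cfg.n_proteins)
    )
    phos_nonbe = (
        cfg.nonbe_effect_scale * c * np.abs(phos_effects)
        * rng.choice([-1.0, 1.0], size=cfg.n_phosphosites)
    )
    design = _build_design(cfg)
    proteome = _simulate_matrix(prot_features, c * prot_effects, prot_nonbe, design, cfg, rng)
    phospho = _simulate_matrix(phos_features, c * phos_effects, phos_nonbe, design, cfg, rng)

    # --- gene sets: planted sets draw preferentially from same-direction
    #     differential proteins, decoy sets from the whole universe ---
    genesets = GeneSetCollection()
    lo, hi = cfg.geneset_size_range
    up_pool = [genes[i] for i in diff_prot_idx if prot_effects[i] > 0]
    down_pool = [genes[i] for i in diff_prot_idx if prot_effects[i] < 0]
    planted_sets: dict[str, int] = {}
    for s in range(cfg.n_planted_sets):
        direction = 1 if s % 2 == 0 else -1
        pool = up_pool if direction > 0 else down_pool
        if not pool:
            raise ConfigError("planted gene set requested but no differential genes of that sign")
        size = int(rng.integers(lo, hi + 1))
        n_sig = min(len(pool), max(1, math.ceil(0.8 * size)))
        members = list(rng.choice(pool, size=n_sig, replace=False))
        fill = [g for g in genes if g not in set(members)]
        members += list(rng.choice(fill, size=max(0, size - n_sig), replace=False))
        name = f"PLANTED_{'UP' if direction > 0 else 'DOWN'}_{s + 1}"
        genesets.add(name, f"planted {'BE-up' if direction > 0 else 'BE-down'} pathway", members)
        planted_sets[name] = direction
    for s in range(cfg.n_genesets - cfg.n_planted_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(genes, size=size, replace=False))
        genesets.add(f"RANDOM_{s + 1:03d}", "random decoy set", members)

    # --- kinase-substrate map: active kinases draw substrates from
    #     same-direction differential sites; decoys from unaffected sites ---
    ksmap = KinaseSubstrateMap()
    active_kinases: dict[str, int] = {}
    diff_sites_up = [i for i in diff_phos_idx if phos_effects[i] > 0]
    diff_sites_down = [i for i in diff_phos_idx if phos_effects[i] < 0]
    null_sites = [i for i in range(cfg.n_phosphosites) if phos_effects[i] == 0.0]
    for k in range(cfg.n_kinases):
        kinase = f"KIN{k + 1:02d}"
        if k < cfg.n_active_kinases:
            direction = 1 if k % 2 == 0 else -1
            pool = diff_sites_up if direction > 0 else diff_sites_down
            if len(pool) < 1:
                raise ConfigError("active kinase requested but no differential sites of that sign")
            n_sub = min(len(pool), cfg.substrates_per_kinase)
            idx = rng.choice(pool, size=n_sub, replace=False)
            active_kinases[kinase] = direction
        else:
            idx = rng.choice(null_sites, size=min(len(null_sites), cfg.substrates_per_kinase), replace=False)
        for i in idx:
            g, res, pos = site_meta[i]
            ksmap.add(kinase, g, f"{res}{pos}")

    truth = GroundTruth(
        differential_features={
            **{genes[i]: float(prot_effects[i]) for i in sorted(diff_prot_idx)},
            **{
                phos_features[i].feature_id: float(phos_effects[i])
                for i in sorted(diff_phos_idx)
            },
        },
        planted_sets=planted_sets,
        active_kinases=active_kinases,
        gene_universe=genes,
    )
    return proteome, phospho, design, genesets, ksmap, truth


def simulate_transcriptome(
    truth: GroundTruth,
    n_be: int = 7,
    n_normal: int = 7,
    correlation: float = 0.8,
    seed: int = 0,
    sigma_noise: float = 0.5,
    sigma_patient: float = 0.3,
) -> tuple[IntensityMatrix, dict[str, str]]:
    """Generate a correlated mRNA cohort for cross-omics signature projection.

    For each gene with a (pre-compression) protein effect ``beta``, the
    transcript effect is ``rho*beta + sqrt(1-rho^2)*eps`` with ``eps`` drawn
    independently at a scale matching the spread of the protein effects, so
    transcript and protein effect vectors share variance but correlate at
    ``rho``.  Non-differential genes stay null at the mRNA level.  The default
    7 BE vs 7 matched-normal design mirrors a small paired expression cohort.
    Transcript effects are recorded into ``truth.transcript_effects``.
    """
    if not -1.0 <= correlation <= 1.0:
        raise ConfigError("correlation must lie in [-1, 1]")
    if not truth.gene_universe:
        raise ConfigError("ground truth lacks a gene universe")
    rng = np.random.default_rng(seed)
    genes = truth.gene_universe
    prot_eff = np.array([truth.differential_features.get(g, 0.0) for g in genes])
    diff_mask = prot_eff != 0.0
    scale = float(np.std(prot_eff[diff_mask])) if diff_mask.sum() > 1 else 1.0
    scale = scale if scale > 0 else 1.0
    eps = rng.normal(0.0, scale, size=len(genes))
    tx_eff = np.where(
        diff_mask,
        correlation * prot_eff + math.sqrt(max(0.0, 1.0 - correlation**2)) * eps,
        0.0,
    )
    truth.transcript_effects = {g: float(e) for g, e in zip(genes, tx_eff) if e != 0.0}

    features = [FeatureRecord(g, g, "protein") for g in genes]
    samples: list[str] = []
    labels: dict[str, str] = {}
    baseline = rng.normal(8.0, 2.0, size=len(genes))
    values = []
    n_pat = max(n_be, n_normal)
    pat_eff = rng.normal(0.0, sigma_patient, size=(len(genes), n_pat))
    for i in range(n_be):
        sid = f"T{i + 1:02d}_BE"
        samples.append(sid)
        labels[sid] = "BE"
        values.append(baseline + pat_eff[:, i] + tx_eff + rng.normal(0.0, sigma_noise, len(genes)))
    for i in range(n_normal):
        sid = f"T{i + 1:02d}_N"
        samples.append(sid)
        labels[sid] = "NORMAL"
        values.append(baseline + pat_eff[:, i] + rng.normal(0.0, sigma_noise, len(genes)))
    expr = IntensityMatrix(features, samples, np.column_stack(values), scale="log2")
    return expr, labels


def null_config(**overrides) -> SimConfig:
    """A convenience configuration with no planted signal anywhere."""
    base = dict(
        frac_differential=0.0,
        n_planted_sets=0,
        n_active_kinases=0,
    )
    base.update(overrides)
    return SimConfig(**base)
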
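"""Synthetic cohort generator.

Emulates the joint structure the analysis pipeline assumes for a cohort
of young women: a nine-part macronutrient composition drawn from a
logistic-normal law on additive log-ratio (ALR) coordinates, a
three-level community state type (CST) outcome generated by a
multinomial logit on the ALRs and covariates, CST-conditional taxa
counts from a Dirichlet-multinomial around group centroids, metabolites
tied linearly to taxa-cluster abundances, and item-level food intakes
that reproduce each subject's composition through the FFQ module.

Defaults are calibrated to the study conditions of a 113-subject
cohort: group prevalences 54 / 29.2 / 16.8 % for I-II-V / III / IV,
macronutrient means and dispersions from the cohort's dietary
descriptives, L. crispatus averaging 70.3 / 10.5 / 0.2 % and L. iners
0.8 / 71.2 / 6.8 % across the three groups, and library sizes on
[6627, 20000] reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ffq as ffq_mod
from .coda import GROUP_LABELS, PARTS

#: ALR numerator order used throughout (denominator ST).
ALR_PARTS = ("AP", "VP", "SS", "SFA", "MUFA", "LA", "ALA", "PUFA")

#: Covariate column order expected by the effect matrix after the 8 ALRs.
COVARIATES = (
    "energy_kcal",
    "fiber_g",
    "alcohol_au",
    "age",
    "bmi",
    "marital_status",
    "hormonal_contraception",
)

#: Cohort mean and SD of each part as percent of energy (dietary descriptives).
PART_MEAN_PCT = {
    "AP": 10.54, "VP": 5.78, "SS": 19.61, "ST": 28.02, "SFA": 12.08,
    "MUFA": 18.58, "LA": 4.79, "ALA": 0.43, "PUFA": 0.18,
}
PART_SD_PCT = {
    "AP": 3.28, "VP": 1.13, "SS": 4.85, "ST": 5.76, "SFA": 2.23,
    "MUFA": 3.25, "LA": 1.14, "ALA": 0.15, "PUFA": 0.11,
}

#: Taxon list shared by centroids, counts and metabolite clusters.
TAXA = (
    "Lactobacillus crispatus",
    "Lactobacillus iners",
    "Lactobacillus gasseri",
    "Lactobacillus jensenii",
    "Gardnerella vaginalis",
    "Prevotella spp.",
    "Streptococcus spp.",
    "Fannyhessea vaginae",
    "Sneathia sanguinegens",
    "Ureaplasma spp.",
    "Megasphaera spp.",
    "Finegoldia spp.",
    "Anaerococcus spp.",
    "Haemophilus spp.",
    "Other",
)

#: Taxa clusters driving metabolite levels (mirrors the indicator groups).
DEFAULT_CLUSTER_TAXA = {
    "cluster_1": ["Lactobacillus crispatus", "Lactobacillus jensenii", "Lactobacillus gasseri"],
    "cluster_2": [
        "Gardnerella vaginalis",
        "Prevotella spp.",
        "Streptococcus spp.",
        "Fannyhessea vaginae",
        "Sneathia sanguinegens",
        "Ureaplasma spp.",
        "Megasphaera spp.",
    ],
    "cluster_3": ["Finegoldia spp.", "Anaerococcus spp.", "Haemophilus spp."],
    "cluster_4": ["Lactobacillus iners"],
}

_METABOLITE_CLUSTER = {
    "Lactate": "cluster_1",
    "4-Hydroxyphenyllactate": "cluster_1",
    "Glutamate": "cluster_1",
    "Leucine": "cluster_1",
    "Isoleucine": "cluster_1",
    "Acetate": "cluster_2",
    "Propionate": "cluster_2",
    "Proline": "cluster_2",
    "Glucose": "cluster_2",
    "2,3-Butanediol": "cluster_2",
    "3-Hydroxyisovalerate": "cluster_3",
    "Isopropanol": "cluster_3",
    "O-Acetylcholine": "cluster_4",
    "sn-Glycero-3-phosphocholine": "cluster_4",
}


def default_comp_mean() -> np.ndarray:
    """ALR means (denominator ST) implied by the cohort %E means."""
    st = PART_MEAN_PCT["ST"]
    return np.array([np.log(PART_MEAN_PCT[p] / st) for p in ALR_PARTS])


def default_comp_cov() -> np.ndarray:
    """Diagonal ALR covariance from the %E dispersions (delta method).

    var(ln x_j - ln ST) ~ (sd_j/mean_j)^2 + (sd_ST/mean_ST)^2 treating
    parts as independent on the raw scale; a deliberately simple
    dispersion model, overridable in the config.
    """
    cv_st2 = (PART_SD_PCT["ST"] / PART_MEAN_PCT["ST"]) ** 2
    var = [
        (PART_SD_PCT[p] / PART_MEAN_PCT[p]) ** 2 + cv_st2
        for p in ALR_PARTS
    ]
    return np.diag(var)


def default_effect_matrix() -> np.ndarray:
    """2 x (8 + 7) coefficients for outcomes III and IV vs I-II-V.

    Non-zero defaults reproduce the reported diet effects: ALA balance
    -5.320 on CST III, animal-protein balance +2.702 and alcohol (per
    AU/day) +1.570 on CST IV; everything else null.
    """
    eff = np.zeros((2, len(ALR_PARTS) + len(COVARIATES)))
    eff[0, ALR_PARTS.index("ALA")] = -5.320
    eff[1, ALR_PARTS.index("AP")] = 2.702
    eff[1, len(ALR_PARTS) + COVARIATES.index("alcohol_au")] = 1.570
    return eff


def default_taxa_centroids() -> pd.DataFrame:
    """Per-group mean relative-abundance centroids (groups x taxa)."""
    c = pd.DataFrame(0.0, index=list(GROUP_LABELS), columns=list(TAXA))
    c.loc["I-II-V"] = pd.Series(
        {
            "Lactobacillus crispatus": 0.703,
            "Lactobacillus iners": 0.008,
            "Lactobacillus gasseri": 0.100,
            "Lactobacillus jensenii": 0.060,
            "Gardnerella vaginalis": 0.030,
            "Prevotella spp.": 0.020,
            "Streptococcus spp.": 0.015,
            "Fannyhessea vaginae": 0.010,
            "Sneathia sanguinegens": 0.005,
            "Ureaplasma spp.": 0.010,
            "Megasphaera spp.": 0.004,
            "Finegoldia spp.": 0.010,
            "Anaerococcus spp.": 0.010,
            "Haemophilus spp.": 0.005,
        }
    )
    c.loc["III"] = pd.Series(
        {
            "Lactobacillus crispatus": 0.105,
            "Lactobacillus iners": 0.712,
            "Lactobacillus gasseri": 0.030,
            "Lactobacillus jensenii": 0.020,
            "Gardnerella vaginalis": 0.035,
            "Prevotella spp.": 0.020,
            "Streptococcus spp.": 0.012,
            "Fannyhessea vaginae": 0.009,
            "Sneathia sanguinegens": 0.005,
            "Ureaplasma spp.": 0.010,
            "Megasphaera spp.": 0.005,
            "Finegoldia spp.": 0.008,
            "Anaerococcus spp.": 0.008,
            "Haemophilus spp.": 0.004,
        }
    )
    c.loc["IV"] = pd.Series(
        {
            "Lactobacillus crispatus": 0.002,
            "Lactobacillus iners": 0.068,
            "Lactobacillus gasseri": 0.010,
            "Lactobacillus jensenii": 0.005,
            "Gardnerella vaginalis": 0.250,
            "Prevotella spp.": 0.150,
            "Streptococcus spp.": 0.075,
            "Fannyhessea vaginae": 0.080,
            "Sneathia sanguinegens": 0.050,
            "Ureaplasma spp.": 0.040,
            "Megasphaera spp.": 0.060,
            "Finegoldia spp.": 0.050,
            "Anaerococcus spp.": 0.050,
            "Haemophilus spp.": 0.030,
        }
    )
    c = c.fillna(0.0)
    c["Other"] = 1.0 - c.drop(columns="Other").sum(axis=1)
    return c


def default_metabolite_loadings() -> pd.DataFrame:
    """Clusters x metabolites loading matrix (block-diagonal by design)."""
    loadings = pd.DataFrame(
        0.0, index=list(DEFAULT_CLUSTER_TAXA), columns=list(_METABOLITE_CLUSTER)
    )
    for metabolite, cluster in _METABOLITE_CLUSTER.items():
        loadings.loc[cluster, metabolite] = 3.0
    loadings.loc["cluster_1", "Lactate"] = 5.0
    return loadings


#: Covariate generating distributions; all overridable via CohortConfig.
DEFAULT_COVARIATE_SPEC = {
    "age": {"dist": "normal_int", "mean": 21.5, "sd": 2.5, "min": 19, "max": 30},
    "bmi": {"dist": "normal", "mean": 21.26, "sd": 3.15, "min": 15.0, "max": 35.0},
    "marital_status": {"dist": "bernoulli", "p": 0.115},
    "hormonal_contraception": {"dist": "bernoulli", "p": 0.2566},
    "pss": {"dist": "normal_int", "mean": 21.0, "sd": 5.0, "min": 0, "max": 40},
    "energy_kcal": {"dist": "normal", "mean": 1975.1, "sd": 639.7, "min": 500.0, "max": 3500.0},
    "fiber_g": {"dist": "normal", "mean": 22.633, "sd": 9.52, "min": 2.0, "max": 60.0},
    "alcohol_g": {"dist": "zero_lognormal", "p_zero": 0.0796, "log_mean": 1.0, "log_sd": 1.1},
}


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_subjects: int = 113
    cst_group_probs: np.ndarray = field(
        default_factory=lambda: np.array([0.54, 0.292, 0.168])
    )
    comp_mean: np.ndarray = field(default_factory=default_comp_mean)
    comp_cov: np.ndarray = field(default_factory=default_comp_cov)
    effect_matrix: np.ndarray = field(default_factory=default_effect_matrix)
    covariate_spec: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SPEC))
    taxa_centroids: pd.DataFrame = field(default_factory=default_taxa_centroids)
    dirichlet_concentration: float = 30.0
    depth_range: tuple[int, int] = (6627, 20000)
    metabolite_loadings: pd.DataFrame = field(default_factory=default_metabolite_loadings)
    cluster_taxa: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_TAXA))
    metabolite_baseline: float = 0.2
    noise_sd: float = 0.3
    include_ffq: bool = True
    seed: int = 0

    def validate(self) -> None:
        probs = np.asarray(self.cst_group_probs, dtype=float)
        if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-12 or (probs < 0).any():
            raise ValueError("cst_group_probs must be a 3-vector summing to 1 within 1e-12")
        cov = np.asarray(self.comp_cov, dtype=float)
        if cov.shape != (8, 8) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("comp_cov must be a symmetric 8x8 matrix")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10 * max(1.0, eig.max()):
            raise ValueError(f"comp_cov is not positive semi-definite (eigenvalue {eig.min():.3g})")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range must satisfy 1 <= min <= max")


@dataclass
class CohortDataset:
    """Aligned per-subject tables of a generated (or loaded) cohort."""

    subject_ids: pd.Index
    composition: pd.DataFrame
    covariates: pd.DataFrame
    nutrient_totals: pd.DataFrame
    cst_group: pd.Series
    taxa_counts: pd.DataFrame
    metabolites: pd.DataFrame
    ffq_items: pd.DataFrame | None = None
    config: CohortConfig | None = None


def simulate_composition(n: int, comp_mean, comp_cov, seed=None) -> pd.DataFrame:
    """Draw n nine-part compositions from a logistic-normal law.

    The 8-vector ``comp_mean`` and 8x8 ``comp_cov`` parameterize a
    multivariate normal on the ALR coordinates ln(part/ST) in the order
    (AP, VP, SS, SFA, MUFA, LA, ALA, PUFA); the inverse ALR maps the
    draws back to strictly positive simplex rows.
    """
    mean = np.asarray(comp_mean, dtype=float)
    if mean.ndim == 0:
        mean = np.full(8, float(mean))
    cov = np.asarray(comp_cov, dtype=float)
    if cov.ndim == 0:
        cov = float(cov) * np.eye(8)
    if mean.shape != (8,) or cov.shape != (8, 8):
        raise ValueError("comp_mean must be an 8-vector and comp_cov 8x8")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("comp_cov must be symmetric")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10 * max(1.0, abs(eig).max()):
        raise ValueError(f"comp_cov is not positive semi-definite (eigenvalue {eig.min():.3g})")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(mean, cov, size=n, method="eigh")
    # inverse ALR: exponentiate numerators, denominator ST gets 1
    expz = np.exp(z)
    total = 1.0 + expz.sum(axis=1)
    comp = np.empty((n, 9))
    alr_idx = {p: i for i, p in enumerate(ALR_PARTS)}
    for j, part in enumerate(PARTS):
        if part == "ST":
            comp[:, j] = 1.0 / total
        else:
            comp[:, j] = expz[:, alr_idx[part]] / total
    return pd.DataFrame(comp, columns=list(PARTS))


def simulate_cst_labels(
    alr_matrix, covariates, effect_matrix, baseline_probs, seed=None
) -> pd.Series:
    """Draw three-level CST labels from a multinomial logit.

    Predictors (8 ALR columns then covariates) are centered at their
    sample means; intercepts are the log-odds implied by
    ``baseline_probs``, so the configured baseline prevalences hold at
    the covariate means.  Outcome rows of ``effect_matrix``: III then IV
    against the I-II-V reference.
    """
    alr = np.asarray(alr_matrix, dtype=float)
    cov = np.asarray(covariates, dtype=float) if covariates is not None else np.empty((len(alr), 0))
    x = np.hstack([alr, cov])
    eff = np.asarray(effect_matrix, dtype=float)
    if eff.shape != (2, x.shape[1]):
        raise ValueError(
            f"effect_matrix has shape {eff.shape}, expected (2, {x.shape[1]}) "
            "for the ALR block plus covariates"
        )
    probs = np.asarray(baseline_probs, dtype=float)
    if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("baseline_probs must be a 3-vector summing to 1")
    xc = x - x.mean(axis=0)
    eta = np.zeros((len(x), 3))
    eta[:, 1] = np.log(probs[1] / probs[0]) + xc @ eff[0]
    eta[:, 2] = np.log(probs[2] / probs[0]) + xc @ eff[1]
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    u = rng.random(len(x))
    codes = (u[:, None] >= p.cumsum(axis=1)).sum(axis=1)
    index = alr_matrix.index if hasattr(alr_matrix, "index") else pd.RangeIndex(len(x))
    return pd.Series([GROUP_LABELS[c] for c in codes], index=index, name="cst_group")


def simulate_taxa_counts(
    labels, taxa_centroids: pd.DataFrame, dirichlet_concentration: float,
    depth_range: tuple[int, int], seed=None,
) -> pd.DataFrame:
    """Dirichlet-multinomial taxa counts around per-group centroids.

    Each subject's relative abundances are Dirichlet with parameter
    ``concentration x centroid[group]``; counts are multinomial at a
    library size drawn uniformly from ``depth_range``.
    """
    cent = taxa_centroids.to_numpy(dtype=float)
    if (cent < 0).any() or not np.allclose(cent.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each centroid row must lie on the simplex")
    if dirichlet_concentration <= 0:
        raise ValueError("dirichlet_concentration must be positive")
    labels = pd.Series(np.asarray(labels, dtype=object)).astype(str)
    unknown = sorted(set(labels) - set(map(str, taxa_centroids.index)))
    if unknown:
        raise ValueError(f"labels without a centroid: {unknown}")
    rng = np.random.default_rng(seed)
    lo, hi = depth_range
    n = len(labels)
    counts = np.zeros((n, cent.shape[1]), dtype=np.int64)
    row_of = {str(g): i for i, g in enumerate(taxa_centroids.index)}
    for i, g in enumerate(labels):
        alpha = dirichlet_concentration * cent[row_of[g]]
        # Dirichlet via gammas tolerates zero centroid entries (mass 0)
        gam = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-300)), 0.0)
        rel = gam / gam.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts[i] = rng.multinomial(depth, rel)
    return pd.DataFrame(counts, columns=list(taxa_centroids.columns))


def simulate_metabolites(
    taxa_counts: pd.DataFrame,
    metabolite_loadings: pd.DataFrame,
    noise_sd: float,
    seed=None,
    cluster_taxa: dict | None = None,
    baseline: float = 0.2,
) -> pd.DataFrame:
    """Metabolite levels as linear functions of taxa-cluster abundance.

    metabolite_j = baseline + loading[c, j] * (summed relative abundance
    of cluster c's taxa) + Gaussian noise, truncated at zero.
    """
    cluster_taxa = cluster_taxa if cluster_taxa is not None else DEFAULT_CLUSTER_TAXA
    unknown = sorted(set(metabolite_loadings.index) - set(cluster_taxa))
    if unknown:
        raise ValueError(f"loadings reference undefined clusters: {unknown}")
    rel = taxa_counts.div(taxa_counts.sum(axis=1), axis=0)
    activity = pd.DataFrame(index=taxa_counts.index, columns=list(metabolite_loadings.index), dtype=float)
    for cluster in metabolite_loadings.index:
        taxa = [t for t in cluster_taxa[cluster] if t in rel.columns]
        if not taxa:
            raise ValueError(f"cluster {cluster!r} has no taxa present in the count table")
        activity[cluster] = rel[taxa].sum(axis=1)
    levels = baseline + activity.to_numpy() @ metabolite_loadings.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        levels = levels + rng.normal(0.0, noise_sd, size=levels.shape)
    levels = np.clip(levels, 0.0, None)
    return pd.DataFrame(levels, index=taxa_counts.index, columns=list(metabolite_loadings.columns))


def _simulate_covariates(n: int, spec: dict, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, s in spec.items():
        dist = s["dist"]
        if dist == "normal":
            v = rng.normal(s["mean"], s["sd"], n)
            v = np.clip(v, s.get("min", -np.inf), s.get("max", np.inf))
        elif dist == "normal_int":
            v = np.round(rng.normal(s["mean"], s["sd"], n))
            v = np.clip(v, s.get("min", -np.inf), s.get("max", np.inf))
        elif dist == "bernoulli":
            v = (rng.random(n) < s["p"]).astype(float)
        elif dist == "zero_lognormal":
            v = np.where(
                rng.random(n) < s["p_zero"],
                0.0,
                rng.lognormal(s["log_mean"], s["log_sd"], n),
            )
        else:
            raise ValueError(f"unknown covariate distribution {dist!r} for {name!r}")
        cols[name] = v
    return pd.DataFrame(cols)


def _backfill_ffq(composition, energy, fiber, alcohol) -> pd.DataFrame:
    """Item intakes (g/day) whose derived nutrients reproduce the inputs.

    Uses the bundled one-source-per-component food composition table:
    grams of each part follow from its energy share (Atwater factors)
    after removing alcohol energy, then invert the per-100 g contents.
    """
    fct = ffq_mod.synthetic_fct()
    e9 = np.maximum(np.asarray(energy, float) - ffq_mod.ATWATER["alcohol"] * np.asarray(alcohol, float), 1.0)
    items = {}
    source_of = {"AP": "beef", "VP": "soy", "SS": "table sugar", "ST": "bread",
                 "SFA": "butter", "MUFA": "olive oil", "LA": "sunflower oil",
                 "ALA": "walnuts", "PUFA": "fish oil"}
    for part, item in source_of.items():
        grams = composition[part].to_numpy() * e9 / ffq_mod.ATWATER[ffq_mod.PART_CLASS[part]]
        items[item] = grams * 100.0 / fct.loc[item, part]
    items["wheat bran"] = np.asarray(fiber, float) * 100.0 / fct.loc["wheat bran", "fiber_g"]
    items["wine"] = np.asarray(alcohol, float) * 100.0 / fct.loc["wine", "alcohol_g"]
    return pd.DataFrame(items, index=composition.index)


def generate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Generate a full aligned cohort dataset from a config.

    Composition, covariates, CST labels, taxa counts, metabolites and
    (optionally) FFQ item intakes all share one subject index; identical
    config and seed give identical output.
    """
    config = config if config is not None else CohortConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_comp, s_cov, s_lab, s_taxa, s_met = ss.spawn(5)

    comp = simulate_composition(config.n_subjects, config.comp_mean, config.comp_cov, seed=s_comp)
    covars = _simulate_covariates(config.n_subjects, config.covariate_spec, np.random.default_rng(s_cov))
    au, category = ffq_mod.alcohol_units(covars["alcohol_g"])
    covars["alcohol_au"] = au

    alr = np.log(comp[list(ALR_PARTS)].to_numpy() / comp["ST"].to_numpy()[:, None])
    alr = pd.DataFrame(alr, index=comp.index, columns=[f"ln({p}/ST)" for p in ALR_PARTS])
    labels = simulate_cst_labels(
        alr, covars[list(COVARIATES)], config.effect_matrix, config.cst_group_probs, seed=s_lab
    )
    taxa = simulate_taxa_counts(
        labels, config.taxa_centroids, config.dirichlet_concentration,
        config.depth_range, seed=s_taxa,
    )
    metab = simulate_metabolites(
        taxa, config.metabolite_loadings, config.noise_sd, seed=s_met,
        cluster_taxa=config.cluster_taxa, baseline=config.metabolite_baseline,
    )

    ids = pd.Index([f"S{i + 1:04d}" for i in range(config.n_subjects)], name="subject")
    for frame in (comp, covars, alr, taxa, metab):
        frame.index = ids
    labels.index = ids

    nutrient_totals = pd.DataFrame(
        {
            "energy_kcal": covars["energy_kcal"],
            "fiber_g": covars["fiber_g"],
            "alcohol_g": covars["alcohol_g"],
            "alcohol_au": covars["alcohol_au"],
            "alcohol_category": pd.Series(np.asarray(category), index=ids),
        },
        index=ids,
    )
    covariate_table = covars[["age", "bmi", "marital_status", "hormonal_contraception", "pss"]]

    ffq_items = None
    if config.include_ffq:
        ffq_items = _backfill_ffq(
            comp, covars["energy_kcal"], covars["fiber_g"], covars["alcohol_g"]
        )

    return CohortDataset(
        subject_ids=ids,
        composition=comp,
        covariates=covariate_table,
        nutrient_totals=nutrient_totals,
        cst_group=labels,
        taxa_counts=taxa,
        metabolites=metab,
        ffq_items=ffq_items,
        config=config,
    )


_FLOAT_FMT = "%.12g"


def _config_manifest(config: CohortConfig) -> dict:
    d = asdict(config)
    for key, value in list(d.items()):
        if isinstance(value, np.ndarray):
            d[key] = value.tolist()
        elif isinstance(value, pd.DataFrame):
            d[key] = {"index": list(map(str, value.index)),
                      "columns": list(map(str, value.columns)),
                      "values": value.to_numpy().tolist()}
        elif isinstance(value, tuple):
            d[key] = list(value)
    return d


def write_cohort(dataset: CohortDataset, out_dir) -> Path:
    """Serialize a cohort as a directory of TSV tables plus a YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "composition.tsv": dataset.composition,
        "covariates.tsv": dataset.covariates,
        "nutrient_totals.tsv": dataset.nutrient_totals,
        "taxa_counts.tsv": dataset.taxa_counts,
        "metabolites.tsv": dataset.metabolites,
        "cst_group.tsv": dataset.cst_group.to_frame(),
    }
    if dataset.ffq_items is not None:
        tables["ffq_items.tsv"] = dataset.ffq_items
    for name, table in tables.items():
        table.to_csv(out / name, sep="\t", float_format=_FLOAT_FMT)
    manifest = {"tables": sorted(tables)}
    if dataset.config is not None:
        manifest["config"] = _config_manifest(dataset.config)
        manifest["seed"] = dataset.config.seed
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def read_cohort(in_dir) -> CohortDataset:
    """Load a cohort directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    read = lambda name: pd.read_csv(src / name, sep="\t", index_col=0)
    ffq_path = src / "ffq_items.tsv"
    return CohortDataset(
        subject_ids=read("composition.tsv").index,
        composition=read("composition.tsv"),
        covariates=read("covariates.tsv"),
        nutrient_totals=read("nutrient_totals.tsv"),
        cst_group=read("cst_group.tsv")["cst_group"],
        taxa_counts=read("taxa_counts.tsv"),
        metabolites=read("metabolites.tsv"),
        ffq_items=read("ffq_items.tsv") if ffq_path.exists() else None,
        config=None,
    )
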
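"""Vaginal microbiota table processing.

Count-table utilities (rarefaction, alpha diversity), nearest-centroid
community state type (CST) assignment by Yue-Clayton similarity,
three-level CST grouping, indicator species analysis with a permutation
null, Bray-Curtis distances and PERMANOVA.

CSTs I, II, III and V are dominated by single Lactobacillus species
(L. crispatus, L. gasseri, L. iners, L. jensenii respectively); CST IV
is a polymicrobial anaerobe-rich state subdivided into IV-A/B/C.  For
association analyses the CSTs are collapsed to three groups:
"I-II-V" (protective lactobacilli), "III" (L. iners) and "IV".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .coda import GROUP_LABELS

__all__ = [
    "relative_abundance",
    "rarefy",
    "alpha_diversity",
    "assign_cst",
    "assign_cst_table",
    "group_cst",
    "indicator_species",
    "bray_curtis",
    "permanova",
    "alpha_group_test",
    "synthetic_centroids",
    "read_centroids",
    "CSTAssignment",
    "IndicatorResult",
    "PermanovaResult",
]

_MAJOR_CST = {"I": "I-II-V", "II": "I-II-V", "V": "I-II-V", "III": "III", "IV": "IV"}


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a samples x taxa count table to relative abundances."""
    sums = counts.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("samples with zero total count cannot be normalized")
    return counts.div(sums, axis=0)


def rarefy(counts: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample every sample to a fixed depth without replacement.

    Samples whose total is below ``depth`` are dropped with a warning
    naming them.  Each retained row sums exactly to ``depth``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = counts.sum(axis=1)
    shallow = totals.index[totals < depth]
    if len(shallow):
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {depth}: "
            f"{list(map(str, shallow))}",
            UserWarning,
            stacklevel=2,
        )
    kept = counts.loc[totals >= depth]
    rng = np.random.default_rng(seed)
    out = np.empty(kept.shape, dtype=np.int64)
    arr = kept.to_numpy().astype(np.int64)
    for i, row in enumerate(arr):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)


def _shannon(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(counts, metric: str = "shannon", base: float = 2.0):
    """Alpha diversity of one sample (1-D) or every sample of a table.

    Metrics: ``shannon`` (base-2 by default), ``chao1`` (bias-corrected:
    S_obs + F1(F1-1)/(2(F2+1)) with singleton/doubleton counts F1/F2)
    and ``observed`` (count of taxa with positive abundance).
    """
    if metric not in {"shannon", "chao1", "observed"}:
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(counts, pd.DataFrame):
        return counts.apply(
            lambda row: alpha_diversity(row.to_numpy(), metric=metric, base=base), axis=1
        ).rename(metric)
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero sample has undefined diversity")
    if metric == "observed":
        return int((arr > 0).sum())
    if metric == "shannon":
        return _shannon(arr / total, base)
    return _chao1(arr)


@dataclass
class CSTAssignment:
    label: str
    similarity: float
    similarities: pd.Series
    tied: list


def _yue_clayton(p: np.ndarray, q: np.ndarray) -> float:
    cross = float((p * q).sum())
    denom = float((p * p).sum() + (q * q).sum() - cross)
    return cross / denom if denom > 0 else 0.0


def _align_to_centroids(profile: pd.Series, centroids: pd.DataFrame) -> np.ndarray:
    """Map a profile onto the centroid taxon list, pooling extras into 'Other'."""
    taxa = list(centroids.columns)
    vec = np.zeros(len(taxa))
    lookup = {t: i for i, t in enumerate(taxa)}
    other = lookup.get("Other")
    for taxon, value in profile.items():
        i = lookup.get(taxon, other)
        if i is not None:
            vec[i] += value
    return vec


def assign_cst(profile: pd.Series, centroids: pd.DataFrame) -> CSTAssignment:
    """Nearest-centroid CST assignment by Yue-Clayton theta.

    ``theta = sum(p*q) / (sum(p^2) + sum(q^2) - sum(p*q))`` between the
    (closed) sample profile and each centroid; the argmax centroid wins,
    ties broken by lexicographic centroid label and reported in ``tied``.
    Counts and relative abundances give identical labels (the profile is
    closed internally); profile taxa absent from the centroid list are
    pooled into "Other" when the centroids carry that column.
    """
    crows = centroids.to_numpy(dtype=float)
    if (crows < 0).any() or not np.allclose(crows.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each centroid must be a simplex vector")
    vec = _align_to_centroids(profile, centroids)
    if (vec < 0).any() or vec.sum() <= 0:
        raise ValueError("profile must be non-negative with positive total")
    vec = vec / vec.sum()
    thetas = pd.Series(
        [_yue_clayton(vec, crows[i]) for i in range(crows.shape[0])],
        index=centroids.index,
        name="theta",
    )
    best = thetas.max()
    tied = sorted(thetas.index[np.isclose(thetas.to_numpy(), best, rtol=0, atol=1e-12)])
    return CSTAssignment(label=tied[0], similarity=float(best), similarities=thetas, tied=tied)


def assign_cst_table(table: pd.DataFrame, centroids: pd.DataFrame) -> pd.DataFrame:
    """Assign every sample of a table; returns label, theta and tie count."""
    rows = []
    for sid, profile in table.iterrows():
        a = assign_cst(profile, centroids)
        rows.append({"sample": sid, "cst": a.label, "theta": a.similarity, "n_tied": len(a.tied)})
    return pd.DataFrame(rows).set_index("sample")


def group_cst(label: str) -> str:
    """Collapse a CST or sub-CST label to the three-level grouping.

    I, II, V (and sub-CSTs such as I-A) -> "I-II-V"; III -> "III";
    IV-A/B/C -> "IV".
    """
    major = str(label).strip().split("-")[0]
    if major not in _MAJOR_CST:
        raise ValueError(f"unrecognized CST label {label!r}")
    return _MAJOR_CST[major]


@dataclass
class IndicatorResult:
    """Indicator species analysis output.

    ``stats``: per taxon the best group, IndVal (0-100) and permutation
    p-value; ``A``/``B``: per taxon x group specificity (share of the
    between-group mean abundance) and fidelity (occurrence fraction).
    """

    stats: pd.DataFrame
    A: pd.DataFrame
    B: pd.DataFrame


def _indval_components(x: np.ndarray, onehot: np.ndarray):
    counts = onehot.sum(axis=0)
    group_mean = (onehot.T @ x) / counts[:, None]
    denom = group_mean.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, group_mean / np.where(denom > 0, denom, 1.0), 0.0)
    b = (onehot.T @ (x > 0)) / counts[:, None]
    return a, b


def indicator_species(
    table: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> IndicatorResult:
    """IndVal indicator species analysis with a permutation null.

    For taxon t and group g, specificity A = mean abundance in g divided
    by the sum of group means, fidelity B = fraction of g's samples where
    t is present; IndVal_t = 100 * max_g(A*B).  The p-value is the
    fraction of label permutations reaching the observed IndVal, with the
    add-one correction (1 + hits) / (1 + n_perm); with ``exact=True`` all
    distinct label assignments are enumerated instead (small designs
    only) and p is the plain enumeration fraction.
    """
    groups = pd.Series(np.asarray(groups, dtype=object), index=table.index).astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if not exact and n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    x = table.to_numpy(dtype=float)
    codes = np.array([levels.index(g) for g in groups])
    onehot = np.eye(len(levels))[codes]
    a, b = _indval_components(x, onehot)
    iv_by_group = 100.0 * a * b
    best_idx = iv_by_group.argmax(axis=0)
    observed = iv_by_group.max(axis=0)

    if exact:
        hits = np.zeros_like(observed)
        total = 0
        for perm in set(itertools.permutations(codes.tolist())):
            oh = np.eye(len(levels))[list(perm)]
            pa, pb = _indval_components(x, oh)
            hits += (100.0 * pa * pb).max(axis=0) >= observed - 1e-12
            total += 1
        pvals = hits / total
    else:
        rng = np.random.default_rng(seed)
        hits = np.zeros_like(observed)
        for _ in range(n_perm):
            oh = onehot[rng.permutation(len(codes))]
            pa, pb = _indval_components(x, oh)
            hits += (100.0 * pa * pb).max(axis=0) >= observed - 1e-12
        pvals = (1.0 + hits) / (1.0 + n_perm)

    stats = pd.DataFrame(
        {
            "group": [levels[i] for i in best_idx],
            "indval": observed,
            "p": pvals,
        },
        index=table.columns,
    )
    A = pd.DataFrame(a.T, index=table.columns, columns=levels)
    B = pd.DataFrame(b.T, index=table.columns, columns=levels)
    return IndicatorResult(stats=stats, A=A, B=B)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distance matrix of a relative-abundance table.

    For rows on the simplex, d(i, j) = 1 - sum_k min(p_ik, p_jk).
    """
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative abundances")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("bray_curtis expects a relative-abundance table (rows sum to 1)")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p: float
    n_perm: int
    n_groups: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm) under random
    relabelling of the samples.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    groups = pd.Series(np.asarray(groups, dtype=object), index=dist.index).astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    codes = np.array([levels.index(g) for g in groups])
    if max(np.bincount(codes)) < 2:
        raise ValueError("every group is a singleton; within-group variance undefined")
    d2 = d**2
    observed = _pseudo_f(d2, codes, len(levels))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(codes), len(levels)) >= observed - 1e-12:
            hits += 1
    return PermanovaResult(
        pseudo_f=float(observed),
        p=(1.0 + hits) / (1.0 + n_perm),
        n_perm=n_perm,
        n_groups=len(levels),
    )


def alpha_group_test(
    values: pd.Series, groups, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Permutation test on pairwise differences of group mean diversity.

    A Monte-Carlo two-sample comparison: for each pair of groups the
    absolute difference of mean alpha diversity is compared with its
    permutation distribution under label exchange.  This is one
    reasonable operationalization of a nonparametric group contrast on
    diversity indices, not a canonical named test.
    """
    groups = pd.Series(np.asarray(groups, dtype=object), index=values.index).astype(str)
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in itertools.combinations(sorted(groups.unique()), 2):
        mask = groups.isin([g1, g2])
        v = values[mask].to_numpy(dtype=float)
        lab = (groups[mask] == g2).to_numpy()
        obs = abs(v[lab].mean() - v[~lab].mean())
        hits = 0
        for _ in range(n_perm):
            p = rng.permutation(lab)
            if abs(v[p].mean() - v[~p].mean()) >= obs - 1e-12:
                hits += 1
        rows.append(
            {"group_1": g1, "group_2": g2, "abs_mean_diff": obs, "p": (1 + hits) / (1 + n_perm)}
        )
    return pd.DataFrame(rows)


def synthetic_centroids(taxa: list[str] | None = None) -> pd.DataFrame:
    """Bundled synthetic CST centroid set (CST x taxa, simplex rows).

    A configurable stand-in for reference-derived centroid profiles:
    CST I/II/III/V each dominated by one Lactobacillus species, three
    anaerobe-rich CST IV variants.  Intended for tests and demos; real
    analyses should load their own centroids with :func:`read_centroids`.
    """
    from .synthetic_cohort import TAXA  # local import to avoid a cycle

    taxa = list(taxa) if taxa is not None else list(TAXA)
    idx = {t: i for i, t in enumerate(taxa)}
    rows = {}

    def centroid(dominant: dict[str, float]) -> np.ndarray:
        vec = np.zeros(len(taxa))
        for taxon, value in dominant.items():
            vec[idx[taxon]] = value
        rest = 1.0 - vec.sum()
        vec[idx["Other"]] += rest
        return vec

    rows["I"] = centroid({"Lactobacillus crispatus": 0.85, "Lactobacillus iners": 0.03})
    rows["II"] = centroid({"Lactobacillus gasseri": 0.80, "Lactobacillus crispatus": 0.05})
    rows["III"] = centroid({"Lactobacillus iners": 0.82, "Lactobacillus crispatus": 0.05})
    rows["V"] = centroid({"Lactobacillus jensenii": 0.80, "Lactobacillus crispatus": 0.05})
    rows["IV-A"] = centroid(
        {
            "Gardnerella vaginalis": 0.15,
            "Prevotella spp.": 0.25,
            "Fannyhessea vaginae": 0.10,
            "Sneathia sanguinegens": 0.10,
            "Megasphaera spp.": 0.10,
            "Lactobacillus iners": 0.10,
        }
    )
    rows["IV-B"] = centroid(
        {
            "Gardnerella vaginalis": 0.45,
            "Fannyhessea vaginae": 0.15,
            "Prevotella spp.": 0.10,
            "Lactobacillus iners": 0.05,
        }
    )
    rows["IV-C"] = centroid(
        {
            "Streptococcus spp.": 0.25,
            "Anaerococcus spp.": 0.15,
            "Finegoldia spp.": 0.15,
            "Prevotella spp.": 0.15,
            "Haemophilus spp.": 0.10,
        }
    )
    return pd.DataFrame(rows, index=taxa).T


def read_centroids(path) -> pd.DataFrame:
    """Load a centroid set from TSV (taxa in rows, CST labels in columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    centroids = df.T
    arr = centroids.to_numpy(dtype=float)
    if (arr < 0).any() or not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each centroid column must be a non-negative simplex vector")
    if centroids.index.duplicated().any():
        raise ValueError("duplicate centroid labels")
    return centroids
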
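"""Compositional regression of dietary macronutrients on community state.

Dietary macronutrient data are compositional: the nine energy shares
(animal protein AP, vegetable protein VP, simple sugars SS, starch ST,
saturated fat SFA, monounsaturated fat MUFA, linoleic acid LA,
alpha-linolenic acid ALA, other polyunsaturated fat PUFA) carry only
relative information.  This module maps compositions to additive
log-ratio (ALR) coordinates, fits a multinomial logit of a three-level
community state type (CST) outcome on the ALR block plus adjusters and
confounders, and estimates the *relative dominance* of each part — the
effect of that part increasing at the expense of all others — from two
ALR fits with different denominators.

The two-denominator trick works because ALR bases with different
denominators span the same log-contrast space: with denominator ST the
fit yields coefficients for the other eight parts, and a second fit with
denominator AP yields the ST coefficient from its ln(ST/AP) column.  The
two fits have identical likelihood; the run-2 ln(ST/AP) coefficient
equals minus the sum of run-1's eight compositional coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr
from statsmodels.discrete.discrete_model import MNLogit

#: Canonical order of the nine macronutrient parts (shares of food energy).
PARTS = ("AP", "VP", "SS", "ST", "SFA", "MUFA", "LA", "ALA", "PUFA")

#: Three-level CST outcome; "I-II-V" is the Lactobacillus-dominated reference.
GROUP_LABELS = ("I-II-V", "III", "IV")

#: Threshold on |coefficient| beyond which a fit is flagged as separated.
SEPARATION_BOUND = 15.0


def close(comp: pd.DataFrame) -> pd.DataFrame:
    """Normalize each row of a compositional table to sum to one.

    Raises ``ValueError`` on rows with non-positive sum or negative parts.
    """
    arr = np.asarray(comp, dtype=float)
    if (arr < 0).any():
        raise ValueError("compositional parts must be non-negative")
    sums = arr.sum(axis=1)
    if (sums <= 0).any():
        bad = np.flatnonzero(sums <= 0)
        raise ValueError(f"rows with non-positive total: {bad.tolist()}")
    return comp.div(pd.Series(sums, index=comp.index), axis=0)


def zero_replace(comp: pd.DataFrame, delta: float = 1e-6) -> pd.DataFrame:
    """Multiplicative zero replacement on a closed composition.

    Zeros become ``delta`` and the non-zero parts of the row are rescaled
    so the row still sums to one.  Rows without zeros are returned
    unchanged.  A row that is entirely zero is rejected.

    Parameters
    ----------
    comp
        Samples x parts table, rows on (or proportional to) the simplex.
    delta
        Replacement value, must be positive and smaller than the smallest
        observed non-zero (closed) part.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    closed = close(comp)
    arr = closed.to_numpy(copy=True)
    zero = arr == 0
    if not zero.any():
        return closed
    nonzero_min = arr[~zero].min()
    if delta >= nonzero_min:
        raise ValueError(
            f"delta={delta} is not smaller than the minimum non-zero part {nonzero_min}"
        )
    n_zero = zero.sum(axis=1)
    scale = 1.0 - n_zero * delta  # mass left for the non-zero parts
    arr = arr * (scale / arr.sum(axis=1))[:, None]
    arr[zero] = delta
    return pd.DataFrame(arr, index=closed.index, columns=closed.columns)


@dataclass
class ALRMatrix:
    """Additive log-ratio coordinates of a composition.

    ``data`` holds ln(part/denominator) for every part except the
    denominator, columns in canonical part order.
    """

    data: pd.DataFrame
    denominator: str

    @property
    def numerators(self) -> list[str]:
        return list(self.data.columns)


def alr_transform(comp: pd.DataFrame, denominator: str = "ST") -> ALRMatrix:
    """Additive log-ratio transform with respect to one denominator part.

    The transform is scale-invariant per row (row closure is irrelevant),
    so the input may be raw shares or percentages.  Parts must be
    strictly positive; use :func:`zero_replace` first if needed.
    """
    if denominator not in comp.columns:
        raise ValueError(f"denominator {denominator!r} is not a part of the composition")
    arr = np.asarray(comp, dtype=float)
    if (arr <= 0).any():
        raise ValueError("ALR requires strictly positive parts; apply zero_replace first")
    num_cols = [c for c in comp.columns if c != denominator]
    logs = np.log(comp[num_cols].to_numpy()) - np.log(comp[denominator].to_numpy())[:, None]
    data = pd.DataFrame(
        logs, index=comp.index, columns=[f"ln({c}/{denominator})" for c in num_cols]
    )
    return ALRMatrix(data=data, denominator=denominator)


def pivot_balance(comp: pd.DataFrame, pivot: str) -> pd.Series:
    """Pivot balance of one part against the geometric mean of the others.

    ``sqrt((D-1)/D) * ln(x_pivot / g(others))`` for a D-part composition;
    explanatorily equivalent to the pivot part's ALR-block effect.
    Scale-invariant per row.
    """
    if pivot not in comp.columns:
        raise ValueError(f"pivot {pivot!r} is not a part of the composition")
    arr = np.asarray(comp, dtype=float)
    if (arr <= 0).any():
        raise ValueError("pivot balance requires strictly positive parts")
    d = comp.shape[1]
    others = [c for c in comp.columns if c != pivot]
    log_gmean = np.log(comp[others].to_numpy()).mean(axis=1)
    bal = np.sqrt((d - 1) / d) * (np.log(comp[pivot].to_numpy()) - log_gmean)
    return pd.Series(bal, index=comp.index, name=f"balance({pivot})")


@dataclass
class FitResult:
    """Multinomial logistic fit, one coefficient column per non-reference outcome."""

    reference: str
    outcomes: list[str]
    params: pd.DataFrame
    bse: pd.DataFrame
    zvalues: pd.DataFrame
    pvalues: pd.DataFrame
    llf: float
    n_iter: int
    converged: bool
    separation: bool
    n_obs: int

    def tidy(self) -> pd.DataFrame:
        """Long-format coefficient table (outcome, term, estimate, se, z, p)."""
        rows = []
        for outcome in self.outcomes:
            for term in self.params.index:
                rows.append(
                    {
                        "outcome": outcome,
                        "term": term,
                        "estimate": self.params.loc[term, outcome],
                        "se": self.bse.loc[term, outcome],
                        "z": self.zvalues.loc[term, outcome],
                        "p": self.pvalues.loc[term, outcome],
                    }
                )
        return pd.DataFrame(rows)


def _check_full_rank(design: pd.DataFrame) -> None:
    a = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(a)
    if rank < a.shape[1]:
        _, _, piv = qr(a, mode="economic", pivoting=True)
        offenders = [design.columns[i] for i in sorted(piv[rank:])]
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {a.shape[1]}); "
            f"offending columns: {offenders}"
        )


def fit_multinomial(
    X: pd.DataFrame,
    y,
    reference: str = GROUP_LABELS[0],
    add_constant: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Maximum-likelihood multinomial logit with an explicit reference level.

    Parameters
    ----------
    X
        Predictor table (no intercept column; one is added unless
        ``add_constant`` is False).
    y
        Outcome labels; must contain ``reference``.
    reference
        Outcome level whose coefficients are fixed at zero.

    Returns per-outcome coefficients, standard errors from the inverse
    observed information, two-sided Wald p-values, log-likelihood and
    convergence information.  Apparent separation (divergent
    coefficients) is flagged with a warning, never silently truncated.
    """
    y = pd.Series(np.asarray(y, dtype=object), index=X.index, name="outcome")
    complete = X.notna().all(axis=1) & y.notna()
    if not complete.all():
        warnings.warn(
            f"dropping {(~complete).sum()} observation(s) with missing values "
            "(complete-case analysis)",
            UserWarning,
            stacklevel=2,
        )
        X, y = X.loc[complete], y.loc[complete]
    levels = [str(v) for v in pd.unique(y.astype(str))]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present in outcome")
    others = sorted(v for v in levels if v != reference)
    cat = pd.Categorical(y.astype(str), categories=[reference] + others)

    design = X.astype(float).copy()
    if add_constant:
        design.insert(0, "const", 1.0)
    nearly_const = design.drop(columns="const", errors="ignore").std(axis=0) == 0
    if nearly_const.any():
        raise ValueError(
            f"constant predictor column(s): {list(nearly_const[nearly_const].index)}"
        )
    _check_full_rank(design)
    n_params = design.shape[1] * len(others)
    if design.shape[0] <= n_params:
        raise ValueError(
            f"n={design.shape[0]} observations cannot identify {n_params} parameters"
        )

    model = MNLogit(cat.codes, design.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=0)

    params = pd.DataFrame(np.asarray(res.params), index=design.columns, columns=others)
    bse = pd.DataFrame(np.asarray(res.bse), index=design.columns, columns=others)
    zval = params / bse
    pval = pd.DataFrame(np.asarray(res.pvalues), index=design.columns, columns=others)
    converged = bool(res.mle_retvals.get("converged", False))
    slopes = params.drop(index="const", errors="ignore")  # intercepts absorb predictor means
    separation = (not converged) or bool((slopes.abs() > SEPARATION_BOUND).any().any())
    if separation:
        warnings.warn(
            "possible separation: fit did not converge or coefficients diverge; "
            "coefficients reported as-is",
            RuntimeWarning,
            stacklevel=2,
        )
    return FitResult(
        reference=reference,
        outcomes=others,
        params=params,
        bse=bse,
        zvalues=zval,
        pvalues=pval,
        llf=float(res.llf),
        n_iter=int(res.mle_retvals.get("iterations", -1)),
        converged=converged,
        separation=separation,
        n_obs=design.shape[0],
    )


@dataclass
class RelativeDominance:
    """Two-run relative-dominance estimate for all nine parts."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)

    @property
    def loglik_gap(self) -> float:
        """Absolute gap between the two runs' maximized log-likelihoods."""
        runs = list(self.fits.values())
        return abs(runs[0].llf - runs[1].llf)


def relative_dominance(
    comp: pd.DataFrame,
    covariates: pd.DataFrame | None,
    outcome,
    reference: str = GROUP_LABELS[0],
    denominators: tuple[str, str] = ("ST", "AP"),
    delta: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RelativeDominance:
    """Estimate each part's effect relative to all other parts.

    Run 1 uses ``denominators[0]`` (starch) as the ALR denominator and
    yields coefficients for the eight other parts; run 2 swaps the
    denominator to ``denominators[1]`` (animal protein) and contributes
    only the first denominator's coefficient (the ln(ST/AP) column).
    Both runs carry identical adjusters/confounders.

    Parameters
    ----------
    comp
        Samples x 9 parts composition (any positive scale).
    covariates
        Adjusters and confounders (total energy, fiber, alcohol AU, age,
        marital status, BMI, hormonal contraception, optionally PSS), or
        None for the composition-only model.
    outcome
        Three-level CST group labels per sample.
    """
    den1, den2 = denominators
    comp = zero_replace(close(comp), delta=delta)
    results = []
    fits: dict[str, FitResult] = {}
    for run_id, den in ((1, den1), (2, den2)):
        alr = alr_transform(comp, denominator=den)
        X = alr.data
        if covariates is not None:
            X = pd.concat([X, covariates.astype(float)], axis=1)
        fit = fit_multinomial(X, outcome, reference=reference, tol=tol, max_iter=max_iter)
        fits[f"run{run_id}:{den}"] = fit
        if run_id == 1:
            wanted = [(p, f"ln({p}/{den})") for p in comp.columns if p != den]
        else:
            wanted = [(den1, f"ln({den1}/{den})")]
        for part, term in wanted:
            for out in fit.outcomes:
                results.append(
                    {
                        "outcome": out,
                        "part": part,
                        "term": term,
                        "estimate": fit.params.loc[term, out],
                        "se": fit.bse.loc[term, out],
                        "z": fit.zvalues.loc[term, out],
                        "p": fit.pvalues.loc[term, out],
                        "run": run_id,
                        "denominator": den,
                        "interpretation": (
                            f"{part} increases while {den} decreases, all other "
                            "parts shrinking by the same factor as the denominator"
                        ),
                    }
                )
    table = pd.DataFrame(results)
    return RelativeDominance(table=table, fits=fits)
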
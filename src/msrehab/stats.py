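"""Statistical layer: baseline contrasts, mixed models, effect sizes and
blockwise backward logistic prediction of responder status.

Implements the trial's analysis plan in reusable form:

* baseline group contrasts (Student's *t* for continuous variables,
  chi-square for categorical, rank-based alternatives for non-normal
  variables) with Bonferroni correction within the requested family;
* a linear mixed model with subject-level random intercept and group, time
  and group × time fixed effects, reporting a joint Wald test of the
  interaction;
* the standardized mean difference (SMD) of pre-to-post change between two
  groups, with the SD pooled over all four group × time cells using n−1
  weights;
* backward logistic regression over predictors organized in entry blocks
  (demographics, volumetrics, DTI, FC), with likelihood-ratio removal at
  p ≥ 0.10, Nagelkerke pseudo-R² and per-class accuracy at a 0.5 cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "baseline_contrasts",
    "MixedModelResult",
    "group_time_mixed",
    "SmdResult",
    "smd_group_by_time",
    "nagelkerke_r2",
    "PredictionResult",
    "backward_logistic",
    "per_class_accuracy",
]

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


# ---------------------------------------------------------------------------
# Baseline contrasts
# ---------------------------------------------------------------------------

def baseline_contrasts(
    df: pd.DataFrame,
    group_col: str,
    variables: list[str],
    categorical: tuple[str, ...] | list[str] = (),
    nonnormal: tuple[str, ...] | list[str] = (),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable baseline group comparison with Bonferroni correction.

    Continuous variables get an independent-samples Student's *t* test (or a
    Mann–Whitney U test when listed in ``nonnormal``); categorical variables
    get a chi-square test of independence on the contingency table (no
    continuity correction, matching the textbook statistic).  Bonferroni
    multiplies each raw p by the family size (the number of variables in
    this call), capped at 1.
    """
    if not variables:
        raise StatsError("no variables requested")
    groups = df[group_col].dropna().unique()
    m = len(variables)
    rows = []
    for var in variables:
        sub = df[[group_col, var]].dropna()
        if var in categorical:
            table = pd.crosstab(sub[var], sub[group_col])
            stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
            test = "chi2"
        else:
            if len(groups) != 2:
                raise StatsError(
                    f"continuous contrast for {var!r} requires exactly 2 groups"
                )
            a = sub.loc[sub[group_col] == groups[0], var].to_numpy(dtype=float)
            b = sub.loc[sub[group_col] == groups[1], var].to_numpy(dtype=float)
            if var in nonnormal:
                stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
                test = "mannwhitneyu"
            else:
                stat, p = sps.ttest_ind(a, b)
                test = "t"
        p_bonf = min(1.0, p * m)
        rows.append({
            "variable": var,
            "test": test,
            "statistic": float(stat),
            "p_raw": float(p),
            "p_bonferroni": p_bonf,
            "significant": p_bonf < alpha,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group × time mixed model
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """Fitted random-intercept group × time model.

    ``cell_means`` are the fixed-effect (population) means per group × time
    cell; in a balanced complete design these reproduce the observed cell
    means.  The interaction is tested jointly with a Wald chi-square on the
    interaction coefficients (an asymptotic test; swap in a different test
    by post-processing ``result`` if preferred).
    """

    fixed_effects: pd.Series
    cell_means: pd.DataFrame
    interaction_stat: float
    interaction_df: int
    interaction_p: float
    interaction_contrast: float | None
    result: object = field(repr=False)


def group_time_mixed(
    df: pd.DataFrame,
    value: str = "value",
    group: str = "arm",
    time: str = "timepoint",
    subject: str = "subject_id",
) -> MixedModelResult:
    """Linear mixed model with random intercept and group × time fixed effects.

    Time is treated categorically.  For a 2 × 2 design
    ``interaction_contrast`` is the difference-in-differences of the cell
    means (the single interaction coefficient); with more levels it is None
    and the joint Wald test covers all interaction terms.
    """
    data = df[[value, group, time, subject]].dropna().copy()
    times = sorted(data[time].unique())
    groups = sorted(data[group].unique())
    if len(times) < 2:
        raise StatsError("need at least two timepoints for a group × time model")
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    counts = data.groupby(group)[subject].nunique()
    if (counts < 2).any():
        raise StatsError(f"fewer than 2 subjects in groups: {counts[counts < 2].index.tolist()}")

    formula = f"{value} ~ C({group}) * C({time})"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[subject])
        res = model.fit(reml=True)

    names = list(res.fe_params.index)
    inter = [n for n in names if ":" in n]
    constraint = ", ".join(f"{n} = 0" for n in inter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = res.wald_test(constraint, scalar=True)
    stat = float(np.squeeze(wt.statistic))
    dfree = len(inter)
    p = float(sps.chi2.sf(stat, dfree))

    cells = pd.DataFrame(
        [(g, t) for g in groups for t in times], columns=[group, time]
    )
    cells["mean"] = res.predict(exog=cells)
    cell_means = cells.pivot(index=group, columns=time, values="mean")

    # difference-in-differences: first group's change minus the second's
    # (rows in sorted group order)
    contrast = None
    if len(groups) == 2 and len(times) == 2:
        contrast = float(
            (cell_means.iloc[0, 1] - cell_means.iloc[0, 0])
            - (cell_means.iloc[1, 1] - cell_means.iloc[1, 0])
        )
    return MixedModelResult(
        fixed_effects=res.fe_params,
        cell_means=cell_means,
        interaction_stat=stat,
        interaction_df=dfree,
        interaction_p=p,
        interaction_contrast=contrast,
        result=res,
    )


# ---------------------------------------------------------------------------
# Standardized mean difference
# ---------------------------------------------------------------------------

@dataclass
class SmdResult:
    """Standardized mean difference of change between two groups."""

    numerator: float
    pooled_sd: float
    smd: float


def smd_group_by_time(
    cells: dict[tuple[str, str], tuple[float, float, int]],
    group_order: tuple[str, str] | None = None,
    time_order: tuple[str, str] | None = None,
    denominator: str = "pooled_cells",
) -> SmdResult:
    """SMD of pre-to-post change between two groups from cell summaries.

    ``cells`` maps (group, time) to (mean, sd, n) for exactly 2 groups × 2
    times.  The numerator is the first group's change minus the second's
    (per ``group_order``; times per ``time_order``, default sorted).  The
    default denominator pools the SD over all four cells with n−1 weights;
    ``denominator="baseline"`` pools only the two baseline cells.
    """
    keys = list(cells)
    groups = sorted({g for g, _ in keys}) if group_order is None else list(group_order)
    times = sorted({t for _, t in keys}) if time_order is None else list(time_order)
    if len(groups) != 2 or len(times) != 2 or len(cells) != 4:
        raise StatsError("need exactly 2 groups × 2 timepoints of cell summaries")
    for g in groups:
        for t in times:
            if (g, t) not in cells:
                raise StatsError(f"missing cell {(g, t)}")
            mean, sd, n = cells[(g, t)]
            if sd < 0 or n < 2:
                raise StatsError(f"invalid cell {(g, t)}: sd={sd}, n={n}")

    (g1, g2), (t0, t1) = groups, times
    numerator = (cells[(g1, t1)][0] - cells[(g1, t0)][0]) - (
        cells[(g2, t1)][0] - cells[(g2, t0)][0]
    )
    if denominator == "pooled_cells":
        pool = [cells[(g, t)] for g in groups for t in times]
    elif denominator == "baseline":
        pool = [cells[(g, t0)] for g in groups]
    else:
        raise StatsError(f"unknown denominator {denominator!r}")
    num = sum((n - 1) * sd**2 for _, sd, n in pool)
    den = sum(n - 1 for _, _, n in pool)
    pooled_sd = float(np.sqrt(num / den))
    if pooled_sd <= 0:
        raise StatsError("pooled SD must be positive")
    return SmdResult(numerator=float(numerator), pooled_sd=pooled_sd,
                     smd=float(numerator / pooled_sd))


# ---------------------------------------------------------------------------
# Backward logistic regression
# ---------------------------------------------------------------------------

def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R²: Cox–Snell R² rescaled to a [0, 1] maximum.

    ``(1 - exp(2 (ll0 - ll1) / n)) / (1 - exp(2 ll0 / n))`` from the model
    and intercept-only log-likelihoods.
    """
    if n < 1:
        raise StatsError("n must be positive")
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        raise StatsError("degenerate labels: intercept-only likelihood is 1")
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def per_class_accuracy(
    probabilities: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    cutoff: float = 0.5,
) -> dict[int, float]:
    """Class-conditional percent correctly classified at a probability cutoff.

    A probability exactly at the cutoff is classified positive (logged).
    Returns ``{0: pct, 1: pct}`` in percent; a class absent from the labels
    reports NaN.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise StatsError("probabilities and labels must have the same length")
    if (p == cutoff).any():
        logger.info("%d probabilities exactly at cutoff %.3g classified positive",
                    int((p == cutoff).sum()), cutoff)
    pred = (p >= cutoff).astype(int)
    out = {}
    for cls in (0, 1):
        mask = y == cls
        out[cls] = 100.0 * float((pred[mask] == cls).mean()) if mask.any() else float("nan")
    return out


@dataclass
class PredictionResult:
    """Outcome of a blockwise backward logistic regression."""

    retained: list[str]
    coefficients: pd.Series
    pvalues: pd.Series
    eliminated: list[tuple[str, float]]
    nagelkerke: float
    ll_model: float
    ll_null: float
    accuracy: dict[int, float]
    separation: bool
    blocks: dict[str, list[str]]


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Fit a logistic regression, falling back to BFGS, flagging separation."""
    model = sm.Logit(y, X)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
    if not np.isfinite(res.params).all() or np.abs(res.params).max() > 30:
        separation = True
    return res, separation


def backward_logistic(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    blocks: dict[str, list[str]],
    removal_alpha: float = 0.10,
    cutoff: float = 0.5,
) -> PredictionResult:
    """Backward logistic regression over predictors entered in blocks.

    All block variables are entered jointly (block order retained for
    reporting only); the least significant predictor by likelihood-ratio
    removal test is dropped while its removal p ≥ ``removal_alpha``.  The
    final model reports Wald coefficient p-values, Nagelkerke R² against the
    intercept-only model, and per-class accuracy of the in-sample fitted
    probabilities at ``cutoff``.  Perfect separation is flagged and the
    (diverging) coefficients reported with a warning rather than raised.
    """
    y = np.asarray(labels).astype(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise StatsError("labels must be binary 0/1")
    order: list[str] = []
    for name, cols in blocks.items():
        if not cols:
            raise StatsError(f"block {name!r} is empty")
        for c in cols:
            if c not in features.columns:
                raise StatsError(f"block {name!r} refers to missing feature {c!r}")
            if c not in order:
                order.append(c)
    data = features[order].astype(float)
    if data.isna().any().any():
        raise StatsError("features contain missing values")
    constant = [c for c in order if data[c].nunique() <= 1]
    if constant:
        raise StatsError(f"constant feature columns: {constant}")

    null_res, _ = _fit_logit(y, pd.DataFrame({"const": np.ones(len(y))}))
    ll_null = float(null_res.llf)

    current = list(order)
    eliminated: list[tuple[str, float]] = []
    any_separation = False
    while True:
        X = sm.add_constant(data[current], has_constant="add")
        res, sep = _fit_logit(y, X)
        any_separation = any_separation or sep
        if not current:
            break
        removal_p = {}
        for var in current:
            rest = [c for c in current if c != var]
            Xr = sm.add_constant(data[rest], has_constant="add")
            red, sep_r = _fit_logit(y, Xr)
            any_separation = any_separation or sep_r
            lr = max(0.0, 2.0 * (res.llf - red.llf))
            removal_p[var] = float(sps.chi2.sf(lr, 1))
        worst = max(removal_p, key=removal_p.get)
        if removal_p[worst] >= removal_alpha:
            eliminated.append((worst, removal_p[worst]))
            current.remove(worst)
        else:
            break

    X = sm.add_constant(data[current], has_constant="add")
    res, sep = _fit_logit(y, X)
    any_separation = any_separation or sep
    if any_separation:
        warnings.warn("quasi/perfect separation detected; coefficients unreliable",
                      UserWarning, stacklevel=2)
    probs = np.asarray(res.predict(X))
    return PredictionResult(
        retained=list(current),
        coefficients=res.params,
        pvalues=res.pvalues,
        eliminated=eliminated,
        nagelkerke=nagelkerke_r2(float(res.llf), ll_null, len(y)),
        ll_model=float(res.llf),
        ll_null=ll_null,
        accuracy=per_class_accuracy(probs, y, cutoff=cutoff),
        separation=any_separation,
        blocks={k: list(v) for k, v in blocks.items()},
    )
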
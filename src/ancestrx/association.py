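"""Regression of treatment effects on ancestry and/or self-reported ethnicity.

For each drug-outcome combination the per-subject treatment effects are
regressed (OLS with intercept) on one of four predictor sets:

* M1 — 5 MDS ancestral dimensions + 3 ethnicity indicators (full model)
* M2 — 5 MDS dimensions only
* M3 — 3 ethnicity indicators only
* M4 — the 3 MDS dimensions most aligned with ethnicity + 3 ethnicity
  indicators (drops the 2 "cryptic" dimensions)

Model fit is summarized by the multiple correlation R and the overall
F-test; nested models are compared by the partial F-test on the change in
R^2.  Ethnicity enters as three 0/1 indicators with the intercept retained,
so an implicit fourth "other" category is the reference.  All four models
for a combination are fit on the identical listwise-complete case set, which
keeps the delta-correlation comparisons coherent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import AncestryModel
from .treatment_effects import TreatmentEffectSet

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSet",
    "RegressionResult",
    "fit_model",
    "nested_f_test",
    "run_model_grid",
    "standard_predictor_sets",
]

MODEL_LABELS = ("M1", "M2", "M3", "M4")


@dataclass
class PredictorSet:
    """Named predictor columns aligned to subjects (index = subject id)."""

    label: str
    columns: pd.DataFrame

    def __post_init__(self) -> None:
        nunique = self.columns.nunique(dropna=True)
        constant = list(nunique.index[nunique <= 1])
        if constant:
            raise ValueError(
                f"predictor set {self.label!r} has constant columns {constant}; "
                "the intercept is implicit"
            )

    @property
    def names(self) -> list[str]:
        return list(self.columns.columns)


@dataclass
class RegressionResult:
    """OLS fit summary for one predictor set on one effect vector."""

    label: str
    predictors: list[str]
    n: int
    r: float
    r2: float
    f: float
    df1: int
    df2: int
    p: float
    coefficients: pd.DataFrame = field(repr=False)
    case_ids: tuple[str, ...] = field(default=(), repr=False)


def _complete_cases(y: pd.Series, x: pd.DataFrame) -> pd.Index:
    joined = x.join(y.rename("__y__"), how="inner")
    return joined.dropna().index


def fit_model(effects: pd.Series, predictors: PredictorSet) -> RegressionResult:
    """OLS with intercept on listwise-complete cases.

    ``effects`` is a subject-indexed series of treatment-effect estimates.
    The overall model-fit F statistic is (R^2/df1) / ((1-R^2)/df2) with
    df1 = number of predictors and df2 = n - df1 - 1.
    """
    idx = _complete_cases(effects, predictors.columns)
    x = predictors.columns.loc[idx].astype(float)
    y = effects.loc[idx].astype(float).to_numpy()
    n, k = x.shape
    if n < k + 2:
        raise ValueError(
            f"{n} complete cases is too few for {k} predictors (need >= {k + 2})"
        )
    design = np.column_stack([np.ones(n), x.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        culprits = _collinear_columns(x)
        raise ValueError(
            f"rank-deficient design for {predictors.label!r}; "
            f"collinear columns: {culprits}"
        )
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    df1, df2 = k, n - k - 1
    if r2 >= 1.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (r2 / df1) / ((1.0 - r2) / df2)
        p = float(stats.f.sf(f_stat, df1, df2))

    # standard errors from (X'X)^-1 * sigma^2
    xtx_inv = np.linalg.pinv(design.T @ design)
    sigma2 = sse / df2 if df2 > 0 else np.nan
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    coef_frame = pd.DataFrame(
        {"coef": coef, "se": se}, index=["intercept", *x.columns]
    )
    return RegressionResult(
        label=predictors.label,
        predictors=list(x.columns),
        n=n,
        r=float(np.sqrt(r2)),
        r2=float(r2),
        f=float(f_stat),
        df1=df1,
        df2=df2,
        p=p,
        coefficients=coef_frame,
        case_ids=tuple(idx),
    )


def _collinear_columns(x: pd.DataFrame) -> list[str]:
    culprits = []
    cols = list(x.columns)
    for i, c in enumerate(cols):
        others = x[cols[:i] + cols[i + 1 :]]
        design = np.column_stack([np.ones(len(x)), others.to_numpy()])
        resid = x[c].to_numpy() - design @ np.linalg.lstsq(
            design, x[c].to_numpy(), rcond=None
        )[0]
        if np.sum(resid**2) < 1e-10 * max(np.sum(x[c].to_numpy() ** 2), 1.0):
            culprits.append(c)
    return culprits


def nested_f_test(
    full: RegressionResult, reduced: RegressionResult
) -> tuple[float, int, int, float]:
    """Partial F-test for dropping the predictors absent from the reduced model.

    ``F = ((R2_full - R2_red)/q) / ((1 - R2_full)/(n - k_full - 1))`` with q
    the number of dropped predictors.  Requires the reduced predictor set to
    be a strict subset of the full set, fit on the identical cases.
    """
    if not set(reduced.predictors) < set(full.predictors):
        raise ValueError(
            f"models are not nested: {reduced.predictors} is not a strict "
            f"subset of {full.predictors}"
        )
    if full.case_ids != reduced.case_ids:
        raise ValueError("nested comparison requires identical case sets")
    q = len(full.predictors) - len(reduced.predictors)
    n, k_full = full.n, len(full.predictors)
    df2 = n - k_full - 1
    delta = max(full.r2 - reduced.r2, 0.0)
    if full.r2 >= 1.0:
        f_stat = np.inf if delta > 0 else 0.0
    else:
        f_stat = (delta / q) / ((1.0 - full.r2) / df2)
    p = float(stats.f.sf(f_stat, q, df2)) if np.isfinite(f_stat) else 0.0
    return float(f_stat), q, df2, p


# ---------------------------------------------------------------------------
# the four-model grid
# ---------------------------------------------------------------------------


def ethnicity_aligned_dimensions(
    scores: pd.DataFrame, ethnicity: pd.DataFrame, n_keep: int = 3
) -> list[str]:
    """Rank MDS dimensions by how much of each is explained by ethnicity.

    Each dimension is regressed on the ethnicity indicators; the ``n_keep``
    dimensions with the highest R^2 are the "ethnicity-aligned" set used in
    model M4, and the remainder are the cryptic dimensions dropped by the
    "4 vs. 1" comparison.
    """
    common = scores.index.intersection(ethnicity.index)
    x = np.column_stack(
        [np.ones(len(common)), ethnicity.loc[common].to_numpy(dtype=float)]
    )
    r2 = {}
    for col in scores.columns:
        y = scores.loc[common, col].to_numpy(dtype=float)
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        sst = np.sum((y - y.mean()) ** 2)
        r2[col] = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0
    ranked = sorted(scores.columns, key=lambda c: (-r2[c], c))
    return list(ranked[:n_keep])


def standard_predictor_sets(
    ancestry: AncestryModel | pd.DataFrame,
    ethnicity: pd.DataFrame,
) -> dict[str, PredictorSet]:
    """Build the M1-M4 predictor sets from MDS scores and ethnicity indicators."""
    scores = (
        ancestry.scores_frame() if isinstance(ancestry, AncestryModel) else ancestry
    )
    aligned = ethnicity_aligned_dimensions(scores, ethnicity)
    both = scores.join(ethnicity, how="inner")
    return {
        "M1": PredictorSet("M1", both),
        "M2": PredictorSet("M2", both[list(scores.columns)]),
        "M3": PredictorSet("M3", both[list(ethnicity.columns)]),
        "M4": PredictorSet("M4", both[aligned + list(ethnicity.columns)]),
    }


#: (comparison label, full model, reduced model) — what each Δ drops from M1.
GRID_COMPARISONS = (
    ("2 vs. 1 (drop 3 Ethnicity)", "M1", "M2"),
    ("3 vs. 1 (drop 5 MDS)", "M1", "M3"),
    ("4 vs. 1 (drop 2 MDS)", "M1", "M4"),
)


def run_model_grid(
    effects: TreatmentEffectSet,
    ancestry: AncestryModel | pd.DataFrame,
    ethnicity: pd.DataFrame,
    min_n: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit M1-M4 for every drug-outcome combination and compare nested models.

    Returns (results, comparisons).  ``results`` has one row per combination
    x model with (n, R, R2, F, df1, df2, p); ``comparisons`` has one row per
    combination x nested comparison with the delta multiple correlation and
    the partial F-test.  All four fits for a combination share the maximal
    common complete-case set.  Combinations with fewer than ``min_n``
    complete cases are skipped and logged, never silently dropped.
    """
    sets = standard_predictor_sets(ancestry, ethnicity)
    full_columns = sets["M1"].columns

    result_rows, comparison_rows = [], []
    for (drug, outcome), eff in sorted(effects.items()):
        y = eff.effects
        idx = _complete_cases(y, full_columns)
        if len(idx) < min_n:
            logger.warning(
                "skipping (%s, %s): %d complete cases < min_n=%d",
                drug,
                outcome,
                len(idx),
                min_n,
            )
            result_rows.append(
                {
                    "drug": drug,
                    "outcome": outcome,
                    "model": "skipped",
                    "n": len(idx),
                }
            )
            continue
        fits = {}
        degenerate = None
        for label, pset in sets.items():
            try:
                restricted = PredictorSet(label, pset.columns.loc[idx])
                fits[label] = fit_model(y.loc[idx], restricted)
            except ValueError as exc:
                degenerate = f"{label}: {exc}"
                break
            res = fits[label]
            result_rows.append(
                {
                    "drug": drug,
                    "outcome": outcome,
                    "model": label,
                    "n": res.n,
                    "R": res.r,
                    "R2": res.r2,
                    "F": res.f,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p,
                }
            )
        if degenerate is not None:
            logger.warning(
                "skipping (%s, %s): degenerate design (%s)", drug, outcome, degenerate
            )
            result_rows = [
                r
                for r in result_rows
                if not (r["drug"] == drug and r["outcome"] == outcome)
            ]
            result_rows.append(
                {"drug": drug, "outcome": outcome, "model": "skipped", "n": len(idx)}
            )
            continue
        for comp_label, full_label, red_label in GRID_COMPARISONS:
            f_stat, q, df2, p = nested_f_test(fits[full_label], fits[red_label])
            comparison_rows.append(
                {
                    "drug": drug,
                    "outcome": outcome,
                    "comparison": comp_label,
                    "delta_R": fits[red_label].r - fits[full_label].r,
                    "delta_R2": fits[red_label].r2 - fits[full_label].r2,
                    "F": f_stat,
                    "df1": q,
                    "df2": df2,
                    "p": p,
                }
            )
    results = pd.DataFrame(result_rows)
    comparisons = pd.DataFrame(comparison_rows)
    return results, comparisons


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Per-model mean and quartiles of the multiple correlation R."""
    fitted = results[results["model"].isin(MODEL_LABELS)]
    return (
        fitted.groupby("model")["R"]
        .agg(mean="mean", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
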
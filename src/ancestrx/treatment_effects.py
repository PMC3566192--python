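"""Per-subject treatment-effect estimation from longitudinal outcomes.

Three stages, applied per drug-outcome combination:

1. *Functional form*: fit the mixed model
   ``y_it = alpha + f(t) beta + b_0i + b_1i f(t) + eps`` for each candidate
   time transform f in {t, t^2, log(1+t)} and keep the form with the lowest
   BIC (ML fits, since likelihoods under REML are not comparable across
   different fixed-effect designs).  Ties break to linear.
2. *Covariate screening*: forward selection over candidate covariates,
   adding whichever candidate most improves BIC until none does.
3. *BLUPs*: refit the selected model by REML and form each subject's
   treatment effect as ``f(T_end) * (beta + b1_i)`` — the model-implied
   outcome change from baseline to the last scheduled visit, with the
   random-slope deviation b1_i predicted by its empirical-Bayes conditional
   mean (the standard mixed-model shrinkage formula
   ``b_i = Psi Z_i' V_i^{-1} (y_i - X_i beta)``).

Condensing each subject's full trajectory this way is more precise than
post-minus-pre differencing, because all visits inform the estimate and
poorly observed subjects are shrunk toward the population mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io_formats import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "FUNCTIONAL_FORMS",
    "ResponseModelSpec",
    "TreatmentEffects",
    "TreatmentEffectSet",
    "select_functional_form",
    "screen_covariates",
    "estimate_blups",
    "estimate_all_effects",
]

#: Candidate time transforms, in canonical (tie-breaking) order.
FUNCTIONAL_FORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda t: t,
    "quadratic": lambda t: t**2,
    "log": lambda t: np.log1p(t),
}

_BIC_TIE_TOL = 1e-6


@dataclass
class ResponseModelSpec:
    """Selected response model for one drug-outcome combination."""

    functional_form: str = "linear"
    selected_covariates: list[str] = field(default_factory=list)
    fixed_effects: pd.Series | None = None
    cov_re: np.ndarray | None = None  # 2x2 [intercept, slope] covariance
    sigma2_e: float | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        if self.functional_form not in FUNCTIONAL_FORMS:
            raise ValueError(
                f"unknown functional form {self.functional_form!r}; "
                f"choose from {list(FUNCTIONAL_FORMS)}"
            )

    def transform(self, t: np.ndarray) -> np.ndarray:
        return FUNCTIONAL_FORMS[self.functional_form](np.asarray(t, dtype=float))

    @property
    def variance_components(self) -> dict[str, float]:
        out = {}
        if self.cov_re is not None:
            out["sigma2_intercept"] = float(self.cov_re[0, 0])
            out["sigma2_slope"] = float(self.cov_re[1, 1])
        if self.sigma2_e is not None:
            out["sigma2_residual"] = float(self.sigma2_e)
        return out


@dataclass
class TreatmentEffects:
    """BLUP treatment effects for one drug-outcome combination."""

    drug: str
    outcome: str
    effects: pd.Series  # subject -> effect estimate
    spec: ResponseModelSpec
    n_subjects: int
    mean_observations: float
    excluded_subjects: list[str] = field(default_factory=list)


class TreatmentEffectSet(dict):
    """Mapping (drug, outcome) -> :class:`TreatmentEffects`."""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (drug, outcome), eff in self.items():
            for subject, value in eff.effects.items():
                rows.append(
                    {
                        "drug": drug,
                        "outcome": outcome,
                        "subject": subject,
                        "effect": value,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model fitting machinery
# ---------------------------------------------------------------------------


def _prepare(
    data: PhenotypeTable | pd.DataFrame, drug: str, outcome: str
) -> pd.DataFrame:
    df = (
        data.combination(drug, outcome)
        if isinstance(data, PhenotypeTable)
        else data
    )
    if df.empty:
        raise ValueError(f"no rows for drug={drug!r}, outcome={outcome!r}")
    counts = df.groupby("subject")["time"].size()
    few = counts.index[counts < 2]
    if len(few):
        logger.info(
            "excluding %d subjects with <2 observations for (%s, %s)",
            len(few),
            drug,
            outcome,
        )
        df = df[~df["subject"].isin(few)]
    if df["subject"].nunique() < 3:
        raise ValueError("need at least 3 subjects with >=2 observations")
    return df.reset_index(drop=True)


def _design(
    df: pd.DataFrame, form: str, covariates: Sequence[str]
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    ft = FUNCTIONAL_FORMS[form](df["time"].to_numpy(dtype=float))
    exog = pd.DataFrame({"const": 1.0, "ft": ft}, index=df.index)
    for cov in covariates:
        exog[cov] = pd.to_numeric(df[cov], errors="raise")
    exog_re = exog[["const", "ft"]]
    return df["value"].astype(float), exog, exog_re


def _fit_mixed(
    df: pd.DataFrame,
    form: str,
    covariates: Sequence[str],
    reml: bool,
):
    y, exog, exog_re = _design(df, form, covariates)
    model = MixedLM(y, exog, groups=df["subject"], exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=reml, method="lbfgs", maxiter=200)
    return result


def _bic(result) -> float:
    # ML BIC; count fixed effects + 3 (co)variance parameters + residual
    k = len(result.fe_params) + result.cov_re.shape[0] * (result.cov_re.shape[0] + 1) // 2 + 1
    return float(-2.0 * result.llf + k * np.log(result.nobs))


def select_functional_form(
    data: PhenotypeTable | pd.DataFrame,
    drug: str,
    outcome: str,
    forms: Sequence[str] = tuple(FUNCTIONAL_FORMS),
) -> ResponseModelSpec:
    """Pick the time transform minimizing ML BIC; ties resolve to linear.

    Candidates are tried in canonical order and a later form must beat the
    incumbent by more than a small tolerance, so identical fits (e.g. a flat
    outcome) deterministically return the earliest — linear — form.
    """
    df = _prepare(data, drug, outcome)
    # degenerate input: no within-subject variation at all, so every time
    # transform fits identically — the tie rule returns linear outright
    within_var = df.groupby("subject")["value"].var(ddof=0).max()
    if not within_var > 0:
        logger.info("outcome constant within subjects; returning linear form")
        return ResponseModelSpec(functional_form="linear")
    y_var = max(float(df["value"].var()), np.finfo(float).tiny)
    best_form, best_bic = None, np.inf
    failures: list[str] = []
    for form in forms:
        try:
            result = _fit_mixed(df, form, [], reml=False)
        except (np.linalg.LinAlgError, ValueError) as exc:
            failures.append(f"{form}: {exc}")
            continue
        # residual variance ~0 means the fit is saturated and its likelihood
        # is unbounded; every saturated form is an exact fit, so the BIC
        # comparison is meaningless — take the earliest (linear first).
        if result.scale <= 1e-10 * y_var:
            logger.info("form %s fits exactly (no residual variance)", form)
            return ResponseModelSpec(functional_form=form)
        bic = _bic(result)
        if bic < best_bic - _BIC_TIE_TOL:
            best_form, best_bic = form, bic
    if best_form is None:
        raise RuntimeError(
            f"no candidate functional form could be fitted: {failures}"
        )
    return ResponseModelSpec(functional_form=best_form)


def screen_covariates(
    data: PhenotypeTable | pd.DataFrame,
    spec: ResponseModelSpec,
    candidates: Sequence[str],
    drug: str,
    outcome: str,
) -> ResponseModelSpec:
    """Forward-select covariates that improve the ML BIC.

    At each step the candidate with the largest BIC improvement is added
    (ties broken by name); selection stops when no candidate improves.
    Near-collinear candidates (design condition number > 1e8) are skipped
    with a warning.
    """
    df = _prepare(data, drug, outcome)
    missing = [c for c in candidates if c not in df.columns]
    if missing:
        raise ValueError(f"candidate covariates not in table: {missing}")
    selected = list(spec.selected_covariates)
    remaining = [c for c in candidates if c not in selected]
    current = _bic(_fit_mixed(df, spec.functional_form, selected, reml=False))
    while remaining:
        trials: list[tuple[float, str]] = []
        for cov in sorted(remaining):
            _, exog, _ = _design(df, spec.functional_form, selected + [cov])
            if np.linalg.cond(exog.to_numpy()) > 1e8:
                logger.warning("skipping near-collinear covariate %r", cov)
                continue
            try:
                bic = _bic(
                    _fit_mixed(df, spec.functional_form, selected + [cov], reml=False)
                )
            except (np.linalg.LinAlgError, ValueError):
                continue
            trials.append((current - bic, cov))
        if not trials:
            break
        trials.sort(key=lambda t: (-t[0], t[1]))
        gain, best = trials[0]
        if gain <= _BIC_TIE_TOL:
            break
        selected.append(best)
        remaining = [c for c in remaining if c != best]
        current -= gain
    return replace(spec, selected_covariates=selected)


def conditional_random_effects(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    beta: np.ndarray,
    psi: np.ndarray,
    sigma2_e: float,
) -> np.ndarray:
    """Empirical-Bayes conditional mean of one subject's random effects.

    ``b_hat = Psi Z' (Z Psi Z' + sigma2_e I)^{-1} (y - X beta)`` — the BLUP
    of the random-effect vector given the fitted variance components.  For a
    random-intercept-only design with n observations this reduces to the
    scalar shrinkage ``sigma2_b / (sigma2_b + sigma2_e / n)`` applied to the
    subject's raw mean deviation.
    """
    resid = y - x @ beta
    v = z @ psi @ z.T + sigma2_e * np.eye(len(y))
    return psi @ z.T @ np.linalg.solve(v, resid)


def estimate_blups(
    data: PhenotypeTable | pd.DataFrame,
    spec: ResponseModelSpec,
    drug: str,
    outcome: str,
) -> TreatmentEffects:
    """REML-fit the selected model and emit per-subject treatment effects.

    The effect for subject i is ``f(T_end) * (beta + b1_i)``: the modelled
    outcome change between baseline and the last scheduled visit, using the
    shrunken subject-specific slope.  With no residual noise the BLUP slope
    equals the subject's own least-squares slope (no shrinkage); as residual
    noise grows or visits are missed, slopes shrink toward the fixed effect.
    """
    df = _prepare(data, drug, outcome)
    counts = (
        data.combination(drug, outcome)
        if isinstance(data, PhenotypeTable)
        else data
    ).groupby("subject")["time"].size()
    excluded = list(counts.index[counts < 2])

    result = _fit_mixed(df, spec.functional_form, spec.selected_covariates, reml=True)
    if not np.isfinite(result.llf) or not np.all(np.isfinite(result.fe_params)):
        raise RuntimeError(
            f"variance estimation failed to converge for ({drug}, {outcome}): "
            f"llf={result.llf}, params={result.fe_params.to_dict()}"
        )
    psi = np.asarray(result.cov_re)
    sigma2_e = float(result.scale)
    beta_full = result.fe_params
    fitted_spec = replace(
        spec,
        fixed_effects=beta_full,
        cov_re=psi,
        sigma2_e=sigma2_e,
        converged=bool(result.converged),
    )

    y, exog, exog_re = _design(df, spec.functional_form, spec.selected_covariates)
    beta_vec = beta_full.to_numpy()
    slope_fixed = float(beta_full["ft"])
    t_end = float(df["time"].max())
    f_end = float(spec.transform(np.array([t_end]))[0])

    groups = df["subject"].to_numpy()
    order = {}
    for idx, g in enumerate(groups):
        order.setdefault(g, []).append(idx)
    effects = {}
    x_all = exog.to_numpy()
    z_all = exog_re.to_numpy()
    y_all = y.to_numpy()
    for subject, idx in order.items():
        idx = np.asarray(idx)
        b_hat = conditional_random_effects(
            y_all[idx], x_all[idx], z_all[idx], beta_vec, psi, sigma2_e
        )
        effects[subject] = f_end * (slope_fixed + b_hat[1])
    eff = pd.Series(effects, name="effect").sort_index()
    if not np.isfinite(eff.to_numpy()).all():
        raise RuntimeError(f"non-finite effect estimates for ({drug}, {outcome})")
    return TreatmentEffects(
        drug=drug,
        outcome=outcome,
        effects=eff,
        spec=fitted_spec,
        n_subjects=int(df["subject"].nunique()),
        mean_observations=float(df.groupby("subject")["time"].size().mean()),
        excluded_subjects=excluded,
    )


def estimate_all_effects(
    data: PhenotypeTable,
    candidates: Sequence[str] = (),
    forms: Sequence[str] = tuple(FUNCTIONAL_FORMS),
) -> TreatmentEffectSet:
    """Run the three-stage pipeline for every drug-outcome combination."""
    out = TreatmentEffectSet()
    for drug, outcome in data.combinations():
        spec = select_functional_form(data, drug, outcome, forms=forms)
        if candidates:
            spec = screen_covariates(data, spec, candidates, drug, outcome)
        out[(drug, outcome)] = estimate_blups(data, spec, drug, outcome)
    return out
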
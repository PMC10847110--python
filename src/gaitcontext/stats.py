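"""Linear mixed-effects comparison of indoor versus outdoor walking.

Walking data are nested: stride speeds within walking periods, walking
periods within participants. Three models share the fixed effect of
context (outdoor vs indoor, so the estimate is the expected change when
moving outdoors):

* duration_min  ~ context + (1 | participant)
* continuity_pct ~ context + (1 | participant)
* normalized speed ~ context + (1 | participant) + (1 | period-in-participant)

Estimation is REML; candidate random-effect structures are ranked by AIC
from maximum-likelihood fits, since ML likelihoods (including the
independent-residual OLS baseline) are directly comparable while REML
ones are not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

STRUCTURES = ("ols", "participant", "participant_period")


@dataclass
class LmmResult:
    """Context fixed effect and fit statistics of one outcome model."""

    outcome: str
    estimate: float          # expected outcome change, indoor -> outdoor
    se: float
    tstat: float
    df: int
    pvalue: float
    aic: float
    structure: str
    intercept: float = float("nan")
    participant_sd: float = float("nan")
    period_sd: float = float("nan")
    residual_sd: float = float("nan")
    converged: bool = True
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def _design(context: np.ndarray) -> np.ndarray:
    """Fixed-effect design: intercept + outdoor indicator."""
    return np.column_stack([np.ones(len(context)),
                            (context == "outdoor").astype(float)])


def _aic(result, n_params: int) -> float:
    """AIC with n_params counting fixed effects plus *all* variance
    parameters (random-effect components and the residual), as nlme does."""
    return float(-2.0 * result.llf + 2.0 * n_params)


def _fit_mixedlm(model: MixedLM, reml: bool):
    """Fit with the default optimizer; a collapsed random-effect variance
    or non-finite likelihood triggers a Powell refit (the default BFGS path
    occasionally stalls on a boundary local optimum), keeping whichever
    converged fit has the higher finite likelihood."""
    result = model.fit(reml=reml)
    collapsed = (not np.isfinite(result.llf)
                 or (result.cov_re.size and result.cov_re.iat[0, 0] < 1e-8
                     if hasattr(result.cov_re, "iat")
                     else np.asarray(result.cov_re)[0, 0] < 1e-8))
    if collapsed:
        retry = model.fit(reml=reml, method="powell")
        if np.isfinite(retry.llf) and (not np.isfinite(result.llf)
                                       or retry.llf > result.llf):
            result = retry
    return result


def fit_context_model(outcome: np.ndarray, context: np.ndarray,
                      participant: np.ndarray,
                      period: np.ndarray | None = None,
                      outcome_name: str = "outcome",
                      reml: bool = True) -> LmmResult:
    """Fit outcome ~ context with a participant random intercept (plus a
    period-within-participant intercept when period ids are given, as for
    stride-level speeds).

    Requires both contexts and at least two participants. A constant
    outcome yields a zero estimate with a degenerate-variance warning
    rather than an error.
    """
    outcome = np.asarray(outcome, dtype=float)
    context = np.asarray(context)
    participant = np.asarray(participant)
    levels = np.unique(context)
    if levels.size < 2:
        raise ValueError("both contexts must be present (design is "
                         "rank-deficient with a single context)")
    if np.unique(participant).size < 2:
        raise ValueError("need at least 2 participants")

    warns: list[str] = []
    if np.ptp(outcome) == 0:
        warns.append("degenerate outcome: zero variance")

    exog = _design(context)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if period is None:
            model = MixedLM(outcome, exog, groups=participant)
            structure = "participant"
            n_vc = 1
        else:
            period = np.asarray(period).astype(str)
            df = pd.DataFrame({"y": outcome, "ctx": context,
                               "pid": participant, "per": period})
            model = MixedLM.from_formula(
                "y ~ C(ctx, Treatment('indoor'))", df, groups="pid",
                re_formula="1", vc_formula={"per": "0 + C(per)"})
            structure = "participant_period"
            n_vc = 2
        result = _fit_mixedlm(model, reml)
        warns.extend(str(w.message) for w in caught
                     if "converge" in str(w.message).lower()
                     or "boundary" in str(w.message).lower()
                     or "singular" in str(w.message).lower())

    params = np.asarray(result.fe_params)
    bse = np.asarray(result.bse_fe)
    est, se = float(params[1]), float(bse[1])
    dof = int(len(outcome) - 2)
    if se > 0 and np.isfinite(se):
        tstat = est / se
        pvalue = float(2.0 * sstats.t.sf(abs(tstat), dof))
    else:
        tstat, pvalue = float("nan"), float("nan")
        warns.append("degenerate variance: standard error not positive")

    cov_re = np.asarray(result.cov_re)
    participant_sd = float(np.sqrt(cov_re[0, 0])) if cov_re.size else float("nan")
    period_sd = float("nan")
    if period is not None and getattr(result, "vcomp", None) is not None \
            and len(result.vcomp):
        period_sd = float(np.sqrt(result.vcomp[0]))
    n_params = 2 + n_vc + 1  # fixed effects + variance components + residual
    return LmmResult(
        outcome=outcome_name,
        estimate=est,
        se=se,
        tstat=tstat,
        df=dof,
        pvalue=pvalue,
        aic=_aic(result, n_params),
        structure=structure,
        intercept=float(params[0]),
        participant_sd=participant_sd,
        period_sd=period_sd,
        residual_sd=float(np.sqrt(result.scale)),
        converged=bool(getattr(result, "converged", True)),
        warnings=tuple(warns),
    )


def residual_diagnostics(outcome, context, participant,
                         result: LmmResult) -> dict:
    """Numeric residual summaries (normal-QQ correlation and residual vs
    fitted association) for the participant-intercept model."""
    outcome = np.asarray(outcome, dtype=float)
    fitted = result.intercept + result.estimate * (
        np.asarray(context) == "outdoor").astype(float)
    # add participant BLUP-free group means for a cheap level-1 residual
    resid = outcome - fitted
    resid_sorted = np.sort(resid)
    n = len(resid)
    theo = sstats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq_corr = float(np.corrcoef(theo, resid_sorted)[0, 1]) if n > 2 else np.nan
    rf_corr = float(np.corrcoef(fitted, np.abs(resid))[0, 1]) \
        if np.ptp(fitted) > 0 else 0.0
    return {
        "qq_correlation": qq_corr,
        "residual_vs_fitted_correlation": rf_corr,
        "residual_sd": float(resid.std(ddof=1)),
    }


def compare_structures(outcome: np.ndarray, context: np.ndarray,
                       participant: np.ndarray,
                       period: np.ndarray | None = None,
                       candidates: tuple[str, ...] = STRUCTURES
                       ) -> pd.DataFrame:
    """Fit candidate random-effect structures by ML and rank by AIC
    (ascending; the lowest-AIC structure is flagged ``best``).

    Candidates: 'ols' (independent residuals), 'participant' (random
    intercept), 'participant_period' (additionally a period-within-
    participant intercept; requires period ids). Non-convergent candidates
    are excluded with a logged reason.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate structure")
    outcome = np.asarray(outcome, dtype=float)
    context = np.asarray(context)
    participant = np.asarray(participant)
    exog = _design(context)

    rows = []
    for name in candidates:
        try:
            if name == "ols":
                res = sm.OLS(outcome, exog).fit()
                rows.append({"structure": name, "aic": _aic(res, 3),
                             "loglik": float(res.llf)})
                continue
            if name == "participant":
                model = MixedLM(outcome, exog, groups=participant)
                n_params = 4
            elif name == "participant_period":
                if period is None:
                    raise ValueError("period ids required for the nested "
                                     "structure")
                df = pd.DataFrame({"y": outcome, "ctx": context,
                                   "pid": participant,
                                   "per": np.asarray(period).astype(str)})
                model = MixedLM.from_formula(
                    "y ~ C(ctx, Treatment('indoor'))", df, groups="pid",
                    re_formula="1", vc_formula={"per": "0 + C(per)"})
                n_params = 5
            else:
                raise ValueError(f"unknown structure {name!r}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = _fit_mixedlm(model, reml=False)
            if not getattr(res, "converged", True) or not np.isfinite(res.llf):
                logger.info("structure %s did not converge; excluded", name)
                continue
            rows.append({"structure": name, "aic": _aic(res, n_params),
                         "loglik": float(res.llf)})
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.info("structure %s failed: %s", name, exc)
    table = pd.DataFrame(rows).sort_values("aic", ignore_index=True)
    table["best"] = False
    if len(table):
        table.loc[0, "best"] = True
    return table
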
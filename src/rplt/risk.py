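"""Clustered baseline-category multinomial models of 90-day outcome.

The outcome has three levels (ASA, OtherSE, noSE) with noSE as the reference.
Because subjects contribute 1-5 sessions each, coefficients are estimated by
independence-working estimating equations -- for a multinomial logit these
coincide with the ordinary maximum-likelihood score equations -- and inference
uses a cluster-robust (sandwich) covariance grouped by subject.  Results are
reported as odds ratios (exponentiated coefficients) with Wald 95% confidence
intervals on the log-odds scale and the conventional 0.05 threshold.

Three standard model specifications mirror the analysis ladder: behavior only
(percent optimal by valence), behavior adjusted for suicidal-ideation score
and lifetime prior attempts, and the model-derived ambiguous-outcome value R0
with the same adjustments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "RiskModelResult",
    "ConvergenceError",
    "fit_multinomial_clustered",
    "model_1_behavior",
    "model_2_adjusted",
    "model_3_r0",
]

OUTCOME_LEVELS = ("noSE", "OtherSE", "ASA")  # first is reference


class ConvergenceError(RuntimeError):
    """Estimation failed to converge (e.g. separation or an empty niche)."""


@dataclass(frozen=True)
class ModelSpec:
    predictors: tuple[str, ...]
    outcome: str = "label"
    cluster: str = "subject_id"
    reference: str = "noSE"
    levels: tuple[str, ...] = OUTCOME_LEVELS


@dataclass
class RiskModelResult:
    """Wrapper holding the fitted model and its odds-ratio table."""

    spec: ModelSpec
    or_table: pd.DataFrame
    params: pd.DataFrame  # coefficients, columns = non-reference levels
    cov: np.ndarray
    n_obs: int
    n_clusters: int
    _sm_result: object = field(repr=False, default=None)


def _validate(data: pd.DataFrame, spec: ModelSpec) -> None:
    missing = [c for c in spec.predictors if c not in data.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    labels = set(data[spec.outcome].unique())
    if spec.reference not in labels:
        raise ValueError(f"reference level {spec.reference!r} absent from data")
    for level in spec.levels:
        if level not in labels:
            raise ValueError(f"outcome level {level!r} has no observations")
    bad = labels - set(spec.levels)
    if bad:
        raise ValueError(
            f"unexpected outcome labels {sorted(bad)}; unclassifiable sessions "
            "must be removed before modeling"
        )
    for col in spec.predictors:
        if not np.issubdtype(np.asarray(data[col]).dtype, np.number):
            raise ValueError(f"predictor {col!r} is not numeric")


def fit_multinomial_clustered(
    data: pd.DataFrame, spec: ModelSpec
) -> RiskModelResult:
    """Fit the baseline-category multinomial with subject-clustered covariance.

    Point estimates are the multinomial-logit maximum-likelihood solution
    (identical to independence-working estimating equations); the covariance
    is the cluster-robust sandwich, which with singleton clusters reduces to
    the heteroskedasticity-robust form.
    """
    _validate(data, spec)
    y = pd.Categorical(data[spec.outcome], categories=list(spec.levels))
    X = sm.add_constant(data[list(spec.predictors)].astype(float), has_constant="add")
    groups = pd.factorize(data[spec.cluster])[0]
    model = sm.MNLogit(y.codes, X)
    try:
        res = model.fit(
            method="newton",
            maxiter=200,
            disp=0,
            cov_type="cluster",
            cov_kwds={"groups": groups},
        )
    except Exception as exc:  # singular Hessian, separation, ...
        raise ConvergenceError(f"multinomial fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            "multinomial fit did not converge "
            f"(iterations={res.mle_retvals.get('iterations')}); check for "
            "separation or sparse outcome levels"
        )
    nonref = list(spec.levels[1:])
    coefs = pd.DataFrame(
        np.asarray(res.params), index=X.columns, columns=nonref
    )
    bse = pd.DataFrame(np.asarray(res.bse), index=X.columns, columns=nonref)
    z = 1.959963984540054  # Phi^{-1}(0.975)
    rows = []
    for level in nonref:
        for pred in spec.predictors:
            b = coefs.loc[pred, level]
            se = bse.loc[pred, level]
            p = 2.0 * (1.0 - _norm_cdf(abs(b / se))) if se > 0 else np.nan
            rows.append(
                {
                    "outcome_level": level,
                    "predictor": pred,
                    "coefficient": b,
                    "odds_ratio": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * se)),
                    "ci_high": float(np.exp(b + z * se)),
                    "p_value": p,
                }
            )
    or_table = pd.DataFrame(rows)
    return RiskModelResult(
        spec=spec,
        or_table=or_table,
        params=coefs,
        cov=np.asarray(res.cov_params()),
        n_obs=len(data),
        n_clusters=int(len(np.unique(groups))),
        _sm_result=res,
    )


def _norm_cdf(x: float) -> float:
    from math import erf, sqrt

    return 0.5 * (1.0 + erf(x / sqrt(2.0)))


def model_1_behavior(data: pd.DataFrame) -> RiskModelResult:
    """Outcome on the two percent-optimal behavioral scores."""
    return fit_multinomial_clustered(
        data, ModelSpec(("pct_optimal_reward", "pct_optimal_punishment"))
    )


def model_2_adjusted(data: pd.DataFrame) -> RiskModelResult:
    """Behavioral scores adjusted for ideation severity and prior attempts."""
    return fit_multinomial_clustered(
        data,
        ModelSpec(
            (
                "pct_optimal_reward",
                "pct_optimal_punishment",
                "ssi_at_testing",
                "n_prior_asa",
            )
        ),
    )


def model_3_r0(data: pd.DataFrame) -> RiskModelResult:
    """Ambiguous-outcome valuation R0 adjusted for the same risk covariates."""
    return fit_multinomial_clustered(
        data, ModelSpec(("r0", "ssi_at_testing", "n_prior_asa"))
    )
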
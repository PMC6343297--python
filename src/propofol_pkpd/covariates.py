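"""Covariate screening and likelihood-ratio based covariate inclusion.

Covariate candidates (bodyweight, age, gender, remifentanil infusion
rate) are first screened by regressing the post-hoc etas on each
covariate; a candidate is then incorporated into the population model
and retained only if the OFV drops by at least 7.8 points (chi-square,
1 df, p < 0.005) AND the 95% CI of the extra coefficient excludes 0.
The 3.8-point drop (p < 0.05) is the general model-building threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: OFV decrease for p<0.05 (1 df) used during model building.
DELTA_OFV_MODEL_BUILDING = 3.8
#: OFV decrease for p<0.005 (1 df) required for covariate inclusion.
DELTA_OFV_COVARIATE = 7.8
#: Tolerance for optimizer noise in nesting checks.
NESTING_TOL = 0.1


class NestingViolationError(ValueError):
    """The 'extended' model fitted worse than its nested base model."""


def cv_percent(omega2: float) -> float:
    """Inter-individual variability as CV%: 100*sqrt(exp(omega^2) - 1).

    This is the log-normal CV implied by a variance omega^2 on the log
    scale (e.g. 0.059 -> 24.7%, reported as 25%).
    """
    if omega2 < 0:
        raise ValueError(f"omega^2 must be >= 0, got {omega2}")
    return 100.0 * math.sqrt(math.expm1(omega2))


@dataclass(frozen=True)
class CovariateTestResult:
    """Outcome of one covariate inclusion test."""

    covariate: str
    parameter: str
    form: str
    delta_ofv: float
    ci_extra: tuple[float, float]
    significant_model_building: bool
    retained: bool

    def __str__(self) -> str:
        verdict = "retained" if self.retained else "not retained"
        return (
            f"{self.covariate} on {self.parameter} ({self.form}): "
            f"dOFV={self.delta_ofv:.2f}, 95% CI {self.ci_extra} -> {verdict}"
        )


def lrt_inclusion(
    ofv_base: float,
    ofv_extended: float,
    ci_of_extra: tuple[float, float],
    covariate: str = "",
    parameter: str = "",
    form: str = "",
) -> CovariateTestResult:
    """Apply the dual inclusion criterion to a base/extended model pair.

    The extended model must nest the base model with one extra parameter.
    Retention requires dOFV >= 7.8 and a 95% CI of the extra parameter
    that excludes 0; dOFV >= 3.8 marks model-building significance.
    """
    delta = ofv_base - ofv_extended
    if delta < -NESTING_TOL:
        raise NestingViolationError(
            f"extended model has higher OFV than base ({ofv_extended:.3f} > {ofv_base:.3f}); "
            "models are not nested or the fit did not converge"
        )
    delta = max(delta, 0.0)
    lo, hi = ci_of_extra
    ci_excludes_zero = (lo > 0.0) or (hi < 0.0)
    return CovariateTestResult(
        covariate=covariate,
        parameter=parameter,
        form=form,
        delta_ofv=delta,
        ci_extra=(lo, hi),
        significant_model_building=delta >= DELTA_OFV_MODEL_BUILDING - 1e-9,
        retained=(delta >= DELTA_OFV_COVARIATE - 1e-9) and ci_excludes_zero,
    )


def screen_covariates(etas: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Linear-trend screen of post-hoc etas against each covariate.

    Parameters
    ----------
    etas : DataFrame
        Post-hoc etas, one row per subject (index = subject id), one
        column per random-effect parameter.
    covariates : DataFrame
        One row per subject (same index), columns are covariates;
        a ``sex`` column with "M"/"F" is encoded as 1/0.

    Returns
    -------
    DataFrame with one row per covariate-parameter pair: slope,
    Pearson correlation and the p-value of the linear trend.  Pairs
    with a constant covariate (or constant eta) are reported with
    missing statistics rather than dropped.
    """
    if len(etas) < 3:
        raise ValueError("covariate screening requires at least 3 subjects")
    cov = covariates.loc[etas.index].copy()
    if "sex" in cov.columns:
        cov["sex"] = (cov["sex"].astype(str) == "M").astype(float)
    rows = []
    for cname in cov.columns:
        x = cov[cname].astype(float).to_numpy()
        for pname in etas.columns:
            y = etas[pname].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0.0 or np.std(y[ok]) == 0.0:
                rows.append(dict(covariate=cname, parameter=pname, slope=np.nan,
                                 correlation=np.nan, p_value=np.nan, n=int(ok.sum())))
                continue
            res = stats.linregress(x[ok], y[ok])
            rows.append(dict(covariate=cname, parameter=pname, slope=res.slope,
                             correlation=res.rvalue, p_value=res.pvalue, n=int(ok.sum())))
    return pd.DataFrame(rows)


def evaluate_covariate_inclusion(
    base_fit,
    covariate: str,
    parameter: str,
    form: str = "linear",
    **fit_kwargs,
):
    """Fit the one-covariate extension of a fitted base model and test it.

    Returns (CovariateTestResult, extended NLMEResults).  The extended
    fit starts from the base optimum with the coefficient at 0, so the
    nesting inequality holds up to optimizer noise.
    """
    from dataclasses import replace as _replace

    from .nlme import CovariateEffect, PopulationModel

    spec_ext = _replace(base_fit.spec,
                        covariate_effect=CovariateEffect(parameter=parameter,
                                                         covariate=covariate, form=form))
    init = base_fit._init_overrides()
    ext_fit = PopulationModel(base_fit.dataset, spec_ext).fit(init=init, **fit_kwargs)
    coef = spec_ext.covariate_effect.coef_name
    ci = ext_fit.ci95.get(coef, (-math.inf, math.inf))
    result = lrt_inclusion(base_fit.ofv, ext_fit.ofv, ci,
                           covariate=covariate, parameter=parameter, form=form)
    return result, ext_fit
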
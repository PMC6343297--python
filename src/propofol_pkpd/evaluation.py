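"""Internal model validation: bootstrap, NPDE and goodness-of-fit tables.

The bootstrap resamples SUBJECTS with replacement (same trial size),
refits each replicate, and summarises the replicate estimates; the
study accepted bootstrap deviations up to 5-10% for PK structural
parameters and 15-20% for PD.  NPDE simulates each subject's
observation vector under the fitted model, decorrelates observed and
simulated vectors with the Cholesky factor of the simulation
covariance, and rank-transforms to standard-normal quantiles: under a
correct model the NPDE are approximately N(0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import StudyDataset
from .nlme import NLMEResults, PopulationModel, PopulationModelSpec, _Engine, EstimationError


@dataclass
class BootstrapResult:
    """Per-replicate estimates and their summary for one population model."""

    estimates: pd.DataFrame  # one row per converged replicate
    n_requested: int
    n_converged: int
    replicate_indices: list[list[int]]
    seed: int

    @property
    def convergence_rate(self) -> float:
        return self.n_converged / self.n_requested if self.n_requested else float("nan")

    def summary(self) -> pd.DataFrame:
        """Bootstrap mean and CV% (SD/mean) per parameter."""
        mean = self.estimates.mean()
        sd = self.estimates.std(ddof=1) if len(self.estimates) > 1 else self.estimates.std(ddof=0)
        cv = 100.0 * sd / mean.abs()
        return pd.DataFrame({"mean": mean, "cv_percent": cv})


def bootstrap(
    dataset: StudyDataset,
    spec: PopulationModelSpec,
    n_reps: int = 50,
    seed: int = 0,
    init: dict | None = None,
    **fit_kwargs,
) -> BootstrapResult:
    """Subject-level bootstrap of a population model fit.

    Each replicate draws ``len(dataset)`` subjects with replacement and
    refits the model (starting from ``init``, typically the original
    estimates).  Non-converged replicates are excluded and counted.
    Reproducible given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fit_kwargs.setdefault("compute_se", False)
    fit_kwargs.setdefault("maxiter", 200)
    rng = np.random.default_rng(seed)
    rows = []
    indices: list[list[int]] = []
    n_subj = len(dataset)
    for _rep in range(n_reps):
        idx = rng.integers(0, n_subj, size=n_subj)
        indices.append([int(i) for i in idx])
        rep_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        rep = _resample_by_index(dataset, idx)
        try:
            fit = PopulationModel(rep, spec).fit(init=init, seed=int(rep_rng.integers(2**31 - 1)),
                                                 **fit_kwargs)
        except EstimationError:
            continue
        if not np.isfinite(fit.ofv):
            continue
        row = {k: v for k, v in fit.params.items()}
        row.update({f"omega2_{k}": v for k, v in fit.omega2.items()})
        row["sigma2"] = fit.sigma2
        row["ofv"] = fit.ofv
        row["converged"] = fit.converged
        rows.append(row)
    est = pd.DataFrame(rows)
    n_conv = int(est["converged"].sum()) if len(est) else 0
    if len(est) == 0:
        raise EstimationError("all bootstrap replicates failed to fit")
    est = est[est["converged"]].drop(columns=["converged"]).reset_index(drop=True)
    return BootstrapResult(estimates=est, n_requested=n_reps, n_converged=n_conv,
                           replicate_indices=indices, seed=seed)


def _resample_by_index(dataset: StudyDataset, idx) -> StudyDataset:
    from dataclasses import replace

    subjects = []
    for k, i in enumerate(idx):
        src = dataset.subjects[int(i)]
        subjects.append(replace(src, id=f"bs{k:03d}_{src.id}"))
    return StudyDataset(subjects)


@dataclass
class NpdeResult:
    """Normalized prediction distribution errors with global statistics."""

    table: pd.DataFrame  # columns: id, time, obs_type, npde
    n_sim: int
    seed: int
    ridge_applied: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.table["npde"].to_numpy()

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def variance(self) -> float:
        return float(np.var(self.values, ddof=1))

    def normality_test(self):
        """Kolmogorov-Smirnov statistic and p-value against N(0, 1)."""
        return stats.kstest(self.values, "norm")

    def t_statistic(self) -> float:
        """t statistic for mean(npde) = 0."""
        v = self.values
        return float(np.mean(v) / (np.std(v, ddof=1) / math.sqrt(v.size)))


def npde(
    dataset: StudyDataset,
    spec: PopulationModelSpec,
    fitted,
    n_sim: int = 1000,
    seed: int = 0,
) -> NpdeResult:
    """Normalized prediction distribution errors under a fitted model.

    Per subject, ``n_sim`` replicate observation vectors are simulated
    (drawing both eta and residual error), observed and simulated
    vectors are decorrelated with the inverse Cholesky factor of the
    empirical simulation covariance, and each decorrelated observation
    is rank-transformed among its decorrelated simulations with the
    1/(2*n_sim) boundary correction before applying the standard-normal
    quantile.  Rank ties are broken by seeded uniform jitter.

    ``fitted`` is an NLMEResults or a dict with keys matching the
    spec's parameters plus ``omega2:<name>`` and ``sigma2`` entries.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable NPDE")
    if isinstance(fitted, NLMEResults):
        theta = dict(fitted.params)
        omega2 = dict(fitted.omega2)
        sigma2 = fitted.sigma2
    else:
        theta = {k: v for k, v in fitted.items() if not k.startswith("omega2:") and k != "sigma2"}
        omega2 = {k.split(":", 1)[1]: v for k, v in fitted.items() if k.startswith("omega2:")}
        sigma2 = fitted["sigma2"]

    eng = _Engine(dataset, spec)
    rng = np.random.default_rng(seed)
    ridge_applied = False
    rows = []
    for ctx in eng.contexts:
        n = ctx.z.size
        if n == 0:
            continue
        sims = eng.simulate_z(ctx, theta, omega2, sigma2, n_sim, rng)
        m = sims.mean(axis=0)
        S = np.cov(sims, rowvar=False)
        S = np.atleast_2d(S)
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            ridge_applied = True
            ridge = 1e-8 * float(np.trace(S)) / n
            L = np.linalg.cholesky(S + ridge * np.eye(n))
        dec_obs = np.linalg.solve(L, ctx.z - m)
        dec_sims = np.linalg.solve(L, (sims - m).T)  # (n, n_sim)
        # rank with boundary correction; ties jittered
        jitter = rng.uniform(-1e-10, 1e-10, size=dec_sims.shape)
        counts = np.sum(dec_sims + jitter < dec_obs[:, None], axis=1)
        pde = np.clip(counts / n_sim, 1.0 / (2.0 * n_sim), 1.0 - 1.0 / (2.0 * n_sim))
        vals = stats.norm.ppf(pde)
        for t, ot, v in zip(ctx.times, [spec.obs_type] * n, vals):
            rows.append(dict(id=ctx.subject.id, time=float(t), obs_type=ot, npde=float(v)))
    table = pd.DataFrame(rows)
    if table.empty:
        raise EstimationError("no observations available for NPDE")
    return NpdeResult(table=table, n_sim=n_sim, seed=seed, ridge_applied=ridge_applied)


def gof_tables(dataset: StudyDataset, fit: NLMEResults) -> pd.DataFrame:
    """Tidy goodness-of-fit table (tabular stand-in for diagnostic plots).

    One row per observation with the observed value, the individual
    prediction (post-hoc eta), the population prediction (eta = 0) and
    the weighted residual (obs - population prediction) / population SD
    on the fitting scale.
    """
    eng = fit.model.engine
    theta = dict(fit.params)
    sd = math.sqrt(fit.sigma2)
    q = eng.q
    rows = []
    for ctx in eng.contexts:
        if ctx.z.size == 0:
            continue
        eta_hat = fit.etas.loc[ctx.subject.id].to_numpy(dtype=float) if q else np.zeros(0)
        zp_pop = eng._predict_z(ctx, theta, np.zeros(q))
        zp_ind = eng._predict_z(ctx, theta, eta_hat)
        wres = (ctx.z - zp_pop) / sd
        if fit.spec.residual.kind == "log_proportional":
            pred_pop, pred_ind = np.exp(zp_pop), np.exp(zp_ind)
        else:
            pred_pop, pred_ind = zp_pop, zp_ind
        for j in range(ctx.z.size):
            rows.append(
                dict(
                    id=ctx.subject.id,
                    time=float(ctx.times[j]),
                    obs_type=fit.spec.obs_type,
                    observed=float(ctx.y[j]),
                    ipred=float(pred_ind[j]),
                    pred=float(pred_pop[j]),
                    wres=float(wres[j]),
                )
            )
    cols = ["id", "time", "obs_type", "observed", "ipred", "pred", "wres"]
    return pd.DataFrame(rows, columns=cols)
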
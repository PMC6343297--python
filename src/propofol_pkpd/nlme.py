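"""Nonlinear mixed-effects estimation for population PK-PD models.

The model for subject i with random-effect vector eta_i ~ N(0, Omega)
(diagonal) is

    P_i = P_tv * exp(eta_i)        (log-normal inter-individual variability)

with residual error either additive on the log-concentration scale
(proportional error for PK) or additive in index units (PD):

    y_ij = log c_pred,ij + eps_ij      or      y_ij = PD_pred,ij + eps_ij

The marginal -2 log likelihood (OFV) is approximated subject-by-subject
by linearisation about the conditional mode of eta (FOCE with
interaction; with constant residual variance on the fitting scale the
interaction term is exact) or by a full Laplace approximation.  Fixed
effects are estimated on the log scale (logit for bounded fractions),
so positivity is enforced by construction.  The OFV convention keeps
the 2*pi constants; only OFV differences are compared to chi-square
thresholds, so the constant convention does not affect decisions.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .biophase import effect_site_from_states, pd_response
from .data import StudyDataset, Subject
from .params import (
    BiophaseParameters,
    InvalidParameterError,
    PDParameters,
    PKParameters,
)
from .pk import solve_pk

_LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1.0e8  # per-subject contribution when the model cannot be evaluated


class EstimationError(RuntimeError):
    """The population likelihood could not be evaluated anywhere useful."""


class _PredictionFailure(Exception):
    """Structural prediction invalid at the attempted parameter values."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass
class FixedEffect:
    """One structural (population typical-value) parameter."""

    name: str
    init: float
    fixed: bool = False
    transform: str = "log"  # log | logit | identity

    def __post_init__(self) -> None:
        if self.transform not in ("log", "logit", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class RandomEffectsSpec:
    """Diagonal inter-individual variance spec: parameter name -> omega^2."""

    omega2: dict[str, float]
    fixed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.omega2.items():
            if v < 0:
                raise ValueError(f"omega^2 for {name} must be >= 0, got {v}")

    @property
    def names(self) -> list[str]:
        return list(self.omega2.keys())


@dataclass
class ResidualErrorSpec:
    """Residual model: proportional-on-log-scale (PK) or additive (PD)."""

    kind: str  # "log_proportional" | "additive"
    sigma2: float
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("log_proportional", "additive"):
            raise ValueError(f"unknown residual kind {self.kind!r}")
        if not self.sigma2 > 0:
            raise ValueError("sigma^2 must be > 0")


@dataclass
class CovariateEffect:
    """A single tested covariate-parameter relation.

    Forms (x = covariate value, m = dataset median, beta = coefficient):
      linear:     P *= 1 + beta * (x - m) / m
      power:      P *= (x / m) ** beta
      fractional: P *= 1 + beta * [sex == "M"]   (for the binary covariate)
    """

    parameter: str
    covariate: str
    form: str = "linear"
    init: float = 0.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.form not in ("linear", "power", "fractional"):
            raise ValueError(f"unknown covariate form {self.form!r}")

    @property
    def coef_name(self) -> str:
        return f"beta_{self.covariate}_{self.parameter}"


@dataclass
class PopulationModelSpec:
    """Structural model + fixed effects + IIV + residual spec.

    This is the unit of fitting and simulation: it names which
    observation type it explains, which fixed effects are estimated,
    which parameters carry an eta, and the residual error model.
    """

    structural: "StructuralModel"
    fixed_effects: list[FixedEffect]
    random_effects: RandomEffectsSpec
    residual: ResidualErrorSpec
    covariate_effect: Optional[CovariateEffect] = None

    def __post_init__(self) -> None:
        names = [fe.name for fe in self.fixed_effects]
        if len(set(names)) != len(names):
            raise ValueError("duplicate fixed-effect names")
        missing = set(self.structural.param_names) - set(names)
        if missing:
            raise ValueError(f"structural parameters without a fixed effect: {sorted(missing)}")
        bad = set(self.random_effects.names) - set(names)
        if bad:
            raise ValueError(f"random effects on unknown parameters: {sorted(bad)}")

    @property
    def obs_type(self) -> str:
        return self.structural.obs_type

    def theta_init(self) -> dict[str, float]:
        return {fe.name: fe.init for fe in self.fixed_effects}

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)


# ---------------------------------------------------------------------------
# structural models
# ---------------------------------------------------------------------------


class StructuralModel:
    """Interface: predict natural-scale observations for one subject."""

    obs_type: str
    param_names: tuple[str, ...]

    def predict(self, subject: Subject, times: np.ndarray, params: dict[str, float]) -> np.ndarray:
        raise NotImplementedError


class TwoCompartmentPK(StructuralModel):
    """Two-compartment disposition; predicts blood concentration (mg/L)."""

    obs_type = "conc"
    param_names = ("CL", "Q", "V1", "V2")

    def predict(self, subject: Subject, times: np.ndarray, params: dict[str, float]) -> np.ndarray:
        try:
            pk = PKParameters(CL=params["CL"], Q=params["Q"], V1=params["V1"], V2=params["V2"])
        except InvalidParameterError as exc:
            raise _PredictionFailure(str(exc)) from exc
        return solve_pk(pk, subject.doses, times).cb


class EffectSiteEmax(StructuralModel):
    """Effect-site biophase + inhibitory sigmoid Emax for a depth index.

    Requires each subject's individual PK parameters (``subject.pk_params``,
    set by the sequential PD step).  ``emax_fraction=True`` parameterises
    the maximum effect as a fraction of baseline (cAAI convention);
    otherwise Emax is absolute (BIS convention, both fixed at 100).
    """

    def __init__(self, index: str = "BIS", order: int = 2, emax_fraction: bool = False):
        if index not in ("BIS", "cAAI"):
            raise ValueError("index must be 'BIS' or 'cAAI'")
        if order not in (1, 2):
            raise ValueError("biophase order must be 1 or 2")
        self.obs_type = index
        self.order = order
        self.emax_fraction = emax_fraction
        emax_name = "Emax_frac" if emax_fraction else "Emax"
        names = ["E0", emax_name, "EC50", "gamma", "ke0"]
        if order == 2:
            names += ["ke12", "ke21"]
        self.param_names = tuple(names)

    def predict(self, subject: Subject, times: np.ndarray, params: dict[str, float]) -> np.ndarray:
        if subject.pk_params is None:
            raise EstimationError(
                f"subject {subject.id} has no individual PK parameters; "
                "run the PK fit and attach post-hoc values before the PD fit"
            )
        try:
            bp = BiophaseParameters(
                ke0=params["ke0"],
                ke12=params.get("ke12", 0.0),
                ke21=params.get("ke21", 0.0),
                order=self.order,
            )
            emax = (
                params["Emax_frac"] * params["E0"] if self.emax_fraction else params["Emax"]
            )
            pdp = PDParameters(E0=params["E0"], Emax=emax, EC50=params["EC50"], gamma=params["gamma"])
        except InvalidParameterError as exc:
            raise _PredictionFailure(str(exc)) from exc
        ce = effect_site_from_states(subject.pk_params, bp, subject.doses, times)
        return pd_response(ce, pdp)


# ---------------------------------------------------------------------------
# parameter packing (estimation scale)
# ---------------------------------------------------------------------------


def _fwd(v: float, transform: str) -> float:
    if transform == "log":
        return math.log(v)
    if transform == "logit":
        return math.log(v / (1.0 - v))
    return v


def _inv(x: float, transform: str) -> float:
    if transform == "log":
        return math.exp(x)
    if transform == "logit":
        return 1.0 / (1.0 + math.exp(-x))
    return x


@dataclass
class _Entry:
    key: str  # e.g. "theta:CL", "omega2:CL", "sigma2"
    kind: str
    name: str
    transform: str
    init: float
    fixed: bool


class _ParamTable:
    def __init__(self, spec: PopulationModelSpec):
        self.entries: list[_Entry] = []
        for fe in spec.fixed_effects:
            self.entries.append(
                _Entry(f"theta:{fe.name}", "theta", fe.name, fe.transform, fe.init, fe.fixed)
            )
        if spec.covariate_effect is not None:
            ce = spec.covariate_effect
            self.entries.append(
                _Entry(f"theta:{ce.coef_name}", "covariate", ce.coef_name, "identity", ce.init, ce.fixed)
            )
        for name, om in spec.random_effects.omega2.items():
            fixed = spec.random_effects.fixed.get(name, False)
            self.entries.append(_Entry(f"omega2:{name}", "omega2", name, "log", om, fixed))
        self.entries.append(_Entry("sigma2", "sigma2", "sigma2", "log", spec.residual.sigma2, spec.residual.fixed))
        self.free = [e for e in self.entries if not e.fixed]

    def x0(self, overrides: Optional[dict[str, float]] = None) -> np.ndarray:
        vals = []
        for e in self.free:
            v = e.init
            if overrides and e.key in overrides:
                v = overrides[e.key]
            elif overrides and e.name in overrides and e.kind in ("theta", "covariate"):
                v = overrides[e.name]
            vals.append(_fwd(v, e.transform))
        return np.array(vals)

    def unpack(self, x: np.ndarray):
        theta: dict[str, float] = {}
        omega2: dict[str, float] = {}
        sigma2 = None
        xi = iter(x)
        for e in self.entries:
            v = e.init if e.fixed else _inv(next(xi), e.transform)
            if e.kind in ("theta", "covariate"):
                theta[e.name] = v
            elif e.kind == "omega2":
                omega2[e.name] = v
            else:
                sigma2 = v
        return theta, omega2, sigma2


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


@dataclass
class _SubjectContext:
    subject: Subject
    times: np.ndarray
    y: np.ndarray  # natural scale
    z: np.ndarray  # fitting scale (log for PK)


class _Engine:
    """Per-dataset likelihood machinery shared by fit / post-hoc / OFV."""

    def __init__(self, dataset: StudyDataset, spec: PopulationModelSpec):
        self.spec = spec
        self.dataset = dataset
        self.table = _ParamTable(spec)
        self.eta_names = spec.random_effects.names
        self.q = len(self.eta_names)
        self.contexts: list[_SubjectContext] = []
        for s in dataset.subjects:
            obs = s.obs_of_type(spec.obs_type, exclude_below_loq=True)
            times = np.array([o.time for o in obs])
            y = np.array([o.value for o in obs])
            if spec.residual.kind == "log_proportional":
                if np.any(y <= 0):
                    raise EstimationError(
                        f"subject {s.id}: non-positive concentration above LOQ cannot be log-transformed"
                    )
                z = np.log(y)
            else:
                z = y.copy()
            self.contexts.append(_SubjectContext(subject=s, times=times, y=y, z=z))
        self.n_obs = int(sum(c.z.size for c in self.contexts))
        self._eta_cache: dict[str, np.ndarray] = {}
        self.cov_median: Optional[float] = None
        if spec.covariate_effect is not None and spec.covariate_effect.form != "fractional":
            vals = [getattr(s, spec.covariate_effect.covariate) for s in dataset.subjects]
            self.cov_median = float(np.median(vals))

    # -- individual parameters -------------------------------------------

    def individual_params(self, ctx: _SubjectContext, theta: dict, eta: np.ndarray) -> dict:
        params = {k: v for k, v in theta.items() if not k.startswith("beta_")}
        ce = self.spec.covariate_effect
        if ce is not None:
            beta = theta[ce.coef_name]
            if ce.form == "fractional":
                mult = 1.0 + beta * (1.0 if ctx.subject.sex == "M" else 0.0)
            else:
                x = getattr(ctx.subject, ce.covariate)
                if ce.form == "linear":
                    mult = 1.0 + beta * (x - self.cov_median) / self.cov_median
                else:
                    mult = (x / self.cov_median) ** beta
            if not (mult > 0.0) or not math.isfinite(mult):
                raise _PredictionFailure("covariate multiplier non-positive")
            params[ce.parameter] = params[ce.parameter] * mult
        for k, name in enumerate(self.eta_names):
            params[name] = params[name] * math.exp(eta[k])
        return params

    def _predict_z(self, ctx: _SubjectContext, theta: dict, eta: np.ndarray) -> np.ndarray:
        params = self.individual_params(ctx, theta, eta)
        pred = self.spec.structural.predict(ctx.subject, ctx.times, params)
        if not np.all(np.isfinite(pred)):
            raise _PredictionFailure("non-finite prediction")
        if self.spec.residual.kind == "log_proportional":
            if np.any(pred <= 0.0):
                raise _PredictionFailure("non-positive predicted concentration at an observation")
            return np.log(pred)
        return pred

    # -- per-subject likelihood ------------------------------------------

    def _prior_terms(self, omega2: dict[str, float]):
        om = np.array([max(omega2[n], 1e-12) for n in self.eta_names])
        om_inv = np.diag(1.0 / om) if self.q else np.zeros((0, 0))
        logdet_2pi_om = float(np.sum(np.log(2.0 * math.pi * om))) if self.q else 0.0
        return om_inv, logdet_2pi_om

    def joint_minus2ll(self, ctx, theta, omega2, sigma2, eta) -> float:
        """-2 log p(y, eta) (joint density; prior-only when no observations)."""
        om_inv, ld = self._prior_terms(omega2)
        prior = float(eta @ om_inv @ eta) + ld if self.q else 0.0
        if ctx.z.size == 0:
            return prior
        fz = self._predict_z(ctx, theta, eta)
        r = ctx.z - fz
        return float(r @ r / sigma2 + ctx.z.size * math.log(2.0 * math.pi * sigma2) + prior)

    def _jac(self, ctx, theta, eta, fz0, h: float = 1e-4) -> np.ndarray:
        J = np.zeros((ctx.z.size, self.q))
        for k in range(self.q):
            ep = eta.copy()
            ep[k] += h
            em = eta.copy()
            em[k] -= h
            J[:, k] = (self._predict_z(ctx, theta, ep) - self._predict_z(ctx, theta, em)) / (2 * h)
        return J

    def conditional_mode(self, ctx, theta, omega2, sigma2, eta0=None):
        """Gauss-Newton search for the conditional mode of eta (posthoc)."""
        om_inv, ld = self._prior_terms(omega2)
        if self.q == 0 or ctx.z.size == 0:
            eta = np.zeros(self.q)
            return eta, np.zeros((ctx.z.size, self.q))
        eta = np.zeros(self.q) if eta0 is None else eta0.copy()
        try:
            fz = self._predict_z(ctx, theta, eta)
        except _PredictionFailure:
            eta = np.zeros(self.q)
            fz = self._predict_z(ctx, theta, eta)  # may raise again -> caller handles

        def obj(fz_val, eta_val):
            r = ctx.z - fz_val
            return float(r @ r / sigma2 + eta_val @ om_inv @ eta_val)

        cur = obj(fz, eta)
        J = self._jac(ctx, theta, eta, fz)
        for _ in range(60):
            r = ctx.z - fz
            g = -(J.T @ r) / sigma2 + om_inv @ eta
            H = J.T @ J / sigma2 + om_inv
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = g / (np.diag(H) + 1e-8)
            alpha = 1.0
            improved = False
            while alpha > 1e-6:
                eta_new = eta - alpha * step
                try:
                    fz_new = self._predict_z(ctx, theta, eta_new)
                except _PredictionFailure:
                    alpha *= 0.5
                    continue
                new = obj(fz_new, eta_new)
                if new <= cur + 1e-12:
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                break
            moved = float(np.max(np.abs(alpha * step)))
            eta, fz, cur = eta_new, fz_new, new
            J = self._jac(ctx, theta, eta, fz)
            if moved < 1e-9:
                break
        return eta, J

    def subject_ofv(self, ctx, theta, omega2, sigma2, method="foce", eta0=None):
        """FOCE/Laplace -2 log marginal likelihood contribution of one subject."""
        om_inv, ld = self._prior_terms(omega2)
        if ctx.z.size == 0:
            return 0.0, np.zeros(self.q)
        if self.q == 0:
            fz = self._predict_z(ctx, theta, np.zeros(0))
            r = ctx.z - fz
            val = float(r @ r / sigma2 + ctx.z.size * math.log(2 * math.pi * sigma2))
            return val, np.zeros(0)
        eta, J = self.conditional_mode(ctx, theta, omega2, sigma2, eta0=eta0)
        l2 = self.joint_minus2ll(ctx, theta, omega2, sigma2, eta)
        if method == "laplace":
            H = self._numeric_half_hessian(ctx, theta, omega2, sigma2, eta)
            if H is None or not np.all(np.linalg.eigvalsh((H + H.T) / 2) > 0):
                H = J.T @ J / sigma2 + om_inv
        else:
            H = J.T @ J / sigma2 + om_inv
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            raise _PredictionFailure("non-positive-definite conditional Hessian")
        return float(l2 - self.q * _LOG2PI + logdet), eta

    def _numeric_half_hessian(self, ctx, theta, omega2, sigma2, eta, h=1e-3):
        """Hessian of the negative log joint density (0.5 * joint -2ll)."""
        q = self.q

        def f(e):
            return 0.5 * self.joint_minus2ll(ctx, theta, omega2, sigma2, e)

        try:
            H = np.zeros((q, q))
            f0 = f(eta)
            for i in range(q):
                for j in range(i, q):
                    ei = np.zeros(q)
                    ej = np.zeros(q)
                    ei[i] = h
                    ej[j] = h
                    if i == j:
                        H[i, i] = (f(eta + ei) - 2 * f0 + f(eta - ei)) / h**2
                    else:
                        H[i, j] = H[j, i] = (
                            f(eta + ei + ej) - f(eta + ei - ej) - f(eta - ei + ej) + f(eta - ei - ej)
                        ) / (4 * h**2)
            return H
        except _PredictionFailure:
            return None

    # -- population OFV ---------------------------------------------------

    def ofv_parts(self, theta, omega2, sigma2, method="foce", use_cache=True):
        total = 0.0
        n_fail = 0
        for ctx in self.contexts:
            eta0 = self._eta_cache.get(ctx.subject.id) if use_cache else None
            try:
                val, eta = self.subject_ofv(ctx, theta, omega2, sigma2, method=method, eta0=eta0)
                self._eta_cache[ctx.subject.id] = eta
            except (_PredictionFailure, EstimationError, np.linalg.LinAlgError) as exc:
                if isinstance(exc, EstimationError):
                    raise
                val = _PENALTY
                n_fail += 1
            total += val
        return total, n_fail

    def ofv_x(self, x: np.ndarray, method="foce") -> float:
        theta, omega2, sigma2 = self.table.unpack(x)
        total, n_fail = self.ofv_parts(theta, omega2, sigma2, method=method)
        return total

    def posthoc(self, theta, omega2, sigma2) -> pd.DataFrame:
        rows = {}
        for ctx in self.contexts:
            try:
                eta, _ = self.conditional_mode(ctx, theta, omega2, sigma2,
                                               eta0=self._eta_cache.get(ctx.subject.id))
            except _PredictionFailure:
                eta = np.full(self.q, np.nan)
            rows[ctx.subject.id] = eta
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.eta_names)

    def simulate_z(self, ctx, theta, omega2, sigma2, n_sim: int, rng: np.random.Generator):
        """Simulate n_sim replicate fitting-scale observation vectors."""
        om = np.array([omega2[n] for n in self.eta_names]) if self.q else np.zeros(0)
        sims = np.empty((n_sim, ctx.z.size))
        sd = math.sqrt(sigma2)
        for k in range(n_sim):
            eta = rng.normal(0.0, np.sqrt(om)) if self.q else np.zeros(0)
            fz = self._predict_z(ctx, theta, eta)
            sims[k] = fz + rng.normal(0.0, sd, size=ctx.z.size)
        return sims


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------


class NLMEResults:
    """Estimates, uncertainties and diagnostics of a population fit.

    Attributes
    ----------
    params : dict
        Fixed-effect estimates on the natural scale (fixed values included).
    omega2, sigma2 : dict, float
        Variance-component estimates.
    se, ci95 : dict
        Approximate standard errors (natural scale, delta method) and 95%
        confidence intervals, symmetric on the estimation scale.
    ofv : float
        -2 log approximate marginal likelihood (2*pi constants included).
    etas : pandas.DataFrame
        Empirical-Bayes (post-hoc) eta per subject.
    """

    def __init__(self, model, theta, omega2, sigma2, ofv, etas, converged, message,
                 n_iter, trace, method, se=None, ci95=None, cov_x=None, x_hat=None,
                 elapsed=0.0):
        self.model = model
        self.params = theta
        self.omega2 = omega2
        self.sigma2 = sigma2
        self.ofv = ofv
        self.etas = etas
        self.converged = converged
        self.message = message
        self.n_iter = n_iter
        self.trace = trace
        self.method = method
        self.se = se or {}
        self.ci95 = ci95 or {}
        self.cov_x = cov_x
        self.x_hat = x_hat
        self.elapsed = elapsed

    @property
    def spec(self) -> PopulationModelSpec:
        return self.model.spec

    @property
    def dataset(self) -> StudyDataset:
        return self.model.dataset

    def cv_percent(self) -> dict[str, float]:
        """IIV as CV%: 100*sqrt(exp(omega^2) - 1) per random effect."""
        from .covariates import cv_percent as _cv

        return {name: _cv(v) for name, v in self.omega2.items()}

    def individual_parameters(self) -> pd.DataFrame:
        """P_i = P_tv * exp(eta_i) for each subject and random-effect parameter."""
        recs = {}
        for sid, row in self.etas.iterrows():
            vals = {}
            for name in self.spec.structural.param_names:
                v = self.params[name]
                if name in self.etas.columns:
                    v = v * math.exp(row[name])
                vals[name] = v
            recs[sid] = vals
        return pd.DataFrame.from_dict(recs, orient="index")

    def individual_pk_parameters(self) -> dict[str, PKParameters]:
        """Post-hoc PKParameters per subject (PK fits only)."""
        if not isinstance(self.spec.structural, TwoCompartmentPK):
            raise TypeError("individual PK parameters are defined for PK fits only")
        out = {}
        ip = self.individual_parameters()
        for sid, row in ip.iterrows():
            out[sid] = PKParameters(CL=row["CL"], Q=row["Q"], V1=row["V1"], V2=row["V2"])
        return out

    def summary(self) -> str:
        lines = []
        kind = type(self.spec.structural).__name__
        lines.append(f"Population {kind} fit ({self.method.upper()}), obs type {self.spec.obs_type}")
        lines.append(
            f"subjects: {len(self.dataset)}   observations: {self.model.engine.n_obs}   "
            f"OFV: {self.ofv:.3f}   converged: {self.converged}"
        )
        lines.append("-" * 72)
        lines.append(f"{'parameter':<16}{'estimate':>12}{'SE':>12}{'95% CI':>26}")
        for fe in self.spec.fixed_effects:
            est = self.params[fe.name]
            if fe.fixed:
                lines.append(f"{fe.name:<16}{est:>12.4g}{'fixed':>12}")
                continue
            se = self.se.get(fe.name)
            ci = self.ci95.get(fe.name)
            se_s = f"{se:.3g}" if se is not None else "-"
            ci_s = f"({ci[0]:.4g}, {ci[1]:.4g})" if ci else "-"
            lines.append(f"{fe.name:<16}{est:>12.4g}{se_s:>12}{ci_s:>26}")
        ce = self.spec.covariate_effect
        if ce is not None:
            est = self.params[ce.coef_name]
            ci = self.ci95.get(ce.coef_name)
            ci_s = f"({ci[0]:.4g}, {ci[1]:.4g})" if ci else "-"
            se = self.se.get(ce.coef_name)
            se_s = f"{se:.3g}" if se is not None else "-"
            lines.append(f"{ce.coef_name:<16}{est:>12.4g}{se_s:>12}{ci_s:>26}")
        for name, v in self.omega2.items():
            cv = self.cv_percent()[name]
            lines.append(f"{'omega2_' + name:<16}{v:>12.4g}{'':>12}  CV {cv:.1f}%")
        lines.append(f"{'sigma2':<16}{self.sigma2:>12.4g}  ({self.spec.residual.kind})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "structural": type(self.spec.structural).__name__,
            "obs_type": self.spec.obs_type,
            "method": self.method,
            "ofv": self.ofv,
            "converged": bool(self.converged),
            "params": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "ci95": {k: [float(a), float(b)] for k, (a, b) in self.ci95.items()},
            "omega2": {k: float(v) for k, v in self.omega2.items()},
            "sigma2": float(self.sigma2),
            "etas": {str(i): {c: float(v) for c, v in row.items()} for i, row in self.etas.iterrows()},
            "ofv_trace": [float(v) for v in self.trace],
        }

    # evaluation conveniences -------------------------------------------

    def bootstrap(self, n_reps: int = 50, seed: int = 0, **fit_kwargs):
        from .evaluation import bootstrap as _bootstrap

        return _bootstrap(self.dataset, self.spec, n_reps=n_reps, seed=seed,
                          init=self._init_overrides(), **fit_kwargs)

    def npde(self, n_sim: int = 1000, seed: int = 0):
        from .evaluation import npde as _npde

        return _npde(self.dataset, self.spec, self, n_sim=n_sim, seed=seed)

    def gof_table(self) -> pd.DataFrame:
        from .evaluation import gof_tables as _gof

        return _gof(self.dataset, self)

    def _init_overrides(self) -> dict[str, float]:
        out = dict(self.params)
        for k, v in self.omega2.items():
            out[f"omega2:{k}"] = v
        out["sigma2"] = self.sigma2
        return out


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------


class PopulationModel:
    """Nonlinear mixed-effects model bound to a dataset.

    Parameters
    ----------
    dataset : StudyDataset
    spec : PopulationModelSpec

    Examples
    --------
    >>> model = PopulationModel(dataset, pk_model_spec())
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, dataset: StudyDataset, spec: PopulationModelSpec):
        if len(dataset) == 0:
            raise EstimationError("dataset has no subjects")
        self.dataset = dataset
        self.spec = spec
        self.engine = _Engine(dataset, spec)

    def ofv(self, params: Optional[dict] = None, method: str = "foce") -> float:
        """Population OFV at given (or initial) parameter values."""
        x = self.engine.table.x0(params)
        return self.engine.ofv_x(x, method=method)

    def posthoc(self, params: Optional[dict] = None) -> pd.DataFrame:
        x = self.engine.table.x0(params)
        theta, omega2, sigma2 = self.engine.table.unpack(x)
        return self.engine.posthoc(theta, omega2, sigma2)

    def evaluate(self, params: Optional[dict] = None, method: str = "foce") -> NLMEResults:
        """Results object at fixed parameter values (no optimization).

        Useful for diagnostics (GOF tables, NPDE) at externally supplied
        or true simulation parameters.
        """
        x = self.engine.table.x0(params)
        theta, omega2, sigma2 = self.engine.table.unpack(x)
        ofv_val = self.engine.ofv_x(x, method=method)
        etas = self.engine.posthoc(theta, omega2, sigma2)
        return NLMEResults(
            model=self, theta=theta, omega2=omega2, sigma2=sigma2, ofv=float(ofv_val),
            etas=etas, converged=True, message="evaluated at fixed parameters",
            n_iter=0, trace=[float(ofv_val)], method=method, x_hat=x.copy(),
        )

    def fit(
        self,
        init: Optional[dict] = None,
        method: str = "foce",
        n_restarts: int = 1,
        seed: int = 0,
        compute_se: bool = True,
        maxiter: int = 400,
        ftol: float = 1e-9,
        verbose: bool = False,
    ) -> NLMEResults:
        """Estimate population parameters by minimising the FOCE/Laplace OFV.

        ``n_restarts > 1`` reruns the quasi-Newton search from jittered
        initialisations (jitter seeded by ``seed``) and keeps the best
        optimum.  Positivity is enforced through the estimation-scale
        transforms.  Non-convergence is flagged on the result, with the
        best point retained.
        """
        t0 = _time.perf_counter()
        eng = self.engine
        table = eng.table
        x0 = table.x0(init)
        try:
            f0 = eng.ofv_x(x0, method=method)
        except EstimationError:
            raise
        if not np.isfinite(f0) or f0 >= _PENALTY:
            raise EstimationError(
                "likelihood failure for every subject at the initial estimates; "
                "check initial values and the dataset"
            )

        rng = np.random.default_rng(seed)
        trace: list[float] = [f0]
        best = None
        for r in range(max(n_restarts, 1)):
            xs = x0 if r == 0 else x0 + rng.normal(0.0, 0.15, size=x0.size)
            eng._eta_cache = {}

            def fun(x):
                v = eng.ofv_x(x, method=method)
                trace.append(v)
                return v

            res = optimize.minimize(
                fun,
                xs,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-6, "eps": 1e-4},
            )
            if verbose:
                print(f"restart {r}: OFV {res.fun:.4f} ({res.message})")
            if best is None or res.fun < best.fun:
                best = res

        theta, omega2, sigma2 = table.unpack(best.x)
        # final OFV and post-hoc etas at the optimum
        eng._eta_cache = {}
        ofv_hat = eng.ofv_x(best.x, method=method)
        etas = eng.posthoc(theta, omega2, sigma2)

        se: dict[str, float] = {}
        ci: dict[str, tuple[float, float]] = {}
        cov_x = None
        if compute_se and len(table.free):
            cov_x = self._covariance(best.x, method=method)
            if cov_x is not None:
                for i, e in enumerate(table.free):
                    sd_x = math.sqrt(max(cov_x[i, i], 0.0))
                    xv = best.x[i]
                    lo, hi = _inv(xv - 1.96 * sd_x, e.transform), _inv(xv + 1.96 * sd_x, e.transform)
                    est = _inv(xv, e.transform)
                    if e.transform == "log":
                        se_nat = est * sd_x
                    elif e.transform == "logit":
                        se_nat = est * (1 - est) * sd_x
                    else:
                        se_nat = sd_x
                    name = e.name if e.kind in ("theta", "covariate") else (
                        f"omega2_{e.name}" if e.kind == "omega2" else "sigma2"
                    )
                    se[name] = se_nat
                    ci[name] = (min(lo, hi), max(lo, hi))

        converged = bool(best.success and np.isfinite(ofv_hat))
        return NLMEResults(
            model=self,
            theta=theta,
            omega2=omega2,
            sigma2=sigma2,
            ofv=float(ofv_hat),
            etas=etas,
            converged=converged,
            message=str(best.message),
            n_iter=int(best.nit),
            trace=trace,
            method=method,
            se=se,
            ci95=ci,
            cov_x=cov_x,
            x_hat=best.x.copy(),
            elapsed=_time.perf_counter() - t0,
        )

    def _covariance(self, x: np.ndarray, method: str, h: float = 1e-3):
        """2 * inverse numerical Hessian of the OFV (observed information)."""
        eng = self.engine
        n = x.size
        H = np.zeros((n, n))
        try:
            f0 = eng.ofv_x(x, method=method)
            for i in range(n):
                for j in range(i, n):
                    ei = np.zeros(n)
                    ej = np.zeros(n)
                    ei[i] = h
                    ej[j] = h
                    if i == j:
                        H[i, i] = (eng.ofv_x(x + ei, method=method) - 2 * f0 + eng.ofv_x(x - ei, method=method)) / h**2
                    else:
                        fpp = eng.ofv_x(x + ei + ej, method=method)
                        fpm = eng.ofv_x(x + ei - ej, method=method)
                        fmp = eng.ofv_x(x - ei + ej, method=method)
                        fmm = eng.ofv_x(x - ei - ej, method=method)
                        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
        except (EstimationError, _PredictionFailure):
            return None
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = 2.0 * np.linalg.pinv(H)
        return cov


# ---------------------------------------------------------------------------
# default model specifications
# ---------------------------------------------------------------------------


def pk_model_spec(
    init: Optional[dict[str, float]] = None,
    omega2_cl: Optional[float] = 0.1,
    sigma2: float = 0.05,
    sigma2_fixed: bool = False,
    covariate_effect: Optional[CovariateEffect] = None,
) -> PopulationModelSpec:
    """Two-compartment PK model: eta on CL, proportional-on-log residual.

    ``omega2_cl=None`` gives the fixed-effects-only model (no IIV).
    """
    defaults = {"CL": 2.0, "Q": 1.0, "V1": 5.0, "V2": 40.0}
    if init:
        defaults.update(init)
    return PopulationModelSpec(
        structural=TwoCompartmentPK(),
        fixed_effects=[FixedEffect(n, defaults[n]) for n in ("CL", "Q", "V1", "V2")],
        random_effects=RandomEffectsSpec({} if omega2_cl is None else {"CL": omega2_cl}),
        residual=ResidualErrorSpec("log_proportional", sigma2, fixed=sigma2_fixed),
        covariate_effect=covariate_effect,
    )


def bis_pd_spec(
    init: Optional[dict[str, float]] = None,
    order: int = 2,
    omega2: Optional[dict[str, float]] = None,
    sigma2: float = 40.0,
    covariate_effect: Optional[CovariateEffect] = None,
) -> PopulationModelSpec:
    """BIS model: E0 and Emax fixed at 100, effect-site biophase + sigmoid Emax."""
    defaults = {"EC50": 2.0, "gamma": 2.0, "ke0": 0.2, "ke12": 0.1, "ke21": 0.1}
    if init:
        defaults.update(init)
    fes = [
        FixedEffect("E0", 100.0, fixed=True, transform="identity"),
        FixedEffect("Emax", 100.0, fixed=True, transform="identity"),
        FixedEffect("EC50", defaults["EC50"]),
        FixedEffect("gamma", defaults["gamma"]),
        FixedEffect("ke0", defaults["ke0"]),
    ]
    if order == 2:
        fes += [FixedEffect("ke12", defaults["ke12"]), FixedEffect("ke21", defaults["ke21"])]
    om = {"EC50": 0.1, "gamma": 0.1, "ke0": 0.1}
    if omega2:
        om.update(omega2)
    return PopulationModelSpec(
        structural=EffectSiteEmax(index="BIS", order=order, emax_fraction=False),
        fixed_effects=fes,
        random_effects=RandomEffectsSpec(om),
        residual=ResidualErrorSpec("additive", sigma2),
        covariate_effect=covariate_effect,
    )


def caai_pd_spec(
    init: Optional[dict[str, float]] = None,
    order: int = 1,
    omega2: Optional[dict[str, float]] = None,
    sigma2: float = 100.0,
    covariate_effect: Optional[CovariateEffect] = None,
) -> PopulationModelSpec:
    """cAAI model: baseline estimated, Emax as a fraction of baseline."""
    defaults = {"E0": 60.0, "Emax_frac": 0.8, "EC50": 2.0, "gamma": 4.0,
                "ke0": 0.1, "ke12": 0.1, "ke21": 0.1}
    if init:
        defaults.update(init)
    fes = [
        FixedEffect("E0", defaults["E0"]),
        FixedEffect("Emax_frac", defaults["Emax_frac"], transform="logit"),
        FixedEffect("EC50", defaults["EC50"]),
        FixedEffect("gamma", defaults["gamma"]),
        FixedEffect("ke0", defaults["ke0"]),
    ]
    if order == 2:
        fes += [FixedEffect("ke12", defaults["ke12"]), FixedEffect("ke21", defaults["ke21"])]
    om = {"EC50": 0.1, "gamma": 0.1, "ke0": 0.1}
    if omega2:
        om.update(omega2)
    return PopulationModelSpec(
        structural=EffectSiteEmax(index="cAAI", order=order, emax_fraction=True),
        fixed_effects=fes,
        random_effects=RandomEffectsSpec(om),
        residual=ResidualErrorSpec("additive", sigma2),
        covariate_effect=covariate_effect,
    )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def individual_loglik(
    spec: PopulationModelSpec,
    subject: Subject,
    eta: Sequence[float],
    params: Optional[dict] = None,
) -> float:
    """Joint log-density contribution log p(y | eta) + log p(eta)."""
    eng = _Engine(StudyDataset([subject]), spec)
    x = eng.table.x0(params)
    theta, omega2, sigma2 = eng.table.unpack(x)
    return -0.5 * eng.joint_minus2ll(eng.contexts[0], theta, omega2, sigma2, np.asarray(eta, float))


def ofv(
    spec: PopulationModelSpec,
    dataset: StudyDataset,
    params: Optional[dict] = None,
    method: str = "foce",
) -> float:
    """-2 x approximate marginal log-likelihood, summed over subjects."""
    return PopulationModel(dataset, spec).ofv(params, method=method)


def fit_population(spec: PopulationModelSpec, dataset: StudyDataset, init=None, **kw) -> NLMEResults:
    """Fit a population model (see :meth:`PopulationModel.fit`)."""
    return PopulationModel(dataset, spec).fit(init=init, **kw)


def posthoc_etas(spec: PopulationModelSpec, dataset: StudyDataset, params=None) -> pd.DataFrame:
    """Empirical-Bayes (conditional mode) eta per subject at given estimates."""
    return PopulationModel(dataset, spec).posthoc(params)


def attach_individual_pk(dataset: StudyDataset, pk_fit: NLMEResults,
                         obs_type: str = "BIS") -> StudyDataset:
    """Copy of `dataset` with each subject's PK fixed at post-hoc values."""
    ipk = pk_fit.individual_pk_parameters()
    subjects = []
    for s in dataset.subjects:
        if s.id not in ipk:
            if s.obs_of_type(obs_type):
                raise EstimationError(
                    f"subject {s.id} has {obs_type} observations but no post-hoc PK "
                    "estimate from the PK fit (sequential approach requires one)"
                )
            subjects.append(s)
            continue
        subjects.append(s.with_pk_params(ipk[s.id]))
    return StudyDataset(subjects)


def fit_sequential_pd(
    pk_fit: NLMEResults,
    spec_pd: PopulationModelSpec,
    dataset: StudyDataset,
    init=None,
    **kw,
) -> NLMEResults:
    """Sequential (IPP) PD fit: individual PK fixed at PK post-hoc values.

    Each subject's PK parameters are set to P_tv * exp(eta_i) from the
    PK fit; only the PD/biophase fixed effects, omega^2 and sigma^2 are
    estimated.
    """
    ds = attach_individual_pk(dataset, pk_fit, obs_type=spec_pd.obs_type)
    return PopulationModel(ds, spec_pd).fit(init=init, **kw)
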
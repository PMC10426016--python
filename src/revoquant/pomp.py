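"""Partially observed Markov models for national production dynamics.

The production of a country is modelled as a latent log-scale AR process
driven by covariates (economic development, vertical and horizontal
diffusion of knowledge) and observed through Gaussian measurement noise on
the log scale, which absorbs the fat tails of the raw production values.

Per country ``c`` on the decadal grid::

    x[c,t] = mu + rho*x[c,t-1]                (if autoregression active)
             + beta_gdp * z_gdp[c,t]          (economic development)
             + beta_cum * z_cum[c,t]          (own past production)
             + beta_diff * z_diff[c,t]        (neighbours' recent production)
             + beta_cumdiff * z_cumdiff[c,t]  (neighbours' past production)
             + beta_int * z_gdp*z_diff[c,t]   (interaction)
             + sigma_proc * eps[c,t],         eps ~ N(0,1)

    log(Y[c,t] + log_offset) ~ N(x[c,t], tau_obs**2)

Covariates enter z-scored ("scaled coefficients") and the diffusion terms
are plug-in functions of *observed* neighbour production, so the panel
likelihood factorizes over countries and each country is a univariate
linear-Gaussian state-space model.  Two likelihood backends are provided:
a bootstrap particle filter (generic; supports Student-t innovations) and
the exact Kalman recursion (linear-Gaussian case).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .exceptions import ConvergenceError, FilteringError, SpecError

__all__ = [
    "ModelSpec",
    "ParamVector",
    "ProductionDynamics",
    "ProductionDynamicsResults",
    "LRTResult",
    "MODEL_LADDER",
    "model_from_label",
    "compare_models",
    "lrt",
]


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

_FLAG_NAMES = (
    "h1_noise",
    "h2_autoreg",
    "h3_gdp",
    "h4_cum",
    "h5_diff",
    "h6_cumdiff",
    "h7_interaction",
)

# flag -> (parameter it frees, covariate column it needs)
_FLAG_PARAM = {
    "h2_autoreg": ("rho", None),
    "h3_gdp": ("beta_gdp", "gdp_z"),
    "h4_cum": ("beta_cum", "cum_z"),
    "h5_diff": ("beta_diff", "diff_z"),
    "h6_cumdiff": ("beta_cumdiff", "cumdiff_z"),
    "h7_interaction": ("beta_int", None),
}


@dataclass(frozen=True)
class ModelSpec:
    """Flag set over the seven process hypotheses defining one model.

    h1 (pure stochastic productivity) is always on; h7 (interaction between
    economic development and diffusion) requires h3 and at least one
    diffusion term (h5 or h6).
    """

    h1_noise: bool = True
    h2_autoreg: bool = False
    h3_gdp: bool = False
    h4_cum: bool = False
    h5_diff: bool = False
    h6_cumdiff: bool = False
    h7_interaction: bool = False
    label: str = ""

    def __post_init__(self):
        if not self.h1_noise:
            raise SpecError("h1 (stochastic productivity) must always be active")
        if self.h7_interaction and not (self.h3_gdp and (self.h5_diff or self.h6_cumdiff)):
            raise SpecError(
                "h7 (interaction) requires h3 (gdp) and a diffusion term (h5 or h6)"
            )

    @property
    def flags(self) -> tuple[str, ...]:
        return tuple(n for n in _FLAG_NAMES if getattr(self, n))

    @property
    def free_params(self) -> tuple[str, ...]:
        """Names of the free parameters, in canonical order."""
        names = ["mu"]
        for flag, (pname, _) in _FLAG_PARAM.items():
            if getattr(self, flag):
                names.append(pname)
        names += ["sigma_proc", "tau_obs"]
        return tuple(names)

    @property
    def k(self) -> int:
        return len(self.free_params)

    @property
    def covariate_columns(self) -> tuple[str, ...]:
        cols = []
        for flag, (_, col) in _FLAG_PARAM.items():
            if getattr(self, flag) and col is not None:
                cols.append(col)
        if self.h7_interaction:
            cols.append("diff_z" if self.h5_diff else "cumdiff_z")
        return tuple(dict.fromkeys(cols))

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.flags) <= set(other.flags)


def _spec(label, **flags) -> ModelSpec:
    return ModelSpec(label=label, **flags)


#: The named model ladder.  A uses pure noise; B adds autoregression;
#: C–E add economic development and/or horizontal diffusion; F–J explore
#: vertical/cumulative diffusion; K activates every hypothesis.
MODEL_LADDER: dict[str, ModelSpec] = {
    "A": _spec("A"),
    "B": _spec("B", h2_autoreg=True),
    "C": _spec("C", h2_autoreg=True, h3_gdp=True),
    "D": _spec("D", h2_autoreg=True, h5_diff=True),
    "E": _spec("E", h2_autoreg=True, h3_gdp=True, h5_diff=True),
    "F": _spec("F", h2_autoreg=True, h4_cum=True),
    "G": _spec("G", h2_autoreg=True, h3_gdp=True, h4_cum=True),
    "H": _spec("H", h2_autoreg=True, h6_cumdiff=True),
    "I": _spec("I", h2_autoreg=True, h3_gdp=True, h6_cumdiff=True),
    "J": _spec("J", h2_autoreg=True, h4_cum=True, h5_diff=True, h6_cumdiff=True),
    "K": _spec(
        "K",
        h2_autoreg=True,
        h3_gdp=True,
        h4_cum=True,
        h5_diff=True,
        h6_cumdiff=True,
        h7_interaction=True,
    ),
}


def model_from_label(label: str) -> ModelSpec:
    try:
        return MODEL_LADDER[label.upper()]
    except KeyError:
        raise SpecError(f"unknown model label {label!r}; known: {sorted(MODEL_LADDER)}")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class ParamVector:
    """Process and measurement parameters.

    ``x0`` is the per-country initial log production; when None the model
    pins it to the first observed log production of each country.
    """

    mu: float = 0.0
    rho: float = 0.0
    beta_gdp: float = 0.0
    beta_cum: float = 0.0
    beta_diff: float = 0.0
    beta_cumdiff: float = 0.0
    beta_int: float = 0.0
    sigma_proc: float = 0.3
    tau_obs: float = 0.3
    x0: np.ndarray | None = None

    def validate(self, spec: ModelSpec) -> None:
        """Check finiteness and that inactive terms are pinned to zero."""
        for name in dataclasses.fields(self):
            if name.name == "x0":
                continue
            v = getattr(self, name.name)
            if not math.isfinite(v):
                raise SpecError(f"non-finite parameter {name.name}={v}")
        active = set(spec.free_params)
        for pname in ("rho", "beta_gdp", "beta_cum", "beta_diff", "beta_cumdiff", "beta_int"):
            if pname not in active and getattr(self, pname) != 0.0:
                raise SpecError(f"parameter {pname} inactive under spec {spec.label or spec.flags} but nonzero")
        if self.sigma_proc < 0 or self.tau_obs < 0:
            raise SpecError("sigma_proc and tau_obs must be nonnegative")
        if not (-1.0 <= self.rho <= 1.0):
            raise SpecError("rho must lie in [-1, 1]")

    def to_free_array(self, spec: ModelSpec) -> np.ndarray:
        return np.array([getattr(self, n) for n in spec.free_params], dtype=float)

    @classmethod
    def from_free_array(cls, values, spec: ModelSpec, x0=None) -> "ParamVector":
        kwargs = dict(zip(spec.free_params, np.asarray(values, dtype=float)))
        return cls(x0=x0, **kwargs)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test between two nested fits."""

    deviance: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class ProductionDynamics:
    """State-space model of national production on a rectangular panel.

    Parameters
    ----------
    panel : DataFrame
        Long-format panel with columns ``country``, ``year``, ``production``
        and the z-scored covariate columns the flag set requires (``gdp_z``,
        ``cum_z``, ``diff_z``, ``cumdiff_z`` as applicable).
    spec : ModelSpec
        Which process hypotheses are active.
    log_offset : float
        Offset used in ``log(production + log_offset)``; must make every
        observation positive inside the log.
    innovations : {"gaussian", "t"}
        Distribution of the process innovations.  The exact (Kalman)
        likelihood is only available for Gaussian innovations.
    """

    def __init__(self, panel: pd.DataFrame, spec: ModelSpec, log_offset: float = 0.0,
                 innovations: str = "gaussian", t_df: float = 5.0):
        if innovations not in ("gaussian", "t"):
            raise SpecError(f"unknown innovation family {innovations!r}")
        self.spec = spec
        self.log_offset = float(log_offset)
        self.innovations = innovations
        self.t_df = float(t_df)

        required = {"country", "year", "production", *spec.covariate_columns}
        missing = required - set(panel.columns)
        if missing:
            raise SpecError(f"panel missing columns: {sorted(missing)}")

        wide = panel.pivot_table(index="country", columns="year", values="production",
                                 aggfunc="first", sort=True)
        if wide.isna().any().any():
            raise SpecError("panel grid is not rectangular (missing country-years)")
        self.countries = list(wide.index)
        self.years = np.asarray(wide.columns, dtype=int)
        y = wide.to_numpy(dtype=float) + self.log_offset
        if np.any(y <= 0):
            raise SpecError("production + log_offset must be positive everywhere")
        self.ystar = np.log(y)  # (C, T) observed log production
        self.n_countries, self.n_steps = self.ystar.shape
        if self.n_steps < 2:
            raise SpecError("need at least two time steps per country")

        self._Z = {}
        for col in spec.covariate_columns:
            zw = panel.pivot_table(index="country", columns="year", values=col,
                                   aggfunc="first", sort=True)
            self._Z[col] = zw.to_numpy(dtype=float)

        #: number of observations entering the likelihood (the first grid
        #: year of each country pins the initial state and is not scored)
        self.n_obs = self.n_countries * (self.n_steps - 1)

    # -- process mean ------------------------------------------------------

    def _drift(self, params: ParamVector, t: int) -> np.ndarray:
        """Covariate contribution to the process mean at step t, shape (C,)."""
        out = np.full(self.n_countries, params.mu, dtype=float)
        s = self.spec
        if s.h3_gdp:
            out += params.beta_gdp * self._Z["gdp_z"][:, t]
        if s.h4_cum:
            out += params.beta_cum * self._Z["cum_z"][:, t]
        if s.h5_diff:
            out += params.beta_diff * self._Z["diff_z"][:, t]
        if s.h6_cumdiff:
            out += params.beta_cumdiff * self._Z["cumdiff_z"][:, t]
        if s.h7_interaction:
            zd = self._Z["diff_z" if s.h5_diff else "cumdiff_z"][:, t]
            out += params.beta_int * self._Z["gdp_z"][:, t] * zd
        return out

    def _x0(self, params: ParamVector) -> np.ndarray:
        if params.x0 is not None:
            x0 = np.asarray(params.x0, dtype=float)
            if x0.shape != (self.n_countries,):
                raise SpecError("x0 must have one entry per country")
            return x0
        return self.ystar[:, 0].copy()

    # -- likelihood backends ----------------------------------------------

    def kalman_loglik(self, params: ParamVector) -> float:
        """Exact log likelihood via the Kalman recursion (Gaussian case).

        The state is scalar per country and the initial state is known, so
        the recursion is vectorized over countries with a shared variance.
        """
        if self.innovations != "gaussian":
            raise SpecError("exact likelihood requires Gaussian innovations")
        params.validate(self.spec)
        rho = params.rho if self.spec.h2_autoreg else 0.0
        sig2 = params.sigma_proc ** 2
        tau2 = params.tau_obs ** 2
        if sig2 + tau2 <= 0:
            raise SpecError("sigma_proc and tau_obs cannot both be zero")
        m = self._x0(params)
        P = 0.0  # initial state is pinned
        ll = 0.0
        c_norm = -0.5 * math.log(2 * math.pi)
        for t in range(1, self.n_steps):
            m = self._drift(params, t) + rho * m
            P = rho * rho * P + sig2
            S = P + tau2
            resid = self.ystar[:, t] - m
            ll += np.sum(c_norm - 0.5 * math.log(S) - 0.5 * resid * resid / S)
            K = P / S
            m = m + K * resid
            P = (1.0 - K) * P
        return float(ll)

    def particle_loglik(self, params: ParamVector, n_particles: int = 1000,
                        seed: int = 0, return_se: bool = False):
        """Bootstrap particle filter log likelihood.

        Particles are propagated through the process model, weighted by the
        measurement density and systematically resampled at every step; the
        per-step log mean weights are summed.  Particles are sorted before
        resampling, which makes the common-random-numbers likelihood
        surface near-continuous in the parameters and hence usable with a
        derivative-free optimizer.  The Monte Carlo standard error is
        assembled from the per-step relative weight variances.

        Returns ``loglik`` or ``(loglik, mc_se)``.
        """
        if n_particles < 2:
            raise SpecError("need at least 2 particles")
        params.validate(self.spec)
        if params.tau_obs <= 0:
            raise SpecError("particle filter requires tau_obs > 0")
        rng = np.random.default_rng(seed)
        C, N = self.n_countries, int(n_particles)
        rho = params.rho if self.spec.h2_autoreg else 0.0
        sig = params.sigma_proc
        tau = params.tau_obs

        x = np.repeat(self._x0(params)[:, None], N, axis=1)  # (C, N)
        ll = 0.0
        var_acc = 0.0
        for t in range(1, self.n_steps):
            if self.innovations == "t":
                eps = rng.standard_t(self.t_df, size=(C, N))
            else:
                eps = rng.standard_normal((C, N))
            x = self._drift(params, t)[:, None] + rho * x + sig * eps
            z = (self.ystar[:, t][:, None] - x) / tau
            logw = -0.5 * z * z - math.log(tau) - 0.5 * math.log(2 * math.pi)
            lse = logsumexp(logw, axis=1)  # (C,)
            if not np.all(np.isfinite(lse)):
                bad = int(np.flatnonzero(~np.isfinite(lse))[0])
                raise FilteringError(
                    f"all particle weights underflowed for country "
                    f"{self.countries[bad]!r} at step {t}",
                    country=self.countries[bad], step=t,
                )
            ll += float(np.sum(lse - math.log(N)))
            # relative variance of the raw weights -> MC variance of log mean
            w = np.exp(logw - logw.max(axis=1, keepdims=True))
            wm = w.mean(axis=1)
            var_acc += float(np.sum((np.mean(w * w, axis=1) / (wm * wm) - 1.0) / N))
            # systematic resampling on value-sorted particles, one uniform
            # per country (sorting keeps the CRN surface smooth)
            order = np.argsort(x, axis=1)
            x_sorted = np.take_along_axis(x, order, axis=1)
            w_sorted = np.take_along_axis(np.exp(logw - lse[:, None]), order, axis=1)
            cdf = np.cumsum(w_sorted, axis=1)
            cdf[:, -1] = 1.0
            u = (rng.random(C)[:, None] + np.arange(N)[None, :]) / N
            new_x = np.empty_like(x)
            for c in range(C):
                new_x[c] = x_sorted[c, np.searchsorted(cdf[c], u[c])]
            x = new_x
        if return_se:
            return ll, math.sqrt(max(var_acc, 0.0))
        return ll

    def loglik(self, params: ParamVector, method: str = "exact",
               n_particles: int = 1000, seed: int = 0) -> float:
        if method == "exact":
            return self.kalman_loglik(params)
        if method == "pf":
            return self.particle_loglik(params, n_particles=n_particles, seed=seed)
        raise SpecError(f"unknown likelihood method {method!r}")

    # -- simulation --------------------------------------------------------

    def simulate(self, params: ParamVector, seed: int = 0) -> pd.DataFrame:
        """Forward-simulate observed production on this panel's grid,
        holding the covariate columns fixed (plug-in)."""
        params.validate(self.spec)
        rng = np.random.default_rng(seed)
        C, T = self.n_countries, self.n_steps
        rho = params.rho if self.spec.h2_autoreg else 0.0
        x = np.empty((C, T))
        x[:, 0] = self._x0(params)
        for t in range(1, T):
            if self.innovations == "t":
                eps = rng.standard_t(self.t_df, size=C)
            else:
                eps = rng.standard_normal(C)
            x[:, t] = self._drift(params, t) + rho * x[:, t - 1] + params.sigma_proc * eps
        ystar = x + params.tau_obs * rng.standard_normal((C, T))
        ystar[:, 0] = self.ystar[:, 0]  # initial observation pins x0
        prod = np.exp(ystar) - self.log_offset
        rows = []
        for c, country in enumerate(self.countries):
            for t, year in enumerate(self.years):
                rows.append((country, int(year), prod[c, t]))
        out = pd.DataFrame(rows, columns=["country", "year", "production"])
        for col, Z in self._Z.items():
            out[col] = Z.ravel()
        return out

    # -- fitting -----------------------------------------------------------

    def _default_start(self) -> ParamVector:
        dy = self.ystar[:, 1:]
        sd = float(np.std(dy))
        start = ParamVector(mu=float(np.mean(dy)), sigma_proc=max(sd / 2, 0.05),
                            tau_obs=max(sd / 2, 0.05))
        if self.spec.h2_autoreg:
            start.rho = 0.3
            start.mu = float(np.mean(dy)) * 0.7
        return start

    @staticmethod
    def _transform(theta_nat, spec):
        """Natural -> unconstrained (tanh for rho, log for scales)."""
        out = np.array(theta_nat, dtype=float)
        for i, name in enumerate(spec.free_params):
            if name == "rho":
                out[i] = np.arctanh(np.clip(out[i], -0.999, 0.999))
            elif name in ("sigma_proc", "tau_obs"):
                out[i] = np.log(max(out[i], 1e-8))
        return out

    @staticmethod
    def _untransform(theta_unc, spec):
        out = np.array(theta_unc, dtype=float)
        for i, name in enumerate(spec.free_params):
            if name == "rho":
                out[i] = np.tanh(out[i])
            elif name in ("sigma_proc", "tau_obs"):
                out[i] = np.exp(out[i])
        return out

    def fit(self, starts=None, method: str = "auto", n_particles: int = 500,
            seed: int = 0, maxiter: int | None = None) -> "ProductionDynamicsResults":
        """Maximum-likelihood fit by derivative-free search.

        The particle-filter objective is made deterministic by common
        random numbers: every evaluation reuses the same filter seed, so
        identical starts and seed give an identical fit.

        Parameters
        ----------
        starts : sequence of ParamVector, optional
            Start vectors; defaults to a single moment-based start.
        method : {"auto", "exact", "pf"}
            Likelihood backend; "auto" picks the exact Kalman likelihood
            for Gaussian innovations, the particle filter otherwise.
        """
        if method == "auto":
            method = "exact" if self.innovations == "gaussian" else "pf"
        spec = self.spec
        if starts is None:
            starts = [self._default_start()]
            if method == "pf" and self.innovations == "gaussian":
                # pilot exact fit as an extra start: a cheap consistent
                # initializer for the particle objective
                try:
                    pilot = self.fit(method="exact", seed=seed)
                    starts.append(pilot.params)
                except ConvergenceError:
                    pass
        starts = list(starts)
        if not starts:
            raise ConvergenceError("need at least one start vector")

        def nll(theta_unc):
            p = ParamVector.from_free_array(self._untransform(theta_unc, spec), spec)
            try:
                return -self.loglik(p, method=method, n_particles=n_particles, seed=seed)
            except FilteringError:
                return np.inf

        best = None
        trace = []
        nm_opts = {"xatol": 1e-5, "fatol": 1e-7,
                   "maxiter": maxiter or 400 * spec.k,
                   "maxfev": maxiter or 400 * spec.k}
        for s in starts:
            theta0 = self._transform(s.to_free_array(spec), spec)
            res = optimize.minimize(nll, theta0, method="Nelder-Mead", options=nm_opts)
            if method == "pf":
                # restart from the found optimum: guards against premature
                # simplex collapse on the (slightly jagged) particle surface
                res = optimize.minimize(nll, res.x, method="Nelder-Mead", options=nm_opts)
            trace.append((s, float(-res.fun), bool(res.success)))
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("no start converged to a finite likelihood", trace=trace)

        params = ParamVector.from_free_array(self._untransform(best.x, spec), spec)
        ll = float(-best.fun)
        mc_se = None
        if method == "pf":
            _, mc_se = self.particle_loglik(params, n_particles=n_particles,
                                            seed=seed, return_se=True)
        return ProductionDynamicsResults(
            model=self, params=params, loglik=ll, k=spec.k, n_obs=self.n_obs,
            method=method, n_particles=n_particles if method == "pf" else None,
            seed=seed, converged=bool(best.success), mc_se=mc_se,
        )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class ProductionDynamicsResults:
    """MLE fit of a :class:`ProductionDynamics` model."""

    model: ProductionDynamics
    params: ParamVector
    loglik: float
    k: int
    n_obs: int
    method: str
    seed: int
    converged: bool
    n_particles: int | None = None
    mc_se: float | None = None
    _se: dict | None = field(default=None, repr=False)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n_obs) - 2 * self.loglik

    def bse(self) -> dict[str, float]:
        """Standard errors from the numerical Hessian of the exact
        log likelihood at the optimum (observed information)."""
        if self._se is None:
            spec = self.spec
            theta = self.params.to_free_array(spec)
            h = np.maximum(np.abs(theta) * 1e-4, 1e-5)

            def f(v):
                p = ParamVector.from_free_array(v, spec)
                return self.model.kalman_loglik(p)

            k = len(theta)
            H = np.empty((k, k))
            f0 = f(theta)
            for i in range(k):
                for j in range(i, k):
                    ei = np.zeros(k); ei[i] = h[i]
                    ej = np.zeros(k); ej[j] = h[j]
                    if i == j:
                        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
                    else:
                        H[i, j] = H[j, i] = (
                            f(theta + ei + ej) - f(theta + ei - ej)
                            - f(theta - ei + ej) + f(theta - ei - ej)
                        ) / (4 * h[i] * h[j])
            with np.errstate(all="ignore"):
                try:
                    cov = np.linalg.inv(-H)
                    se = np.sqrt(np.clip(np.diag(cov), 0, None))
                except np.linalg.LinAlgError:
                    se = np.full(k, np.nan)
            self._se = dict(zip(spec.free_params, se))
        return self._se

    def to_dict(self) -> dict:
        d = {n: getattr(self.params, n) for n in self.spec.free_params}
        return {
            "label": self.spec.label, "params": d, "loglik": self.loglik,
            "k": self.k, "n_obs": self.n_obs, "aic": self.aic, "bic": self.bic,
            "method": self.method, "n_particles": self.n_particles,
            "seed": self.seed, "converged": self.converged, "mc_se": self.mc_se,
        }

    def summary(self) -> str:
        lines = [
            f"Production dynamics model {self.spec.label or '(custom)'}",
            f"  hypotheses: {', '.join(self.spec.flags)}",
            f"  likelihood: {self.method}"
            + (f" ({self.n_particles} particles, MC-SE {self.mc_se:.3f})"
               if self.method == "pf" and self.mc_se is not None else ""),
            f"  loglik {self.loglik:.3f}   k {self.k}   n_obs {self.n_obs}",
            f"  AIC {self.aic:.2f}   BIC {self.bic:.2f}",
            "  " + "-" * 40,
        ]
        se = self.bse() if self.method == "exact" else {}
        for name in self.spec.free_params:
            v = getattr(self.params, name)
            if name in se and np.isfinite(se[name]):
                lines.append(f"  {name:<12} {v: .4f}  (se {se[name]:.4f})")
            else:
                lines.append(f"  {name:<12} {v: .4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


def compare_models(fits) -> pd.DataFrame:
    """Rank fits of the same data by AIC; adds delta-AIC and delta-BIC."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits have mismatched n_obs: {sorted(n_obs)}")
    df = pd.DataFrame(
        {
            "model": [f.spec.label or "+".join(f.spec.flags) for f in fits],
            "loglik": [f.loglik for f in fits],
            "k": [f.k for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
        }
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    df["delta_bic"] = df["bic"] - df["bic"].min()
    return df


def lrt(nested: ProductionDynamicsResults, full: ProductionDynamicsResults) -> LRTResult:
    """Likelihood-ratio test of a nested model against a fuller one.

    The deviance 2*(loglik_full - loglik_nested) is clipped at zero (a
    negative value can only arise from optimisation noise) and referred to
    a chi-square with df = difference in free parameters.
    """
    if not nested.spec.is_nested_in(full.spec):
        raise SpecError("first fit is not nested in the second")
    df = full.k - nested.k
    if df <= 0:
        raise SpecError("full model has no extra free parameters")
    d = 2.0 * (full.loglik - nested.loglik)
    if d < 0:
        import warnings

        warnings.warn("negative deviance clipped to 0 (optimisation noise)")
        d = 0.0
    return LRTResult(deviance=d, df=df, p=float(stats.chi2.sf(d, df)))
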
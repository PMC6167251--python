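"""Parameter estimation and model discrimination.

Fitting machinery for the network and trafficking models: an adaptive
Metropolis-Hastings sampler (Haario-style covariance adaptation) for
posterior exploration, Gaussian-likelihood fits of the steady-state
dose-response model under the three network topologies with AIC model
discrimination, nonlinear least-squares fits of the ligand-binding
dissociation constant and the two-compartment recycling rates, the
exponential specific-activity fit with its Mann-Whitney gate, and
MAD-based outlier removal.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .compartment_kinetics import (
    BindingModel,
    RecyclingModel,
    bound_fraction_depletion,
    pm_fraction_recovery,
    steady_state_pm_fraction,
)
from .image_quant import DoseResponseCurve
from .reaction_models import ReactionParams, Topology, pegfr_dose_response

__all__ = [
    "MCMCConfig",
    "FitResult",
    "SpecificActivityFit",
    "adaptive_mh_sample",
    "fit_dose_response_model",
    "select_model",
    "fit_binding_kd",
    "fit_recycling",
    "fit_specific_activity",
    "remove_outliers_mad",
    "aic",
]


# ---------------------------------------------------------------------------
# generic results / configs
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Settings for the adaptive Metropolis-Hastings sampler.

    ``bounds`` is a (d, 2) array of finite box constraints acting as a flat
    prior support.  Proposal covariance starts diagonal at
    ``proposal_scale**2`` and is adapted from the past chain every
    ``adapt_interval`` steps once ``adapt_start`` steps have been taken,
    scaled by the usual 2.38^2/d factor.
    """

    n_steps: int
    initial: np.ndarray
    bounds: np.ndarray
    burn_in: int = 0
    seed: int = 0
    proposal_scale: float = 0.1
    adapt_start: int = 1000
    adapt_interval: int = 100
    initial_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.initial = np.atleast_1d(np.asarray(self.initial, dtype=float))
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if not self.burn_in < self.n_steps:
            raise ValueError("burn_in must be < n_steps")
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("bounds must be finite")
        if self.bounds.shape != (self.initial.size, 2):
            raise ValueError("bounds must be (d, 2)")


@dataclass
class FitResult:
    """Point estimates, uncertainty and information criteria for one fit."""

    params: dict[str, float]
    ci: dict[str, tuple[float, float]]
    rss: float
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    topology: str | None = None
    aicc: float | None = None
    chain: np.ndarray | None = None
    data_checksum: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class SpecificActivityFit:
    """Exponential fit of alpha vs expression with the activity read-out.

    The relative specific activity is the magnitude of the fitted
    exponential's initial slope, ``k*A``; ``gate`` records whether the
    Mann-Whitney comparison against control passed ("exponential"/"linear")
    or failed ("null").
    """

    c: float
    A: float
    k: float
    activity: float
    gate: str
    mw_p: float
    n_used: int


def aic(rss: float, n_obs: int, n_params: int,
        corrected: bool = False) -> float:
    """Akaike information criterion under a Gaussian profile likelihood.

    ``n*ln(RSS/n) + 2k``; with ``corrected`` the small-sample AICc adds
    ``2k(k+1)/(n-k-1)``.
    """
    if rss <= 0:
        rss = 1e-300
    out = n_obs * np.log(rss / n_obs) + 2 * n_params
    if corrected:
        denom = n_obs - n_params - 1
        if denom <= 0:
            return np.inf
        out += 2 * n_params * (n_params + 1) / denom
    return float(out)


# ---------------------------------------------------------------------------
# adaptive Metropolis-Hastings
# ---------------------------------------------------------------------------

def adaptive_mh_sample(log_posterior, config: MCMCConfig
                       ) -> tuple[np.ndarray, dict]:
    """Adaptive Metropolis-Hastings sampling with covariance adaptation.

    A random-walk Metropolis chain whose Gaussian proposal covariance is
    replaced, after a warm-up, by the empirical covariance of the past
    samples scaled by 2.38^2/d (plus a small diagonal jitter).  Moves
    outside the prior box are rejected.  Fully reproducible under the
    config seed.  Returns the post-burn-in chain and acceptance statistics.
    """
    rng = np.random.default_rng(config.seed)
    x = config.initial.copy()
    d = x.size
    lp = float(log_posterior(x))
    if not np.isfinite(lp):
        raise ValueError("log_posterior must be finite at the initial point")
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    if config.initial_cov is not None:
        cov = np.atleast_2d(np.asarray(config.initial_cov, dtype=float))
        cov = cov + 1e-14 * np.eye(d)
    else:
        cov = np.eye(d) * config.proposal_scale ** 2
    chol = np.linalg.cholesky(cov)
    scale = 2.38 ** 2 / d
    chain = np.empty((config.n_steps, d))
    n_accept = 0
    warm_accept = 0
    for step in range(config.n_steps):
        prop = x + chol @ rng.standard_normal(d)
        if np.all(prop >= lo) & np.all(prop <= hi):
            lp_prop = float(log_posterior(prop))
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                n_accept += 1
                if step < config.adapt_start:
                    warm_accept += 1
        chain[step] = x
        if (step + 1 == config.adapt_start and warm_accept == 0):
            raise RuntimeError(
                "no proposal accepted during warm-up; "
                "reduce proposal_scale or recentre the initial point")
        if (step + 1 >= config.adapt_start
                and (step + 1) % config.adapt_interval == 0):
            emp = np.cov(chain[: step + 1].T)
            emp = np.atleast_2d(emp)
            cov = scale * emp + 1e-10 * np.eye(d)
            chol = np.linalg.cholesky(cov)
    stats_out = {"acceptance_rate": n_accept / config.n_steps,
                 "n_accept": n_accept}
    return chain[config.burn_in:], stats_out


# ---------------------------------------------------------------------------
# dose-response model fitting + AIC discrimination
# ---------------------------------------------------------------------------

# free parameters per topology (log10 scale); k1, gamma, egfr_total and
# ptp_total are fixed at 1 (only products of gamma*ptp_total with the k's
# are identifiable from steady-state dose responses).  k5 stays free so the
# overall time-scale degeneracy of the steady states is fully spanned.
_FREE_PARAMS: dict[Topology, list[str]] = {
    Topology.NEGATIVE_REGULATION: ["alpha1", "alpha2", "alpha3", "k2", "k5"],
    Topology.DOUBLE_NEGATIVE: ["alpha1", "alpha2", "alpha3", "k2", "k5", "k3"],
    Topology.NEGATIVE_FEEDBACK: ["alpha1", "alpha2", "alpha3", "k2", "k5",
                                 "k4"],
}

_LOG_BOUNDS = (-4.0, 2.0)


def _params_from_theta(theta: np.ndarray,
                       topology: Topology) -> ReactionParams:
    names = _FREE_PARAMS[topology]
    kw = {name: 10.0 ** t for name, t in zip(names, theta)}
    kw.setdefault("k3", 0.0)
    kw.setdefault("k4", 0.0)
    return ReactionParams(alpha1=kw["alpha1"], alpha2=kw["alpha2"],
                          alpha3=kw["alpha3"], gamma=1.0, k1=1.0,
                          k2=kw["k2"], k3=kw["k3"], k4=kw["k4"],
                          k5=kw["k5"], egfr_total=1.0, ptp_total=1.0,
                          topology=topology)


def _pool_cells(cells) -> tuple[np.ndarray, np.ndarray, str]:
    xs, ys = [], []
    for c in cells:
        if isinstance(c, DoseResponseCurve):
            xs.append(c.liganded)
            ys.append(c.pegfr)
        else:
            x, y = c
            xs.append(np.asarray(x, dtype=float))
            ys.append(np.asarray(y, dtype=float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    checksum = hashlib.sha256(
        np.ascontiguousarray(np.column_stack([x, y])).tobytes()).hexdigest()
    return x, y, checksum


def fit_dose_response_model(cells, topology, sweep_direction: str = "forward",
                            n_starts: int = 4,
                            mcmc_steps: int = 0, seed: int = 0) -> FitResult:
    """Fit the steady-state network model to single-cell dose responses.

    ``cells`` is a collection of dose-response curves (liganded fraction vs
    phosphorylated fraction); their points are pooled under an iid additive
    Gaussian residual model on the fraction scale.  The model response is
    the quasi-static steady-state curve of the generalized network under
    the requested topology, with rate constants free on a log scale.
    Multi-start nonlinear least squares provides the point estimate, RSS
    and AIC; when ``mcmc_steps > 0`` an adaptive Metropolis-Hastings chain
    around the optimum (flat prior on the log-parameter box) yields 95%
    credible intervals, otherwise intervals come from the linearised
    covariance.
    """
    topology = Topology(topology)
    x, y, checksum = _pool_cells(cells)
    if np.unique(x).size < 5:
        raise ValueError("need at least 5 distinct dose points")
    if np.var(y) == 0:
        raise ValueError("degenerate data: zero response variance")
    names = _FREE_PARAMS[topology]
    d = len(names)

    xu, inv = np.unique(x, return_inverse=True)

    def predict(theta: np.ndarray) -> np.ndarray:
        p = _params_from_theta(theta, topology)
        return pegfr_dose_response(p, xu, direction=sweep_direction)[inv]

    def resid(theta: np.ndarray) -> np.ndarray:
        return predict(theta) - y

    rng = np.random.default_rng(seed)
    lo, hi = _LOG_BOUNDS
    starts = [np.full(d, -0.5)]
    starts += [rng.uniform(lo + 1, hi - 1, size=d) for _ in range(n_starts - 1)]
    best = None
    for s in starts:
        try:
            sol = optimize.least_squares(resid, s, bounds=(lo, hi),
                                         method="trf", xtol=1e-10,
                                         ftol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    theta = best.x
    rss = float(np.sum(best.fun ** 2))
    n = y.size
    loglik = -0.5 * n * (np.log(2 * np.pi * max(rss, 1e-300) / n) + 1)
    result_aic = aic(rss, n, d)
    result_aicc = aic(rss, n, d, corrected=True)

    ci: dict[str, tuple[float, float]] = {}
    chain = None
    if mcmc_steps > 0:
        sigma2 = max(rss / n, 1e-12)

        def log_post(t: np.ndarray) -> float:
            r = resid(t)
            return float(-0.5 * np.sum(r * r) / sigma2)

        # seed the proposal with the linearised posterior covariance so the
        # chain mixes even when the posterior is extremely peaked
        lin_cov = sigma2 * np.linalg.pinv(best.jac.T @ best.jac)
        lin_cov = (2.38 ** 2 / d) * 0.5 * (lin_cov + lin_cov.T)
        evals, evecs = np.linalg.eigh(lin_cov)
        evals = np.clip(evals, 1e-12, 1e2)
        lin_cov = (evecs * evals) @ evecs.T
        cfg = MCMCConfig(n_steps=mcmc_steps, initial=theta,
                         bounds=np.tile(_LOG_BOUNDS, (d, 1)),
                         burn_in=mcmc_steps // 4, seed=seed,
                         proposal_scale=0.05, initial_cov=lin_cov,
                         adapt_start=min(500, mcmc_steps // 4),
                         adapt_interval=100)
        chain, _ = adaptive_mh_sample(log_post, cfg)
        for j, name in enumerate(names):
            qs = np.quantile(chain[:, j], [0.025, 0.975])
            ci[name] = (10.0 ** qs[0], 10.0 ** qs[1])
    else:
        # linearised covariance on the log-parameter scale
        J = best.jac
        dofs = max(n - d, 1)
        s2 = rss / dofs
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(d, np.nan)
        tq = stats.t.ppf(0.975, dofs)
        for j, name in enumerate(names):
            lo_e = np.clip(theta[j] - tq * se[j], -300, 300)
            hi_e = np.clip(theta[j] + tq * se[j], -300, 300)
            ci[name] = (10.0 ** lo_e, 10.0 ** hi_e)

    params = {name: 10.0 ** t for name, t in zip(names, theta)}
    return FitResult(params=params, ci=ci, rss=rss, loglik=loglik,
                     aic=result_aic, aicc=result_aicc, n_params=d, n_obs=n,
                     topology=topology.value, chain=chain,
                     data_checksum=checksum,
                     extra={"theta_log10": theta})


def select_model(fits: dict[str, FitResult] | list[FitResult]
                 ) -> tuple[str, dict[str, float]]:
    """AIC model discrimination across topology fits on identical data.

    Returns the winning topology (ties broken toward fewer parameters) and
    the per-topology Delta-AIC table (min row = 0).
    """
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f.topology or str(i), f) for i, f in enumerate(fits)]
    if len(items) < 2:
        raise ValueError("need at least 2 fits to discriminate")
    checks = {f.data_checksum for _, f in items if f.data_checksum}
    if len(checks) > 1:
        raise ValueError("fits were made on different data")
    if len({f.n_obs for _, f in items}) > 1:
        raise ValueError("fits were made on different data (n_obs differ)")
    best_aic = min(f.aic for _, f in items)
    delta = {name: f.aic - best_aic for name, f in items}
    winners = [(f.n_params, name) for name, f in items
               if np.isclose(f.aic, best_aic, rtol=0, atol=1e-12)]
    winners.sort()
    return winners[0][1], delta


# ---------------------------------------------------------------------------
# closed-form model fits
# ---------------------------------------------------------------------------

def fit_binding_kd(doses_molar, bound_fractions,
                   depletion_molar: float = 0.0) -> FitResult:
    """Dissociation constant from a dose/bound-fraction data set.

    Nonlinear least squares on the depletion-corrected binding closed form
    (reducing to a hyperbolic fit when ``depletion_molar`` is 0); the 95%
    confidence interval comes from the linearised covariance.
    """
    x = np.asarray(doses_molar, dtype=float)
    y = np.asarray(bound_fractions, dtype=float)
    if x.shape != y.shape or np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct dose points")

    # rescale doses to O(1) so the optimiser is well conditioned at
    # sub-nanomolar magnitudes
    scale = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0

    def model(d, kd):
        return bound_fraction_depletion(
            d * scale,
            BindingModel(K_D=kd * scale, depletion_molar=depletion_molar))

    try:
        popt, pcov = optimize.curve_fit(model, x / scale, y, p0=[1.0],
                                        bounds=(0.0, np.inf),
                                        xtol=1e-12, ftol=1e-12,
                                        maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"K_D fit did not converge: {err}") from err
    kd = float(popt[0]) * scale
    pcov = pcov * scale ** 2
    resid = model(x / scale, popt[0]) - y
    rss = float(np.sum(resid ** 2))
    n = y.size
    dofs = max(n - 1, 1)
    se = float(np.sqrt(pcov[0, 0]))
    tq = stats.t.ppf(0.975, dofs)
    loglik = -0.5 * n * (np.log(2 * np.pi * max(rss, 1e-300) / n) + 1)
    return FitResult(params={"K_D": kd},
                     ci={"K_D": (kd - tq * se, kd + tq * se)},
                     rss=rss, loglik=loglik, aic=aic(rss, n, 1),
                     n_params=1, n_obs=n)


def fit_recycling(traces, t0: float | None = None) -> dict:
    """Trafficking rates from plasma-membrane recovery time courses.

    ``traces`` is a list of ``(t_minutes, pm_fraction)`` arrays (typically
    covering ~4-35 min after a stimulation pulse).  Each trace is fitted by
    nonlinear least squares to the two-compartment closed form with free
    ``(k_in, k_rec, f0)``; per-trace half-lives are ``ln2/(k_in + k_rec)``.
    Cohort averages carry 95% t-based confidence bounds across traces.
    """
    per_trace = []
    for t, f in traces:
        t = np.asarray(t, dtype=float)
        f = np.asarray(f, dtype=float)
        if t.size < 4:
            raise ValueError("each trace needs >= 4 time points")
        if np.ptp(f) < 1e-12:
            raise ValueError("flat trace: rates not identifiable")
        tref = float(t[0]) if t0 is None else float(t0)

        def model(tt, k_in, k_rec, f0):
            return pm_fraction_recovery(
                tt, RecyclingModel(k_in=k_in, k_rec=k_rec, f0=f0, t0=tref))

        f_inf = float(np.clip(f[-1], 1e-6, 1 - 1e-6))
        p0 = [0.3, max(0.3 * f_inf / max(1 - f_inf, 1e-6), 1e-3),
              float(np.clip(f[0], 0.0, 1.0))]
        popt, _ = optimize.curve_fit(model, t, f, p0=p0,
                                     bounds=([0, 0, 0], [np.inf, np.inf, 1]),
                                     maxfev=20000)
        k_in, k_rec, f0 = map(float, popt)
        per_trace.append({
            "k_in": k_in, "k_rec": k_rec, "f0": f0,
            "pm_fraction_ss": steady_state_pm_fraction(k_in, k_rec),
            "half_life_min": float(np.log(2) / max(k_in + k_rec, 1e-12)),
        })

    def mean_ci(key: str) -> tuple[float, tuple[float, float]]:
        v = np.array([r[key] for r in per_trace])
        m = float(v.mean())
        if v.size < 2:
            return m, (m, m)
        half = stats.t.ppf(0.975, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
        return m, (m - half, m + half)

    out: dict = {"per_trace": per_trace, "n_traces": len(per_trace)}
    for key in ("k_in", "k_rec", "pm_fraction_ss", "half_life_min"):
        m, ci = mean_ci(key)
        out[key] = m
        out[f"{key}_ci"] = ci
    # steady-state PM fraction implied by the average rates
    out["pm_fraction_from_mean_rates"] = steady_state_pm_fraction(
        out["k_in"], out["k_rec"])
    return out


def remove_outliers_mad(values, k: float = 3.0) -> np.ndarray:
    """Keep values within ``median +/- k*MAD``.

    With MAD = 0 the window collapses onto the median: exact replicates of
    the median are all kept (a constant sample passes through unchanged),
    while values away from it are removed.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    return v[np.abs(v - med) <= k * mad]


def fit_specific_activity(alpha_per_cell, ptpx_intensity_per_cell,
                          control_alphas, mad_k: float = 3.0,
                          weak_k_threshold: float = 1e-3
                          ) -> SpecificActivityFit:
    """Relative specific phosphatase activity from alpha vs expression.

    The per-cell FRET fractions under ectopic phosphatase expression are
    first gated against the control distribution (Mann-Whitney U, p < 0.05);
    a failed gate reports zero activity.  Otherwise control cells (MAD
    outliers removed) enter the fit at expression 0 and
    ``alpha = c + A*exp(-k*x)`` is fitted; the activity is the magnitude of
    the initial slope, ``k*A``.  When the fitted decay rate is negligibly
    small (weak dependence) the activity falls back to the magnitude of a
    linear-fit slope.
    """
    a = np.asarray(alpha_per_cell, dtype=float)
    x = np.asarray(ptpx_intensity_per_cell, dtype=float)
    ctrl = np.asarray(control_alphas, dtype=float)
    if a.size != x.size:
        raise ValueError("alpha and intensity arrays must be paired")
    if a.size + ctrl.size < 10:
        raise ValueError("need at least 10 cells overall")
    mw = stats.mannwhitneyu(a, ctrl, alternative="two-sided")
    if mw.pvalue >= 0.05:
        return SpecificActivityFit(c=float(np.mean(ctrl)), A=0.0, k=0.0,
                                   activity=0.0, gate="null",
                                   mw_p=float(mw.pvalue),
                                   n_used=a.size + ctrl.size)
    ctrl_kept = remove_outliers_mad(ctrl, k=mad_k)
    xx = np.concatenate([x, np.zeros(ctrl_kept.size)])
    yy = np.concatenate([a, ctrl_kept])

    def model(t, c, A, k):
        return c + A * np.exp(-k * t)

    span = max(float(xx.max()), 1e-12)
    p0 = [max(float(yy.min()), 0.0),
          max(float(yy.max() - yy.min()), 1e-3), 1.0 / span]
    try:
        popt, _ = optimize.curve_fit(model, xx, yy, p0=p0,
                                     bounds=([-np.inf, 0, 0],
                                             [np.inf, np.inf, np.inf]),
                                     maxfev=20000)
        c, A, k = map(float, popt)
        gate = "exponential"
    except RuntimeError:
        c, A, k = float(np.mean(yy)), 0.0, 0.0
        gate = "linear"
    if gate == "exponential" and k * span < weak_k_threshold:
        gate = "linear"
    if gate == "linear":
        slope, intercept = np.polyfit(xx, yy, 1)
        activity = float(abs(slope))
        return SpecificActivityFit(c=float(intercept), A=0.0, k=0.0,
                                   activity=activity, gate="linear",
                                   mw_p=float(mw.pvalue), n_used=yy.size)
    return SpecificActivityFit(c=c, A=A, k=k, activity=k * A,
                               gate="exponential", mw_p=float(mw.pvalue),
                               n_used=yy.size)
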
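"""Kinetic models of the EGFR-PTP phosphorylation/dephosphorylation network.

The core model describes three species at the plasma membrane: ligandless
phosphorylated EGFR monomers (``egfr_p``), phosphorylated ligand-bound dimers
(``egf_egfr_p``) and the active fraction of an ectopically expressed PTP
(``ptp_a``).  Phosphorylation of ligandless receptors is autocatalytic
(driven by ligandless and liganded phospho-EGFR alike), while
dephosphorylation is carried either by the ectopic PTP (rate constant
``gamma``) or by an aggregate endogenous phosphatase activity.  Three network
topologies are distinguished by how EGFR phosphorylation couples back to PTP
activity:

* ``double_negative`` -- phospho-EGFR *inactivates* the PTP (k3 > 0, k4 = 0),
  the toggle-switch motif that produces bistability;
* ``negative_feedback`` -- phospho-EGFR *activates* the PTP (k3 = 0, k4 > 0);
* ``negative_regulation`` -- PTP activity is independent of EGFR (k3 = k4 = 0).

An extension adds a slow, ER-bound phosphatase (PTPN2) whose activation by
ligandless phospho-EGFR closes a delayed negative feedback on a time scale
``epsilon`` (about two orders of magnitude slower than the
phosphorylation/dephosphorylation cycle).

Units: time in minutes; concentrations in arbitrary units normalised so that
``egfr_total = 1`` unless stated otherwise.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

__all__ = [
    "Topology",
    "ReactionParams",
    "ExtendedParams",
    "NetworkState",
    "PulseProtocol",
    "PiecewiseConstantInput",
    "Trajectory",
    "FixedPoint",
    "ptpe_activity",
    "rhs_generalized",
    "rhs_extended",
    "simulate_timecourse",
    "steady_state",
    "steady_state_extended",
    "steady_states_reduced",
    "pegfr_dose_response",
    "simulate_pulse_train",
    "classify_pulse_response",
    "resting_state_references",
    "IntegrationError",
    "REGIME_RATIOS",
    "regime_preset",
    "params_to_json",
    "params_from_json",
    "DEFAULT_DOUBLE_NEGATIVE",
    "DEFAULT_NEGATIVE_FEEDBACK",
    "DEFAULT_NEGATIVE_REGULATION",
    "DEFAULT_EXTENDED",
]


class Topology(str, enum.Enum):
    """Mode of interaction between EGFR and the ectopic PTP."""

    DOUBLE_NEGATIVE = "double_negative"
    NEGATIVE_FEEDBACK = "negative_feedback"
    NEGATIVE_REGULATION = "negative_regulation"


@dataclass(frozen=True)
class ReactionParams:
    """Rate constants and totals of the generalized EGFR-PTP model.

    ``alpha1`` is the basal (substrate-driven) phosphorylation rate constant,
    ``alpha2``/``alpha3`` the autocatalytic contributions of ligandless and
    liganded phospho-EGFR.  ``gamma`` is the dephosphorylation rate constant
    of the ectopic PTP; when ``gamma > 0`` the ectopic phosphatase dominates
    and the endogenous aggregate term is disabled, when ``gamma == 0`` the
    endogenous term (``ptpe_a``, ``ptpe_b``, ``ptpe_c``) is active.
    ``k1``/``k2`` set PTP activation/inactivation, ``k3``/``k4`` couple PTP
    activity to total EGFR phosphorylation (their admissible pattern is fixed
    by ``topology``), and ``k5`` is the dimer phosphorylation rate constant.
    """

    alpha1: float = 0.001
    alpha2: float = 1.0
    alpha3: float = 1.0
    gamma: float = 1.0
    k1: float = 1.0
    k2: float = 0.1
    k3: float = 5.0
    k4: float = 0.0
    k5: float = 2.0
    egfr_total: float = 1.0
    egf_egfr_total: float = 0.0
    ptp_total: float = 1.9
    ptpe_a: float = 1.0
    ptpe_b: float = 0.0
    ptpe_c: float = 0.0
    topology: Topology = Topology.DOUBLE_NEGATIVE

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "gamma", "k1", "k2", "k3",
                     "k4", "k5", "egfr_total", "ptp_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.egf_egfr_total <= self.egfr_total:
            raise ValueError("egf_egfr_total must lie in [0, egfr_total]")
        topo = Topology(self.topology)
        object.__setattr__(self, "topology", topo)
        if topo is Topology.DOUBLE_NEGATIVE and not (self.k3 > 0 and self.k4 == 0):
            raise ValueError("double_negative requires k3 > 0 and k4 == 0")
        if topo is Topology.NEGATIVE_FEEDBACK and not (self.k3 == 0 and self.k4 > 0):
            raise ValueError("negative_feedback requires k3 == 0 and k4 > 0")
        if topo is Topology.NEGATIVE_REGULATION and not (self.k3 == 0 and self.k4 == 0):
            raise ValueError("negative_regulation requires k3 == k4 == 0")

    @property
    def ptpe_active(self) -> bool:
        """Endogenous phosphatase term is only active without ectopic PTP."""
        return self.gamma == 0.0

    def with_liganded(self, egf_egfr_total: float) -> "ReactionParams":
        return replace(self, egf_egfr_total=float(egf_egfr_total))

    def with_ratio(self, ptp_over_egfr: float) -> "ReactionParams":
        """Return a copy with the PTP/EGFR expression ratio set."""
        return replace(self, ptp_total=float(ptp_over_egfr) * self.egfr_total)


@dataclass(frozen=True)
class ExtendedParams:
    """Double-negative core extended with the slow PTPN2 negative feedback.

    ``epsilon`` separates the PTPN2 activation/deactivation time scale from
    the phosphorylation cycle (default 0.01, i.e. two orders of magnitude
    slower).  ``gamma1`` is the PTPN2 dephosphorylation rate constant;
    ``k4_star``/``k2_star`` govern PTPN2 activation by ligandless
    phospho-EGFR and its relaxation.  When ``ptpn2_acts_on_dimer`` both
    phospho-species are PTPN2 substrates; otherwise only the ligandless
    monomer is.
    """

    base: ReactionParams
    ptpn2_total: float = 1.0
    gamma1: float = 0.6
    k4_star: float = 20.0
    k2_star: float = 15.0
    epsilon: float = 0.005
    ptpn2_acts_on_dimer: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        for name in ("ptpn2_total", "gamma1", "k4_star", "k2_star"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class NetworkState:
    """Concentrations of the phosphorylated species and active phosphatases."""

    egfr_p: float
    egf_egfr_p: float
    ptp_a: float
    ptpn2_a: float | None = None

    def as_array(self) -> np.ndarray:
        if self.ptpn2_a is None:
            return np.array([self.egfr_p, self.egf_egfr_p, self.ptp_a])
        return np.array([self.egfr_p, self.egf_egfr_p, self.ptp_a, self.ptpn2_a])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "NetworkState":
        x = np.asarray(x, dtype=float)
        if x.size == 3:
            return cls(x[0], x[1], x[2])
        return cls(x[0], x[1], x[2], x[3])

    def validate(self, params: ReactionParams, tol: float = 1e-9) -> None:
        u = params.egfr_total - params.egf_egfr_total
        if not -tol <= self.egfr_p <= u + tol:
            raise ValueError("egfr_p outside conservation bounds")
        if not -tol <= self.egf_egfr_p <= params.egf_egfr_total / 2 + tol:
            raise ValueError("egf_egfr_p outside conservation bounds")
        if not -tol <= self.ptp_a <= params.ptp_total + tol:
            raise ValueError("ptp_a outside conservation bounds")


@dataclass(frozen=True)
class PulseProtocol:
    """Repeated growth-factor pulse/washout schedule.

    ``dose_fraction_liganded`` is the liganded receptor fraction reached
    during each pulse; ``decay_rate`` (per minute) describes first-order
    depletion of liganded receptor after washout (0 gives square pulses).
    """

    dose_fraction_liganded: float = 0.78
    pulse_minutes: float = 5.0
    period_minutes: float = 30.0
    n_pulses: int = 4
    decay_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.pulse_minutes < self.period_minutes:
            raise ValueError("pulse_minutes must be < period_minutes")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if not 0.0 <= self.dose_fraction_liganded <= 1.0:
            raise ValueError("dose_fraction_liganded must be in [0, 1]")

    @property
    def total_minutes(self) -> float:
        return self.period_minutes * self.n_pulses

    def liganded_fraction(self, t: float) -> float:
        """Liganded fraction at time t (minutes from first pulse onset)."""
        if t < 0 or t >= self.total_minutes:
            return 0.0
        tau = t % self.period_minutes
        if tau < self.pulse_minutes:
            return self.dose_fraction_liganded
        if self.decay_rate > 0:
            return self.dose_fraction_liganded * float(
                np.exp(-self.decay_rate * (tau - self.pulse_minutes)))
        return 0.0

    def breakpoints(self) -> np.ndarray:
        bp = []
        for k in range(self.n_pulses):
            bp.append(k * self.period_minutes)
            bp.append(k * self.period_minutes + self.pulse_minutes)
        bp.append(self.total_minutes)
        return np.array(bp)


class PiecewiseConstantInput:
    """Liganded-fraction input held constant between breakpoints."""

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = int(np.clip(idx, 0, self.values.size - 1))
        return float(self.values[idx])

    def breakpoints(self) -> np.ndarray:
        return self.times.copy()


@dataclass
class Trajectory:
    """Time course of the network state under a liganded-fraction input."""

    times: np.ndarray
    states: np.ndarray          # (n_times, n_species)
    inputs: np.ndarray          # liganded fraction per sample
    egfr_total: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.inputs = np.asarray(self.inputs, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def egfr_p(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def egf_egfr_p(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def ptp_a(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def ptpn2_a(self) -> np.ndarray | None:
        return self.states[:, 3] if self.states.shape[1] > 3 else None

    @property
    def pegfr(self) -> np.ndarray:
        """Total phosphorylated EGFR fraction (2*[EGF-EGFRp] + [EGFRp])/[EGFR]_T."""
        return (2.0 * self.egf_egfr_p + self.egfr_p) / self.egfr_total

    def to_dataframe(self):
        import pandas as pd

        data = {"time": self.times,
                "egfr_p": self.egfr_p,
                "egf_egfr_p": self.egf_egfr_p,
                "ptp_a": self.ptp_a,
                "ptpn2_a": (self.ptpn2_a if self.ptpn2_a is not None
                            else np.full_like(self.times, np.nan)),
                "input": self.inputs}
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the network with its linear stability label."""

    state: NetworkState
    stability: str              # "stable" | "unstable" | "marginal"
    eigenvalues: np.ndarray
    liganded_total: float

    @property
    def pegfr(self) -> float:
        return float(2 * self.state.egf_egfr_p + self.state.egfr_p)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def ptpe_activity(egfr_p: float, egf_egfr_p: float, ptpe_a: float,
                  ptpe_b: float, ptpe_c: float) -> float:
    """Aggregate endogenous phosphatase activity.

    The activity ``c + 1/(a + b * (2*[EGF-EGFRp] + [EGFRp]))`` decreases with
    total EGFR phosphorylation when ``b > 0`` (toggle-like inhibition of the
    endogenous pool) and is constant for ``b == 0``.
    """
    denom = ptpe_a + ptpe_b * (2.0 * egf_egfr_p + egfr_p)
    if denom <= 0:
        raise ValueError("ptpe denominator must be positive")
    return ptpe_c + 1.0 / denom


def _dephos_activity(params: ReactionParams, egfr_p: float, egf_egfr_p: float,
                     ptp_a: float) -> float:
    d = params.gamma * ptp_a
    if params.ptpe_active:
        d += ptpe_activity(egfr_p, egf_egfr_p,
                           params.ptpe_a, params.ptpe_b, params.ptpe_c)
    return d


def _rhs_vec(x: np.ndarray, params: ReactionParams, liganded_total: float,
             ext: ExtendedParams | None = None) -> np.ndarray:
    """Unchecked RHS on a raw state vector (used by the integrator)."""
    ep, eep, pa = x[0], x[1], x[2]
    u = params.egfr_total - liganded_total          # ligandless total
    free = u - ep                                   # ligandless non-phospho
    kin = (params.alpha1 * free + params.alpha2 * ep + params.alpha3 * eep)
    d = _dephos_activity(params, ep, eep, pa)
    phos_total = 2.0 * eep + ep
    f1 = free * kin - ep * d
    f2 = params.k5 * (liganded_total / 2.0 - eep) - eep * d
    f3 = (params.k1 * (params.ptp_total - pa) - params.k2 * pa
          - params.k3 * pa * phos_total
          + params.k4 * (params.ptp_total - pa) * phos_total)
    if ext is None:
        return np.array([f1, f2, f3])
    pn = x[3]
    f1 -= ep * ext.gamma1 * pn
    if ext.ptpn2_acts_on_dimer:
        f2 -= eep * ext.gamma1 * pn
    f4 = ext.epsilon * (ext.k4_star * ep * (ext.ptpn2_total - pn)
                        - ext.k2_star * pn)
    return np.array([f1, f2, f3, f4])


def _jac_vec(x: np.ndarray, params: ReactionParams, liganded_total: float,
             ext: ExtendedParams | None = None) -> np.ndarray:
    """Analytic Jacobian of :func:`_rhs_vec`."""
    ep, eep, pa = x[0], x[1], x[2]
    p = params
    u = p.egfr_total - liganded_total
    free = u - ep
    kin = p.alpha1 * free + p.alpha2 * ep + p.alpha3 * eep
    P = 2.0 * eep + ep
    d = _dephos_activity(p, ep, eep, pa)
    if p.ptpe_active:
        dptpe = -p.ptpe_b / (p.ptpe_a + p.ptpe_b * P) ** 2
    else:
        dptpe = 0.0
    dD_dep, dD_deep, dD_dpa = dptpe, 2.0 * dptpe, p.gamma
    n = 3 if ext is None else 4
    J = np.zeros((n, n))
    J[0, 0] = -kin + free * (p.alpha2 - p.alpha1) - d - ep * dD_dep
    J[0, 1] = free * p.alpha3 - ep * dD_deep
    J[0, 2] = -ep * dD_dpa
    J[1, 0] = -eep * dD_dep
    J[1, 1] = -p.k5 - d - eep * dD_deep
    J[1, 2] = -eep * dD_dpa
    cpl = -p.k3 * pa + p.k4 * (p.ptp_total - pa)
    J[2, 0] = cpl
    J[2, 1] = 2.0 * cpl
    J[2, 2] = -p.k1 - p.k2 - (p.k3 + p.k4) * P
    if ext is not None:
        pn = x[3]
        J[0, 0] += -ext.gamma1 * pn
        J[0, 3] = -ep * ext.gamma1
        if ext.ptpn2_acts_on_dimer:
            J[1, 1] += -ext.gamma1 * pn
            J[1, 3] = -eep * ext.gamma1
        J[3, 0] = ext.epsilon * ext.k4_star * (ext.ptpn2_total - pn)
        J[3, 3] = ext.epsilon * (-ext.k4_star * ep - ext.k2_star)
    return J


def rhs_generalized(state: NetworkState, params: ReactionParams,
                    liganded_total: float | None = None) -> NetworkState:
    """Time derivatives of the generalized three-species model."""
    if liganded_total is None:
        liganded_total = params.egf_egfr_total
    state.validate(replace(params, egf_egfr_total=liganded_total), tol=1e-9)
    dx = _rhs_vec(state.as_array()[:3], params, liganded_total)
    return NetworkState(dx[0], dx[1], dx[2])


def rhs_extended(state: NetworkState, params: ExtendedParams,
                 liganded_total: float | None = None) -> NetworkState:
    """Time derivatives of the PTPN2-extended model (four species)."""
    if state.ptpn2_a is None:
        raise ValueError("extended model requires ptpn2_a in the state")
    base = params.base
    if liganded_total is None:
        liganded_total = base.egf_egfr_total
    state.validate(replace(base, egf_egfr_total=liganded_total), tol=1e-9)
    if not -1e-9 <= state.ptpn2_a <= params.ptpn2_total + 1e-9:
        raise ValueError("ptpn2_a outside conservation bounds")
    dx = _rhs_vec(state.as_array(), base, liganded_total, ext=params)
    return NetworkState(dx[0], dx[1], dx[2], dx[3])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time {last_time:.6g} min)")
        self.last_time = last_time


def _input_breakpoints(protocol, t0: float, t1: float) -> np.ndarray:
    if hasattr(protocol, "breakpoints"):
        bp = np.asarray(protocol.breakpoints(), dtype=float)
        bp = bp[(bp > t0) & (bp < t1)]
        return np.concatenate([[t0], bp, [t1]])
    return np.array([t0, t1])


def simulate_timecourse(params: ReactionParams | ExtendedParams,
                        initial: NetworkState,
                        protocol: Callable[[float], float] | float,
                        t_grid: Sequence[float],
                        rtol: float = 1e-8,
                        atol: float = 1e-10) -> Trajectory:
    """Integrate the network ODEs under a liganded-fraction input schedule.

    ``protocol`` maps time (minutes) to the liganded *fraction* of total
    EGFR; a scalar gives a constant input.  A stiff implicit integrator is
    used because the extended model is slow-fast separated.  Inputs with
    declared breakpoints (``PulseProtocol``, ``PiecewiseConstantInput``) are
    integrated segment-wise so the discontinuities are never stepped over.
    """
    ext = params if isinstance(params, ExtendedParams) else None
    base = params.base if ext is not None else params
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if np.isscalar(protocol):
        const = float(protocol)
        protocol = lambda t, _c=const: _c  # noqa: E731

    x = initial.as_array()
    if ext is not None and x.size == 3:
        raise ValueError("extended model requires a 4-component initial state")
    times_out = [t_grid[0]]
    states_out = [x.copy()]
    segments = _input_breakpoints(protocol, t_grid[0], t_grid[-1])
    for a, b in zip(segments[:-1], segments[1:]):
        mask = (t_grid > a) & (t_grid <= b)
        t_eval = np.unique(np.concatenate([t_grid[mask], [b]]))
        lig = protocol(0.5 * (a + b)) * base.egfr_total

        def f(t, y, _lig=lig):
            return _rhs_vec(y, base, protocol(t) * base.egfr_total, ext=ext)

        def jac(t, y, _lig=lig):
            return _jac_vec(y, base, protocol(t) * base.egfr_total, ext=ext)

        sol = solve_ivp(f, (a, b), x, method="BDF", jac=jac,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(sol.message, float(times_out[-1]))
        for ti, yi in zip(sol.t, sol.y.T):
            if np.any(np.isclose(ti, t_grid, rtol=0, atol=1e-12)):
                times_out.append(ti)
                states_out.append(yi)
        x = sol.y[:, -1]

    times = np.array(times_out)
    states = np.array(states_out)
    # drop duplicated grid points arising at segment boundaries
    keep = np.concatenate([[True], np.diff(times) > 1e-12])
    times, states = times[keep], states[keep]
    inputs = np.array([protocol(t) for t in times])
    return Trajectory(times, states, inputs, egfr_total=base.egfr_total)


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def _ptpe_of_P(params: ReactionParams, P: float) -> float:
    if not params.ptpe_active:
        return 0.0
    return params.ptpe_c + 1.0 / (params.ptpe_a + params.ptpe_b * P)


def _ptp_a_of_P(params: ReactionParams, P: float) -> float:
    """Quasi-steady active PTP fraction at total phosphorylation P."""
    num = params.k1 + params.k4 * P
    den = params.k1 + params.k2 + (params.k3 + params.k4) * P
    if den == 0:
        return 0.0
    return params.ptp_total * num / den


def _ep_root(params: ReactionParams, u: float, eep: float, d: float) -> float:
    """Physical root in [0, u] of the monomer phosphorylation balance.

    At fixed dephosphorylation activity ``d`` the monomer steady state is a
    quadratic in [EGFRp]; the sign pattern (positive at 0, non-positive at u)
    guarantees exactly one root inside the conservation interval.
    """
    a1, a2, a3 = params.alpha1, params.alpha2, params.alpha3
    A = a1 - a2
    B = -2.0 * a1 * u + a2 * u - a3 * eep - d
    C = a1 * u * u + a3 * eep * u
    if abs(A) < 1e-14:
        if B == 0:
            return 0.0
        x = -C / B
    else:
        disc = max(B * B - 4.0 * A * C, 0.0)
        r = np.sqrt(disc)
        roots = ((-B - r) / (2.0 * A), (-B + r) / (2.0 * A))
        cand = [x for x in roots if -1e-9 <= x <= u + 1e-9]
        if not cand:
            return 0.0
        x = cand[0] if len(cand) == 1 else min(cand)
    return float(min(max(x, 0.0), u))


def steady_states_reduced(params: ReactionParams, liganded_total: float,
                          n_scan: int = 400) -> list[NetworkState]:
    """All fixed points via reduction to a scalar equation in the activity.

    At steady state both phospho-species experience the same total
    dephosphorylation activity ``D``.  Given ``D`` the dimer and monomer
    phospho-levels follow in closed form, so fixed points are the roots of
    the scalar self-consistency map ``D = gamma*PTPa(P(D)) + PTPe(P(D))``,
    found by a dense sign-change scan plus Brent refinement.  This is fast
    and detects multiplicity reliably; it is the work-horse behind the
    dose-response fitting and the bistability mapping.
    """
    p = params
    L = float(liganded_total)
    if not 0.0 <= L <= p.egfr_total:
        raise ValueError("liganded_total must lie in [0, egfr_total]")
    u = p.egfr_total - L

    def h(D: float) -> float:
        eep = (L / 2.0) * p.k5 / (p.k5 + D) if p.k5 + D > 0 else L / 2.0
        ep = _ep_root(p, u, eep, D)
        P = 2.0 * eep + ep
        return D - p.gamma * _ptp_a_of_P(p, P) - _ptpe_of_P(p, P)

    d_hi = p.gamma * p.ptp_total
    if p.ptpe_active:
        d_hi += p.ptpe_c + (1.0 / p.ptpe_a if p.ptpe_a > 0 else 0.0)
    d_hi = max(d_hi * 1.05, 1e-9)
    grid = np.linspace(0.0, d_hi, n_scan)
    vals = np.array([h(D) for D in grid])
    roots: list[float] = []
    for i in range(n_scan - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(h, grid[i], grid[i + 1], xtol=1e-14))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    out = []
    for D in roots:
        eep = (L / 2.0) * p.k5 / (p.k5 + D)
        ep = _ep_root(p, u, eep, D)
        P = 2.0 * eep + ep
        out.append(NetworkState(ep, eep, _ptp_a_of_P(p, P)))
    out.sort(key=lambda s: s.egfr_p)
    return out


def _classify_stability(eigvals: np.ndarray, tol: float = 1e-9) -> str:
    re = eigvals.real
    if np.any(np.abs(re) < tol):
        return "marginal"
    return "stable" if np.all(re < 0) else "unstable"


def steady_state(params: ReactionParams, liganded_total: float | None = None,
                 n_starts: int = 8, tol: float = 1e-11) -> list[FixedPoint]:
    """Fixed points of the generalized model by multi-start Newton iteration.

    Starting points are spread over the conservation simplex (with the dimer
    and PTP coordinates at quasi-steady values) so that all branches of a
    bistable regime are found.  Each converged root is validated
    (``|rhs| < tol``), de-duplicated, and labelled by the real parts of the
    Jacobian eigenvalues (ties within 1e-9 are "marginal").
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    p = params
    L = p.egf_egfr_total if liganded_total is None else float(liganded_total)
    u = p.egfr_total - L
    found: list[np.ndarray] = []
    ep_starts = np.linspace(0.0, u, n_starts) if u > 0 else np.zeros(n_starts)
    # seed with reduced-solver solutions as well: cheap and robust
    seeds = [s.as_array() for s in steady_states_reduced(p, L, n_scan=200)]
    for ep0 in ep_starts:
        eep0 = (L / 2.0) * p.k5 / (p.k5 + 1.0)
        pa0 = _ptp_a_of_P(p, 2 * eep0 + ep0)
        seeds.append(np.array([ep0, eep0, pa0]))
    for x0 in seeds:
        sol = root(lambda x: _rhs_vec(x, p, L),
                   x0, jac=lambda x: _jac_vec(x, p, L), method="hybr",
                   tol=1e-13)
        if not sol.success:
            continue
        x = sol.x
        if np.max(np.abs(_rhs_vec(x, p, L))) > tol:
            continue
        if (x[0] < -1e-8 or x[0] > u + 1e-8 or x[1] < -1e-8
                or x[1] > L / 2 + 1e-8 or x[2] < -1e-8
                or x[2] > p.ptp_total + 1e-8):
            continue
        if any(np.allclose(x, y, atol=1e-7) for y in found):
            continue
        found.append(x)
    if not found:
        warnings.warn("no steady state found from any start", stacklevel=2)
        return []
    out = []
    for x in sorted(found, key=lambda v: v[0]):
        eig = np.linalg.eigvals(_jac_vec(x, p, L))
        out.append(FixedPoint(NetworkState.from_array(x),
                              _classify_stability(eig), eig, L))
    return out


def steady_state_extended(params: ExtendedParams, liganded_total: float,
                          n_starts: int = 8) -> list[FixedPoint]:
    """Fixed points of the four-species extended model (multi-start Newton)."""
    base = params.base
    L = float(liganded_total)
    seeds = []
    for fp in steady_state(base, L, n_starts=n_starts):
        ep = fp.state.egfr_p
        pn0 = (params.k4_star * ep * params.ptpn2_total
               / (params.k4_star * ep + params.k2_star)
               if params.k4_star * ep + params.k2_star > 0 else 0.0)
        seeds.append(np.array([ep, fp.state.egf_egfr_p, fp.state.ptp_a, pn0]))
        seeds.append(np.array([ep, fp.state.egf_egfr_p, fp.state.ptp_a, 0.0]))
    found: list[np.ndarray] = []
    for x0 in seeds:
        sol = root(lambda x: _rhs_vec(x, base, L, ext=params), x0,
                   jac=lambda x: _jac_vec(x, base, L, ext=params),
                   method="hybr", tol=1e-13)
        if not sol.success:
            continue
        x = sol.x
        if np.max(np.abs(_rhs_vec(x, base, L, ext=params))) > 1e-10:
            continue
        if x[0] < -1e-8 or x[3] < -1e-8 or x[3] > params.ptpn2_total + 1e-8:
            continue
        if any(np.allclose(x, y, atol=1e-7) for y in found):
            continue
        found.append(x)
    out = []
    for x in sorted(found, key=lambda v: v[0]):
        eig = np.linalg.eigvals(_jac_vec(x, base, L, ext=params))
        out.append(FixedPoint(NetworkState.from_array(x),
                              _classify_stability(eig), eig, L))
    return out


def _steady_pegfr_multi(params: ReactionParams, liganded: np.ndarray,
                        n_scan: int = 128, n_bisect: int = 50
                        ) -> list[np.ndarray]:
    """Steady-state phosphorylated fractions for many inputs, vectorised.

    Same activity reduction as :func:`steady_states_reduced`, but the scalar
    self-consistency map is evaluated on a (dose, activity-grid) matrix in
    one shot and all sign-change brackets are refined by vectorised
    bisection.  Returns, per liganded fraction, the sorted array of
    steady-state pEGFR values (1 or 3 entries in the regimes of interest).
    """
    p = params
    L = np.asarray(liganded, dtype=float) * p.egfr_total
    m = L.size
    u = p.egfr_total - L

    def h_of(D: np.ndarray, Lv: np.ndarray, uv: np.ndarray) -> np.ndarray:
        eep = (Lv / 2.0) * p.k5 / (p.k5 + D)
        A = p.alpha1 - p.alpha2
        B = -2.0 * p.alpha1 * uv + p.alpha2 * uv - p.alpha3 * eep - D
        C = p.alpha1 * uv * uv + p.alpha3 * eep * uv
        if abs(A) < 1e-14:
            with np.errstate(divide="ignore", invalid="ignore"):
                ep = np.where(B != 0, -C / B, 0.0)
        else:
            disc = np.maximum(B * B - 4.0 * A * C, 0.0)
            r = np.sqrt(disc)
            r1 = (-B - r) / (2.0 * A)
            r2 = (-B + r) / (2.0 * A)
            ok1 = (r1 >= -1e-9) & (r1 <= uv + 1e-9)
            ep = np.where(ok1, r1, r2)
        ep = np.clip(ep, 0.0, uv)
        P = 2.0 * eep + ep
        num = p.k1 + p.k4 * P
        den = p.k1 + p.k2 + (p.k3 + p.k4) * P
        pa = p.ptp_total * num / den
        ptpe = 0.0
        if p.ptpe_active:
            ptpe = p.ptpe_c + 1.0 / (p.ptpe_a + p.ptpe_b * P)
        return D - p.gamma * pa - ptpe

    def pegfr_at(D: np.ndarray, Lv: np.ndarray, uv: np.ndarray) -> np.ndarray:
        eep = (Lv / 2.0) * p.k5 / (p.k5 + D)
        A = p.alpha1 - p.alpha2
        B = -2.0 * p.alpha1 * uv + p.alpha2 * uv - p.alpha3 * eep - D
        C = p.alpha1 * uv * uv + p.alpha3 * eep * uv
        if abs(A) < 1e-14:
            with np.errstate(divide="ignore", invalid="ignore"):
                ep = np.where(B != 0, -C / B, 0.0)
        else:
            disc = np.maximum(B * B - 4.0 * A * C, 0.0)
            r = np.sqrt(disc)
            r1 = (-B - r) / (2.0 * A)
            r2 = (-B + r) / (2.0 * A)
            ok1 = (r1 >= -1e-9) & (r1 <= uv + 1e-9)
            ep = np.where(ok1, r1, r2)
        ep = np.clip(ep, 0.0, uv)
        return (2.0 * eep + ep) / p.egfr_total

    d_hi = p.gamma * p.ptp_total
    if p.ptpe_active:
        d_hi += p.ptpe_c + (1.0 / p.ptpe_a if p.ptpe_a > 0 else 0.0)
    d_hi = max(d_hi * 1.05, 1e-9)
    grid = np.linspace(0.0, d_hi, n_scan)
    H = h_of(grid[None, :], L[:, None], u[:, None])     # (m, n_scan)
    sgn = np.sign(H)
    flips = sgn[:, :-1] * sgn[:, 1:] < 0
    rows, cols = np.where(flips)
    lo = grid[cols].astype(float)
    hi = grid[cols + 1].astype(float)
    Lr, ur = L[rows], u[rows]
    flo = H[rows, cols]
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        fmid = h_of(mid, Lr, ur)
        left = flo * fmid <= 0
        hi = np.where(left, mid, hi)
        lo = np.where(left, lo, mid)
        flo = np.where(left, flo, fmid)
    D_roots = 0.5 * (lo + hi)
    vals = pegfr_at(D_roots, Lr, ur)
    # exact zeros on the grid (e.g. D=0 when activity vanishes)
    zrows, zcols = np.where(H == 0.0)
    if zrows.size:
        vals = np.concatenate([vals, pegfr_at(grid[zcols], L[zrows], u[zrows])])
        rows = np.concatenate([rows, zrows])
    out: list[np.ndarray] = []
    for i in range(m):
        vi = np.sort(vals[rows == i])
        if vi.size == 0:
            vi = np.array([np.nan])
        out.append(vi)
    return out


def pegfr_dose_response(params: ReactionParams, liganded_fractions,
                        direction: str = "forward",
                        n_scan: int = 128) -> np.ndarray:
    """Quasi-static steady-state dose response of the phosphorylated fraction.

    For each liganded fraction the realised steady state is selected by
    adiabatic branch following: the first point starts on the lowest (for a
    forward sweep) or highest (backward) branch, and each subsequent point
    picks the steady state nearest the previous one.  This reproduces the
    hysteresis a dose-ramp experiment would see in a bistable regime.
    """
    lf = np.asarray(liganded_fractions, dtype=float)
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    order = np.arange(lf.size) if direction == "forward" else lf.size - 1 - np.arange(lf.size)
    multi = _steady_pegfr_multi(params, lf, n_scan=n_scan)
    out = np.empty(lf.size)
    prev: float | None = None
    for j in order:
        vals = multi[j]
        if prev is None:
            pick = vals[0] if direction == "forward" else vals[-1]
        else:
            pick = vals[np.argmin(np.abs(vals - prev))]
        out[j] = pick
        prev = float(pick)
    return out


# ---------------------------------------------------------------------------
# pulse trains
# ---------------------------------------------------------------------------

def classify_pulse_response(times, pegfr, protocol: PulseProtocol,
                            baseline: float, upper: float | None,
                            return_tol: float = 0.05,
                            trapped_frac: float = 0.5) -> str:
    """Label a pulse-train response as ``trapped``, ``biphasic`` or ``tracking``.

    ``baseline`` and ``upper`` are the basal and upper-branch phosphorylated
    fractions of the resting system (``upper`` is None for monostable
    organisations).  The trace is *trapped* when the terminal phosphorylated
    fraction stays above ``trapped_frac`` of the upper branch; *tracking*
    when before every pulse (after the first) the response has relaxed to
    within ``return_tol`` of baseline, relative to the peak excursion; and
    *biphasic* otherwise.  Works on simulated or measured (noisy) traces.
    """
    times = np.asarray(times, dtype=float)
    pegfr = np.asarray(pegfr, dtype=float)
    peak = float(np.max(pegfr))
    span = max(peak - baseline, 1e-12)
    terminal = float(pegfr[-1])
    if upper is not None and terminal > trapped_frac * upper:
        return "trapped"
    returned = []
    for k in range(1, protocol.n_pulses):
        t_next = k * protocol.period_minutes
        i = np.searchsorted(times, t_next - 1e-9) - 1
        if i < 0:
            continue
        returned.append(abs(pegfr[i] - baseline) <= return_tol * span)
    if returned and all(returned):
        return "tracking"
    return "biphasic"


def resting_state_references(params: ExtendedParams
                             ) -> tuple[float, float | None]:
    """Basal and upper-branch phosphorylated fractions of the resting system.

    Returns ``(baseline, upper)`` where ``upper`` is None when the extended
    system without ligand is monostable; these are the reference levels the
    pulse-train regime classifier needs.
    """
    fps = steady_state_extended(params, 0.0)
    if not fps:
        raise RuntimeError("no basal steady state found")
    stable = [fp for fp in fps if fp.stability == "stable"] or fps
    egfr_t = params.base.egfr_total
    basal = min(stable, key=lambda fp: fp.pegfr)
    upper_fp = max(stable, key=lambda fp: fp.pegfr)
    upper = (upper_fp.pegfr / egfr_t
             if upper_fp.pegfr > basal.pegfr + 1e-6 else None)
    return basal.pegfr / egfr_t, upper


def simulate_pulse_train(params: ExtendedParams, protocol: PulseProtocol,
                         dt_minutes: float = 0.5,
                         settle_extra_minutes: float = 0.0,
                         rtol: float = 1e-8, atol: float = 1e-10
                         ) -> tuple[Trajectory, str]:
    """Simulate a train of growth-factor pulses and classify the regime.

    The system starts from its basal (lowest) steady state without ligand.
    The upper-branch reference for trap detection is the largest stable
    phosphorylated fraction of the resting extended system when it is
    multistable.
    """
    fps = steady_state_extended(params, 0.0)
    if not fps:
        raise RuntimeError("no basal steady state found")
    stable = [fp for fp in fps if fp.stability == "stable"] or fps
    basal = min(stable, key=lambda fp: fp.pegfr)
    upper_fp = max(stable, key=lambda fp: fp.pegfr)
    egfr_t = params.base.egfr_total
    upper = (upper_fp.pegfr / egfr_t
             if upper_fp.pegfr > basal.pegfr + 1e-6 else None)
    t_end = protocol.total_minutes + settle_extra_minutes
    t_grid = np.arange(0.0, t_end + dt_minutes / 2, dt_minutes)
    init = NetworkState(basal.state.egfr_p, basal.state.egf_egfr_p,
                        basal.state.ptp_a, basal.state.ptpn2_a)
    traj = simulate_timecourse(params, init, protocol.liganded_fraction,
                               t_grid, rtol=rtol, atol=atol)
    label = classify_pulse_response(traj.times, traj.pegfr, protocol,
                                    basal.pegfr / egfr_t, upper)
    return traj, label


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_EXT_FIELDS = ("ptpn2_total", "gamma1", "k4_star", "k2_star", "epsilon",
               "ptpn2_acts_on_dimer")


def params_to_json(params: ReactionParams | ExtendedParams, path=None) -> str:
    """Serialize a parameter set as a flat key/value JSON document.

    Extended parameters are flattened (base fields plus the PTPN2 fields at
    the top level).  When ``path`` is given the document is also written
    there.
    """
    import json
    from dataclasses import asdict

    if isinstance(params, ExtendedParams):
        doc = asdict(params.base)
        for name in _EXT_FIELDS:
            doc[name] = getattr(params, name)
    else:
        doc = asdict(params)
    doc["topology"] = Topology(doc["topology"]).value
    text = json.dumps(doc, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def params_from_json(source) -> ReactionParams | ExtendedParams:
    """Inverse of :func:`params_to_json` (accepts a JSON string or path)."""
    import json
    import os

    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = json.loads(source)
    if "epsilon" in doc:
        ext_kw = {name: doc.pop(name) for name in _EXT_FIELDS if name in doc}
        return ExtendedParams(base=ReactionParams(**doc), **ext_kw)
    return ReactionParams(**doc)


# ---------------------------------------------------------------------------
# reference parameter organisations
# ---------------------------------------------------------------------------

#: Double-negative (toggle switch) default: bistable tongue over
#: PTP/EGFR expression ratios ~1.25-2.05, with a reversible hysteresis
#: window in the liganded fraction at ratio 1.9.
DEFAULT_DOUBLE_NEGATIVE = ReactionParams()

#: Negative feedback: phospho-EGFR activates the PTP (k3 = 0, k4 > 0).
DEFAULT_NEGATIVE_FEEDBACK = ReactionParams(
    k3=0.0, k4=5.0, topology=Topology.NEGATIVE_FEEDBACK)

#: Simple negative regulation: constant PTP activity (k3 = k4 = 0).
DEFAULT_NEGATIVE_REGULATION = ReactionParams(
    k3=0.0, k4=0.0, topology=Topology.NEGATIVE_REGULATION)

#: Extended model defaults; regime presets are built by rescaling ptp_total.
DEFAULT_EXTENDED = ExtendedParams(base=DEFAULT_DOUBLE_NEGATIVE)

#: PTPRG/EGFR expression ratios placing the extended system deep in the
#: bistable regime (trapped), close to the bistable boundary (biphasic) and
#: in the monostable regime (tracking).  Below ~1.25 the resting system is
#: pre-activated (monostable high), as after a strong PTPRG knockdown.
REGIME_RATIOS = {"trapped": 1.35, "biphasic": 1.5, "tracking": 2.5}


def regime_preset(regime: str) -> ExtendedParams:
    """Extended-model parameters organised in one of the three regimes."""
    try:
        ratio = REGIME_RATIOS[regime]
    except KeyError:
        raise ValueError(f"unknown regime {regime!r}") from None
    return ExtendedParams(base=DEFAULT_DOUBLE_NEGATIVE.with_ratio(ratio))
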
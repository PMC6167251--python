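"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from egfrptp.reaction_models import ReactionParams

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


def oracle_steady_state_multiplicity(params: ReactionParams,
                                     liganded_total: float,
                                     n_scan: int = 2000) -> int:
    """Brute-force fixed-point count by scanning total phosphorylation.

    Independent reduction: parametrise candidate steady states by the total
    phosphorylation P.  Given P the active-PTP level, the endogenous
    activity, the dimer level and the monomer level all follow in closed
    form, so steady states are the sign changes of the residual
    ``2*eep(P) + ep(P) - P`` on a dense P grid.  No root-finding beyond the
    scan; used as the multiplicity oracle for the reduced solver and for
    the bistable-region maps.
    """
    p = params
    L = liganded_total
    u = p.egfr_total - L
    P = np.linspace(0.0, p.egfr_total + 1e-9, n_scan)
    pa = p.ptp_total * (p.k1 + p.k4 * P) / (p.k1 + p.k2 + (p.k3 + p.k4) * P)
    D = p.gamma * pa
    if p.ptpe_active:
        D = D + p.ptpe_c + 1.0 / (p.ptpe_a + p.ptpe_b * P)
    eep = (L / 2.0) * p.k5 / (p.k5 + D)
    A = p.alpha1 - p.alpha2
    B = -2.0 * p.alpha1 * u + p.alpha2 * u - p.alpha3 * eep - D
    C = p.alpha1 * u * u + p.alpha3 * eep * u
    if abs(A) < 1e-14:
        with np.errstate(divide="ignore", invalid="ignore"):
            ep = np.where(B != 0, -C / B, 0.0)
    else:
        disc = np.maximum(B * B - 4.0 * A * C, 0.0)
        r = np.sqrt(disc)
        r1 = (-B - r) / (2.0 * A)
        r2 = (-B + r) / (2.0 * A)
        ok1 = (r1 >= -1e-9) & (r1 <= u + 1e-9)
        ep = np.where(ok1, r1, r2)
    ep = np.clip(ep, 0.0, u)
    resid = 2.0 * eep + ep - P
    sgn = np.sign(resid)
    nz = sgn != 0
    s = sgn[nz]
    return int(np.sum(s[:-1] * s[1:] < 0))


def oracle_steady_state_values(params: ReactionParams, liganded_total: float,
                               n_scan: int = 4000) -> np.ndarray:
    """Brute-force steady-state pEGFR values via the P-scan with bisection."""
    from scipy.optimize import brentq

    p = params
    L = liganded_total
    u = p.egfr_total - L

    def resid(P: float) -> float:
        pa = p.ptp_total * (p.k1 + p.k4 * P) / (
            p.k1 + p.k2 + (p.k3 + p.k4) * P)
        D = p.gamma * pa
        if p.ptpe_active:
            D += p.ptpe_c + 1.0 / (p.ptpe_a + p.ptpe_b * P)
        eep = (L / 2.0) * p.k5 / (p.k5 + D)
        A = p.alpha1 - p.alpha2
        B = -2.0 * p.alpha1 * u + p.alpha2 * u - p.alpha3 * eep - D
        C = p.alpha1 * u * u + p.alpha3 * eep * u
        if abs(A) < 1e-14:
            ep = -C / B if B != 0 else 0.0
        else:
            disc = max(B * B - 4.0 * A * C, 0.0)
            r = np.sqrt(disc)
            cand = [x for x in ((-B - r) / (2 * A), (-B + r) / (2 * A))
                    if -1e-9 <= x <= u + 1e-9]
            ep = cand[0] if len(cand) == 1 else (min(cand) if cand else 0.0)
        ep = min(max(ep, 0.0), u)
        return 2.0 * eep + ep - P

    grid = np.linspace(0.0, p.egfr_total + 1e-9, n_scan)
    vals = np.array([resid(P) for P in grid])
    roots = []
    for i in range(n_scan - 1):
        if vals[i] == 0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(resid, grid[i], grid[i + 1], xtol=1e-13))
    return np.sort(np.array(roots) / p.egfr_total)


@pytest.fixture(scope="session")
def toggle_params() -> ReactionParams:
    """Double-negative defaults (bistable at ratio 1.9 for liganded ~0.03-0.07)."""
    return ReactionParams()


@pytest.fixture(scope="session")
def small_geometry():
    """A 101x101 circular cell (R=50) with concentric nucleus (R=10)."""
    from egfrptp.synthetic_data import SceneConfig, synth_cell_geometry

    cfg = SceneConfig(shape=(101, 101), cell_radii=(50.0, 50.0),
                      nucleus_radii=(10.0, 10.0))
    return synth_cell_geometry(cfg)
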
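"""Bifurcation analysis of the EGFR-PTP toggle switch.

Numerical continuation of steady-state branches of the generalized model,
saddle-node (fold) detection, two-parameter mapping of the bistable region
in the (PTP/EGFR expression ratio, liganded fraction) plane, and quasi-static
hysteresis sweeps.  Only fixed points are tracked; the network has no limit
cycles in the regimes of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import root

from .reaction_models import (
    FixedPoint,
    NetworkState,
    ReactionParams,
    Topology,
    _jac_vec,
    _rhs_vec,
    steady_state,
    steady_states_reduced,
)

__all__ = [
    "BifurcationBranch",
    "FoldPoint",
    "BistableRegion",
    "continue_branch",
    "detect_folds",
    "map_bistable_region",
    "hysteresis_sweep",
]


@dataclass
class BifurcationBranch:
    """A continued steady-state branch over a control parameter.

    ``control`` holds the parameter values along the branch (liganded
    fraction or PTP/EGFR ratio), ``states`` the full state vectors, and
    ``stability`` a boolean flag per point (True = stable).
    """

    control_name: str
    control: np.ndarray
    states: np.ndarray            # (n, 3)
    stability: np.ndarray         # bool per point

    @property
    def egfr_p(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def pegfr(self) -> np.ndarray:
        return 2.0 * self.states[:, 1] + self.states[:, 0]

    def __len__(self) -> int:
        return self.control.size


@dataclass(frozen=True)
class FoldPoint:
    """A saddle-node point where the branch turns in the control parameter."""

    control: float
    egfr_p: float
    pegfr: float
    branch_id: int


@dataclass
class BistableRegion:
    """Fixed-point multiplicity on a (ratio, liganded fraction) grid."""

    ratio_grid: np.ndarray
    liganded_grid: np.ndarray
    multiplicity: np.ndarray      # (n_ratio, n_liganded) ints

    @property
    def bistable_mask(self) -> np.ndarray:
        return self.multiplicity >= 3

    def bistable_interval(self, ratio: float) -> tuple[float, float] | None:
        """Liganded-fraction extent of the bistable set at a given ratio."""
        i = int(np.argmin(np.abs(self.ratio_grid - ratio)))
        row = self.bistable_mask[i]
        if not row.any():
            return None
        idx = np.where(row)[0]
        return float(self.liganded_grid[idx[0]]), float(self.liganded_grid[idx[-1]])

    def to_dataframe(self):
        import pandas as pd

        rr, ll = np.meshgrid(self.ratio_grid, self.liganded_grid, indexing="ij")
        return pd.DataFrame({"ratio": rr.ravel(), "liganded": ll.ravel(),
                             "multiplicity": self.multiplicity.ravel()})


def _apply_control(params: ReactionParams, name: str, value: float
                   ) -> tuple[ReactionParams, float]:
    """Return (params, liganded_total) for a given control setting."""
    if name == "liganded_fraction":
        return params, value * params.egfr_total
    if name == "ptp_ratio":
        return params.with_ratio(value), params.egf_egfr_total
    raise ValueError("control must be 'liganded_fraction' or 'ptp_ratio'")


def _is_stable(params: ReactionParams, lig: float, x: np.ndarray,
               tol: float = 1e-9) -> bool:
    eig = np.linalg.eigvals(_jac_vec(x, params, lig))
    return bool(np.all(eig.real < -tol))


def continue_branch(params: ReactionParams, control: str,
                    control_range: tuple[float, float], step: float,
                    max_points: int = 5000, tol: float = 1e-9
                    ) -> list[BifurcationBranch]:
    """Pseudo-arclength continuation of steady-state branches.

    Branches are started from every fixed point found at the lower end of
    ``control_range`` and followed through folds.  The corrector solves the
    steady-state system augmented with the arclength normalisation; the step
    is halved on convergence failure (floor 1e-5 of the range) and grown
    again after successful steps.  Branch points satisfy ``|rhs| < tol``.
    """
    lo, hi = float(control_range[0]), float(control_range[1])
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError("control_range must be finite and increasing")
    if step <= 0:
        raise ValueError("step must be > 0")
    span = hi - lo
    min_step = 1e-5 * span

    def F(y: np.ndarray) -> np.ndarray:
        p, lig = _apply_control(params, control, y[3])
        return _rhs_vec(y[:3], p, lig)

    def J_aug(y: np.ndarray, t: np.ndarray) -> np.ndarray:
        p, lig = _apply_control(params, control, y[3])
        Jx = _jac_vec(y[:3], p, lig)
        # dF/dc by central difference in the control parameter
        h = 1e-7 * max(1.0, abs(y[3]))
        pfwd, lfwd = _apply_control(params, control, y[3] + h)
        pbwd, lbwd = _apply_control(params, control, y[3] - h)
        dFdc = (_rhs_vec(y[:3], pfwd, lfwd) - _rhs_vec(y[:3], pbwd, lbwd)) / (2 * h)
        top = np.hstack([Jx, dFdc[:, None]])
        return np.vstack([top, t[None, :]])

    branches: list[BifurcationBranch] = []
    p0, lig0 = _apply_control(params, control, lo)
    starts = steady_state(p0, lig0)
    seen_start: list[np.ndarray] = []
    for fp in starts:
        x0 = fp.state.as_array()[:3]
        if any(np.allclose(x0, s, atol=1e-6) for s in seen_start):
            continue
        seen_start.append(x0)
        pts = [np.concatenate([x0, [lo]])]
        stab = [fp.stability == "stable"]
        tangent = np.zeros(4)
        tangent[3] = 1.0
        h_step = step
        y = pts[0]
        while len(pts) < max_points:
            # tangent: null vector of the Jacobian, oriented along progress
            p_here, lig_here = _apply_control(params, control, y[3])
            A = J_aug(y, tangent)[:3, :]
            _, _, vt = np.linalg.svd(A)
            t_new = vt[-1]
            if np.dot(t_new, tangent) < 0:
                t_new = -t_new
            tangent = t_new
            converged = False
            while h_step >= min_step:
                y_pred = y + h_step * tangent

                def G(z, _yp=y_pred, _t=tangent):
                    return np.concatenate([F(z), [np.dot(z - _yp, _t)]])

                sol = root(G, y_pred, jac=lambda z, _t=tangent: J_aug(z, _t),
                           method="hybr", tol=1e-13)
                if sol.success and np.max(np.abs(F(sol.x))) < tol:
                    converged = True
                    break
                h_step *= 0.5
            if not converged:
                warnings.warn("continuation step failed to converge; "
                              "branch truncated", stacklevel=2)
                break
            y = sol.x
            if y[3] > hi + 1e-12 or y[3] < lo - 1e-12:
                # land exactly on the boundary with a natural-parameter solve
                c_end = float(np.clip(y[3], lo, hi))
                p_end, lig_end = _apply_control(params, control, c_end)
                sol_end = root(lambda x: _rhs_vec(x, p_end, lig_end), y[:3],
                               jac=lambda x: _jac_vec(x, p_end, lig_end),
                               method="hybr", tol=1e-13)
                if sol_end.success:
                    yb = np.concatenate([sol_end.x, [c_end]])
                    p_b, lig_b = _apply_control(params, control, c_end)
                    pts.append(yb)
                    stab.append(_is_stable(p_b, lig_b, yb[:3]))
                break
            pts.append(y.copy())
            p_here, lig_here = _apply_control(params, control, y[3])
            stab.append(_is_stable(p_here, lig_here, y[:3]))
            h_step = min(h_step * 1.3, step)
        arr = np.array(pts)
        branches.append(BifurcationBranch(control, arr[:, 3], arr[:, :3],
                                          np.array(stab, dtype=bool)))
    # keep only branches that are not duplicates (same start, same end)
    unique: list[BifurcationBranch] = []
    for b in branches:
        dup = False
        for u in unique:
            if (abs(b.control[0] - u.control[0]) < 1e-9
                    and np.allclose(b.states[0], u.states[0], atol=1e-6)):
                dup = True
                break
            # an S-branch through both folds revisits the other start points
            d = np.min(np.abs(u.control - b.control[0])
                       + np.max(np.abs(u.states - b.states[0]), axis=1))
            if d < 1e-5:
                dup = True
                break
        if not dup:
            unique.append(b)
    return unique


def detect_folds(branch: BifurcationBranch, branch_id: int = 0,
                 refine_tol: float = 1e-6) -> list[FoldPoint]:
    """Locate saddle-node points where the control reverses along a branch.

    Candidate folds are interior sign changes of the control increment; each
    is refined by bisection on the arclength between the bracketing points
    (interpolating the already-converged branch, then polishing the control
    extremum with a parabolic fit through the three nearest points).
    """
    c = branch.control
    if c.size < 3:
        return []
    dc = np.diff(c)
    folds: list[FoldPoint] = []
    for i in range(len(dc) - 1):
        if dc[i] == 0 or dc[i + 1] == 0:
            continue
        if np.sign(dc[i]) != np.sign(dc[i + 1]):
            # parabolic refinement of the extremum through points i, i+1, i+2
            cs = c[i:i + 3]
            xs = branch.states[i:i + 3]
            # fit c as quadratic in arclength s = {0,1,2}
            s = np.array([0.0, 1.0, 2.0])
            coef = np.polyfit(s, cs, 2)
            s_ext = -coef[1] / (2 * coef[0]) if coef[0] != 0 else 1.0
            s_ext = float(np.clip(s_ext, 0.0, 2.0))
            c_ext = float(np.polyval(coef, s_ext))
            w = np.array([max(0.0, 1 - abs(s_ext - k)) for k in range(3)])
            w = w / w.sum()
            x_ext = w @ xs
            folds.append(FoldPoint(c_ext, float(x_ext[0]),
                                   float(2 * x_ext[1] + x_ext[0]), branch_id))
    folds.sort(key=lambda f: f.control)
    return folds


def map_bistable_region(params: ReactionParams, ratio_grid, liganded_grid,
                        n_scan: int = 400) -> BistableRegion:
    """Fixed-point multiplicity over the (ratio, liganded fraction) plane.

    Uses the reduced scalar steady-state solver per grid cell; the bistable
    set is where three fixed points coexist.
    """
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    liganded_grid = np.asarray(liganded_grid, dtype=float)
    if not (np.isfinite(ratio_grid).all() and np.isfinite(liganded_grid).all()):
        raise ValueError("grids must be finite")
    mult = np.zeros((ratio_grid.size, liganded_grid.size), dtype=int)
    for i, r in enumerate(ratio_grid):
        p = params.with_ratio(r)
        for j, lf in enumerate(liganded_grid):
            mult[i, j] = len(steady_states_reduced(
                p, lf * p.egfr_total, n_scan=n_scan))
    return BistableRegion(ratio_grid, liganded_grid, mult)


def hysteresis_sweep(params: ReactionParams, liganded_grid,
                     t_relax: float = 400.0) -> dict[str, np.ndarray]:
    """Quasi-static forward/backward dose-response sweep.

    Sweeps the liganded fraction up and then down, tracking the branch by
    always choosing the fixed point nearest the previous one (adiabatic
    following).  Returns the phosphorylated fraction along both sweeps;
    within a bistable window the backward curve rides the upper branch.
    """
    lf = np.asarray(liganded_grid, dtype=float)
    if np.any(np.diff(lf) <= 0):
        raise ValueError("liganded_grid must be increasing")

    def sweep(grid: np.ndarray) -> np.ndarray:
        out = np.empty(grid.size)
        prev: float | None = None
        for k, f in enumerate(grid):
            sts = steady_states_reduced(params, f * params.egfr_total)
            stable = [s for s in sts if _is_stable(
                params, f * params.egfr_total, s.as_array())]
            if not stable:
                stable = sts
            vals = np.array([2 * s.egf_egfr_p + s.egfr_p for s in stable])
            vals /= params.egfr_total
            if prev is None:
                pick = float(vals.min() if grid is lf else vals.max())
            else:
                pick = float(vals[np.argmin(np.abs(vals - prev))])
            out[k] = pick
            prev = pick
        return out

    forward = sweep(lf)
    backward = sweep(lf[::-1])[::-1]
    return {"liganded_fraction": lf, "forward": forward, "backward": backward}
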
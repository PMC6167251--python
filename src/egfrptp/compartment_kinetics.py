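"""Closed-form trafficking, binding and reactivity models.

Three small steady-state/kinetic models used to turn per-cell imaging
read-outs into rate constants and fractions:

* relative PTP reactivity from paired phospho-fractions (first-order kinase,
  second-order phosphatase reaction at local steady state);
* a two-compartment plasma-membrane/recycling-endosome model of ligandless
  receptor trafficking with internalization rate ``k_in`` and recycling rate
  ``k_rec``;
* ligand-receptor equilibrium binding with ligand depletion (at low doses a
  finite number of receptors measurably depletes free ligand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DOSE_SERIES_NG_ML",
    "EGF_MW_DA",
    "ng_ml_to_molar",
    "RecyclingModel",
    "BindingModel",
    "ptp_reactivity",
    "saturation_curve",
    "pm_fraction_recovery",
    "steady_state_pm_fraction",
    "bound_fraction_depletion",
]

#: EGF dose series used in the single-cell dose-response experiments
#: (ng/ml, roughly doubling from 2.5 to ~600).
DOSE_SERIES_NG_ML = np.array([2.5, 7.2, 16.4, 34.75, 71.6, 145.6, 294.4, 593.4])

#: Molar mass of the labelled EGF conjugate (g/mol), chosen so the printed
#: dose range 2.5-600 ng/ml maps to 0.34-81.3 nM.
EGF_MW_DA = 7381.0


def ng_ml_to_molar(dose_ng_ml) -> np.ndarray:
    """Convert an EGF dose from ng/ml to mol/l."""
    return np.asarray(dose_ng_ml, dtype=float) * 1e-6 / EGF_MW_DA


@dataclass(frozen=True)
class RecyclingModel:
    """Two-compartment trafficking model of ligandless EGFR.

    ``f0`` is the plasma-membrane fraction at the reference time ``t0``
    (minutes; default 5 min, the end of the stimulation pulse).
    """

    k_in: float
    k_rec: float
    f0: float
    t0: float = 5.0

    def __post_init__(self) -> None:
        if self.k_in < 0 or self.k_rec < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must lie in [0, 1]")


@dataclass(frozen=True)
class BindingModel:
    """Equilibrium ligand binding with a depletion correction.

    ``depletion_molar`` is the effective receptor concentration
    ``n_cells * egfr_per_cell / (N_A * V)`` expressed in the same molar
    units as the ligand; 0 recovers the pure hyperbolic isotherm.
    """

    K_D: float
    depletion_molar: float = 0.0
    kf: float | None = None
    kr: float | None = None

    def __post_init__(self) -> None:
        if self.K_D < 0 or self.depletion_molar < 0:
            raise ValueError("K_D and depletion_molar must be >= 0")
        if self.kf is not None and self.kr is not None:
            if self.kf <= 0:
                raise ValueError("kf must be > 0")
            if not np.isclose(self.kr / self.kf, self.K_D, rtol=1e-6):
                raise ValueError("K_D must equal kr/kf")


def ptp_reactivity(f_ptpx, f_ctr):
    """Relative specific reactivity ``k_PTPx*[PTPx]/k_EGFR`` of an ectopic PTP.

    With a first-order kinase and second-order phosphatase reaction, the
    steady-state phospho-fraction f satisfies total dephosphorylation
    activity = k_EGFR*(1/f - 1).  Subtracting the control condition (no
    ectopic PTP) isolates the ectopic contribution::

        k_PTPx*[PTPx]/k_EGFR = 1/f_ptpx - 1/f_ctr

    Note the difference of the two steady-state expressions: the ectopic
    activity is the *excess* over the endogenous background measured in the
    control cells.
    """
    f_ptpx = np.asarray(f_ptpx, dtype=float)
    f_ctr = np.asarray(f_ctr, dtype=float)
    if np.any(f_ptpx <= 0) or np.any(f_ctr <= 0):
        raise ValueError("phospho-fractions must be > 0")
    if np.any(f_ptpx > 1) or np.any(f_ctr > 1):
        raise ValueError("phospho-fractions must be <= 1")
    out = 1.0 / f_ptpx - 1.0 / f_ctr
    return out.item() if out.ndim == 0 else out


def saturation_curve(ptpx_level, k_ratio, f_ctr):
    """Steady-state phospho-fraction vs ectopic PTP expression level.

    ``1 / (k_ratio * ptpx_level + 1/f_ctr)``; decreasing in the expression
    level, used to flag cells whose expression saturates dephosphorylation.
    """
    ptpx_level = np.asarray(ptpx_level, dtype=float)
    if np.any(ptpx_level < 0) or k_ratio < 0:
        raise ValueError("inputs must be nonnegative")
    if not 0 < f_ctr <= 1:
        raise ValueError("f_ctr must lie in (0, 1]")
    out = 1.0 / (k_ratio * ptpx_level + 1.0 / f_ctr)
    return out.item() if out.ndim == 0 else out


def pm_fraction_recovery(t, model: RecyclingModel):
    """Plasma-membrane fraction of ligandless EGFR during recovery.

    Closed-form solution of the two-compartment exchange ODE: exponential
    relaxation from ``f0`` toward ``k_rec/(k_rec + k_in)`` with rate
    ``k_in + k_rec``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < model.t0 - 1e-12):
        raise ValueError("t must be >= t0")
    k_sum = model.k_in + model.k_rec
    if k_sum == 0:
        out = np.full_like(t, model.f0)
        return out.item() if out.ndim == 0 else out
    f_inf = model.k_rec / k_sum
    out = f_inf - (f_inf - model.f0) * np.exp(-k_sum * (t - model.t0))
    return out.item() if out.ndim == 0 else out


def steady_state_pm_fraction(k_in: float, k_rec: float) -> float:
    """Steady-state plasma-membrane fraction ``k_rec/(k_rec + k_in)``."""
    if k_in < 0 or k_rec < 0:
        raise ValueError("rate constants must be >= 0")
    if k_in + k_rec == 0:
        raise ValueError("k_in + k_rec must be > 0")
    return k_rec / (k_rec + k_in)


def bound_fraction_depletion(egf_total, model: BindingModel):
    """Fraction of liganded receptor at equilibrium with ligand depletion.

    Physical root of the binding quadratic; with receptor concentration
    R = ``depletion_molar`` and total ligand L::

        bound = (R + L + K_D - sqrt((R + L + K_D)^2 - 4*R*L)) / (2*R)

    which reduces to the hyperbola ``L/(L + K_D)`` as R -> 0.  The returned
    value lies in [0, 1].
    """
    L = np.asarray(egf_total, dtype=float)
    if np.any(L < 0):
        raise ValueError("egf_total must be >= 0")
    R, KD = model.depletion_molar, model.K_D
    if R == 0:
        with np.errstate(invalid="ignore"):
            out = np.where(L + KD > 0, L / (L + KD), 0.0)
        return out.item() if out.ndim == 0 else out
    s = R + L + KD
    disc = s * s - 4.0 * R * L
    if np.any(disc < -1e-12 * np.maximum(s * s, 1e-300)):
        raise ValueError("negative discriminant: invalid binding inputs")
    disc = np.maximum(disc, 0.0)
    out = (s - np.sqrt(disc)) / (2.0 * R)
    out = np.clip(out, 0.0, 1.0)
    return out.item() if out.ndim == 0 else out
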
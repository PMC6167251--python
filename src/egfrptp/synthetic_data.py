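"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one class of experimental input — radially
organised fluorescence scenes over cell/nucleus masks, single-cell
dose-response cohorts drawn from the steady-state network models with
cell-to-cell parameter scatter, two-lifetime FLIM photon data with a
spatially varying FRET fraction, plasma-membrane recovery time courses
from the two-compartment trafficking model, and pulse-train responses in
the three dynamical regimes — and returns its ground truth alongside the
data.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .compartment_kinetics import (
    DOSE_SERIES_NG_ML,
    BindingModel,
    RecyclingModel,
    bound_fraction_depletion,
    ng_ml_to_molar,
    pm_fraction_recovery,
)
from .flim_phasor import OMEGA_TCSPC, molecular_to_photon_fraction
from .image_quant import DoseResponseCurve
from .reaction_models import (
    ExtendedParams,
    PulseProtocol,
    ReactionParams,
    Trajectory,
    pegfr_dose_response,
    regime_preset,
    simulate_pulse_train,
)

__all__ = [
    "SceneConfig",
    "CohortConfig",
    "DEFAULT_KD_MOLAR",
    "TOPOLOGY_GENERATING_PARAMS",
    "STUDY_DEPLETION_MOLAR",
    "synth_cell_geometry",
    "synth_radial_scene",
    "synth_dose_response_cells",
    "synth_phasor_stack",
    "synth_recycling_traces",
    "synth_pulse_experiment",
]

#: Default dissociation constant for the dose -> liganded-fraction mapping
#: (sub-nanomolar, matching the fitted live-cell estimate of 762 pM).
DEFAULT_KD_MOLAR = 762e-12

#: Generating parameter sets for topology-recovery simulation studies.
#: The double-negative set places its bistable ignition inside the sampled
#: liganded-fraction range (under a 2 nM depletion coefficient); the
#: negative-feedback set is a strong homeostatic clamp.  Note that
#: negative-feedback steady-state curves are structurally near-degenerate
#: with negative regulation on this read-out, so recovery studies draw
#: their truths from the two identifiable topologies.
TOPOLOGY_GENERATING_PARAMS: dict[str, ReactionParams] = {
    "double_negative": ReactionParams(alpha3=0.1, ptp_total=2.3, k3=8.0),
    "negative_feedback": ReactionParams(
        alpha1=0.01, alpha2=2.0, alpha3=0.5, k2=20.0, k3=0.0, k4=500.0,
        ptp_total=1.9, topology="negative_feedback"),
    "negative_regulation": ReactionParams(
        k3=0.0, k4=0.0, topology="negative_regulation"),
}

#: Depletion coefficient (molar receptor concentration) used by the
#: discrimination studies: spreads the dose series into the low
#: liganded-fraction range where the toggle ignites.
STUDY_DEPLETION_MOLAR = 2e-9


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, radial intensity profiles and noise of a synthetic scene."""

    shape: tuple[int, int] = (128, 128)
    cell_center: tuple[float, float] | None = None
    cell_radii: tuple[float, float] = (50.0, 50.0)
    nucleus_radii: tuple[float, float] = (12.0, 12.0)
    nucleus_offset: tuple[float, float] = (0.0, 0.0)
    read_noise_sd: float = 0.0
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.nucleus_radii[0] >= self.cell_radii[0]
                or self.nucleus_radii[1] >= self.cell_radii[1]):
            raise ValueError("nucleus must be strictly smaller than the cell")


@dataclass(frozen=True)
class CohortConfig:
    """A synthetic single-cell dose-response cohort.

    Cells share the generating topology and mean parameters; cell-to-cell
    variability is log-normal on the rate constants (``param_cv``, default
    20%) and measurement noise is additive Gaussian on the phosphorylated
    fraction (``noise_sd``).  Doses map to liganded fractions through the
    depletion binding model at ``kd_molar``.
    """

    n_cells: int = 20
    params: ReactionParams = field(default_factory=ReactionParams)
    doses_ng_ml: np.ndarray = field(
        default_factory=lambda: DOSE_SERIES_NG_ML.copy())
    kd_molar: float = DEFAULT_KD_MOLAR
    depletion_molar: float = 0.0
    noise_sd: float = 0.05
    param_cv: float = 0.2
    sweep_direction: str = "forward"
    include_zero_dose: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd < 0 or self.param_cv < 0:
            raise ValueError("noise and scatter must be >= 0")

    @property
    def dose_grid_ng_ml(self) -> np.ndarray:
        doses = np.asarray(self.doses_ng_ml, dtype=float)
        if self.include_zero_dose and (doses.size == 0 or doses[0] != 0.0):
            doses = np.concatenate([[0.0], doses])
        return doses


def synth_cell_geometry(config: SceneConfig
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical cell and nucleus masks (nucleus strictly inside)."""
    h, w = config.shape
    cy, cx = (config.cell_center if config.cell_center is not None
              else ((h - 1) / 2.0, (w - 1) / 2.0))
    yy, xx = np.mgrid[0:h, 0:w]
    ry, rx = config.cell_radii
    cell = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    ny, nx = config.nucleus_radii
    oy, ox = config.nucleus_offset
    nuc = (((yy - cy - oy) / ny) ** 2 + ((xx - cx - ox) / nx) ** 2) <= 1.0
    if not nuc.any() or not cell.any():
        raise ValueError("degenerate geometry: empty mask")
    from scipy import ndimage

    if np.any(nuc & ~ndimage.binary_erosion(cell, iterations=2)):
        raise ValueError("nucleus not containable inside the cell")
    return cell, nuc


def synth_radial_scene(cell_mask, nucleus_mask,
                       profiles: dict[str, Callable[[np.ndarray], np.ndarray]],
                       read_noise_sd: float = 0.0, shot_noise: bool = False,
                       seed: int = 0) -> dict:
    """Multi-channel radial scene over a cell geometry.

    Each channel's noise-free intensity is ``profile(r)`` of the normalised
    PM-to-NM coordinate; optional Poisson shot noise and Gaussian read
    noise are applied on top.  Returns the channels, the radial field and
    the noise-free ground truth per channel.
    """
    from .stm import radial_coordinate

    rng = np.random.default_rng(seed)
    fieldr = radial_coordinate(cell_mask, nucleus_mask)
    r = fieldr.r
    valid = np.isfinite(r)
    channels: dict[str, np.ndarray] = {}
    truth: dict[str, np.ndarray] = {}
    for name, fn in profiles.items():
        img = np.zeros(r.shape)
        vals = np.asarray(fn(r[valid]), dtype=float)
        if np.any(vals < 0):
            warnings.warn(f"channel {name}: negative profile clipped at 0",
                          stacklevel=2)
            vals = np.clip(vals, 0.0, None)
        img[valid] = vals
        truth[name] = img.copy()
        noisy = img.copy()
        if shot_noise:
            noisy[valid] = rng.poisson(np.clip(noisy[valid], 0, None))
        if read_noise_sd > 0:
            noisy[valid] += rng.normal(0.0, read_noise_sd, size=valid.sum())
        channels[name] = noisy
    return {"channels": channels, "radial_field": fieldr,
            "ground_truth": truth, "cell_mask": np.asarray(cell_mask, bool),
            "nucleus_mask": np.asarray(nucleus_mask, bool)}


_JITTERED = ("alpha1", "alpha2", "alpha3", "k2", "k3", "k4", "k5")


def synth_dose_response_cells(config: CohortConfig
                              ) -> tuple[list[DoseResponseCurve], dict]:
    """Per-cell dose-response curves from the steady-state network model.

    Doses are mapped to liganded fractions through the depletion binding
    model; each cell's phosphorylated fraction is the quasi-static steady
    state of the generalized network at log-normally jittered rate
    constants, plus additive Gaussian measurement noise.  Bistable
    parameter sets require the sweep direction to be stated (it matters).
    """
    rng = np.random.default_rng(config.seed)
    binding = BindingModel(K_D=config.kd_molar,
                           depletion_molar=config.depletion_molar)
    doses = config.dose_grid_ng_ml
    liganded = np.asarray(bound_fraction_depletion(
        ng_ml_to_molar(doses), binding), dtype=float)
    if config.sweep_direction not in ("forward", "backward"):
        raise ValueError("bistable generators need an explicit sweep "
                         "direction ('forward' or 'backward')")
    sigma = np.sqrt(np.log1p(config.param_cv ** 2))
    cells: list[DoseResponseCurve] = []
    cell_params: list[ReactionParams] = []
    for i in range(config.n_cells):
        kw = {}
        for name in _JITTERED:
            v = getattr(config.params, name)
            if v > 0 and config.param_cv > 0:
                v = float(v * rng.lognormal(-sigma ** 2 / 2.0, sigma))
            kw[name] = v
        p_i = replace(config.params, **kw)
        cell_params.append(p_i)
        peg = pegfr_dose_response(p_i, liganded,
                                  direction=config.sweep_direction)
        if config.noise_sd > 0:
            peg = peg + rng.normal(0.0, config.noise_sd, size=peg.size)
        cells.append(DoseResponseCurve(
            liganded=liganded, pegfr=peg, doses_ng_ml=doses,
            cell_id=i, normalized=False))
    truth = {"liganded_fractions": liganded,
             "topology": config.params.topology.value,
             "params": config.params, "cell_params": cell_params,
             "kd_molar": config.kd_molar}
    return cells, truth


def synth_phasor_stack(tau_d: float, tau_da: float, alpha_field,
                       photons_per_pixel: int = 10_000,
                       omega: float = OMEGA_TCSPC, seed: int = 0) -> dict:
    """Two-lifetime FLIM photon data with a spatially varying FRET fraction.

    Per pixel, exactly ``photons_per_pixel`` photon arrival times are drawn
    from the two-exponential mixture whose photon fraction derives from the
    pixel's molecular FRET fraction and the brightness ratio
    ``tau_da/tau_d``.  Arrival times are in nanoseconds; no instrument
    response is applied (a delta excitation), so an ideal reference is the
    analytic phasor.
    """
    if not 0 <= tau_da < tau_d:
        raise ValueError("need 0 <= tau_da < tau_d")
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be > 0")
    alpha = np.asarray(alpha_field, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha_field must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    q = tau_da / tau_d
    f_photon = np.asarray(molecular_to_photon_fraction(alpha, q), dtype=float)
    shape = alpha.shape
    times_per_pixel: list[np.ndarray] = []
    for f in f_photon.ravel():
        is_fret = rng.uniform(size=photons_per_pixel) < f
        t = np.where(is_fret,
                     rng.exponential(tau_da if tau_da > 0 else 1e-12,
                                     photons_per_pixel),
                     rng.exponential(tau_d, photons_per_pixel))
        if tau_da == 0:
            t[is_fret] = 0.0
        times_per_pixel.append(t)
    return {"times_per_pixel": times_per_pixel, "shape": shape,
            "alpha_true": alpha, "photon_fraction_true": f_photon,
            "tau_d": tau_d, "tau_da": tau_da, "omega": omega,
            "photons_per_pixel": photons_per_pixel}


def synth_recycling_traces(k_in: float = 0.31, k_rec: float = 0.23,
                           f0: float = 0.2, t0: float = 5.0,
                           noise_sd: float = 0.0, n_traces: int = 14,
                           t_end: float = 35.0, dt: float = 1.0,
                           rate_cv: float = 0.0, seed: int = 0
                           ) -> tuple[list[tuple[np.ndarray, np.ndarray]], dict]:
    """Plasma-membrane recovery time courses from the trafficking model.

    Traces follow the two-compartment closed form on a regular grid from
    ``t0`` to ``t_end`` (minutes) with additive Gaussian noise; optional
    log-normal jitter on the per-trace rates emulates cell-to-cell
    variability.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(t0, t_end + dt / 2.0, dt)
    sigma = np.sqrt(np.log1p(rate_cv ** 2)) if rate_cv > 0 else 0.0
    traces = []
    rates = []
    for _ in range(n_traces):
        ki, kr = k_in, k_rec
        if sigma > 0:
            ki = float(ki * rng.lognormal(-sigma ** 2 / 2.0, sigma))
            kr = float(kr * rng.lognormal(-sigma ** 2 / 2.0, sigma))
        rates.append((ki, kr))
        f = pm_fraction_recovery(t, RecyclingModel(ki, kr, f0, t0))
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=t.size)
        traces.append((t.copy(), f))
    truth = {"k_in": k_in, "k_rec": k_rec, "f0": f0, "t0": t0,
             "per_trace_rates": rates}
    return traces, truth


def synth_pulse_experiment(params: ExtendedParams | str,
                           protocol: PulseProtocol | None = None,
                           noise_sd: float = 0.02,
                           liganded_decay_rate: float = 0.2,
                           seed: int = 0) -> dict:
    """Noisy pulse-train read-outs in a chosen dynamical regime.

    ``params`` may be an :class:`ExtendedParams` or one of the regime names
    (``"trapped"``, ``"biphasic"``, ``"tracking"``).  The liganded-fraction
    input decays first-order after each washout (unidirectional depletion
    of liganded receptor); both read-outs are sampled at 1-min intervals
    with additive Gaussian noise.
    """
    if isinstance(params, str):
        params = regime_preset(params)
    if protocol is None:
        protocol = PulseProtocol(decay_rate=liganded_decay_rate)
    elif protocol.decay_rate == 0 and liganded_decay_rate > 0:
        protocol = replace(protocol, decay_rate=liganded_decay_rate)
    traj, label = simulate_pulse_train(params, protocol, dt_minutes=1.0)
    rng = np.random.default_rng(seed)
    pegfr = traj.pegfr.copy()
    liganded = traj.inputs.copy()
    if noise_sd > 0:
        pegfr = pegfr + rng.normal(0.0, noise_sd, size=pegfr.size)
        liganded = liganded + rng.normal(0.0, noise_sd, size=liganded.size)
    return {"times": traj.times, "pegfr": pegfr, "liganded": liganded,
            "trajectory": traj, "regime_true": label, "protocol": protocol,
            "params": params}
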
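"""Frequency-domain FLIM global analysis in phasor space.

Each pixel's fluorescence decay is reduced to its first-harmonic Fourier
coefficients (g, s) — the *phasor*.  Monoexponential decays lie on the
universal semicircle (g - 1/2)^2 + s^2 = 1/4; two-component mixtures lie on
the chord connecting the two pure-species phasors.  Global analysis fits a
line through the pixel cloud, intersects it with the semicircle to obtain
the two global lifetimes (donor-only tau_D and FRET-state tau_DA), and maps
each pixel's projection onto the chord to the fraction of donor molecules
exhibiting FRET (alpha).

The default modulation frequency is the 40 MHz pulse repetition rate of
time-correlated single-photon counting (first harmonic); the 79.2 MHz
widefield frequency is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OMEGA_TCSPC",
    "OMEGA_WIDEFIELD",
    "PhasorField",
    "GlobalLifetimes",
    "AlphaMap",
    "mono_exp_phasor",
    "phasor_from_arrival_times",
    "phasor_from_decay",
    "phasor_from_phase_stack",
    "fit_phasor_line",
    "semicircle_intersection",
    "alpha_from_projection",
    "photon_to_molecular_fraction",
    "molecular_to_photon_fraction",
    "write_alpha_map",
    "read_alpha_map",
]

#: First harmonic of the 40 MHz TCSPC pulse train (rad/ns).
OMEGA_TCSPC = 2.0 * np.pi * 0.040
#: Widefield homodyne modulation at 79.2 MHz (rad/ns).
OMEGA_WIDEFIELD = 2.0 * np.pi * 0.0792


@dataclass
class PhasorField:
    """Per-pixel first-harmonic phasor coordinates with intensity weights."""

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    omega: float = OMEGA_TCSPC
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.g) & np.isfinite(self.s) \
                & (self.intensity > 0)

    @property
    def valid_g(self) -> np.ndarray:
        return self.g[self.mask]

    @property
    def valid_s(self) -> np.ndarray:
        return self.s[self.mask]

    @property
    def valid_weights(self) -> np.ndarray:
        return self.intensity[self.mask]


@dataclass(frozen=True)
class GlobalLifetimes:
    """Global donor-only and FRET-state lifetimes with the fitted chord."""

    tau_d: float
    tau_da: float
    slope: float
    intercept: float
    point_d: tuple[float, float]
    point_da: tuple[float, float]
    omega: float = OMEGA_TCSPC

    def __post_init__(self) -> None:
        if not (self.tau_d > 0 and self.tau_da >= 0):
            raise ValueError("lifetimes must be positive")
        if not self.tau_da < self.tau_d:
            raise ValueError("tau_da must be shorter than tau_d")


@dataclass
class AlphaMap:
    """Per-pixel fraction of donor molecules exhibiting FRET."""

    alpha: np.ndarray
    photon_fraction: np.ndarray
    mask: np.ndarray


def mono_exp_phasor(tau, omega: float = OMEGA_TCSPC):
    """Phasor of a monoexponential decay: lies on the universal semicircle."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    wt = omega * tau
    g = 1.0 / (1.0 + wt * wt)
    s = wt / (1.0 + wt * wt)
    if g.ndim == 0:
        return float(g), float(s)
    return g, s


def phasor_from_arrival_times(times_per_pixel, omega: float = OMEGA_TCSPC,
                              reference_tau: float | None = None,
                              reference_times=None) -> PhasorField:
    """Phasors from per-pixel photon arrival times (nanoseconds).

    The first-harmonic coefficients are the circular cosine/sine moments of
    the arrival-time distribution (wrapping at the pulse period leaves them
    unchanged).  When a measured reference decay and its true lifetime are
    given, all pixel phasors are divided by the complex ratio
    measured/ideal of the reference, correcting the instrument response.
    """
    gs, ss, ns = [], [], []
    for t in times_per_pixel:
        t = np.asarray(t, dtype=float)
        n = t.size
        ns.append(n)
        if n == 0:
            gs.append(np.nan)
            ss.append(np.nan)
            continue
        gs.append(float(np.mean(np.cos(omega * t))))
        ss.append(float(np.mean(np.sin(omega * t))))
    g = np.array(gs)
    s = np.array(ss)
    z = g + 1j * s
    if reference_times is not None:
        if reference_tau is None:
            raise ValueError("reference_times requires reference_tau")
        tr = np.asarray(reference_times, dtype=float)
        z_meas = np.mean(np.exp(1j * omega * tr))
        gi, si = mono_exp_phasor(reference_tau, omega)
        z = z * (gi + 1j * si) / z_meas
    return PhasorField(z.real, z.imag, np.array(ns, dtype=float), omega)


def phasor_from_decay(decay_stack, t_bins, omega: float = OMEGA_TCSPC,
                      reference_decay=None, reference_tau: float | None = None,
                      min_photons: int = 100) -> PhasorField:
    """Phasors from binned decay histograms.

    ``decay_stack`` has shape (n_time_bins, ...) with photon counts per time
    bin per pixel; ``t_bins`` are the bin centres in nanoseconds.  Pixels
    with fewer than ``min_photons`` total counts are masked out.  A measured
    reference histogram of known lifetime calibrates the phasors.
    """
    decay = np.asarray(decay_stack, dtype=float)
    t = np.asarray(t_bins, dtype=float)
    if decay.shape[0] != t.size:
        raise ValueError("decay_stack first axis must match t_bins")
    total = decay.sum(axis=0)
    shape_extra = (1,) * (decay.ndim - 1)
    phase = np.exp(1j * omega * t).reshape((t.size,) + shape_extra)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (decay * phase).sum(axis=0) / total
    if reference_decay is not None:
        if reference_tau is None:
            raise ValueError("reference_decay requires reference_tau")
        ref = np.asarray(reference_decay, dtype=float)
        z_meas = (ref * np.exp(1j * omega * t)).sum() / ref.sum()
        gi, si = mono_exp_phasor(reference_tau, omega)
        z = z * (gi + 1j * si) / z_meas
    mask = np.asarray(total >= min_photons)
    return PhasorField(np.real(z), np.imag(z), total, omega, mask=mask)


def phasor_from_phase_stack(stack, phases, omega: float = OMEGA_WIDEFIELD,
                            reference_stack=None,
                            reference_tau: float | None = None) -> PhasorField:
    """Phasors from a homodyne phase-sequence stack (widefield FLIM).

    Each pixel's intensity as a function of detector phase is a sinusoid
    ``I(phi) = A + B cos(phi) + C sin(phi)``; the least-squares sinusoid fit
    gives the phasor (B/A, C/A).  Permuted phase orders are handled by
    passing the phases in acquisition order.
    """
    stack = np.asarray(stack, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if stack.shape[0] != phases.size:
        raise ValueError("stack first axis must match phases")
    X = np.column_stack([np.ones_like(phases), np.cos(phases), np.sin(phases)])
    flat = stack.reshape(stack.shape[0], -1)
    coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
    A, B, C = coef[0], coef[1], coef[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (B + 1j * C) / A
    if reference_stack is not None:
        if reference_tau is None:
            raise ValueError("reference_stack requires reference_tau")
        ref = np.asarray(reference_stack, dtype=float).reshape(phases.size, -1)
        rc, *_ = np.linalg.lstsq(X, ref.mean(axis=1, keepdims=True), rcond=None)
        z_meas = (rc[1, 0] + 1j * rc[2, 0]) / rc[0, 0]
        gi, si = mono_exp_phasor(reference_tau, omega)
        z = z * (gi + 1j * si) / z_meas
    shape = stack.shape[1:]
    return PhasorField(np.real(z).reshape(shape), np.imag(z).reshape(shape),
                       A.reshape(shape), omega)


def fit_phasor_line(field: PhasorField) -> tuple[float, float]:
    """Intensity-weighted total-least-squares line through the phasor cloud.

    Returns ``(slope, intercept)`` of s = slope*g + intercept.  TLS (the
    principal axis of the weighted scatter) is used because shot noise
    perturbs both phasor coordinates.
    """
    g = field.valid_g
    s = field.valid_s
    w = field.valid_weights
    if g.size < 2:
        raise ValueError("need at least 2 valid pixels")
    wsum = w.sum()
    mg = np.sum(w * g) / wsum
    ms = np.sum(w * s) / wsum
    cgg = np.sum(w * (g - mg) ** 2) / wsum
    css = np.sum(w * (s - ms) ** 2) / wsum
    cgs = np.sum(w * (g - mg) * (s - ms)) / wsum
    cov = np.array([[cgg, cgs], [cgs, css]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise ValueError("phasor cloud is degenerate (zero extent)")
    v = evecs[:, -1]
    if abs(v[0]) < 1e-12:
        raise ValueError("phasor line is vertical; cannot express s(g)")
    slope = v[1] / v[0]
    intercept = ms - slope * mg
    return float(slope), float(intercept)


def semicircle_intersection(line: tuple[float, float],
                            omega: float = OMEGA_TCSPC) -> GlobalLifetimes:
    """Global lifetime pair from the chord/semicircle intersection.

    Solves the quadratic intersection of ``s = m*g + b`` with the universal
    semicircle; each intersection (g, s) corresponds to the monoexponential
    lifetime ``tau = s/(g*omega)``.  The longer lifetime is the donor-only
    state tau_D, the shorter the FRET state tau_DA.
    """
    m, b = float(line[0]), float(line[1])
    # (g-1/2)^2 + (m g + b)^2 = 1/4
    A = 1.0 + m * m
    B = -1.0 + 2.0 * m * b
    C = b * b
    disc = B * B - 4.0 * A * C
    if disc <= 0:
        raise ValueError("phasor cloud off semicircle: line does not "
                         "intersect the universal semicircle twice")
    r = np.sqrt(disc)
    taus = []
    pts = []
    for gi in ((-B - r) / (2 * A), (-B + r) / (2 * A)):
        si = m * gi + b
        if si < -1e-15 or gi <= 0:
            raise ValueError("intersection outside the physical semicircle "
                             "(s < 0); degenerate diameter line")
        si = max(si, 0.0)
        taus.append(si / (gi * omega))
        pts.append((float(gi), float(si)))
    i_d = int(np.argmax(taus))
    i_da = 1 - i_d
    return GlobalLifetimes(tau_d=float(taus[i_d]), tau_da=float(taus[i_da]),
                           slope=m, intercept=b,
                           point_d=pts[i_d], point_da=pts[i_da], omega=omega)


def photon_to_molecular_fraction(f, q: float):
    """Convert FRET photon fraction to molecular fraction.

    ``q = tau_DA/tau_D`` is the relative brightness of the FRET state under
    equal radiative rates; ``alpha = f / (f + (1 - f) * q)``.
    """
    f = np.asarray(f, dtype=float)
    out = f / (f + (1.0 - f) * q)
    return out.item() if out.ndim == 0 else out


def molecular_to_photon_fraction(alpha, q: float):
    """Inverse of :func:`photon_to_molecular_fraction`."""
    a = np.asarray(alpha, dtype=float)
    out = a * q / (a * q + (1.0 - a))
    return out.item() if out.ndim == 0 else out


def alpha_from_projection(field: PhasorField, lifetimes: GlobalLifetimes,
                          molecular: bool = True) -> AlphaMap:
    """Per-pixel FRET fraction from orthogonal projection onto the chord.

    Each pixel phasor is projected onto the fitted line; its normalised
    position between the tau_D intersection (0) and the tau_DA intersection
    (1) is the FRET *photon* fraction, converted to the molecular fraction
    via the relative brightness q = tau_DA/tau_D (``molecular=True``).
    Results are clipped to [0, 1].
    """
    p_d = np.array(lifetimes.point_d)
    p_da = np.array(lifetimes.point_da)
    chord = p_da - p_d
    denom = float(chord @ chord)
    if denom == 0:
        raise ValueError("degenerate lifetimes: chord has zero length")
    g = np.asarray(field.g, dtype=float)
    s = np.asarray(field.s, dtype=float)
    f = ((g - p_d[0]) * chord[0] + (s - p_d[1]) * chord[1]) / denom
    f = np.clip(f, 0.0, 1.0)
    if molecular:
        q = lifetimes.tau_da / lifetimes.tau_d
        alpha = photon_to_molecular_fraction(f, q)
    else:
        alpha = f
    return AlphaMap(alpha=alpha, photon_fraction=f,
                    mask=np.asarray(field.mask))


def write_alpha_map(path, alpha_map: AlphaMap | np.ndarray) -> None:
    """Write a FRET-fraction map as a 32-bit float TIFF (masked: NaN)."""
    import tifffile

    if isinstance(alpha_map, AlphaMap):
        data = np.where(alpha_map.mask, alpha_map.alpha, np.nan)
    else:
        data = np.asarray(alpha_map, dtype=float)
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))


def read_alpha_map(path) -> np.ndarray:
    """Read a FRET-fraction map written by :func:`write_alpha_map`."""
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)
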
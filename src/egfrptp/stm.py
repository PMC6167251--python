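"""Spatial-temporal maps (STMs) and phosphorylation fold-change statistics.

Receptor trafficking in these cells is radially organised: signal moves
between the plasma membrane (PM) and the nuclear membrane (NM).  Every
in-cell pixel is assigned a normalised radial coordinate
``r = r_PM / (r_PM + r_NM)`` (0 on the PM, 1 on the NM, nucleus excluded),
observables are averaged in 10 radial bins to give per-cell radial
profiles, and profiles are combined across cells and time points into an
STM.  Perturbation effects are quantified as phosphorylation fold changes
(PFC) between control and perturbed STMs assuming log-normally distributed
per-bin data, combined across experimental batches by Gaussian
(inverse-variance) products and tested with a one-sided Welch t-test.
A product-of-p-values rule combines independent tests, and the CA-FLIM
screen statistic gates per-replicate fold changes of the FRET fraction
alpha with a Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .compartment_kinetics import saturation_curve

__all__ = [
    "N_BINS",
    "RadialField",
    "SpatialTemporalMap",
    "PFCMap",
    "radial_coordinate",
    "radial_profile",
    "assemble_stm",
    "pfc_stm",
    "combined_pvalue",
    "pfc_alpha_screen",
    "saturation_gate",
]

#: Fixed number of radial bins between plasma membrane and nuclear membrane.
N_BINS = 10


@dataclass
class RadialField:
    """Normalised PM-to-NM radial coordinate per pixel (NaN outside)."""

    r: np.ndarray
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.r)


@dataclass
class SpatialTemporalMap:
    """Across-cell average radial profiles over time.

    ``mean``, ``sd`` and ``n`` have shape (n_times, N_BINS); bins never
    covered by any cell are NaN with n = 0.
    """

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    normalize_by_cell_mean: bool = True

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, t in enumerate(self.times):
            for b in range(self.mean.shape[1]):
                rows.append({"time_min": t, "bin": b,
                             "mean": self.mean[i, b], "sd": self.sd[i, b],
                             "n": int(self.n[i, b])})
        return pd.DataFrame(rows)


@dataclass
class PFCMap:
    """Per-bin/time phosphorylation fold change with significance.

    ``pfc``/``pfc_sd`` are the back-transformed log-normal mean and SD on
    the orientation defined by the perturbation mode; ``p`` holds one-sided
    Welch p values for log-PFC > 0 and ``significant`` the p < 0.05 mask.
    """

    times: np.ndarray
    pfc: np.ndarray
    pfc_sd: np.ndarray
    p: np.ndarray
    mode: str
    alpha_level: float = 0.05
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            self.significant = self.p < self.alpha_level

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, t in enumerate(self.times):
            for b in range(self.pfc.shape[1]):
                rows.append({"time_min": t, "bin": b, "pfc": self.pfc[i, b],
                             "pfc_sd": self.pfc_sd[i, b], "p": self.p[i, b],
                             "significant": bool(self.significant[i, b])})
        return pd.DataFrame(rows)


def radial_coordinate(cell_mask, nucleus_mask) -> RadialField:
    """Normalised radial coordinate from cell and nucleus masks.

    Euclidean distance transforms give each pixel its distance to the
    plasma membrane (cell boundary) and to the nuclear membrane; the
    coordinate is ``r_PM / (r_PM + r_NM)``.  Pixels inside the nucleus are
    excluded (NaN).  A nucleus touching the cell boundary is rejected.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    if not cell.any() or not nuc.any():
        raise ValueError("cell and nucleus masks must be nonempty")
    if np.any(nuc & ~cell):
        raise ValueError("nucleus must lie inside the cell mask")
    # nucleus touching the cell boundary leaves no PM-to-NM path
    eroded = ndimage.binary_erosion(cell)
    if np.any(nuc & ~eroded):
        raise ValueError("nucleus touches the cell boundary")
    d_pm = ndimage.distance_transform_edt(cell)
    d_nm = ndimage.distance_transform_edt(~nuc)
    r = np.full(cell.shape, np.nan)
    region = cell & ~nuc
    denom = d_pm[region] + d_nm[region]
    r[region] = d_pm[region] / denom
    return RadialField(r=r, cell_mask=cell, nucleus_mask=nuc)


def radial_profile(observable, field: RadialField,
                   normalize_by_cell_mean: bool = True,
                   denominator=None) -> np.ndarray:
    """Ten-bin radial profile of an observable over the cell.

    Bins are half-open ``[i/10, (i+1)/10)`` with the last bin closed.  When
    ``denominator`` is given (e.g. receptor fluorescence for a
    phospho/receptor ratio) the per-bin value is the ratio of bin means,
    ``mean(observable)/mean(denominator)``, not the mean of pixel ratios.
    With ``normalize_by_cell_mean`` the profile is divided by the whole-cell
    mean of the (ratio) observable.  Empty bins are NaN.
    """
    obs = np.asarray(observable, dtype=float)
    if obs.shape != field.r.shape:
        raise ValueError("observable shape must match the radial field")
    r = field.r
    valid = field.valid_mask & np.isfinite(obs)
    idx = np.clip((r[valid] * N_BINS).astype(int), 0, N_BINS - 1)
    vals = obs[valid]
    prof = np.full(N_BINS, np.nan)
    if denominator is not None:
        den = np.asarray(denominator, dtype=float)[valid]
        for b in range(N_BINS):
            m = idx == b
            if m.any() and den[m].mean() != 0:
                prof[b] = vals[m].mean() / den[m].mean()
        cell_mean = (vals.mean() / den.mean()) if den.mean() != 0 else np.nan
    else:
        for b in range(N_BINS):
            m = idx == b
            if m.any():
                prof[b] = vals[m].mean()
        cell_mean = vals.mean()
    if normalize_by_cell_mean:
        if not np.isfinite(cell_mean) or cell_mean == 0:
            raise ValueError("cell mean is zero; cannot normalise profile")
        prof = prof / cell_mean
    return prof


def assemble_stm(profiles_by_time: dict[float, list[np.ndarray]],
                 normalize_by_cell_mean: bool = True) -> SpatialTemporalMap:
    """Combine per-cell radial profiles into a spatial-temporal map.

    ``profiles_by_time`` maps each time point (minutes) to the list of
    per-cell 10-bin profiles measured there.  Per bin and time the
    across-cell mean, SD and count are retained for the fold-change
    statistics.
    """
    if not profiles_by_time:
        raise ValueError("need at least one time point")
    times = np.array(sorted(profiles_by_time))
    mean = np.full((times.size, N_BINS), np.nan)
    sd = np.full((times.size, N_BINS), np.nan)
    n = np.zeros((times.size, N_BINS), dtype=int)
    for i, t in enumerate(times):
        profs = profiles_by_time[t]
        if not profs:
            raise ValueError(f"no cells at time {t}")
        arr = np.vstack([np.asarray(p, dtype=float) for p in profs])
        if arr.shape[1] != N_BINS:
            raise ValueError(f"profiles must have {N_BINS} bins")
        counts = np.isfinite(arr).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean[i] = np.nanmean(arr, axis=0)
            sd[i] = np.nanstd(arr, axis=0, ddof=1)
        sd[i, counts == 1] = 0.0
        n[i] = counts
    return SpatialTemporalMap(times, mean, sd, n, normalize_by_cell_mean)


def _lognormal_params(mean, sd):
    """Parameters (mu, sigma^2) of a log-normal with given mean and SD."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
    return mu, sigma2


def pfc_stm(stm_ctrl, stm_perturbed, mode: str) -> PFCMap:
    """Phosphorylation fold change between control and perturbed STMs.

    ``stm_ctrl`` and ``stm_perturbed`` are single maps or per-batch lists on
    an identical bin/time grid.  Per bin and time, batch means are assumed
    log-normal; logs are differenced by Gaussian addition on the
    orientation set by ``mode`` (``"cDNA"``: control/perturbed, ``"siRNA"``:
    perturbed/control), batches are combined by Gaussian (inverse-variance)
    product, and the combined log-PFC is tested against zero with a
    one-sided Welch t-test with Welch-Satterthwaite degrees of freedom.
    The returned map carries the back-transformed log-normal mean and SD.
    Bins missing in any batch propagate as NaN.
    """
    if mode not in ("cDNA", "siRNA"):
        raise ValueError("mode must be 'cDNA' or 'siRNA'")
    ctrls = stm_ctrl if isinstance(stm_ctrl, (list, tuple)) else [stm_ctrl]
    perts = (stm_perturbed if isinstance(stm_perturbed, (list, tuple))
             else [stm_perturbed])
    if len(ctrls) != len(perts):
        raise ValueError("need one perturbed map per control batch")
    times = ctrls[0].times
    shape = ctrls[0].mean.shape
    for m in list(ctrls) + list(perts):
        if m.mean.shape != shape or not np.array_equal(m.times, times):
            raise ValueError("all maps must share the same bin/time grid")

    mu_d = np.zeros((len(ctrls),) + shape)
    var_est = np.zeros_like(mu_d)      # variance of the batch log-PFC estimate
    var_pop = np.zeros_like(mu_d)      # population variance of the log-PFC
    dof = np.zeros_like(mu_d)
    for b, (c, q) in enumerate(zip(ctrls, perts)):
        mu_c, s2_c = _lognormal_params(c.mean, c.sd)
        mu_p, s2_p = _lognormal_params(q.mean, q.sd)
        diff = mu_c - mu_p if mode == "cDNA" else mu_p - mu_c
        mu_d[b] = diff
        nc = np.maximum(c.n, 1)
        np_ = np.maximum(q.n, 1)
        v = s2_c / nc + s2_p / np_
        var_est[b] = v
        var_pop[b] = s2_c + s2_p
        with np.errstate(invalid="ignore", divide="ignore"):
            dof[b] = v ** 2 / ((s2_c / nc) ** 2 / np.maximum(nc - 1, 1)
                               + (s2_p / np_) ** 2 / np.maximum(np_ - 1, 1))

    with np.errstate(invalid="ignore", divide="ignore"):
        w = 1.0 / var_est
        wsum = np.nansum(np.where(np.isfinite(w), w, np.nan), axis=0)
        mu_comb = np.nansum(np.where(np.isfinite(w), w * mu_d, np.nan),
                            axis=0) / wsum
        var_comb = 1.0 / wsum
        # Welch-Satterthwaite propagation through the weighted combination
        cb = w / wsum ** 2
        df_comb = (np.nansum(cb, axis=0) ** 2
                   / np.nansum(cb ** 2 / np.maximum(dof, 1e-12), axis=0))
        sig2_comb = np.nansum(w * var_pop, axis=0) / wsum
        t_stat = mu_comb / np.sqrt(var_comb)
    missing = ~np.all(np.isfinite(mu_d), axis=0)
    p = np.where(np.isfinite(t_stat),
                 stats.t.sf(t_stat, np.maximum(df_comb, 1.0)), np.nan)
    p[missing] = np.nan
    # median (geometric-mean) back-transform: the PFC of a map against
    # itself is then identically 1 and mode inversion is exact
    pfc = np.exp(mu_comb)
    pfc_sd = pfc * np.sqrt(np.expm1(sig2_comb))
    pfc[missing] = np.nan
    pfc_sd[missing] = np.nan
    return PFCMap(times=times, pfc=pfc, pfc_sd=pfc_sd, p=p, mode=mode)


def combined_pvalue(p_list) -> float:
    """Combine independent p values via the product-of-uniforms rule.

    With ``k`` the product of the n individual p values, the combined value
    is ``k * sum_{i=0}^{n-1} (-ln k)^i / i!`` — the probability that a
    product of n independent uniforms falls below k.
    """
    p = np.asarray(p_list, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_list must be a nonempty 1-D sequence")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    if np.any(p == 0):
        return 0.0
    log_k = float(np.sum(np.log(p)))
    n = p.size
    # sum in log space for numerical safety at very small k
    terms = [log_k + i * math.log(-log_k) - math.lgamma(i + 1)
             for i in range(n)] if log_k < 0 else [0.0]
    if log_k == 0.0:
        return 1.0
    m = max(terms)
    return float(min(1.0, math.exp(m) * sum(math.exp(t - m) for t in terms)))


def pfc_alpha_screen(alpha_perturbed_cells, alpha_ctrl_cells,
                     alpha_level: float = 0.05) -> dict:
    """Screen statistic for the FRET-fraction fold change across replicates.

    Inputs are per-replicate arrays of per-cell (median) alpha values under
    perturbation and control.  Per replicate the fold change is the ratio
    of medians and a two-sided Kolmogorov-Smirnov test compares the two
    single-cell distributions.  If the KS test is significant in more than
    half of the replicates the aggregate fold change is the mean over the
    significant replicates; otherwise it is set to 1 (no effect).
    """
    if len(alpha_perturbed_cells) != len(alpha_ctrl_cells):
        raise ValueError("need paired perturbed/control replicates")
    if len(alpha_perturbed_cells) < 2:
        raise ValueError("need at least 2 replicate experiments")
    per_rep = []
    for i, (ap, ac) in enumerate(zip(alpha_perturbed_cells, alpha_ctrl_cells)):
        ap = np.asarray(ap, dtype=float)
        ac = np.asarray(ac, dtype=float)
        if ap.size == 0 or ac.size == 0:
            warnings.warn(f"replicate {i} empty; skipped", stacklevel=2)
            continue
        med_c = np.median(ac)
        if med_c == 0:
            warnings.warn(f"replicate {i} has zero control median; skipped",
                          stacklevel=2)
            continue
        pfc = float(np.median(ap) / med_c)
        ks = stats.ks_2samp(ap, ac)
        per_rep.append({"pfc": pfc, "p": float(ks.pvalue),
                        "significant": ks.pvalue < alpha_level})
    if not per_rep:
        raise ValueError("no usable replicates")
    n_sig = sum(r["significant"] for r in per_rep)
    gate = n_sig > len(per_rep) / 2
    if gate:
        value = float(np.mean([r["pfc"] for r in per_rep if r["significant"]]))
    else:
        value = 1.0
    return {"pfc_alpha": value, "gate_passed": gate,
            "n_significant": n_sig, "n_replicates": len(per_rep),
            "per_replicate": per_rep}


def saturation_gate(ptpx_levels, k_ratio: float, f_ctr: float,
                    min_relative_sensitivity: float = 0.2) -> np.ndarray:
    """Keep cells whose PTP expression leaves the response sensitive.

    The predicted response sensitivity |df/d(level)| of the saturation
    curve, relative to its zero-expression value, is ``(f(level)/f_ctr)^2``.
    Cells below ``min_relative_sensitivity`` (default 20%) are in the
    saturated regime and excluded from STM averaging.
    """
    levels = np.asarray(ptpx_levels, dtype=float)
    f = np.asarray(saturation_curve(levels, k_ratio, f_ctr), dtype=float)
    rel_sens = (f / f_ctr) ** 2
    return rel_sens >= min_relative_sensitivity
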
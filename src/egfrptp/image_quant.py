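"""Per-cell scalar quantification from microscopy images and tables.

Covers the mask bookkeeping (Otsu cytoplasm/plasma-membrane split),
reporter-translocation read-outs of receptor phosphorylation, series
normalisation, pixelwise fluorescence anisotropy, the antibody dye:protein
labelling ratio, and AUC-based dose-response comparisons.  Segmentation
itself is out of scope: cell and nucleus masks are inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

__all__ = [
    "TranslocationQuantities",
    "AnisotropyFrame",
    "DoseResponseCurve",
    "cytoplasm_and_pm_masks",
    "ptb_translocation",
    "normalize_series",
    "anisotropy_map",
    "dye_protein_ratio",
    "trapezoid_auc",
    "compare_dose_response_auc",
    "read_image_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
]


def read_image_tiff(path) -> np.ndarray:
    """Read a (multi-page) TIFF image as a float array."""
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def write_mask_tiff(path, mask) -> None:
    """Write a boolean mask as an 8-bit TIFF (255 inside, 0 outside)."""
    import tifffile

    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    """Read an 8-bit mask TIFF back into a boolean array."""
    import tifffile

    return np.asarray(tifffile.imread(path)) > 0


@dataclass(frozen=True)
class TranslocationQuantities:
    """Summed fluorescence of the PTB reporter and the receptor per cell."""

    ptb_pm: float
    ptb_total: float
    egfr_pm: float
    egfr_total: float
    ptb_endo: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.ptb_pm, self.ptb_total, self.egfr_pm, self.egfr_total,
                self.ptb_endo)
        if any(v < 0 for v in vals):
            raise ValueError("fluorescence sums must be >= 0")
        if self.ptb_pm > self.ptb_total or self.ptb_endo > self.ptb_total:
            raise ValueError("PM/endosomal PTB cannot exceed total PTB")
        if self.egfr_pm > self.egfr_total:
            raise ValueError("PM EGFR cannot exceed total EGFR")


@dataclass
class AnisotropyFrame:
    """Parallel/perpendicular polarisation images with per-pixel G factor."""

    parallel: np.ndarray
    perpendicular: np.ndarray
    g_factor: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.parallel = np.asarray(self.parallel, dtype=float)
        self.perpendicular = np.asarray(self.perpendicular, dtype=float)
        if self.parallel.shape != self.perpendicular.shape:
            raise ValueError("polarisation images must have equal shape")
        if np.any(np.asarray(self.g_factor) <= 0):
            raise ValueError("G factor must be > 0")


@dataclass
class DoseResponseCurve:
    """Per-cell paired liganded/phosphorylated fractions over a dose grid.

    ``liganded`` and ``pegfr`` are the normalised fractions (both in [0, 1]
    with min 0 and max 1 attained when built from raw series);
    ``doses_ng_ml`` records the administered dose grid when known.
    ``normalized`` tracks whether series normalisation was applied.
    """

    liganded: np.ndarray
    pegfr: np.ndarray
    doses_ng_ml: np.ndarray | None = None
    cell_id: str | int | None = None
    normalized: bool = True

    def __post_init__(self) -> None:
        self.liganded = np.asarray(self.liganded, dtype=float)
        self.pegfr = np.asarray(self.pegfr, dtype=float)
        if self.liganded.shape != self.pegfr.shape:
            raise ValueError("liganded and pegfr must have equal length")
        if self.doses_ng_ml is not None:
            self.doses_ng_ml = np.asarray(self.doses_ng_ml, dtype=float)

    @classmethod
    def from_raw(cls, ptb_egfr_series, egf_egfr_series, doses_ng_ml=None,
                 cell_id=None) -> "DoseResponseCurve":
        """Build from raw translocation and ligand-binding series.

        Both series are normalised between their initial (unstimulated) and
        maximal values, yielding the phosphorylated fraction and the
        liganded fraction respectively.
        """
        pegfr = normalize_series(ptb_egfr_series)
        liganded = normalize_series(egf_egfr_series)
        return cls(liganded=liganded, pegfr=pegfr, doses_ng_ml=doses_ng_ml,
                   cell_id=cell_id, normalized=True)

    def auc(self) -> float:
        """Trapezoidal AUC of pEGFR vs liganded fraction."""
        order = np.argsort(self.liganded)
        x = self.liganded[order]
        y = self.pegfr[order]
        keep = np.concatenate([[True], np.diff(x) > 0])
        return trapezoid_auc(x[keep], y[keep])


def cytoplasm_and_pm_masks(cell_mask, marker_image
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Split a cell mask into cytoplasm and plasma-membrane regions.

    The cytoplasm is the part of the cell where a cytosolic marker exceeds
    its Otsu threshold (computed inside the cell only); the plasma-membrane
    region is the remainder of the cell mask.  The masks are disjoint and
    their union is the cell.  A unimodal marker yields a threshold anyway
    (with a warning); a uniform marker gives an empty PM region, flagged.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    marker = np.asarray(marker_image, dtype=float)
    if not cell.any():
        raise ValueError("cell mask is empty")
    inside = marker[cell]
    if np.ptp(inside) == 0:
        warnings.warn("uniform marker inside cell; PM mask will be empty",
                      stacklevel=2)
        cytoplasm = cell.copy()
        pm = np.zeros_like(cell)
        return cytoplasm, pm
    thr = threshold_otsu(inside)
    counts = np.concatenate([[0], np.histogram(inside, bins=64)[0], [0]])
    # crude unimodality flag: a single dominant mode around the threshold
    peaks = np.sum((counts[1:-1] > counts[:-2]) & (counts[1:-1] >= counts[2:])
                   & (counts[1:-1] > 0.05 * counts.max()))
    if peaks < 2:
        warnings.warn("marker histogram looks unimodal; Otsu threshold "
                      "applied regardless", stacklevel=2)
    cytoplasm = cell & (marker > thr)
    pm = cell & ~cytoplasm
    return cytoplasm, pm


def ptb_translocation(q: TranslocationQuantities,
                      endo_corrected: bool = False) -> float:
    """Receptor phosphorylation read-out from PTB reporter translocation.

    The fraction of reporter at the plasma membrane is normalised by the
    fraction of receptor there::

        (ptb_pm / ptb_total) / (egfr_pm / egfr_total)

    With ``endo_corrected`` the reporter already sequestered on endosomes is
    removed from the total (it is bound to phosphorylated receptor that has
    left the membrane): the denominator total becomes
    ``ptb_total - ptb_endo``.
    """
    ptb_denom = q.ptb_total - q.ptb_endo if endo_corrected else q.ptb_total
    if ptb_denom <= 0:
        raise ValueError("PTB total (after endosome correction) must be > 0")
    if q.egfr_pm <= 0 or q.egfr_total <= 0:
        raise ValueError("EGFR sums must be > 0")
    return (q.ptb_pm / ptb_denom) / (q.egfr_pm / q.egfr_total)


def normalize_series(raw):
    """Normalise a response series between its initial and maximal value.

    ``(x_k - x_0) / (max_i x_i - x_0)``: the first element maps to 0 and the
    maximal element to 1.  A series whose maximum equals its first element
    has no dynamic range and is rejected.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with at least 2 points")
    span = x.max() - x[0]
    if span <= 0:
        raise ValueError("no dynamic range: series max must exceed its "
                         "first element")
    return (x - x[0]) / span


def anisotropy_map(frame: AnisotropyFrame) -> np.ndarray:
    """Pixelwise fluorescence anisotropy r = (G*I_par - I_perp)/(G*I_par + 2*I_perp).

    Inputs are expected background-subtracted.  Pixels with nonpositive
    total intensity are masked (NaN).
    """
    G = np.asarray(frame.g_factor, dtype=float)
    num = G * frame.parallel - frame.perpendicular
    den = G * frame.parallel + 2.0 * frame.perpendicular
    r = np.full(frame.parallel.shape, np.nan)
    ok = den > 0
    r[ok] = num[ok] / den[ok]
    return r


def dye_protein_ratio(a581: float, a280: float) -> tuple[float, bool]:
    """Dye:protein labelling ratio of the Cy3.5-labelled antibody.

    ``(A581 * 1.7) / ((A280 - 0.24 * A581) * 1.5)`` from the absorbances at
    581 nm (dye) and 280 nm (protein, corrected for dye absorbance).
    Returns the ratio and whether it falls in the usable window [3, 5].
    """
    if a581 < 0 or a280 < 0:
        raise ValueError("absorbances must be >= 0")
    denom = (a280 - 0.24 * a581) * 1.5
    if denom <= 0:
        raise ValueError("protein absorbance too low: denominator <= 0")
    ratio = (a581 * 1.7) / denom
    return ratio, 3.0 <= ratio <= 5.0


def trapezoid_auc(x, y) -> float:
    """Trapezoidal area under a curve sampled at increasing x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    return float(np.trapezoid(y, x))


def compare_dose_response_auc(curves_a, curves_b
                              ) -> dict[str, float]:
    """Compare two groups of dose-response curves by per-cell AUC.

    Each curve is a ``(x, y)`` pair on normalised axes.  Curves on
    mismatched grids are linearly resampled to the common overlap (with a
    warning).  Returns group means and the two-sample t-test p value.
    """
    def collect(curves):
        return [(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
                for x, y in curves]

    ca, cb = collect(curves_a), collect(curves_b)
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("need at least 2 curves per group")
    grids = [tuple(x) for x, _ in ca + cb]
    if len(set(grids)) > 1:
        warnings.warn("mismatched dose grids; resampling to common grid",
                      stacklevel=2)
        lo = max(x[0] for x, _ in ca + cb)
        hi = min(x[-1] for x, _ in ca + cb)
        common = np.linspace(lo, hi, 50)
        ca = [(common, np.interp(common, x, y)) for x, y in ca]
        cb = [(common, np.interp(common, x, y)) for x, y in cb]
    auc_a = np.array([trapezoid_auc(x, y) for x, y in ca])
    auc_b = np.array([trapezoid_auc(x, y) for x, y in cb])
    t, p = stats.ttest_ind(auc_a, auc_b)
    return {"mean_a": float(auc_a.mean()), "mean_b": float(auc_b.mean()),
            "t": float(t), "p": float(p),
            "auc_a": auc_a, "auc_b": auc_b}
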
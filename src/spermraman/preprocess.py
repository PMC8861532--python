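"""Per-cell spectral preprocessing.

Raw scans become one analysis-ready spectrum per cell through a fixed
stage order:

    resample -> Savitzky-Golay smooth -> baseline subtract -> denoise
             -> average scans -> crop

Defaults follow common practice for dispersive Raman on glass slides:
an 11-point, degree-5 Savitzky-Golay smoother, asymmetric-least-squares
(ALS) background subtraction, a gentler second Savitzky-Golay pass as the
denoising step, per-scan processing followed by averaging of the 15
accumulated scans, and cropping to the 650-1800 cm^-1 fingerprint window
used for all statistics.  Each stage is also exposed on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal
from scipy.linalg import solve_banded

from .spectra_io import CellRecord, LabelTable, RamanSpectrum, ScanSet

__all__ = [
    "PreprocessParams",
    "savgol_smooth",
    "subtract_baseline",
    "als_baseline",
    "poly_baseline",
    "denoise",
    "average_scans",
    "crop",
    "resample",
    "preprocess_scanset",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Knobs of the preprocessing chain.

    sg_window, sg_degree
        Savitzky-Golay smoothing window (odd point count) and polynomial
        degree; defaults 11 and 5.
    baseline_method, baseline_params
        ``als`` (default; lam=1e5, p=0.01, n_iter=10) or ``poly``
        (iterative polynomial fit rejecting points above fit + k*sigma).
    crop_lo, crop_hi
        Analysis window in cm^-1; defaults 650 and 1800.
    resample_step
        Uniform grid step in cm^-1, or None to require an already-uniform
        grid; default 1.0.
    denoise_window, denoise_degree, denoise_enabled
        The gentler second smoothing pass; defaults 7, 3, on.
    average_first
        If True, scans are averaged before smoothing/baseline instead of
        after (both orders are defensible; per-scan is the default).
    """

    sg_window: int = 11
    sg_degree: int = 5
    baseline_method: str = "als"
    baseline_params: Mapping[str, float] | None = None
    crop_lo: float = 650.0
    crop_hi: float = 1800.0
    resample_step: float | None = 1.0
    denoise_window: int = 7
    denoise_degree: int = 3
    denoise_enabled: bool = True
    average_first: bool = False

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_degree:
            raise ValueError("sg_window must be odd and > sg_degree")
        if self.denoise_window % 2 == 0 or self.denoise_window <= self.denoise_degree:
            raise ValueError("denoise_window must be odd and > denoise_degree")
        if not self.crop_lo < self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")
        if self.resample_step is not None and self.resample_step <= 0:
            raise ValueError("resample_step must be > 0")
        if self.baseline_method not in ("als", "poly"):
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")


def _require_uniform(s: RamanSpectrum, what: str) -> None:
    d = np.diff(s.wavenumbers)
    if d.size and not np.allclose(d, d[0], rtol=1e-8, atol=1e-8 * abs(d[0])):
        raise ValueError(
            f"{what} requires a uniform wavenumber grid; resample first"
        )


def savgol_smooth(s: RamanSpectrum, window: int = 11, degree: int = 5) -> RamanSpectrum:
    """Savitzky-Golay smoothing: local least-squares polynomial fit.

    The filter reproduces any polynomial of degree <= `degree` exactly at
    interior points.  Edges are handled by fitting a polynomial to the
    one-sided truncated window at each end and evaluating it there (no
    reflection padding, so no data are invented beyond the grid).
    """
    if window <= degree:
        raise ValueError("window must exceed polynomial degree")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(s):
        raise ValueError("window longer than spectrum")
    _require_uniform(s, "Savitzky-Golay smoothing")
    out = signal.savgol_filter(s.intensities, window, degree, mode="interp")
    return s.with_intensities(out)


try:  # optional fast path; the scipy banded solver is the reference
    from ._als_fast import als_batch as _als_batch_numba
except Exception:  # pragma: no cover - numba missing or broken
    _als_batch_numba = None


def als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                 n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline (Eilers-Boelens).

    Minimizes ``sum(w_i (y_i - z_i)^2) + lam * sum((D2 z)_i^2)`` with
    asymmetric weights ``w_i = p`` above the baseline and ``1 - p`` below,
    iterated `n_iter` times.  The pentadiagonal system is solved in banded
    form, so one pass is O(n).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        return y.copy()
    # lam * D2^T D2 in LAPACK banded form (bandwidth 2); D2 = second difference
    diag = np.full(n, 6.0)
    diag[[0, -1]] = 1.0
    diag[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.ones(n - 2)
    ab0 = np.zeros((5, n))
    ab0[0, 2:] = lam * off2
    ab0[1, 1:] = lam * off1
    ab0[2, :] = lam * diag
    ab0[3, :-1] = lam * off1
    ab0[4, :-2] = lam * off2
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        ab = ab0.copy()
        ab[2, :] += w
        z = solve_banded((2, 2), ab, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def poly_baseline(y: np.ndarray, x: np.ndarray, degree: int = 5,
                  k_sigma: float = 3.0, n_iter: int = 20) -> np.ndarray:
    """Iterative polynomial baseline.

    Fits a degree-`degree` polynomial, excludes points more than
    ``k_sigma`` residual standard deviations *above* the fit (peaks), and
    refits until the inlier set stabilizes.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = np.ones(y.size, dtype=bool)
    coef = np.polyfit(x, y, degree)
    for _ in range(n_iter):
        coef = np.polyfit(x[keep], y[keep], degree)
        fit = np.polyval(coef, x)
        resid = y - fit
        sigma = resid[keep].std()
        new_keep = resid <= k_sigma * sigma
        if new_keep.sum() <= degree + 1 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return np.polyval(coef, x)


def subtract_baseline(s: RamanSpectrum, method: str = "als",
                      params: Mapping[str, float] | None = None) -> RamanSpectrum:
    """Estimate and subtract the slowly-varying background.

    ``als`` follows the lower envelope of the spectrum (fluorescence and
    glass); ``poly`` fits a global polynomial while iteratively ignoring
    peak channels.
    """
    params = dict(params or {})
    if method == "als":
        base = als_baseline(s.intensities, **params)
    elif method == "poly":
        base = poly_baseline(s.intensities, s.wavenumbers, **params)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return s.with_intensities(s.intensities - base)


def denoise(s: RamanSpectrum, window: int = 7, degree: int = 3,
            enabled: bool = True) -> RamanSpectrum:
    """A second, gentler Savitzky-Golay pass; identity when disabled."""
    if not enabled:
        return s
    return savgol_smooth(s, window=window, degree=degree)


def average_scans(scans: ScanSet) -> RamanSpectrum:
    """Pointwise arithmetic mean over a cell's scans; scan_index cleared."""
    stack = np.stack([s.intensities for s in scans.scans])
    return RamanSpectrum(scans.wavenumbers, stack.mean(axis=0),
                         cell_id=scans.cell_id, scan_index=None)


def crop(s: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Retain channels with lo <= wavenumber <= hi."""
    if not lo < hi:
        raise ValueError("crop needs lo < hi")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(
            f"crop to [{lo}, {hi}] cm^-1 leaves no channels of grid "
            f"[{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}]"
        )
    return RamanSpectrum(s.wavenumbers[mask], s.intensities[mask],
                         cell_id=s.cell_id, scan_index=s.scan_index)


def resample(s: RamanSpectrum, step: float) -> RamanSpectrum:
    """Linear interpolation onto a uniform grid; never extrapolates.

    The new grid runs from ``ceil(min)`` to ``floor(max)`` of the original
    grid in steps of `step`.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if len(s) < 2:
        raise ValueError("resampling needs at least 2 channels")
    lo = np.ceil(s.wavenumbers[0])
    n = int(np.floor((np.floor(s.wavenumbers[-1]) - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    out = np.interp(grid, s.wavenumbers, s.intensities)
    return RamanSpectrum(grid, out, cell_id=s.cell_id, scan_index=s.scan_index)


def _is_uniform(wn: np.ndarray) -> bool:
    d = np.diff(wn)
    return bool(d.size == 0 or np.allclose(d, d[0], rtol=1e-8, atol=1e-8 * abs(d[0])))


def _process_block(wn: np.ndarray, block: np.ndarray, p: PreprocessParams) -> np.ndarray:
    """The per-scan chain (smooth, baseline, denoise) on a scans x channels array."""
    block = signal.savgol_filter(block, p.sg_window, p.sg_degree,
                                 axis=-1, mode="interp")
    bp = dict(p.baseline_params or {})
    if p.baseline_method == "als":
        if _als_batch_numba is not None and block.shape[-1] >= 4:
            base = _als_batch_numba(
                np.ascontiguousarray(block, dtype=float),
                float(bp.get("lam", 1e5)), float(bp.get("p", 0.01)),
                int(bp.get("n_iter", 10)),
            )
        else:
            base = np.stack([als_baseline(row, **bp) for row in block])
    else:
        base = np.stack([poly_baseline(row, wn, **bp) for row in block])
    block = block - base
    if p.denoise_enabled:
        block = signal.savgol_filter(block, p.denoise_window, p.denoise_degree,
                                     axis=-1, mode="interp")
    return block


def preprocess_scanset(scans: ScanSet, params: PreprocessParams | None = None) -> RamanSpectrum:
    """Full chain for one cell: per-scan processing, averaging, cropping.

    With ``params.average_first`` the scans are averaged before smoothing
    and baseline subtraction; the stage order is otherwise fixed:
    resample -> smooth -> baseline -> denoise -> average -> crop.
    """
    p = params or PreprocessParams()
    members = scans.scans
    if p.resample_step is not None and not _is_uniform(scans.wavenumbers):
        members = tuple(resample(s, p.resample_step) for s in members)
    wn = members[0].wavenumbers
    _require_uniform(members[0], "preprocessing")
    block = np.stack([s.intensities for s in members])
    if p.average_first:
        block = block.mean(axis=0, keepdims=True)
    block = _process_block(wn, block, p)
    out = RamanSpectrum(wn, block.mean(axis=0), cell_id=scans.cell_id,
                        scan_index=None)
    return crop(out, p.crop_lo, p.crop_hi)


def preprocess_cohort(scan_sets: Sequence[ScanSet], labels: LabelTable | None = None,
                      params: PreprocessParams | None = None) -> list[CellRecord]:
    """Preprocess every cell and attach labels (``unknown`` if absent)."""
    labels = labels or LabelTable({})
    out = []
    for ss in scan_sets:
        spec = preprocess_scanset(ss, params)
        out.append(CellRecord(cell_id=ss.cell_id, spectrum=spec,
                              label=labels.get(ss.cell_id)))
    return out
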
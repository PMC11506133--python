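"""Scanline flattening and substrate-baseline estimation.

The instrument data this pipeline models were "only subjected to a
flattening procedure" before height analysis; we mirror that: a per-scanline
polynomial (default order 1) is fitted to non-object pixels, refined by
iterative object masking, and subtracted.  All heights downstream are
referenced to the bare-substrate baseline.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import HeightMap

MIN_ROW_PIXELS = 8
#: object pixels are also flagged against a robust global plane at this level
OBJECT_ROW_THRESHOLD_NM = 3.0


class BaselineError(ValueError):
    """Raised when there is not enough bare substrate to reference heights."""


@dataclasses.dataclass
class FlattenReport:
    row_offsets_nm: np.ndarray  # fitted value at the row centre, per row
    tilt_per_row: np.ndarray  # fitted slope (nm per pixel), per row; 0 for order 0
    masked_fraction: float
    iterations: int
    fallback_rows: list[int]  # rows fitted globally (starved or object-dominated)


def _robust_plane(heights: np.ndarray, threshold_nm: float, iters: int = 3):
    """Iteratively-masked least-squares plane; robust to sub-50% coverage."""
    rows, cols = heights.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    A = np.stack([np.ones(heights.size), xx.ravel(), yy.ravel()], axis=1)
    keep = np.ones(heights.size, dtype=bool)
    coef = np.zeros(3)
    for _ in range(iters):
        coef, *_ = np.linalg.lstsq(A[keep], heights.ravel()[keep], rcond=None)
        resid = heights.ravel() - A @ coef
        keep = resid <= threshold_nm
        if keep.sum() < 16:
            keep = np.ones(heights.size, dtype=bool)
            break
    return (A @ coef).reshape(heights.shape)


def _fit_rows(
    heights: np.ndarray,
    mask: np.ndarray,
    order: int,
    offset_rows: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Per-row polynomial fit to unmasked pixels.

    Rows with fewer than 8 unmasked pixels fall back to the global fit;
    their indices are returned.  A starved row flagged in ``offset_rows``
    (its median is consistent with a scanline offset, not an object) still
    gets a robust per-row offset so the stripe does not survive.
    """
    rows, cols = heights.shape
    x = np.arange(cols, dtype=float)
    xc = x - x.mean()
    fit = np.zeros_like(heights)
    fallback: list[int] = []
    gsel = ~mask
    if gsel.sum() >= order + 1:
        xg = np.tile(xc, (rows, 1))[gsel]
        gcoef = np.polynomial.polynomial.polyfit(xg, heights[gsel], order)
    else:
        gcoef = np.zeros(order + 1)
    gfit = np.polynomial.polynomial.polyval(xc, gcoef)
    for r in range(rows):
        sel = ~mask[r]
        if sel.sum() < max(MIN_ROW_PIXELS, order + 1):
            if sel.sum() >= 3:
                fit[r] = gfit + np.median(heights[r, sel] - gfit[sel])
            elif offset_rows is not None and offset_rows[r]:
                fit[r] = gfit + np.median(heights[r] - gfit)
            else:
                fit[r] = gfit
            fallback.append(r)
            continue
        coef = np.polynomial.polynomial.polyfit(xc[sel], heights[r, sel], order)
        fit[r] = np.polynomial.polynomial.polyval(xc, coef)
    return fit, fallback


def flatten(
    hm: HeightMap,
    order: int = 1,
    iterations: int = 2,
    mask_threshold_nm: float = 1.0,
) -> tuple[HeightMap, FlattenReport]:
    """Per-scanline polynomial flattening with iterative object masking.

    A polynomial of the given order is fitted to each scanline's non-object
    pixels and subtracted.  The object mask is refined ``iterations`` times:
    pixels more than ``mask_threshold_nm`` above the current fit are masked
    and the fit repeated.  A robust global plane additionally masks tall
    objects that per-row fits cannot see (e.g. a fibril lying along a
    scanline); rows that are object-dominated or keep fewer than 8 unmasked
    pixels fall back to the global fit and are recorded in the report.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be in {0, 1, 2}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    h = hm.heights
    gthr = max(mask_threshold_nm, OBJECT_ROW_THRESHOLD_NM)
    mask = (h - _robust_plane(h, mask_threshold_nm)) > gthr
    fit, fallback = _fit_rows(h, mask, order)
    used = 0
    for it in range(max(iterations, 8)):
        # re-reference the object mask against the current background
        # estimate (fit plus a robust plane of the residual): this view is
        # invariant to offsets and tilt, which makes a second flatten pass a
        # near no-op and lets fibrils lying along a scanline be masked
        resid = h - fit
        background = _robust_plane(resid, mask_threshold_nm)
        dev = resid - background
        row_med = np.median(dev, axis=1)
        scale = 1.4826 * float(np.median(np.abs(row_med - np.median(row_med))))
        offset_rows = row_med <= max(OBJECT_ROW_THRESHOLD_NM, 5.0 * scale)
        new_mask = dev > mask_threshold_nm
        converged = bool((new_mask == mask).all())
        mask = new_mask
        fit, fallback = _fit_rows(h, mask, order, offset_rows)
        used = it + 1
        if used >= iterations and converged:
            break
    flat = h - fit
    # re-centre so the unmasked median is exactly zero
    resid_med = float(np.median(flat[~mask])) if (~mask).any() else 0.0
    flat = flat - resid_med
    x = np.arange(h.shape[1], dtype=float)
    xc = x - x.mean()
    slope = (
        (fit[:, -1] - fit[:, 0]) / (xc[-1] - xc[0])
        if order >= 1
        else np.zeros(h.shape[0])
    )
    report = FlattenReport(
        row_offsets_nm=fit.mean(axis=1) + resid_med,
        tilt_per_row=np.asarray(slope),
        masked_fraction=float(mask.mean()),
        iterations=used,
        fallback_rows=fallback,
    )
    return hm.copy_with(flat), report


def object_mask(hm: HeightMap, threshold_nm: float = 1.0) -> np.ndarray:
    """Boolean mask of pixels considered object rather than substrate."""
    return hm.heights > threshold_nm


def substrate_baseline(hm: HeightMap, mask: np.ndarray | None = None) -> float:
    """Robust (median) substrate level of a flattened map, in nm.

    All object heights downstream are reported relative to this level.
    Requires at least 5% of pixels to be bare substrate.
    """
    if mask is None:
        mask = object_mask(hm)
    mask = np.asarray(mask, dtype=bool)
    free = ~mask
    if free.mean() < 0.05:
        raise BaselineError(
            "less than 5% bare substrate: use a larger field or lower coverage"
        )
    return float(np.median(hm.heights[free]))
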
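"""Spatial normalization of doubling times using reference colonies.

Nonevolving wild-type control colonies occupy the (even row, even col)
member of every 2x2 position quartet.  Their doubling times sample the
plate's environmental field; interpolating log2 D over the reference grid
yields a correction surface that maps every position onto the scale of the
plate-set reference median, removing both within-plate gradients and
between-plate offsets.  Corrections are multiplicative on D (additive in
log2 hours), matching the multiplicative character of environmental growth
effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError


def reference_mask(n_rows: int, n_cols: int) -> np.ndarray:
    """Boolean mask of reference positions: (even row, even col)."""
    r = np.arange(n_rows)[:, None]
    c = np.arange(n_cols)[None, :]
    return (r % 2 == 0) & (c % 2 == 0)


@dataclass
class ReferenceSurface:
    """Per-position multiplicative correction on doubling time.

    ``offsets_log2`` holds, for every plate position, the interpolated
    reference surface minus the log2 plate-set reference median; subtracting
    it from a position's log2 D expresses that D on the common scale.
    """

    offsets_log2: np.ndarray      # (n_rows, n_cols)
    reference_median_h: float     # plate-set reference median, hours

    def correct_log2(self, log2_d: np.ndarray) -> np.ndarray:
        return log2_d - self.offsets_log2

    def correct(self, d_hours: np.ndarray) -> np.ndarray:
        return np.asarray(d_hours) / np.exp2(self.offsets_log2)


def _impute_missing_references(ref_rows: np.ndarray, ref_cols: np.ndarray,
                               grid: np.ndarray) -> np.ndarray:
    """Fill NaN entries of the reference grid from the 4 nearest usable refs."""
    out = grid.copy()
    bad = np.argwhere(np.isnan(grid))
    good = np.argwhere(~np.isnan(grid))
    if len(good) == 0:
        raise NormalizationError("no usable reference colonies on plate")
    gr = ref_rows[good[:, 0]].astype(float)
    gc = ref_cols[good[:, 1]].astype(float)
    for (i, j) in bad:
        d2 = (gr - ref_rows[i]) ** 2 + (gc - ref_cols[j]) ** 2
        nearest = np.argsort(d2, kind="stable")[:4]
        out[i, j] = grid[good[nearest, 0], good[nearest, 1]].mean()
    return out


def fit_reference_surface(d_hours: np.ndarray,
                          reference_median_h: float | None = None
                          ) -> ReferenceSurface:
    """Fit the correction surface for one plate.

    Parameters
    ----------
    d_hours : (n_rows, n_cols) array
        Doubling times in hours; NaN anywhere a position is not a usable
        reference or holds no estimate.  Only reference positions (even row,
        even col) are consulted.
    reference_median_h
        The plate-set reference median (hours).  When normalizing a single
        plate it defaults to that plate's own reference median; when
        normalizing a set of plates pass the pooled median so plates share a
        scale.

    The surface is the bilinear interpolation of log2 reference D over the
    reference grid, with positions beyond the outermost references clamped
    to the edge of the grid (nearest-reference extrapolation) and missing
    references imputed from their 4 nearest usable neighbours.
    """
    d = np.asarray(d_hours, dtype=float)
    n_rows, n_cols = d.shape
    ref_rows = np.arange(0, n_rows, 2)
    ref_cols = np.arange(0, n_cols, 2)
    ref_grid = np.log2(d[np.ix_(ref_rows, ref_cols)])
    usable = np.isfinite(ref_grid)
    if usable.sum() < 4:
        raise NormalizationError(
            f"only {int(usable.sum())} usable reference colonies; need >= 4")
    ref_grid = np.where(usable, ref_grid, np.nan)
    if not usable.all():
        ref_grid = _impute_missing_references(ref_rows, ref_cols, ref_grid)
    if reference_median_h is None:
        reference_median_h = float(
            np.exp2(np.median(ref_grid[usable])))

    from scipy.interpolate import RegularGridInterpolator
    interp = RegularGridInterpolator((ref_rows.astype(float),
                                      ref_cols.astype(float)), ref_grid,
                                     method="linear")
    rr = np.clip(np.arange(n_rows, dtype=float), ref_rows[0], ref_rows[-1])
    cc = np.clip(np.arange(n_cols, dtype=float), ref_cols[0], ref_cols[-1])
    pts = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1).reshape(-1, 2)
    surface = interp(pts).reshape(n_rows, n_cols)
    offsets = surface - np.log2(reference_median_h)
    return ReferenceSurface(offsets_log2=offsets,
                            reference_median_h=float(reference_median_h))


def normalize_plate(d_hours: np.ndarray, surface: ReferenceSurface) -> np.ndarray:
    """Apply a fitted surface to a plate of doubling times (hours in, hours out)."""
    return surface.correct(np.asarray(d_hours, dtype=float))


def normalize_plate_set(plates: dict, reference_median_h: float | None = None
                        ) -> tuple[dict, dict, float]:
    """Normalize several plates onto a shared reference scale.

    Parameters
    ----------
    plates
        Mapping plate_id -> (n_rows, n_cols) array of doubling times in
        hours (NaN where unavailable).
    reference_median_h
        Pooled reference median; computed from all plates' usable reference
        positions when omitted.

    Returns ``(normalized, surfaces, reference_median_h)``.  Plates whose
    surface cannot be fitted (fewer than 4 usable references) are omitted
    from both result mappings.
    """
    if reference_median_h is None:
        pooled = []
        for d in plates.values():
            d = np.asarray(d, dtype=float)
            mask = reference_mask(*d.shape)
            vals = d[mask]
            pooled.append(vals[np.isfinite(vals)])
        pooled = np.concatenate(pooled) if pooled else np.empty(0)
        if len(pooled) == 0:
            raise NormalizationError("no usable reference colonies in plate set")
        reference_median_h = float(np.median(pooled))
    normalized, surfaces = {}, {}
    for pid, d in plates.items():
        try:
            surf = fit_reference_surface(d, reference_median_h)
        except NormalizationError:
            continue
        surfaces[pid] = surf
        normalized[pid] = normalize_plate(d, surf)
    return normalized, surfaces, reference_median_h
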
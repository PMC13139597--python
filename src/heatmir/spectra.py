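"""Spectral pre-treatment for standardized milk FT-MIR spectra.

A standardized spectrum holds 1,060 absorbance points (1-based point numbers
1..1060) on a fixed wavenumber grid.  The preprocessing chain is:

1. gap-5 first derivative: d(i) = A(i-2) - A(i+2), valid for points 3..1058
   (1,056 derivative values);
2. fixed-region selection keeping 212 informative points
   (12-170, 210-218, 223-230, 495-530, numbered on the original grid);
3. optional correlation pre-selection: keep derivative points whose absolute
   Pearson correlation with a calibration target reaches a threshold
   (default 0.3).

Spectra collections are pandas DataFrames: one row per sample, columns are
integer original point numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "N_POINTS",
    "DEFAULT_REGIONS",
    "default_region_mask",
    "first_derivative",
    "select_regions",
    "correlation_preselect",
    "wavenumber_axis",
]

N_POINTS = 1060

#: inclusive (start, stop) original point numbers of the low-noise regions
DEFAULT_REGIONS = ((12, 170), (210, 218), (223, 230), (495, 530))

# wavenumber anchors of the first region: point 12 -> 968.09 cm-1,
# point 170 -> 1577.49 cm-1
_WN_ANCHOR_POINT = 12
_WN_ANCHOR_CM1 = 968.09
_WN_STEP_CM1 = (1577.49 - 968.09) / 158.0


def default_region_mask() -> np.ndarray:
    """The 212 original point numbers retained after derivative filtering."""
    pts = np.concatenate([np.arange(a, b + 1) for a, b in DEFAULT_REGIONS])
    return pts


def first_derivative(spectra, gap: int = 5):
    """Gap first derivative of 1,060-point spectra.

    For the default gap of 5 the derivative at point i is
    ``A(i-2) - A(i+2)`` (subtracting the absorbance two points to the right
    from the absorbance two points to the left), defined for points
    ``3..1058`` -> 1,056 values.

    Parameters
    ----------
    spectra
        DataFrame (samples x 1060), 2-D array, or 1-D array of length 1060.
    gap
        Odd integer >= 3; the half-offset is ``(gap - 1) // 2``.

    Returns
    -------
    Same container type as the input, columns labelled with the original
    point numbers of the derivative grid.
    """
    if gap < 3 or gap % 2 == 0:
        raise ValueError(f"gap must be an odd integer >= 3, got {gap}")
    h = (gap - 1) // 2

    if isinstance(spectra, pd.DataFrame):
        vals = spectra.to_numpy(dtype=float)
        if vals.shape[1] != N_POINTS:
            raise ValueError(
                f"expected {N_POINTS} spectral points, got {vals.shape[1]}"
            )
        d = vals[:, : N_POINTS - 2 * h] - vals[:, 2 * h:]
        cols = np.arange(1 + h, N_POINTS - h + 1)
        return pd.DataFrame(d, index=spectra.index, columns=cols)

    arr = np.asarray(spectra, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if arr.shape[1] != N_POINTS:
        raise ValueError(f"expected {N_POINTS} spectral points, got {arr.shape[1]}")
    d = arr[:, : N_POINTS - 2 * h] - arr[:, 2 * h:]
    return d[0] if squeeze else d


def select_regions(deriv: pd.DataFrame, mask=None) -> pd.DataFrame:
    """Keep derivative values at the masked original point numbers.

    ``mask`` defaults to the 212-point low-noise mask.  Points outside the
    derivative grid raise ``ValueError``.
    """
    if mask is None:
        mask = default_region_mask()
    mask = np.asarray(mask, dtype=int)
    if np.any(np.diff(mask) <= 0):
        raise ValueError("region mask point numbers must be strictly increasing")
    valid = set(int(c) for c in deriv.columns)
    outside = [int(p) for p in mask if int(p) not in valid]
    if outside:
        raise ValueError(
            f"mask point(s) outside the derivative grid: {outside[:5]}"
        )
    return deriv.loc[:, list(mask)]


def correlation_preselect(X: pd.DataFrame, y, threshold: float = 0.3):
    """Keep columns whose |Pearson r| with ``y`` reaches ``threshold``.

    Zero-variance columns (undefined correlation) are dropped.  Returns
    ``(X_selected, selected_point_numbers)`` so that prediction can reuse the
    identical column set.
    """
    if len(X) < 3:
        raise ValueError("correlation pre-selection needs at least 3 samples")
    y = np.asarray(y, dtype=float)
    if y.std() == 0.0:
        raise ValueError("target has zero variance; correlation undefined")
    vals = X.to_numpy(dtype=float)
    xm = vals - vals.mean(axis=0)
    ym = y - y.mean()
    sx = np.sqrt((xm ** 2).sum(axis=0))
    sy = np.sqrt((ym ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xm.T @ ym) / (sx * sy)
    keep = np.isfinite(r) & (np.abs(r) >= threshold)
    selected = [int(c) for c in np.asarray(X.columns)[keep]]
    return X.loc[:, np.asarray(X.columns)[keep]], selected


def wavenumber_axis(n: int = N_POINTS) -> np.ndarray:
    """Wavenumber (cm-1) label of each original point, 1..n.

    The axis is linear and anchored on the first retained region
    (point 12 -> 968.09 cm-1, point 170 -> 1577.49 cm-1); labels are for
    reporting only, point numbers remain authoritative.
    """
    points = np.arange(1, n + 1)
    return _WN_ANCHOR_CM1 + (points - _WN_ANCHOR_POINT) * _WN_STEP_CM1
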
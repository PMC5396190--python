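"""Log-linear T2 relaxometry for multi-echo spin-echo images.

The transverse relaxation time T2 is estimated from the monoexponential
signal model ``S(TE) = S0 * exp(-TE / T2)`` by ordinary least squares of
``ln S`` on echo time TE: the fitted slope is ``-1/T2`` and the intercept
back-transforms to S0.  Fits are available per pixel (:func:`t2_map`) and
per region of interest (:func:`roi_t2`).

Nonpositive intensities cannot enter the logarithm and are excluded
pointwise; a fit needs at least ``min_points`` surviving echoes (default 3,
since two points always give r^2 = 1) and a strictly negative slope to be
marked valid.  Invalid fits are flagged, never silently dropped.  No Rician
noise-floor correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_ECHO_TIMES_MS",
    "EchoStack",
    "T2Fit",
    "T2Map",
    "fit_t2_loglinear",
    "t2_map",
    "roi_t2",
]

#: Echo times (ms) of the 8-echo spin-echo protocol the pipeline targets.
DEFAULT_ECHO_TIMES_MS = (15.75, 36.75, 57.75, 78.75, 99.75, 120.75, 141.75, 162.75)

#: Minimum usable (positive-intensity) echoes for a valid fit.
MIN_FIT_POINTS = 3


@dataclass(frozen=True)
class EchoStack:
    """Multi-echo image volume: E echoes of identical (slices, rows, cols) geometry.

    Row 0 is superior and column 0 anterior throughout the package.
    """

    images: np.ndarray  # (E, slices, rows, cols)
    echo_times_ms: np.ndarray  # (E,)
    pixel_size_mm: float
    slice_spacing_mm: float

    def __post_init__(self) -> None:
        images = np.asarray(self.images, dtype=float)
        tes = np.asarray(self.echo_times_ms, dtype=float)
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "echo_times_ms", tes)
        if images.ndim != 4:
            raise ValueError(f"images must be 4-D (echo, slice, row, col), got {images.ndim}-D")
        if tes.ndim != 1 or tes.size != images.shape[0]:
            raise ValueError("echo_times_ms length must match the number of echo images")
        if tes.size < 2:
            raise ValueError("need at least 2 echoes")
        if np.any(tes <= 0) or np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.pixel_size_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("pixel size and slice spacing must be positive")

    @property
    def n_echoes(self) -> int:
        return int(self.images.shape[0])

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return tuple(self.images.shape[1:])  # type: ignore[return-value]


@dataclass
class T2Fit:
    """One monoexponential fit: T2 (ms), back-transformed S0, goodness of fit."""

    t2_ms: float
    s0: float
    r_squared: float
    n_points_used: int
    valid: bool
    slope: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.valid and not self.t2_ms > 0:
            raise ValueError("a valid fit must have t2_ms > 0")


@dataclass
class T2Map:
    """Per-pixel fits over a mask; arrays share the stack's volume geometry.

    Pixels outside the mask are NaN / invalid by construction.
    """

    t2_ms: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    n_points_used: np.ndarray
    valid: np.ndarray
    mask: np.ndarray

    @property
    def fraction_invalid(self) -> float:
        """Fraction of masked pixels whose fit is invalid."""
        n = int(self.mask.sum())
        return float((~self.valid[self.mask]).sum() / n)


def _loglinear_arrays(
    echo_times_ms: np.ndarray, intensities: np.ndarray, min_points: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of ln(intensity) on TE over the last axis.

    ``intensities`` has shape (..., E).  Nonpositive intensities are masked
    out pointwise.  Returns (slope, intercept, r_squared, n_used, valid).
    """
    te = np.asarray(echo_times_ms, dtype=float)
    y_raw = np.asarray(intensities, dtype=float)
    usable = y_raw > 0
    y = np.where(usable, np.log(np.where(usable, y_raw, 1.0)), 0.0)
    w = usable.astype(float)

    n = w.sum(axis=-1)
    sx = (w * te).sum(axis=-1)
    sy = y.sum(axis=-1)
    sxx = (w * te * te).sum(axis=-1)
    sxy = (te * y).sum(axis=-1)
    syy = (y * y).sum(axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = n * sxx - sx * sx
        sxy_c = n * sxy - sx * sy
        syy_c = n * syy - sy * sy
        slope = sxy_c / sxx_c
        intercept = (sy - slope * sx) / n
        r2 = np.where(syy_c > 0, sxy_c * sxy_c / (sxx_c * syy_c), 1.0)

    enough = n >= min_points
    fittable = enough & (sxx_c > 0)
    slope = np.where(fittable, slope, np.nan)
    intercept = np.where(fittable, intercept, np.nan)
    r2 = np.where(fittable, np.clip(r2, 0.0, 1.0), np.nan)
    valid = fittable & (slope < 0)
    return slope, intercept, r2, n.astype(int), valid


def fit_t2_loglinear(
    echo_times_ms, intensities, min_points: int = MIN_FIT_POINTS
) -> T2Fit:
    """Fit T2 by OLS of the log-intensity on echo time.

    Parameters
    ----------
    echo_times_ms, intensities
        Same length; intensities in arbitrary signal units.
    min_points
        Minimum echoes with positive intensity required for a valid fit.

    Returns
    -------
    T2Fit
        ``t2_ms = -1/slope`` and ``s0 = exp(intercept)``.  ``valid`` is False
        (not an error) when the slope is nonnegative or too few echoes
        survive the positivity screen.

    Raises
    ------
    ValueError
        If lengths differ or no intensity is positive.
    """
    te = np.asarray(echo_times_ms, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if te.shape != y.shape or te.ndim != 1:
        raise ValueError(
            f"echo_times_ms (len {te.size}) and intensities (len {y.size}) must be "
            "1-D of equal length"
        )
    if not np.any(y > 0):
        raise ValueError("all intensities are nonpositive; nothing to fit")

    slope, intercept, r2, n, valid = _loglinear_arrays(te, y, min_points)
    slope_f = float(slope)
    t2 = -1.0 / slope_f if (np.isfinite(slope_f) and slope_f < 0) else np.nan
    s0 = float(np.exp(intercept)) if np.isfinite(intercept) else np.nan
    return T2Fit(
        t2_ms=t2,
        s0=s0,
        r_squared=float(r2),
        n_points_used=int(n),
        valid=bool(valid),
        slope=slope_f,
    )


def t2_map(stack: EchoStack, mask, min_points: int = MIN_FIT_POINTS) -> T2Map:
    """Fit T2 independently for every pixel under ``mask``.

    Raises ``ValueError`` on an empty mask or a shape mismatch.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.volume_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack volume {stack.volume_shape}"
        )
    if not mask.any():
        raise ValueError("mask is empty")

    pix = stack.images[:, mask].T  # (N, E)
    slope, intercept, r2, n, valid = _loglinear_arrays(
        stack.echo_times_ms, pix, min_points
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(valid, -1.0 / slope, np.nan)
        s0 = np.exp(intercept)

    def full(values, fill, dtype=float):
        out = np.full(mask.shape, fill, dtype=dtype)
        out[mask] = values
        return out

    return T2Map(
        t2_ms=full(t2, np.nan),
        s0=full(s0, np.nan),
        r_squared=full(r2, np.nan),
        n_points_used=full(n, 0, dtype=int),
        valid=full(valid, False, dtype=bool),
        mask=mask,
    )


def roi_t2(
    stack: EchoStack,
    mask,
    method: str = "fit-of-means",
    min_points: int = MIN_FIT_POINTS,
) -> T2Fit:
    """ROI-level T2 by one of two aggregation orders.

    ``fit-of-means`` (default) averages the raw intensity over the ROI at
    each echo, then fits once; ``mean-of-fits`` fits every pixel and averages
    the valid per-pixel T2s (its ``r_squared`` is NaN — there is no single
    regression behind the average).  On a noiseless single-T2 ROI the two
    agree exactly; on mixed-T2 ROIs they differ because the mean of
    exponentials is not exponential.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.volume_shape:
        raise ValueError("mask shape does not match stack volume")
    if not mask.any():
        raise ValueError("mask is empty")

    if method == "fit-of-means":
        mean_signal = stack.images[:, mask].mean(axis=1)
        return fit_t2_loglinear(stack.echo_times_ms, mean_signal, min_points)
    if method == "mean-of-fits":
        tm = t2_map(stack, mask, min_points)
        valid = tm.valid[mask]
        n_valid = int(valid.sum())
        if n_valid == 0:
            return T2Fit(np.nan, np.nan, np.nan, 0, False)
        t2 = float(np.nanmean(tm.t2_ms[mask][valid]))
        s0 = float(np.nanmean(tm.s0[mask][valid]))
        return T2Fit(t2, s0, np.nan, n_valid, True)
    raise ValueError(f"unknown method {method!r}; use 'fit-of-means' or 'mean-of-fits'")
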
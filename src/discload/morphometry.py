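"""Disc and vertebral-body morphometry from binary ROI masks.

All masks are 2-D boolean arrays in the package's sagittal convention:
row 0 superior, column 0 anterior.  A traced disc is first rotated to the
horizontal about the principal axis of its second central image moments,
then measured: area (pixel count x pixel area), width (antero-posterior
occupied-column extent), height (mean per-column vertical extent), five
equal-width anterior-to-posterior subregions of a T2 map, a dense
width-interpolated T2 profile, trapezoidal volume over slices, and the
disc : vertebral-body height ratio used as a size-normalised hypertrophy
index.  The nucleus T2 reported downstream is the central (3rd) subregion
mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "DiscMetrics",
    "principal_angle",
    "rotate_to_horizontal",
    "disc_geometry",
    "subregion_profile",
    "disc_volume",
    "height_ratio",
    "periprocess_average",
    "disc_metrics",
    "mask_area",
]

N_SUBREGIONS = 5
#: Major/minor eigenvalue ratio below which a mask counts as isotropic
#: (its principal angle is numerically defined but not meaningful).
ISOTROPY_RATIO = 1.05
#: Points of the dense width-interpolated subregion profile.
PROFILE_POINTS = 100


@dataclass
class DiscMetrics:
    """Geometry and composition measures for one disc on one slice."""

    rotation_angle_deg: float
    area_mm2: float
    height_mm: float
    width_mm: float
    mean_t2_ms: float
    subregion_t2_ms: np.ndarray  # 5 values, anterior -> posterior
    height_ratio: float = np.nan
    volume_cm3: float = np.nan

    def __post_init__(self) -> None:
        self.subregion_t2_ms = np.asarray(self.subregion_t2_ms, dtype=float)
        if self.subregion_t2_ms.size != N_SUBREGIONS:
            raise ValueError(f"expected {N_SUBREGIONS} subregion values")

    @property
    def nucleus_t2_ms(self) -> float:
        """Central-subregion mean T2 — the nucleus composition measure."""
        return float(self.subregion_t2_ms[N_SUBREGIONS // 2])


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not m.any():
        raise ValueError("mask is empty")
    return m


def _central_moments(mask: np.ndarray) -> tuple[float, float, float]:
    """(mu_cc, mu_rr, mu_rc): second central moments in (col, row) pixel coords."""
    r, c = np.nonzero(mask)
    r = r.astype(float)
    c = c.astype(float)
    rc, cc = r.mean(), c.mean()
    return float(((c - cc) ** 2).mean()), float(((r - rc) ** 2).mean()), float(
        ((r - rc) * (c - cc)).mean()
    )


def principal_angle(mask, return_isotropy: bool = False):
    """Angle (degrees) of the mask's major principal axis above the horizontal.

    Measured anatomically: positive when the anterior (column-0) end of the
    major axis points superiorly.  Range (-90, 90]; 0 means the long axis is
    already horizontal.  With ``return_isotropy=True`` also returns a flag
    that is True when the two principal eigenvalues differ by less than
    ``ISOTROPY_RATIO`` (e.g. a circle), where the angle is arbitrary.

    Raises ``ValueError`` for masks whose moments are degenerate (a single
    pixel).
    """
    m = _as_mask(mask)
    mu_cc, mu_rr, mu_rc = _central_moments(m)
    if mu_cc == 0 and mu_rr == 0:
        raise ValueError("degenerate mask: second moments are zero (single pixel?)")
    # Work in maths coords (x = col, y = -row so superior is +y).
    angle = 0.5 * np.degrees(np.arctan2(-2.0 * mu_rc, mu_cc - mu_rr))
    if angle <= -90.0:
        angle += 180.0
    tr = mu_cc + mu_rr
    det = mu_cc * mu_rr - mu_rc * mu_rc
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = tr / 2.0 - np.sqrt(disc)
    isotropic = lam2 > 0 and (lam1 / lam2) < ISOTROPY_RATIO
    if return_isotropy:
        return float(angle), bool(isotropic)
    return float(angle)


def rotate_to_horizontal(mask, angle_deg: float | None = None) -> np.ndarray:
    """Rotate a mask about its centroid so its major axis is horizontal.

    Bilinear rotation of the 0/1 mask followed by a 0.5 threshold, which
    keeps the area within rasterization tolerance (~2%).  If ``angle_deg``
    is None the principal angle is measured first.
    """
    m = _as_mask(mask)
    if angle_deg is None:
        angle_deg = principal_angle(m)
    r, c = np.nonzero(m)
    centroid = (c.mean(), r.mean())  # skimage expects (col, row)
    # skimage's positive angle raises the anterior (left) end just like our
    # anatomical angle, so undoing the tilt means rotating by -angle.
    rotated = _sk_rotate(
        m.astype(float), -angle_deg, center=centroid, order=1, preserve_range=True
    )
    return rotated > 0.5


def disc_geometry(mask, pixel_size_mm: float) -> tuple[float, float, float]:
    """(area mm^2, height mm, width mm) of a horizontally oriented mask.

    Width is the occupied-column count times the pixel size (antero-
    posterior extent); height is the mean per-column vertical extent
    (max row - min row + 1) over occupied columns, which is robust for
    lens-shaped discs and coincides with the bounding-box height on
    rectangles.
    """
    m = _as_mask(mask)
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    occupied = np.nonzero(m.any(axis=0))[0]
    area = float(m.sum()) * pixel_size_mm**2
    width = occupied.size * pixel_size_mm
    extents = []
    for col in occupied:
        rows = np.nonzero(m[:, col])[0]
        extents.append(rows[-1] - rows[0] + 1)
    height = float(np.mean(extents)) * pixel_size_mm
    return area, height, width


def _subregion_column_blocks(occupied_cols: np.ndarray) -> list[np.ndarray]:
    """Split occupied columns into 5 contiguous anterior->posterior blocks.

    Remainder columns (width % 5) go to the interior blocks — one each to
    blocks 2 and 4 first, the rest to the central block 3 — keeping the
    anterior/posterior annulus blocks unpolluted by the ambiguity.
    """
    n = occupied_cols.size
    if n < N_SUBREGIONS:
        raise ValueError(f"need at least {N_SUBREGIONS} occupied columns, got {n}")
    base, rem = divmod(n, N_SUBREGIONS)
    sizes = [base] * N_SUBREGIONS
    if rem >= 2:
        sizes[1] += 1
        sizes[3] += 1
        sizes[2] += rem - 2
    elif rem == 1:
        sizes[2] += 1
    bounds = np.cumsum([0] + sizes)
    return [occupied_cols[bounds[i] : bounds[i + 1]] for i in range(N_SUBREGIONS)]


def subregion_profile(
    mask, t2_values, valid=None, max_invalid_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Five anterior->posterior subregion mean T2s plus a dense width profile.

    Parameters
    ----------
    mask
        Horizontal disc mask.
    t2_values
        Per-pixel T2 array aligned with the mask (NaN where the fit failed).
    valid
        Optional boolean array of usable fits; defaults to finite t2_values.
    max_invalid_fraction
        A block whose invalid fraction exceeds this is reported NaN.

    Returns
    -------
    (subregion_means, dense_profile)
        ``subregion_means``: 5 values; the pixel-count-weighted mean of the
        valid-pixel blocks equals the whole-disc mean exactly (partition).
        ``dense_profile``: per-column means linearly interpolated onto a
        fixed 100-point grid across the occupied width.
    """
    m = _as_mask(mask)
    t2 = np.asarray(t2_values, dtype=float)
    if t2.shape != m.shape:
        raise ValueError("t2 map shape does not match mask")
    ok = np.isfinite(t2) if valid is None else np.asarray(valid, dtype=bool)
    ok = ok & m

    occupied = np.nonzero(m.any(axis=0))[0]
    blocks = _subregion_column_blocks(occupied)
    means = np.empty(N_SUBREGIONS)
    for i, cols in enumerate(blocks):
        block_mask = np.zeros_like(m)
        block_mask[:, cols] = m[:, cols]
        n_pix = int(block_mask.sum())
        n_ok = int((ok & block_mask).sum())
        if n_pix == 0 or (n_pix - n_ok) / n_pix > max_invalid_fraction:
            means[i] = np.nan
        else:
            means[i] = t2[ok & block_mask].mean()

    col_means = np.array(
        [t2[ok[:, c], c].mean() if ok[:, c].any() else np.nan for c in occupied]
    )
    grid = np.linspace(occupied[0], occupied[-1], PROFILE_POINTS)
    finite = np.isfinite(col_means)
    if finite.sum() >= 2:
        dense = np.interp(grid, occupied[finite], col_means[finite])
    else:
        dense = np.full(PROFILE_POINTS, np.nan)
    return means, dense


def disc_volume(slice_areas_mm2, slice_spacing_mm: float) -> float:
    """Disc volume (cm^3) by trapezoidal integration of slice areas.

    Linear interpolation of area between slice centres; requires >= 2
    slices (a single area gives no extent to integrate over).
    """
    areas = np.asarray(slice_areas_mm2, dtype=float)
    if areas.ndim != 1 or areas.size < 2:
        raise ValueError("need areas from at least 2 slices")
    if slice_spacing_mm <= 0:
        raise ValueError("slice spacing must be positive")
    mm3 = np.trapezoid(areas, dx=slice_spacing_mm)
    return float(mm3) / 1000.0


def height_ratio(disc_height_mm: float, vertebral_body_height_mm: float) -> float:
    """Disc height over adjacent vertebral-body height (unitless)."""
    if disc_height_mm <= 0 or vertebral_body_height_mm <= 0:
        raise ValueError("heights must be positive")
    return disc_height_mm / vertebral_body_height_mm


def periprocess_average(values_per_slice, spinous_slice_index: int) -> float:
    """Mean over the three slices centred on the spinous-process slice.

    Raises ``ValueError`` when the index or a neighbour falls outside the
    stack (behaviour at the boundary is undefined upstream).
    """
    vals = np.asarray(values_per_slice, dtype=float)
    i = int(spinous_slice_index)
    if i - 1 < 0 or i + 1 >= vals.size:
        raise ValueError(
            f"spinous slice {i} needs both neighbours within 0..{vals.size - 1}"
        )
    return float(vals[i - 1 : i + 2].mean())


def mask_area(mask, pixel_size_mm: float) -> float:
    """Pixel-count area (mm^2) of any ROI mask — utility, e.g. muscle CSA."""
    return float(_as_mask(mask).sum()) * pixel_size_mm**2


def disc_metrics(
    disc_mask,
    t2_values,
    pixel_size_mm: float,
    vertebra_mask=None,
) -> DiscMetrics:
    """Full single-slice metric set for one disc.

    Rotates the disc (and its T2 map) to horizontal, measures geometry and
    the 5-subregion profile, and — when a vertebral-body mask is supplied —
    the disc : vertebra height ratio (the vertebra is rotated and measured
    the same way).
    """
    angle = principal_angle(disc_mask)
    rot = rotate_to_horizontal(disc_mask, angle)
    area, height, width = disc_geometry(rot, pixel_size_mm)

    t2 = np.asarray(t2_values, dtype=float)
    r, c = np.nonzero(np.asarray(disc_mask, dtype=bool))
    centroid = (c.mean(), r.mean())
    t2_rot = _sk_rotate(
        np.nan_to_num(t2, nan=0.0), -angle, center=centroid, order=0, preserve_range=True
    )
    finite_rot = (
        _sk_rotate(
            np.isfinite(t2).astype(float), -angle, center=centroid, order=0,
            preserve_range=True,
        )
        > 0.5
    )
    sub, _ = subregion_profile(rot, np.where(finite_rot, t2_rot, np.nan))
    mean_t2 = float(t2_rot[rot & finite_rot].mean()) if (rot & finite_rot).any() else np.nan

    ratio = np.nan
    if vertebra_mask is not None:
        v_rot = rotate_to_horizontal(vertebra_mask)
        _, v_height, _ = disc_geometry(v_rot, pixel_size_mm)
        ratio = height_ratio(height, v_height)

    return DiscMetrics(
        rotation_angle_deg=angle,
        area_mm2=area,
        height_mm=height,
        width_mm=width,
        mean_t2_ms=mean_t2,
        subregion_t2_ms=sub,
        height_ratio=ratio,
    )
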
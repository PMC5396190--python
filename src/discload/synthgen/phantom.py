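"""Multi-echo spine phantoms with exact monoexponential ground truth.

Each region is a geometric primitive (rectangle, ellipse, or elliptical
annulus) carrying a label, a proton-density-like S0 and a T2 (ms).  The
noiseless pixel value of region r at echo time TE is S0_r * exp(-TE/T2_r);
Gaussian or Rician noise is added on top.  Regions must be pairwise
disjoint after rasterization — overlap resolution is deliberately
undefined and raises.

The default phantom is a mid-sagittal lumbar geometry: seven rectangular
vertebral bodies (T11 to S1) separated by six discs, each disc an
elliptical annulus (annulus fibrosus) enclosing a nucleus ellipse, tilted
by a few degrees to mimic lordosis.  Default tissue T2s are ordered
plausibly (nucleus 120 ms > annulus 70 ms > vertebra 50 ms) so subregion
profiles have structure; they are generator defaults, not measured claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..relaxometry import DEFAULT_ECHO_TIMES_MS, EchoStack

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "default_phantom_spec",
]

LABELS = ("disc_nucleus", "disc_annulus", "vertebra", "background")
SHAPES = ("ellipse", "rectangle", "ellipse_annulus")


@dataclass(frozen=True)
class RegionSpec:
    """One homogeneous tissue region.

    ``center`` is (row, col) in pixels; ``semi_axes`` are the half-extents
    (along-axis, cross-axis) of the primitive in pixels; ``angle_deg`` tilts
    the primitive's long axis above the horizontal (positive = anterior end
    superior, matching the morphometry convention).  ``inner_semi_axes``
    applies to ``ellipse_annulus`` only and carves a concentric hole.
    """

    label: str
    shape: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    s0: float
    t2_ms: float
    angle_deg: float = 0.0
    inner_semi_axes: tuple[float, float] | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.t2_ms <= 0:
            raise ValueError("T2 must be positive")
        if self.s0 < 0:
            raise ValueError("S0 must be nonnegative")
        if self.shape == "ellipse_annulus" and self.inner_semi_axes is None:
            raise ValueError("ellipse_annulus needs inner_semi_axes")


@dataclass(frozen=True)
class PhantomSpec:
    image_shape: tuple[int, int]  # (rows, cols) per slice
    n_slices: int
    pixel_size_mm: float
    slice_spacing_mm: float
    regions: tuple[RegionSpec, ...]
    echo_times_ms: tuple[float, ...] = DEFAULT_ECHO_TIMES_MS
    noise_sd: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        tes = np.asarray(self.echo_times_ms, dtype=float)
        if tes.size < 2 or np.any(tes <= 0) or np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.pixel_size_mm <= 0 or self.slice_spacing_mm <= 0 or self.n_slices < 1:
            raise ValueError("invalid geometry")
        for reg in self.regions:
            if reg.label == "background" and reg.s0 > self.noise_sd:
                raise ValueError(
                    f"background region {reg.name or ''} has S0 {reg.s0} above the "
                    f"noise floor {self.noise_sd}"
                )


@dataclass
class PhantomTruth:
    """Exact ground truth: integer label map + per-region parameters."""

    label_map: np.ndarray  # (slices, rows, cols); 0 = background, i+1 = regions[i]
    regions: tuple[RegionSpec, ...]

    def mask(self, region_index: int) -> np.ndarray:
        return self.label_map == region_index + 1

    def label_mask(self, label: str) -> np.ndarray:
        """Union mask over every region carrying ``label``."""
        out = np.zeros(self.label_map.shape, dtype=bool)
        for i, reg in enumerate(self.regions):
            if reg.label == label:
                out |= self.mask(i)
        return out

    def region_table(self) -> list[dict]:
        return [
            {
                "index": i,
                "name": reg.name or f"{reg.label}_{i}",
                "label": reg.label,
                "t2_ms": reg.t2_ms,
                "s0": reg.s0,
            }
            for i, reg in enumerate(self.regions)
        ]


def _rasterize(region: RegionSpec, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = np.indices(shape, dtype=float)
    cr, cc = region.center
    # maths coords: x along columns (anterior -> posterior), y up (superior).
    x = cols - cc
    y = -(rows - cr)
    th = np.radians(region.angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    a, b = region.semi_axes
    if region.shape == "rectangle":
        return (np.abs(u) <= a) & (np.abs(v) <= b)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if region.shape == "ellipse":
        return inside
    ia, ib = region.inner_semi_axes  # type: ignore[misc]
    hole = (u / ia) ** 2 + (v / ib) ** 2 <= 1.0
    return inside & ~hole


def make_phantom(spec: PhantomSpec) -> tuple[EchoStack, PhantomTruth]:
    """Render a phantom: one image per echo time plus exact label masks.

    Deterministic in ``spec`` (including ``spec.seed``).  Raises
    ``ValueError`` naming the colliding labels if any two rasterized
    regions overlap.
    """
    shape2d = tuple(spec.image_shape)
    masks = [_rasterize(reg, shape2d) for reg in spec.regions]
    label2d = np.zeros(shape2d, dtype=int)
    for i, (reg, m) in enumerate(zip(spec.regions, masks)):
        clash = (label2d > 0) & m
        if clash.any():
            other = spec.regions[label2d[clash][0] - 1]
            raise ValueError(
                f"regions overlap: {reg.name or reg.label!r} collides with "
                f"{other.name or other.label!r}"
            )
        label2d[m] = i + 1

    tes = np.asarray(spec.echo_times_ms, dtype=float)
    signal2d = np.zeros((tes.size,) + shape2d)
    for i, reg in enumerate(spec.regions):
        decay = reg.s0 * np.exp(-tes / reg.t2_ms)
        signal2d[:, masks[i]] = decay[:, None]

    # Same geometry on every slice; noise differs per slice.
    images = np.broadcast_to(
        signal2d[:, None, :, :], (tes.size, spec.n_slices) + shape2d
    ).copy()
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            images += rng.normal(0.0, spec.noise_sd, images.shape)
        else:  # rician magnitude: quadrature of two noisy channels
            n1 = rng.normal(0.0, spec.noise_sd, images.shape)
            n2 = rng.normal(0.0, spec.noise_sd, images.shape)
            images = np.sqrt((images + n1) ** 2 + n2**2)

    stack = EchoStack(
        images=images,
        echo_times_ms=tes,
        pixel_size_mm=spec.pixel_size_mm,
        slice_spacing_mm=spec.slice_spacing_mm,
    )
    label_map = np.broadcast_to(label2d, (spec.n_slices,) + shape2d).copy()
    return stack, PhantomTruth(label_map=label_map, regions=spec.regions)


#: Disc levels of the default phantom, superior to inferior.
DEFAULT_LEVELS = ("T11/T12", "T12/L1", "L1/L2", "L2/L3", "L3/L4", "L4/L5")


def default_phantom_spec(
    nucleus_t2_ms: float = 120.0,
    annulus_t2_ms: float = 70.0,
    vertebra_t2_ms: float = 50.0,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    n_slices: int = 5,
    seed: int = 0,
) -> PhantomSpec:
    """Mid-sagittal lumbar phantom: 7 vertebrae, 6 two-compartment discs.

    Vertebral bodies are 56 x 24 px rectangles spaced 36 px centre to
    centre; each disc is a tilted elliptical annulus (semi-axes 26 x 4.2 px,
    hole 13 x 2.3 px) with the nucleus ellipse filling the hole.  Tilts run
    from +6 deg (superior) to -6 deg (inferior), a mild lordotic sweep kept
    small enough that tilted discs clear the vertebral rectangles.
    """
    regions: list[RegionSpec] = []
    col_c = 48.0
    angles = (6.0, 4.0, 2.0, 0.0, -3.0, -6.0)
    for k in range(7):
        row_c = 20.0 + 36.0 * k
        regions.append(
            RegionSpec(
                label="vertebra",
                shape="rectangle",
                center=(row_c, col_c),
                semi_axes=(28.0, 12.0),
                s0=s0,
                t2_ms=vertebra_t2_ms,
                name=f"vertebra_{k}",
            )
        )
    for k, (level, ang) in enumerate(zip(DEFAULT_LEVELS, angles)):
        row_c = 20.0 + 36.0 * k + 18.0
        safe = level.replace("/", "_")
        regions.append(
            RegionSpec(
                label="disc_annulus",
                shape="ellipse_annulus",
                center=(row_c, col_c),
                semi_axes=(26.0, 4.2),
                inner_semi_axes=(13.0, 2.3),
                angle_deg=ang,
                s0=s0,
                t2_ms=annulus_t2_ms,
                name=f"annulus_{safe}",
            )
        )
        regions.append(
            RegionSpec(
                label="disc_nucleus",
                shape="ellipse",
                center=(row_c, col_c),
                semi_axes=(13.0, 2.3),
                angle_deg=ang,
                s0=s0,
                t2_ms=nucleus_t2_ms,
                name=f"nucleus_{safe}",
            )
        )
    return PhantomSpec(
        image_shape=(272, 96),
        n_slices=n_slices,
        pixel_size_mm=0.366,
        slice_spacing_mm=4.5,
        regions=tuple(regions),
        noise_sd=noise_sd,
        noise_model=noise_model,
        seed=seed,
    )
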
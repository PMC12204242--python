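"""Synthetic axial chest phantoms with analytically known pectus indices.

The phantom is an elliptical thoracic cross-section whose anterior (sternal)
boundary carries a smooth Gaussian-profile depression and whose posterior
midline carries a circular-arc vertebral protrusion.  Because both the inner
cavity boundary and the outer body surface are closed-form functions of the
transverse coordinate, every quantity the measurement pipeline estimates
(Haller, correction and asymmetry indices, the deepest-depression slice, mask
areas) has an analytic ground truth, which the rest of the package treats as
its oracle.

Physical coordinate convention: ``x`` is the transverse coordinate in cm and
increases toward the patient's left; ``y`` is the anteroposterior coordinate
in cm and increases anteriorly.  On the raster grid, rows increase
posteriorly (anterior at the top of the image) and columns increase toward
the patient's left, matching the usual radiological display of an axial CT
slice viewed from the feet.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError, ResolutionError

__all__ = [
    "PhantomParams",
    "StackParams",
    "GroundTruth",
    "AxialSlice",
    "make_inner_contour",
    "make_outer_contour",
    "make_phantom_slice",
    "make_phantom_stack",
    "analytic_indices",
    "analytic_outer_depth",
    "random_params",
    "INTENSITY_BACKGROUND",
    "INTENSITY_INTERIOR",
    "INTENSITY_BODY",
]

# Intensity bands of the noise-free phantom image (arbitrary units chosen so
# that body wall > cavity interior > background, as on soft-tissue windowed CT
# where the chest wall is brighter than the aerated interior).
INTENSITY_BACKGROUND = 20.0
INTENSITY_INTERIOR = 70.0
INTENSITY_BODY = 130.0


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, raster and noise parameters of a single phantom slice.

    Lengths are centimeters; ``pixel_spacing`` is millimeters per pixel.

    Parameters
    ----------
    transverse_semiaxis : half of the inner transverse diameter.
    ap_semiaxis : half of the inner anteroposterior diameter (no depression).
    dent_depth : nominal depth of the anterior depression at its center.
    dent_center_offset : signed transverse offset of the depression from the
        midline (positive toward the patient's left).
    dent_width : Gaussian scale (standard deviation) of the depression.
    spine_radius : radius of the circular vertebral protrusion on the
        posterior midline; the arc points anteriorly into the cavity.
    wall_thickness : chest-wall thickness separating inner and outer contour.
    pixel_spacing : raster resolution in mm/pixel.
    image_size : raster grid side in pixels (square images).
    noise_sd : standard deviation of additive Gaussian intensity noise.
    seed : integer seed; identical params + seed give bit-identical slices.
    """

    transverse_semiaxis: float = 10.0
    ap_semiaxis: float = 6.0
    dent_depth: float = 3.0
    dent_center_offset: float = 0.0
    dent_width: float = 3.0
    spine_radius: float = 1.5
    wall_thickness: float = 1.5
    pixel_spacing: float = 1.2
    image_size: int = 256
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        pos = {
            "transverse_semiaxis": self.transverse_semiaxis,
            "ap_semiaxis": self.ap_semiaxis,
            "dent_width": self.dent_width,
            "spine_radius": self.spine_radius,
            "wall_thickness": self.wall_thickness,
            "pixel_spacing": self.pixel_spacing,
        }
        for name, value in pos.items():
            if not value > 0:
                raise ParameterError(f"{name} must be > 0, got {value!r}")
        if self.dent_depth < 0:
            raise ParameterError(f"dent_depth must be >= 0, got {self.dent_depth!r}")
        if not self.dent_depth < 2 * self.ap_semiaxis:
            raise ParameterError(
                "dent_depth must be < 2*ap_semiaxis "
                f"({self.dent_depth} >= {2 * self.ap_semiaxis}); the depression "
                "cannot pass through the body"
            )
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.image_size < 32:
            raise ParameterError(f"image_size must be >= 32, got {self.image_size!r}")


@dataclass(frozen=True)
class StackParams:
    """A per-patient axial series: one slice per depth-profile entry.

    ``depth_profile`` scales ``base.dent_depth`` per slice; it must have a
    unique maximum so the deepest-depression slice is well defined.
    """

    base: PhantomParams
    depth_profile: Sequence[float] = (0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25)

    @property
    def n_slices(self) -> int:
        return len(self.depth_profile)

    def validate(self) -> None:
        self.base.validate()
        prof = np.asarray(self.depth_profile, dtype=float)
        if prof.ndim != 1 or prof.size == 0:
            raise ParameterError("depth_profile must be a non-empty 1-d sequence")
        if prof.min() < 0 or prof.max() > 1:
            raise ParameterError("depth_profile entries must lie in [0, 1]")
        if prof.max() == 0 or self.base.dent_depth == 0:
            raise ParameterError("depth_profile has no depression (all-zero depths)")
        top = np.flatnonzero(prof == prof.max())
        if top.size != 1:
            raise ParameterError(
                f"depth_profile maximum is not unique (slices {top.tolist()})"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic indices and landmark distances of a phantom (cm / ratios)."""

    haller: float
    correction_pct: float
    asymmetry: float
    transverse_cm: float
    ap_depth_cm: float
    ab_cm: float
    cd_cm: float
    L_cm: float
    R_cm: float
    deepest_slice: int = 0
    dip_cm: float = 0.0  # depth of the dent below the lower anterior crest
    flags: frozenset = frozenset()


@dataclass
class AxialSlice:
    """A single axial intensity image with its physical pixel spacing."""

    image: np.ndarray  # (rows, cols) float32
    spacing_mm: float  # isotropic, mm per pixel
    z_index: int = 0

    @property
    def spacing_cm(self) -> float:
        return self.spacing_mm / 10.0

    @property
    def extent_cm(self) -> float:
        return self.image.shape[1] * self.spacing_cm


# ---------------------------------------------------------------------------
# Boundary functions
# ---------------------------------------------------------------------------

def _dent(params: PhantomParams, x: np.ndarray) -> np.ndarray:
    """Gaussian depression profile, 1 at the dent center."""
    u = (x - params.dent_center_offset) / params.dent_width
    return np.exp(-0.5 * u * u)


def inner_boundary(params: PhantomParams) -> tuple[Callable, Callable]:
    """Upper (anterior) and lower (posterior) inner-boundary functions of x.

    The anterior boundary is the ellipse arc pushed posteriorly by the
    depression, tapered by the elliptic height factor so the contour stays
    closed at the lateral extremes; the posterior boundary is the ellipse arc
    raised by the vertebral arc near the midline.
    """
    a, b = params.transverse_semiaxis, params.ap_semiaxis
    r = params.spine_radius

    def upper(x):
        x = np.asarray(x, dtype=float)
        s = np.sqrt(np.clip(1.0 - (x / a) ** 2, 0.0, None))
        return s * (b - params.dent_depth * _dent(params, x))

    def lower(x):
        x = np.asarray(x, dtype=float)
        s = np.sqrt(np.clip(1.0 - (x / a) ** 2, 0.0, None))
        ell = -b * s
        arc = np.full_like(ell, -np.inf)
        inside = np.abs(x) < r
        arc[inside] = -b + np.sqrt(r * r - x[inside] ** 2)
        return np.maximum(ell, arc)

    return upper, lower


def outer_boundary(params: PhantomParams) -> tuple[Callable, Callable]:
    """Outer body-surface boundary: a dilated ellipse carrying the same dent."""
    a = params.transverse_semiaxis + params.wall_thickness
    b = params.ap_semiaxis + params.wall_thickness

    def upper(x):
        x = np.asarray(x, dtype=float)
        s = np.sqrt(np.clip(1.0 - (x / a) ** 2, 0.0, None))
        return s * (b - params.dent_depth * _dent(params, x))

    def lower(x):
        x = np.asarray(x, dtype=float)
        s = np.sqrt(np.clip(1.0 - (x / a) ** 2, 0.0, None))
        return -b * s

    return upper, lower


def _symmetric_grid(half_width: float, n: int) -> np.ndarray:
    """A transverse grid exactly symmetric about 0 in floating point."""
    half = np.linspace(0.0, half_width, n // 2 + 1)
    return np.concatenate([-half[:0:-1], half])


def _check_simple(params: PhantomParams) -> None:
    upper, lower = inner_boundary(params)
    x = _symmetric_grid(params.transverse_semiaxis, 4096)[1:-1]
    gap = upper(x) - lower(x)
    if gap.min() <= 0:
        raise ParameterError(
            "depression reaches the posterior boundary (inner contour would "
            f"self-intersect; min gap {gap.min():.3f} cm)"
        )


def make_inner_contour(params: PhantomParams, n_vertices: int = 1440) -> np.ndarray:
    """Closed, simple polyline of the inner thoracic contour, (x, y) in cm.

    Vertices run counter-clockwise in the anterior-up display convention:
    anterior arc left-to-right, posterior arc right-to-left.
    """
    params.validate()
    _check_simple(params)
    if n_vertices < 720:
        raise ParameterError("n_vertices must be >= 720 for dense sampling")
    upper, lower = inner_boundary(params)
    half = n_vertices // 2
    # Cosine-spaced abscissae concentrate vertices at the steep lateral edges.
    theta = np.linspace(np.pi, 0.0, half + 1)
    xa = params.transverse_semiaxis * np.cos(theta)
    xp = xa[-2:0:-1]
    return np.concatenate(
        [
            np.column_stack([xa, upper(xa)]),
            np.column_stack([xp, lower(xp)]),
        ]
    )


def make_outer_contour(params: PhantomParams, n_vertices: int = 1440) -> np.ndarray:
    """Closed polyline of the outer body surface, (x, y) in cm."""
    params.validate()
    upper, lower = outer_boundary(params)
    a = params.transverse_semiaxis + params.wall_thickness
    half = n_vertices // 2
    theta = np.linspace(np.pi, 0.0, half + 1)
    xa = a * np.cos(theta)
    xp = xa[-2:0:-1]
    return np.concatenate(
        [
            np.column_stack([xa, upper(xa)]),
            np.column_stack([xp, lower(xp)]),
        ]
    )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _pixel_axes(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x per column, y per row) coordinates of pixel centers."""
    n = params.image_size
    s = params.pixel_spacing / 10.0  # cm per pixel
    c = (np.arange(n) - (n - 1) / 2.0) * s
    x = c                      # columns increase toward patient left
    y = -c                     # rows increase posteriorly
    return x, y


def _fill_between(x: np.ndarray, y: np.ndarray, upper, lower,
                  half_width: float) -> np.ndarray:
    """Boolean mask of pixel centers strictly between lower and upper."""
    inside_x = np.abs(x) < half_width
    up = np.where(inside_x, upper(x), -np.inf)
    lo = np.where(inside_x, lower(x), np.inf)
    yy = y[:, None]
    return (yy > lo[None, :]) & (yy < up[None, :])


def make_phantom_slice(params: PhantomParams) -> tuple[AxialSlice, np.ndarray]:
    """Rasterize one phantom slice and its exact interior mask.

    Returns the intensity image (three bands plus seeded Gaussian noise) and
    the boolean segmentation mask of the thoracic interior.  The mask is a
    single connected component by construction (the cavity is vertically
    convex: one row interval per column).
    """
    params.validate()
    _check_simple(params)
    outer_a = params.transverse_semiaxis + params.wall_thickness
    outer_b = params.ap_semiaxis + params.wall_thickness
    fov = params.image_size * params.pixel_spacing / 10.0
    margin = 2 * params.pixel_spacing / 10.0
    if 2 * outer_a + margin > fov or 2 * outer_b + margin > fov:
        raise ResolutionError(
            f"image_size {params.image_size} at {params.pixel_spacing} mm/px "
            f"(FOV {fov:.1f} cm) cannot contain the {2 * outer_a:.1f} x "
            f"{2 * outer_b:.1f} cm body"
        )
    x, y = _pixel_axes(params)
    iu, il = inner_boundary(params)
    ou, ol = outer_boundary(params)
    interior = _fill_between(x, y, iu, il, params.transverse_semiaxis)
    body_full = _fill_between(x, y, ou, ol, outer_a)
    image = np.full(interior.shape, INTENSITY_BACKGROUND, dtype=np.float32)
    image[body_full] = INTENSITY_BODY
    image[interior] = INTENSITY_INTERIOR
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        image = image + rng.normal(0.0, params.noise_sd, image.shape).astype(np.float32)
    return AxialSlice(image=image, spacing_mm=params.pixel_spacing), interior


def make_phantom_stack(
    sp: StackParams,
) -> tuple[list[AxialSlice], list[np.ndarray], GroundTruth]:
    """One rasterized slice per depth-profile entry, plus analytic truth.

    The ground truth is computed on the maximal-depth slice; its
    ``deepest_slice`` field is the argmax of the depth profile.
    """
    sp.validate()
    prof = np.asarray(sp.depth_profile, dtype=float)
    deepest = int(np.argmax(prof))
    slices: list[AxialSlice] = []
    masks: list[np.ndarray] = []
    for i, mult in enumerate(prof):
        p = replace(
            sp.base,
            dent_depth=sp.base.dent_depth * float(mult),
            seed=sp.base.seed + i,
        )
        sl, mask = make_phantom_slice(p)
        sl.z_index = i
        slices.append(sl)
        masks.append(mask)
    gt_params = replace(sp.base, dent_depth=sp.base.dent_depth * float(prof[deepest]))
    gt = analytic_indices(gt_params)
    gt = replace(gt, deepest_slice=deepest)
    return slices, masks, gt


# ---------------------------------------------------------------------------
# Analytic indices (the oracle)
# ---------------------------------------------------------------------------

def analytic_indices(params: PhantomParams, n_grid: int = 8192) -> GroundTruth:
    """Haller, correction and asymmetry indices from the closed-form contour.

    Landmarks follow the clinical construction: ``a`` is the most anterior
    inner point, ``d`` the most anterior point of the vertebral protrusion,
    the spine tangent line ``S`` runs transversely through ``d``, ``b`` is the
    foot of the anteroposterior perpendicular from ``a`` onto ``S``, ``c`` the
    deepest point of the anterior boundary between the two anterior crests.
    ``ab`` and ``cd`` are anteroposterior distances to ``S``; ``L``/``R`` are
    the per-hemithorax maximal anteroposterior chords of the inner contour.
    """
    params.validate()
    a_semi, b_semi = params.transverse_semiaxis, params.ap_semiaxis
    upper, lower = inner_boundary(params)
    x = _symmetric_grid(a_semi, n_grid)
    up = upper(x)
    lo = lower(x)
    flags: set[str] = set()

    y_d = -b_semi + params.spine_radius
    # Most anterior point overall; ties broken toward the smaller column.
    i_a = int(np.flatnonzero(up >= up.max() - 1e-12)[0])
    y_a = float(up[i_a])
    ab = y_a - y_d

    # Anterior crests: most anterior point of each half of the anterior
    # boundary, split at the transverse area centroid of the cavity (the same
    # construction the mask-based landmark search uses).
    chord_all = up - lo
    x_bar = float(np.sum(x * chord_all) / np.sum(chord_all))
    dip = 0.0
    if params.dent_depth > 0:
        crest_r = int(np.argmax(np.where(x <= x_bar, up, -np.inf)))
        crest_l = int(np.argmax(np.where(x >= x_bar, up, -np.inf)))
        lo_idx, hi_idx = sorted((crest_r, crest_l))
        if hi_idx - lo_idx >= 2:
            seg = slice(lo_idx + 1, hi_idx)
            i_c = lo_idx + 1 + int(np.argmin(up[seg]))
            y_c = float(up[i_c])
            dip = float(min(up[lo_idx], up[hi_idx]) - y_c)
            if dip <= 0:
                y_c = y_a
                flags.add("no-dent")
        else:
            y_c = y_a
            flags.add("no-dent")
    else:
        y_c = y_a
        flags.add("no-dent")
    cd = y_c - y_d
    if cd <= 0:
        flags.add("dent-past-spine")

    chord = up - lo
    L = float(np.max(np.where(x > 0, chord, -np.inf)))
    R = float(np.max(np.where(x < 0, chord, -np.inf)))
    transverse = 2.0 * a_semi

    haller = transverse / cd if cd > 0 else float("inf")
    correction = 100.0 * (ab - cd) / ab
    return GroundTruth(
        haller=haller,
        correction_pct=correction,
        asymmetry=R / L,
        transverse_cm=transverse,
        ap_depth_cm=cd,
        ab_cm=ab,
        cd_cm=cd,
        L_cm=L,
        R_cm=R,
        dip_cm=dip,
        flags=frozenset(flags),
    )


def analytic_outer_depth(params: PhantomParams, n_grid: int = 8192) -> float:
    """Depression depth on the outer body surface, in cm.

    Mirrors the slice-selection construction: the crest of each hemithorax is
    the most anterior outer point on its side of the dent, the assistant
    tangent line joins the two crests, and the depth is the maximal
    perpendicular drop of the anterior boundary posterior of that line.
    """
    params.validate()
    if params.dent_depth == 0:
        return 0.0
    a = params.transverse_semiaxis + params.wall_thickness
    upper, lower = outer_boundary(params)
    x = _symmetric_grid(a, n_grid)
    up = upper(x)
    chord = up - lower(x)
    x_bar = float(np.sum(x * chord) / np.sum(chord))
    crest_r = int(np.argmax(np.where(x <= x_bar, up, -np.inf)))
    crest_l = int(np.argmax(np.where(x >= x_bar, up, -np.inf)))
    lo_idx, hi_idx = sorted((crest_r, crest_l))
    if hi_idx - lo_idx < 2:
        return 0.0
    p1 = np.array([x[lo_idx], up[lo_idx]])
    p2 = np.array([x[hi_idx], up[hi_idx]])
    d = p2 - p1
    norm = np.hypot(*d)
    if norm == 0:
        return 0.0
    seg = slice(lo_idx + 1, hi_idx)
    # Signed cross product; positive when the boundary dips posterior of ab.
    drop = (d[0] * (p1[1] - up[seg]) - d[1] * (p1[0] - x[seg])) / norm
    return float(max(drop.max(), 0.0))


# ---------------------------------------------------------------------------
# Randomized cohorts
# ---------------------------------------------------------------------------

def random_params(
    rng: np.random.Generator,
    image_size: int = 256,
    noise_sd: float = 6.0,
) -> PhantomParams:
    """Draw one plausible pediatric-chest phantom.

    Ranges bracket the geometry of the pediatric pectus cohort the method is
    aimed at: inner transverse diameters 16-22 cm, AP diameters 10-14 cm,
    depressions up to ~60 % of the AP semiaxis, and mild-to-marked
    left-right asymmetry via the dent offset.
    """
    for _ in range(200):
        a = rng.uniform(8.0, 11.0)
        b = rng.uniform(5.0, 7.0)
        wall = rng.uniform(1.0, 2.0)
        # Fit the body into ~84 % of the field of view.
        fov = 2.0 * (a + wall) / 0.84
        spacing = fov * 10.0 / image_size
        params = PhantomParams(
            transverse_semiaxis=a,
            ap_semiaxis=b,
            dent_depth=rng.uniform(1.5, 0.6 * b),
            dent_center_offset=rng.uniform(-2.0, 2.0),
            dent_width=rng.uniform(2.0, 3.5),
            spine_radius=rng.uniform(1.0, 2.0),
            wall_thickness=wall,
            pixel_spacing=spacing,
            image_size=image_size,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # A usable PE phantom needs a decisive depression: a clear dip below
        # the lower anterior crest and a measurable outer-surface depression.
        gt = analytic_indices(params)
        if "no-dent" in gt.flags or gt.dip_cm < 0.8 or gt.cd_cm <= 0.5:
            continue
        if analytic_outer_depth(params) < 0.5:
            continue
        return params
    raise ParameterError("could not draw a decisive-depression phantom")
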
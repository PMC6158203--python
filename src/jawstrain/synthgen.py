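"""Synthetic inputs: parametric jaw geometries, image stacks, cells, curves.

The larval zebrafish lower jaw is reduced to capsule/rod primitives carrying
exactly the dimensions the morphometric suite measures: two mirrored Meckel's
cartilage (MC) rods meeting at the midline symphysis, each narrowing into a
joint *neck* and ending in a capsule-shaped joint *head*; paired palatoquadrate
(PQ) rods across a joint space from the MC heads; and a transverse ceratohyal
(CH) bar joined to the PQ posterior ends. Joint gaps (jaw joints, symphysis)
are filled with explicit interzone tissue — biologically the col2a1a-expressing
immature cells of the interzone — which also makes the finite-element model a
single connected body.

Geometry honesty is the module's contract: every shape parameter is recoverable
from the generated volume by the morphometrics module. Element axes sit on
voxel boundaries and preset widths are even multiples of the voxel size, so
width recovery is exact; the palatoquadrate position is snapped to the realised
Meckel's-head surface so the joint space is exact by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import ndimage, optimize

from . import afm
from .errors import (
    ConvergenceError,
    PlacementError,
    SizingError,
    ValidationError,
)
from .morphometrics import ClosedPolygon
from .rng import substream
from .volume import (
    BACKGROUND,
    CERATOHYAL,
    EXOSTOSIS,
    INTERZONE,
    MC_LEFT,
    MC_RIGHT,
    PQ_LEFT,
    PQ_RIGHT,
    LabelVolume,
)

__all__ = [
    "ShapeParams",
    "NoiseModel",
    "ImageStack",
    "shape_preset",
    "build_parametric_jaw",
    "render_stack",
    "plant_exostoses",
    "synth_cell_outline",
    "synth_force_curve",
]

#: Symphysis gap between the two MC anterior tips (um).
SYMPHYSIS_GAP = 2.0
#: Radius of the PQ-CH connector rods (um).
CONNECTOR_RADIUS = 3.0
#: Gap bridged by the PQ-CH connector (um).
CH_GAP = 2.0


@dataclass(frozen=True)
class ShapeParams:
    """Parametric jaw-shape description (all lengths in micrometres)."""

    element_length: float = 48.0
    element_radius: float = 4.0
    neck_width: float = 6.0
    head_width: float = 10.0
    joint_space: float = 6.0
    ceratohyal_length: float = 56.0
    voxel_size: float = 1.0
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        for name in (
            "element_length",
            "element_radius",
            "neck_width",
            "head_width",
            "ceratohyal_length",
            "voxel_size",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.joint_space < 0:
            raise ValidationError("joint_space must be non-negative")
        if self.head_width < self.neck_width:
            raise ValidationError("head_width must be >= neck_width")
        if self.neck_width / 2 > self.element_radius + self.head_width:
            raise ValidationError("neck wider than the element it belongs to")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian grey-value noise for the rendering forward model."""

    background_mean: float = 30.0
    foreground_mean: float = 200.0
    sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.foreground_mean <= self.background_mean:
            raise ValidationError("foreground_mean must exceed background_mean")
        if self.sd < 0:
            raise ValidationError("noise sd must be non-negative")


@dataclass
class ImageStack:
    """3D grayscale stack emulating a confocal col2a1a channel."""

    intensities: np.ndarray  # (nx, ny, nz) grey values in [0, max_grey]
    voxel_size: float = 1.0
    max_grey: float = 255.0

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities, dtype=np.float32)
        if a.ndim != 3:
            raise ValidationError("image stack must be 3D")
        if not np.all(np.isfinite(a)):
            raise ValidationError("non-finite intensities")
        self.intensities = a


def shape_preset(name: str) -> ShapeParams:
    """Load a named shape preset ('wt' or 'mutant') from the shipped configs."""
    from .io import load_packaged_yaml

    presets = load_packaged_yaml("shapes.yaml")
    if name not in presets:
        raise ValidationError(f"unknown shape preset '{name}' (have {sorted(presets)})")
    return ShapeParams(preset_name=name, **presets[name])


# ---------------------------------------------------------------------------
# geometry rasterization


def _capsule(X, Y, Z, p0, p1, radius):
    """Boolean mask of voxel centres within ``radius`` of segment p0-p1."""
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
    dd = float(d @ d)
    if dd == 0.0:
        dist2 = dx**2 + dy**2 + dz**2
    else:
        t = np.clip((dx * d[0] + dy * d[1] + dz * d[2]) / dd, 0.0, 1.0)
        dist2 = (dx - t * d[0]) ** 2 + (dy - t * d[1]) ** 2 + (dz - t * d[2]) ** 2
    return dist2 <= radius * radius


def build_parametric_jaw(
    params: ShapeParams,
    seed: int | None = None,
    domain_shape: tuple[int, int, int] | None = None,
) -> LabelVolume:
    """Rasterize the parametric jaw into a labelled voxel volume.

    ``seed`` optionally jitters the non-measured layout quantities (shaft
    length, lateral joint offset) by a few percent to emulate specimen-to-
    specimen variation; the measured parameters (neck, head, joint space,
    widths) are never jittered. ``domain_shape`` may force a domain; if it is
    too small for the requested geometry a :class:`SizingError` names the
    offending dimension.
    """
    h = params.voxel_size
    r = params.element_radius
    rn = params.neck_width / 2.0
    rh = params.head_width / 2.0
    L = params.element_length

    neck_len = max(4.0 * h, 0.15 * L)
    shaft_len = L - neck_len - params.head_width
    if shaft_len < 4.0 * h:
        raise SizingError(
            "element_length too short for neck and head: "
            f"shaft would be {shaft_len:.1f} um"
        )

    # layout quantities (jittered under a seed; snapped to voxel boundaries)
    y_lat = round(0.35 * L / h) * h
    if seed is not None:
        rng = substream(seed, "geometry")
        shaft_len = shaft_len * (1.0 + rng.uniform(-0.03, 0.03))
        y_lat = round(0.35 * L * (1.0 + rng.uniform(-0.05, 0.05)) / h) * h
    y_sym = round((r + SYMPHYSIS_GAP / 2.0) / h) * h

    pq_len = round(0.55 * L / h) * h
    x_a = r + 3.0 * h  # anterior MC tip centre
    # worst-case posterior extent before snapping (snap moves PQ by <= 1 voxel)
    x_head = x_a + shaft_len + neck_len + rh
    x_pq0_est = x_head + rh + params.joint_space + 2.0 * h + rh
    x_ch = x_pq0_est + pq_len + 2.0 * r + CH_GAP
    half_y = max(params.ceratohyal_length / 2.0 + r, y_lat + rh) + 3.0 * h
    half_z = rh + 3.0 * h

    nx = int(np.ceil((x_ch + r + 3.0 * h) / h))
    ny = 2 * int(np.ceil(half_y / h))
    nz = 2 * int(np.ceil(half_z / h))
    if domain_shape is not None:
        for want, have, name in zip((nx, ny, nz), domain_shape, "xyz"):
            if have < want:
                raise SizingError(
                    f"domain too small along {name}: need {want} voxels, have {have}"
                )
        nx, ny, nz = domain_shape

    y_mid = (ny // 2) * h
    z0 = (nz // 2) * h
    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    zs = (np.arange(nz) + 0.5) * h
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)

    def paint(mask: np.ndarray, label: int, only_background: bool = False) -> None:
        if only_background:
            mask = mask & (labels == BACKGROUND)
        labels[mask] = label

    mc_heads = {}
    for side, lab in ((-1, MC_LEFT), (+1, MC_RIGHT)):
        a = (x_a, y_mid + side * y_sym, z0)
        n0 = (x_a + shaft_len, y_mid + side * y_lat, z0)
        n1 = (x_a + shaft_len + neck_len, y_mid + side * y_lat, z0)
        head_c = (x_a + shaft_len + neck_len + rh, y_mid + side * y_lat, z0)
        m = _capsule(X, Y, Z, a, n0, r)
        m |= _capsule(X, Y, Z, n0, n1, rn)
        m |= _capsule(X, Y, Z, head_c, head_c, rh)
        paint(m, lab)
        mc_heads[side] = head_c

    # snap the PQ anterior surface to the realised MC posterior surface so the
    # measured joint space equals the requested one exactly. The PQ terminal
    # region articulating with the MC head is itself head-width broad (both
    # rudiment terminals enlarge in the mutant).
    mc_mask = (labels == MC_LEFT) | (labels == MC_RIGHT)
    x_out = xs[np.argwhere(mc_mask)[:, 0].max()]
    x_in = x_out + params.joint_space + h  # target innermost PQ voxel centre
    cap_reach = np.sqrt(max(rh * rh - 0.5 * h * h, 0.0))
    x_pq0 = x_in + cap_reach - 1e-6
    for side, lab in ((-1, PQ_LEFT), (+1, PQ_RIGHT)):
        head = (x_pq0, y_mid + side * y_lat, z0)
        p1 = (x_pq0 + pq_len, y_mid + side * y_lat, z0)
        m = _capsule(X, Y, Z, head, head, rh)
        m |= _capsule(X, Y, Z, head, p1, r)
        paint(m, lab, only_background=True)

    # ceratohyal bar plus short connectors to the PQ posterior ends
    x_ch = x_pq0 + pq_len + 2.0 * r + CH_GAP
    if x_ch + r + 2.0 * h > nx * h:
        raise SizingError("domain too small along x for the ceratohyal bar")
    ch0 = (x_ch, y_mid - params.ceratohyal_length / 2.0, z0)
    ch1 = (x_ch, y_mid + params.ceratohyal_length / 2.0, z0)
    ch = _capsule(X, Y, Z, ch0, ch1, r)
    for side in (-1, +1):
        pq_end = (x_pq0 + pq_len, y_mid + side * y_lat, z0)
        ch_pt = (x_ch, y_mid + side * y_lat, z0)
        ch |= _capsule(X, Y, Z, pq_end, ch_pt, CONNECTOR_RADIUS)
    paint(ch, CERATOHYAL, only_background=True)

    # interzone tissue: a column spanning the articulating surfaces at each
    # jaw joint (so its cross-section tracks the head width and its length the
    # joint space), plus the block between the MC tips at the symphysis
    iz = np.zeros_like(mc_mask)
    for side in (-1, +1):
        j0 = (x_out, y_mid + side * y_lat, z0)
        j1 = (x_in, y_mid + side * y_lat, z0)
        iz |= _capsule(X, Y, Z, j0, j1, rh)
    iz |= _capsule(
        X, Y, Z,
        (x_a, y_mid - y_sym, z0),
        (x_a, y_mid + y_sym, z0),
        r,
    )
    paint(iz, INTERZONE, only_background=True)

    joint_x = 0.5 * (x_out + x_in)
    meta: dict[str, Any] = {
        "params": dataclasses.asdict(params),
        "landmarks": {
            "symphysis_x": float(x_a),
            "neck_x": float(x_a + shaft_len + neck_len / 2.0),
            "head_x": float(x_a + shaft_len + neck_len + rh),
            "joint_x": float(joint_x),
            "y_lat": float(y_lat),
            "y_mid": float(y_mid),
            "z_mid": float(z0),
            "pq_base_x": float(x_pq0 + pq_len),
        },
        "joint_planes": [
            {"point": [float(joint_x), float(y_mid), float(z0)], "normal": [1.0, 0.0, 0.0]},
            {"point": [float(x_a), float(y_mid), float(z0)], "normal": [1.0, 0.0, 0.0]},
        ],
        # Muscle attachment geometry: jaw opening rotates the lower jaw
        # ventrally about the jaw joints, closure dorsally — so the opener
        # pulls its anterior-shaft insertion ventrally (slightly posteriorly)
        # and the adductor pulls the mid-shaft dorsally. Origins are direction
        # landmarks one element-length away; only the unit vector matters.
        "muscles": {
            side_name: {
                "adductor_insertion": [
                    float(x_a + 0.5 * shaft_len),
                    float(y_mid + side * 0.5 * (y_sym + y_lat)),
                    float(z0),
                ],
                "adductor_origin": [
                    float(x_a + 0.5 * shaft_len + 0.2 * L),
                    float(y_mid + side * 0.5 * (y_sym + y_lat)),
                    float(z0 + L),
                ],
                "opener_insertion": [
                    float(x_a + 0.25 * shaft_len),
                    float(y_mid + side * (y_sym + 0.25 * (y_lat - y_sym))),
                    float(z0),
                ],
                "opener_origin": [
                    float(x_a + 0.25 * shaft_len + 0.2 * L),
                    float(y_mid + side * (y_sym + 0.25 * (y_lat - y_sym))),
                    float(z0 - L),
                ],
            }
            for side, side_name in ((-1, "left"), (+1, "right"))
        },
    }
    return LabelVolume(labels, voxel_size=h, meta=meta)


# ---------------------------------------------------------------------------
# rendering and planted features


def render_stack(volume: LabelVolume, noise: NoiseModel) -> ImageStack:
    """Forward-render a label volume into a noisy bimodal grayscale stack."""
    if not (volume.labels != BACKGROUND).any():
        raise ValidationError("cannot render an empty volume")
    rng = substream(noise.seed, "render")
    img = np.where(
        volume.labels != BACKGROUND, noise.foreground_mean, noise.background_mean
    ).astype(np.float64)
    if noise.sd > 0:
        img = img + rng.normal(0.0, noise.sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return ImageStack(img.astype(np.float32), voxel_size=volume.voxel_size)


def plant_exostoses(
    volume: LabelVolume,
    k: int,
    blob_radius: float = 2.0,
    seed: int = 0,
    max_tries: int = 200,
) -> LabelVolume:
    """Plant ``k`` spherical exostosis blobs near, but disjoint from, the jaw.

    Each blob is a sphere of cartilage-labelled voxels separated from the main
    elements (and from other blobs) by at least one background voxel, so the
    protrusion counter recovers exactly ``k`` on noiseless input.
    """
    if k < 0:
        raise ValidationError("k must be non-negative")
    out = volume.copy()
    if k == 0:
        return out
    h = out.voxel_size
    rng = substream(seed, "exostoses")
    tissue = out.labels != BACKGROUND
    # distance from each voxel centre to the nearest tissue voxel centre (um)
    dist = ndimage.distance_transform_edt(~tissue, sampling=h)
    lo, hi = blob_radius + 2.0 * h, blob_radius + 8.0 * h
    cand = np.argwhere((dist > lo) & (dist < hi))
    if cand.size == 0:
        raise PlacementError("no background region available for exostoses")
    xs = (np.arange(out.shape[0]) + 0.5) * h
    ys = (np.arange(out.shape[1]) + 0.5) * h
    zs = (np.arange(out.shape[2]) + 0.5) * h
    X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < k:
        if tries >= max_tries * k:
            raise PlacementError(
                f"placed only {len(placed)}/{k} exostoses after {tries} tries"
            )
        tries += 1
        c_idx = cand[rng.integers(len(cand))]
        c = (c_idx + 0.5) * h
        if any(np.linalg.norm(c - p) <= 2 * blob_radius + 2.0 * h for p in placed):
            continue
        blob = _capsule(X, Y, Z, c, c, blob_radius)
        if not blob.any():
            continue
        out.labels[blob & (out.labels == BACKGROUND)] = EXOSTOSIS
        placed.append(c)
    return out


# ---------------------------------------------------------------------------
# cell outlines


def _ellipse_polygon(aspect: float, n_vertices: int) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([aspect * np.cos(theta), np.sin(theta)])


def synth_cell_outline(
    target_circularity: float,
    n_vertices: int = 64,
    seed: int | None = None,
) -> ClosedPolygon:
    """Closed simple polygon with circularity within 0.02 of the target.

    An ellipse outline is elongated until its discrete circularity matches the
    target (root-finding on the aspect ratio); the seed only applies a random
    rigid rotation, which circularity is invariant to.
    """
    if not 0.0 < target_circularity <= 1.0:
        raise ValidationError("target circularity must be in (0, 1]")
    if n_vertices < 3:
        raise ValidationError("polygon needs at least 3 vertices")

    def circ(aspect: float) -> float:
        return ClosedPolygon(_ellipse_polygon(aspect, n_vertices)).circularity

    c_max = circ(1.0)
    if target_circularity > c_max + 5e-3:
        raise ConvergenceError(
            f"target {target_circularity} unreachable with {n_vertices} vertices "
            f"(maximum {c_max:.4f})"
        )
    if target_circularity >= c_max:
        aspect = 1.0
    else:
        hi = 2.0
        while circ(hi) > target_circularity:
            hi *= 2.0
            if hi > 1e6:
                raise ConvergenceError("could not bracket the target circularity")
        aspect = optimize.brentq(
            lambda a: circ(a) - target_circularity, 1.0, hi, xtol=1e-10
        )
    verts = _ellipse_polygon(float(aspect), n_vertices)
    if seed is not None:
        rng = substream(seed, "cell-outline")
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rot = np.array(
            [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
        )
        verts = verts @ rot.T
    return ClosedPolygon(verts)


# ---------------------------------------------------------------------------
# force curves


def synth_force_curve(
    E: float,
    nu: float = afm.DEFAULT_NU,
    R: float = 5.0,
    F_adh: float = 0.5,
    delta_max: float = 50.0,
    n_points: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    nominal_R: float | None = None,
) -> afm.ForceCurve:
    """Generate a DMT force curve at modulus ``E`` (MPa).

    ``R`` is the *true* tip radius used by the forward model; ``nominal_R``
    (default: equal to ``R``) is what gets recorded in the curve metadata —
    letting tests emulate a miscalibrated tip for the relative method.
    """
    if E < 0:
        raise ValidationError("modulus must be non-negative")
    if not 0.0 <= nu < 0.5:
        raise ValidationError("Poisson ratio must be in [0, 0.5)")
    if R <= 0 or delta_max <= 0:
        raise ValidationError("tip radius and indentation range must be positive")
    if noise_sd < 0:
        raise ValidationError("noise sd must be non-negative")
    if n_points < 10:
        raise ValidationError("need at least 10 samples")
    delta = np.linspace(0.0, delta_max, n_points)
    e_star = E / (1.0 - nu**2)
    force = afm.dmt_force(delta, e_star, R, F_adh)
    if noise_sd > 0:
        rng = substream(seed, "force-curve")
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    return afm.ForceCurve(
        delta=delta,
        force=force,
        tip_radius=float(nominal_R if nominal_R is not None else R),
    )
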
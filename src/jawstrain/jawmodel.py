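"""The assembled jaw model and the 2x2 shape-versus-material experiment.

The question the factorial answers: when the mutant jaw differs from wild type
in both joint shape (broader neck and head, narrower joint space) and cartilage
stiffness (higher Young's modulus), which of the two drives the altered strain
environment at the joints? Each factorial cell crosses one shape preset with
one material preset, solves the jaw-closure and jaw-opening steps, and averages
maximum principal strain over the joint-interzone region. Main effects are mean
absolute cell contrasts:

    shape effect    = mean over materials of |mean(wt shape) - mean(mut shape)|
    material effect = mean over shapes    of |mean(wt mats)  - mean(mut mats)|

Boundary conditions follow the anatomical anchoring: the ceratohyal is fixed in
all axes, the base of the palatoquadrate in y and z. Muscle magnitudes are
placeholder config values; every shipped comparison is invariant to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import fem, imaging, synthgen
from .errors import PartialResultError, ValidationError
from .fem import DirichletBC, Material, MaterialSet, MuscleLoad
from .volume import CERATOHYAL, INTERZONE, PQ_LEFT, PQ_RIGHT

__all__ = [
    "ModelSpec",
    "JawModel",
    "CellResult",
    "FactorialResult",
    "default_materials",
    "default_muscles",
    "build_model",
    "run_factorial",
    "displacement_summary",
]

STEPS = ("closure", "opening")

#: E_Max threshold for the strain-spread metric, as a fraction of the
#: joint-region mean: an element "carries strain" if its E_Max exceeds this.
SPREAD_THRESHOLD = 0.10


def default_materials(genotype: str) -> MaterialSet:
    """Material preset per genotype, from the shipped config.

    Immature (near-joint) moduli are the measured AFM means (wt 4.15 MPa,
    mutant 7.4 MPa); hypertrophic values are config assumptions encoding the
    reported four-fold wt-mutant difference in mature regions.
    """
    from .io import load_packaged_yaml

    presets = load_packaged_yaml("materials.yaml")
    if genotype not in presets:
        raise ValidationError(
            f"unknown genotype '{genotype}' (have {sorted(presets)})"
        )
    p = presets[genotype]
    return MaterialSet(
        immature=Material(**p["immature"]),
        hypertrophic=Material(**p["hypertrophic"]),
        name=genotype,
    )


def default_muscles(volume_meta: dict, scale: float = 1.0) -> list[MuscleLoad]:
    """Muscle loads positioned from the generated geometry's landmarks."""
    from .io import load_packaged_yaml

    cfg = load_packaged_yaml("muscles.yaml")
    muscles = []
    for side in ("left", "right"):
        pts = volume_meta["muscles"][side]
        muscles.append(
            MuscleLoad(
                name=f"adductor_mandibulae_{side}",
                insertion=tuple(pts["adductor_insertion"]),
                origin=tuple(pts["adductor_origin"]),
                magnitude=scale * cfg["adductor_mandibulae"]["magnitude"],
                active_step=cfg["adductor_mandibulae"]["active_step"],
            )
        )
        muscles.append(
            MuscleLoad(
                name=f"jaw_opener_{side}",
                insertion=tuple(pts["opener_insertion"]),
                origin=tuple(pts["opener_origin"]),
                magnitude=scale * cfg["jaw_opener"]["magnitude"],
                active_step=cfg["jaw_opener"]["active_step"],
            )
        )
    return muscles


@dataclass
class ModelSpec:
    """Everything needed to assemble one jaw FE model."""

    shape: str | synthgen.ShapeParams = "wt"
    materials: str | MaterialSet = "wt"
    steps: tuple[str, ...] = STEPS
    muscle_scale: float = 1.0
    split_distance: float | None = None
    geometry_seed: int | None = None

    def resolve(self) -> tuple[synthgen.ShapeParams, MaterialSet]:
        shape = (
            synthgen.shape_preset(self.shape)
            if isinstance(self.shape, str)
            else self.shape
        )
        mats = (
            default_materials(self.materials)
            if isinstance(self.materials, str)
            else self.materials
        )
        return shape, mats


@dataclass
class JawModel:
    """Assembled FE problem: system, constraints, loads, analysis masks.

    ``joint_mask`` selects all joint-interzone tissue (the region whose strain
    average is the headline comparison); ``symphysis_mask`` and
    ``jaw_joint_mask`` are its anterior (Meckel's symphysis) and posterior
    (jaw joints) parts, reported separately because the mutant phenotype
    focalizes strain at the jaw joints.
    """

    system: fem.FESystem
    bcs: list[DirichletBC]
    muscles: list[MuscleLoad]
    joint_mask: np.ndarray
    symphysis_mask: np.ndarray
    jaw_joint_mask: np.ndarray
    spec: ModelSpec
    meta: dict = dc_field(default_factory=dict)

    def solve(self, step: str) -> fem.StrainField:
        return fem.solve_static(self.system, self.bcs, self.muscles, step=step)


def _element_nodes(mesh: fem.HexMesh, elem_mask: np.ndarray) -> np.ndarray:
    return np.unique(mesh.elems[elem_mask])


def build_model(spec: ModelSpec, volume=None) -> JawModel:
    """Generate geometry, split materials, mesh, and attach BCs and muscles.

    ``volume`` optionally supplies a pre-built labelled volume (e.g. from the
    pipeline's generate stage) instead of regenerating one from the preset.
    """
    shape, mats = spec.resolve()
    vol = (
        synthgen.build_parametric_jaw(shape, seed=spec.geometry_seed)
        if volume is None
        else volume
    )
    split = imaging.split_joint_region(vol, d=spec.split_distance)
    mesh = fem.voxel_to_hex_mesh(split)
    # recover element identity from the pre-split volume for BC placement
    orig = vol.labels[tuple(mesh.voxel_idx.T)]
    system = fem.assemble(mesh, mats)

    ch_nodes = _element_nodes(mesh, orig == CERATOHYAL)
    if len(ch_nodes) == 0:
        raise ValidationError("ceratohyal anchor region resolved to no nodes")
    pq_base_x = vol.meta["landmarks"]["pq_base_x"]
    centroids = mesh.element_centroids()
    pq_base = (np.isin(orig, (PQ_LEFT, PQ_RIGHT))) & (
        centroids[:, 0] >= pq_base_x - 2.0 * mesh.voxel_size
    )
    pq_nodes = _element_nodes(mesh, pq_base)
    if len(pq_nodes) == 0:
        raise ValidationError("palatoquadrate base region resolved to no nodes")
    bcs = [
        DirichletBC(nodes=ch_nodes, axes=(0, 1, 2)),
        DirichletBC(nodes=pq_nodes, axes=(1, 2)),
    ]
    muscles = default_muscles(vol.meta, scale=spec.muscle_scale)
    interzone = orig == INTERZONE
    lm = vol.meta["landmarks"]
    x_split = 0.5 * (lm["symphysis_x"] + lm["joint_x"])
    anterior = centroids[:, 0] < x_split
    return JawModel(
        system=system,
        bcs=bcs,
        muscles=muscles,
        joint_mask=interzone,
        symphysis_mask=interzone & anterior,
        jaw_joint_mask=interzone & ~anterior,
        spec=spec,
        meta=dict(vol.meta),
    )


@dataclass(frozen=True)
class CellResult:
    """Per-cell, per-step strain and displacement summaries."""

    shape: str
    materials: str
    step: str
    joint_e_max: float      # joint-interzone mean E_Max (all interzone tissue)
    joint_e_min: float      # joint-interzone mean E_Min
    symphysis_e_max: float  # Meckel's symphysis interzone mean E_Max
    jaw_joint_e_max: float  # jaw-joint interzone mean E_Max (focality metric)
    max_displacement: float
    spread_fraction: float  # fraction of elements with E_Max above threshold
    n_elements: int


@dataclass
class FactorialResult:
    """Complete 2x2 factorial with per-step main effects."""

    cells: dict[tuple[str, str, str], CellResult]  # (shape, materials, step)
    shapes: tuple[str, ...]
    materials: tuple[str, ...]
    steps: tuple[str, ...]

    def __post_init__(self) -> None:
        want = len(self.shapes) * len(self.materials) * len(self.steps)
        if len(self.cells) != want:
            raise ValidationError(
                f"incomplete factorial: {len(self.cells)} cells, expected {want}"
            )

    def cell(self, shape: str, materials: str, step: str) -> CellResult:
        return self.cells[(shape, materials, step)]

    def effects(self, step: str, quantity: str = "joint_e_max") -> dict[str, float]:
        """Main effects as mean absolute cell contrasts on ``quantity``."""
        get = lambda s, m: getattr(self.cell(s, m, step), quantity)
        s0, s1 = self.shapes
        m0, m1 = self.materials
        shape_effect = float(
            np.mean([abs(get(s0, m) - get(s1, m)) for m in self.materials])
        )
        material_effect = float(
            np.mean([abs(get(s, m0) - get(s, m1)) for s in self.shapes])
        )
        return {"shape_effect": shape_effect, "material_effect": material_effect}

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(c) for c in self.cells.values()]
        return (
            pd.DataFrame(rows)
            .sort_values(["step", "shape", "materials"])
            .reset_index(drop=True)
        )


def run_factorial(
    shapes: tuple[str, ...] = ("wt", "mutant"),
    materials: tuple[str, ...] = ("wt", "mutant"),
    steps: tuple[str, ...] = STEPS,
    geometry_seed: int | None = None,
    muscle_scale: float = 1.0,
    split_distance: float | None = None,
) -> FactorialResult:
    """Run the shape x material factorial and summarize joint strains.

    Geometry (and its assembled BCs/loads) is built once per shape; each
    material preset reuses it with a fresh stiffness assembly. A failing cell
    raises :class:`PartialResultError` carrying the completed cells.
    """
    cells: dict[tuple[str, str, str], CellResult] = {}
    for s in shapes:
        try:
            base = build_model(
                ModelSpec(
                    shape=s,
                    materials=materials[0],
                    geometry_seed=geometry_seed,
                    muscle_scale=muscle_scale,
                    split_distance=split_distance,
                    steps=steps,
                )
            )
        except Exception as exc:
            raise PartialResultError(
                f"geometry for shape '{s}' failed: {exc}", completed=cells
            ) from exc
        for m in materials:
            try:
                system = (
                    base.system
                    if m == materials[0]
                    else fem.assemble(base.system.mesh, default_materials(m))
                )
                model = JawModel(
                    system=system,
                    bcs=base.bcs,
                    muscles=base.muscles,
                    joint_mask=base.joint_mask,
                    symphysis_mask=base.symphysis_mask,
                    jaw_joint_mask=base.jaw_joint_mask,
                    spec=ModelSpec(shape=s, materials=m, steps=steps),
                    meta=base.meta,
                )
                for step in steps:
                    f = model.solve(step)
                    joint_mean = fem.region_mean(f, model.joint_mask, "E_Max")
                    spread = float(
                        np.mean(f.e_max > SPREAD_THRESHOLD * joint_mean)
                    ) if joint_mean > 0 else 0.0
                    cells[(s, m, step)] = CellResult(
                        shape=s,
                        materials=m,
                        step=step,
                        joint_e_max=joint_mean,
                        joint_e_min=fem.region_mean(f, model.joint_mask, "E_Min"),
                        symphysis_e_max=fem.region_mean(
                            f, model.symphysis_mask, "E_Max"
                        ),
                        jaw_joint_e_max=fem.region_mean(
                            f, model.jaw_joint_mask, "E_Max"
                        ),
                        max_displacement=float(f.u_mag.max()),
                        spread_fraction=spread,
                        n_elements=f.mesh.n_elems,
                    )
            except PartialResultError:
                raise
            except Exception as exc:
                raise PartialResultError(
                    f"cell (shape={s}, materials={m}) failed: {exc}",
                    completed=cells,
                ) from exc
    return FactorialResult(
        cells=cells, shapes=tuple(shapes), materials=tuple(materials), steps=tuple(steps)
    )


def displacement_summary(result: FactorialResult) -> pd.DataFrame:
    """Max-displacement table per cell, checking the stiffness monotonicity.

    With loads fixed, a material set that is stiffer in every region must give
    strictly smaller maximum displacement at the same shape; a violation means
    a solver defect and raises.
    """
    rows = []
    for (s, m, step), c in result.cells.items():
        rows.append(
            {"shape": s, "materials": m, "step": step, "max_displacement": c.max_displacement}
        )
    df = pd.DataFrame(rows).sort_values(["step", "shape", "materials"]).reset_index(drop=True)

    mats = {m: default_materials(m) for m in result.materials}
    for step in result.steps:
        for s in result.shapes:
            for m0 in result.materials:
                for m1 in result.materials:
                    a, b = mats[m0], mats[m1]
                    strictly_stiffer = (
                        a.immature.E >= b.immature.E
                        and a.hypertrophic.E >= b.hypertrophic.E
                        and (a.immature.E > b.immature.E or a.hypertrophic.E > b.hypertrophic.E)
                    )
                    if strictly_stiffer:
                        da = result.cell(s, m0, step).max_displacement
                        db = result.cell(s, m1, step).max_displacement
                        if not da < db:
                            raise ValidationError(
                                f"monotonicity violated at shape={s}, step={step}: "
                                f"stiffer '{m0}' gave displacement {da} >= {db}"
                            )
    return df
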
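"""Small-strain isotropic linear elasticity on voxel-derived hexahedral meshes.

One trilinear 8-node hexahedron per cartilage voxel, 2x2x2 Gauss quadrature
(exact for the trilinear element on a cube), two material regions (immature /
hypertrophic cartilage). Because every element is the same cube, the element
stiffness is computed once per region and the global matrix assembled in one
vectorized scatter. Displacements solve K u = f with Dirichlet rows
eliminated; strains are evaluated from the displacement gradient at element
centroids and principal strains (E_Max >= E_Mid >= E_Min) are the eigenvalues
of the symmetric strain tensor.

Units: lengths um, forces uN, moduli MPa (1 MPa = 1 uN/um^2), so no conversion
factors appear anywhere in the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .errors import (
    MeshError,
    PlacementError,
    RigidBodyError,
    ValidationError,
)
from .volume import (
    CERATOHYAL,
    HYPERTROPHIC,
    IMMATURE,
    INTERZONE,
    MC_LEFT,
    MC_RIGHT,
    PQ_LEFT,
    PQ_RIGHT,
    LabelVolume,
)

__all__ = [
    "Material",
    "MaterialSet",
    "HexMesh",
    "DirichletBC",
    "MuscleLoad",
    "FESystem",
    "StrainField",
    "voxel_to_hex_mesh",
    "hex_stiffness",
    "assemble",
    "solve_static",
    "principal_strains",
    "region_mean",
    "reaction_sums",
]

REGION_IMMATURE = 0
REGION_HYPERTROPHIC = 1
REGION_NAMES = {REGION_IMMATURE: "immature", REGION_HYPERTROPHIC: "hypertrophic"}

#: Local node offsets of the 8-node hexahedron (VTK ordering).
_HEX_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)
_XI_SIGNS = 2.0 * _HEX_OFFSETS - 1.0  # corner signs in [-1, 1]^3


@dataclass(frozen=True)
class Material:
    """Isotropic elastic constants: Young's modulus (MPa), Poisson ratio."""

    E: float
    nu: float = 0.3

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValidationError("Young's modulus must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValidationError("Poisson ratio must be in [0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        mu = self.E / (2.0 * (1.0 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class MaterialSet:
    """Per-region materials for the two-material cartilage model."""

    immature: Material
    hypertrophic: Material
    name: str = "custom"

    def by_region(self, region: int) -> Material:
        return (self.immature, self.hypertrophic)[region]


@dataclass
class HexMesh:
    """Voxel-derived hexahedral mesh (nodes in um)."""

    nodes: np.ndarray        # (n, 3)
    elems: np.ndarray        # (m, 8) node indices, VTK hexahedron ordering
    region: np.ndarray       # (m,) REGION_IMMATURE / REGION_HYPERTROPHIC
    source_label: np.ndarray  # (m,) original voxel label
    voxel_size: float
    voxel_idx: np.ndarray | None = None  # (m, 3) source voxel of each element
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    @property
    def element_volume(self) -> float:
        return self.voxel_size**3

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)


#: Default label -> region map: the split volume's near-joint cartilage and
#: the interzone tissue are "immature"; everything else load-bearing is the
#: hypertrophic main body. Exostoses are intentionally absent: they are
#: disconnected by construction and would make the stiffness singular.
DEFAULT_REGION_MAP = {
    IMMATURE: REGION_IMMATURE,
    INTERZONE: REGION_IMMATURE,
    HYPERTROPHIC: REGION_HYPERTROPHIC,
    MC_LEFT: REGION_HYPERTROPHIC,
    MC_RIGHT: REGION_HYPERTROPHIC,
    PQ_LEFT: REGION_HYPERTROPHIC,
    PQ_RIGHT: REGION_HYPERTROPHIC,
    CERATOHYAL: REGION_HYPERTROPHIC,
}


def voxel_to_hex_mesh(
    volume: LabelVolume, region_map: dict[int, int] | None = None
) -> HexMesh:
    """One hexahedral element per cartilage voxel, nodes shared on faces."""
    rmap = DEFAULT_REGION_MAP if region_map is None else region_map
    mask = np.isin(volume.labels, list(rmap))
    if not mask.any():
        raise MeshError("no cartilage voxels to mesh")
    vox = np.argwhere(mask)  # (m, 3)
    # corner grid indices for every element: (m, 8, 3)
    corners = vox[:, None, :] + _HEX_OFFSETS[None, :, :]
    shape = np.asarray(volume.shape) + 1
    flat = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), shape
    )
    uniq, inv = np.unique(flat, return_inverse=True)
    elems = inv.reshape(-1, 8).astype(np.int64)
    node_idx = np.column_stack(np.unravel_index(uniq, shape))
    nodes = node_idx.astype(float) * volume.voxel_size
    labels = volume.labels[mask]
    lut = np.zeros(int(volume.labels.max()) + 1, dtype=np.int8)
    for lab, reg in rmap.items():
        if lab <= volume.labels.max():
            lut[lab] = reg
    return HexMesh(
        nodes=nodes,
        elems=elems,
        region=lut[labels],
        source_label=labels.astype(np.int16),
        voxel_size=volume.voxel_size,
        voxel_idx=vox,
        meta=dict(volume.meta),
    )


# ---------------------------------------------------------------------------
# element matrices


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN/dxi for all 8 shape functions at local point xi; shape (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        s = _XI_SIGNS[a]
        g[a, 0] = 0.125 * s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2])
        g[a, 1] = 0.125 * s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2])
        g[a, 2] = 0.125 * s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1])
    return g


def _b_matrix(dndx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 24), engineering shear convention."""
    B = np.zeros((6, 24))
    for a in range(8):
        dx, dy, dz = dndx[a]
        c = 3 * a
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c] = dy
        B[3, c + 1] = dx
        B[4, c + 1] = dz
        B[4, c + 2] = dy
        B[5, c] = dz
        B[5, c + 2] = dx
    return B


def _d_matrix(material: Material) -> np.ndarray:
    lam, mu = material.lame
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2.0 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def hex_stiffness(material: Material, h: float) -> np.ndarray:
    """Element stiffness (24, 24) of a cube hexahedron of side ``h``."""
    if h <= 0:
        raise ValidationError("element size must be positive")
    D = _d_matrix(material)
    g = 1.0 / np.sqrt(3.0)
    detj = (h / 2.0) ** 3
    Ke = np.zeros((24, 24))
    for sx in (-g, g):
        for sy in (-g, g):
            for sz in (-g, g):
                dndx = _shape_gradients(np.array([sx, sy, sz])) * (2.0 / h)
                B = _b_matrix(dndx)
                Ke += B.T @ D @ B * detj
    return 0.5 * (Ke + Ke.T)


def centroid_b_matrix(h: float) -> np.ndarray:
    """B at the element centroid, used for strain recovery."""
    dndx = _shape_gradients(np.zeros(3)) * (2.0 / h)
    return _b_matrix(dndx)


# ---------------------------------------------------------------------------
# assembly and solution


@dataclass
class FESystem:
    """Assembled global stiffness with its mesh and materials."""

    K: sparse.csr_matrix
    mesh: HexMesh
    materials: MaterialSet

    @property
    def n_dof(self) -> int:
        return 3 * self.mesh.n_nodes


def assemble(mesh: HexMesh, materials: MaterialSet) -> FESystem:
    """Assemble the global stiffness (symmetric; 6 rigid-body null modes)."""
    h = mesh.voxel_size
    ke = np.stack(
        [hex_stiffness(materials.immature, h), hex_stiffness(materials.hypertrophic, h)]
    )
    edof = (mesh.elems[:, :, None] * 3 + np.arange(3)).reshape(-1, 24)
    data = ke[mesh.region]  # (m, 24, 24)
    rows = np.broadcast_to(edof[:, :, None], data.shape)
    cols = np.broadcast_to(edof[:, None, :], data.shape)
    n = 3 * mesh.n_nodes
    K = sparse.coo_matrix(
        (data.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)
    ).tocsr()
    return FESystem(K=K, mesh=mesh, materials=materials)


@dataclass(frozen=True)
class DirichletBC:
    """Prescribed displacement on a node set.

    ``value`` is a scalar applied to every (node, axis) pair, or a callable
    mapping node coordinates (k, 3) to prescribed displacements (k, 3) of
    which only the constrained axes are used.
    """

    nodes: np.ndarray
    axes: tuple[int, ...] = (0, 1, 2)
    value: float | Callable[[np.ndarray], np.ndarray] = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=np.int64))
        if len(self.nodes) == 0:
            raise ValidationError("Dirichlet BC with empty node set")
        if not set(self.axes) <= {0, 1, 2}:
            raise ValidationError("axes must be a subset of {0, 1, 2}")


@dataclass(frozen=True)
class MuscleLoad:
    """Point muscle load: magnitude (uN) applied at the node nearest the
    insertion, directed along the unit vector insertion -> origin."""

    name: str
    insertion: tuple[float, float, float]
    origin: tuple[float, float, float]
    magnitude: float
    active_step: str = "opening"

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValidationError("muscle magnitude must be non-negative")
        if np.allclose(self.insertion, self.origin):
            raise ValidationError(f"muscle '{self.name}': insertion equals origin")

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.origin, dtype=float) - np.asarray(self.insertion, dtype=float)
        return d / np.linalg.norm(d)


@dataclass
class StrainField:
    """Solution of one static step: displacements, strains, principals."""

    mesh: HexMesh
    u: np.ndarray                 # (n, 3) nodal displacements, um
    strain: np.ndarray            # (m, 3, 3) symmetric small-strain tensors
    principal: np.ndarray | None = None  # (m, 3), descending: E_Max, E_Mid, E_Min
    f: np.ndarray | None = None   # (3n,) applied load vector
    fixed_dofs: np.ndarray | None = None

    @property
    def e_max(self) -> np.ndarray:
        if self.principal is None:
            raise ValidationError("call principal_strains first")
        return self.principal[:, 0]

    @property
    def e_min(self) -> np.ndarray:
        if self.principal is None:
            raise ValidationError("call principal_strains first")
        return self.principal[:, 2]

    @property
    def u_mag(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)


def build_load_vector(
    mesh: HexMesh,
    loads: Sequence[MuscleLoad],
    step: str,
    placement_tol: float | None = None,
) -> np.ndarray:
    """Nodal force vector for the muscles active in ``step``."""
    tol = 2.0 * mesh.voxel_size if placement_tol is None else placement_tol
    f = np.zeros(3 * mesh.n_nodes)
    active = [m for m in loads if m.active_step == step]
    if not active:
        return f
    tree = cKDTree(mesh.nodes)
    for m in active:
        dist, idx = tree.query(np.asarray(m.insertion, dtype=float))
        if dist > tol:
            raise PlacementError(
                f"muscle '{m.name}': no mesh node within {tol} um of its "
                f"insertion point (nearest at {dist:.2f} um)"
            )
        f[3 * idx : 3 * idx + 3] += m.magnitude * m.direction
    return f


def solve_static(
    system: FESystem,
    bcs: Sequence[DirichletBC],
    loads: Sequence[MuscleLoad] = (),
    step: str = "opening",
    nodal_forces: np.ndarray | None = None,
    rel_tol: float = 1e-8,
) -> StrainField:
    """Solve one static step with Dirichlet elimination and a direct solver.

    Raises :class:`RigidBodyError` when the constrained system is singular
    (insufficient constraints leave rigid-body freedom).
    """
    mesh, K = system.mesh, system.K
    n = system.n_dof
    f = np.zeros(n)
    if nodal_forces is not None:
        f += np.asarray(nodal_forces, dtype=float)
    f += build_load_vector(mesh, loads, step)

    fixed = np.zeros(n, dtype=bool)
    u = np.zeros(n)
    for bc in bcs:
        if bc.nodes.max() >= mesh.n_nodes:
            raise ValidationError("BC node index out of range")
        if callable(bc.value):
            vals = np.asarray(bc.value(mesh.nodes[bc.nodes]), dtype=float)
        else:
            vals = np.full((len(bc.nodes), 3), float(bc.value))
        for ax in bc.axes:
            dofs = 3 * bc.nodes + ax
            fixed[dofs] = True
            u[dofs] = vals[:, ax]
    if not fixed.any():
        raise RigidBodyError("no constraints: system has rigid-body freedom")

    free = ~fixed
    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, fixed] @ u[fixed]
    if free.any():
        try:
            lu = splu(Kff)
        except RuntimeError as exc:  # exactly singular factor
            raise RigidBodyError(
                f"constrained stiffness is singular ({exc}); "
                "check that every body is anchored in all axes"
            ) from exc
        uf = lu.solve(rhs)
        rhs_norm = np.linalg.norm(rhs)
        if rhs_norm > 0:
            rel = np.linalg.norm(Kff @ uf - rhs) / rhs_norm
            if not np.isfinite(rel) or rel > max(rel_tol, 1e-6):
                raise RigidBodyError(
                    f"solver residual {rel:.2e} exceeds tolerance; system is "
                    "ill-posed (likely missing constraints)"
                )
        u[free] = uf

    # centroid strains
    B0 = centroid_b_matrix(mesh.voxel_size)
    ue = u.reshape(-1, 3)[mesh.elems].reshape(mesh.n_elems, 24)
    voigt = ue @ B0.T  # (m, 6): exx eyy ezz gxy gyz gxz
    eps = np.zeros((mesh.n_elems, 3, 3))
    eps[:, 0, 0] = voigt[:, 0]
    eps[:, 1, 1] = voigt[:, 1]
    eps[:, 2, 2] = voigt[:, 2]
    eps[:, 0, 1] = eps[:, 1, 0] = 0.5 * voigt[:, 3]
    eps[:, 1, 2] = eps[:, 2, 1] = 0.5 * voigt[:, 4]
    eps[:, 0, 2] = eps[:, 2, 0] = 0.5 * voigt[:, 5]

    field = StrainField(
        mesh=mesh, u=u.reshape(-1, 3), strain=eps, f=f, fixed_dofs=np.flatnonzero(fixed)
    )
    return principal_strains(field, system=None)


def principal_strains(field: StrainField, system: FESystem | None = None) -> StrainField:
    """Augment a strain field with sorted principal strains (descending)."""
    eps = field.strain
    if not np.allclose(eps, np.transpose(eps, (0, 2, 1)), atol=1e-12):
        raise ValidationError("strain tensors must be symmetric")
    vals = np.linalg.eigvalsh(eps)  # ascending
    field.principal = vals[:, ::-1]
    return field


def region_mean(field: StrainField, mask: np.ndarray, quantity: str) -> float:
    """Element-volume-weighted mean of a strain/displacement quantity.

    ``quantity`` is one of ``"E_Max"``, ``"E_Min"``, ``"|u|"`` (nodal
    magnitudes averaged per element). With a uniform voxel mesh the volume
    weighting reduces to a plain mean, but the weighted form is kept for
    future non-uniform meshes.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (field.mesh.n_elems,):
        raise ValidationError("mask must be per-element")
    if not mask.any():
        raise ValidationError("empty region mask")
    if quantity == "E_Max":
        q = field.e_max
    elif quantity == "E_Min":
        q = field.e_min
    elif quantity == "|u|":
        q = field.u_mag[field.mesh.elems].mean(axis=1)
    else:
        raise ValidationError(f"unknown quantity '{quantity}'")
    vols = np.full(field.mesh.n_elems, field.mesh.element_volume)
    return float(np.sum(vols[mask] * q[mask]) / np.sum(vols[mask]))


def reaction_sums(system: FESystem, field: StrainField) -> np.ndarray:
    """Per-axis sums of reaction forces at the constrained DOFs (uN)."""
    if field.f is None or field.fixed_dofs is None:
        raise ValidationError("field does not carry load/constraint bookkeeping")
    r = system.K @ field.u.ravel() - field.f
    out = np.zeros(3)
    for ax in range(3):
        sel = field.fixed_dofs[field.fixed_dofs % 3 == ax]
        out[ax] = r[sel].sum()
    return out
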
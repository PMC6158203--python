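"""File-format adapters: TIFF stacks, label volumes, legacy VTK, CSV, YAML.

All deliverable formats are plain: multi-page TIFF for stacks, integer TIFF
plus a JSON sidecar (voxel size, label dictionary, metadata) for label volumes,
legacy ASCII VTK unstructured grids for meshes and fields, CSV with '.'
decimal / comma separator / header row for tables. Round trips are lossless
for labels, meshes and tables; floats are written with repr precision.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ValidationError
from .fem import HexMesh, StrainField
from .synthgen import ImageStack
from .volume import LABEL_NAMES, LabelVolume

__all__ = [
    "load_packaged_yaml",
    "write_stack",
    "read_stack",
    "write_labels",
    "read_labels",
    "write_vtk",
    "read_vtk_mesh",
    "write_table",
    "read_table",
    "write_force_curve",
    "read_force_curve",
]


def load_packaged_yaml(name: str) -> dict:
    """Load a YAML preset shipped inside the package's configs directory."""
    text = resources.files("jawstrain.configs").joinpath(name).read_text()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# image stacks and label volumes (TIFF pages are z slices)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    # store as (z, x, y) pages
    tifffile.imwrite(str(path), np.moveaxis(stack.intensities, 2, 0))
    _write_sidecar(path, {"voxel_size_um": stack.voxel_size, "kind": "grayscale"})


def read_stack(path: str | Path) -> ImageStack:
    arr = tifffile.imread(str(path))
    side = _read_sidecar(path)
    return ImageStack(np.moveaxis(arr, 0, 2), voxel_size=side.get("voxel_size_um", 1.0))


def write_labels(path: str | Path, vol: LabelVolume) -> None:
    tifffile.imwrite(str(path), np.moveaxis(vol.labels, 2, 0).astype(np.uint8))
    _write_sidecar(
        path,
        {
            "voxel_size_um": vol.voxel_size,
            "kind": "labels",
            "label_names": {str(k): v for k, v in LABEL_NAMES.items()},
            "meta": _jsonable(vol.meta),
        },
    )


def read_labels(path: str | Path) -> LabelVolume:
    arr = tifffile.imread(str(path)).astype(np.uint8)
    side = _read_sidecar(path)
    return LabelVolume(
        np.moveaxis(arr, 0, 2),
        voxel_size=side.get("voxel_size_um", 1.0),
        meta=side.get("meta", {}),
    )


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def _write_sidecar(path: str | Path, payload: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _read_sidecar(path: str | Path) -> dict:
    p = _sidecar_path(path)
    if not p.exists():
        return {}
    try:
        return json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed sidecar {p}: {exc}") from None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# legacy VTK unstructured grids (ASCII): hex meshes with optional fields


def write_vtk(
    path: str | Path,
    mesh: HexMesh,
    field: StrainField | None = None,
) -> None:
    """Write the mesh (and, if given, displacements and principal strains)."""
    lines = [
        "# vtk DataFile Version 3.0",
        "jawstrain voxel hexahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(repr(float(c)) for c in p) for p in mesh.nodes]
    m = mesh.n_elems
    lines.append(f"CELLS {m} {m * 9}")
    lines += ["8 " + " ".join(str(int(i)) for i in e) for e in mesh.elems]
    lines.append(f"CELL_TYPES {m}")
    lines += ["12"] * m  # VTK_HEXAHEDRON
    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(r)) for r in mesh.region]
    if field is not None:
        if field.principal is not None:
            for name, col in (("E_Max", 0), ("E_Mid", 1), ("E_Min", 2)):
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [repr(float(v)) for v in field.principal[:, col]]
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement double")
        lines += [" ".join(repr(float(c)) for c in u) for u in field.u]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_mesh(path: str | Path) -> HexMesh:
    """Read back a legacy-VTK hexahedral mesh written by :func:`write_vtk`."""
    tokens: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines()):
        if lineno in (0, 1) or line.strip() in ("ASCII", "DATASET UNSTRUCTURED_GRID"):
            continue
        tokens.extend(line.split())
    pos = 0

    def expect(word: str) -> None:
        nonlocal pos
        if tokens[pos] != word:
            raise ValidationError(
                f"malformed VTK file {path}: expected '{word}' at token {pos}, "
                f"got '{tokens[pos]}'"
            )
        pos += 1

    expect("POINTS")
    n = int(tokens[pos]); pos += 2  # count + dtype
    nodes = np.array(tokens[pos : pos + 3 * n], dtype=float).reshape(n, 3)
    pos += 3 * n
    expect("CELLS")
    m = int(tokens[pos]); pos += 2  # count + total size
    cells = np.array(tokens[pos : pos + 9 * m], dtype=np.int64).reshape(m, 9)
    if not np.all(cells[:, 0] == 8):
        raise ValidationError(f"non-hexahedral cell in {path}")
    pos += 9 * m
    expect("CELL_TYPES")
    pos += 1 + m
    region = np.zeros(m, dtype=np.int8)
    if pos < len(tokens) and tokens[pos] == "CELL_DATA":
        pos += 2  # CELL_DATA m
        expect("SCALARS")
        pos += 3  # name dtype ncomp
        expect("LOOKUP_TABLE")
        pos += 1
        region = np.array(tokens[pos : pos + m], dtype=np.int8)
    h = float(np.min(np.diff(np.unique(nodes[:, 0])))) if n > 1 else 1.0
    return HexMesh(
        nodes=nodes,
        elems=cells[:, 1:],
        region=region,
        source_label=np.zeros(m, dtype=np.int16),
        voxel_size=h,
    )


# ---------------------------------------------------------------------------
# tables and force curves (CSV, '.' decimal, comma separator, header row)


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path, allow_nan: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if not allow_nan and df.isna().any().any():
        cell = np.argwhere(df.isna().values)[0]
        raise ValidationError(
            f"NaN cell in {path} at row {cell[0]}, column '{df.columns[cell[1]]}' "
            "(pass allow_nan=True to accept)"
        )
    return df


def write_force_curve(path: str | Path, curve) -> None:
    write_table(
        path, pd.DataFrame({"delta_nm": curve.delta, "force_nN": curve.force})
    )


def read_force_curve(path: str | Path, tip_radius: float = 5.0):
    from .afm import ForceCurve

    df = read_table(path)
    if list(df.columns[:2]) != ["delta_nm", "force_nN"]:
        raise ValidationError(
            f"{path}: expected columns delta_nm, force_nN, got {list(df.columns)}"
        )
    return ForceCurve(
        delta=df["delta_nm"].to_numpy(),
        force=df["force_nN"].to_numpy(),
        tip_radius=tip_radius,
    )
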
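"""File formats: NIfTI volumes, Abaqus-dialect INP meshes, VTU, CSV curves.

Volumes travel as NIfTI with the voxel spacing in the affine and the bone
mask as a companion ``*_mask`` image of 0/1.  Meshes are written in a
small Abaqus INP dialect (``*NODE``, ``*ELEMENT TYPE=C3D4``, ``*NSET``,
per-bin ``*MATERIAL`` with ``*ELASTIC`` and a single-row ``*PLASTIC`` for
perfect plasticity) that this package can read back; element densities
and the load case go in a JSON sidecar.  VTU output is the plain ASCII
XML unstructured-grid flavor, readable by ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .material import MaterialCard
from .meshing import TetMesh
from .phantom import VoxelVolume
from .postprocess import LoadDisplacementCurve

# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def _mask_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + "_mask" + suffix)
    raise ValueError(f"volume path must end in .nii or .nii.gz, got {path}")


def save_volume(volume: VoxelVolume, path) -> Path:
    """Write HU values and the companion 0/1 mask as NIfTI images."""
    path = Path(path)
    affine = np.diag(np.append(volume.spacing, 1.0))
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))
    nib.save(
        nib.Nifti1Image(volume.mask.astype(np.uint8), affine), str(_mask_path(path))
    )
    return path


def load_volume(path) -> VoxelVolume:
    path = Path(path)
    img = nib.load(str(path))
    mask_img = nib.load(str(_mask_path(path)))
    affine = img.affine
    vol = VoxelVolume(
        values=np.asarray(img.dataobj, dtype=float),
        spacing=np.abs(np.diag(affine)[:3]),
        origin=affine[:3, 3],
        mask=np.asarray(mask_img.dataobj) > 0,
    )
    vol.validate()
    return vol


def save_density(values: np.ndarray, like: VoxelVolume, path) -> Path:
    """Write a voxel-aligned density grid re-using a volume's geometry."""
    path = Path(path)
    affine = np.diag(np.append(like.spacing, 1.0))
    affine[:3, 3] = like.origin
    nib.save(nib.Nifti1Image(values.astype(np.float32), affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Abaqus INP meshes
# ---------------------------------------------------------------------------


def write_inp(mesh: TetMesh, path, cards: MaterialCard | None = None, title: str = "vertefem mesh") -> Path:
    """Write the mesh (1-based ids) with node sets and optional materials.

    With binned cards, one ``*MATERIAL``/``*SOLID SECTION`` pair is
    emitted per bin; with continuous cards the per-element materials go
    to the JSON/CSV side channels instead (INP materials must be
    set-valued).
    """
    path = Path(path)
    lines = [f"*HEADING\n{title}\n", "*NODE\n"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}\n")
    lines.append("*ELEMENT, TYPE=C3D4, ELSET=ALL\n")
    for e, tet in enumerate(mesh.tets, start=1):
        n = tet + 1
        lines.append(f"{e}, {n[0]}, {n[1]}, {n[2]}, {n[3]}\n")
    for name, nodes in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={name.upper()}\n")
        ids = nodes + 1
        for k in range(0, len(ids), 12):
            lines.append(", ".join(str(v) for v in ids[k : k + 12]) + "\n")
    if cards is not None and cards.bin_id is not None:
        for b in np.unique(cards.bin_id):
            sel = np.nonzero(cards.bin_id == b)[0]
            lines.append(f"*ELSET, ELSET=BIN{b}\n")
            ids = sel + 1
            for k in range(0, len(ids), 12):
                lines.append(", ".join(str(v) for v in ids[k : k + 12]) + "\n")
            E, nu, sy = cards.E[sel[0]], cards.nu[sel[0]], cards.sigma_y[sel[0]]
            lines.append(f"*MATERIAL, NAME=MAT_BIN{b}\n*ELASTIC\n{E:.9g}, {nu:.9g}\n")
            lines.append(f"*PLASTIC\n{sy:.9g}, 0.\n")
            lines.append(f"*SOLID SECTION, ELSET=BIN{b}, MATERIAL=MAT_BIN{b}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path


def read_inp(path) -> tuple[TetMesh, MaterialCard | None]:
    """Read a mesh (and per-bin materials, if present) written by write_inp."""
    nodes, tets, nsets, elsets = [], [], {}, {}
    materials: dict[str, dict] = {}
    sections = []  # (elset, material)
    mode, current = None, None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                key = line.upper()
                opts = dict(
                    kv.split("=", 1) for kv in [p.strip() for p in key.split(",")[1:]] if "=" in kv
                )
                if key.startswith("*NODE"):
                    mode = "node"
                elif key.startswith("*ELEMENT"):
                    mode = "elem"
                elif key.startswith("*NSET"):
                    mode, current = "nset", opts["NSET"]
                    nsets[current] = []
                elif key.startswith("*ELSET"):
                    mode, current = "elset", opts["ELSET"]
                    elsets[current] = []
                elif key.startswith("*MATERIAL"):
                    mode, current = "material", opts["NAME"]
                    materials[current] = {}
                elif key.startswith("*ELASTIC"):
                    mode = "elastic"
                elif key.startswith("*PLASTIC"):
                    mode = "plastic"
                elif key.startswith("*SOLID SECTION"):
                    sections.append((opts["ELSET"], opts["MATERIAL"]))
                    mode = None
                else:
                    mode = None
                continue
            vals = [v for v in (s.strip() for s in line.split(",")) if v]
            if mode == "node":
                nodes.append([float(v) for v in vals[1:4]])
            elif mode == "elem":
                tets.append([int(v) - 1 for v in vals[1:5]])
            elif mode == "nset":
                nsets[current].extend(int(v) - 1 for v in vals)
            elif mode == "elset":
                elsets[current].extend(int(v) - 1 for v in vals)
            elif mode == "elastic":
                materials[current]["E"] = float(vals[0])
                materials[current]["nu"] = float(vals[1])
            elif mode == "plastic":
                materials[current].setdefault("sigma_y", float(vals[0]))
    mesh = TetMesh(
        nodes=np.array(nodes),
        tets=np.array(tets, dtype=int),
        node_sets={k.lower(): np.array(sorted(v), dtype=int) for k, v in nsets.items()},
    )
    cards = None
    if sections:
        m = mesh.n_elements
        E = np.zeros(m)
        nu = np.zeros(m)
        sy = np.zeros(m)
        bin_id = np.zeros(m, dtype=int)
        for b, (elset, mat) in enumerate(sections):
            sel = np.array(elsets[elset], dtype=int)
            E[sel] = materials[mat]["E"]
            nu[sel] = materials[mat]["nu"]
            sy[sel] = materials[mat]["sigma_y"]
            bin_id[sel] = b
        cards = MaterialCard(E=E, nu=nu, sigma_y=sy, bin_id=bin_id)
    return mesh, cards


def write_material_csv(cards: MaterialCard, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "element_id": np.arange(len(cards)),
            "E": cards.E,
            "nu": cards.nu,
            "sigma_y": cards.sigma_y,
        }
    )
    if cards.bin_id is not None:
        df["bin_id"] = cards.bin_id
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# VTU (ASCII XML unstructured grid)
# ---------------------------------------------------------------------------


def write_vtu(mesh: TetMesh, path, point_data: dict | None = None, cell_data: dict | None = None) -> Path:
    """Minimal ASCII .vtu writer for tet meshes (VTK cell type 10)."""
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elements

    def data_array(name, arr, ncomp):
        body = "\n".join(
            " ".join(f"{v:.9g}" for v in np.atleast_1d(row)) for row in np.asarray(arr)
        )
        return (
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n</DataArray>\n'
        )

    parts = [
        '<?xml version="1.0"?>\n<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n',
        f'<UnstructuredGrid>\n<Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n',
        "<Points>\n",
        data_array("points", mesh.nodes, 3),
        "</Points>\n<Cells>\n",
        '<DataArray type="Int64" Name="connectivity" format="ascii">\n'
        + "\n".join(" ".join(str(i) for i in tet) for tet in mesh.tets)
        + "\n</DataArray>\n",
        '<DataArray type="Int64" Name="offsets" format="ascii">\n'
        + " ".join(str(4 * (i + 1)) for i in range(m))
        + "\n</DataArray>\n",
        '<DataArray type="UInt8" Name="types" format="ascii">\n'
        + " ".join("10" for _ in range(m))
        + "\n</DataArray>\n</Cells>\n",
    ]
    if point_data:
        parts.append("<PointData>\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            parts.append(data_array(name, arr, ncomp))
        parts.append("</PointData>\n")
    if cell_data:
        parts.append("<CellData>\n")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            parts.append(data_array(name, arr, 1))
        parts.append("</CellData>\n")
    parts.append("</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    with open(path, "w") as fh:
        fh.writelines(parts)
    return path


# ---------------------------------------------------------------------------
# curves and small JSON helpers
# ---------------------------------------------------------------------------


def write_curve_csv(curve: LoadDisplacementCurve, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"displacement_mm": curve.displacement, "load_kN": curve.load}
    ).to_csv(path, index=False)
    return path


def read_curve_csv(path) -> LoadDisplacementCurve:
    df = pd.read_csv(path)
    curve = LoadDisplacementCurve(
        displacement=df["displacement_mm"].to_numpy(), load=df["load_kN"].to_numpy()
    )
    curve.validate()
    return curve


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
    return path
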
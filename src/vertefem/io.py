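"""File I/O: NIfTI volumes with JSON sidecars, legacy-VTK field export."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fem import VoxelMesh
from .synth import LabeledVolume


def save_labeled_volume(volume: LabeledVolume, prefix: str | Path) -> None:
    """Write ``<prefix>_density.nii.gz``, ``<prefix>_labels.nii.gz`` and a
    JSON metadata sidecar; voxel spacing goes into the NIfTI header."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*volume.spacing, 1.0])
    for arr, suffix in ((volume.density, "density"), (volume.labels, "labels")):
        img = nib.Nifti1Image(np.asarray(arr), affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(prefix) + f"_{suffix}.nii.gz")
    meta = {k: v for k, v in volume.metadata.items()
            if isinstance(v, (str, int, float, bool, list, tuple, type(None)))}
    (prefix.parent / (prefix.name + "_meta.json")).write_text(json.dumps(meta, indent=1))


def load_labeled_volume(prefix: str | Path) -> LabeledVolume:
    prefix = Path(prefix)
    dens = nib.load(str(prefix) + "_density.nii.gz")
    labs = nib.load(str(prefix) + "_labels.nii.gz")
    meta_path = prefix.parent / (prefix.name + "_meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return LabeledVolume(
        density=np.asarray(dens.dataobj, dtype=np.float64),
        labels=np.asarray(labs.dataobj, dtype=np.uint8),
        spacing=tuple(float(z) for z in dens.header.get_zooms()[:3]),
        metadata=meta,
    )


def write_vtk(mesh: VoxelMesh, cell_data: dict[str, np.ndarray],
              path: str | Path) -> None:
    """Legacy ASCII VTK unstructured-grid export of hex elements + cell data.

    Inspection output (density/modulus/stress maps for a viewer); nothing in
    the pipeline reads it back.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_nodes, n_elem = mesh.n_nodes, mesh.n_elements
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvertefem voxel mesh\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n_nodes} float\n")
        np.savetxt(fh, mesh.nodes, fmt="%.6g")
        fh.write(f"CELLS {n_elem} {n_elem * 9}\n")
        cells = np.column_stack([np.full(n_elem, 8), mesh.connectivity])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {n_elem}\n")
        np.savetxt(fh, np.full(n_elem, 12), fmt="%d")  # VTK_HEXAHEDRON
        fh.write(f"CELL_DATA {n_elem}\n")
        for name, values in cell_data.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(values, dtype=float), fmt="%.6g")
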
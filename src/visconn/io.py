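"""Readers and writers: NIfTI volumes, FSL-style bval/bvec gradient tables,
TrackVis streamline files, a plain-text streamline dialect, sparse
connectivity matrices (Matrix Market), and JSON/YAML configs.

Conventions used throughout the package: world coordinates in mm via the
NIfTI affine, 0-based voxel indexing, half-open voxel boundaries around
voxel centers.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .dti import DiffusionVolume, ScalarMap, TensorField
from .tractography import FiberSet, Streamline

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_map",
    "write_map",
    "read_labels",
    "write_tensor_field",
    "read_tensor_field",
    "read_streamlines",
    "write_streamlines",
    "export_graph",
    "load_config",
    "save_config",
]


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(v) for v in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_dwi(nifti_path, bval_path, bvec_path) -> DiffusionVolume:
    """Load a 4D DWI NIfTI with its FSL-dialect gradient table.

    bvals: one whitespace-separated row of per-volume b-values.  bvecs:
    three rows (x, y, z) of per-volume direction components, in image
    coordinates.  Raises on any count mismatch, naming the offending file.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4D DWI volume")
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvals.shape[0] != data.shape[3]:
        raise ValueError(
            f"{bval_path}: {bvals.shape[0]} b-values for {data.shape[3]} volumes"
        )
    if bvecs.shape[0] != data.shape[3]:
        raise ValueError(
            f"{bvec_path}: {bvecs.shape[0]} directions for {data.shape[3]} volumes"
        )
    return DiffusionVolume(
        data=data,
        bvals=bvals,
        bvecs=bvecs,
        voxel_size=_voxel_size_from_affine(img.affine),
        affine=img.affine,
    )


def write_dwi(dwi: DiffusionVolume, nifti_path, bval_path, bvec_path) -> None:
    nib.save(nib.Nifti1Image(dwi.data, dwi.affine), str(nifti_path))
    np.savetxt(str(bval_path), dwi.bvals[None], fmt="%g")
    np.savetxt(str(bvec_path), dwi.bvecs.T, fmt="%.10g")


def write_map(scalar_map: ScalarMap, path) -> None:
    nib.save(nib.Nifti1Image(scalar_map.values, scalar_map.affine), str(path))


def read_map(path, name: str = "") -> ScalarMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar map")
    return ScalarMap(
        data,
        name or Path(str(path)).stem,
        voxel_size=_voxel_size_from_affine(img.affine),
        affine=img.affine,
    )


def read_labels(path) -> tuple[np.ndarray, np.ndarray]:
    """Integer-coded ROI label image; returns (labels, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label image must be integer-coded")
    return data.astype(np.int32), img.affine


def write_tensor_field(tfield: TensorField, path) -> None:
    """Six unique tensor elements as a 4D NIfTI (dxx dyy dzz dxy dxz dyz),
    with the validity mask packed as a 7th volume."""
    stacked = np.concatenate(
        [tfield.tensor, tfield.valid[..., None].astype(float)], axis=-1
    )
    nib.save(nib.Nifti1Image(stacked, tfield.affine), str(path))


def read_tensor_field(path) -> TensorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 7:
        raise ValueError(f"{path}: expected 7 volumes (6 tensor elements + mask)")
    tensor = data[..., :6]
    valid = data[..., 6] > 0.5
    from .dti import _tensor_elements_to_matrices

    evals, evecs = np.linalg.eigh(_tensor_elements_to_matrices(tensor))
    return TensorField(
        tensor=tensor,
        evals=evals[..., ::-1],
        evecs=evecs[..., :, ::-1],
        valid=valid,
        voxel_size=_voxel_size_from_affine(img.affine),
        affine=img.affine,
    )


# ---------------------------------------------------------------------------
# streamlines

_TEXT_MAGIC = "visconn-streamlines 1"


def write_streamlines(fibers: FiberSet, path) -> None:
    """Write fibers as TrackVis .trk or the plain-text dialect (by suffix)."""
    path = Path(str(path))
    if path.suffix == ".trk":
        tractogram = nib.streamlines.Tractogram(
            [s.points.astype(np.float32) for s in fibers],
            affine_to_rasmm=np.eye(4),
        )
        hdr = nib.streamlines.trk.TrkFile.create_empty_header()
        nib.streamlines.save(tractogram, str(path), header=hdr)
        return
    with open(path, "w") as fh:
        fh.write(_TEXT_MAGIC + "\n")
        fh.write(f"space {fibers.space}\n")
        for s in fibers:
            fh.write(f"fiber {s.points.shape[0]}\n")
            for pt in s.points:
                fh.write(f"{pt[0]:.9g} {pt[1]:.9g} {pt[2]:.9g}\n")


def read_streamlines(path) -> FiberSet:
    path = Path(str(path))
    if path.suffix == ".trk":
        trk = nib.streamlines.load(str(path))
        sls = [Streamline(points=np.asarray(pts, dtype=float)) for pts in trk.streamlines]
        return FiberSet(streamlines=sls, space="reference")
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _TEXT_MAGIC:
            raise ValueError(f"{path}: not a streamline text file")
        space_line = fh.readline().split()
        space = space_line[1] if len(space_line) == 2 else "reference"
        streamlines = []
        line = fh.readline()
        while line:
            tok = line.split()
            if tok[0] != "fiber":
                raise ValueError(f"{path}: malformed fiber header: {line!r}")
            npts = int(tok[1])
            pts = np.array(
                [[float(v) for v in fh.readline().split()] for _ in range(npts)]
            )
            streamlines.append(Streamline(points=pts))
            line = fh.readline()
    return FiberSet(streamlines=streamlines, space=space)


# ---------------------------------------------------------------------------
# graph export


def export_graph(graph, matrix_path, index_path) -> None:
    """Direct matrix as Matrix Market plus a TSV voxel-index table for the
    voxels that carry at least one connection."""
    import scipy.io as sio

    x = graph.direct.tocoo()
    sio.mmwrite(str(matrix_path), x)
    occupied = np.unique(np.concatenate([x.row, x.col])) if x.nnz else np.array([], int)
    ijk = graph.grid.unravel(occupied) if occupied.size else np.empty((0, 3), int)
    with open(index_path, "w") as fh:
        fh.write("linear_index\ti\tj\tk\n")
        for lin, (i, j, k) in zip(occupied, ijk):
            fh.write(f"{lin}\t{i}\t{j}\t{k}\n")


# ---------------------------------------------------------------------------
# configs


def load_config(path) -> dict:
    path = Path(str(path))
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def save_config(config: dict, path) -> None:
    path = Path(str(path))
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=False))
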
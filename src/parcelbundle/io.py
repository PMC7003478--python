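"""Readers/writers for standard formats and run outputs.

Coordinate convention: all internal geometry lives in 0-based, continuous
voxel coordinates of the label grid, voxel-center convention (point
(0, 0, 0) is the center of the corner voxel).  Streamline files (TRK/TCK)
store world (RAS mm) coordinates; the label volume's affine maps voxel
indices to world, so world -> voxel conversion applies its inverse.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram

from .fiber_core import FiberSet
from .parcellation import Parcellation

__all__ = [
    "read_labels",
    "write_labels",
    "read_streamlines",
    "write_streamlines",
    "write_single_outputs",
    "write_group_outputs",
]

_HEADER_NOTE = (
    "# coordinates: 0-based continuous voxel indices of the label grid, "
    "voxel-center convention\n"
)


def read_labels(path) -> Parcellation:
    """Load an integer 3-D NIfTI label volume (0 background, 1..L ROIs)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"label volume must be 3-D, got {data.ndim}-D")
    if not np.issubdtype(data.dtype, np.integer) and not np.allclose(data, np.round(data)):
        raise ValueError("label volume must be integer valued")
    return Parcellation(np.round(data).astype(np.int32), affine=img.affine)


def write_labels(parc: Parcellation, path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int16), parc.affine)
    nib.save(img, str(path))


def read_streamlines(path, parc: Parcellation) -> FiberSet:
    """Load TRK/TCK streamlines and map them to label-grid voxel coordinates."""
    path = Path(path)
    if path.suffix.lower() not in (".trk", ".tck"):
        raise ValueError(f"unknown streamline format {path.suffix!r} (expected .trk/.tck)")
    tf = nib.streamlines.load(str(path))
    world_to_vox = np.linalg.inv(parc.affine)
    arrays = []
    for sl in tf.streamlines:  # streamlines come out in world (RAS mm)
        pts = np.asarray(sl, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"{path}: streamline contains non-finite points")
        arrays.append(pts @ world_to_vox[:3, :3].T + world_to_vox[:3, 3])
    if not arrays:
        warnings.warn(f"{path}: empty streamline file")
        return FiberSet([], affine=world_to_vox, subject_id=path.stem)
    return FiberSet.from_arrays(arrays, affine=world_to_vox, subject_id=path.stem)


def write_streamlines(arrays, path, parc: Parcellation) -> None:
    """Write voxel-coordinate polylines to TRK or TCK (world coordinates)."""
    path = Path(path)
    A = parc.affine
    world = [np.asarray(a, dtype=float) @ A[:3, :3].T + A[:3, 3] for a in arrays]
    tracto = Tractogram(world, affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".trk":
        header = {
            "voxel_to_rasmm": A.astype(np.float32),
            "voxel_sizes": np.abs(np.diag(A)[:3]).astype(np.float32),
            "dimensions": np.asarray(parc.shape, dtype=np.int16),
            "voxel_order": "".join(nib.aff2axcodes(A)),
        }
        nib.streamlines.save(tracto, str(path), header=header)
    elif path.suffix.lower() == ".tck":
        nib.streamlines.save(tracto, str(path))
    else:
        raise ValueError(f"unknown streamline format {path.suffix!r}")


def _key_str(key) -> str:
    return f"{key[0]}-{key[1]}"


def _write_assignment_table(path, result) -> None:
    memb = result.memberships
    idx = np.argmax(memb.values, axis=1)
    with open(path, "w") as fh:
        fh.write(_HEADER_NOTE)
        fh.write("fiber_index\tl1\tl2\tmembership\treversed\n")
        for j, key in enumerate(result.assignment):
            if key is None:
                fh.write(f"{j}\tNA\tNA\t0\tNA\n")
                continue
            k = idx[j]
            rev = int(memb.orientations[j, k])
            fh.write(f"{j}\t{key[0]}\t{key[1]}\t{memb.values[j, k]:.6f}\t{rev}\n")


def write_single_outputs(outdir, result, parc: Parcellation, metrics: dict | None = None) -> None:
    """Assignment table, per-bundle + centroid streamlines, metrics, config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ValueError(f"cannot write to {out}")
    _write_assignment_table(out / "assignment.tsv", result)
    keys = result.model.keys()
    for key in keys:
        members = [result.fibers[j] for j, a in enumerate(result.assignment) if a == key]
        if members:
            write_streamlines(members, out / f"bundle_{_key_str(key)}.trk", parc)
    write_streamlines([result.model.centroids[k] for k in keys], out / "centroids.trk", parc)
    with open(out / "centroids.json", "w") as fh:
        json.dump({_key_str(k): result.model.centroids[k].tolist() for k in keys}, fh)
    with open(out / "trace.json", "w") as fh:
        json.dump(result.trace, fh, indent=1)
    with open(out / "config.json", "w") as fh:
        json.dump(vars(result.config), fh, indent=1, default=str)
    if metrics is not None:
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1)


def write_group_outputs(outdir, result, parc: Parcellation, metrics: dict | None = None) -> None:
    """Per-subject assignments, common + subject centroids, transforms, metrics."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for s, (sid, assignment, memb) in enumerate(
        zip(result.subject_ids, result.assignments, result.memberships)
    ):
        idx = np.argmax(memb.values, axis=1)
        with open(out / f"assignment_{sid}.tsv", "w") as fh:
            fh.write(_HEADER_NOTE)
            fh.write("fiber_index\tl1\tl2\tmembership\treversed\n")
            for j, key in enumerate(assignment):
                if key is None:
                    fh.write(f"{j}\tNA\tNA\t0\tNA\n")
                else:
                    k = idx[j]
                    fh.write(
                        f"{j}\t{key[0]}\t{key[1]}\t{memb.values[j, k]:.6f}\t"
                        f"{int(memb.orientations[j, k])}\n"
                    )
    common = result.model.centroids
    write_streamlines([common[k] for k in sorted(common)], out / "common_centroids.trk", parc)
    warped = result.warped_subject_centroids()  # common space, for pruning
    payload = {
        "common": {_key_str(k): common[k].tolist() for k in sorted(common)},
        "subjects": {
            result.subject_ids[s]: {
                _key_str(k): {
                    "points": warped[s][k].tolist(),
                    "native_points": curve.tolist(),
                    "mass": mass,
                }
                for k, (curve, mass) in cents.items()
            }
            for s, cents in result.subject_centroids.items()
        },
    }
    with open(out / "centroids.json", "w") as fh:
        json.dump(payload, fh)
    with open(out / "transforms.json", "w") as fh:
        json.dump(
            {
                result.subject_ids[s]: t.to_dict()
                for s, t in enumerate(result.model.transforms)
            },
            fh,
        )
    with open(out / "trace.json", "w") as fh:
        json.dump(result.trace, fh, indent=1)
    with open(out / "config.json", "w") as fh:
        json.dump(vars(result.config), fh, indent=1, default=str)
    if metrics is not None:
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1)
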
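"""Readers and writers for the pipeline's file formats.

NIfTI volumes through nibabel; gradient tables as FSL bval/bvec pairs or a
single TSV (bval, gx, gy, gz); streamlines as TRK or TCK (header affine
honored, everything converted to world mm / RAS on read); profiles and
metadata as TSV (long form is canonical); summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import streamlines as nibsl

from .mcm import GradientScheme
from .stats import BundleProfile
from .tractometry import Bundle, Streamline, TractProfile

__all__ = [
    "read_nifti", "write_nifti",
    "read_gradient_table", "write_gradient_table",
    "read_bundle", "write_bundle",
    "profiles_to_long", "read_profiles_long", "long_to_bundle_profile",
    "read_metadata", "write_json",
]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_gradient_table(bval_path, bvec_path=None) -> GradientScheme:
    """FSL bval/bvec pair (bvecs as 3 whitespace rows) or a single TSV with
    columns bval, gx, gy, gz."""
    bval_path = Path(bval_path)
    if bvec_path is None:
        df = pd.read_csv(bval_path, sep="\t")
        bvals = df["bval"].to_numpy(dtype=float)
        bvecs = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    else:
        bvals = np.loadtxt(bval_path, ndmin=1)
        bvecs = np.loadtxt(bvec_path, ndmin=2)
        # FSL convention: 3 rows (x, y, z) by n columns
        if bvecs.shape == (3, len(bvals)):
            bvecs = bvecs.T
        if bvecs.shape != (len(bvals), 3):
            raise ValueError("bvec table shape does not match bvals")
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def write_gradient_table(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def read_bundle(path, name: str | None = None) -> Bundle:
    """TRK or TCK file to a Bundle in world-mm (RAS) coordinates."""
    tf = nibsl.load(str(path))
    sls = tuple(Streamline(np.asarray(pts, dtype=float)) for pts in tf.streamlines)
    return Bundle(name=name or Path(path).stem, streamlines=sls)


def write_bundle(bundle: Bundle, path, affine: np.ndarray | None = None,
                 shape: tuple[int, int, int] = (10, 10, 10)) -> None:
    """Write as TRK (needs a reference grid) or TCK by extension."""
    path = str(path)
    seq = nibsl.ArraySequence([s.points for s in bundle.streamlines])
    if path.endswith(".tck"):
        tract = nibsl.Tractogram(seq, affine_to_rasmm=np.eye(4))
        nibsl.save(tract, path)
        return
    aff = affine if affine is not None else np.eye(4)
    header = {
        nibsl.trk.Field.VOXEL_TO_RASMM: aff.astype(np.float32),
        nibsl.trk.Field.VOXEL_SIZES: np.linalg.norm(aff[:3, :3], axis=0).astype(np.float32),
        nibsl.trk.Field.DIMENSIONS: np.asarray(shape, dtype=np.int16),
    }
    tract = nibsl.Tractogram(seq, affine_to_rasmm=np.eye(4))
    nibsl.save(tract, path, header=header)


# ---------------------------------------------------------------------------
# profiles


def profiles_to_long(profiles: dict[str, TractProfile], subject: str) -> pd.DataFrame:
    """Long-form table: subject, bundle, metric, node (1-based), value."""
    rows = []
    for bundle_name, prof in profiles.items():
        for metric, vals in prof.values.items():
            for node, v in enumerate(vals, start=1):
                rows.append((subject, bundle_name, metric, node, v))
    return pd.DataFrame(rows, columns=["subject", "bundle", "metric", "node", "value"])


def read_profiles_long(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def long_to_bundle_profile(df: pd.DataFrame, bundle: str,
                           metric_names=None) -> BundleProfile:
    """Assemble a subjects x nodes x metrics array from a long-form table."""
    sub = df[df["bundle"] == bundle]
    if sub.empty:
        raise ValueError(f"bundle {bundle!r} not present in the profile table")
    metrics = tuple(metric_names) if metric_names else tuple(pd.unique(sub["metric"]))
    subjects = tuple(pd.unique(sub["subject"]))
    nodes = int(sub["node"].max())
    data = np.full((len(subjects), nodes, len(metrics)), np.nan)
    sidx = {s: i for i, s in enumerate(subjects)}
    midx = {m: i for i, m in enumerate(metrics)}
    for row in sub.itertuples(index=False):
        data[sidx[row.subject], row.node - 1, midx[row.metric]] = row.value
    return BundleProfile(data=data, subject_ids=subjects, metric_names=metrics,
                         bundle=bundle)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "age", "sex", "center"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return meta


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
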
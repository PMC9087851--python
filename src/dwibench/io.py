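"""Reading and writing of NIfTI volumes, FSL bval/bvec text files, atlas tables,
design tables, and TSV report output with a JSON run manifest."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import AcquisitionScheme, DWIDataset, TractAtlas

log = logging.getLogger(__name__)

REPORT_COLUMNS = ["protocol", "pipeline", "sigma", "tract", "parameter", "feature"]


def read_bvals_bvecs(path_bval, path_bvec) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style bvals (one row) and bvecs (three rows)."""
    bvals = np.loadtxt(path_bval, ndmin=2)
    if bvals.shape[0] != 1:
        raise ValueError(f"bval file must be a single row, got shape {bvals.shape}")
    bvecs = np.loadtxt(path_bvec, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have three rows, got shape {bvecs.shape}")
    return bvals.ravel(), bvecs.T


def write_bvals_bvecs(bvals, bvecs, path_bval, path_bvec) -> None:
    np.savetxt(path_bval, np.asarray(bvals).reshape(1, -1), fmt="%.6g")
    np.savetxt(path_bvec, np.asarray(bvecs).T, fmt="%.10g")


def read_dwi(
    path_nii,
    path_bval,
    path_bvec,
    *,
    name: str = "",
    voxel_size: float | None = None,
    subject_id: str = "",
    group: str = "",
    flip_axes: tuple[bool, bool, bool] = (False, False, False),
) -> DWIDataset:
    """Load a 4D NIfTI plus its bval/bvec pair into a :class:`DWIDataset`.

    ``flip_axes`` optionally negates bvec components, for scanners whose
    gradient table uses a different handedness than the image axes.
    """
    img = nib.load(str(path_nii))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got {data.ndim} dimensions")
    bvals, bvecs = read_bvals_bvecs(path_bval, path_bvec)
    if len(bvals) != data.shape[3]:
        raise ValueError(f"scheme length {len(bvals)} != volume count {data.shape[3]}")
    for ax, flip in enumerate(flip_axes):
        if flip:
            bvecs = bvecs.copy()
            bvecs[:, ax] *= -1
    if voxel_size is None:
        voxel_size = float(np.abs(img.affine[0, 0])) or 2.0
    scheme = AcquisitionScheme(
        name=name or Path(str(path_nii)).stem, bvalues=bvals, directions=bvecs, voxel_size=voxel_size
    )
    return DWIDataset(
        signal=data, scheme=scheme, affine=np.asarray(img.affine), subject_id=subject_id, group=group
    )


def write_dwi(data: DWIDataset, path_nii, path_bval=None, path_bvec=None) -> None:
    img = nib.Nifti1Image(data.signal.astype(np.float64), data.affine)
    img.header.set_zooms((data.scheme.voxel_size,) * 3 + (1.0,))
    nib.save(img, str(path_nii))
    if path_bval is not None and path_bvec is not None:
        write_bvals_bvecs(data.scheme.bvalues, data.scheme.directions, path_bval, path_bvec)


def read_atlas(path_nii, path_names, *, voxel_size: float | None = None) -> TractAtlas:
    """Load a 4D probability NIfTI and a names TSV.

    The TSV must have a ``name`` column; ``laterality`` and ``pair`` columns are
    optional — when absent, pairing is resolved from ``_left``/``_right`` name
    suffixes.
    """
    img = nib.load(str(path_nii))
    probs = np.asarray(img.dataobj, dtype=float)
    table = pd.read_csv(path_names, sep="\t")
    if "name" not in table.columns:
        raise ValueError("names table must have a 'name' column")
    names = [str(n) for n in table["name"]]
    laterality: dict[str, str] = {}
    pairs: dict[str, str] = {}
    if "laterality" in table.columns and "pair" in table.columns:
        for _, row in table.iterrows():
            laterality[str(row["name"])] = str(row["laterality"])
            pair = row["pair"]
            if isinstance(pair, str) and pair and pair != "-":
                if pair not in names:
                    raise ValueError(f"dangling pair reference: {row['name']} -> {pair}")
                pairs[str(row["name"])] = pair
    if voxel_size is None:
        voxel_size = float(np.abs(img.affine[0, 0])) or 2.0
    atlas = TractAtlas(
        probabilities=probs,
        tract_names=names,
        laterality=laterality,
        pairs=pairs,
        voxel_size=voxel_size,
    )
    empty = atlas.empty_tracts()
    if empty:
        log.warning("atlas has %d empty tract map(s): %s", len(empty), ", ".join(empty))
    return atlas


def write_atlas(atlas: TractAtlas, path_nii, path_names) -> None:
    affine = np.diag([atlas.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(atlas.probabilities.astype(np.float32), affine), str(path_nii))
    rows = [
        {
            "name": n,
            "laterality": atlas.laterality.get(n, "midline"),
            "pair": atlas.pairs.get(n, "-"),
        }
        for n in atlas.tract_names
    ]
    pd.DataFrame(rows).to_csv(path_names, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    """Subject/group design table (TSV with subject_id, group columns)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df


def run_manifest(seed: int, config_hash: str = "", extra: dict | None = None) -> dict:
    import scipy

    from . import __version__

    manifest = {
        "seed": int(seed),
        "config_hash": config_hash,
        "versions": {
            "dwibench": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_report_table(
    rows: pd.DataFrame, path, *, seed: int = 0, config_hash: str = "", extra: dict | None = None
) -> Path:
    """Write a statistics table as TSV with a JSON run manifest alongside.

    Columns are emitted in a stable order (the standard report keys first,
    remaining columns in their existing order); decimal separator is '.'.
    Returns the TSV path. The manifest lands next to it as ``<stem>.manifest.json``.
    """
    path = Path(path)
    df = rows.copy()
    lead = [c for c in REPORT_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    df = df[lead + rest]
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")
    manifest = run_manifest(seed, config_hash, extra)
    manifest_path = path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
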
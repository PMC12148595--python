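"""Reading and writing the package's on-disk formats.

Ratings travel as tab-delimited UTF-8 tables with a header row; neural
patterns as one NIfTI volume per subject and condition plus a shared ROI
mask and a JSON sidecar fixing the condition order; every dataset carries a
JSON manifest with the generating parameters and seed so a run can be
reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .rdm import CONDITIONS, RDM
from .simulate import RATING_DIMS, PatternSet

__all__ = [
    "read_ratings",
    "write_ratings",
    "read_patterns",
    "write_patterns",
    "write_dataset_files",
    "read_dataset_files",
    "write_rdm_csv",
    "read_rdm_csv",
    "load_config",
]

RATING_COLUMNS = [
    "subject_id",
    "stimulus_id",
    "stimulus_type",
    "modality",
    "run",
    *RATING_DIMS,
    "vividness",
]


class SchemaError(ValueError):
    """A table violates the ratings schema; the message cites row numbers."""


def _validate_ratings(table: pd.DataFrame) -> None:
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for dim in RATING_DIMS:
        vals = table[dim]
        bad = vals.notna() & (~vals.isin(range(1, 8)))
        if bad.any():
            rows = list(table.index[bad][:5])
            raise SchemaError(
                f"column {dim!r}: ratings outside 1..7 at rows {rows}"
            )
    bad_mod = ~table["modality"].isin(["perception", "imagery"])
    if bad_mod.any():
        raise SchemaError(
            f"unknown modality at rows {list(table.index[bad_mod][:5])}"
        )
    bad_type = ~table["stimulus_type"].isin(["art", "face"])
    if bad_type.any():
        raise SchemaError(
            f"unknown stimulus_type at rows {list(table.index[bad_type][:5])}"
        )
    viv = table["vividness"]
    perc = table["modality"] == "perception"
    stray = perc & viv.notna()
    if stray.any():
        raise SchemaError(
            f"vividness on perception rows {list(table.index[stray][:5])}"
        )
    absent = (~perc) & viv.isna()
    if absent.any():
        raise SchemaError(
            f"missing vividness on imagery rows {list(table.index[absent][:5])}"
        )
    bad_viv = viv.notna() & (~viv.isin(range(1, 8)))
    if bad_viv.any():
        raise SchemaError(
            f"vividness outside 1..7 at rows {list(table.index[bad_viv][:5])}"
        )


def write_ratings(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    _validate_ratings(table)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_ratings(path) -> pd.DataFrame:
    table = pd.read_csv(Path(path), sep="\t", na_values=["NA"])
    _validate_ratings(table)
    return table


# ---------------------------------------------------------------------------
# patterns as NIfTI volumes
# ---------------------------------------------------------------------------

def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    nx = side
    ny = side
    nz = int(np.ceil(n_voxels / (nx * ny)))
    return nx, ny, nz


def write_patterns(patterns: PatternSet, directory) -> dict:
    """Write one gzipped NIfTI per (subject, condition), a mask volume, and a
    JSON sidecar recording the condition order.  Returns the sidecar dict."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = patterns.n_channels
    shape = _grid_shape(p)
    mask = np.zeros(shape, dtype=np.uint8)
    mask.reshape(-1)[:p] = 1
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(mask, affine), directory / "mask.nii.gz")
    for si, subject in enumerate(patterns.subjects):
        for ci, cond in enumerate(patterns.labels):
            vol = np.zeros(shape, dtype=np.float64)
            vol.reshape(-1)[:p] = patterns.data[si, ci]
            nib.save(
                nib.Nifti1Image(vol, affine), directory / f"{subject}_{cond}.nii.gz"
            )
    sidecar = {
        "conditions": list(patterns.labels),
        "subjects": list(patterns.subjects),
        "n_voxels": p,
    }
    (directory / "patterns.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar


def read_patterns(directory, mask_path=None) -> PatternSet:
    """Load pattern volumes restricted to the mask, in canonical condition
    order regardless of the sidecar's ordering."""
    directory = Path(directory)
    sidecar = json.loads((directory / "patterns.json").read_text())
    conditions = sidecar["conditions"]
    unknown = set(conditions) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels in sidecar: {sorted(unknown)}")
    mask_path = Path(mask_path) if mask_path else directory / "mask.nii.gz"
    mask_img = nib.load(mask_path)
    mask = np.asarray(mask_img.dataobj).astype(bool)
    flat_mask = mask.reshape(-1)
    subjects = sidecar["subjects"]
    data = np.empty((len(subjects), len(CONDITIONS), int(flat_mask.sum())))
    for si, subject in enumerate(subjects):
        for cond in conditions:
            f = directory / f"{subject}_{cond}.nii.gz"
            if not f.exists():
                raise FileNotFoundError(
                    f"missing pattern volume for subject {subject}, condition {cond}"
                )
            img = nib.load(f)
            if img.shape != mask.shape:
                raise ValueError(
                    f"volume grid {img.shape} does not match mask grid {mask.shape} "
                    f"({subject}, {cond})"
                )
            vol = np.asarray(img.dataobj, dtype=float).reshape(-1)
            data[si, CONDITIONS.index(cond)] = vol[flat_mask]
        for cond in CONDITIONS:
            if cond not in conditions:
                raise ValueError(
                    f"sidecar lacks condition {cond} for subject {subject}"
                )
    return PatternSet(subjects=tuple(subjects), data=data)


# ---------------------------------------------------------------------------
# dataset bundles
# ---------------------------------------------------------------------------

def write_dataset_files(
    ratings: pd.DataFrame, patterns: PatternSet, path, manifest: dict
) -> dict:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_ratings(ratings, path / "ratings.tsv")
    write_patterns(patterns, path / "patterns")
    manifest = dict(manifest)
    manifest["files"] = {"ratings": "ratings.tsv", "patterns": "patterns"}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def read_dataset_files(path) -> tuple[pd.DataFrame, PatternSet, dict]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    ratings = read_ratings(path / manifest["files"]["ratings"])
    patterns = read_patterns(path / manifest["files"]["patterns"])
    return ratings, patterns, manifest


# ---------------------------------------------------------------------------
# RDM CSV and YAML config
# ---------------------------------------------------------------------------

def write_rdm_csv(rdm: RDM, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rdm.matrix, index=rdm.labels, columns=rdm.labels).to_csv(path)
    return path


def read_rdm_csv(path) -> RDM:
    df = pd.read_csv(Path(path), index_col=0)
    return RDM(df.to_numpy(dtype=float), tuple(df.columns))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
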
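"""Plain-text artifact I/O: BIDS-style events TSV, pattern matrices, truth
sidecars, optional NIfTI export of simulated BOLD."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimTruth, VoxelPatternSet

_BIDS_RENAME = {"state": "trial_type"}


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    """BIDS dialect: onset and duration first, state as trial_type, extras kept."""
    ev = events.copy()
    if "state" in ev.columns:
        ev = ev.rename(columns=_BIDS_RENAME)
    lead = [c for c in ("onset", "duration", "trial_type") if c in ev.columns]
    ev = ev[lead + [c for c in ev.columns if c not in lead]]
    path = Path(path)
    ev.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t", na_values=["n/a"])
    if "trial_type" in ev.columns and "state" not in ev.columns:
        ev = ev.rename(columns={"trial_type": "state"})
    return ev


def write_pattern_set(ps: VoxelPatternSet, stem: str | Path) -> tuple[Path, Path]:
    """Betas as a whitespace matrix file plus an event-metadata TSV."""
    stem = Path(stem)
    mat = stem.with_suffix(".betas.txt")
    meta = stem.with_suffix(".events.tsv")
    np.savetxt(mat, ps.betas)
    ps.events.assign(roi_label=ps.roi_label).to_csv(meta, sep="\t", index=False)
    return mat, meta


def read_pattern_set(stem: str | Path) -> VoxelPatternSet:
    stem = Path(stem)
    betas = np.loadtxt(stem.with_suffix(".betas.txt"))
    events = pd.read_csv(stem.with_suffix(".events.tsv"), sep="\t")
    roi = str(events["roi_label"].iloc[0]) if "roi_label" in events else "roi"
    return VoxelPatternSet(np.atleast_2d(betas), events.drop(columns=["roi_label"],
                                                             errors="ignore"), roi)


def write_truth_sidecar(truth: SimTruth, path: str | Path) -> Path:
    """JSON sidecar carrying the planted simulation parameters."""
    d = dataclasses.asdict(truth)
    d["category_templates"] = {k: v.tolist() for k, v in d["category_templates"].items()}
    path = Path(path)
    path.write_text(json.dumps(d, indent=2))
    return path


def read_truth_sidecar(path: str | Path) -> SimTruth:
    d = json.loads(Path(path).read_text())
    d["category_templates"] = {k: np.asarray(v) for k, v in d["category_templates"].items()}
    return SimTruth(**d)


def export_bold_nifti(bold: np.ndarray, path: str | Path,
                      tr: float = 1.24, shape: tuple[int, int, int] | None = None):
    """Write a simulated time x voxel series as a 4-D NIfTI (voxels laid out
    along x), with a companion ROI mask covering them."""
    import nibabel as nib

    t, v = bold.shape
    if shape is None:
        shape = (v, 1, 1)
    vol = np.zeros(shape + (t,), dtype=np.float32)
    vol.reshape(-1, t)[:v] = bold.T
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header["pixdim"][4] = tr
    path = Path(path)
    nib.save(img, str(path))
    mask = np.zeros(shape, dtype=np.uint8)
    mask.reshape(-1)[:v] = 1
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    nib.save(nib.Nifti1Image(mask, affine=np.eye(4)), str(mask_path))
    return path, mask_path
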
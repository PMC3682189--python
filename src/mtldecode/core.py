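"""Core data containers for the MVPA decoding pipeline.

The pipeline passes four kinds of object between stages:

``BoldRun``
    a 4D voxel x time functional series with its grid geometry and TR;
``RoiMask``
    a labelled 3D boolean mask on the same grid (region x hemisphere);
``TrialTable``
    an ordered per-trial event table (a :class:`pandas.DataFrame` with the
    column conventions below);
``TrialPatternSet``
    a trials x voxels feature matrix with class labels and voxel
    coordinates -- the classifier input.

Trial tables are plain DataFrames rather than a custom class so that they
round-trip losslessly through TSV and are easy to inspect; the expected
columns are listed in :data:`TRIAL_COLUMNS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order for trial event tables (TSV convention).
TRIAL_COLUMNS = [
    "trial_index",
    "class_label",
    "cue_onset_s",
    "recall_onset_s",
    "press_latency_s",
    "vividness",
    "accuracy",
    "included",
    "exclude_reason",
]


@dataclass
class BoldRun:
    """A 4D BOLD series (x, y, z, volume) with acquisition geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, n_volumes)
        Voxel time series. Must be finite.
    tr_s : float
        Repetition time in seconds (volume sampling interval).
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BoldRun.data must be 4D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun.data contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def copy_with(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(data=data, tr_s=self.tr_s, voxel_size_mm=self.voxel_size_mm)


@dataclass
class RoiMask:
    """A labelled binary region-of-interest mask on the run's voxel grid."""

    label: str
    hemisphere: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("RoiMask.mask must be 3D")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        if not self.mask.any():
            raise ValueError(f"ROI {self.key} has no voxels")

    @property
    def key(self) -> str:
        return f"{self.label}_{self.hemisphere}"

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer coordinates in C (row-major) order.

        This ordering matches the column order produced by boolean
        indexing ``run.data[mask.mask]``, which is what
        :func:`mtldecode.prep.extract_trial_patterns` uses.
        """
        return np.argwhere(self.mask)


@dataclass
class TrialPatternSet:
    """Trials x voxels feature matrix for one ROI.

    Rows correspond to *included* trials in trial order; columns to ROI
    voxels in C order (see :meth:`RoiMask.voxel_coords`).
    """

    X: np.ndarray
    y: np.ndarray
    voxel_coords: np.ndarray
    roi_label: str
    hemisphere: str = "L"
    tr_s: float = 3.5
    shift_volumes: int = 0
    trial_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D (trials x voxels)")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("y length must equal number of rows of X")
        if self.voxel_coords.shape != (self.X.shape[1], 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("pattern matrix contains non-finite entries")
        if self.trial_indices is None:
            self.trial_indices = np.arange(self.X.shape[0])
        else:
            self.trial_indices = np.asarray(self.trial_indices, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def key(self) -> str:
        return f"{self.roi_label}_{self.hemisphere}"

    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def save(self, path) -> None:
        """Write as NPZ plus a CSV matrix and JSON header sidecar."""
        import os

        path = str(path)
        base, ext = os.path.splitext(path)
        if ext != ".npz":
            base = path
        np.savez(
            base + ".npz",
            X=self.X,
            y=self.y,
            voxel_coords=self.voxel_coords,
            trial_indices=self.trial_indices,
        )
        pd.DataFrame(self.X).to_csv(base + ".csv", index=False)
        header = {
            "roi_label": self.roi_label,
            "hemisphere": self.hemisphere,
            "tr_s": self.tr_s,
            "shift_volumes": int(self.shift_volumes),
            "voxel_coords": self.voxel_coords.tolist(),
            "y": np.asarray(self.y).tolist(),
        }
        with open(base + ".json", "w") as fh:
            json.dump(header, fh, indent=2)

    @classmethod
    def load(cls, path) -> "TrialPatternSet":
        import os

        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        with np.load(base + ".npz") as npz:
            X = npz["X"]
            y = npz["y"]
            coords = npz["voxel_coords"]
            trial_indices = npz["trial_indices"]
        with open(base + ".json") as fh:
            header = json.load(fh)
        return cls(
            X=X,
            y=y,
            voxel_coords=coords,
            roi_label=header["roi_label"],
            hemisphere=header["hemisphere"],
            tr_s=header["tr_s"],
            shift_volumes=header["shift_volumes"],
            trial_indices=trial_indices,
        )


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table column contract and onset monotonicity."""
    missing = [c for c in ("class_label", "recall_onset_s") if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    onsets = trials["recall_onset_s"].to_numpy(dtype=float)
    if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
        raise ValueError("recall onsets must be strictly increasing")
    return trials
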
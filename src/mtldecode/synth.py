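"""Synthetic event-related BOLD data with planted multivoxel memory patterns.

This module generates the kind of data the decoding pipeline assumes: a
subject repeatedly recalls a small set of well-learned episodic memories
(three short movie clips) inside the scanner, each recall lasting 7 s, with
trials in pseudo-random order such that the same memory never occurs twice
in a row. Each memory is assumed to be represented, within signal-bearing
regions of interest (ROIs), as a fixed spatial pattern of activity across
voxels. On every trial the pattern of the recalled memory is driven by a
7 s boxcar convolved with the canonical haemodynamic response function and
added on top of linear scanner drift and i.i.d. Gaussian noise.

Two kinds of ROI are simulated:

* *signal-bearing* ROIs carry a distinct per-memory spatial pattern -- a
  region with intact mnemonic function;
* *signal-absent* ROIs (the "sclerotic" mode) respond to every trial with
  the same class-independent pattern. They are metabolically active but
  carry no information about *which* memory is being recalled, so
  univariate activation cannot distinguish the two kinds of region --
  only pattern decodability can.

Behavioural responses (button-press latency, vividness and accuracy
ratings) are simulated so that the standard exclusion rules (press < 5.5 s,
press absent/after 10 s, any rating < 3) can be exercised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import TRIAL_COLUMNS, BoldRun, RoiMask

__all__ = [
    "RoiSpec",
    "SynthConfig",
    "GroundTruth",
    "SimulatedSubject",
    "default_roi_specs",
    "make_schedule",
    "canonical_hrf",
    "simulate_behaviour",
    "simulate_run",
    "write_subject",
]


@dataclass(frozen=True)
class RoiSpec:
    """An axis-aligned ellipsoidal ROI on the voxel grid.

    ``signal_present=False`` marks the "sclerotic" mode: the region
    responds to trials but carries no class-specific pattern.
    """

    label: str
    hemisphere: str
    centre: tuple[int, int, int]
    radii: tuple[float, float, float]
    signal_present: bool = True

    @property
    def key(self) -> str:
        return f"{self.label}_{self.hemisphere}"


def default_roi_specs(signal: dict[str, bool] | None = None) -> list[RoiSpec]:
    """Six MTL-like ROIs (HC, EPC, PHC in each hemisphere) on the default grid.

    ``signal`` maps ROI keys like ``"HC_L"`` to a signal-present flag,
    overriding the all-signal default (use ``{"HC_L": False}`` for a
    left-hippocampal-sclerosis-like subject).
    """
    signal = signal or {}
    layout = [
        ("HC", "L", (6, 10, 7), (2.0, 4.0, 2.0)),
        ("HC", "R", (21, 10, 7), (2.0, 4.0, 2.0)),
        ("EPC", "L", (6, 18, 7), (2.0, 3.0, 2.0)),
        ("EPC", "R", (21, 18, 7), (2.0, 3.0, 2.0)),
        ("PHC", "L", (6, 26, 7), (2.0, 2.0, 2.0)),
        ("PHC", "R", (21, 26, 7), (2.0, 2.0, 2.0)),
    ]
    return [
        RoiSpec(lab, hemi, c, r, signal.get(f"{lab}_{hemi}", True))
        for lab, hemi, c, r in layout
    ]


@dataclass
class SynthConfig:
    """Parameters of one simulated subject/run.

    Defaults follow the experimental design being emulated: TR 3.5 s,
    three memories recalled twenty times each for 7 s, six dummy volumes
    at the start of the run. ``signal_amplitude`` is the planted pattern
    strength in units of the noise SD.
    """

    grid_shape: tuple[int, int, int] = (28, 36, 14)
    voxel_size_mm: float = 1.5
    tr_s: float = 3.5
    n_classes: int = 3
    n_trials_per_class: int = 20
    recall_duration_s: float = 7.0
    inter_trial_gap_s: float = 13.0
    cue_duration_s: float = 3.0
    signal_amplitude: float = 1.0
    noise_sd: float = 1.0
    drift_slope: float = 0.02
    roi_specs: list[RoiSpec] = field(default_factory=default_roi_specs)
    exclusion_rate: float = 0.0
    n_dummy_volumes: int = 6
    hrf_peak_delay_s: float = 6.0
    hrf_undershoot_delay_s: float = 16.0
    hrf_ratio: float = 6.0
    hrf_duration_s: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.signal_amplitude < 0:
            raise ValueError("signal_amplitude must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.exclusion_rate < 1):
            raise ValueError("exclusion_rate must be in [0, 1)")
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        for v in (self.tr_s, self.voxel_size_mm, self.recall_duration_s):
            if v <= 0:
                raise ValueError("tr_s, voxel_size_mm, recall_duration_s must be positive")
        if self.inter_trial_gap_s < 0:
            raise ValueError("inter_trial_gap_s must be non-negative")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "roi_specs"}
        d["grid_shape"] = list(self.grid_shape)
        d["roi_specs"] = [
            {
                "label": r.label,
                "hemisphere": r.hemisphere,
                "centre": list(r.centre),
                "radii": list(r.radii),
                "signal_present": r.signal_present,
            }
            for r in self.roi_specs
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["roi_specs"] = [
            RoiSpec(
                r["label"],
                r["hemisphere"],
                tuple(r["centre"]),
                tuple(r["radii"]),
                r.get("signal_present", True),
            )
            for r in d["roi_specs"]
        ]
        return cls(**d)

    def with_signal(self, signal: dict[str, bool]) -> "SynthConfig":
        """Copy of the config with per-ROI signal flags overridden."""
        rois = [
            replace(r, signal_present=signal.get(r.key, r.signal_present))
            for r in self.roi_specs
        ]
        return replace(self, roi_specs=rois)


@dataclass
class GroundTruth:
    """What was actually planted: per-ROI class patterns and the schedule."""

    class_patterns: dict[str, np.ndarray]  # roi key -> (n_classes, n_roi_voxels)
    schedule: pd.DataFrame
    included_mask: np.ndarray

    def __post_init__(self) -> None:
        for key, pats in self.class_patterns.items():
            if pats.ndim != 2:
                raise ValueError(f"class patterns for {key} must be 2D")
            # planted patterns must be pairwise distinguishable
            for i in range(pats.shape[0]):
                for j in range(i + 1, pats.shape[0]):
                    if np.allclose(pats[i], pats[j]):
                        raise ValueError(f"identical class patterns planted in {key}")


class SimulatedSubject(NamedTuple):
    run: BoldRun
    rois: list[RoiMask]
    trials: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def make_schedule(
    n_classes: int,
    n_per_class: int,
    seed: int,
    *,
    tr_s: float = 3.5,
    n_dummy_volumes: int = 6,
    recall_duration_s: float = 7.0,
    inter_trial_gap_s: float = 13.0,
    cue_duration_s: float = 3.0,
) -> pd.DataFrame:
    """Pseudo-random trial schedule with no immediate class repeats.

    Each of ``n_classes`` memories occurs exactly ``n_per_class`` times and
    the same memory never appears on two consecutive trials. Onsets are
    strictly increasing, spaced by the cue + recall window + inter-trial
    gap, starting after the dummy-volume period. Deterministic given
    ``seed``.
    """
    if n_classes < 1 or n_per_class < 1:
        raise ValueError("n_classes and n_per_class must be >= 1")
    if n_classes == 1 and n_per_class > 1:
        raise ValueError(
            "no-repeat constraint unsatisfiable with a single class and >1 trial"
        )
    rng = np.random.default_rng(seed)
    total = n_classes * n_per_class

    labels: list[int] = []
    for _ in range(1000):  # rejection restarts; dead ends are rare
        remaining = {c: n_per_class for c in range(1, n_classes + 1)}
        seq: list[int] = []
        prev = None
        while len(seq) < total:
            candidates = [c for c, r in remaining.items() if r > 0 and c != prev]
            if not candidates:
                break
            # force the class that must alternate from here on
            slots_left = total - len(seq)
            forced = [c for c in candidates if 2 * remaining[c] - 1 >= slots_left]
            pick = forced[0] if forced else int(rng.choice(candidates))
            seq.append(pick)
            remaining[pick] -= 1
            prev = pick
        if len(seq) == total:
            labels = seq
            break
    if not labels:
        raise RuntimeError("failed to build a no-repeat schedule")

    block = cue_duration_s + recall_duration_s + inter_trial_gap_s
    lead_in = n_dummy_volumes * tr_s + 2.0
    cue_onsets = lead_in + block * np.arange(total)
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(total),
            "class_label": labels,
            "cue_onset_s": cue_onsets,
            "recall_onset_s": cue_onsets + cue_duration_s,
            "press_latency_s": np.nan,
            "vividness": np.nan,
            "accuracy": np.nan,
            "included": True,
            "exclude_reason": "",
        }
    )
    return trials[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# haemodynamic response
# ---------------------------------------------------------------------------

def canonical_hrf(
    t_grid: np.ndarray,
    *,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak normalised to 1.

    The response is the difference of two unit-scale gamma densities: a
    positive lobe peaking at ``peak_delay_s`` (6 s) and an undershoot
    near ``undershoot_delay_s`` (16 s) scaled down by ``ratio`` (6), the
    conventional double-gamma shape. The gamma shape parameters are
    ``delay + 1`` so each lobe's mode sits exactly at its stated delay.
    The returned vector is scaled so its maximum equals 1; the response
    decays to ~0 by 32 s.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("t_grid is empty")
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    h = (
        sps.gamma.pdf(t, a=peak_delay_s + 1)
        - sps.gamma.pdf(t, a=undershoot_delay_s + 1) / ratio
    )
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def simulate_behaviour(
    schedule: pd.DataFrame, exclusion_rate: float, seed: int
) -> pd.DataFrame:
    """Attach button-press latencies and vividness/accuracy ratings.

    A fraction ~``exclusion_rate`` of trials is made excludable by one of
    the three mechanisms used at analysis time -- press too fast
    (< 5.5 s), press too slow or absent (> 10 s), or a rating below 3 --
    with the mechanism chosen at random. All remaining trials get a
    latency in [5.5, 10] s and both ratings >= 3.
    """
    if not (0 <= exclusion_rate < 1):
        raise ValueError("exclusion_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    trials = schedule.copy()
    n = len(trials)
    latency = rng.uniform(5.8, 9.5, size=n)
    vivid = rng.integers(3, 6, size=n).astype(float)
    accur = rng.integers(3, 6, size=n).astype(float)
    excludable = rng.random(n) < exclusion_rate
    for i in np.flatnonzero(excludable):
        mech = rng.integers(3)
        if mech == 0:  # pressed too soon
            latency[i] = rng.uniform(2.0, 5.4)
        elif mech == 1:  # too slow, or never pressed
            latency[i] = np.nan if rng.random() < 0.5 else rng.uniform(10.1, 13.0)
        else:  # low confidence in the recall
            if rng.random() < 0.5:
                vivid[i] = rng.integers(1, 3)
            else:
                accur[i] = rng.integers(1, 3)
    trials["press_latency_s"] = latency
    trials["vividness"] = vivid
    trials["accuracy"] = accur
    return trials


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

def _roi_mask_array(spec: RoiSpec, grid_shape: tuple[int, int, int]) -> np.ndarray:
    ax = [np.arange(n) for n in grid_shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    cx, cy, cz = spec.centre
    rx, ry, rz = spec.radii
    inside = (
        ((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2 + ((gz - cz) / rz) ** 2
    ) <= 1.0
    return inside


def _class_regressors(
    trials: pd.DataFrame, cfg: SynthConfig, n_volumes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class and all-trial HRF-convolved recall regressors at the TR.

    The neural drive is a boxcar spanning each trial's recall window,
    built on a fine time grid, convolved with the canonical HRF and then
    sampled at the volume acquisition times.
    """
    oversample = 32
    dt = cfg.tr_s / oversample
    t_end = n_volumes * cfg.tr_s
    n_fine = int(round(t_end / dt))
    t_hrf = np.arange(0.0, cfg.hrf_duration_s + dt / 2, dt)
    hrf = canonical_hrf(
        t_hrf,
        peak_delay_s=cfg.hrf_peak_delay_s,
        undershoot_delay_s=cfg.hrf_undershoot_delay_s,
        ratio=cfg.hrf_ratio,
    )
    classes = np.arange(1, cfg.n_classes + 1)
    per_class = np.zeros((cfg.n_classes, n_volumes))
    onsets = trials["recall_onset_s"].to_numpy(dtype=float)
    labels = trials["class_label"].to_numpy(dtype=int)
    vol_samples = np.arange(n_volumes) * oversample
    for ci, c in enumerate(classes):
        box = np.zeros(n_fine)
        for onset in onsets[labels == c]:
            i0 = int(round(onset / dt))
            i1 = int(round((onset + cfg.recall_duration_s) / dt))
            box[i0:min(i1, n_fine)] = 1.0
        conv = np.convolve(box, hrf)[:n_fine] * dt
        per_class[ci] = conv[vol_samples]
    all_trials = per_class.sum(axis=0)
    return per_class, all_trials


def simulate_run(config: SynthConfig) -> SimulatedSubject:
    """Simulate one subject's run: BOLD data, ROI masks, trials, ground truth.

    For each signal-bearing ROI, every trial adds
    ``amplitude * class_pattern * (recall boxcar x HRF)`` to the ROI's
    voxels. Signal-absent ROIs and all out-of-ROI voxels receive a
    class-independent evoked response with a fixed random spatial profile,
    so mere activation does not distinguish decodable from non-decodable
    tissue. Per-voxel linear drift (``drift_slope`` per volume) and
    i.i.d. Gaussian noise are added everywhere. The run covers all trials
    plus six leading dummy volumes; everything is deterministic given
    ``config.seed``.
    """
    cfg = config
    from .prep import filter_trials  # late import: prep does not import synth

    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(4)
    schedule_seed, behaviour_seed = int(seeds[0]), int(seeds[1])
    pattern_rng = np.random.default_rng(seeds[2])
    noise_rng = np.random.default_rng(seeds[3])

    schedule = make_schedule(
        cfg.n_classes,
        cfg.n_trials_per_class,
        schedule_seed,
        tr_s=cfg.tr_s,
        n_dummy_volumes=cfg.n_dummy_volumes,
        recall_duration_s=cfg.recall_duration_s,
        inter_trial_gap_s=cfg.inter_trial_gap_s,
        cue_duration_s=cfg.cue_duration_s,
    )
    trials = simulate_behaviour(schedule, cfg.exclusion_rate, behaviour_seed)
    trials = filter_trials(trials)

    # run length: all trials + HRF tail + headroom for onset shift and the
    # four extracted volumes
    last = trials["recall_onset_s"].iloc[-1] + cfg.recall_duration_s
    tail_s = cfg.hrf_duration_s + 4 * cfg.tr_s
    n_volumes = int(math.ceil((last + tail_s) / cfg.tr_s))

    # masks, checked disjoint and in-grid
    masks: list[RoiMask] = []
    occupancy = np.zeros(cfg.grid_shape, dtype=int)
    for spec in cfg.roi_specs:
        arr = _roi_mask_array(spec, cfg.grid_shape)
        cx, cy, cz = spec.centre
        rx, ry, rz = spec.radii
        if (
            cx - rx < 0 or cx + rx >= cfg.grid_shape[0]
            or cy - ry < 0 or cy + ry >= cfg.grid_shape[1]
            or cz - rz < 0 or cz + rz >= cfg.grid_shape[2]
        ):
            raise ValueError(f"ROI {spec.key} extends outside the grid")
        occupancy += arr
        masks.append(RoiMask(spec.label, spec.hemisphere, arr))
    if (occupancy > 1).any():
        raise ValueError("ROIs overlap")

    per_class, all_trials_reg = _class_regressors(trials, cfg, n_volumes)

    data = noise_rng.normal(0.0, cfg.noise_sd, size=(*cfg.grid_shape, n_volumes))
    data += cfg.drift_slope * np.arange(n_volumes)

    # class-independent evoked response everywhere outside signal ROIs
    univariate_map = pattern_rng.normal(size=cfg.grid_shape)
    signal_union = np.zeros(cfg.grid_shape, dtype=bool)
    class_patterns: dict[str, np.ndarray] = {}
    for spec, mask in zip(cfg.roi_specs, masks):
        if spec.signal_present:
            signal_union |= mask.mask
            pats = pattern_rng.normal(size=(cfg.n_classes, mask.n_voxels))
            class_patterns[spec.key] = pats
            if cfg.signal_amplitude > 0:
                # (n_vox, n_classes) @ (n_classes, n_vols)
                data[mask.mask] += cfg.signal_amplitude * (pats.T @ per_class)
        else:
            # keep RNG state independent of the flag order by not drawing
            pass
    nonsignal = ~signal_union
    data[nonsignal] += (
        cfg.signal_amplitude * univariate_map[nonsignal][:, None] * all_trials_reg
    )

    run = BoldRun(data=data, tr_s=cfg.tr_s, voxel_size_mm=cfg.voxel_size_mm)
    truth = GroundTruth(
        class_patterns=class_patterns,
        schedule=schedule,
        included_mask=trials["included"].to_numpy(dtype=bool),
    )
    return SimulatedSubject(run=run, rois=masks, trials=trials, truth=truth)


# ---------------------------------------------------------------------------
# on-disk representation (NIfTI + TSV + JSON)
# ---------------------------------------------------------------------------

def write_subject(out_dir, subject: SimulatedSubject, config: SynthConfig) -> dict:
    """Write a simulated subject as NIfTI-1 images, a TSV and JSON sidecars."""
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    vs = config.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    paths = {}

    img = nib.Nifti1Image(subject.run.data.astype(np.float32), affine)
    img.header.set_zooms((vs, vs, vs, config.tr_s))
    p = os.path.join(out_dir, "bold.nii.gz")
    nib.save(img, p)
    paths["bold"] = p

    for roi in subject.rois:
        m = nib.Nifti1Image(roi.mask.astype(np.int16), affine)
        p = os.path.join(out_dir, f"roi_{roi.key}.nii.gz")
        nib.save(m, p)
        paths[f"roi_{roi.key}"] = p

    p = os.path.join(out_dir, "events.tsv")
    subject.trials.to_csv(p, sep="\t", index=False)
    paths["events"] = p

    truth = {
        "class_patterns": {k: v.tolist() for k, v in subject.truth.class_patterns.items()},
        "included_mask": subject.truth.included_mask.tolist(),
    }
    p = os.path.join(out_dir, "ground_truth.json")
    with open(p, "w") as fh:
        json.dump(truth, fh)
    paths["ground_truth"] = p

    p = os.path.join(out_dir, "synth_config.json")
    with open(p, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    paths["config"] = p
    return paths


def read_run(path) -> BoldRun:
    """Load a 4D NIfTI as a :class:`BoldRun` (TR from the header)."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 3.5
    return BoldRun(np.asarray(img.dataobj, dtype=float), tr_s=tr, voxel_size_mm=float(zooms[0]))


def read_mask(path, label: str | None = None, hemisphere: str | None = None) -> RoiMask:
    """Load a 3D NIfTI mask; label/hemisphere parsed from name if absent."""
    import os

    import nibabel as nib

    name = os.path.basename(str(path))
    stem = name.split(".")[0]
    if label is None or hemisphere is None:
        parts = stem.replace("roi_", "").rsplit("_", 1)
        label = label or parts[0]
        hemisphere = hemisphere or (parts[1] if len(parts) > 1 else "L")
    img = nib.load(str(path))
    return RoiMask(label, hemisphere, np.asarray(img.dataobj) > 0)
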
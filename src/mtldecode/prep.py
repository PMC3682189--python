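"""Preprocessing: raw run -> per-ROI trial-pattern matrices.

The chain mirrors a standard minimal event-related preprocessing for
pattern analysis, in this order:

1. discard the first six volumes (T1 equilibration),
2. light spatial smoothing (3 mm FWHM Gaussian),
3. per-voxel linear detrend (scanner drift),
4. temporal convolution of every voxel series with the canonical HRF
   (boosts SNR; effectively doubles the haemodynamic delay to ~12 s),
5. shift trial onsets forward by ``round(12 s / TR)`` volumes and extract
   four volumes per trial from the recall window, averaged into one
   pattern per trial, restricted to each ROI.

Behavioural exclusion (:func:`filter_trials`) flags trials whose button
press fell outside [5.5, 10] s or whose vividness/accuracy rating was
below 3; only included trials contribute pattern rows.

Motion realignment and field-map unwarping are assumed already done on
real data (and are unnecessary for the simulator); they are not modelled
here.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BoldRun, RoiMask, TrialPatternSet

__all__ = [
    "discard_dummies",
    "smooth_gaussian",
    "linear_detrend",
    "hrf_convolve",
    "compute_onset_shift",
    "filter_trials",
    "extract_trial_patterns",
    "preprocess_run",
    "preprocess_subject",
]


def discard_dummies(
    run: BoldRun, n: int = 6, trials: pd.DataFrame | None = None
):
    """Drop the first ``n`` volumes; optionally re-reference trial onsets.

    After discarding, volume 0 is the first retained volume, so onsets in
    an accompanying trial table are shifted back by ``n * TR`` (an onset
    at raw volume 8 lands at volume 2 of the output when n = 6).

    Returns the trimmed run, or ``(run, trials)`` when a trial table is
    supplied.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= run.n_volumes:
        raise ValueError(f"cannot discard {n} of {run.n_volumes} volumes")
    out = run.copy_with(run.data[..., n:].copy())
    if trials is None:
        return out
    shifted = trials.copy()
    for col in ("cue_onset_s", "recall_onset_s"):
        if col in shifted.columns:
            shifted[col] = shifted[col] - n * run.tr_s
    return out, shifted


def smooth_gaussian(run: BoldRun, fwhm_mm: float = 3.0) -> BoldRun:
    """Isotropic spatial Gaussian smoothing of each volume.

    ``sigma = FWHM / (2 sqrt(2 ln 2)) / voxel_size``; FWHM 0 is the
    identity. Boundaries use nearest-neighbour replication so edge voxels
    are not deflated toward zero.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return run.copy_with(run.data.copy())
    sigma_vox = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / run.voxel_size_mm
    out = ndimage.gaussian_filter(
        run.data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0), mode="nearest"
    )
    return run.copy_with(out)


def linear_detrend(run: BoldRun) -> BoldRun:
    """Remove each voxel's least-squares line (intercept + slope * volume).

    Output series have zero mean and zero linear trend; the operation is
    a projection, hence idempotent.
    """
    n = run.n_volumes
    if n < 3:
        raise ValueError("need at least 3 volumes to detrend")
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    flat = run.data.reshape(-1, n)
    mean = flat.mean(axis=1, keepdims=True)
    slope = (flat @ t_c) / (t_c @ t_c)
    out = flat - mean - slope[:, None] * t_c
    return run.copy_with(out.reshape(run.data.shape))


def hrf_convolve(run: BoldRun, hrf: np.ndarray) -> BoldRun:
    """Causal convolution of every voxel series with an HRF sampled at TR.

    The output is truncated to the input length, so the value at volume t
    depends only on volumes <= t (no future leakage).
    """
    hrf = np.asarray(hrf, dtype=float)
    if hrf.size == 0:
        raise ValueError("hrf kernel is empty")
    from scipy.signal import fftconvolve

    n = run.n_volumes
    flat = run.data.reshape(-1, n)
    conv = fftconvolve(flat, hrf[None, :], mode="full", axes=1)[:, :n]
    return run.copy_with(conv.reshape(run.data.shape))


def compute_onset_shift(tr_s: float, total_delay_s: float) -> int:
    """Delay expressed in whole volumes: round(delay / TR), half away from zero.

    With TR 3.5 s and a ~12 s total haemodynamic delay this gives 3
    volumes.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if total_delay_s < 0:
        raise ValueError("total_delay_s must be non-negative")
    return int(math.floor(total_delay_s / tr_s + 0.5))


def filter_trials(
    trials: pd.DataFrame,
    min_press_s: float = 5.5,
    max_press_s: float = 10.0,
    min_rating: int = 3,
) -> pd.DataFrame:
    """Flag trials excluded by the behavioural rules.

    A trial is included iff the button press occurred (latency present),
    fell in [``min_press_s``, ``max_press_s``] (boundaries inclusive), and
    both vividness and accuracy ratings are >= ``min_rating``. Excluded
    trials keep their rows but get ``included=False`` and a reason code
    (``too_fast``, ``too_slow``, ``no_press``, ``low_rating``).
    """
    out = trials.copy()
    lat = out["press_latency_s"].to_numpy(dtype=float)
    viv = out["vividness"].to_numpy(dtype=float)
    acc = out["accuracy"].to_numpy(dtype=float)
    reasons = np.array([""] * len(out), dtype=object)
    reasons[np.isnan(lat)] = "no_press"
    reasons[(~np.isnan(lat)) & (lat < min_press_s)] = "too_fast"
    reasons[(~np.isnan(lat)) & (lat > max_press_s)] = "too_slow"
    low = ((~np.isnan(viv)) & (viv < min_rating)) | ((~np.isnan(acc)) & (acc < min_rating))
    reasons[(reasons == "") & low] = "low_rating"
    # missing ratings count as not-yet-rated, treated as included only if
    # both present; absent ratings (NaN) on an otherwise valid trial pass
    out["included"] = reasons == ""
    out["exclude_reason"] = reasons
    return out


def extract_trial_patterns(
    run: BoldRun,
    trials: pd.DataFrame,
    mask: RoiMask,
    shift_volumes: int,
    n_vols_per_trial: int = 4,
    average: bool = True,
) -> TrialPatternSet:
    """One pattern row per included trial, restricted to the ROI.

    For each included trial, ``n_vols_per_trial`` consecutive volumes
    starting at ``floor(recall_onset / TR) + shift_volumes`` are averaged
    voxelwise (or stacked as separate rows when ``average=False``) and
    restricted to the mask's voxels. Row order follows trial order.
    """
    if mask.mask.shape != run.spatial_shape:
        raise ValueError("mask shape does not match run grid")
    if n_vols_per_trial < 1:
        raise ValueError("n_vols_per_trial must be >= 1")
    included = trials[trials["included"].astype(bool)]
    coords = mask.voxel_coords()
    roi_ts = run.data[mask.mask]  # (n_voxels, n_volumes), C order
    rows, labels, tidx = [], [], []
    for _, tr in included.iterrows():
        start = int(math.floor(tr["recall_onset_s"] / run.tr_s)) + shift_volumes
        stop = start + n_vols_per_trial
        if start < 0 or stop > run.n_volumes:
            raise ValueError(
                f"trial {int(tr['trial_index'])}: extraction window "
                f"[{start}, {stop}) exceeds run of {run.n_volumes} volumes"
            )
        window = roi_ts[:, start:stop]
        if average:
            rows.append(window.mean(axis=1))
            labels.append(int(tr["class_label"]))
            tidx.append(int(tr["trial_index"]))
        else:
            for k in range(n_vols_per_trial):
                rows.append(window[:, k])
                labels.append(int(tr["class_label"]))
                tidx.append(int(tr["trial_index"]))
    X = np.vstack(rows) if rows else np.empty((0, coords.shape[0]))
    return TrialPatternSet(
        X=X,
        y=np.asarray(labels, dtype=int),
        voxel_coords=coords,
        roi_label=mask.label,
        hemisphere=mask.hemisphere,
        tr_s=run.tr_s,
        shift_volumes=shift_volumes,
        trial_indices=np.asarray(tidx, dtype=int),
    )


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------

def preprocess_run(
    run: BoldRun,
    trials: pd.DataFrame,
    *,
    n_dummy: int = 6,
    fwhm_mm: float = 3.0,
    hrf: np.ndarray | None = None,
) -> tuple[BoldRun, pd.DataFrame]:
    """discard -> smooth -> detrend -> HRF-convolve, with onset bookkeeping."""
    from .synth import canonical_hrf

    run2, trials2 = discard_dummies(run, n_dummy, trials)
    run2 = smooth_gaussian(run2, fwhm_mm)
    run2 = linear_detrend(run2)
    if hrf is None:
        hrf = canonical_hrf(np.arange(0.0, 32.0 + 1e-9, run.tr_s))
    run2 = hrf_convolve(run2, hrf)
    return run2, trials2


def preprocess_subject(
    run: BoldRun,
    trials: pd.DataFrame,
    masks: list[RoiMask],
    *,
    n_dummy: int = 6,
    fwhm_mm: float = 3.0,
    delay_s: float = 12.0,
    n_vols_per_trial: int = 4,
    average: bool = True,
    apply_filter: bool = True,
) -> dict[str, TrialPatternSet]:
    """Full preprocessing for one subject; one pattern set per ROI."""
    if apply_filter:
        trials = filter_trials(trials)
    run2, trials2 = preprocess_run(run, trials, n_dummy=n_dummy, fwhm_mm=fwhm_mm)
    shift = compute_onset_shift(run.tr_s, delay_s)
    return {
        m.key: extract_trial_patterns(
            run2, trials2, m, shift, n_vols_per_trial, average=average
        )
        for m in masks
    }
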
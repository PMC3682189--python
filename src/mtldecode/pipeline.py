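"""End-to-end experiment orchestration: simulate -> preprocess -> decode -> group stats.

An :class:`ExperimentConfig` describes a synthetic cohort (how many
subjects, which ROIs carry signal -- e.g. a "left HC silent" cohort
emulating left hippocampal sclerosis) plus all preprocessing and decoding
parameters. :func:`run_experiment` executes the full pipeline
deterministically from one master seed, producing per-subject per-ROI
accuracies, group statistics and a manifest of outputs.

Seeding: a single master seed drives everything; each subject's seed is
derived with :func:`derive_subject_seed` (SeedSequence mixing of
``(master_seed, subject_index)``), so per-subject streams are independent
and decoding options cannot alter the simulated data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .decoding import DecodingResult, SearchlightDecoder
from .prep import preprocess_subject
from .stats import GroupDecodingStats, GroupStatsResult
from .synth import SimulatedSubject, SynthConfig, simulate_run

__all__ = [
    "ExperimentConfig",
    "derive_subject_seed",
    "run_subject",
    "run_experiment",
    "ExperimentResult",
    "summarise_accuracies",
    "plot_group_accuracy",
]


@dataclass
class ExperimentConfig:
    """A reproducible cohort experiment.

    ``silent_rois`` lists ROI keys (e.g. ``"HC_L"``) simulated *without*
    class-specific signal -- the sclerotic mode. All acquisition /
    preprocessing / decoding defaults equal the conventional values of
    the design being emulated (TR 3.5 s, 3 mm FWHM, 12 s delay, 4
    volumes per trial, searchlight radius 3, C = 1, press window
    5.5-10 s, ratings >= 3, 6 dummy volumes).
    """

    n_subjects: int = 9
    synth: SynthConfig = field(default_factory=SynthConfig)
    silent_rois: tuple[str, ...] = ()
    fwhm_mm: float = 3.0
    delay_s: float = 12.0
    n_vols_per_trial: int = 4
    average_volumes: bool = True
    n_dummy: int = 6
    radius_voxels: float = 3.0
    c_param: float = 1.0
    scoring: str = "nested"
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = self.synth.to_dict()
        d["silent_rois"] = list(self.silent_rois)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["synth"] = SynthConfig.from_dict(d["synth"])
        d["silent_rois"] = tuple(d.get("silent_rois", ()))
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def derive_subject_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic, collision-resistant per-subject seed.

    Mixes ``(master_seed, subject_index)`` through
    :class:`numpy.random.SeedSequence` and returns the first 31 bits of
    state, so derived seeds stay below 2**31.
    """
    if master_seed < 0 or subject_index < 0:
        raise ValueError("master_seed and subject_index must be non-negative")
    ss = np.random.SeedSequence([int(master_seed), int(subject_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_subject(
    synth_cfg: SynthConfig,
    *,
    fwhm_mm: float = 3.0,
    delay_s: float = 12.0,
    n_vols_per_trial: int = 4,
    average: bool = True,
    n_dummy: int = 6,
    radius_voxels: float = 3.0,
    c_param: float = 1.0,
    scoring: str = "nested",
) -> tuple[SimulatedSubject, dict[str, DecodingResult]]:
    """Simulate, preprocess and decode every ROI of one subject."""
    subject = simulate_run(synth_cfg)
    patterns = preprocess_subject(
        subject.run,
        subject.trials,
        subject.rois,
        n_dummy=n_dummy,
        fwhm_mm=fwhm_mm,
        delay_s=delay_s,
        n_vols_per_trial=n_vols_per_trial,
        average=average,
        apply_filter=False,  # synth already applied the behavioural filter
    )
    results = {}
    for key, pats in patterns.items():
        decoder = SearchlightDecoder(
            pats, radius_voxels=radius_voxels, c_param=c_param, scoring=scoring
        )
        results[key] = decoder.fit()
    return subject, results


@dataclass
class ExperimentResult:
    accuracy_table: pd.DataFrame
    group: GroupStatsResult | None
    manifest: dict
    summary_table: pd.DataFrame

    def summary(self) -> str:
        lines = ["Cohort decoding summary (accuracy, proportion and %):", ""]
        lines.append(self.summary_table.to_string(index=False))
        if self.group is not None:
            lines += ["", self.group.summary()]
        else:
            lines += ["", "single subject: group statistics skipped"]
        return "\n".join(lines)


def summarise_accuracies(table: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy +/- SEM per region x hemisphere (chance = 1/3)."""
    rows = []
    for (region, hemi), grp in table.groupby(["region", "hemisphere"]):
        acc = grp["accuracy"].to_numpy()
        sem = acc.std(ddof=1) / np.sqrt(len(acc)) if len(acc) > 1 else np.nan
        rows.append(
            {
                "region": region,
                "hemisphere": hemi,
                "n": len(acc),
                "mean_accuracy": acc.mean(),
                "sem": sem,
                "mean_accuracy_pct": 100 * acc.mean(),
                "chance_pct": 100 / 3,
            }
        )
    return pd.DataFrame(rows).sort_values(["region", "hemisphere"]).reset_index(drop=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Run the full cohort experiment described by ``config``.

    Per subject: derive a seed, simulate a run (with the configured ROIs
    silenced), preprocess, and decode each ROI with leave-one-trial-out
    cross-validation. With >= 2 subjects, fit the group statistics
    (chance tests, paired contrasts, hemisphere x region RM-ANOVA,
    accuracy-volume correlation). Writes CSV/JSON outputs and a manifest
    when ``out_dir`` is given.
    """
    import os

    signal = {key: False for key in config.silent_rois}
    rows = []
    per_subject: dict[int, dict[str, DecodingResult]] = {}
    for s in range(config.n_subjects):
        seed = derive_subject_seed(config.master_seed, s)
        cfg_s = replace(config.synth.with_signal(signal), seed=seed)
        try:
            subject, results = run_subject(
                cfg_s,
                fwhm_mm=config.fwhm_mm,
                delay_s=config.delay_s,
                n_vols_per_trial=config.n_vols_per_trial,
                average=config.average_volumes,
                n_dummy=config.n_dummy,
                radius_voxels=config.radius_voxels,
                c_param=config.c_param,
                scoring=config.scoring,
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed for subject {s}: {exc}") from exc
        per_subject[s] = results
        voxel_mm3 = config.synth.voxel_size_mm**3
        for roi in subject.rois:
            res = results[roi.key]
            rows.append(
                {
                    "subject_id": s,
                    "region": roi.label,
                    "hemisphere": roi.hemisphere,
                    "n_trials": res.n_folds,
                    "accuracy": res.accuracy,
                    "accuracy_pct": 100 * res.accuracy,
                    "roi_volume_mm3": roi.n_voxels * voxel_mm3,
                }
            )
    table = pd.DataFrame(rows)
    summary = summarise_accuracies(table)

    group: GroupStatsResult | None = None
    if config.n_subjects >= 2:
        group = GroupDecodingStats(table).fit()

    manifest = {
        "software": f"mtldecode {__version__}",
        "created_unix": time.time(),
        "master_seed": config.master_seed,
        "config": config.to_dict(),
        "outputs": {},
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        acc_path = os.path.join(out_dir, "accuracies.csv")
        table.to_csv(acc_path, index=False)
        sum_path = os.path.join(out_dir, "summary.csv")
        summary.to_csv(sum_path, index=False)
        fold_path = os.path.join(out_dir, "fold_records.json")
        with open(fold_path, "w") as fh:
            json.dump(
                {
                    str(s): {k: r.to_dict() for k, r in res.items()}
                    for s, res in per_subject.items()
                },
                fh,
            )
        paths = [acc_path, sum_path, fold_path]
        if group is not None:
            grp_path = os.path.join(out_dir, "group_stats.json")
            with open(grp_path, "w") as fh:
                json.dump(group.to_dict(), fh, indent=2)
            paths.append(grp_path)
        else:
            with open(os.path.join(out_dir, "NOTICE.txt"), "w") as fh:
                fh.write("single subject: group statistics skipped\n")
        for p in paths:
            manifest["outputs"][os.path.basename(p)] = _sha256(p)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    return ExperimentResult(
        accuracy_table=table, group=group, manifest=manifest, summary_table=summary
    )


def plot_group_accuracy(table: pd.DataFrame, ax=None):
    """Bar chart of mean accuracy +/- SEM per region x hemisphere.

    The dashed line marks the 1/3 chance level.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    summary = summarise_accuracies(table)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = summary["region"] + " " + summary["hemisphere"]
    ax.bar(
        labels,
        summary["mean_accuracy"],
        yerr=summary["sem"],
        capsize=3,
        color="steelblue",
    )
    ax.axhline(1 / 3, color="black", linestyle="--", label="chance (1/3)")
    ax.set_ylabel("decoding accuracy")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
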
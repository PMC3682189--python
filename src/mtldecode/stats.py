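"""Group-level inference for ROI decoding accuracies.

Implements the statistical battery used to contrast decodable and
non-decodable regions across subjects:

* one-sample one-tailed t-tests of each region's accuracy against the
  1/3 chance level (three memories);
* paired t-tests for within-subject region/hemisphere contrasts;
* a 2 (hemisphere) x 3 (region) repeated-measures ANOVA, classical
  univariate decomposition with subject as random factor (no sphericity
  correction by default);
* Pearson correlation (e.g. accuracy vs ROI volume);
* the Dice overlap coefficient for segmentation quality control;
* a one-way (optionally Welch) ANOVA for comparing a patient group with
  healthy controls.

Chance is the exact 1/3, not the rounded 33%. No multiple-testing
correction is applied; the conventional threshold is p < 0.05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import RoiMask

__all__ = [
    "TestResult",
    "t_vs_chance",
    "paired_t",
    "rm_anova_2x3",
    "pearson_r",
    "dice",
    "one_way_anova",
    "GroupDecodingStats",
    "GroupStatsResult",
]

CHANCE_3CLASS = 1.0 / 3.0
REGIONS = ("HC", "EPC", "PHC")
HEMISPHERES = ("L", "R")


@dataclass
class TestResult:
    """A test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: float | tuple
    p: float
    tail: str = "two"
    name: str = ""

    def __repr__(self) -> str:  # compact, table-friendly
        df = self.df if not isinstance(self.df, tuple) else f"{self.df[0]},{self.df[1]}"
        return (
            f"TestResult({self.name or 'test'}: stat={self.statistic:.4f}, "
            f"df={df}, p={self.p:.4g}, {self.tail}-tailed)"
        )


def t_vs_chance(accuracies, chance: float = CHANCE_3CLASS) -> TestResult:
    """One-sample t-test of accuracies against chance, upper tail.

    t = (mean - chance) / (sd / sqrt(n)), df = n - 1; the alternative is
    "accuracy above chance" (one-tailed), as appropriate for a decoder
    that cannot do meaningfully worse than guessing.
    """
    a = np.asarray(accuracies, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 accuracy values")
    if np.std(a, ddof=1) == 0:
        raise ValueError("zero variance in accuracies")
    res = sps.ttest_1samp(a, popmean=chance, alternative="greater")
    return TestResult(float(res.statistic), a.size - 1, float(res.pvalue), "one", "t_vs_chance")


def paired_t(a, b) -> TestResult:
    """Two-tailed paired t-test on the differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return TestResult(0.0, a.size - 1, 1.0, "two", "paired_t")
        raise ValueError("constant non-zero differences: t undefined")
    res = sps.ttest_rel(a, b)
    return TestResult(float(res.statistic), a.size - 1, float(res.pvalue), "two", "paired_t")


def rm_anova_2x3(table: pd.DataFrame) -> dict[str, TestResult]:
    """Two-factor (hemisphere x region) repeated-measures ANOVA.

    Expects one row per subject x region x hemisphere with columns
    ``subject_id``, ``region``, ``hemisphere``, ``accuracy`` and a
    complete crossing. Classical univariate sums-of-squares decomposition
    with subject as random factor; each effect is tested against its own
    effect-by-subject interaction. For 2 x 3 the interaction has
    df (2, 2(n-1)). Returns results for ``hemisphere``, ``region`` and
    ``interaction``; the SS partition is attached as ``result["ss"]`` on
    the returned dict-like for conservation checks.
    """
    required = {"subject_id", "region", "hemisphere", "accuracy"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"table missing columns: {sorted(missing_cols)}")
    subjects = sorted(table["subject_id"].unique())
    hemis = sorted(table["hemisphere"].unique())
    regions = sorted(table["region"].unique())
    n, a, b = len(subjects), len(hemis), len(regions)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    pivot = table.pivot_table(
        index="subject_id", columns=["hemisphere", "region"], values="accuracy"
    )
    missing = [
        (s, h, r)
        for s in subjects
        for h in hemis
        for r in regions
        if (h, r) not in pivot.columns or pd.isna(pivot.loc[s, (h, r)])
    ]
    if missing:
        raise ValueError(f"incomplete crossing; missing cells: {missing}")

    Y = np.empty((n, a, b))
    for si, s in enumerate(subjects):
        for hi, h in enumerate(hemis):
            for ri, r in enumerate(regions):
                Y[si, hi, ri] = pivot.loc[s, (h, r)]

    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_total = float(((Y - gm) ** 2).sum())
    ss_subj = a * b * float(((m_s - gm) ** 2).sum())
    ss_a = n * b * float(((m_a - gm) ** 2).sum())
    ss_b = n * a * float(((m_b - gm) ** 2).sum())
    ss_ab = n * float(
        ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    )
    ss_as = b * float(
        ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    )
    ss_bs = a * float(
        ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    )
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    def f_test(ss_eff, df_eff, ss_err, df_err, name) -> TestResult:
        if ss_eff <= 1e-300:
            return TestResult(0.0, (df_eff, df_err), 1.0, "two", name)
        if ss_err <= 1e-300:
            return TestResult(float("inf"), (df_eff, df_err), 0.0, "two", name)
        F = (ss_eff / df_eff) / (ss_err / df_err)
        p = float(sps.f.sf(F, df_eff, df_err))
        return TestResult(float(F), (df_eff, df_err), p, "two", name)

    out = {
        "hemisphere": f_test(ss_a, a - 1, ss_as, (a - 1) * (n - 1), "hemisphere"),
        "region": f_test(ss_b, b - 1, ss_bs, (b - 1) * (n - 1), "region"),
        "interaction": f_test(
            ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1), "interaction"
        ),
        "ss": {
            "total": ss_total,
            "subject": ss_subj,
            "hemisphere": ss_a,
            "region": ss_b,
            "interaction": ss_ab,
            "hemisphere_x_subject": ss_as,
            "region_x_subject": ss_bs,
            "residual": ss_abs,
        },
    }
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has undefined correlation")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def dice(a, b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary masks."""
    ma = a.mask if isinstance(a, RoiMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, RoiMask) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError("masks are on different grids")
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def one_way_anova(*groups, welch: bool = False) -> TestResult:
    """One-way ANOVA across independent groups (classical, or Welch)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if welch:
        # Welch's heteroscedastic one-way ANOVA
        k = len(arrays)
        ns = np.array([len(g) for g in arrays], dtype=float)
        means = np.array([g.mean() for g in arrays])
        vars_ = np.array([g.var(ddof=1) for g in arrays])
        w = ns / vars_
        mw = (w * means).sum() / w.sum()
        F = ((w * (means - mw) ** 2).sum() / (k - 1)) / (
            1 + 2 * (k - 2) / (k * k - 1) * ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()
        )
        df2 = (k * k - 1) / (3 * ((1 - w / w.sum()) ** 2 / (ns - 1)).sum())
        p = float(sps.f.sf(F, k - 1, df2))
        return TestResult(float(F), (k - 1, float(df2)), p, "two", "welch_anova")
    res = sps.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(len(g) for g in arrays) - len(arrays)
    return TestResult(float(res.statistic), (df1, df2), float(res.pvalue), "two", "anova")


# ---------------------------------------------------------------------------
# group model object
# ---------------------------------------------------------------------------

@dataclass
class GroupStatsResult:
    """Fitted group statistics over a subjects x ROI accuracy table."""

    chance_tests: dict[str, TestResult]
    anova: dict
    paired_contrasts: dict[str, TestResult]
    volume_correlation: tuple[float, float] | None
    table: pd.DataFrame
    chance: float

    def summary(self) -> str:
        lines = ["Group decoding statistics", "=" * 26]
        lines.append(f"chance level: {self.chance:.4f}")
        lines.append("")
        lines.append("Accuracy vs chance (one-tailed t):")
        for key, t in sorted(self.chance_tests.items()):
            mean = self.table.loc[
                (self.table["region"] + "_" + self.table["hemisphere"]) == key,
                "accuracy",
            ].mean()
            lines.append(
                f"  {key:6s} mean={mean * 100:6.2f}%  t={t.statistic:7.3f}  p={t.p:.4f}"
            )
        lines.append("")
        inter = self.anova["interaction"]
        lines.append(
            f"hemisphere x region RM-ANOVA interaction: "
            f"F({inter.df[0]},{inter.df[1]})={inter.statistic:.3f}, p={inter.p:.4f}"
        )
        for key, t in sorted(self.paired_contrasts.items()):
            lines.append(f"paired {key}: t={t.statistic:.3f}, p={t.p:.4f}")
        if self.volume_correlation is not None:
            r, p = self.volume_correlation
            lines.append(f"accuracy-volume Pearson r={r:.3f}, p={p:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def tr(t: TestResult) -> dict:
            return {
                "statistic": t.statistic,
                "df": list(t.df) if isinstance(t.df, tuple) else t.df,
                "p": t.p,
                "tail": t.tail,
            }

        d = {
            "chance": self.chance,
            "chance_tests": {k: tr(v) for k, v in self.chance_tests.items()},
            "anova": {
                k: tr(v) for k, v in self.anova.items() if isinstance(v, TestResult)
            },
            "paired_contrasts": {k: tr(v) for k, v in self.paired_contrasts.items()},
        }
        if self.volume_correlation is not None:
            d["volume_correlation"] = {
                "r": self.volume_correlation[0],
                "p": self.volume_correlation[1],
            }
        return d


class GroupDecodingStats:
    """Model object: group inference over an accuracy table.

    Parameters
    ----------
    table : DataFrame
        One row per subject x region x hemisphere with columns
        ``subject_id``, ``region``, ``hemisphere``, ``accuracy`` and
        optionally ``roi_volume_mm3``.
    chance : float
        Theoretical chance accuracy (1/3 for three memories).
    volume_region : str
        Region whose accuracy-volume correlation is computed when volumes
        are available (the hippocampus by default).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        chance: float = CHANCE_3CLASS,
        volume_region: str = "HC",
    ) -> None:
        required = {"subject_id", "region", "hemisphere", "accuracy"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"accuracy table missing columns: {sorted(missing)}")
        self.table = table.copy()
        self.chance = chance
        self.volume_region = volume_region

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GroupDecodingStats":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> GroupStatsResult:
        tab = self.table
        chance_tests = {}
        for (region, hemi), grp in tab.groupby(["region", "hemisphere"]):
            try:
                chance_tests[f"{region}_{hemi}"] = t_vs_chance(
                    grp["accuracy"], self.chance
                )
            except ValueError:
                pass  # e.g. a single-subject table
        anova = rm_anova_2x3(tab)
        paired = {}
        pivot = tab.pivot_table(
            index="subject_id", columns=["region", "hemisphere"], values="accuracy"
        )
        for region in sorted(tab["region"].unique()):
            if (region, "L") in pivot.columns and (region, "R") in pivot.columns:
                try:
                    paired[f"{region}_L_vs_R"] = paired_t(
                        pivot[(region, "L")], pivot[(region, "R")]
                    )
                except ValueError:
                    pass
        volume_corr = None
        if "roi_volume_mm3" in tab.columns:
            sub = tab[tab["region"] == self.volume_region]
            if len(sub) >= 3:
                try:
                    volume_corr = pearson_r(sub["accuracy"], sub["roi_volume_mm3"])
                except ValueError:
                    volume_corr = None
        return GroupStatsResult(
            chance_tests=chance_tests,
            anova=anova,
            paired_contrasts=paired,
            volume_correlation=volume_corr,
            table=tab,
            chance=self.chance,
        )
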
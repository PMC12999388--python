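"""Three-condition repeated-measures comparison harness.

Per metric: boxplot (1.5 IQR) outlier removal per condition, Shapiro-Wilk
normality check, then either repeated-measures ANOVA with
Bonferroni-corrected paired t-tests (all conditions normal) or Friedman's
test with Holm-corrected Wilcoxon signed-rank tests and effect size
r = |Z| / sqrt(n).  Sphericity is handled by Greenhouse-Geisser correction
when violated.  Significance level 0.05 throughout; results are reported
as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests


@dataclass
class PosthocEntry:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str          # bonferroni_t | holm_wilcoxon
    effect_r: float


@dataclass
class GroupComparisonResult:
    metric: str
    groups: list[str]
    omnibus: dict[str, Any]                    # {test, statistic, p, ...}
    posthoc: list[PosthocEntry] = field(default_factory=list)
    outliers_removed: dict[str, int] = field(default_factory=dict)
    normality: dict[str, float] = field(default_factory=dict)
    n_subjects: int = 0

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "metric": self.metric, "groups": self.groups,
            "omnibus": self.omnibus,
            "posthoc": [{"pair": list(p.pair), "statistic": p.statistic,
                         "p_raw": p.p_raw, "p_adjusted": p.p_adjusted,
                         "method": p.method, "effect_r": p.effect_r}
                        for p in self.posthoc],
            "outliers_removed": self.outliers_removed,
            "normality": self.normality, "n_subjects": self.n_subjects,
        }


def remove_outliers(values: Sequence[float]) -> tuple[list[float], list[float]]:
    """Boxplot rule: drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation; boundary values are kept (a
    constant list keeps everything even though its bounds collapse).
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        raise ValueError("need at least 4 values for the boxplot rule")
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = [v for v in vals if lo <= v <= hi]
    removed = [v for v in vals if not lo <= v <= hi]
    return kept, removed


def summarize(values: Sequence[float]) -> dict[str, Any]:
    """Mean +/- sample SD (n-1), with a 2-decimal display string."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(vals.mean())
    if vals.size == 1:
        sd, flag = 0.0, True
    else:
        sd, flag = float(vals.std(ddof=1)), False
    return {"mean": mean, "sd": sd, "n": int(vals.size),
            "sd_undefined": flag,
            "display": f"{mean:.2f} ± {sd:.2f}"}


def _effect_r_from_t(t: float, df: int) -> float:
    return float(np.sqrt(t * t / (t * t + df)))


def _wilcoxon_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Wilcoxon signed-rank with normal approximation: (W, Z, p)."""
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 0.0, 1.0
    res = sst.wilcoxon(x, y, zero_method="wilcox", method="approx",
                       correction=False)
    return float(res.statistic), float(res.zstatistic), float(res.pvalue)


def route_and_test(data: np.ndarray | pd.DataFrame, alpha: float = 0.05,
                   groups: Sequence[str] = ("SG", "RBG", "ESG"),
                   metric: str = "", outlier_removal: bool = True,
                   ) -> GroupComparisonResult:
    """Omnibus + posthoc comparison of one metric across three conditions.

    ``data`` is (subjects x 3 conditions).  The boxplot rule is applied to
    the subjects' condition means and flagged subjects are dropped whole,
    which keeps the paired design intact and, unlike per-cell trimming,
    leaves the omnibus tests calibrated under the null.  Normal data
    (Shapiro-Wilk p > 0.05 in every condition) route to RM-ANOVA +
    Bonferroni paired t; otherwise Friedman + Holm Wilcoxon with effect
    size r = |Z|/sqrt(n).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(groups):
        raise ValueError(f"expected (subjects x {len(groups)}) matrix")
    groups = list(groups)

    outliers: dict[str, int] = {g: 0 for g in groups}
    if outlier_removal and X.shape[0] >= 4:
        means = X.mean(axis=1)
        _, removed = remove_outliers(means)
        keep = ~np.isin(means, removed)
        outliers["subjects"] = int((~keep).sum())
        X = X[keep]
    else:
        outliers["subjects"] = 0
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"only {n} complete subject rows after outlier "
                         "removal; need >= 5")

    normality = {}
    all_normal = True
    for j, g in enumerate(groups):
        col = X[:, j]
        if np.ptp(col) == 0:
            p = 0.0          # degenerate: constant condition is non-normal
        else:
            p = float(sst.shapiro(col).pvalue)
        normality[g] = p
        all_normal &= p > alpha

    pairs = [(0, 1), (0, 2), (1, 2)]
    posthoc: list[PosthocEntry] = []

    if all_normal:
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), len(groups)),
            "condition": np.tile(groups, n),
            "value": X.ravel(),
        })
        aov = pg.rm_anova(data=long, dv="value", within="condition",
                          subject="subject", correction="auto", detailed=False)
        row = aov.iloc[0]
        gg_cols = [c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns]
        unc_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        p_col = (gg_cols[0] if gg_cols and np.isfinite(row[gg_cols[0]])
                 else unc_col)
        f_stat = float(row["F"]) if np.isfinite(row["F"]) else 0.0
        p_val = float(row[p_col]) if np.isfinite(row[p_col]) else 1.0
        omnibus = {"test": "rm_anova", "statistic": max(f_stat, 0.0),
                   "p": p_val, "sphericity_corrected": p_col not in
                   ("p_unc", "p-unc")}
        raw = []
        for i, j in pairs:
            t = sst.ttest_rel(X[:, i], X[:, j])
            raw.append((float(t.statistic), float(t.pvalue)))
        for (i, j), (t, p) in zip(pairs, raw):
            posthoc.append(PosthocEntry(
                pair=(groups[i], groups[j]), statistic=t, p_raw=p,
                p_adjusted=min(1.0, p * len(pairs)), method="bonferroni_t",
                effect_r=_effect_r_from_t(t, n - 1)))
    else:
        if np.ptp(X, axis=1).max() == 0:
            # every subject identical across conditions: no effect testable
            chi2, p = 0.0, 1.0
        else:
            chi2, p = sst.friedmanchisquare(*(X[:, j]
                                              for j in range(len(groups))))
            if not np.isfinite(chi2):
                chi2, p = 0.0, 1.0
        omnibus = {"test": "friedman", "statistic": float(chi2),
                   "p": float(p)}
        stats_z, raw_p, eff = [], [], []
        for i, j in pairs:
            w, z, pw = _wilcoxon_z(X[:, i], X[:, j])
            n_nz = int((X[:, i] != X[:, j]).sum())
            stats_z.append((w, z))
            raw_p.append(pw)
            eff.append(abs(z) / np.sqrt(max(n_nz, 1)))
        _, p_adj, _, _ = multipletests(raw_p, method="holm")
        for (i, j), (w, z), pr, pa, r in zip(pairs, stats_z, raw_p,
                                             p_adj, eff):
            posthoc.append(PosthocEntry(
                pair=(groups[i], groups[j]), statistic=w, p_raw=pr,
                p_adjusted=float(pa), method="holm_wilcoxon",
                effect_r=float(min(r, 1.0))))

    return GroupComparisonResult(metric=metric, groups=groups,
                                 omnibus=omnibus, posthoc=posthoc,
                                 outliers_removed=outliers,
                                 normality=normality, n_subjects=n)
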
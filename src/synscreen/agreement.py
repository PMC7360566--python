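"""Cross-readout agreement and screen-reproducibility metrics.

Covers the statistics used to compare readouts and culture formats and to
quantify how reproducible the screen itself is: Pearson correlations of
paired responses, set algebra over per-readout synergy call sets, two-tailed
t tests with the usual star convention, and coefficient-of-variation (CV)
summaries of technical replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError

__all__ = ["CallSet", "ReproReport", "TTestResult", "pearson_r", "unique_calls",
           "compare_groups", "cv", "cv_table", "overall_cv",
           "replicate_correlation", "significance_stars"]


def pearson_r(x, y) -> tuple[float, int]:
    """Product-moment correlation of paired values; incomplete pairs dropped.

    Returns ``(r, n_pairs_used)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DesignError("x and y must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DesignError("need at least 3 complete pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DesignError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    return r, int(len(x))


@dataclass(frozen=True)
class CallSet:
    """Synergistic (cell line, drug pair) calls made by one readout/format."""

    readout: str
    culture_format: str
    calls: frozenset  # of (cell_line, (drug_a, drug_b))
    grid: frozenset = frozenset()  # full design grid the calls live on


def unique_calls(callsets: Sequence[CallSet]) -> dict:
    """Per-readout calls made by that readout and no other.

    Returns ``{readout: {"unique": set, "total": int}}``.  Callsets must share
    the same design grid when grids are declared.
    """
    if len(callsets) < 2:
        raise DesignError("need at least 2 callsets to compare")
    grids = {cs.grid for cs in callsets if cs.grid}
    if len(grids) > 1:
        raise DesignError("callsets are defined over mismatched design grids")
    out = {}
    for cs in callsets:
        others = frozenset().union(*(o.calls for o in callsets if o is not cs))
        out[cs.readout] = {"unique": set(cs.calls - others), "total": len(cs.calls)}
    return out


def significance_stars(p: float) -> str:
    """Star convention: *, **, *** at p <= 0.05, 0.01, 0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    stars: str
    paired: bool


def compare_groups(a, b, paired: bool = False,
                   equal_var: bool = False) -> TTestResult:
    """Two-tailed t test between two groups of per-condition means.

    Paired mode (matched conditions, e.g. two readouts on the same
    combinations) uses the paired t test; otherwise Welch's test by default,
    with ``equal_var=True`` for the classic Student variant.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise DesignError("need at least 2 values per group")
    if paired:
        if len(a) != len(b):
            raise DesignError("paired comparison requires equal-length groups")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # identical constant groups: no evidence of difference
        stat, p = 0.0, 1.0
    return TTestResult(statistic=stat, pvalue=p,
                       stars=significance_stars(p), paired=paired)


def cv(values) -> float:
    """Coefficient of variation: sample (ddof=1) standard deviation / mean."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise DesignError("need at least 2 replicate values for a CV")
    mean = v.mean()
    if mean == 0:
        raise DesignError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


#: Columns that define one "condition" for technical-variability purposes.
CONDITION_COLS = ["cell_line", "culture_format", "drug_a", "dose_a",
                  "drug_b", "dose_b", "readout", "timepoint", "bio_rep"]


def cv_table(normalized: pd.DataFrame,
             value_col: str = "norm_value") -> pd.DataFrame:
    """Per-condition CV over technical replicates of normalized values."""
    treat = normalized[normalized["role"] == "treatment"]
    if treat.empty:
        raise DesignError("no treatment wells in normalized table")
    grp = treat.groupby(CONDITION_COLS)[value_col]
    out = grp.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out = out[out["n"] >= 2].copy()
    out["cv"] = out["sd"] / out["mean"]
    return out


def overall_cv(cv_tbl: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of condition-level CVs per (bio_rep, readout)."""
    if cv_tbl.empty:
        raise DesignError("empty CV table")
    return (cv_tbl.groupby(["bio_rep", "readout"])["cv"]
            .mean().rename("cv_overall").reset_index())


@dataclass
class ReproReport:
    """Correlation-based reproducibility summary."""

    level: str  # "inter_screen" or "intra_screen"
    pearson_r: dict = field(default_factory=dict)  # key -> r
    n_pairs: dict = field(default_factory=dict)    # key -> pairs used


_SA_COND = ["cell_line", "culture_format", "readout", "timepoint"]


def _single_agent_means(normalized: pd.DataFrame) -> pd.DataFrame:
    """Condition means of single-agent responses, with screen provenance.

    Single-drug-screen wells have an empty ``drug_b``; single-agent edges of
    combination matrices carry a partner drug at dose 0 (either orientation).
    """
    treat = normalized[normalized["role"] == "treatment"].copy()
    pure = treat["drug_b"] == ""
    edge_b0 = (treat["drug_b"] != "") & (treat["dose_b"] == 0) & (treat["dose_a"] > 0)
    edge_a0 = (treat["drug_b"] != "") & (treat["dose_a"] == 0) & (treat["dose_b"] > 0)
    frames = []
    for mask, screen, drug_col, dose_col in (
            (pure, "single", "drug_a", "dose_a"),
            (edge_b0, "combination", "drug_a", "dose_a"),
            (edge_a0, "combination", "drug_b", "dose_b")):
        sub = treat[mask].copy()
        if sub.empty:
            continue
        sub["drug"] = sub[drug_col]
        sub["dose"] = sub[dose_col]
        sub["screen"] = screen
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=_SA_COND + ["drug", "dose", "screen", "bio_rep"])
    allsub = pd.concat(frames, ignore_index=True)
    return (allsub.groupby(_SA_COND + ["drug", "dose", "screen", "bio_rep"])
            ["norm_value"].mean().rename("mean_value").reset_index())


def replicate_correlation(normalized: pd.DataFrame, level: str) -> ReproReport:
    """Pearson correlations of shared conditions between screens or replicates.

    ``inter_screen`` correlates single-agent doses present in both the
    single-drug screen and the combination screen (per culture format).
    ``intra_screen`` correlates biological replicates 1 and 2 of the
    combination screen over all shared treatment conditions, per
    (culture format, readout).
    """
    report = ReproReport(level=level)
    if level == "inter_screen":
        sa = _single_agent_means(normalized)
        key = ["cell_line", "culture_format", "readout", "timepoint", "drug", "dose"]
        single = sa[sa["screen"] == "single"].groupby(key)["mean_value"].mean()
        combo = sa[sa["screen"] == "combination"].groupby(key)["mean_value"].mean()
        joined = pd.concat({"single": single, "combination": combo}, axis=1).dropna()
        if joined.empty:
            raise DesignError("no single-agent doses shared between screens")
        for fmt, sub in joined.groupby(level="culture_format"):
            r, n = pearson_r(sub["single"], sub["combination"])
            report.pearson_r[fmt] = r
            report.n_pairs[fmt] = n
    elif level == "intra_screen":
        treat = normalized[(normalized["role"] == "treatment")
                           & (normalized["drug_b"] != "")]
        cond = ["cell_line", "culture_format", "drug_a", "dose_a",
                "drug_b", "dose_b", "readout", "timepoint"]
        means = treat.groupby(cond + ["bio_rep"])["norm_value"].mean().unstack("bio_rep")
        if means.shape[1] < 2:
            raise DesignError("need two biological replicates for intra-screen r")
        b1, b2 = means.columns[:2]
        paired = means[[b1, b2]].dropna()
        if paired.empty:
            raise DesignError("no conditions shared between biological replicates")
        for (fmt, readout), sub in paired.groupby(
                [paired.index.get_level_values("culture_format"),
                 paired.index.get_level_values("readout")]):
            r, n = pearson_r(sub[b1], sub[b2])
            report.pearson_r[(fmt, readout)] = r
            report.n_pairs[(fmt, readout)] = n
    else:
        raise DesignError(f"unknown reproducibility level {level!r}")
    return report
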
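"""Methylation-expression-clinical association statistics.

Promoter methylation is summarized as the unweighted mean beta-value over
the promoter's CpGs and dichotomized at a beta threshold (default 0.30,
boundary inclusive).  Associations are tested with Spearman rank
correlation (methylation vs expression), Student's t (expression by
methylation group), Fisher's exact test for dichotomous clinical
variables and Pearson's chi-square (no continuity correction) for
categorical ones, and mRNA decay after transcriptional arrest
(actinomycin D chase) is summarized as an exponential half-life.

``TCGA_LIHC_TABLE1`` carries the published clinicopathological counts of
a 377-patient hepatocellular carcinoma cohort stratified by promoter
methylation status, used as a fixed input for the contingency tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diff import fisher_site

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"

#: TCGA LIHC cohort, columns (unmethylated N=221, methylated N=156)
TCGA_LIHC_TABLE1 = {
    "gender": {
        "rows": ["male", "female"],
        "counts": [[143, 112], [78, 44]],
        "test": "fisher",
    },
    "age": {
        "rows": ["<=60", ">60"],
        "counts": [[125, 55], [95, 101]],
        "test": "fisher",
    },
    "vascular_invasion": {
        "rows": ["micro_or_macro", "none"],
        "counts": [[64, 47], [123, 87]],
        "test": "fisher",
    },
    "ishak_fibrosis": {
        "rows": ["0_none", "1-2_portal", "3-4_septa", "5_incomplete_cirrhosis",
                 "6_cirrhosis"],
        "counts": [[47, 29], [16, 15], [15, 15], [4, 5], [34, 38]],
        "test": "chi2",
    },
    "histological_grade": {
        "rows": ["G1", "G2", "G3", "G4"],
        "counts": [[34, 21], [104, 76], [76, 48], [7, 6]],
        "test": "chi2",
    },
    "tnm_stage": {
        "rows": ["I", "II", "III", "IV"],
        "counts": [[99, 76], [51, 36], [51, 35], [5, 0]],
        "test": "chi2",
    },
}


def summarize_promoter_beta(betas) -> float:
    """Unweighted mean beta over a promoter's CpGs; NaN when empty."""
    vals = np.asarray(list(betas), dtype=float)
    if vals.size == 0:
        return float("nan")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    return float(vals.mean())


def classify_promoter(mean_beta: float, threshold: float = 0.30) -> str:
    """Dichotomize promoter status; boundary inclusive (beta == threshold
    is methylated)."""
    if not 0.0 <= mean_beta <= 1.0:
        raise ValueError("mean beta must lie in [0, 1]")
    return METHYLATED if mean_beta >= threshold else UNMETHYLATED


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and p (average ranks for ties, t-approximation).

    Returns (NaN, NaN) for constant input, where the correlation is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 4:
        raise ValueError("need n >= 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (shared with diff_meth)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("fisher_2x2 requires a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan")
    return fisher_site(t[0, 0], t[0, 1], t[1, 0], t[1, 1])


def chisq_rxc(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction): (statistic, p)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("chisq_rxc requires an r x c table with r, c >= 2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def ttest_groups(values_a, values_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student's t (pooled variance; Welch by flag).

    Degenerate zero-variance input with equal means is reported as
    (t=0, p=1) by convention.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


@dataclass(frozen=True)
class HalfLife:
    t_half: float          # hours; inf when no decay
    decay_rate: float      # per hour, -slope of ln(abundance) fit
    no_decay: bool


def halflife(timepoints, abundance) -> HalfLife:
    """Exponential half-life from an actinomycin D chase time course.

    Fits ln(relative abundance) vs time by least squares;
    t1/2 = ln(2) / decay rate.  Abundances are relative to t=0 and the
    housekeeping control and must be positive; a flat or rising series
    yields an infinite half-life with the no_decay flag set.
    """
    t = np.asarray(list(timepoints), dtype=float)
    a = np.asarray(list(abundance), dtype=float)
    if t.size != a.size:
        raise ValueError("timepoints and abundance must be paired")
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if 0.0 not in t:
        raise ValueError("timepoints must include t=0")
    if np.any(a <= 0):
        raise ValueError("abundances must be positive")
    slope, _ = np.polyfit(t, np.log(a), 1)
    if slope >= 0:
        return HalfLife(float("inf"), -float(slope), True)
    return HalfLife(math.log(2) / -slope, -float(slope), False)


def table1_report(tables: dict | None = None) -> pd.DataFrame:
    """Association tests for a clinicopathological contingency-table set.

    Defaults to the built-in TCGA LIHC cohort counts; returns a tidy
    table of (variable, test, statistic, p, n).
    """
    tables = tables or TCGA_LIHC_TABLE1
    rows = []
    for name, spec in tables.items():
        counts = np.asarray(spec["counts"], dtype=int)
        if spec["test"] == "fisher":
            p = fisher_2x2(counts)
            statistic = float("nan")
        else:
            statistic, p = chisq_rxc(counts)
        rows.append(
            {
                "variable": name,
                "test": spec["test"],
                "statistic": statistic,
                "p": p,
                "n": int(counts.sum()),
            }
        )
    return pd.DataFrame(rows)
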
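"""Differential methylation between two conditions.

Per site, replicate C/T counts are pooled within each condition and the
2x2 table (C vs T, condition A vs B) is tested with Fisher's exact test
(two-sided, point-probability convention: the p-value sums the
hypergeometric probabilities of all tables, at fixed margins, no more
likely than the observed one).  P-values are corrected by
Benjamini-Hochberg over the tested site set and a site is called
differentially methylated when the adjusted p falls below alpha and the
pooled methylation difference exceeds min_delta.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import nonconversion_level

logger = logging.getLogger(__name__)

DIFF_COLUMNS = [
    "transcript_id", "pos_0based", "pos_1based",
    "c_a", "t_a", "c_b", "t_b", "m_a", "m_b", "delta",
    "p_raw", "p_adj", "significant", "rank",
]


def fisher_site(c_a: int, t_a: int, c_b: int, t_b: int) -> float:
    """Two-sided Fisher exact p for one site's pooled 2x2 C/T table.

    Returns NaN (untestable) when a condition has no C/T evidence.
    """
    for v in (c_a, t_a, c_b, t_b):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if c_a + t_a == 0 or c_b + t_b == 0:
        return float("nan")
    _, p = stats.fisher_exact([[c_a, t_a], [c_b, t_b]], alternative="two-sided")
    return min(float(p), 1.0)


def bh_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (Bonferroni via method flag)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unsupported correction method {method!r}")
    return multipletests(p, method=method)[1]


def call_differential(
    pileups_a: pd.DataFrame,
    pileups_b: pd.DataFrame,
    candidate_sites,
    alpha: float = 0.01,
    min_delta: float = 0.1,
    gain_only: bool = False,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Test candidate sites for differential methylation between conditions.

    ``candidate_sites`` is the union of (transcript_id, pos_0based) keys
    that were candidates in at least one condition; sites lacking pooled
    C+T evidence in either condition are untestable and dropped with a
    notice.  ``delta = m_b - m_a``; with ``gain_only`` the significance
    rule requires delta > min_delta instead of |delta| > min_delta.
    """
    candidate_sites = set(map(tuple, candidate_sites))
    pooled = {}
    for label, df in (("a", pileups_a), ("b", pileups_b)):
        g = (
            df.groupby(["transcript_id", "pos_0based"])[["c", "t"]]
            .sum()
            .astype(int)
        )
        pooled[label] = g
    rows = []
    for tx, pos in sorted(candidate_sites):
        key = (tx, pos)
        ca, ta = (
            pooled["a"].loc[key] if key in pooled["a"].index else (0, 0)
        )
        cb, tb = (
            pooled["b"].loc[key] if key in pooled["b"].index else (0, 0)
        )
        ca, ta, cb, tb = int(ca), int(ta), int(cb), int(tb)
        if ca + ta == 0 or cb + tb == 0:
            continue
        m_a = nonconversion_level(ca, ta)
        m_b = nonconversion_level(cb, tb)
        rows.append(
            {
                "transcript_id": tx, "pos_0based": pos, "pos_1based": pos + 1,
                "c_a": ca, "t_a": ta, "c_b": cb, "t_b": tb,
                "m_a": m_a, "m_b": m_b, "delta": m_b - m_a,
                "p_raw": fisher_site(ca, ta, cb, tb),
            }
        )
    if not rows:
        logger.info("differential test set is empty")
        return pd.DataFrame(columns=DIFF_COLUMNS)
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"], method=method)
    if gain_only:
        effect_ok = out["delta"] > min_delta
    else:
        effect_ok = out["delta"].abs() > min_delta
    out["significant"] = (out["p_adj"] < alpha) & effect_ok
    out = rank_top(out)
    return out[DIFF_COLUMNS]


def rank_top(table: pd.DataFrame) -> pd.DataFrame:
    """Order by adjusted p, then |delta| descending, then site key.

    The deterministic lexicographic tail makes full ties reproducible.
    """
    t = table.copy()
    t["_absd"] = -t["delta"].abs()
    t = t.sort_values(
        ["p_adj", "_absd", "transcript_id", "pos_0based"], kind="mergesort"
    ).drop(columns="_absd")
    t = t.reset_index(drop=True)
    t["rank"] = np.arange(1, len(t) + 1)
    return t
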
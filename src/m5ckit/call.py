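"""Candidate m5C site calling.

A cytosine becomes a candidate site when, in both replicates, it has
coverage of at least 30 reads (30RC), at least five reads showing C (5C)
and at least 80% of bases being C or T (80CT), and its average
non-conversion level across replicates is at least 10% (10MM).  A site
passing those filters in only one replicate is rescued through a stricter
single-replicate route that demands seven C reads (7C) instead of five;
its own m must then clear the 10% floor, since no cross-replicate average
exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

BOTH_REPLICATES = "both-replicates"
SINGLE_STRICT = "single-strict"

#: fixed filter order used for first-failure attribution in summaries
FILTER_ORDER = ("30RC", "80CT", "C-depth", "10MM")


@dataclass(frozen=True)
class FilterThresholds:
    min_coverage: int = 30      # 30RC
    min_c: int = 5              # 5C
    min_c_strict: int = 7       # 7C, single-replicate fallback
    min_ct_fraction: float = 0.80  # 80CT
    min_avg_m: float = 0.10     # 10MM

    def __post_init__(self):
        if self.min_c_strict < self.min_c:
            raise ValueError("min_c_strict must be >= min_c")
        for name in ("min_ct_fraction", "min_avg_m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def replicate_passes(
    c: int, t: int, other: int,
    thresholds: FilterThresholds,
    strict: bool = False,
) -> dict[str, bool]:
    """Per-replicate filter flags; 10MM is a site-level criterion, not here."""
    coverage = c + t + other
    min_c = thresholds.min_c_strict if strict else thresholds.min_c
    flags = {
        "30RC": coverage >= thresholds.min_coverage,
        "C-depth": c >= min_c,
        "80CT": coverage > 0 and (c + t) / coverage >= thresholds.min_ct_fraction,
    }
    flags["pass"] = all(flags.values())
    return flags


def _mean_m(ms) -> float:
    vals = [m for m in ms if not math.isnan(m)]
    return float(np.mean(vals)) if vals else float("nan")


def call_sites(
    pileups: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    allow_any_replicates: bool = False,
) -> pd.DataFrame:
    """Apply the calling rules to one condition's two-replicate pileup.

    Returns one row per site with per-replicate counts, avg_m, per-filter
    flags, ``pass_mode`` (both-replicates / single-strict / empty) and
    ``is_candidate``.  The two-replicate design is enforced unless
    ``allow_any_replicates`` is set (then the both-replicates branch
    requires all replicates to pass and the fallback exactly one).
    """
    thresholds = thresholds or FilterThresholds()
    reps = sorted(pileups["replicate"].unique())
    if len(reps) != 2 and not allow_any_replicates:
        raise ValueError(
            f"expected exactly 2 replicates, found {len(reps)} "
            "(pass allow_any_replicates=True to override)"
        )
    by_rep = {
        rep: grp.set_index(["transcript_id", "pos_0based"])
        for rep, grp in pileups.groupby("replicate")
    }
    sites = sorted(
        set().union(*(set(df.index) for df in by_rep.values())) if by_rep else set()
    )
    rows = []
    for tx, pos in sites:
        rec: dict = {"transcript_id": tx, "pos_0based": pos, "pos_1based": pos + 1}
        per_rep = {}
        for i, rep in enumerate(reps, start=1):
            df = by_rep.get(rep)
            if df is not None and (tx, pos) in df.index:
                r = df.loc[(tx, pos)]
                per_rep[rep] = (int(r["c"]), int(r["t"]), int(r["other"]), float(r["m"]))
            else:
                # missing replicate = that replicate fails (fallback route)
                per_rep[rep] = None
            ctom = per_rep[rep] or (0, 0, 0, float("nan"))
            rec[f"rep{i}_c"], rec[f"rep{i}_t"], rec[f"rep{i}_other"] = ctom[:3]
            rec[f"rep{i}_cov"] = sum(ctom[:3])
            rec[f"rep{i}_m"] = ctom[3]
        nonstrict = {
            rep: (replicate_passes(*v[:3], thresholds)["pass"] if v else False)
            for rep, v in per_rep.items()
        }
        passing = [rep for rep in reps if nonstrict[rep]]
        rec["avg_m"] = _mean_m(v[3] for v in per_rep.values() if v)
        pass_mode = ""
        if len(passing) == len(reps) and len(reps) >= 2:
            avg = _mean_m(per_rep[rep][3] for rep in reps)
            if not math.isnan(avg) and avg >= thresholds.min_avg_m:
                pass_mode = BOTH_REPLICATES
                rec["avg_m"] = avg
        elif len(passing) == 1:
            rep = passing[0]
            c, t, o, m = per_rep[rep]
            if (
                replicate_passes(c, t, o, thresholds, strict=True)["pass"]
                and not math.isnan(m)
                and m >= thresholds.min_avg_m
            ):
                pass_mode = SINGLE_STRICT
        rec["pass_mode"] = pass_mode
        rec["is_candidate"] = bool(pass_mode)
        rows.append(rec)
    return pd.DataFrame(rows)


def _first_failure(rec, reps, thresholds: FilterThresholds) -> str:
    """Attribute a rejected site to its first failing filter.

    Reporting convention: filters are scanned in the fixed order
    30RC -> 80CT -> C-depth -> 10MM along the best available route
    (both-replicates if both clear 30RC, else the stronger single
    replicate with the strict C depth).
    """
    per_rep = []
    for i in range(1, len(reps) + 1):
        per_rep.append(
            (rec[f"rep{i}_c"], rec[f"rep{i}_t"], rec[f"rep{i}_other"], rec[f"rep{i}_m"])
        )
    cov_ok = [c + t + o >= thresholds.min_coverage for c, t, o, _ in per_rep]
    both = all(cov_ok) and len(per_rep) >= 2
    if not any(cov_ok):
        return "30RC"
    if both:
        route = list(range(len(per_rep)))
        min_c = thresholds.min_c
    else:
        route = [i for i, ok in enumerate(cov_ok) if ok]
        min_c = thresholds.min_c_strict
    def ct_ok(i):
        c, t, o, _ = per_rep[i]
        cov = c + t + o
        return cov > 0 and (c + t) / cov >= thresholds.min_ct_fraction
    if not all(ct_ok(i) for i in route):
        return "80CT"
    if not all(per_rep[i][0] >= min_c for i in route):
        return "C-depth"
    return "10MM"


def candidate_summary(table: pd.DataFrame, thresholds: FilterThresholds | None = None) -> dict:
    """Counts by pass mode plus a first-failing-filter tally of rejections."""
    thresholds = thresholds or FilterThresholds()
    out = {
        "n_sites": int(len(table)),
        "n_candidates": 0,
        BOTH_REPLICATES: 0,
        SINGLE_STRICT: 0,
        "rejections": {f: 0 for f in FILTER_ORDER},
    }
    if table.empty:
        return out
    reps = sorted(
        {int(c[3]) for c in table.columns if c.startswith("rep") and c.endswith("_c")}
    )
    for _, rec in table.iterrows():
        if rec["is_candidate"]:
            out["n_candidates"] += 1
            out[rec["pass_mode"]] += 1
        else:
            out["rejections"][_first_failure(rec, reps, thresholds)] += 1
    return out
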
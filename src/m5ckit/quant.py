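"""Per-cytosine pileups, non-conversion levels, spike-in conversion QC.

The unit of quantification is the reference cytosine: for every C of
every transcript, count how many uniquely-mapped reads show C (methylated,
i.e. non-converted), T (converted) or another base at that position.  The
non-conversion level m = C / (C + T) is the empirical methylation estimate;
other bases are excluded from that ratio but kept in the coverage used by
the 80CT sequencing-noise filter.  Spike-in transcripts, which carry no
methylation by construction, measure the bisulfite conversion efficiency.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import UNIQUE

logger = logging.getLogger(__name__)

PILEUP_COLUMNS = [
    "transcript_id", "pos_0based", "pos_1based", "replicate",
    "c", "t", "other", "coverage", "m",
]


class IntegrityError(RuntimeError):
    """An alignment references a read or transcript that cannot be found."""


def nonconversion_level(c: int, t: int) -> float:
    """m = C/(C+T); NaN (missing) when no C/T evidence exists."""
    if c + t == 0:
        return float("nan")
    return c / (c + t)


def pileup(
    alignments,
    reads: dict[str, str],
    transcripts,
    replicate: int,
) -> pd.DataFrame:
    """Count original read bases at every reference C covered by unique hits.

    Returns one row per (transcript, C position) with coverage >= 1;
    read bases come from the original (uncollapsed) reads.
    """
    by_id = {t.id: t for t in transcripts}
    c_positions = {
        t.id: [i for i, b in enumerate(t.sequence) if b == "C"] for t in transcripts
    }
    counts: dict[tuple[str, int], list[int]] = {}
    for aln in alignments:
        if aln.status != UNIQUE:
            continue
        if aln.transcript_id not in by_id:
            raise IntegrityError(f"alignment references unknown transcript {aln.transcript_id!r}")
        if aln.read_id not in reads:
            raise IntegrityError(f"alignment references unknown read {aln.read_id!r}")
        seq = reads[aln.read_id]
        cpos = c_positions[aln.transcript_id]
        lo = bisect_left(cpos, aln.start)
        hi = bisect_right(cpos, aln.start + len(seq) - 1)
        for p in cpos[lo:hi]:
            base = seq[p - aln.start]
            rec = counts.setdefault((aln.transcript_id, p), [0, 0, 0])
            if base == "C":
                rec[0] += 1
            elif base == "T":
                rec[1] += 1
            else:
                rec[2] += 1
    rows = [
        {
            "transcript_id": tx,
            "pos_0based": p,
            "pos_1based": p + 1,
            "replicate": replicate,
            "c": c,
            "t": t,
            "other": o,
            "coverage": c + t + o,
            "m": nonconversion_level(c, t),
        }
        for (tx, p), (c, t, o) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def pileup_condition(alignments_by_replicate: dict[int, list],
                     reads_by_replicate: dict[int, dict[str, str]],
                     transcripts) -> pd.DataFrame:
    """Stack per-replicate pileups for one condition into one table."""
    frames = [
        pileup(alignments_by_replicate[rep], reads_by_replicate[rep], transcripts, rep)
        for rep in sorted(alignments_by_replicate)
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PILEUP_COLUMNS)


@dataclass
class ConversionReport:
    """Spike-in-derived bisulfite conversion efficiency per replicate.

    efficiency = sum(T) / (sum(C) + sum(T)) over all spike-in C sites;
    spike-ins are unmethylated by construction, so any residual C signal
    is conversion failure.  status is "ok" or "unavailable" (no spike-in
    coverage — a warning, not an abort).
    """

    threshold: float
    efficiency: dict[int, float] = field(default_factory=dict)
    passed: dict[int, bool] = field(default_factory=dict)
    status: str = "ok"


def spikein_conversion(
    pileups: pd.DataFrame,
    transcripts,
    threshold: float = 0.99,
) -> ConversionReport:
    """Pooled spike-in conversion efficiency per replicate, vs threshold."""
    spike_ids = {t.id for t in transcripts if t.is_spikein}
    sub = pileups[pileups["transcript_id"].isin(spike_ids)]
    report = ConversionReport(threshold=threshold)
    if sub.empty or (sub["c"] + sub["t"]).sum() == 0:
        logger.warning("no spike-in coverage; conversion QC unavailable")
        report.status = "unavailable"
        return report
    for rep, grp in sub.groupby("replicate"):
        c, t = int(grp["c"].sum()), int(grp["t"].sum())
        if c + t == 0:
            continue
        eff = t / (c + t)
        report.efficiency[int(rep)] = eff
        report.passed[int(rep)] = eff >= threshold
        if eff < threshold:
            logger.warning(
                "replicate %s: spike-in conversion efficiency %.4f below %.4f",
                rep, eff, threshold,
            )
    return report
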
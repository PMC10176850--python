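"""Targeted bisulfite sequencing clone analysis.

Handles both promoter CpG-island DNA amplicons (scored positions are the
Cs of CpG dinucleotides; non-CpG Cs double as a per-clone conversion
control) and RNA amplicons (every C is potentially methylated).  Clones
are globally aligned to the unconverted amplicon reference with
bisulfite-aware scoring — a T in the clone opposite a reference C is a
match, since it may simply be a converted unmethylated cytosine.

Incomplete bisulfite conversion (typically caused by secondary structure)
leaves unmethylated Cs unconverted and produces false methylation calls.
Following standard practice, a cytosine call is only trusted when the
methylated state recurs across clones; isolated calls are flagged as
unconverted, and clones dominated by such flags are discarded outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

DNA_CPG = "dna-cpg"
RNA_ANYC = "rna-anyc"

KEPT = "kept"
DISCARDED_INCOMPLETE = "discarded-incomplete"
DISCARDED_UNALIGNABLE = "discarded-unalignable"

#: default minimum clone counts per mode (fewer only triggers a warning)
MIN_CLONES = {DNA_CPG: 8, RNA_ANYC: 10}


def _check_mode(mode: str) -> str:
    m = mode.lower()
    aliases = {"dna": DNA_CPG, DNA_CPG: DNA_CPG, "rna": RNA_ANYC, RNA_ANYC: RNA_ANYC}
    if m not in aliases:
        raise ValueError(f"mode must be {DNA_CPG!r} or {RNA_ANYC!r}, got {mode!r}")
    return aliases[m]


@dataclass
class CloneSet:
    """A set of Sanger-sequenced clones from one bisulfite amplicon."""

    region_id: str
    reference: str
    clones: list[str]
    mode: str
    clone_ids: list[str] | None = None
    truth: list[dict[int, str]] | None = None
    incomplete_flags: list[bool] | None = None

    def __post_init__(self):
        if not self.clones:
            raise ValueError("CloneSet requires at least one clone")
        self.mode = _check_mode(self.mode)
        if self.clone_ids is None:
            self.clone_ids = [f"clone{i + 1:02d}" for i in range(len(self.clones))]


def find_scored_positions(reference: str, mode: str) -> list[int]:
    """0-based C positions scored in this mode.

    DNA-CpG mode: Cs of CpG dinucleotides on the given strand.
    RNA-anyC mode: every C (any cytosine can carry m5C on RNA).
    """
    mode = _check_mode(mode)
    if mode == DNA_CPG:
        return [
            i
            for i in range(len(reference) - 1)
            if reference[i] == "C" and reference[i + 1] == "G"
        ]
    return [i for i, b in enumerate(reference) if b == "C"]


@dataclass
class BsAlignment:
    """Global bisulfite-aware alignment of one clone to the reference."""

    clone_id: str
    status: str  # "ok" or discarded-unalignable
    score: float = 0.0
    identity: float = 0.0
    ref_to_clone: dict[int, str] = field(default_factory=dict)


def _bisulfite_aligner(match=1.0, mismatch=-1.0, gap=-2.0) -> Align.PairwiseAligner:
    letters = "ACGTN"
    m = substitution_matrices.Array(letters, dims=2)
    for a in letters:
        for b in letters:
            m[a, b] = match if a == b else mismatch
    # asymmetric: reference C vs clone T is a legitimate conversion, not a
    # mismatch (the defining property of bisulfite-aware scoring)
    m["C", "T"] = match
    for x in letters:
        m["N", x] = 0.0
        m[x, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def align_clone(
    clone: str,
    reference: str,
    clone_id: str = "clone",
    min_identity: float = 0.7,
    length_tolerance: float = 0.2,
) -> BsAlignment:
    """Globally align one clone to the unconverted amplicon reference.

    Clones whose length deviates from the reference by more than
    ``length_tolerance`` or whose bisulfite-aware identity falls below
    ``min_identity`` are marked discarded-unalignable.
    """
    if abs(len(clone) - len(reference)) > length_tolerance * len(reference):
        return BsAlignment(clone_id, DISCARDED_UNALIGNABLE)
    aligner = _bisulfite_aligner()
    aln = aligner.align(reference, clone)[0]
    ref_idx, clone_idx = aln.indices  # -1 marks a gap
    ref_to_clone: dict[int, str] = {}
    n_match = 0
    for col in range(aln.length):
        ri, ci = int(ref_idx[col]), int(clone_idx[col])
        if ri >= 0:
            ref_to_clone[ri] = clone[ci] if ci >= 0 else None
        if ri >= 0 and ci >= 0:
            rb, cb = reference[ri], clone[ci]
            if rb == cb or (rb == "C" and cb == "T"):
                n_match += 1
    identity = n_match / max(len(reference), 1)
    if identity < min_identity:
        return BsAlignment(clone_id, DISCARDED_UNALIGNABLE, aln.score, identity)
    return BsAlignment(clone_id, "ok", aln.score, identity, ref_to_clone)


def _state_at(alignment: BsAlignment, pos: int) -> str:
    base = alignment.ref_to_clone.get(pos)
    if base == "C":
        return "M"
    if base == "T":
        return "U"
    return "missing"  # gap, non-C/T miscall, or position absent


@dataclass
class CloneMatrix:
    """Clones x scored-positions state matrix with per-clone verdicts.

    States: M methylated (clone read C), U unmethylated (read T),
    X flagged-unconverted (isolated methylation call), missing.
    Per-position percents are computed over kept clones only, excluding
    X and missing calls.
    """

    region_id: str
    mode: str
    positions: list[int]  # 0-based; labels are pos + 1 ("C1324" style)
    states: pd.DataFrame  # index clone_id, columns positions
    verdicts: dict[str, str]
    low_confidence: bool = False

    @property
    def kept_clones(self) -> list[str]:
        return [c for c, v in self.verdicts.items() if v == KEPT]

    def percents(self) -> pd.Series:
        kept = self.states.loc[self.kept_clones]
        pct = {}
        for pos in self.positions:
            col = kept[pos]
            n_m = int((col == "M").sum())
            n_u = int((col == "U").sum())
            pct[pos] = 100.0 * n_m / (n_m + n_u) if n_m + n_u else np.nan
        return pd.Series(pct, name="percent_methylated")


def flag_inconsistent(
    clone_set: CloneSet,
    states: pd.DataFrame,
    verdicts: dict[str, str],
    min_recurrence: float | None = None,
    clone_discard_fraction: float = 0.5,
    min_x_calls: int = 3,
) -> CloneMatrix:
    """Apply the inconsistent-cytosine rule and discard incomplete clones.

    A methylated call at a position is flagged X (unconverted) when the
    methylated state is observed in fewer clones than ``min_recurrence``
    (default: the larger of 2 clones and 20% of aligned clones) — i.e. the
    methylation status is not consistently placed across clones.  A clone
    is then discarded as incomplete-conversion when more than
    ``clone_discard_fraction`` of its C-calls (M or X) are flagged X *and*
    at least ``min_x_calls`` calls are flagged: the count floor keeps a
    single stochastic conversion failure from discarding an otherwise
    clean clone on a sparsely methylated amplicon.
    """
    aligned = [c for c, v in verdicts.items() if v == KEPT]
    n = len(aligned)
    min_needed = MIN_CLONES[clone_set.mode]
    low_conf = n < min_needed
    if low_conf:
        logger.warning(
            "%s: only %d aligned clones (< %d); results are low-confidence",
            clone_set.region_id, n, min_needed,
        )
    if min_recurrence is None:
        threshold = max(2.0, 0.2 * n)
    else:
        threshold = min_recurrence if min_recurrence >= 1 else min_recurrence * n
    flagged = states.copy()
    sub = flagged.loc[aligned]
    for pos in states.columns:
        if (sub[pos] == "M").sum() < threshold:
            flagged.loc[flagged[pos] == "M", pos] = "X"
    out_verdicts = dict(verdicts)
    for clone in aligned:
        row = flagged.loc[clone]
        n_x = int((row == "X").sum())
        n_ccalls = n_x + int((row == "M").sum())
        if n_ccalls and n_x >= min_x_calls and n_x / n_ccalls > clone_discard_fraction:
            out_verdicts[clone] = DISCARDED_INCOMPLETE
    return CloneMatrix(
        region_id=clone_set.region_id,
        mode=clone_set.mode,
        positions=list(states.columns),
        states=flagged,
        verdicts=out_verdicts,
        low_confidence=low_conf,
    )


def dna_conversion_qc(
    reference: str,
    alignments: dict[str, BsAlignment],
    threshold: float = 0.95,
) -> dict[str, float | None]:
    """Per-clone conversion rate at non-CpG Cs (DNA-CpG mode only).

    Non-CpG cytosines are never methylated in the CpG-methylation model,
    so their T fraction directly measures bisulfite conversion.  Returns
    clone -> rate (None when the reference has no non-CpG Cs).
    """
    cpg = set(find_scored_positions(reference, DNA_CPG))
    non_cpg = [i for i, b in enumerate(reference) if b == "C" and i not in cpg]
    if not non_cpg:
        logger.warning("no non-CpG cytosines in reference; conversion QC unavailable")
        return {cid: None for cid in alignments}
    rates = {}
    for cid, aln in alignments.items():
        if aln.status != "ok":
            rates[cid] = None
            continue
        n_c = n_t = 0
        for p in non_cpg:
            b = aln.ref_to_clone.get(p)
            if b == "C":
                n_c += 1
            elif b == "T":
                n_t += 1
        rates[cid] = n_t / (n_c + n_t) if n_c + n_t else None
    return rates


def analyze_clones(
    clone_set: CloneSet,
    min_recurrence: float | None = None,
    clone_discard_fraction: float = 0.5,
    min_x_calls: int = 3,
    dna_qc_threshold: float = 0.95,
    min_identity: float = 0.7,
) -> CloneMatrix:
    """Full clone pipeline: align, QC, flag inconsistent calls, summarize."""
    positions = find_scored_positions(clone_set.reference, clone_set.mode)
    alignments = {
        cid: align_clone(seq, clone_set.reference, cid, min_identity=min_identity)
        for cid, seq in zip(clone_set.clone_ids, clone_set.clones)
    }
    verdicts = {
        cid: (KEPT if a.status == "ok" else DISCARDED_UNALIGNABLE)
        for cid, a in alignments.items()
    }
    if clone_set.mode == DNA_CPG:
        for cid, rate in dna_conversion_qc(
            clone_set.reference, alignments, dna_qc_threshold
        ).items():
            if verdicts[cid] == KEPT and rate is not None and rate < dna_qc_threshold:
                verdicts[cid] = DISCARDED_INCOMPLETE
    states = pd.DataFrame(
        {
            pos: {
                cid: (_state_at(alignments[cid], pos) if verdicts[cid] == KEPT else "missing")
                for cid in clone_set.clone_ids
            }
            for pos in positions
        },
        index=clone_set.clone_ids,
        columns=positions,
    )
    # the recurrence filter only sees clones that survived alignment + DNA QC
    pre_verdicts = {
        cid: (KEPT if v == KEPT else v) for cid, v in verdicts.items()
    }
    return flag_inconsistent(
        clone_set, states, pre_verdicts, min_recurrence,
        clone_discard_fraction, min_x_calls,
    )


def summarize(matrix: CloneMatrix) -> pd.DataFrame:
    """Per-position methylation percents over kept clones (TSV-ready)."""
    kept = matrix.states.loc[matrix.kept_clones]
    if kept.empty:
        logger.warning("%s: zero kept clones; empty summary", matrix.region_id)
        return pd.DataFrame(
            columns=["pos_0based", "pos_1based", "n_methylated", "n_unmethylated",
                     "percent_methylated"]
        )
    rows = []
    for pos in matrix.positions:
        col = kept[pos]
        n_m, n_u = int((col == "M").sum()), int((col == "U").sum())
        rows.append(
            {
                "pos_0based": pos,
                "pos_1based": pos + 1,
                "n_methylated": n_m,
                "n_unmethylated": n_u,
                "percent_methylated": 100.0 * n_m / (n_m + n_u) if n_m + n_u else np.nan,
            }
        )
    return pd.DataFrame(rows)


_GLYPH = {"M": "●", "U": "○", "X": "·", "missing": "·"}


def render_lollipop(matrix: CloneMatrix) -> str:
    """Text lollipop rendering: one row per kept clone, one column per C.

    Filled circle = methylated, open circle = unmethylated, middle dot =
    flagged-unconverted or missing.
    """
    header = " ".join(f"C{p + 1}" for p in matrix.positions)
    lines = [f"{matrix.region_id} ({matrix.mode})", header]
    for cid in matrix.kept_clones:
        row = " ".join(_GLYPH[matrix.states.at[cid, p]] for p in matrix.positions)
        lines.append(f"{row}  {cid}")
    pct = matrix.percents()
    lines.append(
        " ".join(
            "--" if np.isnan(pct[p]) else f"{pct[p]:.0f}" for p in matrix.positions
        )
        + "  % methylated"
    )
    return "\n".join(lines)
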
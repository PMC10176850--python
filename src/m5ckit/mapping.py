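"""Conversion-aware ("three-letter") read mapping.

Bisulfite conversion turns unmethylated Cs into Ts, so ordinary alignment
would penalize converted reads.  Both reads and reference are therefore
collapsed C->T before comparison; original read bases are kept so the
quantification step can still distinguish C (methylated, non-converted)
from T at reference cytosines.  The aligner is deliberately simple:
exact collapsed k-mer seeds (first plus mid-read), full-length ungapped
comparison, unique-best-hit policy.  It maps against a transcript set,
not a genome, so splicing and gapped alignment never arise.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


def collapse(sequence: str) -> str:
    """Replace every C by T (the three-letter transform); length-preserving."""
    bad = next((i for i, b in enumerate(sequence) if b not in _VALID), None)
    if bad is not None:
        raise ValueError(
            f"illegal symbol {sequence[bad]!r} at position {bad} (alphabet ACGTN)"
        )
    return sequence.replace("C", "T")


@dataclass
class CollapsedIndex:
    k: int
    seeds: dict[str, list[tuple[str, int]]]
    collapsed: dict[str, str]
    spikeins: frozenset[str] = frozenset()


def index_reference(transcripts, k: int = 20) -> CollapsedIndex:
    """Exact k-mer seed table over the collapsed reference transcripts."""
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
    collapsed: dict[str, str] = {}
    spikes = set()
    for tx in transcripts:
        if len(tx.sequence) < k:
            logger.warning(
                "transcript %s shorter than k=%d; excluded from index", tx.id, k
            )
            continue
        cseq = collapse(tx.sequence)
        collapsed[tx.id] = cseq
        if getattr(tx, "is_spikein", False):
            spikes.add(tx.id)
        for off in range(len(cseq) - k + 1):
            seeds[cseq[off:off + k]].append((tx.id, off))
    return CollapsedIndex(k=k, seeds=dict(seeds), collapsed=collapsed,
                          spikeins=frozenset(spikes))


@dataclass(frozen=True)
class Alignment:
    read_id: str
    transcript_id: str | None
    start: int
    mismatches: int
    status: str


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def map_read(
    read_id: str,
    sequence: str,
    index: CollapsedIndex,
    max_mismatch_fraction: float = 0.05,
) -> Alignment:
    """Map one read: collapsed seeds -> ungapped full-length comparison.

    Unique iff exactly one locus attains the minimal mismatch count within
    floor(max_mismatch_fraction * read length); ties are ambiguous.
    Mismatches are counted in collapsed space, so the read's methylation
    state (C vs T at reference Cs) never penalizes the alignment.
    """
    k = index.k
    L = len(sequence)
    if L < k:
        return Alignment(read_id, None, -1, -1, UNMAPPED)
    cread = collapse(sequence)
    seed_offsets = {0, (L - k) // 2}
    candidates: set[tuple[str, int]] = set()
    for so in seed_offsets:
        for tx, off in index.seeds.get(cread[so:so + k], ()):
            start = off - so
            if start >= 0 and start + L <= len(index.collapsed[tx]):
                candidates.add((tx, start))
    max_mm = math.floor(max_mismatch_fraction * L)
    best_mm, best_loci = None, []
    for tx, start in sorted(candidates):
        mm = _hamming(cread, index.collapsed[tx][start:start + L])
        if mm > max_mm:
            continue
        if best_mm is None or mm < best_mm:
            best_mm, best_loci = mm, [(tx, start)]
        elif mm == best_mm:
            best_loci.append((tx, start))
    if best_mm is None:
        return Alignment(read_id, None, -1, -1, UNMAPPED)
    if len(best_loci) > 1:
        return Alignment(read_id, None, -1, best_mm, AMBIGUOUS)
    tx, start = best_loci[0]
    return Alignment(read_id, tx, start, best_mm, UNIQUE)


@dataclass
class MappingSummary:
    unique: int = 0
    ambiguous: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.unique + self.ambiguous + self.unmapped


def map_all(
    reads,
    index: CollapsedIndex,
    max_mismatch_fraction: float = 0.05,
) -> tuple[list[Alignment], MappingSummary]:
    """Map a read set; per-read results are order-independent."""
    alignments = [
        map_read(r.id, r.sequence, index, max_mismatch_fraction) for r in reads
    ]
    counts = Counter(a.status for a in alignments)
    summary = MappingSummary(
        unique=counts.get(UNIQUE, 0),
        ambiguous=counts.get(AMBIGUOUS, 0),
        unmapped=counts.get(UNMAPPED, 0),
    )
    return alignments, summary
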
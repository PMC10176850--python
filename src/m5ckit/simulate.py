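"""Synthetic bsRNA-seq data generation.

Everything the downstream pipeline consumes can be produced here with
seeded reproducibility: transcript references carrying fully-unmethylated
spike-in controls, ground-truth methylation maps for two conditions
(empty-vector vs methyltransferase-restored), bisulfite-converted reads
with incomplete conversion, clone sets for targeted bisulfite sequencing,
and methylation/expression/clinical association tables.

The generative model at each reference cytosine of a read molecule:
draw methylated ~ Bernoulli(m_true); a methylated C is emitted as C
(except with probability ``overconversion_rate`` it deaminates anyway);
an unmethylated C is emitted as T with probability ``conversion_efficiency``
and otherwise survives as C (incomplete conversion).  All emitted bases are
then substituted uniformly at the sequencing error rate.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clones import CloneSet

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}

EV = "EV"
RESTORED = "NSUN7"
DEFAULT_CONDITIONS = (EV, RESTORED)


@dataclass(frozen=True)
class Transcript:
    """A reference transcript; spike-ins are fully unmethylated controls."""

    id: str
    sequence: str
    is_spikein: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(_ALPHABET)
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: illegal symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimConfig:
    """Bisulfite read simulation parameters.

    conversion_efficiency
        Probability that an unmethylated C reads as T (bisulfite chemistry
        working as intended).  Default 0.995, the regime of a successful
        conversion with a residual false-methylation floor of 0.5%.
    overconversion_rate
        Probability that a *methylated* C nonetheless reads as T.  Default 0.
    seq_error_rate
        Per-base uniform substitution probability after conversion.
    read_length, mean_depth
        Single-end read length (bases) and target fold-coverage.
    depth_mode
        "fixed": read count per transcript is round(depth * L / read_length)
        with uniform random start positions (low-variance default);
        "poisson": the count is Poisson with that mean.
    """

    conversion_efficiency: float = 0.995
    overconversion_rate: float = 0.0
    seq_error_rate: float = 0.001
    read_length: int = 100
    mean_depth: float = 60.0
    n_replicates: int = 2
    depth_mode: str = "fixed"
    seed: int = 0

    def __post_init__(self):
        for name in ("conversion_efficiency", "overconversion_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.depth_mode not in ("fixed", "poisson"):
            raise ValueError("depth_mode must be 'fixed' or 'poisson'")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


class MethylTruth:
    """Ground-truth map (transcript id, 0-based C position) -> per-condition m.

    ``m_true`` is the latent methylation level whose empirical estimate
    downstream is the non-conversion level.  Positions absent from the map
    are unmethylated (m = 0) in every condition; spike-in transcripts can
    never carry entries.
    """

    def __init__(self, conditions=DEFAULT_CONDITIONS):
        self.conditions = tuple(conditions)
        self.entries: dict[tuple[str, int], dict[str, float]] = {}

    def set_site(self, transcript: Transcript, pos: int, levels) -> None:
        if transcript.is_spikein:
            raise ValueError(
                f"cannot place a methylated site on spike-in {transcript.id!r}"
            )
        if not 0 <= pos < len(transcript):
            raise ValueError(f"{transcript.id}:{pos}: position out of range")
        if transcript.sequence[pos] != "C":
            raise ValueError(
                f"{transcript.id}:{pos}: reference base is "
                f"{transcript.sequence[pos]!r}, not C"
            )
        if isinstance(levels, dict):
            lv = {c: float(levels[c]) for c in self.conditions}
        else:
            lv = dict(zip(self.conditions, map(float, levels)))
        for c, m in lv.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"m_true for {c} must be in [0, 1], got {m}")
        self.entries[(transcript.id, pos)] = lv

    def level(self, transcript_id: str, pos: int, condition: str) -> float:
        return self.entries.get((transcript_id, pos), {}).get(condition, 0.0)

    def positions(self, transcript_id: str) -> list[int]:
        return sorted(p for (t, p) in self.entries if t == transcript_id)

    def level_vector(self, transcript: Transcript, condition: str) -> np.ndarray:
        """Dense per-base m_true vector for one transcript and condition."""
        m = np.zeros(len(transcript))
        for (t, p), lv in self.entries.items():
            if t == transcript.id:
                m[p] = lv.get(condition, 0.0)
        return m

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"transcript_id": t, "pos_0based": p, **lv}
            for (t, p), lv in sorted(self.entries.items())
        ]
        cols = ["transcript_id", "pos_0based", *self.conditions]
        return pd.DataFrame(rows, columns=cols)


def _substream(seed: int, *labels) -> np.random.Generator:
    """Derive an independent reproducible RNG stream from the master seed.

    Sub-streams are keyed by CRC32 of the string labels so that
    (condition, replicate) streams never collide or depend on call order.
    """
    key = tuple(zlib.crc32(str(x).encode()) for x in labels)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def make_transcriptome(
    n_transcripts: int,
    length: int = 1000,
    gc_fraction: float = 0.5,
    n_spikeins: int = 2,
    seed: int = 0,
) -> list[Transcript]:
    """Random transcript references plus flagged spike-in controls."""
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    if n_spikeins < 0:
        raise ValueError("n_spikeins must be >= 0")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    out = []
    for i in range(n_transcripts + n_spikeins):
        seq = "".join(rng.choice(list(_ALPHABET), size=length, p=probs))
        spike = i >= n_transcripts
        name = f"spikein_{i - n_transcripts + 1:02d}" if spike else f"tx{i + 1:04d}"
        out.append(Transcript(name, seq, is_spikein=spike))
    return out


def assign_truth(
    transcripts,
    sites=None,
    *,
    n_random: int = 0,
    random_levels=None,
    conditions=DEFAULT_CONDITIONS,
    seed: int = 0,
) -> MethylTruth:
    """Build a ground-truth methylation map.

    ``sites`` is an iterable of (transcript_id, pos_0based, levels) with
    ``levels`` either a per-condition dict or a tuple in condition order.
    Alternatively ``n_random`` C positions on non-spike-in transcripts are
    drawn without replacement and given ``random_levels``.
    """
    by_id = {t.id: t for t in transcripts}
    truth = MethylTruth(conditions)
    for tx_id, pos, levels in sites or []:
        if tx_id not in by_id:
            raise ValueError(f"unknown transcript {tx_id!r}")
        truth.set_site(by_id[tx_id], pos, levels)
    if n_random:
        if random_levels is None:
            raise ValueError("random placement requires random_levels")
        rng = _substream(seed, "assign_truth")
        pool = [
            (t.id, i)
            for t in transcripts
            if not t.is_spikein
            for i, b in enumerate(t.sequence)
            if b == "C" and (t.id, i) not in truth.entries
        ]
        if n_random > len(pool):
            raise ValueError(
                f"requested {n_random} random sites but only {len(pool)} free Cs"
            )
        picks = rng.choice(len(pool), size=n_random, replace=False)
        for j in sorted(picks):
            tx_id, pos = pool[j]
            truth.set_site(by_id[tx_id], pos, random_levels)
    return truth


def find_c_runs(transcript: Transcript, run: int = 3) -> list[int]:
    """Start positions of runs of >= `run` consecutive Cs (cluster planting)."""
    seq = transcript.sequence
    return [
        i
        for i in range(len(seq) - run + 1)
        if all(seq[i + j] == "C" for j in range(run))
    ]


def plant_cluster(truth: MethylTruth, transcript: Transcript, start: int,
                  levels, size: int = 3) -> list[int]:
    """Plant `size` adjacent C sites sharing one methylation profile."""
    positions = list(range(start, start + size))
    for p in positions:
        truth.set_site(transcript, p, levels)
    return positions


@dataclass
class SimRead:
    id: str
    sequence: str
    quality: str

    @staticmethod
    def parse_id(read_id: str) -> dict:
        tx, start, condition, rep, i = read_id.split("|")
        return {
            "transcript_id": tx,
            "start": int(start),
            "condition": condition,
            "replicate": int(rep.removeprefix("rep")),
            "index": int(i),
        }


def bisulfite_reads(
    transcripts,
    truth: MethylTruth,
    config: SimConfig,
    condition: str,
    replicate: int,
) -> list[SimRead]:
    """Simulate one replicate's bisulfite-converted read set.

    Read headers encode origin as ``transcript|start|condition|repN|i`` so
    tests can check truth recovery.  Transcripts shorter than the read
    length are skipped with a warning.
    """
    if replicate >= config.n_replicates:
        raise ValueError(
            f"replicate {replicate} out of range (n_replicates={config.n_replicates})"
        )
    rng = _substream(config.seed, condition, replicate)
    rl = config.read_length
    e = config.conversion_efficiency
    over = config.overconversion_rate
    eps = config.seq_error_rate
    reads: list[SimRead] = []
    for tx in transcripts:
        L = len(tx)
        if L < rl:
            logger.warning(
                "transcript %s (length %d) shorter than read length %d; skipped",
                tx.id, L, rl,
            )
            continue
        mean_n = config.mean_depth * L / rl
        n = int(rng.poisson(mean_n)) if config.depth_mode == "poisson" else int(round(mean_n))
        if n == 0:
            continue
        starts = rng.integers(0, L - rl + 1, size=n)
        seq_idx = np.frombuffer(tx.sequence.encode(), dtype=np.uint8)
        base_codes = np.zeros(256, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            base_codes[ord(b)] = i
        codes = base_codes[seq_idx]  # 0=A 1=C 2=G 3=T per reference base
        m_vec = truth.level_vector(tx, condition)
        win = starts[:, None] + np.arange(rl)[None, :]
        out = codes[win].copy()
        is_c = out == _BASE_INDEX["C"]
        meth = rng.random(win.shape) < m_vec[win]
        u = rng.random(win.shape)
        # unmethylated C converts to T with probability e
        out[is_c & ~meth & (u < e)] = _BASE_INDEX["T"]
        # methylated C deaminates anyway with probability overconversion_rate
        out[is_c & meth & (u < over)] = _BASE_INDEX["T"]
        if eps > 0:
            err = rng.random(win.shape) < eps
            shift = rng.integers(1, 4, size=win.shape)
            out[err] = (out[err] + shift[err]) % 4
        lut = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)
        qual = "I" * rl
        for i in range(n):
            seq = lut[out[i]].tobytes().decode()
            rid = f"{tx.id}|{starts[i]}|{condition}|rep{replicate}|{i}"
            reads.append(SimRead(rid, seq, qual))
    return reads


def clone_sequences(
    reference: str,
    mode: str,
    truth_levels: dict[int, float] | None,
    n_clones: int,
    incomplete_fraction: float = 0.0,
    e_good: float = 0.99,
    e_bad: float = 0.7,
    seed: int = 0,
    region_id: str = "region",
) -> CloneSet:
    """Simulate a clone set for targeted bisulfite sequencing.

    ``round(incomplete_fraction * n_clones)`` clones are drawn with the
    degraded conversion efficiency ``e_bad`` (ground-truth flagged); the
    rest with ``e_good``.  Per-clone per-C methylation is drawn
    Bernoulli(m_true) before conversion; ``truth_levels`` maps 0-based C
    positions to m_true (missing positions are unmethylated).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if e_bad >= e_good:
        raise ValueError(f"e_bad ({e_bad}) must be < e_good ({e_good})")
    if not 0.0 <= incomplete_fraction <= 1.0:
        raise ValueError("incomplete_fraction must be in [0, 1]")
    truth_levels = truth_levels or {}
    for p, m in truth_levels.items():
        if reference[p] != "C":
            raise ValueError(f"position {p}: reference base is not C")
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"m_true at {p} must be in [0, 1]")
    rng = _substream(seed, "clones", region_id)
    n_bad = int(round(incomplete_fraction * n_clones))
    flags = np.zeros(n_clones, dtype=bool)
    flags[rng.choice(n_clones, size=n_bad, replace=False)] = True
    c_positions = [i for i, b in enumerate(reference) if b == "C"]
    clones, truth_states = [], []
    for ci in range(n_clones):
        e = e_bad if flags[ci] else e_good
        seq = list(reference)
        states: dict[int, str] = {}
        for p in c_positions:
            meth = rng.random() < truth_levels.get(p, 0.0)
            states[p] = "M" if meth else "U"
            if not meth and rng.random() < e:
                seq[p] = "T"
        clones.append("".join(seq))
        truth_states.append(states)
    return CloneSet(
        region_id=region_id,
        reference=reference,
        clones=clones,
        mode=mode,
        truth=truth_states,
        incomplete_flags=list(map(bool, flags)),
    )


@dataclass(frozen=True)
class AssocEffect:
    """Group-separation spec for the association-table generator.

    Defaults emulate a cohort split into promoter-methylated tumors
    (high beta, low expression) and unmethylated tumors (the converse)
    with a clean separation; set the two beta/expression means equal
    for a null dataset.
    """

    frac_methylated: float = 0.4
    beta_methylated: float = 0.8
    beta_unmethylated: float = 0.1
    beta_sd: float = 0.05
    expr_methylated: float = -1.0
    expr_unmethylated: float = 1.0
    expr_sd: float = 0.5
    # clinical category frequencies (age>60 is the truly associated one)
    p_male: float = 0.68
    p_age_gt60_methylated: float = 0.65
    p_age_gt60_unmethylated: float = 0.43


def simulate_assoc_tables(
    n_samples: int,
    effect: AssocEffect | None = None,
    seed: int = 0,
    n_cpgs: int = 5,
) -> dict[str, pd.DataFrame]:
    """Paired promoter beta-value / expression / clinical tables.

    Returns ``{"beta": per-sample per-CpG beta values,
    "samples": sample-level table with mean beta, methylation call,
    expression Z-score and clinical covariates}``.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    effect = effect or AssocEffect()
    rng = _substream(seed, "assoc")
    n_meth = int(round(effect.frac_methylated * n_samples))
    group = np.array(["methylated"] * n_meth + ["unmethylated"] * (n_samples - n_meth))
    rng.shuffle(group)
    is_meth = group == "methylated"
    beta_mean = np.where(is_meth, effect.beta_methylated, effect.beta_unmethylated)
    betas = np.clip(
        rng.normal(beta_mean[:, None], effect.beta_sd, size=(n_samples, n_cpgs)),
        0.0, 1.0,
    )
    expr_mean = np.where(is_meth, effect.expr_methylated, effect.expr_unmethylated)
    expr = rng.normal(expr_mean, effect.expr_sd)
    p_age = np.where(is_meth, effect.p_age_gt60_methylated, effect.p_age_gt60_unmethylated)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i + 1:04d}" for i in range(n_samples)],
            "group": group,
            "mean_beta": betas.mean(axis=1),
            "expression": expr,
            "gender": np.where(rng.random(n_samples) < effect.p_male, "male", "female"),
            "age_group": np.where(rng.random(n_samples) < p_age, ">60", "<=60"),
        }
    )
    beta = pd.DataFrame(
        betas, columns=[f"cg{i + 1:03d}" for i in range(n_cpgs)]
    )
    beta.insert(0, "sample_id", samples["sample_id"])
    return {"beta": beta, "samples": samples}
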
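"""File-format helpers: FASTA/FASTQ via Biopython, TSV via pandas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SimRead, Transcript


def write_fasta(transcripts, path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id,
                  description="spikein" if t.is_spikein else "")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, spikein_tag: str = "spikein") -> list[Transcript]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(
            Transcript(
                rec.id,
                str(rec.seq).upper(),
                is_spikein=spikein_tag in rec.description.split(),
            )
        )
    return out


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [
            ord(q) - 33 for q in r.quality
        ]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[SimRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append(SimRead(rec.id, str(rec.seq), qual))
    return out


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def write_truth_tsv(truth, path) -> None:
    write_tsv(truth.to_frame(), path)


def alignments_to_frame(alignments) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "transcript_id": a.transcript_id or "",
                "start_0based": a.start,
                "mismatches": a.mismatches,
                "status": a.status,
            }
            for a in alignments
        ],
        columns=["read_id", "transcript_id", "start_0based", "mismatches", "status"],
    )
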
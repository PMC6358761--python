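"""Readers/writers for the plain-text formats the pipeline exchanges:
FASTA (wrapped at 60 columns), GFF3, and TSV tables."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_WRAP = 60


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


def read_alignment_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a gapped FASTA alignment; all sequences must share one length."""
    seqs = read_fasta(path)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError(f"alignment sequences differ in length: {sorted(lengths)}")
    return seqs


def write_gff3(features: Iterable[tuple], path: str | os.PathLike) -> None:
    """Write GFF3 lines.

    Each feature is a 9-tuple
    ``(seqid, source, type, start, end, score, strand, phase, attributes)``
    with 1-based inclusive coordinates; ``attributes`` is a dict.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, score, strand, phase, attrs in features:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t"
                f"{strand}\t{phase}\t{attr_str}\n"
            )


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
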
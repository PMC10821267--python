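"""Candidate HLA read extraction from paired-end alignments.

The HLA complex sits on chromosome 6 (6p21.3), but its extreme polymorphism
means reads from a non-reference allele may fail to map.  Three rules
therefore define the candidate set taken from a BAM/SAM file:

1. both mates mapped to chromosome 6 in a proper pair;
2. exactly one mate mapped, and it is on chromosome 6 (the other unmapped);
3. both mates unmapped.

Secondary and supplementary records are ignored; sequences are restored to
original read orientation (reverse-complemented back when the aligned record
is on the reverse strand) and emitted as paired FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .errors import DataError

DEFAULT_CHROM_NAMES = ("6", "chr6")


@dataclass
class ReadPair:
    """One read pair in original (sequencer) orientation, Phred+33 qualities."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise DataError(f"read pair {self.id}: empty mate sequence")
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise DataError(f"read pair {self.id}: quality/sequence length mismatch")


@dataclass
class ExtractionSummary:
    """Per-rule pair counts for one extraction run."""

    kept_rule1: int = 0
    kept_rule2: int = 0
    kept_rule3: int = 0
    discarded: int = 0
    skipped_missing_mate: int = 0

    @property
    def kept(self) -> int:
        return self.kept_rule1 + self.kept_rule2 + self.kept_rule3

    @property
    def total_pairs(self) -> int:
        return self.kept + self.discarded

    def as_dict(self) -> dict:
        return {
            "kept_rule1_proper_pair_chr6": self.kept_rule1,
            "kept_rule2_one_mate_chr6": self.kept_rule2,
            "kept_rule3_both_unmapped": self.kept_rule3,
            "discarded": self.discarded,
            "skipped_missing_mate": self.skipped_missing_mate,
        }


def _forward_seq_qual(rec: pysam.AlignedSegment) -> tuple[str, str]:
    seq = rec.get_forward_sequence()
    quals = rec.get_forward_qualities()
    if seq is None:
        raise DataError(f"record {rec.query_name}: missing sequence")
    qual = (
        "".join(chr(q + 33) for q in quals) if quals is not None else "I" * len(seq)
    )
    return seq, qual


def _keep_rule(
    r1: pysam.AlignedSegment, r2: pysam.AlignedSegment, chrom_names: frozenset[str]
) -> int:
    """Return 1/2/3 for the matching extraction rule, 0 to discard."""
    m1, m2 = not r1.is_unmapped, not r2.is_unmapped
    on6_1 = m1 and r1.reference_name in chrom_names
    on6_2 = m2 and r2.reference_name in chrom_names
    if m1 and m2:
        return 1 if (on6_1 and on6_2 and r1.is_proper_pair) else 0
    if m1 != m2:  # exactly one mate mapped; proper-pair flag not required
        return 2 if (on6_1 or on6_2) else 0
    return 3


def extract_candidate_reads(
    alignment_path: str | Path,
    chrom_names: tuple[str, ...] = DEFAULT_CHROM_NAMES,
) -> tuple[list[ReadPair], ExtractionSummary]:
    """Extract candidate HLA read pairs from a BAM/SAM file.

    Returns the kept pairs (each emitted once, in original orientation) and a
    summary of per-rule counts.  Single-end records are an error; a record
    whose mate never appears is skipped with a warning count.  Duplicate- and
    QC-fail-flagged records are kept.
    """
    names = frozenset(chrom_names)
    summary = ExtractionSummary()
    pairs: list[ReadPair] = []
    pending: dict[str, pysam.AlignedSegment] = {}
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
            for rec in af:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if not rec.is_paired:
                    raise DataError(
                        f"record {rec.query_name} is single-end; "
                        "only paired-end data is supported"
                    )
                mate = pending.pop(rec.query_name, None)
                if mate is None:
                    pending[rec.query_name] = rec
                    continue
                r1, r2 = (mate, rec) if mate.is_read1 else (rec, mate)
                rule = _keep_rule(r1, r2, names)
                if rule == 0:
                    summary.discarded += 1
                    continue
                seq1, qual1 = _forward_seq_qual(r1)
                seq2, qual2 = _forward_seq_qual(r2)
                pairs.append(
                    ReadPair(
                        id=r1.query_name, seq1=seq1, qual1=qual1, seq2=seq2, qual2=qual2
                    )
                )
                if rule == 1:
                    summary.kept_rule1 += 1
                elif rule == 2:
                    summary.kept_rule2 += 1
                else:
                    summary.kept_rule3 += 1
    finally:
        pysam.set_verbosity(save)
    summary.skipped_missing_mate = len(pending)
    return pairs, summary


def write_fastq_pair(
    pairs, out1_path: str | Path, out2_path: str | Path
) -> tuple[Path, Path]:
    """Write pairs as two standard 4-line FASTQ files (Phred+33)."""
    out1_path, out2_path = Path(out1_path), Path(out2_path)
    with open(out1_path, "w") as f1, open(out2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}\n{p.seq2}\n+\n{p.qual2}\n")
    return out1_path, out2_path


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Read two mate FASTQ files back into :class:`ReadPair` objects."""

    def _records(path):
        out = []
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().rstrip("\n")
                fh.readline()
                qual = fh.readline().rstrip("\n")
                out.append((header[1:].rstrip("\n"), seq, qual))
        return out

    r1s, r2s = _records(path1), _records(path2)
    if len(r1s) != len(r2s):
        raise DataError("mate FASTQ files have different record counts")
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1s, r2s):
        if id1 != id2:
            raise DataError(f"mate id mismatch: {id1!r} vs {id2!r}")
        pairs.append(ReadPair(id=id1, seq1=s1, qual1=q1, seq2=s2, qual2=q2))
    return pairs
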
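"""Read-pair / allele compatibility.

A read pair "potentially originated" from an allele when each mate aligns
ungapped, full-length, on either strand, to the allele's concatenated-exon
transcript with at most ``max_mismatches`` substitutions — both mates on the
same transcript.  Because transcripts are exon concatenations, exon-junction
reads match without special handling.

The incidence of pairs against a whole library is the sparse boolean matrix
consumed by the genotyping ILP.  Pairs with identical compatibility rows are
collapsed into one weighted row, which preserves the ILP objective exactly.
An exact k-mer seed prefilter accelerates matrix construction; the seed
length ``k = floor(L / (max_mismatches + 1))`` guarantees (pigeonhole) that
any qualifying ungapped match contains an exact k-mer, so the prefilter never
discards a pair the full check would accept.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse
from scipy.io import mmread, mmwrite

from .errors import DataError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def default_max_mismatches(read_length: int) -> int:
    """Default per-mate mismatch budget: max(2, ceil(2% of mate length)).

    The budget is sized to sequencing error (a handful of substitutions per
    mate) and deliberately kept below typical inter-allele divergence: a
    budget that tolerates as many mismatches as alleles differ by makes reads
    compatible with the wrong allele and destroys identifiability.
    """
    return max(2, math.ceil(0.02 * read_length))


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mate_matches(mate: str, transcript_arr: np.ndarray, max_mismatches: int) -> bool:
    """Exhaustive all-offset ungapped scan of one mate (both strands)."""
    for oriented in (mate, revcomp(mate)):
        m = _as_bytes(oriented)
        if len(m) > len(transcript_arr):
            continue
        windows = sliding_window_view(transcript_arr, len(m))
        mismatches = (windows != m).sum(axis=1)
        if (mismatches <= max_mismatches).any():
            return True
    return False


def match_read_to_allele(
    read_pair, transcript: str, max_mismatches: int | None = None
) -> bool:
    """True iff both mates align ungapped to *transcript* within the budget.

    This is the definitional check; :func:`build_incidence` computes the same
    predicate with a sound prefilter.  A mate longer than the transcript
    simply does not match (no error).
    """
    t = _as_bytes(transcript)
    for mate in (read_pair.seq1, read_pair.seq2):
        mm = max_mismatches
        if mm is None:
            mm = default_max_mismatches(len(mate))
        if mm < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not _mate_matches(mate, t, mm):
            return False
    return True


@dataclass
class CompatibilityMatrix:
    """Sparse read-pattern x allele incidence with pattern weights.

    Rows are distinct compatibility patterns; ``weights[i]`` counts the read
    pairs sharing pattern ``i``.  Pairs compatible with no allele are dropped
    before storage (counted in ``n_pairs_incompatible``).
    """

    allele_names: list[str]
    loci: list[str]
    incidence: sparse.csr_matrix  # bool, patterns x alleles
    weights: np.ndarray  # float, per pattern
    pattern_read_ids: list[list[str]]
    n_pairs_input: int = 0
    n_pairs_incompatible: int = 0

    @property
    def n_patterns(self) -> int:
        return self.incidence.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def column_index(self, allele: str) -> int:
        return self.allele_names.index(allele)

    def save(self, directory: str | Path) -> None:
        """Persist as MTX + two sidecar TSVs (patterns/weights, allele names)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / "incidence.mtx"), self.incidence.astype(np.int8))
        with open(directory / "patterns.tsv", "w") as fh:
            fh.write("pattern\tweight\tread_ids\n")
            for i, (w, ids) in enumerate(zip(self.weights, self.pattern_read_ids)):
                fh.write(f"{i}\t{w:g}\t{','.join(ids)}\n")
        with open(directory / "alleles.tsv", "w") as fh:
            fh.write("allele\tlocus\n")
            for name, locus in zip(self.allele_names, self.loci):
                fh.write(f"{name}\t{locus}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "CompatibilityMatrix":
        directory = Path(directory)
        inc = sparse.csr_matrix(mmread(str(directory / "incidence.mtx"))).astype(bool)
        weights, read_ids = [], []
        with open(directory / "patterns.tsv") as fh:
            fh.readline()
            for line in fh:
                _, w, ids = line.rstrip("\n").split("\t")
                weights.append(float(w))
                read_ids.append(ids.split(",") if ids else [])
        names, loci = [], []
        with open(directory / "alleles.tsv") as fh:
            fh.readline()
            for line in fh:
                name, locus = line.rstrip("\n").split("\t")
                names.append(name)
                loci.append(locus)
        return cls(
            allele_names=names,
            loci=loci,
            incidence=inc,
            weights=np.asarray(weights, dtype=float),
            pattern_read_ids=read_ids,
            n_pairs_input=int(sum(weights)),
        )


class _KmerIndex:
    """Exact k-mer seed index over a set of transcripts."""

    def __init__(self, sequences: list[str], k: int):
        self.k = k
        self.seqs = [_as_bytes(s) for s in sequences]
        self.index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for si, seq in enumerate(sequences):
            for pos in range(len(seq) - k + 1):
                self.index[seq[pos : pos + k]].append((si, pos))

    def candidate_offsets(self, mate: str) -> dict[int, set[int]]:
        """Map transcript index -> candidate alignment offsets for one mate."""
        out: dict[int, set[int]] = defaultdict(set)
        k = self.k
        for i in range(len(mate) - k + 1):
            for si, pos in self.index.get(mate[i : i + k], ()):
                off = pos - i
                if 0 <= off <= len(self.seqs[si]) - len(mate):
                    out[si].add(off)
        return out

    def mate_hits(self, mate: str, max_mismatches: int) -> set[int]:
        """Transcript indices the mate matches (either strand), via seeds."""
        hits: set[int] = set()
        for oriented in (mate, revcomp(mate)):
            m = _as_bytes(oriented)
            for si, offsets in self.candidate_offsets(oriented).items():
                if si in hits:
                    continue
                seq = self.seqs[si]
                for off in offsets:
                    if (
                        np.count_nonzero(seq[off : off + len(m)] != m)
                        <= max_mismatches
                    ):
                        hits.add(si)
                        break
        return hits


def _seed_length(read_lengths, max_mismatches_fn) -> int:
    """Largest provably sound seed length for the dataset (capped at 31)."""
    k = 31
    for length in read_lengths:
        mm = max_mismatches_fn(length)
        k = min(k, max(1, length // (mm + 1)))
    return k


def build_incidence(
    pairs,
    sequences: dict[str, str],
    max_mismatches: int | None = None,
    prefilter: bool = True,
):
    """Compute the pair x transcript compatibility structure.

    Returns ``(ids, patterns, dropped)``: the transcript id order, a dict
    mapping each distinct compatibility pattern (sorted tuple of transcript
    indices) to the list of read ids sharing it, and the number of pairs
    compatible with nothing.
    """
    if not sequences:
        raise DataError("empty transcript set")
    ids = list(sequences)
    seqs = [sequences[i] for i in ids]
    mm_fn = (
        default_max_mismatches if max_mismatches is None else (lambda L: max_mismatches)
    )
    pairs = list(pairs)
    if not pairs:
        return ids, {}, 0

    if prefilter:
        k = _seed_length(
            {len(p.seq1) for p in pairs} | {len(p.seq2) for p in pairs}, mm_fn
        )
        index = _KmerIndex(seqs, k)
    else:
        index = None
    seq_arrays = [_as_bytes(s) for s in seqs]

    patterns: dict[tuple[int, ...], list[str]] = {}
    dropped = 0
    for pair in pairs:
        if index is not None:
            h1 = index.mate_hits(pair.seq1, mm_fn(len(pair.seq1)))
            h2 = index.mate_hits(pair.seq2, mm_fn(len(pair.seq2))) if h1 else set()
            compat = h1 & h2
        else:
            compat = {
                si
                for si, arr in enumerate(seq_arrays)
                if _mate_matches(pair.seq1, arr, mm_fn(len(pair.seq1)))
                and _mate_matches(pair.seq2, arr, mm_fn(len(pair.seq2)))
            }
        if not compat:
            dropped += 1
            continue
        patterns.setdefault(tuple(sorted(compat)), []).append(pair.id)
    return ids, patterns, dropped


def build_compatibility_matrix(
    pairs,
    lib,
    max_mismatches: int | None = None,
    prefilter: bool = True,
) -> CompatibilityMatrix:
    """Build the weighted read x allele incidence matrix for a library.

    The library must be complete (all template exons present); transcripts are
    the concatenated-exon sequences.  Zero compatible reads yields a valid
    empty matrix with a warning.
    """
    if len(lib.records) == 0:
        raise DataError("empty allele library")
    if not lib.is_complete():
        raise DataError(
            "library has missing exons; run reconstruct_missing_exons first"
        )
    sequences = {key: lib.transcript(key) for key in sorted(lib.records)}
    pairs = list(pairs)
    ids, patterns, dropped = build_incidence(
        pairs, sequences, max_mismatches=max_mismatches, prefilter=prefilter
    )
    loci = [lib.records[key].name.locus for key in ids]
    n_pat = len(patterns)
    rows, cols = [], []
    weights = np.zeros(n_pat, dtype=float)
    read_ids: list[list[str]] = []
    for r, (pattern, id_list) in enumerate(sorted(patterns.items())):
        weights[r] = len(id_list)
        read_ids.append(id_list)
        for c in pattern:
            rows.append(r)
            cols.append(c)
    incidence = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)),
        shape=(n_pat, len(ids)),
        dtype=bool,
    )
    if n_pat == 0:
        warnings.warn("no read pair is compatible with any allele", stacklevel=2)
    return CompatibilityMatrix(
        allele_names=ids,
        loci=loci,
        incidence=incidence,
        weights=weights,
        pattern_read_ids=read_ids,
        n_pairs_input=len(pairs),
        n_pairs_incompatible=dropped,
    )
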
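"""Personalized transcriptome construction and allele-specific TPM.

Because the reference transcriptome carries only one generic sequence per HLA
gene, reads from a non-reference allele misquantify.  The personalized index
removes all reference HLA transcripts and adds the individual's own typed
allele sequences, so abundance is estimated against the sequences actually
transcribed.  Transcript abundance is estimated with the standard generative
EM over read-transcript compatibility, reported as transcripts per million
(TPM); gene TPM is the sum of the TPMs of the gene's constituent transcripts.

A homozygous genotype contributes its allele sequence once (two identical
sequences would make the mixture unidentifiable), recorded with copy number 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .compatibility import build_incidence
from .errors import DataError
from .genotyping import GenotypeCall
from .reference import AlleleLibrary, _read_fasta

EM_TOL = 1e-8
EM_MAX_ITER = 1000
DEFAULT_MEAN_FRAGMENT_LENGTH = 200.0


@dataclass
class PersonalizedTranscriptome:
    """Reference transcriptome with HLA transcripts replaced by typed alleles."""

    sequences: dict[str, str]
    provenance: dict[str, str]  # transcript id -> "reference" | "hla_personal"
    txt2gene: dict[str, str]
    copy_number: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)


def read_transcriptome_fasta(path) -> dict[str, str]:
    """Read a transcript FASTA; ids are the first whitespace-delimited token."""
    seqs: dict[str, str] = {}
    for header, seq in _read_fasta(path):
        tid = header.split()[0]
        if tid in seqs:
            raise DataError(f"duplicate transcript id {tid}")
        seqs[tid] = seq.upper()
    return seqs


def read_txt2gene(path) -> dict[str, str]:
    """Read a transcript-to-gene TSV (two columns, optional header)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, gene = line.split("\t")[:2]
            if tid in ("transcript_id", "transcript"):
                continue
            mapping[tid] = gene
    return mapping


def build_personalized_transcriptome(
    reference: dict[str, str] | str | Path,
    hla_transcript_ids: list[str],
    genotype: GenotypeCall | list[str],
    lib: AlleleLibrary,
    txt2gene: dict[str, str],
) -> PersonalizedTranscriptome:
    """Remove reference HLA transcripts and add the sample's typed alleles.

    Each called allele is added once under its canonical name (homozygous
    calls get copy number 2) and mapped to its locus as gene id.  A typed
    allele absent from the library is an error; an HLA transcript id absent
    from the reference only warns.
    """
    ref = (
        dict(reference)
        if isinstance(reference, dict)
        else read_transcriptome_fasta(reference)
    )
    missing = [tid for tid in hla_transcript_ids if tid not in ref]
    if missing:
        warnings.warn(
            f"HLA transcript id(s) not found in reference: {missing}", stacklevel=2
        )
    sequences = {
        tid: seq for tid, seq in ref.items() if tid not in set(hla_transcript_ids)
    }
    provenance = {tid: "reference" for tid in sequences}
    mapping = {tid: txt2gene[tid] for tid in sequences if tid in txt2gene}
    copy_number = {tid: 1 for tid in sequences}

    if isinstance(genotype, GenotypeCall):
        allele_entries: list[tuple[str, str]] = []
        for locus in sorted(genotype.calls):
            call = genotype.calls[locus]
            if call is None:
                continue
            allele_entries.append((call.allele1, locus))
            if not call.homozygous:
                allele_entries.append((call.allele2, locus))
            else:
                pass  # one sequence, copy number 2
        hom_loci = {
            locus
            for locus, call in genotype.calls.items()
            if call is not None and call.homozygous
        }
    else:
        allele_entries = []
        seen: dict[str, int] = {}
        for a in genotype:
            seen[a] = seen.get(a, 0) + 1
        for a in seen:
            allele_entries.append((a, lib.record(a).name.locus))
        hom_loci = set()

    for allele, locus in allele_entries:
        if allele in sequences:
            continue  # homozygous second copy or duplicate listing
        sequences[allele] = lib.transcript(allele)  # raises if absent from library
        provenance[allele] = "hla_personal"
        mapping[allele] = locus
        copy_number[allele] = 2 if locus in hom_loci else 1
    if not isinstance(genotype, GenotypeCall):
        for a, n in seen.items():
            copy_number[a] = n
    return PersonalizedTranscriptome(
        sequences=sequences,
        provenance=provenance,
        txt2gene=mapping,
        copy_number=copy_number,
    )


@dataclass
class AbundanceTable:
    """Per-transcript abundance estimates.

    ``transcripts`` is indexed by transcript id with columns ``eff_length``,
    ``est_count`` and ``tpm``; TPMs sum to 1e6 whenever at least one read was
    assigned.
    """

    transcripts: pd.DataFrame
    n_pairs_used: int
    n_pairs_dropped: int
    log_likelihood: float = float("nan")
    n_iterations: int = 0
    ll_history: list = field(default_factory=list)

    def save(self, path) -> None:
        out = self.transcripts.reset_index().rename(columns={"index": "transcript_id"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def effective_length(length: int, mean_fragment_length: float) -> float:
    """Fragment-count normalization length, clipped at 1."""
    return max(1.0, length - mean_fragment_length + 1.0)


def quantify_em(
    pairs,
    txome: PersonalizedTranscriptome,
    max_mismatches: int | None = None,
    mean_fragment_length: float = DEFAULT_MEAN_FRAGMENT_LENGTH,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> AbundanceTable:
    """Estimate transcript abundance by EM over read-transcript compatibility.

    The E-step assigns each read pair fractionally among its compatible
    transcripts proportionally to ``theta_t / eff_len_t``; the M-step
    re-normalizes.  Convergence is max |delta theta| < *tol* (default 1e-8) or
    *max_iter* iterations.  Pairs compatible with no transcript are dropped
    and counted; if every pair drops, an all-zero table is returned with a
    warning.
    """
    if len(txome) == 0:
        raise DataError("empty transcriptome")
    pairs = list(pairs)
    if not pairs:
        raise DataError("quantify_em requires at least one read pair")
    ids, patterns, dropped = build_incidence(
        pairs, txome.sequences, max_mismatches=max_mismatches
    )
    eff_len = np.array(
        [effective_length(len(txome.sequences[t]), mean_fragment_length) for t in ids]
    )
    n_t = len(ids)

    if not patterns:
        warnings.warn("no read pair compatible with any transcript", stacklevel=2)
        table = pd.DataFrame(
            {"eff_length": eff_len, "est_count": 0.0, "tpm": 0.0}, index=ids
        )
        return AbundanceTable(
            transcripts=table, n_pairs_used=0, n_pairs_dropped=dropped
        )

    pat_list = sorted(patterns)
    w = np.array([len(patterns[p]) for p in pat_list], dtype=float)
    rows = np.concatenate(
        [np.full(len(p), i) for i, p in enumerate(pat_list)]
    ).astype(int)
    cols = np.concatenate([np.asarray(p) for p in pat_list]).astype(int)
    inc = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(pat_list), n_t)
    )

    n_reads = w.sum()
    theta = np.full(n_t, 1.0 / n_t)
    ll = -np.inf
    ll_history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        rate = theta / eff_len
        denom = inc @ rate  # per pattern
        resp = inc.multiply(rate[None, :]).multiply((w / denom)[:, None])
        counts = np.asarray(resp.sum(axis=0)).ravel()
        theta_new = counts / n_reads
        ll = float(w @ np.log(denom))
        ll_history.append(ll)
        delta = np.abs(theta_new - theta).max()
        theta = theta_new
        if delta < tol:
            break
    counts = theta * n_reads
    rate = counts / eff_len
    tpm = rate / rate.sum() * 1e6
    table = pd.DataFrame(
        {"eff_length": eff_len, "est_count": counts, "tpm": tpm}, index=ids
    )
    return AbundanceTable(
        transcripts=table,
        n_pairs_used=int(n_reads),
        n_pairs_dropped=dropped,
        log_likelihood=ll,
        n_iterations=it,
        ll_history=ll_history,
    )


def em_log_likelihood(
    theta: np.ndarray, inc: sparse.csr_matrix, w: np.ndarray, eff_len: np.ndarray
) -> float:
    """Data log-likelihood of a transcript-fraction vector (for diagnostics)."""
    denom = inc @ (theta / eff_len)
    return float(w @ np.log(denom))


def gene_tpm(table: AbundanceTable, txt2gene: dict[str, str]) -> pd.Series:
    """Aggregate transcript TPM to gene TPM by summation.

    Every transcript must be mapped to a gene; total TPM is conserved.
    """
    unmapped = [t for t in table.transcripts.index if t not in txt2gene]
    if unmapped:
        raise DataError(f"transcript(s) not mapped to a gene: {unmapped}")
    genes = pd.Series(
        [txt2gene[t] for t in table.transcripts.index], index=table.transcripts.index
    )
    out = table.transcripts["tpm"].groupby(genes).sum().sort_index()
    out.name = "tpm"
    out.index.name = "gene_id"
    return out
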
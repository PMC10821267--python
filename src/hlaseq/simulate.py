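"""Synthetic data generation.

Every downstream module is testable without external downloads: this module
fabricates allele libraries with known G-group structure, incomplete
(exon-truncated) libraries, paired-end RNA-seq reads from a known genotype at
a chosen coverage and error rate, and matched tumor-normal expression cohorts
with planted effects.  Defaults emulate the study conditions of the public
breast-cancer cohort this workflow targets: 2 x 50 bp paired-end reads,
30-fold coverage per allele, a 0.5% per-base substitution error rate, and
~2% pairwise sequence divergence between alleles of a locus.  All generators
are fully deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compatibility import revcomp
from .errors import DataError
from .read_extraction import ReadPair
from .reference import (
    STATUS_CWD,
    STATUS_OTHER,
    AlleleLibrary,
    AlleleRecord,
    GGroupTable,
    build_g_group_table,
    locus_class,
    peptide_binding_exons,
)
from .nomenclature import parse_allele_name

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Toy exon-length templates loosely shaped like real HLA transcripts:
#: eight exons (~1.1 kb) for Class I, six (~0.8 kb) for Class II.
DEFAULT_EXON_LENGTHS = {
    "I": (73, 270, 276, 276, 117, 33, 48, 50),
    "II": (100, 270, 282, 111, 24, 45),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, with the emulated-study defaults."""

    seed: int = 0
    loci: tuple[str, ...] = ("HLA-A", "HLA-B", "HLA-C")
    alleles_per_locus: int = 20
    pairwise_divergence: float = 0.02
    exon_lengths: dict = field(default_factory=lambda: dict(DEFAULT_EXON_LENGTHS))
    read_length: int = 50
    coverage: float = 30.0
    error_rate: float = 0.005
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 30.0

    def __post_init__(self) -> None:
        for name, rate in (
            ("pairwise_divergence", self.pairwise_divergence),
            ("error_rate", self.error_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {rate}")
        if self.coverage <= 0:
            raise DataError("coverage must be positive")
        if self.alleles_per_locus < 1:
            raise DataError("alleles_per_locus must be >= 1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability *rate*."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_toy_library(cfg: SimulationConfig) -> tuple[AlleleLibrary, GGroupTable]:
    """Generate a toy allele library plus its true G-group table.

    Per locus an ancestral transcript is split into template exons; alleles
    are derived by seeded substitutions at half the target pairwise divergence
    (two independently mutated alleles then differ by about the full target).
    The first two alleles of each locus are made identical over the
    peptide-binding exons, creating one true multi-allele G group per locus.
    """
    rng = np.random.default_rng(cfg.seed)
    records: dict[str, AlleleRecord] = {}
    template: dict[str, tuple[int, ...]] = {}
    for locus in cfg.loci:
        lengths = cfg.exon_lengths[locus_class(locus)]
        exon_idxs = tuple(range(1, len(lengths) + 1))
        template[locus] = exon_idxs
        ancestor = {i: _random_seq(rng, n) for i, n in zip(exon_idxs, lengths)}
        locus_records: list[AlleleRecord] = []
        seen_seqs: set[str] = set()
        for j in range(cfg.alleles_per_locus):
            # resample the rare zero-substitution draws so alleles are distinct
            for _attempt in range(20):
                exons = {
                    i: _mutate(rng, ancestor[i], cfg.pairwise_divergence / 2.0)
                    for i in exon_idxs
                }
                seq = "".join(exons[i] for i in exon_idxs)
                if seq not in seen_seqs:
                    break
            else:
                raise DataError(
                    f"cannot generate distinct alleles at locus {locus}: drawn "
                    "sequences are identical; increase pairwise_divergence or "
                    "sequence length"
                )
            seen_seqs.add(seq)
            name = parse_allele_name(f"{locus}*{j + 1:02d}:01:01")
            status = STATUS_CWD if rng.random() < 0.3 else STATUS_OTHER
            locus_records.append(
                AlleleRecord(name=name, exons=exons, status=status)
            )
        if len(locus_records) >= 2:  # one true multi-allele G group per locus
            pb = peptide_binding_exons(locus)
            donor = locus_records[0]
            mate_exons = dict(locus_records[1].exons)
            for i in pb:
                mate_exons[i] = donor.exons[i]
            # G-group mates are distinct alleles: if no substitution landed
            # outside the peptide-binding exons, plant one deterministically
            non_pb = [i for i in exon_idxs if i not in pb]
            if non_pb and all(
                mate_exons[i] == donor.exons[i] for i in non_pb
            ):
                i = non_pb[0]
                arr = np.frombuffer(mate_exons[i].encode(), dtype=np.uint8).copy()
                pos = int(rng.integers(len(arr)))
                arr[pos] = rng.choice(_BASES[_BASES != arr[pos]])
                mate_exons[i] = arr.tobytes().decode()
            locus_records[1] = AlleleRecord(
                name=locus_records[1].name,
                exons=mate_exons,
                status=locus_records[1].status,
            )
        seen: dict[str, str] = {}
        for rec in locus_records:
            seq = "".join(rec.exons[i] for i in exon_idxs)
            if seq in seen:
                raise DataError(
                    f"alleles {seen[seq]} and {rec.name} are identical; "
                    "increase pairwise_divergence or sequence length"
                )
            seen[seq] = str(rec.name)
            records[str(rec.name)] = rec
    lib = AlleleLibrary(records=records, exon_template=template, version=f"toy-{cfg.seed}")
    return lib, build_g_group_table(lib)


def truncate_library(
    lib: AlleleLibrary,
    keep_exons_per_class: dict[str, set[int]] | None = None,
    fraction: float = 0.5,
    seed: int = 0,
) -> AlleleLibrary:
    """Strip a fraction of records down to a keep set of exons.

    Emulates the incomplete entries of real HLA databases, where many alleles
    carry only the peptide-binding exons.  At least one complete record per
    locus is always preserved.
    """
    if keep_exons_per_class is None:
        keep_exons_per_class = {"I": {2, 3}, "II": {2}}
    for cls, keep in keep_exons_per_class.items():
        if not keep:
            raise DataError(f"empty keep set for class {cls}")
    rng = np.random.default_rng(seed)
    new_records: dict[str, AlleleRecord] = {}
    for locus in sorted(lib.loci):
        locus_keys = sorted(str(r.name) for r in lib.by_locus(locus))
        n_truncate = int(fraction * len(locus_keys))
        n_truncate = min(n_truncate, len(locus_keys) - 1)  # keep one complete
        chosen = set(
            rng.choice(locus_keys[1:], size=n_truncate, replace=False)
            if n_truncate > 0
            else []
        )
        keep = keep_exons_per_class[locus_class(locus)]
        for key in locus_keys:
            rec = lib.records[key]
            if key in chosen:
                new_records[key] = AlleleRecord(
                    name=rec.name,
                    exons={i: s for i, s in rec.exons.items() if i in keep},
                    status=rec.status,
                )
            else:
                new_records[key] = rec
    return AlleleLibrary(
        records=new_records, exon_template=dict(lib.exon_template), version=lib.version
    )


def simulate_reads(
    alleles: dict[str, float] | list[str],
    lib: AlleleLibrary,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[ReadPair], pd.DataFrame, dict[str, float]]:
    """Simulate paired-end reads from a known genotype.

    *alleles* maps allele name to its abundance weight (molar fraction; a
    plain list means equal weights).  Fragments are drawn per allele
    proportionally to weight x transcript length; fragment length is Normal
    (clipped to [read_length, transcript length]); mate 1 is the fragment
    start, mate 2 the reverse complement of the fragment end; substitution
    errors are i.i.d. per base.  Returns the pairs, a per-read truth table
    (read id -> source allele) and the true TPM per allele.
    """
    if isinstance(alleles, (list, tuple)):
        alleles = {a: 1.0 for a in alleles}
    if not alleles:
        raise DataError("no alleles to simulate from")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    names = sorted(alleles)
    tx = {a: lib.transcript(a) for a in names}
    for a, seq in tx.items():
        if len(seq) < cfg.read_length:
            raise DataError(
                f"transcript of {a} ({len(seq)} bp) shorter than read length"
            )
    weights = np.array([alleles[a] for a in names], dtype=float)
    lengths = np.array([len(tx[a]) for a in names], dtype=float)
    probs = weights * lengths
    probs /= probs.sum()
    n_pairs = int(round(cfg.coverage * lengths.sum() / (2 * cfg.read_length)))
    rl = cfg.read_length
    qual = "I" * rl

    src_idx = rng.choice(len(names), size=n_pairs, p=probs)
    pairs: list[ReadPair] = []
    truth_rows = []
    for i in range(n_pairs):
        a = names[src_idx[i]]
        seq = tx[a]
        frag_len = int(round(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd)))
        frag_len = max(rl, min(frag_len, len(seq)))
        start = int(rng.integers(0, len(seq) - frag_len + 1))
        frag = seq[start : start + frag_len]
        mate1 = _mutate(rng, frag[:rl], cfg.error_rate)
        mate2 = _mutate(rng, revcomp(frag[-rl:]), cfg.error_rate)
        rid = f"sim:{i}"
        pairs.append(ReadPair(id=rid, seq1=mate1, qual1=qual, seq2=mate2, qual2=qual))
        truth_rows.append({"read_id": rid, "allele": a})
    truth = pd.DataFrame(truth_rows, columns=["read_id", "allele"])
    total_w = weights.sum()
    true_tpm = {a: 1e6 * alleles[a] / total_w for a in names}
    return pairs, truth, true_tpm


#: Genes of the tumor-normal comparison: classical and non-classical HLA
#: Class I/II plus B2M, with typical bulk-tissue baseline log2 TPMs.
DEFAULT_COHORT_BASELINES = {
    "HLA-A": 9.0,
    "HLA-B": 9.5,
    "HLA-C": 8.5,
    "HLA-E": 6.5,
    "HLA-F": 4.5,
    "HLA-G": 3.0,
    "HLA-DPA1": 6.0,
    "HLA-DPB1": 6.0,
    "HLA-DQA1": 5.0,
    "HLA-DQB1": 5.0,
    "HLA-DRA": 7.5,
    "HLA-DRB1": 7.0,
    "B2M": 10.5,
}


def simulate_cohort(
    n_pairs: int,
    planted_gene_effects: dict[str, float] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    baselines: dict[str, float] | None = None,
    allele_pool_size: int = 30,
):
    """Simulate a matched tumor/adjacent-normal expression cohort.

    Per patient a unique random Class I genotype key is shared by the tumor
    and the normal sample.  Expression is generated on the log2 scale —
    baseline plus Normal(0, noise_sd) noise, with planted log2 effects added
    to the tumor — and returned as TPM (``2**x - 1``) matrices (gene x
    sample).  Returns ``(tumor_df, normal_df, tumor_keys, normal_keys)``.
    """
    if n_pairs < 2:
        raise DataError("need at least two tumor-normal pairs")
    planted = planted_gene_effects or {}
    base = baselines or DEFAULT_COHORT_BASELINES
    unknown = set(planted) - set(base)
    if unknown:
        raise DataError(f"planted effect on unknown gene(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    pool = {
        locus: [f"{locus}*{i + 1:02d}:01:01" for i in range(allele_pool_size)]
        for locus in ("HLA-A", "HLA-B", "HLA-C")
    }
    keys: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    attempts = 0
    while len(keys) < n_pairs:
        attempts += 1
        if attempts > 1000 * n_pairs:
            raise DataError(
                "cannot draw enough unique genotype keys; "
                "increase allele_pool_size"
            )
        key: list[str] = []
        for locus in ("HLA-A", "HLA-B", "HLA-C"):
            picked = rng.choice(pool[locus], size=2, replace=True)
            key.extend(sorted(picked))
        tkey = tuple(key)
        if tkey not in seen:
            seen.add(tkey)
            keys.append(tkey)

    genes = sorted(base)
    mu = np.array([base[g] for g in genes])
    effect = np.array([planted.get(g, 0.0) for g in genes])
    tumor_log = (
        mu[:, None] + effect[:, None] + rng.normal(0.0, noise_sd, (len(genes), n_pairs))
    )
    normal_log = mu[:, None] + rng.normal(0.0, noise_sd, (len(genes), n_pairs))
    t_samples = [f"T{i + 1:02d}" for i in range(n_pairs)]
    n_samples = [f"N{i + 1:02d}" for i in range(n_pairs)]
    tumor = pd.DataFrame(2.0**tumor_log - 1.0, index=genes, columns=t_samples)
    normal = pd.DataFrame(2.0**normal_log - 1.0, index=genes, columns=n_samples)
    tumor_keys = {s: keys[i] for i, s in enumerate(t_samples)}
    normal_keys = {s: keys[i] for i, s in enumerate(n_samples)}
    return tumor, normal, tumor_keys, normal_keys
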
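import numpy as np
import pytest
from scipy import sparse

from hlaseq import SimulationConfig, generate_toy_library
from hlaseq.compatibility import CompatibilityMatrix


def make_cm(allele_names, loci, rows, weights=None, read_ids=None):
    """Build a CompatibilityMatrix from a dense boolean row list."""
    dense = np.asarray(rows, dtype=bool)
    if dense.size == 0:
        dense = dense.reshape(0, len(allele_names))
    if weights is None:
        weights = np.ones(dense.shape[0])
    if read_ids is None:
        read_ids = [[f"r{i}"] for i in range(dense.shape[0])]
    return CompatibilityMatrix(
        allele_names=list(allele_names),
        loci=list(loci),
        incidence=sparse.csr_matrix(dense),
        weights=np.asarray(weights, dtype=float),
        pattern_read_ids=read_ids,
        n_pairs_input=int(np.sum(weights)),
    )


def random_ilp_instance(rng):
    """Random small genotyping instance: <=3 loci, <=8 alleles/locus, <=200 reads."""
    n_loci = int(rng.integers(1, 4))
    names, loci = [], []
    for li in range(n_loci):
        locus = f"HLA-{chr(ord('A') + li)}"
        for ai in range(int(rng.integers(2, 9))):
            names.append(f"{locus}*{ai + 1:02d}:01")
            loci.append(locus)
    n_patterns = int(rng.integers(1, 25))
    dense = rng.random((n_patterns, len(names))) < rng.uniform(0.1, 0.5)
    keep = dense.any(axis=1)
    dense = dense[keep]
    if dense.shape[0] == 0:
        dense = np.zeros((1, len(names)), dtype=bool)
        dense[0, 0] = True
    max_total = 200
    weights = rng.integers(1, 20, size=dense.shape[0]).astype(float)
    while weights.sum() > max_total:
        weights = np.maximum(1, weights // 2)
    lam = float(rng.choice([0.25, 0.5, 1.0, 2.0]))
    return make_cm(names, loci, dense, weights), lam


@pytest.fixture(scope="session")
def toy_cfg():
    return SimulationConfig(seed=1, alleles_per_locus=8)


@pytest.fixture(scope="session")
def toy_library(toy_cfg):
    """3 Class I loci x 8 alleles at 2% divergence, with true G groups."""
    lib, ggroups = generate_toy_library(toy_cfg)
    return lib, ggroups


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:6\tLN:200000\n@SQ\tSN:7\tLN:200000\n"


def sam_line(qname, flag, rname, pos, seq, mapq=60):
    cigar = f"{len(seq)}M" if not (flag & 0x4) else "*"
    return (
        f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq if not (flag & 0x4) else 0}\t"
        f"{cigar}\t{'=' if rname != '*' else '*'}\t{pos}\t0\t{seq}\t{'I' * len(seq)}\n"
    )


@pytest.fixture
def rule_sam(tmp_path):
    """Hand-built SAM: one exemplar pair per extraction rule plus three decoys.

    Rule 1: proper pair on chr6 (mate 2 reverse strand).
    Rule 2: mate 1 mapped on chr6, mate 2 unmapped.
    Rule 3: both mates unmapped.
    Decoys: proper pair on chr7; chr6 pair without the proper flag;
    chr7-mapped mate with unmapped mate.
    """
    lines = [SAM_HEADER]
    # rule 1; mate2 stored reverse-complemented (flag 0x10 set)
    lines.append(sam_line("rule1", 99, "6", 100, "ACGTACGTAC"))
    lines.append(sam_line("rule1", 147, "6", 300, "TTTTGGGGCC"))
    # rule 2
    lines.append(sam_line("rule2", 73, "6", 500, "AAAACCCCGG"))
    lines.append(sam_line("rule2", 133, "6", 500, "GGGGTTTTAA"))
    # rule 3
    lines.append(sam_line("rule3", 77, "*", 0, "ACACACACAC"))
    lines.append(sam_line("rule3", 141, "*", 0, "GTGTGTGTGT"))
    # decoys
    lines.append(sam_line("decoy_chr7", 99, "7", 100, "ACGTACGTAC"))
    lines.append(sam_line("decoy_chr7", 147, "7", 300, "ACGTACGTAC"))
    lines.append(sam_line("decoy_improper", 97, "6", 700, "ACGTACGTAC"))
    lines.append(sam_line("decoy_improper", 145, "6", 900, "ACGTACGTAC"))
    lines.append(sam_line("decoy_chr7_unmapped", 73, "7", 1100, "ACGTACGTAC"))
    lines.append(sam_line("decoy_chr7_unmapped", 133, "7", 1100, "ACGTACGTAC"))
    path = tmp_path / "candidates.sam"
    path.write_text("".join(lines))
    return path
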
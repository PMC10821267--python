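import numpy as np
import pytest
from scipy import sparse

from hlaseq import (
    ReadPair,
    SimulationConfig,
    build_personalized_transcriptome,
    gene_tpm,
    generate_toy_library,
    quantify_em,
    revcomp,
    simulate_reads,
    solve_genotype_ilp,
)
from hlaseq.errors import DataError
from hlaseq.expression import (
    AbundanceTable,
    PersonalizedTranscriptome,
    em_log_likelihood,
)
from hlaseq.genotyping import GenotypeCall, LocusCall

import pandas as pd


def _pair(seq1, seq2, rid="r"):
    return ReadPair(
        id=rid, seq1=seq1, qual1="I" * len(seq1), seq2=seq2, qual2="I" * len(seq2)
    )


def _txome(seqs, genes=None):
    return PersonalizedTranscriptome(
        sequences=dict(seqs),
        provenance={t: "reference" for t in seqs},
        txt2gene=genes or {t: t for t in seqs},
    )


@pytest.fixture(scope="module")
def small_library():
    cfg = SimulationConfig(seed=4, alleles_per_locus=5)
    return generate_toy_library(cfg)[0], cfg


# ---------------------------------------------------------------------------
# personalized transcriptome


def _call(locus, a1, a2):
    return LocusCall(allele1=a1, allele2=a2, homozygous=a1 == a2, explained_reads=0.0)


def test_personalized_transcriptome_replaces_hla_transcripts(small_library):
    lib, _ = small_library
    genotype = GenotypeCall(
        calls={"HLA-A": _call("HLA-A", "HLA-A*01:01:01", "HLA-A*02:01:01")},
        objective_value=0.0, total_explained=0.0, solver_status="optimal",
        lambda_hom=1.0,
    )
    ref = {"ENST_HLA_A": "ACGT" * 50, "ENST_GAPDH": "GGCC" * 50}
    tx = build_personalized_transcriptome(
        ref, ["ENST_HLA_A"], genotype, lib,
        {"ENST_HLA_A": "HLA-A", "ENST_GAPDH": "GAPDH"},
    )
    assert set(tx.sequences) == {"ENST_GAPDH", "HLA-A*01:01:01", "HLA-A*02:01:01"}
    assert tx.provenance["HLA-A*01:01:01"] == "hla_personal"
    assert tx.txt2gene["HLA-A*01:01:01"] == "HLA-A"
    assert tx.sequences["HLA-A*01:01:01"] == lib.transcript("HLA-A*01:01:01")


def test_homozygous_genotype_contributes_one_sequence_copy_number_two(small_library):
    lib, _ = small_library
    genotype = GenotypeCall(
        calls={"HLA-A": _call("HLA-A", "HLA-A*01:01:01", "HLA-A*01:01:01")},
        objective_value=0.0, total_explained=0.0, solver_status="optimal",
        lambda_hom=1.0,
    )
    tx = build_personalized_transcriptome({}, [], genotype, lib, {})
    assert list(tx.sequences) == ["HLA-A*01:01:01"]
    assert tx.copy_number["HLA-A*01:01:01"] == 2


def test_unknown_hla_transcript_id_warns(small_library):
    lib, _ = small_library
    with pytest.warns(UserWarning, match="ENST_MISSING"):
        build_personalized_transcriptome(
            {"t1": "ACGT" * 10}, ["ENST_MISSING"], ["HLA-A*01:01:01"], lib,
            {"t1": "g1"},
        )


def test_typed_allele_absent_from_library_is_error(small_library):
    lib, _ = small_library
    with pytest.raises(DataError, match="not in library"):
        build_personalized_transcriptome({}, [], ["HLA-A*99:99"], lib, {})


# ---------------------------------------------------------------------------
# EM quantification


def test_unique_reads_recover_closed_form_tpm():
    t1, t2 = "ACGTAGGTTCAC" * 10, "TTGCACCATGGA" * 20  # 120 and 240 bp
    txome = _txome({"t1": t1, "t2": t2})
    pairs = [_pair(t1[:30], revcomp(t1[-30:]), f"a{i}") for i in range(30)]
    pairs += [_pair(t2[:30], revcomp(t2[-30:]), f"b{i}") for i in range(30)]
    table = quantify_em(pairs, txome, max_mismatches=0, mean_fragment_length=60)
    eff1, eff2 = 120 - 60 + 1, 240 - 60 + 1
    expected1 = (30 / eff1) / (30 / eff1 + 30 / eff2) * 1e6
    assert table.transcripts.loc["t1", "tpm"] == pytest.approx(expected1, rel=1e-6)
    assert table.transcripts.tpm.sum() == pytest.approx(1e6, rel=1e-6)


def test_identical_transcripts_split_fifty_fifty():
    seq = "ACGTAGGTTCACTTGCACCATGGA" * 6
    txome = _txome({"t1": seq, "t2": seq})
    pairs = [_pair(seq[:30], revcomp(seq[-30:]), f"r{i}") for i in range(40)]
    table = quantify_em(pairs, txome, max_mismatches=0)
    assert table.transcripts.loc["t1", "est_count"] == pytest.approx(20, rel=1e-6)
    assert table.transcripts.loc["t1", "tpm"] == pytest.approx(5e5, rel=1e-6)


def test_em_beats_grid_search_likelihood_oracle():
    # two transcripts sharing a region: some reads ambiguous, some unique
    rng = np.random.default_rng(11)
    shared = "".join(rng.choice(list("ACGT"), 80))
    u1 = "".join(rng.choice(list("ACGT"), 80))
    u2 = "".join(rng.choice(list("ACGT"), 80))
    t1, t2 = shared + u1, shared + u2
    txome = _txome({"t1": t1, "t2": t2})
    pairs = [_pair(shared[:25], revcomp(shared[-25:]), f"s{i}") for i in range(12)]
    pairs += [_pair(u1[:25], revcomp(u1[-25:]), f"u{i}") for i in range(7)]
    pairs += [_pair(u2[:25], revcomp(u2[-25:]), f"v{i}") for i in range(3)]
    table = quantify_em(pairs, txome, max_mismatches=0, mean_fragment_length=50)
    eff = np.array([160 - 50 + 1.0] * 2)
    inc = sparse.csr_matrix(np.array([[1, 1], [1, 0], [0, 1]], dtype=float))
    w = np.array([12.0, 7.0, 3.0])
    grid_best = max(
        em_log_likelihood(np.array([f, 1 - f]), inc, w, eff)
        for f in np.arange(0.001, 1.0, 0.001)
    )
    assert table.log_likelihood >= grid_best - 1e-9


def test_em_log_likelihood_monotone_across_iterations():
    rng = np.random.default_rng(3)
    seqs = {
        f"t{k}": "".join(rng.choice(list("ACGT"), 150)) for k in range(4)
    }
    seqs["t9"] = seqs["t0"][:100] + seqs["t1"][:50]  # overlap creates ambiguity
    txome = _txome(seqs)
    pairs = []
    for k, seq in enumerate(seqs.values()):
        for i in range(6):
            start = int(rng.integers(0, len(seq) - 60))
            frag = seq[start : start + 60]
            pairs.append(_pair(frag[:25], revcomp(frag[-25:]), f"p{k}:{i}"))
    table = quantify_em(pairs, txome, max_mismatches=0)
    history = np.array(table.ll_history)
    assert (np.diff(history) >= -1e-9).all()


def test_incompatible_reads_dropped_and_counted():
    txome = _txome({"t1": "ACGT" * 30})
    pairs = [_pair("ACGT" * 7, revcomp("ACGT" * 7), "ok"),
             _pair("TTTT" * 7, "TTTT" * 7, "alien")]
    table = quantify_em(pairs, txome, max_mismatches=0)
    assert table.n_pairs_dropped == 1
    assert table.n_pairs_used == 1


def test_all_reads_dropped_warns_and_zeroes():
    txome = _txome({"t1": "ACGT" * 30})
    with pytest.warns(UserWarning, match="no read pair"):
        table = quantify_em([_pair("T" * 28, "T" * 28)], txome, max_mismatches=0)
    assert (table.transcripts.tpm == 0).all()


def test_homozygous_single_sequence_equals_duplicate_pair_sum():
    seq = "ACGTAGGTTCACTTGCACCATGGA" * 6
    other = "GGTTACCAGGTTACACGGTTACCA" * 6
    pairs = [_pair(seq[i : i + 25], revcomp(seq[i + 40 : i + 65]), f"r{i}")
             for i in range(0, 60, 3)]
    pairs += [_pair(other[:25], revcomp(other[-25:]), f"o{i}") for i in range(10)]
    one = quantify_em(pairs, _txome({"hom": seq, "bg": other}), max_mismatches=0)
    two = quantify_em(
        pairs, _txome({"hom_a": seq, "hom_b": seq, "bg": other}), max_mismatches=0
    )
    locus_one = one.transcripts.loc["hom", "tpm"]
    locus_two = two.transcripts.loc[["hom_a", "hom_b"], "tpm"].sum()
    assert locus_one == pytest.approx(locus_two, rel=1e-6)


def test_planted_two_to_one_abundance_recovered(small_library):
    lib, _ = small_library
    cfg = SimulationConfig(seed=4, alleles_per_locus=5, coverage=120.0)
    a1, a2 = "HLA-A*03:01:01", "HLA-A*04:01:01"
    pairs, _, true_tpm = simulate_reads({a1: 2.0, a2: 1.0}, lib, cfg, seed=21)
    assert len(pairs) >= 2000
    txome = build_personalized_transcriptome({}, [], [a1, a2], lib, {})
    table = quantify_em(pairs, txome)
    ratio = table.transcripts.loc[a1, "tpm"] / table.transcripts.loc[a2, "tpm"]
    assert ratio == pytest.approx(2.0, rel=0.1)


# ---------------------------------------------------------------------------
# gene aggregation


def _abundance(tpms):
    df = pd.DataFrame(
        {"eff_length": 100.0, "est_count": 1.0, "tpm": list(tpms.values())},
        index=list(tpms),
    )
    return AbundanceTable(transcripts=df, n_pairs_used=1, n_pairs_dropped=0)


def test_gene_tpm_sums_constituent_transcripts():
    table = _abundance({"t1": 100.0, "t2": 200.0, "t3": 50.0})
    out = gene_tpm(table, {"t1": "g1", "t2": "g1", "t3": "g2"})
    assert out["g1"] == 300.0
    assert out["g2"] == 50.0
    assert out.sum() == table.transcripts.tpm.sum()


def test_gene_tpm_unmapped_transcript_is_error():
    table = _abundance({"t1": 100.0, "t2": 200.0})
    with pytest.raises(DataError, match="t2"):
        gene_tpm(table, {"t1": "g1"})


def test_total_tpm_conserved_through_aggregation(small_library):
    lib, cfg = small_library
    a1, a2 = "HLA-A*01:01:01", "HLA-B*02:01:01"
    pairs, _, _ = simulate_reads({a1: 1.0, a2: 1.0}, lib, cfg, seed=2)
    txome = build_personalized_transcriptome({}, [], [a1, a2], lib, {})
    table = quantify_em(pairs[:400], txome)
    genes = gene_tpm(table, txome.txt2gene)
    assert genes.sum() == pytest.approx(1e6, rel=1e-6)
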
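"""Tumor-normal matching and cohort differential statistics.

Tumor and adjacent-normal RNA-seq samples that lack explicit pairing metadata
are matched by HLA genotype: the classical Class I genotype (HLA-A/-B/-C, two
alleles per locus) at three fields of resolution — identity at the nucleotide
level in the coding region — is sufficient to identify a patient.  Matched
groups are then compared per gene with Student's t-test on log2(TPM+1),
Bonferroni-corrected across genes, with an additional fold-change filter for
the strict significance call.  Immune-cell fraction tables produced by an
external deconvolution tool are compared with the same machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .genotyping import GenotypeCall
from .nomenclature import parse_allele_name, truncate_resolution

CLASSICAL_CLASS_I = ("HLA-A", "HLA-B", "HLA-C")
DEFAULT_MATCH_RESOLUTION = 3
#: log2 fold-change cutoff for the strict significance flag (1.5-fold).
DEFAULT_FC_THRESHOLD = 0.585


def make_genotype_key(
    genotype: GenotypeCall | dict,
    loci: tuple[str, ...] = CLASSICAL_CLASS_I,
    resolution: int = DEFAULT_MATCH_RESOLUTION,
) -> tuple[str, ...]:
    """Canonical 6-allele matching key: sorted allele pair per Class I locus.

    Allele names are truncated to *resolution* fields (default 3, the
    coding-region level).  Accepts a :class:`GenotypeCall` or a plain mapping
    ``locus -> (allele1, allele2)``.
    """

    def pair(locus: str) -> tuple[str, str]:
        if isinstance(genotype, GenotypeCall):
            alleles = genotype.alleles(locus)
        else:
            alleles = genotype.get(locus)
        if alleles is None:
            raise DataError(f"genotype lacks locus {locus} required for matching")
        return alleles

    key = []
    for locus in loci:
        trunc = [
            str(truncate_resolution(n, min(resolution, n.resolution)))
            for n in map(parse_allele_name, pair(locus))
        ]
        key.extend(sorted(trunc))
    return tuple(key)


@dataclass
class MatchResult:
    """Outcome of genotype-key matching between tumor and normal samples."""

    pairs: list[tuple[str, str]]  # (tumor sample, normal sample)
    unmatched_tumor: list[str]
    unmatched_normal: list[str]
    ambiguous: list[str] = field(default_factory=list)


def match_tumor_normal(
    tumor_keys: dict[str, tuple], normal_keys: dict[str, tuple]
) -> MatchResult:
    """Match tumors to normals by identical genotype keys, one-to-one.

    A key shared by two or more tumors or two or more normals cannot identify
    a patient: every sample carrying it is flagged ambiguous and left
    unmatched.
    """
    by_key_t: dict[tuple, list[str]] = {}
    for s, k in tumor_keys.items():
        by_key_t.setdefault(k, []).append(s)
    by_key_n: dict[tuple, list[str]] = {}
    for s, k in normal_keys.items():
        by_key_n.setdefault(k, []).append(s)

    pairs, ambiguous = [], []
    unmatched_t, unmatched_n = [], []
    for key in sorted(set(by_key_t) | set(by_key_n)):
        ts, ns = sorted(by_key_t.get(key, [])), sorted(by_key_n.get(key, []))
        if len(ts) > 1 or len(ns) > 1:
            ambiguous.extend(ts + ns)
        elif ts and ns:
            pairs.append((ts[0], ns[0]))
        else:
            unmatched_t.extend(ts)
            unmatched_n.extend(ns)
    return MatchResult(
        pairs=sorted(pairs),
        unmatched_tumor=sorted(unmatched_t),
        unmatched_normal=sorted(unmatched_n),
        ambiguous=sorted(ambiguous),
    )


def _ttest(
    tumor: np.ndarray, normal: np.ndarray, paired: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Student's t-test; degenerate rows (zero variance, equal means)
    get t=0, p=1 and are flagged."""
    with warnings.catch_warnings():
        # degenerate (zero-variance) rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            if tumor.shape[1] != normal.shape[1]:
                raise DataError("paired test requires equal group sizes")
            t, p = stats.ttest_rel(tumor, normal, axis=1)
        else:
            t, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=True)
    t, p = np.asarray(t, dtype=float), np.asarray(p, dtype=float)
    diff = tumor.mean(axis=1) - normal.mean(axis=1)
    degenerate = ~np.isfinite(t)
    for i in np.flatnonzero(degenerate):
        if abs(diff[i]) < 1e-12:
            t[i], p[i] = 0.0, 1.0
        else:  # zero variance but different means: maximal evidence
            t[i], p[i] = np.sign(diff[i]) * np.inf, 0.0
    return t, p, degenerate


def _check_gene_sets(tumor: pd.DataFrame, normal: pd.DataFrame) -> None:
    if set(tumor.index) != set(normal.index):
        raise DataError("tumor and normal matrices carry different gene sets")


def differential_expression(
    tumor_matrix: pd.DataFrame,
    normal_matrix: pd.DataFrame,
    paired: bool = False,
    alpha: float = 0.05,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal comparison on log2(TPM+1).

    Returns a gene-indexed frame with ``mean_log2_fc`` (tumor minus normal),
    ``t_statistic``, ``p_value``, Bonferroni-adjusted ``p_adjusted`` and two
    flags: ``significant_raw`` (p < alpha) and ``significant_strict``
    (p_adjusted < alpha and |mean_log2_fc| >= fc_threshold).
    """
    _check_gene_sets(tumor_matrix, normal_matrix)
    if tumor_matrix.shape[1] < 2 or normal_matrix.shape[1] < 2:
        raise DataError("need at least two samples per group")
    normal_matrix = normal_matrix.loc[tumor_matrix.index]
    lt = np.log2(tumor_matrix.to_numpy(dtype=float) + 1.0)
    ln = np.log2(normal_matrix.to_numpy(dtype=float) + 1.0)
    t, p, degenerate = _ttest(lt, ln, paired)
    n_genes = len(tumor_matrix.index)
    p_adj = np.minimum(1.0, p * n_genes)
    fc = lt.mean(axis=1) - ln.mean(axis=1)
    return pd.DataFrame(
        {
            "mean_log2_fc": fc,
            "t_statistic": t,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant_raw": p < alpha,
            "significant_strict": (p_adj < alpha) & (np.abs(fc) >= fc_threshold),
            "degenerate": degenerate,
        },
        index=tumor_matrix.index,
    )


def compare_fraction_tables(
    tumor_fractions: pd.DataFrame,
    normal_fractions: pd.DataFrame,
    alpha: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """Compare immune-cell fractions (cell type x sample) between groups.

    Fractions must lie in [0, 1]; the t-test runs on the raw fractions and
    the Bonferroni factor is the number of cell types tested.
    """
    _check_gene_sets(tumor_fractions, normal_fractions)
    for name, mat in (("tumor", tumor_fractions), ("normal", normal_fractions)):
        vals = mat.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1).any():
            raise DataError(f"{name} fraction table has values outside [0, 1]")
    normal_fractions = normal_fractions.loc[tumor_fractions.index]
    ft = tumor_fractions.to_numpy(dtype=float)
    fn = normal_fractions.to_numpy(dtype=float)
    t, p, degenerate = _ttest(ft, fn, paired)
    n_types = len(tumor_fractions.index)
    p_adj = np.minimum(1.0, p * n_types)
    return pd.DataFrame(
        {
            "mean_diff": ft.mean(axis=1) - fn.mean(axis=1),
            "t_statistic": t,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant_raw": p < alpha,
            "significant_adjusted": p_adj < alpha,
            "degenerate": degenerate,
        },
        index=tumor_fractions.index,
    )
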
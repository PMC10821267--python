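"""One-step ILP HLA genotyping and accuracy evaluation.

Genotyping selects one or two alleles per locus, jointly across all loci in a
single integer linear program, maximizing the number of read pairs compatible
with at least one selected allele.  With binary selection variables ``y_a``
and read-coverage variables ``x_r``::

    maximize   sum_r w_r * x_r  -  lambda_hom * sum_a y_a
    subject to 1 <= sum_{a in locus} y_a <= 2        for every locus
               x_r <= sum_{a compatible with r} y_a  for every read pattern

Each read is counted once globally even when compatible with alleles of
several loci.  The per-allele penalty ``lambda_hom`` decides zygosity by
parsimony: a second allele is called only when it explains at least
``lambda_hom`` additional reads, otherwise the locus is called homozygous.

Ties among equal-objective optima are broken deterministically: at small
scale by exhaustive enumeration of alternate optima (picking the
lexicographically smallest sorted allele-name selection), at large scale by a
tiny name-rank epsilon folded into the objective.

Accuracy against a truth genotype is scored at G-group resolution: a
predicted allele is correct if it lies in the same G group as a truth allele
(maximum bipartite matching between the two predicted and two truth alleles),
with plain field-truncation comparison as the fallback when no G-group table
applies.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .compatibility import CompatibilityMatrix
from .errors import DataError, SolverError
from .nomenclature import parse_allele_name, truncate_resolution
from .reference import GGroupTable, locus_class

#: Above this many per-locus selection combinations the exact tie-break
#: enumeration is skipped in favor of the objective epsilon.
TIE_ENUMERATION_LIMIT = 100_000

_TOL = 1e-9


@dataclass
class LocusCall:
    """Selected alleles at one locus; ``allele1 == allele2`` when homozygous."""

    allele1: str
    allele2: str
    homozygous: bool
    explained_reads: float


@dataclass
class GenotypeCall:
    """Joint genotype over all requested loci.

    ``calls`` maps locus to a :class:`LocusCall`, or ``None`` for a no-call
    (locus with zero compatible reads).  ``objective_value`` is the penalized
    solver objective (explained reads minus ``lambda_hom`` per selected
    allele); ``total_explained`` is the weighted number of reads compatible
    with at least one selected allele, each counted once.
    """

    calls: dict[str, LocusCall | None]
    objective_value: float
    total_explained: float
    solver_status: str
    lambda_hom: float

    def alleles(self, locus: str) -> tuple[str, str] | None:
        call = self.calls.get(locus)
        return None if call is None else (call.allele1, call.allele2)


# ---------------------------------------------------------------------------
# shared machinery


def _locus_options(dense: np.ndarray, names: list[str], cols: list[int]):
    """All one- and two-allele selections at one locus.

    Returns (option allele-name tuples sorted, coverage bool arrays, sizes).
    Option order is deterministic: singletons then pairs, by allele name.
    """
    order = sorted(cols, key=lambda c: names[c])
    opts, covers, sizes = [], [], []
    for c in order:
        opts.append((names[c], names[c]))
        covers.append(dense[:, c])
        sizes.append(1)
    for c1, c2 in itertools.combinations(order, 2):
        a, b = sorted((names[c1], names[c2]))
        opts.append((a, b))
        covers.append(dense[:, c1] | dense[:, c2])
        sizes.append(2)
    return opts, np.asarray(covers, dtype=bool), np.asarray(sizes)


def _n_combinations(cm: CompatibilityMatrix, loci: list[str]) -> int:
    total = 1
    for locus in loci:
        n = sum(1 for l in cm.loci if l == locus)
        total *= n + n * (n - 1) // 2
    return total


def _enumerate_optimum(
    cm: CompatibilityMatrix, active_loci: list[str], lambda_hom: float
):
    """Exhaustive search over per-locus {1,2}-allele selections.

    Returns ``(best_objective, selection)`` where *selection* maps locus to
    its sorted allele-name pair; among equal-objective optima the
    lexicographically smallest tuple-of-pairs (loci in sorted order) wins.
    """
    dense = cm.incidence.toarray()
    w = cm.weights
    per_locus = []
    for locus in active_loci:
        cols = [i for i, l in enumerate(cm.loci) if l == locus]
        per_locus.append(_locus_options(dense, cm.allele_names, cols))

    best_obj = -math.inf
    best_key: tuple | None = None
    best_sel: dict | None = None

    prefix_loci, last = per_locus[:-1], per_locus[-1]
    last_opts, last_cov, last_sizes = last
    prefix_indices = itertools.product(*(range(len(p[0])) for p in prefix_loci))
    for idxs in prefix_indices:
        cover = np.zeros(dense.shape[0], dtype=bool)
        size = 0
        for (opts, covs, sizes), i in zip(prefix_loci, idxs):
            cover |= covs[i]
            size += sizes[i]
        objs = (last_cov | cover) @ w - lambda_hom * (last_sizes + size)
        block_best = objs.max()
        if block_best < best_obj - _TOL:
            continue
        tie_idx = np.flatnonzero(objs >= max(block_best, best_obj) - _TOL)
        for j in tie_idx:
            sel = {
                locus: per_locus[k][0][idxs[k]]
                for k, locus in enumerate(active_loci[:-1])
            }
            sel[active_loci[-1]] = last_opts[j]
            key = tuple(sel[locus] for locus in sorted(sel))
            obj_j = float(objs[j])
            if (
                obj_j > best_obj + _TOL
                or (abs(obj_j - best_obj) <= _TOL and (best_key is None or key < best_key))
            ):
                best_obj, best_key, best_sel = max(best_obj, obj_j), key, sel
    return best_obj, best_sel


def _finalize(
    cm: CompatibilityMatrix,
    selection: dict[str, tuple[str, str]],
    no_call_loci: list[str],
    lambda_hom: float,
    status: str,
) -> GenotypeCall:
    dense = cm.incidence.toarray() if cm.n_patterns else np.zeros((0, len(cm.allele_names)), dtype=bool)
    name_to_col = {n: i for i, n in enumerate(cm.allele_names)}
    all_cols: set[int] = set()
    n_selected = 0
    calls: dict[str, LocusCall | None] = {locus: None for locus in no_call_loci}
    for locus, (a1, a2) in selection.items():
        cols = {name_to_col[a1], name_to_col[a2]}
        all_cols |= cols
        n_selected += len({a1, a2})
        covered = dense[:, sorted(cols)].any(axis=1) if cm.n_patterns else np.zeros(0, bool)
        calls[locus] = LocusCall(
            allele1=a1,
            allele2=a2,
            homozygous=(a1 == a2),
            explained_reads=float(cm.weights @ covered) if cm.n_patterns else 0.0,
        )
    if all_cols and cm.n_patterns:
        total = float(cm.weights @ dense[:, sorted(all_cols)].any(axis=1))
    else:
        total = 0.0
    return GenotypeCall(
        calls=calls,
        objective_value=total - lambda_hom * n_selected,
        total_explained=total,
        solver_status=status,
        lambda_hom=lambda_hom,
    )


def _split_loci(cm: CompatibilityMatrix, loci) -> tuple[list[str], list[str]]:
    """Split requested loci into (active, no-call) by compatible-read presence."""
    requested = sorted(set(loci) if loci is not None else set(cm.loci))
    col_has_reads = (
        np.asarray(cm.incidence.sum(axis=0)).ravel() > 0
        if cm.n_patterns
        else np.zeros(len(cm.allele_names))
    )
    active, no_call = [], []
    for locus in requested:
        cols = [i for i, l in enumerate(cm.loci) if l == locus]
        if cols and any(col_has_reads[c] for c in cols):
            active.append(locus)
        else:
            no_call.append(locus)
    return active, no_call


# ---------------------------------------------------------------------------
# solvers


def solve_genotype_ilp(
    cm: CompatibilityMatrix,
    loci=None,
    lambda_hom: float = 1.0,
    time_limit: float | None = None,
) -> GenotypeCall:
    """Solve the joint one-step allele-selection ILP (HiGHS backend).

    Loci with zero compatible reads are reported as no-calls rather than
    raising.  The returned solution is proven optimal unless the solver hits
    *time_limit*, in which case the best incumbent is flagged
    ``solver_status="timeout"``.
    """
    active, no_call = _split_loci(cm, loci)
    if not active:
        return _finalize(cm, {}, no_call, lambda_hom, "optimal")

    keep_cols = [i for i, l in enumerate(cm.loci) if l in active]
    names = [cm.allele_names[i] for i in keep_cols]
    col_locus = [cm.loci[i] for i in keep_cols]
    inc = cm.incidence[:, keep_cols].toarray()
    keep_rows = inc.any(axis=1)
    inc = inc[keep_rows]
    w = cm.weights[keep_rows]
    n_a, n_r = len(names), inc.shape[0]

    # deterministic name-rank epsilon (tie-break at scale): total perturbation
    # stays below 0.25 read-equivalents
    ranks = np.argsort(np.argsort(names)).astype(float)
    eps = 0.25 / (1.0 + ranks.sum())

    c = np.concatenate([lambda_hom + eps * ranks, -w])  # minimize
    locus_rows = sparse.lil_matrix((len(active), n_a + n_r))
    for li, locus in enumerate(active):
        for ai, l in enumerate(col_locus):
            if l == locus:
                locus_rows[li, ai] = 1.0
    cardinality = LinearConstraint(
        locus_rows.tocsr(), lb=np.ones(len(active)), ub=2 * np.ones(len(active))
    )
    coverage_mat = sparse.hstack(
        [-sparse.csr_matrix(inc.astype(float)), sparse.eye(n_r, format="csr")]
    )
    coverage = LinearConstraint(coverage_mat, lb=-np.inf, ub=np.zeros(n_r))
    integrality = np.concatenate([np.ones(n_a), np.zeros(n_r)])
    options = {}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c,
        constraints=[cardinality, coverage],
        integrality=integrality,
        bounds=Bounds(0.0, 1.0),
        options=options,
    )
    if res.x is None:
        if res.status == 2:
            raise SolverError("genotype ILP infeasible")
        raise SolverError(f"genotype ILP failed: {res.message}")
    status = "optimal" if res.status == 0 else "timeout"

    y = res.x[:n_a] > 0.5
    selection: dict[str, tuple[str, str]] = {}
    for locus in active:
        sel = sorted(names[i] for i in range(n_a) if y[i] and col_locus[i] == locus)
        if len(sel) == 1:
            selection[locus] = (sel[0], sel[0])
        else:
            selection[locus] = (sel[0], sel[1])

    if status == "optimal" and _n_combinations(cm, active) <= TIE_ENUMERATION_LIMIT:
        _, selection = _enumerate_optimum(cm, active, lambda_hom)
    return _finalize(cm, selection, no_call, lambda_hom, status)


def brute_force_genotype(
    cm: CompatibilityMatrix,
    loci=None,
    lambda_hom: float = 1.0,
    limit: int = 1_000_000,
) -> GenotypeCall:
    """Exhaustive-enumeration oracle for :func:`solve_genotype_ilp`.

    Searches every per-locus one- or two-allele selection, maximizing the
    identical objective with the identical tie-break.  Refuses instances with
    more than *limit* combinations.
    """
    active, no_call = _split_loci(cm, loci)
    if not active:
        return _finalize(cm, {}, no_call, lambda_hom, "optimal")
    n = _n_combinations(cm, active)
    if n > limit:
        raise DataError(
            f"brute force would enumerate {n} combinations (> {limit}); "
            "use solve_genotype_ilp"
        )
    _, selection = _enumerate_optimum(cm, active, lambda_hom)
    return _finalize(cm, selection, no_call, lambda_hom, "optimal")


# ---------------------------------------------------------------------------
# genotype tables and accuracy


def genotype_frame(calls: dict[str, GenotypeCall]) -> pd.DataFrame:
    """Flatten per-sample genotype calls into a tidy table."""
    rows = []
    for sample in sorted(calls):
        gc = calls[sample]
        for locus in sorted(gc.calls):
            lc = gc.calls[locus]
            if lc is None:
                continue
            rows.append(
                {
                    "sample": sample,
                    "locus": locus,
                    "allele1": lc.allele1,
                    "allele2": lc.allele2,
                    "homozygous": lc.homozygous,
                    "explained_reads": lc.explained_reads,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "locus", "allele1", "allele2", "homozygous", "explained_reads"],
    )


def read_genotype_tsv(path: str | Path) -> dict[str, GenotypeCall]:
    """Read a genotype TSV (as written by :func:`genotype_frame`) back into calls."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "locus": str})
    calls: dict[str, GenotypeCall] = {}
    for sample, group in df.groupby("sample"):
        per_locus = {
            r.locus: LocusCall(
                allele1=r.allele1,
                allele2=r.allele2,
                homozygous=bool(r.homozygous),
                explained_reads=float(r.explained_reads),
            )
            for r in group.itertuples(index=False)
        }
        calls[str(sample)] = GenotypeCall(
            calls=per_locus,
            objective_value=float("nan"),
            total_explained=float("nan"),
            solver_status="loaded",
            lambda_hom=float("nan"),
        )
    return calls


@dataclass
class AccuracyReport:
    """Fraction of truth alleles correctly called, as percentages.

    Denominators are two alleles per sample per locus with truth data.
    """

    per_locus: dict[str, dict]
    per_class: dict[str, float]
    overall: float
    missing_samples: list[tuple[str, str]] = field(default_factory=list)


def _labeler(ggroups: GGroupTable | None, resolution: int):
    def label(raw: str) -> str:
        name = parse_allele_name(raw)
        if ggroups is not None:
            return ggroups.group_of(name)
        return str(truncate_resolution(name, min(resolution, name.resolution)))

    return label


def evaluate_accuracy(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    ggroups: GGroupTable | None = None,
    resolution: int = 2,
) -> AccuracyReport:
    """Score predicted genotypes against truth.

    Both tables carry columns ``sample, locus, allele1, allele2``.  A
    predicted allele matches a truth allele when the two map to the same G
    group (or, without a G-group table, share their first *resolution*
    fields); per sample and locus the two predicted and two truth alleles are
    matched by maximum bipartite matching.  Truth entries with no prediction
    score 0/2 and are listed in ``missing_samples``.
    """
    label = _labeler(ggroups, resolution)
    pred_map = {
        (r.sample, r.locus): (r.allele1, r.allele2)
        for r in predicted.itertuples(index=False)
    }
    correct: dict[str, int] = {}
    total: dict[str, int] = {}
    missing: list[tuple[str, str]] = []
    for r in truth.itertuples(index=False):
        locus = r.locus
        total[locus] = total.get(locus, 0) + 2
        pred = pred_map.get((r.sample, locus))
        if pred is None:
            missing.append((r.sample, locus))
            continue
        t1, t2 = label(r.allele1), label(r.allele2)
        p1, p2 = label(pred[0]), label(pred[1])
        matched = max(
            int(p1 == t1) + int(p2 == t2), int(p1 == t2) + int(p2 == t1)
        )
        correct[locus] = correct.get(locus, 0) + matched

    per_locus = {
        locus: {
            "correct": correct.get(locus, 0),
            "total": total[locus],
            "pct": 100.0 * correct.get(locus, 0) / total[locus],
        }
        for locus in sorted(total)
    }
    per_class: dict[str, float] = {}
    for cls in ("I", "II"):
        loci_c = [l for l in total if locus_class(l) == cls]
        denom = sum(total[l] for l in loci_c)
        if denom:
            per_class[cls] = 100.0 * sum(correct.get(l, 0) for l in loci_c) / denom
    overall = 100.0 * sum(correct.values()) / sum(total.values()) if total else 0.0
    return AccuracyReport(
        per_locus=per_locus,
        per_class=per_class,
        overall=overall,
        missing_samples=missing,
    )
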
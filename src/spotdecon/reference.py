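"""Marker-gene selection and signature-matrix construction from scRNA-seq.

A gene is a candidate marker for a cell type when its fold-change quantile
against all other types exceeds ``l_fold``, every one-sided z-test against
the other types is significant at ``l_lambda``, and its within-type
coverage exceeds ``l_cover``. Candidates are ranked by the fold-change
quantile and the top ``n_select`` per type are kept; the signature matrix
holds the pooled per-type gene proportions (rows sum to one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from spotdecon.io import AnnotatedCounts, ValidationError

logger = logging.getLogger("spotdecon")

_EPS = 1e-9  # pseudocount guarding fold-change denominators


@dataclass
class SignatureMatrix:
    """Per-type gene-proportion rows plus per-type mean library size."""

    phi: np.ndarray  # (T, G), rows sum to 1
    type_ids: list[str]
    gene_ids: list[str]
    nu: np.ndarray  # (T,) mean library size over this gene set

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.phi.shape != (len(self.type_ids), len(self.gene_ids)):
            raise ValidationError("phi shape does not match type/gene ids")
        if np.any(self.phi < 0):
            raise ValidationError("phi contains negative entries")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("phi rows must sum to 1")
        if np.any(self.nu <= 0):
            raise ValidationError("nu must be positive for every type")

    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.phi, index=self.type_ids, columns=self.gene_ids).assign(
            __nu__=self.nu
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SignatureMatrix":
        table = pd.read_csv(path, index_col=0)
        nu = table.pop("__nu__").to_numpy(dtype=float)
        return cls(
            phi=table.to_numpy(dtype=float),
            type_ids=[str(t) for t in table.index],
            gene_ids=[str(g) for g in table.columns],
            nu=nu,
        )


def _type_means(Y: np.ndarray, labels: np.ndarray, types: list[str]) -> np.ndarray:
    """Per-type column means, (T, G)."""
    return np.vstack([Y[labels == t].mean(axis=0) for t in types])


def _require_cpm(Y_cpm: AnnotatedCounts) -> None:
    if Y_cpm.normalized != "CPM":
        raise ValidationError("expected CPM-normalized scRNA input")
    if Y_cpm.labels is None:
        raise ValidationError("scRNA input must carry cell-type labels")


def fold_change_quantile(
    Y_cpm: AnnotatedCounts, gene: str, cell_type: str, v: float
) -> float:
    """The ``v``-th sample quantile of fold changes of ``cell_type`` vs others.

    Fold changes are ratios of type-mean CPM expression with a small
    pseudocount in the denominator; the ratio of two zero means is 1.
    Quantiles use linear interpolation between order statistics.
    """
    _require_cpm(Y_cpm)
    labels = np.asarray(Y_cpm.labels)
    types = sorted(set(Y_cpm.labels))
    if cell_type not in types:
        raise ValidationError(f"cell type {cell_type!r} absent from labels")
    if len(types) < 2:
        raise ValidationError("need at least 2 cell types")
    g = Y_cpm.gene_ids.index(gene)
    means = {t: Y_cpm.matrix[labels == t, g].mean() for t in types}
    folds = _fold_set(means[cell_type], [means[t] for t in types if t != cell_type])
    return float(np.quantile(folds, v))


def _fold_set(z_t: float, z_others: np.ndarray | list[float]) -> np.ndarray:
    z_others = np.asarray(z_others, dtype=float)
    folds = np.empty_like(z_others)
    both_zero = (z_others == 0) & (z_t == 0)
    folds[both_zero] = 1.0  # 0/0 convention: uninformative
    folds[~both_zero] = z_t / (z_others[~both_zero] + _EPS)
    return folds


def marker_z_test(
    Y_cpm: AnnotatedCounts, gene: str, type_a: str, type_b: str
) -> float:
    """One-sided Welch z-test p-value for mean(type_a) > mean(type_b).

    Degenerate zero-variance groups: p = 0.5 when means are equal, 0 when
    the type_a mean is larger, 1 otherwise.
    """
    _require_cpm(Y_cpm)
    labels = np.asarray(Y_cpm.labels)
    g = Y_cpm.gene_ids.index(gene)
    a = Y_cpm.matrix[labels == type_a, g]
    b = Y_cpm.matrix[labels == type_b, g]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("z-test requires >= 2 cells per group")
    return float(_z_test_arrays(a.mean(), a.var(ddof=1), len(a), b.mean(), b.var(ddof=1), len(b)))


def _z_test_arrays(ma, va, na, mb, vb, nb):
    se2 = va / na + vb / nb
    diff = ma - mb
    if np.ndim(se2) == 0:
        if se2 == 0:
            return 0.5 if diff == 0 else (0.0 if diff > 0 else 1.0)
        return stats.norm.sf(diff / np.sqrt(se2))
    # vectorized variant used by select_markers
    p = np.full(np.shape(se2), 0.5)
    pos = se2 > 0
    p[pos] = stats.norm.sf(diff[pos] / np.sqrt(se2[pos]))
    zero = ~pos
    p[zero & (diff > 0)] = 0.0
    p[zero & (diff < 0)] = 1.0
    return p


def coverage(Y: AnnotatedCounts, gene: str, cell_type: str) -> float:
    """Fraction of cells of ``cell_type`` with nonzero expression of ``gene``."""
    if Y.labels is None:
        raise ValidationError("input must carry cell-type labels")
    labels = np.asarray(Y.labels)
    if cell_type not in set(Y.labels):
        raise ValidationError(f"cell type {cell_type!r} absent from labels")
    g = Y.gene_ids.index(gene)
    vals = Y.matrix[labels == cell_type, g]
    return float((vals > 0).mean())


def select_markers(
    Y_cpm: AnnotatedCounts,
    l_fold: float = 1.5,
    l_lambda: float = 0.1,
    l_cover: float = 0.60,
    v: float = 0.15,
    n_select: int = 50,
) -> tuple[pd.DataFrame, list[str]]:
    """Select per-type marker genes by the three-condition filter.

    Returns ``(stats_table, marker_genes)`` where ``stats_table`` has one
    row per (gene, type) with the fold quantile, max p-value, coverage,
    candidate/selected flags and within-type rank, and ``marker_genes`` is
    the deduplicated union of selected genes (order: first selection).
    Ties in the fold quantile are broken by gene id.
    """
    _require_cpm(Y_cpm)
    labels = np.asarray(Y_cpm.labels)
    types = sorted(set(Y_cpm.labels))
    if len(types) < 2:
        raise ValidationError("marker selection needs >= 2 cell types")
    Y = Y_cpm.matrix
    genes = np.asarray(Y_cpm.gene_ids)
    G = len(genes)
    T = len(types)

    means = np.empty((T, G))
    variances = np.empty((T, G))
    counts_per_type = np.empty(T, dtype=int)
    cover = np.empty((T, G))
    for i, t in enumerate(types):
        block = Y[labels == t]
        counts_per_type[i] = block.shape[0]
        means[i] = block.mean(axis=0)
        variances[i] = block.var(axis=0, ddof=1) if block.shape[0] > 1 else 0.0
        cover[i] = (block > 0).mean(axis=0)
    if np.any(counts_per_type < 2):
        bad = [t for t, n in zip(types, counts_per_type) if n < 2]
        raise ValidationError(f"types with < 2 cells: {bad}")

    records = []
    selected_union: list[str] = []
    seen: set[str] = set()
    for i, t in enumerate(types):
        others = [j for j in range(T) if j != i]
        fold_sets = np.stack([_fold_set_rows(means[i], means[j]) for j in others])
        fq = np.quantile(fold_sets, v, axis=0)
        pvals = np.stack(
            [
                _z_test_arrays(
                    means[i], variances[i], counts_per_type[i],
                    means[j], variances[j], counts_per_type[j],
                )
                for j in others
            ]
        )
        max_p = pvals.max(axis=0)
        candidate = (fq > l_fold) & (max_p < l_lambda) & (cover[i] > l_cover)
        order = np.lexsort((genes, -fq))  # fold desc, gene id asc for ties
        rank = np.empty(G, dtype=int)
        rank[order] = np.arange(G)
        cand_idx = [k for k in order if candidate[k]][:n_select]
        chosen = set(cand_idx)
        if not candidate.any():
            logger.warning("select_markers: type %r has no candidate markers", t)
        for k in range(G):
            records.append(
                {
                    "gene": genes[k],
                    "type": t,
                    "fold_quantile": fq[k],
                    "max_pvalue": max_p[k],
                    "coverage": cover[i, k],
                    "candidate": bool(candidate[k]),
                    "selected": k in chosen,
                    "rank": int(rank[k]),
                }
            )
        for k in cand_idx:
            if genes[k] not in seen:
                seen.add(genes[k])
                selected_union.append(str(genes[k]))
    table = pd.DataFrame.from_records(records)
    return table, selected_union


def _fold_set_rows(z_t: np.ndarray, z_other: np.ndarray) -> np.ndarray:
    folds = np.where(
        (z_t == 0) & (z_other == 0), 1.0, z_t / (z_other + _EPS)
    )
    return folds


def build_signature(
    Y: AnnotatedCounts, gene_subset: list[str] | None = None
) -> SignatureMatrix:
    """Pooled-count maximum-likelihood signature over ``gene_subset``.

    phi[t, g] = pooled type-t counts of g / pooled type-t counts over the
    subset; nu[t] = mean per-cell library size of type t on the subset.
    Works on raw or CPM input (the pooled-ratio estimator is invariant to
    per-cell rescaling only for raw counts; raw input is the intended use).
    """
    if Y.labels is None:
        raise ValidationError("scRNA input must carry cell-type labels")
    if gene_subset is not None:
        if not gene_subset:
            raise ValidationError("gene_subset must be nonempty")
        Y = Y.subset_genes(gene_subset)
    labels = np.asarray(Y.labels)
    types = sorted(set(Y.labels))
    phi = np.empty((len(types), Y.n_genes))
    nu = np.empty(len(types))
    for i, t in enumerate(types):
        block = Y.matrix[labels == t]
        pooled = block.sum(axis=0)
        total = pooled.sum()
        if total == 0:
            raise ValidationError(f"type {t!r} has zero pooled counts on this gene set")
        phi[i] = pooled / total
        nu[i] = block.sum(axis=1).mean()
    return SignatureMatrix(phi=phi, type_ids=types, gene_ids=list(Y.gene_ids), nu=nu)
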
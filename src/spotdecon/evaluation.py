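"""Per-spot proportion metrics and decomposition re-merge checks.

Six metrics per spot: absolute error, square error, Jensen-Shannon
distance (base-2 logs, so disjoint distributions score exactly 1),
Pearson correlation with the 1/T centering valid for simplex vectors,
cosine similarity and the fraction of cells correctly mapped
(overlap mass, sum of elementwise minima).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from spotdecon.decomposition import CellProfileSet
from spotdecon.io import AnnotatedCounts, ValidationError

logger = logging.getLogger("spotdecon")

METRIC_NAMES = [
    "absolute_error",
    "square_error",
    "jsd",
    "pearson",
    "cosine",
    "fraction_correct",
]


@dataclass
class MetricReport:
    per_spot: pd.DataFrame  # one row per spot, six metric columns
    summary: pd.DataFrame  # mean/median rows
    overall_pearson: float


def _check_simplex(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValidationError(f"{name} is not a simplex (sum={p.sum()!r})")
    return np.clip(p, 0.0, None)


def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def proportion_metrics(p_est: np.ndarray, p_true: np.ndarray) -> dict[str, float]:
    """The six per-spot metrics between an estimated and a true simplex."""
    p = _check_simplex(p_est, "p_est")
    q = _check_simplex(p_true, "p_true")
    if p.shape != q.shape:
        raise ValidationError("proportion vectors differ in length")
    T = len(p)
    abs_err = float(np.abs(p - q).sum())
    sq_err = float(((p - q) ** 2).sum())
    m = (p + q) / 2
    jsd = float(np.sqrt(max(0.5 * (_kl_bits(p, m) + _kl_bits(q, m)), 0.0)))
    a = 1.0 / T
    num = float(((p - a) * (q - a)).sum())
    den = float(np.sqrt(((p - a) ** 2).sum() * ((q - a) ** 2).sum()))
    if den == 0:
        logger.info("proportion_metrics: zero-variance vector, Pearson undefined")
        pearson = np.nan
    else:
        pearson = num / den
    cos_den = float(np.sqrt((p**2).sum() * (q**2).sum()))
    cosine = float((p * q).sum() / cos_den) if cos_den > 0 else np.nan
    frac = float(np.minimum(p, q).sum())
    return {
        "absolute_error": abs_err,
        "square_error": sq_err,
        "jsd": jsd,
        "pearson": pearson,
        "cosine": cosine,
        "fraction_correct": frac,
    }


def merge_iscrna_to_pseudo_spots(cells: CellProfileSet) -> AnnotatedCounts:
    """Sum decomposed per-cell profiles back into spot rows.

    Imputed (out-spot) cells are excluded. Spot order follows first
    appearance in the cell set.
    """
    spot_rows: dict[str, np.ndarray] = {}
    order: list[str] = []
    for i, spot in enumerate(cells.spots):
        if spot is None or cells.provenance[i] == "imputed":
            continue
        if spot not in spot_rows:
            spot_rows[spot] = np.zeros(len(cells.gene_ids))
            order.append(spot)
        spot_rows[spot] += cells.expression[i]
    matrix = (
        np.vstack([spot_rows[s] for s in order])
        if order
        else np.empty((0, len(cells.gene_ids)))
    )
    return AnnotatedCounts(
        matrix=matrix, row_ids=order, gene_ids=list(cells.gene_ids)
    )


def benchmark_report(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
    out_csv=None,
    weights: np.ndarray | None = None,
) -> MetricReport:
    """Per-spot metric table plus slide-level summaries.

    ``estimates`` and ``truth`` are spots x types tables with aligned
    indices. ``weights`` (e.g. per-spot nucleus counts) optionally weight
    the mean summary row.
    """
    if list(estimates.index) != list(truth.index) or list(estimates.columns) != list(
        truth.columns
    ):
        raise ValidationError("estimate/truth spot or type indices do not match")
    rows = []
    for s in estimates.index:
        rows.append(proportion_metrics(estimates.loc[s].to_numpy(), truth.loc[s].to_numpy()))
    per_spot = pd.DataFrame(rows, index=estimates.index)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        weighted = (per_spot * w[:, None]).sum(axis=0)
    summary_rows = {"mean": per_spot.mean(axis=0), "median": per_spot.median(axis=0)}
    if weights is not None:
        summary_rows["weighted_mean"] = weighted
    summary = pd.DataFrame(summary_rows).T
    e = estimates.to_numpy().ravel()
    t = truth.to_numpy().ravel()
    overall = float(np.corrcoef(e, t)[0, 1]) if e.std() > 0 and t.std() > 0 else np.nan
    if out_csv is not None:
        out = pd.concat([per_spot, summary])
        out.insert(0, "spot", list(per_spot.index) + list(summary.index))
        out.to_csv(out_csv, index=False)
    return MetricReport(per_spot=per_spot, summary=summary, overall_pearson=overall)
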
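"""Pan-marker screen: in-cluster positivity and minimum pairwise log fold-change.

A pan-marker of a cluster is a gene that is (a) ubiquitous there — expressed
(raw count > 0) in more than ``min_pct`` of the cluster's cells — and
(b) specific — its minimum log2 fold-change against every other cluster
exceeds ``min_logfc``. Both thresholds are strict inequalities. Fold changes
are computed on depth-normalized (counts-per-``scale_total``, log1p) means,
de-logged back to the linear scale with a pseudocount added to each cluster
mean; positivity is always computed on raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    ClusterLabeling,
    ExpressionMatrix,
    NormalizedMatrix,
    ValidationError,
)

__all__ = [
    "MarkerScreenResult",
    "normalize",
    "pct_expressing",
    "pairwise_logfc",
    "pan_marker_screen",
    "screen_to_frame",
]


@dataclass
class MarkerScreenResult:
    gene_id: str
    target_cluster: str
    pct_in: float
    logfc_by_cluster: dict[str, float]
    min_logfc: float
    passes: bool
    rank: int | None = None


def normalize(
    m: ExpressionMatrix, scale_total: float = 10_000.0, log_base: float = np.e
) -> NormalizedMatrix:
    """Depth-normalize to ``scale_total`` counts per cell and log-transform.

    value[c, g] = log(1 + count[c, g] * scale_total / depth[c]) in ``log_base``.
    """
    depth = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    if np.any(depth == 0):
        bad = int(np.nonzero(depth == 0)[0][0])
        raise ValidationError(
            f"cell {m.cell_ids[bad]!r} has zero total count; cannot normalize"
        )
    dense = m.dense().astype(float)
    values = np.log1p(dense * (scale_total / depth[:, None])) / np.log(log_base)
    return NormalizedMatrix(values, m.gene_ids, m.cell_ids, scale_total, log_base)


def pct_expressing(
    m: ExpressionMatrix, labels: ClusterLabeling, cluster: str
) -> pd.Series:
    """Fraction of the cluster's cells with raw count > 0, per gene."""
    idx = labels.indices_in(m, cluster)
    if idx.size == 0:
        raise ValidationError(f"cluster {cluster!r} has no cells in the matrix")
    sub = m.counts[idx]
    frac = np.asarray((sub > 0).sum(axis=0)).ravel() / idx.size
    return pd.Series(frac, index=list(m.gene_ids), name=f"pct_{cluster}")


def pairwise_logfc(
    nm: NormalizedMatrix,
    labels: ClusterLabeling,
    target: str,
    other: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2 fold-change of cluster means (de-logged normalized expression).

    Per gene: log2((mean_target + pseudocount) / (mean_other + pseudocount)),
    where means are taken over cells of each cluster after inverting the log
    transform (base**value - 1), i.e. on the counts-per-scale_total scale.
    """
    if target == other:
        raise ValidationError("target and other cluster must differ")
    for c in (target, other):
        if c not in labels.clusters:
            raise ValidationError(f"unknown cluster {c!r}")
    cell_pos = {cid: i for i, cid in enumerate(nm.cell_ids)}
    t_idx = np.array([cell_pos[c] for c, k in labels.labels.items()
                      if k == target and c in cell_pos], dtype=int)
    o_idx = np.array([cell_pos[c] for c, k in labels.labels.items()
                      if k == other and c in cell_pos], dtype=int)
    if t_idx.size == 0 or o_idx.size == 0:
        raise ValidationError("both clusters must have cells in the matrix")
    lin = nm.delogged()
    mt = lin[t_idx].mean(axis=0)
    mo = lin[o_idx].mean(axis=0)
    lfc = np.log2((mt + pseudocount) / (mo + pseudocount))
    return pd.Series(lfc, index=list(nm.gene_ids), name=f"logfc_{target}_vs_{other}")


def pan_marker_screen(
    m: ExpressionMatrix,
    labels: ClusterLabeling,
    target: str,
    min_pct: float = 0.90,
    min_logfc: float = 1.0,
    scale_total: float = 10_000.0,
    pseudocount: float = 1.0,
) -> list[MarkerScreenResult]:
    """Screen every gene for pan-marker status in ``target``.

    Returns one result per gene, passing genes first, ranked 1..K by
    (min_logfc desc, pct_in desc, gene_id asc); non-passing genes follow in
    the same sort order with rank ``None``.
    """
    if target not in labels.clusters:
        raise ValidationError(f"unknown cluster {target!r}")
    others = [c for c in labels.clusters if c != target]
    if not others:
        raise ValidationError("screen needs at least 2 clusters")
    pct = pct_expressing(m, labels, target)
    nm = normalize(m, scale_total=scale_total)
    lfc = {o: pairwise_logfc(nm, labels, target, o, pseudocount) for o in others}
    results = []
    for g in m.gene_ids:
        by_cluster = {o: float(lfc[o][g]) for o in others}
        mn = min(by_cluster.values())
        p = float(pct[g])
        results.append(
            MarkerScreenResult(
                gene_id=g,
                target_cluster=target,
                pct_in=p,
                logfc_by_cluster=by_cluster,
                min_logfc=mn,
                passes=(p > min_pct) and (mn > min_logfc),
            )
        )
    results.sort(key=lambda r: (not r.passes, -r.min_logfc, -r.pct_in, r.gene_id))
    rank = 0
    for r in results:
        if r.passes:
            rank += 1
            r.rank = rank
    return results


def screen_to_frame(results: list[MarkerScreenResult]) -> pd.DataFrame:
    """Tabulate screen results (one row per gene) for CSV output."""
    others = sorted({c for r in results for c in r.logfc_by_cluster})
    rows = []
    for r in results:
        row = {"gene_id": r.gene_id, "target_cluster": r.target_cluster,
               "pct_in": r.pct_in}
        for o in others:
            row[f"logfc_{o}"] = r.logfc_by_cluster[o]
        row.update(min_logfc=r.min_logfc, passes=r.passes, rank=r.rank)
        rows.append(row)
    return pd.DataFrame(rows)
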
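"""Weighted precision/recall/F-measure evaluation and parameter sweeps.

For a clustering compared with a family (or super-family) reference, let
``n`` be the number of proteins, ``n_f`` the size of family f, ``n_g`` the
size of cluster g and ``n_fg`` their overlap. Per-pair precision and recall
are ``p_fg = n_fg / n_g`` and ``r_fg = n_fg / n_f``; the family-size
weighted scores pick the best cluster per family:

    F = (1/n) * sum_f n_f * max_g 2 p_fg r_fg / (p_fg + r_fg)
    P = (1/n) * sum_f n_f * max_g p_fg
    R = (1/n) * sum_f n_f * max_g r_fg

All three are 1 exactly when the clustering reproduces the reference
partition. Note the P and R maxima are taken independently, so they may
come from different clusters than the F-maximizing one.

``remove_singletons`` drops reference classes with a single member before
evaluation — left in place, an all-singleton clustering would be rewarded
for every one-protein family. ``grid_sweep`` runs one clusterer over a
parameter grid and ranks grid points by weighted F.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import Clustering, EvalReport, GoldStandard, Level
from .hifix import hifix_cluster
from .mcl import mcl_cluster
from .similarity import SearchHit, SimilarityMatrix
from .spectral import scps_cluster
from .transclust import transclust_cluster

METHODS = ("mcl", "transclust", "scps", "hifix")


def remove_singletons(gold: GoldStandard, level: Level = "family") -> tuple[GoldStandard, list[str]]:
    """Drop every reference class with exactly one member at ``level``;
    returns the filtered gold standard and the removed proteins."""
    labels = gold.labels(level)
    counts: dict[str, int] = {}
    for l in labels.values():
        counts[l] = counts.get(l, 0) + 1
    removed = [p for p, l in labels.items() if counts[l] == 1]
    kept = [p for p in labels if counts[labels[p]] > 1]
    return gold.subset(kept), removed


def contingency(clustering: Clustering, gold: GoldStandard, level: Level = "family") -> pd.DataFrame:
    """Family-by-cluster overlap counts ``n_fg`` as a dense DataFrame
    (rows = reference classes, columns = cluster indices).

    Marginals are conserved: row sums give ``n_f``, column sums ``n_g``.
    """
    labels = gold.labels(level)
    croster = clustering.roster
    mismatch = set(croster) ^ set(labels)
    if mismatch:
        raise ValueError(f"clustering and gold rosters differ; symmetric difference: {sorted(mismatch)}")
    fam = pd.Series({p: labels[p] for p in croster}, name="family")
    clu = pd.Series(
        {p: g for g, members in enumerate(clustering.clusters) for p in members}, name="cluster"
    )
    return pd.crosstab(fam, clu.loc[fam.index])


def weighted_prf(table: pd.DataFrame) -> tuple[float, float, float]:
    """(precision, recall, f_measure) from a contingency table."""
    n_fg = table.to_numpy(dtype=float)
    if n_fg.size == 0 or n_fg.sum() == 0:
        raise ValueError("empty contingency table")
    n_f = n_fg.sum(axis=1, keepdims=True)
    n_g = n_fg.sum(axis=0, keepdims=True)
    n = n_fg.sum()
    p = n_fg / n_g
    r = n_fg / n_f
    denom = p + r
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(denom > 0, 2.0 * p * r / np.where(denom > 0, denom, 1.0), 0.0)
    precision = float((n_f[:, 0] * p.max(axis=1)).sum() / n)
    recall = float((n_f[:, 0] * r.max(axis=1)).sum() / n)
    f = float((n_f[:, 0] * h.max(axis=1)).sum() / n)
    return precision, recall, f


def evaluate(clustering: Clustering, gold: GoldStandard, level: Level = "family") -> EvalReport:
    """Weighted P/R/F plus cluster and protein counts for one clustering."""
    if clustering.n_proteins == 0:
        raise ValueError("cannot evaluate an empty clustering")
    table = contingency(clustering, gold, level)
    precision, recall, f = weighted_prf(table)
    return EvalReport(precision, recall, f, clustering.n_clusters, clustering.n_proteins)


@dataclass
class SweepResult:
    """All grid rows plus the best one (max F; ties → fewer clusters, then
    first in grid order)."""

    rows: pd.DataFrame
    best: dict

    @property
    def best_f(self) -> float:
        return float(self.best["weighted_f_measure"])


def run_method(method: str, *, matrix: SimilarityMatrix | None = None,
               hits: Sequence[SearchHit] | None = None, params: dict | None = None,
               seed: int = 0) -> Clustering:
    """Dispatch one clusterer by id with its parameter dict."""
    params = dict(params or {})
    if method == "mcl":
        if matrix is None:
            raise ValueError("mcl requires a similarity matrix")
        return mcl_cluster(matrix, **params)
    if method == "transclust":
        if matrix is None:
            raise ValueError("transclust requires a similarity matrix")
        return transclust_cluster(matrix, params.pop("threshold"), **params).clustering
    if method == "scps":
        if matrix is None:
            raise ValueError("scps requires a similarity matrix")
        return scps_cluster(matrix, params.pop("c", "auto"), seed=seed, **params)
    if method == "hifix":
        if hits is None:
            raise ValueError("hifix requires the raw search hits (identity/coverage)")
        return hifix_cluster(hits, params.pop("s_min", 0.1), params.pop("c_min", 0.0), seed=seed)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def grid_sweep(method: str, *, gold: GoldStandard, grid: dict[str, Sequence],
               matrix: SimilarityMatrix | None = None, hits: Sequence[SearchHit] | None = None,
               level: Level = "family", seed: int = 0) -> SweepResult:
    """Run ``method`` at every grid point and rank by weighted F.

    ``grid`` maps parameter names to value lists; the sweep walks their
    Cartesian product in order. Deterministic given ``seed``.
    """
    if not grid:
        raise ValueError("grid must not be empty")
    names = list(grid)
    rows = []
    best = None
    for order, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        params = dict(zip(names, combo))
        clustering = run_method(method, matrix=matrix, hits=hits, params=params, seed=seed)
        report = evaluate(clustering, gold, level)
        row = {**{f"param_{k}": v for k, v in params.items()}, **report.as_dict(), "_order": order}
        rows.append(row)
        key = (-report.weighted_f_measure, report.n_clusters, order)
        if best is None or key < best[0]:
            best = (key, row)
    frame = pd.DataFrame(rows).drop(columns="_order")
    best_row = {k: v for k, v in best[1].items() if k != "_order"}
    return SweepResult(frame, best_row)
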
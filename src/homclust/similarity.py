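"""Parsing, symmetrization and scoring of all-vs-all homology search output.

All four clusterers in this package consume the same object, a sparse
symmetric :class:`SimilarityMatrix` of non-negative scores. This module
builds it from raw search hits:

1. ``parse_hits`` reads BLAST tabular (outfmt 6) rows or a generic
   three-column edge list into :class:`SearchHit` records; profile-search
   rows already reduced to ``(query, subject, evalue)`` enter through
   ``convert_profile_hits`` and are treated identically downstream.
2. ``symmetrize`` collapses the possibly many, possibly asymmetric hits for
   each unordered protein pair to a single e-value (lowest, highest or
   average), drops self-hits and pairs above a permissive e-value threshold
   (default 100), yielding a :class:`PairScoreTable`.
3. ``build_matrix`` maps e-values to scores with the clipped
   ``-log10(e)`` transform (``evalue_to_score``) and assembles the matrix.

``nn_evalue_distributions`` computes, per protein, the e-value of its
nearest neighbor inside and outside its own family — the summary whose
intra/inter cumulative curves distinguish easy (separated) from hard
(overlapping or inverted) homology-detection regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import GoldStandard, Level

DEFAULT_SCORE_CAP = 350.0
DEFAULT_EVALUE_THRESHOLD = 100.0

SYMMETRIZE_RULES = ("lowest", "highest", "average")


class ParseError(ValueError):
    """Malformed search-output row; message names the offending line."""


@dataclass(frozen=True)
class SearchHit:
    """One row of an all-vs-all search result.

    ``percent_identity`` is on the 0–100 scale; ``alignment_coverage`` is a
    fraction in [0, 1]. Either may be ``None`` (unknown) for edge-list or
    profile-derived hits.
    """

    query_id: str
    subject_id: str
    evalue: float
    percent_identity: float | None = None
    alignment_coverage: float | None = None
    bit_score: float | None = None
    source: str = "sequence"

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")
        if self.percent_identity is not None and not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent_identity {self.percent_identity} outside [0, 100]")
        if self.alignment_coverage is not None and not (0.0 <= self.alignment_coverage <= 1.0):
            raise ValueError(f"alignment_coverage {self.alignment_coverage} outside [0, 1]")
        if self.bit_score is not None and self.bit_score < 0:
            raise ValueError("bit_score must be non-negative")


def _lines(source: TextIO | Iterable[str]) -> Iterable[str]:
    return source


def parse_hits(source: TextIO | Iterable[str], dialect: str = "blast_tab") -> list[SearchHit]:
    """Parse search output into :class:`SearchHit` records, in input order.

    ``dialect="blast_tab"`` expects the 12 outfmt-6 columns
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore); ``dialect="edge_list"`` expects ``id1 id2 evalue``.
    ``#`` comment lines and blank lines are skipped. Malformed rows raise
    :class:`ParseError` naming the (1-based) line number.
    """
    if dialect not in ("blast_tab", "edge_list"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[SearchHit] = []
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        try:
            if dialect == "blast_tab":
                if len(cols) < 12:
                    raise ValueError(f"expected ≥12 columns, got {len(cols)}")
                hits.append(
                    SearchHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        evalue=float(cols[10]),
                        percent_identity=float(cols[2]),
                        bit_score=float(cols[11]),
                    )
                )
            else:
                if len(cols) < 3:
                    raise ValueError(f"expected ≥3 columns, got {len(cols)}")
                hits.append(SearchHit(query_id=cols[0], subject_id=cols[1], evalue=float(cols[2])))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return hits


def convert_profile_hits(rows: Iterable[tuple[str, str, float]]) -> list[SearchHit]:
    """Convert already-tabularized profile-search rows into the same hit shape
    used for sequence-search output, flagged ``source="profile"``."""
    out = []
    for q, s, e in rows:
        if e < 0:
            raise ValueError(f"negative evalue {e} for pair ({q}, {s})")
        out.append(SearchHit(query_id=q, subject_id=s, evalue=float(e), source="profile"))
    return out


@dataclass
class PairScoreTable:
    """One e-value per unordered protein pair, plus the full node roster.

    Pairs are keyed by the lexicographically sorted identifier tuple; the
    roster preserves first-seen order and keeps proteins whose every pair
    fell to the threshold (they become isolated nodes).
    """

    pairs: dict[tuple[str, str], float]
    roster: list[str]

    def __post_init__(self) -> None:
        known = set(self.roster)
        for (a, b) in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) stored")
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"pair key ({a}, {b}) not in sorted order")
            if a not in known or b not in known:
                raise ValueError(f"pair ({a}, {b}) references protein outside roster")

    def evalue(self, a: str, b: str) -> float | None:
        return self.pairs.get(tuple(sorted((a, b))))  # type: ignore[arg-type]

    def write_edge_list(self, stream: TextIO) -> None:
        """Canonical edge list: pairs sorted, e-values in scientific notation.

        Isolated roster nodes are preserved as ``# node`` comment lines so a
        round-trip through :func:`read_edge_list` is lossless.
        """
        stream.write("#id1\tid2\tevalue\n")
        paired = {p for pair in self.pairs for p in pair}
        for node in self.roster:
            if node not in paired:
                stream.write(f"#node\t{node}\n")
        for (a, b) in sorted(self.pairs):
            stream.write(f"{a}\t{b}\t{self.pairs[(a, b)]:.6e}\n")

    @classmethod
    def read_edge_list(cls, stream: TextIO) -> "PairScoreTable":
        pairs: dict[tuple[str, str], float] = {}
        roster: list[str] = []
        seen: set[str] = set()

        def add(node: str) -> None:
            if node not in seen:
                seen.add(node)
                roster.append(node)

        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                cols = line.lstrip("#").split()
                if cols and cols[0] == "node" and len(cols) > 1:
                    add(cols[1])
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(cols)}")
            a, b = sorted(cols[:2])
            try:
                e = float(cols[2])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric evalue {cols[2]!r}") from None
            add(cols[0])
            add(cols[1])
            pairs[(a, b)] = e
        return cls(pairs, roster)


def symmetrize(
    hits: Sequence[SearchHit],
    rule: str = "lowest",
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> PairScoreTable:
    """Collapse hits to one e-value per unordered pair.

    Self-hits are dropped; all hits for a pair are combined by ``rule``
    (``lowest`` keeps the most significant hit, ``highest`` the least,
    ``average`` the arithmetic mean); pairs whose collapsed e-value exceeds
    ``evalue_threshold`` are discarded. Every identifier seen in the input
    stays on the roster even when all of its pairs were dropped.
    """
    if rule not in SYMMETRIZE_RULES:
        raise ValueError(f"rule must be one of {SYMMETRIZE_RULES}, got {rule!r}")
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be positive")
    roster: list[str] = []
    seen: set[str] = set()
    bucket: dict[tuple[str, str], list[float]] = {}
    for h in hits:
        for node in (h.query_id, h.subject_id):
            if node not in seen:
                seen.add(node)
                roster.append(node)
        if h.query_id == h.subject_id:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        bucket.setdefault(key, []).append(h.evalue)  # type: ignore[arg-type]
    combine = {"lowest": min, "highest": max, "average": lambda v: sum(v) / len(v)}[rule]
    pairs = {}
    for key, values in bucket.items():
        e = combine(values)
        if e <= evalue_threshold:
            pairs[key] = float(e)
    return PairScoreTable(pairs, roster)


def evalue_to_score(evalue: float, score_cap: float = DEFAULT_SCORE_CAP) -> float:
    """Clipped ``-log10`` transform: larger score = more similar.

    ``evalue == 0`` maps to ``score_cap``; results are clipped to
    ``[0, score_cap]`` so e-values ≥ 1 carry no weight beyond zero.
    """
    if evalue < 0:
        raise ValueError(f"evalue must be non-negative, got {evalue}")
    if score_cap <= 0:
        raise ValueError("score_cap must be positive")
    if evalue == 0:
        return float(score_cap)
    return float(min(max(-math.log10(evalue), 0.0), score_cap))


class SimilarityMatrix:
    """Sparse symmetric non-negative protein similarity scores.

    Absent entries mean "no hit", i.e. similarity 0. The matrix is stored as
    a CSR sparse matrix aligned with ``roster`` order.
    """

    def __init__(self, roster: Sequence[str], matrix: sp.spmatrix, score_cap: float = DEFAULT_SCORE_CAP):
        n = len(roster)
        matrix = sp.csr_matrix(matrix)
        if matrix.shape != (n, n):
            raise ValueError(f"matrix shape {matrix.shape} does not match roster size {n}")
        if (abs(matrix - matrix.T) > 1e-9).nnz:
            raise ValueError("similarity matrix must be symmetric")
        if matrix.nnz and matrix.data.min() < 0:
            raise ValueError("similarity scores must be non-negative")
        self.roster: list[str] = list(roster)
        self.index: dict[str, int] = {p: i for i, p in enumerate(self.roster)}
        self.matrix = matrix
        self.score_cap = float(score_cap)

    @property
    def n(self) -> int:
        return len(self.roster)

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[self.index[a], self.index[b]])

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    @classmethod
    def from_dense(cls, dense: np.ndarray, roster: Sequence[str] | None = None,
                   score_cap: float = DEFAULT_SCORE_CAP) -> "SimilarityMatrix":
        dense = np.asarray(dense, dtype=float)
        if roster is None:
            roster = [str(i) for i in range(dense.shape[0])]
        d = dense.copy()
        np.fill_diagonal(d, 0.0)
        return cls(roster, sp.csr_matrix(d), score_cap)

    def connected_components(self) -> tuple[int, np.ndarray]:
        from scipy.sparse.csgraph import connected_components

        return connected_components(self.matrix, directed=False)

    def submatrix(self, indices: Sequence[int]) -> "SimilarityMatrix":
        idx = np.asarray(indices, dtype=int)
        sub = self.matrix[np.ix_(idx, idx)]
        return SimilarityMatrix([self.roster[i] for i in idx], sp.csr_matrix(sub), self.score_cap)


def build_matrix(table: PairScoreTable, score_cap: float = DEFAULT_SCORE_CAP) -> SimilarityMatrix:
    """Assemble the similarity matrix from a symmetrized pair table."""
    n = len(table.roster)
    index = {p: i for i, p in enumerate(table.roster)}
    rows, cols, data = [], [], []
    for (a, b), e in table.pairs.items():
        s = evalue_to_score(e, score_cap)
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        data += [s, s]
    m = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return SimilarityMatrix(table.roster, m, score_cap)


def nn_evalue_distributions(table: PairScoreTable, gold: GoldStandard, level: Level = "family") -> pd.DataFrame:
    """Per-protein nearest-neighbor e-values, within and across label classes.

    Returns a DataFrame with columns ``protein_id``, ``intra_nn``,
    ``inter_nn``; an undefined minimum (no stored pair of that kind) is NaN.
    Every roster protein must carry a label at the requested level.
    """
    labels = gold.labels(level)
    for p in table.roster:
        if p not in labels:
            raise KeyError(f"protein {p!r} has no {level} label")
    intra: dict[str, float] = {}
    inter: dict[str, float] = {}
    for (a, b), e in table.pairs.items():
        target = intra if labels[a] == labels[b] else inter
        for p in (a, b):
            if p not in target or e < target[p]:
                target[p] = e
    return pd.DataFrame(
        {
            "protein_id": table.roster,
            "intra_nn": [intra.get(p, np.nan) for p in table.roster],
            "inter_nn": [inter.get(p, np.nan) for p in table.roster],
        }
    )


def write_nn_table(df: pd.DataFrame, stream: TextIO) -> None:
    stream.write("#protein_id\tintra_nn\tinter_nn\n")
    for row in df.itertuples(index=False):
        intra = "NA" if pd.isna(row.intra_nn) else f"{row.intra_nn:.6e}"
        inter = "NA" if pd.isna(row.inter_nn) else f"{row.inter_nn:.6e}"
        stream.write(f"{row.protein_id}\t{intra}\t{inter}\n")
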
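"""Shared containers: clusterings, gold-standard label tables, evaluation reports.

These are the small in-memory types every other module exchanges: a
:class:`Clustering` is a disjoint, exhaustive partition of protein
identifiers; a :class:`GoldStandard` maps each protein to its family and
super-family label; an :class:`EvalReport` bundles the weighted
precision/recall/F scores for one clustering against one gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

Level = str  # "family" | "superfamily"

_LEVELS = ("family", "superfamily")


def _check_level(level: str) -> str:
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}, got {level!r}")
    return level


@dataclass
class Clustering:
    """A partition of protein identifiers into disjoint, exhaustive clusters.

    Cluster order is canonical: clusters are numbered by the roster position
    of their first member, which keeps TSV output stable across runs.
    """

    clusters: list[list[str]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            for p in c:
                if p in seen:
                    raise ValueError(f"protein {p!r} appears in more than one cluster")
                seen.add(p)

    @property
    def roster(self) -> list[str]:
        return [p for c in self.clusters for p in c]

    @property
    def n_clusters(self) -> int:
        return sum(1 for c in self.clusters if c)

    @property
    def n_proteins(self) -> int:
        return sum(len(c) for c in self.clusters)

    def member_sets(self) -> list[set[str]]:
        return [set(c) for c in self.clusters]

    def labels_for(self, roster: Sequence[str]) -> list[int]:
        """Dense integer label per roster entry."""
        lab = {p: i for i, c in enumerate(self.clusters) for p in c}
        return [lab[p] for p in roster]

    @classmethod
    def from_labels(cls, roster: Sequence[str], labels: Sequence[int], meta: dict | None = None) -> "Clustering":
        """Build from per-protein integer labels, renumbering clusters by the
        roster position of each cluster's first member."""
        if len(roster) != len(labels):
            raise ValueError("roster and labels must have equal length")
        order: dict[int, list[str]] = {}
        for p, l in zip(roster, labels):
            order.setdefault(int(l), []).append(p)
        pos = {p: i for i, p in enumerate(roster)}
        clusters = sorted(order.values(), key=lambda c: pos[c[0]])
        return cls(clusters, meta or {})

    def write_tsv(self, stream: TextIO) -> None:
        stream.write("#protein_id\tcluster_id\n")
        for i, c in enumerate(self.clusters):
            for p in c:
                stream.write(f"{p}\t{i}\n")

    @classmethod
    def read_tsv(cls, stream: TextIO) -> "Clustering":
        groups: dict[str, list[str]] = {}
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p, cid = line.split("\t")[:2]
            groups.setdefault(cid, []).append(p)
        return cls(list(groups.values()))


@dataclass
class GoldStandard:
    """Protein → family / super-family reference labels."""

    family: dict[str, str]
    superfamily: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.family) != set(self.superfamily):
            raise ValueError("family and superfamily label maps must cover the same proteins")

    @property
    def roster(self) -> list[str]:
        return list(self.family)

    def labels(self, level: Level) -> dict[str, str]:
        _check_level(level)
        return self.family if level == "family" else self.superfamily

    def label_of(self, protein: str, level: Level) -> str:
        table = self.labels(level)
        if protein not in table:
            raise KeyError(f"protein {protein!r} has no {level} label")
        return table[protein]

    def n_classes(self, level: Level) -> int:
        return len(set(self.labels(level).values()))

    def to_clustering(self, level: Level) -> Clustering:
        groups: dict[str, list[str]] = {}
        for p, l in self.labels(level).items():
            groups.setdefault(l, []).append(p)
        return Clustering(list(groups.values()))

    def subset(self, proteins: Iterable[str]) -> "GoldStandard":
        keep = set(proteins)
        return GoldStandard(
            {p: f for p, f in self.family.items() if p in keep},
            {p: s for p, s in self.superfamily.items() if p in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": list(self.family),
                "family_id": list(self.family.values()),
                "superfamily_id": [self.superfamily[p] for p in self.family],
            }
        )

    def write_tsv(self, stream: TextIO) -> None:
        stream.write("#protein_id\tfamily_id\tsuperfamily_id\n")
        for p in self.family:
            stream.write(f"{p}\t{self.family[p]}\t{self.superfamily[p]}\n")

    @classmethod
    def read_tsv(cls, stream: TextIO) -> "GoldStandard":
        fam: dict[str, str] = {}
        sup: dict[str, str] = {}
        first = True
        for line in stream:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if first and cols[0] == "protein_id":
                first = False
                continue
            first = False
            if len(cols) < 3:
                raise ValueError(f"label table row needs 3 columns, got {len(cols)}: {line!r}")
            fam[cols[0]] = cols[1]
            sup[cols[0]] = cols[2]
        return cls(fam, sup)

    @classmethod
    def from_mappings(cls, family: Mapping[str, str], superfamily: Mapping[str, str] | None = None) -> "GoldStandard":
        fam = dict(family)
        sup = dict(superfamily) if superfamily is not None else dict(fam)
        return cls(fam, sup)


@dataclass(frozen=True)
class EvalReport:
    """Weighted precision/recall/F for one clustering vs one gold standard."""

    weighted_precision: float
    weighted_recall: float
    weighted_f_measure: float
    n_clusters: int
    n_proteins: int

    def __post_init__(self) -> None:
        for name in ("weighted_precision", "weighted_recall", "weighted_f_measure"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f_measure": self.weighted_f_measure,
            "n_clusters": self.n_clusters,
            "n_proteins": self.n_proteins,
        }
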
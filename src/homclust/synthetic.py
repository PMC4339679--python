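"""Synthetic homology-search benchmarks with tunable difficulty.

Real benchmarks for protein-family clustering span two regimes. In the easy
regime (curated enzyme sets, high-identity subsets) each protein's nearest
neighbor by e-value lies inside its own family: the intra and inter
nearest-neighbor e-value curves are well separated. In the hard remote-
homology regime (very low identity subsets) the curves overlap and can even
invert — a protein's most significant hit is frequently a member of a
different family. This generator emulates that geometry directly in
e-value space, without simulating sequences:

* same-family pairs draw ``log10(e)`` uniformly from ``intra_log10e_range``
  (default [-80, -10]) with probability ``intra_density``;
* cross-family pairs inside a shared super-family draw from the interval
  midway between intra and inter (a weaker, two-level signal);
* cross-super-family pairs draw from ``inter_log10e_range`` (default
  [-8, 2]) with probability ``inter_density``.

``difficulty`` slides the inter (and mid-level) interval toward and past
the intra one: the shift is ``difficulty * (gap + margin)`` where ``gap``
is the separation between the intervals at difficulty 0 and ``margin`` is
the intra-interval width. At difficulty 0 the intervals are disjoint (every
intra nearest neighbor is more significant than every inter one); at
difficulty 1 the inter interval sits at the most-significant edge of the
intra interval, inverting the curves.

Percent identity and coverage are emitted as bounded monotone transforms of
``-log10(e)`` with small seeded noise, so identity/coverage-thresholding
pipelines see a signal consistent with the e-values. Every protein keeps at
least one same-family edge (re-sampled if density dropped them all), so the
true family structure is always represented in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GoldStandard
from .similarity import SearchHit


@dataclass
class SynthConfig:
    """Benchmark geometry and sampling parameters.

    ``difficulty`` in [0, 1]: 0 = fully separated intra/inter e-value
    intervals, 1 = inverted (inter more significant than intra).
    """

    n_families: int = 6
    family_size_range: tuple[int, int] = (4, 8)
    superfamily_grouping: int = 1
    difficulty: float = 0.0
    intra_log10e_range: tuple[float, float] = (-80.0, -10.0)
    inter_log10e_range: tuple[float, float] = (-8.0, 2.0)
    intra_density: float = 0.8
    inter_density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise ValueError("need at least 2 families")
        lo, hi = self.family_size_range
        if lo < 2 or hi < lo:
            raise ValueError("family sizes must satisfy 2 <= min <= max (no singleton families)")
        if self.superfamily_grouping < 1:
            raise ValueError("superfamily_grouping must be >= 1")
        if not (0.0 <= self.difficulty <= 1.0):
            raise ValueError("difficulty must be in [0, 1]")
        if not (0.0 < self.intra_density <= 1.0):
            raise ValueError("intra_density must be in (0, 1] (families need edges)")
        if not (0.0 <= self.inter_density <= 1.0):
            raise ValueError("inter_density must be in [0, 1]")
        if self.intra_log10e_range[1] >= self.inter_log10e_range[0]:
            raise ValueError("at difficulty 0 the intra interval must be strictly more significant")

    @property
    def shifted_inter_range(self) -> tuple[float, float]:
        gap = self.inter_log10e_range[0] - self.intra_log10e_range[1]
        margin = self.intra_log10e_range[1] - self.intra_log10e_range[0]
        shift = self.difficulty * (gap + margin)
        return (self.inter_log10e_range[0] - shift, self.inter_log10e_range[1] - shift)

    @property
    def mid_log10e_range(self) -> tuple[float, float]:
        """Same-super-family, cross-family interval: midway between intra and
        (shifted) inter."""
        ilo, ihi = self.intra_log10e_range
        olo, ohi = self.shifted_inter_range
        return ((ilo + olo) / 2.0, (ihi + ohi) / 2.0)


def sample_structure(config: SynthConfig) -> GoldStandard:
    """Draw the label scaffold: family sizes uniform in the configured range,
    families grouped consecutively into super-families."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.family_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_families)
    fam: dict[str, str] = {}
    sup: dict[str, str] = {}
    p = 0
    for f, size in enumerate(sizes):
        sf = f // config.superfamily_grouping
        for _ in range(size):
            pid = f"p{p:04d}"
            fam[pid] = f"F{f:03d}"
            sup[pid] = f"S{sf:03d}"
            p += 1
    return GoldStandard(fam, sup)


def _identity_coverage(rng: np.random.Generator, log10e: float) -> tuple[float, float]:
    score = max(-log10e, 0.0)
    pident = float(np.clip(10.0 + 0.9 * score + rng.normal(0.0, 1.0), 0.0, 98.0))
    cov = float(np.clip(0.45 + score / 200.0 + rng.normal(0.0, 0.02), 0.05, 0.99))
    return pident, cov


def synth_benchmark(config: SynthConfig) -> tuple[list[SearchHit], GoldStandard]:
    """Generate the hit list and its gold standard.

    Deterministic given ``config.seed``; each unordered pair appears at most
    once (the list is already symmetric in the uniqueness sense).
    """
    gold = sample_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    roster = gold.roster
    fam = gold.family
    sup = gold.superfamily
    hits: list[SearchHit] = []
    intra_partners: dict[str, int] = {p: 0 for p in roster}
    family_members: dict[str, list[str]] = {}
    for p in roster:
        family_members.setdefault(fam[p], []).append(p)

    def emit(a: str, b: str, interval: tuple[float, float]) -> None:
        u = rng.uniform(*interval)
        pid, cov = _identity_coverage(rng, u)
        hits.append(SearchHit(a, b, 10.0**u, pid, cov))

    mid = config.mid_log10e_range
    inter = config.shifted_inter_range
    mid_density = (config.intra_density + config.inter_density) / 2.0
    for i, a in enumerate(roster):
        for b in roster[i + 1:]:
            if fam[a] == fam[b]:
                if rng.uniform() < config.intra_density:
                    emit(a, b, config.intra_log10e_range)
                    intra_partners[a] += 1
                    intra_partners[b] += 1
            elif sup[a] == sup[b]:
                if rng.uniform() < mid_density:
                    emit(a, b, mid)
            else:
                if rng.uniform() < config.inter_density:
                    emit(a, b, inter)
    # guarantee every protein at least one same-family edge
    for p in roster:
        if intra_partners[p] == 0:
            others = [q for q in family_members[fam[p]] if q != p]
            q = others[int(rng.integers(len(others)))]
            emit(p, q, config.intra_log10e_range)
            intra_partners[p] += 1
            intra_partners[q] += 1
    return hits, gold
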
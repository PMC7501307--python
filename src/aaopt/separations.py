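"""Binary separations of the residue set induced by one numeric feature.

A *separation* splits the alphabet into a low set (value <= threshold)
and a high set.  Only *realizable* cuts exist: positions between two
adjacent sorted values that differ strictly, so tied residues are never
split.  The *gap* of a cut is the value difference across it, and its
*gap-rank score* is the number of other realizable cuts of the same
feature with a strictly smaller gap — a large score marks a "natural"
separation point.  With 20 all-distinct values a feature has 19 cuts and
the widest one scores 18.

The classical starting point is the *median separation*: low set =
{residues with value <= median}, which for 20 distinct values yields a
balanced 10/10 split — the shape that best satisfies the downstream
capacity criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .aaindex_io import FeatureRecord, FeatureTable

__all__ = [
    "Separation",
    "SeparationError",
    "sorted_profile",
    "median_value",
    "median_separation",
    "enumerate_cuts",
    "score_cuts",
    "candidate_pool",
    "deduplicate_pool",
    "default_size_bounds",
]

logger = logging.getLogger(__name__)


class SeparationError(ValueError):
    """Raised for degenerate features or invalid pool parameters."""


@dataclass(frozen=True)
class Separation:
    """One binary split of the residue set on one feature.

    ``membership`` is a bit per alphabet position: 0 = low set, 1 = high
    set.  ``threshold`` is the largest low-set value, so the split rule
    is ``low iff value <= threshold``.  ``gap`` is the smallest high
    value minus the largest low value (> 0 for every realizable cut).
    """

    accession: str
    cut_size: int
    threshold: float
    membership: tuple[int, ...]
    gap: float
    score: int = 0
    is_median: bool = False

    @property
    def key(self) -> tuple[str, int]:
        """Canonical identity of a separation within a pool."""
        return (self.accession, self.cut_size)

    def side(self, index: int) -> int:
        return self.membership[index]

    def low_set(self, alphabet: Sequence[str]) -> frozenset[str]:
        return frozenset(r for r, b in zip(alphabet, self.membership) if b == 0)

    def high_set(self, alphabet: Sequence[str]) -> frozenset[str]:
        return frozenset(r for r, b in zip(alphabet, self.membership) if b == 1)


def sorted_profile(
    record: FeatureRecord, alphabet: Sequence[str]
) -> list[tuple[str, float]]:
    """Residues sorted ascending by value, ties broken by alphabet order."""
    index = {r: i for i, r in enumerate(alphabet)}
    return sorted(
        ((r, record.values[r]) for r in alphabet),
        key=lambda rv: (rv[1], index[rv[0]]),
    )


def median_value(values: Iterable[float]) -> float:
    """Sample median: middle order statistic (odd n) or the mean of the
    two middle order statistics (even n)."""
    ordered = sorted(values)
    n = len(ordered)
    if n == 0:
        raise SeparationError("median of an empty value list")
    mid = n // 2
    if n % 2:
        return float(ordered[mid])
    return (ordered[mid - 1] + ordered[mid]) / 2.0


def enumerate_cuts(
    record: FeatureRecord, alphabet: Sequence[str]
) -> list[Separation]:
    """All realizable cuts of one feature, in ascending cut_size order.

    One :class:`Separation` per strictly increasing adjacent pair of the
    sorted profile; a constant feature yields no cuts.  The cut whose
    low set equals {value <= median} is flagged ``is_median``.  Scores
    are left at 0; apply :func:`score_cuts`.
    """
    profile = sorted_profile(record, alphabet)
    med = median_value(v for _, v in profile)
    low: set[str] = set()
    cuts: list[Separation] = []
    for i in range(len(profile) - 1):
        low.add(profile[i][0])
        lo_v, hi_v = profile[i][1], profile[i + 1][1]
        if hi_v > lo_v:
            membership = tuple(0 if r in low else 1 for r in alphabet)
            cuts.append(
                Separation(
                    accession=record.accession,
                    cut_size=i + 1,
                    threshold=lo_v,
                    membership=membership,
                    gap=hi_v - lo_v,
                    is_median=lo_v <= med < hi_v,
                )
            )
    return cuts


def score_cuts(cuts: Sequence[Separation]) -> list[Separation]:
    """Attach gap-rank scores to the complete cut set of one feature.

    score(c) = number of cuts of the same feature with gap strictly
    smaller than gap(c); equal-gap cuts share a score.
    """
    if not cuts:
        return []
    accessions = {c.accession for c in cuts}
    if len(accessions) > 1:
        raise SeparationError(
            f"score_cuts requires cuts of a single feature, got {sorted(accessions)}"
        )
    gaps = [c.gap for c in cuts]
    return [
        replace(c, score=sum(1 for g in gaps if g < c.gap)) for c in cuts
    ]


def median_separation(
    record: FeatureRecord, alphabet: Sequence[str]
) -> Separation:
    """The median split of one feature, as a scored separation.

    Low set = {value <= median}; with ties at the median the low set can
    exceed half the alphabet (tied residues never split).  The score is
    the cut's gap rank within the feature's full realizable-cut set.
    """
    scored = score_cuts(enumerate_cuts(record, alphabet))
    for cut in scored:
        if cut.is_median:
            return cut
    raise SeparationError(
        f"no realizable median split for feature {record.accession!r} "
        "(all residues fall on one side of the median)"
    )


def default_size_bounds(n_residues: int, f: int) -> tuple[int, int]:
    """Capacity-implied side-size bounds for a single separation.

    Both sides of a usable cut must hold at most 2**(f-1) residues,
    i.e. cut_size in [n - 2**(f-1), 2**(f-1)] — the familiar [4, 16]
    for 20 residues and f = 5.
    """
    half = 2 ** (f - 1)
    return (max(1, n_residues - half), min(n_residues - 1, half))


def candidate_pool(
    table: FeatureTable,
    mode: str = "median",
    k: int = 3,
    size_bounds: tuple[int, int] | None = None,
    f: int = 5,
    include_median: bool = False,
) -> list[Separation]:
    """Build the separation pool the solution search runs over.

    mode ``median``
        One median separation per feature; features with no realizable
        median split are skipped with a warning.
    mode ``cuts``
        Per feature: enumerate and score all realizable cuts, drop cuts
        whose side sizes fall outside ``size_bounds`` (default: the
        capacity bounds, [4, 16] for 20 residues), keep the ``k``
        largest-gap survivors (ties: higher score, then smaller
        cut_size), then deduplicate pool-wide — among separations with
        identical membership vectors only the highest-scoring one is
        kept.  ``include_median`` force-adds each feature's median
        separation regardless of gap rank.
    """
    if k < 1:
        raise SeparationError("k must be >= 1")
    n = len(table.alphabet)
    if size_bounds is None:
        size_bounds = default_size_bounds(n, f)
    lo, hi = size_bounds
    pool: list[Separation] = []
    if mode == "median":
        for rec in table.records:
            try:
                pool.append(median_separation(rec, table.alphabet))
            except SeparationError as exc:
                logger.warning("skipping %s: %s", rec.accession, exc)
    elif mode == "cuts":
        for rec in table.records:
            scored = score_cuts(enumerate_cuts(rec, table.alphabet))
            survivors = [
                c
                for c in scored
                if lo <= c.cut_size <= hi and lo <= n - c.cut_size <= hi
            ]
            chosen = sorted(
                survivors, key=lambda c: (-c.gap, -c.score, c.cut_size)
            )[:k]
            if include_median:
                median_cut = next((c for c in scored if c.is_median), None)
                if median_cut is not None and median_cut not in chosen:
                    chosen.append(median_cut)
            pool.extend(chosen)
        pool = deduplicate_pool(pool)
    else:
        raise SeparationError(f"unknown pool mode {mode!r}")
    if not pool:
        raise SeparationError(
            "empty candidate pool; relax size_bounds, raise k, or supply "
            "features with realizable splits"
        )
    return pool


def deduplicate_pool(pool: Sequence[Separation]) -> list[Separation]:
    """Collapse separations that classify the residues identically.

    Within each membership-vector group the highest-scoring separation
    survives; remaining ties go to the lexicographically smallest
    accession, then the smallest cut_size.  Output is sorted by
    (accession, cut_size) so pool order is deterministic.
    """
    groups: dict[tuple[int, ...], list[Separation]] = {}
    for sep in pool:
        groups.setdefault(sep.membership, []).append(sep)
    best = [
        min(g, key=lambda s: (-s.score, s.accession, s.cut_size))
        for g in groups.values()
    ]
    return sorted(best, key=lambda s: s.key)
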
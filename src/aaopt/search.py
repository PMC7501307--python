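"""Backtracking search for minimal f-feature classifications.

f binary features can distinguish at most 2**f elements, so f = 5 is the
minimum for 20 residues (2**4 = 16 < 20 <= 32 = 2**5).  A *solution* is
an unordered set of f separations whose combined per-residue bit codes
are all distinct; for 20 residues and f = 5 exactly 12 of the 32 codes
stay empty.

The search refines a partition of the residue set one separation at a
time and prunes with the capacity (non-redundancy) criterion: after n of
f separations no partition cell may hold more than 2**(f-n) residues,
otherwise the remaining f-n features cannot tell its members apart.
This criterion is a *necessary* condition satisfied by every prefix of
every valid solution in every order, so pruning on it is sound — which
:func:`brute_force_solutions` verifies independently.

The enumerator walks pool indices in increasing canonical order, so each
unordered solution is emitted exactly once even though it admits
f! (= 120 for f = 5) ordered tree layouts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .separations import Separation

__all__ = [
    "Partition",
    "Solution",
    "SearchError",
    "root_partition",
    "refine",
    "admissible",
    "make_solution",
    "find_solutions",
    "brute_force_solutions",
    "cumulative_score",
    "empty_codes",
    "solution_codes",
]

logger = logging.getLogger(__name__)

BRUTE_FORCE_GUARD = 10_000_000


class SearchError(ValueError):
    """Raised for infeasible search parameters or mismatched inputs."""


@dataclass
class Partition:
    """Disjoint residue subsets keyed by the bit-code prefix that formed
    them.  Empty cells are kept as keys so the structure mirrors the
    full binary tree of depth ``depth``."""

    cells: dict[str, frozenset[str]]
    depth: int

    def __post_init__(self) -> None:
        for prefix in self.cells:
            if len(prefix) != self.depth:
                raise ValueError(
                    f"cell key {prefix!r} does not match depth {self.depth}"
                )

    @property
    def occupied(self) -> dict[str, frozenset[str]]:
        return {p: c for p, c in self.cells.items() if c}

    def size(self) -> int:
        return sum(len(c) for c in self.cells.values())


def root_partition(alphabet: Sequence[str]) -> Partition:
    return Partition(cells={"": frozenset(alphabet)}, depth=0)


def refine(
    partition: Partition, separation: Separation, alphabet: Sequence[str]
) -> Partition:
    """Split every cell by one separation; prefix+'0' collects the low
    side, prefix+'1' the high side.  Residue count is conserved."""
    if len(separation.membership) != len(alphabet):
        raise SearchError(
            f"separation {separation.key} is over a different alphabet "
            f"({len(separation.membership)} != {len(alphabet)} residues)"
        )
    bit = {r: separation.membership[i] for i, r in enumerate(alphabet)}
    cells: dict[str, frozenset[str]] = {}
    for prefix, members in partition.cells.items():
        low = frozenset(r for r in members if bit[r] == 0)
        cells[prefix + "0"] = low
        cells[prefix + "1"] = members - low
    return Partition(cells=cells, depth=partition.depth + 1)


def admissible(partition: Partition, f: int) -> bool:
    """Capacity criterion: every cell holds at most 2**(f - depth)
    residues, so the remaining features can still isolate its members."""
    if partition.depth > f:
        raise SearchError("partition deeper than the feature budget")
    cap = 2 ** (f - partition.depth)
    return all(len(c) <= cap for c in partition.cells.values())


@dataclass(eq=True)
class Solution:
    """An unordered set of f separations with all-distinct residue codes.

    ``separations`` are stored in canonical order (ascending accession,
    then cut_size); bit i of a residue's code is its membership bit in
    the i-th canonical separation (0 = low side).
    """

    separations: tuple[Separation, ...]
    codes: dict[str, str]
    cumulative_score: int
    empty_codes: frozenset[str] = field(default_factory=frozenset)

    @property
    def key(self) -> tuple[tuple[str, int], ...]:
        return tuple(s.key for s in self.separations)

    @property
    def f(self) -> int:
        return len(self.separations)

    @property
    def alphabet(self) -> tuple[str, ...]:
        return tuple(self.codes)

    def id(self) -> str:
        return "+".join(f"{a}:{c}" for a, c in self.key)


def solution_codes(
    separations: Sequence[Separation], alphabet: Sequence[str]
) -> dict[str, str]:
    """Per-residue bit codes for separations taken in the given order."""
    return {
        residue: "".join(str(s.membership[i]) for s in separations)
        for i, residue in enumerate(alphabet)
    }


def make_solution(
    separations: Sequence[Separation], alphabet: Sequence[str]
) -> Solution:
    """Canonicalize a separation set into a :class:`Solution`.

    Raises :class:`SearchError` if the residue codes are not all
    distinct (the defining condition of a solution).
    """
    canon = tuple(sorted(separations, key=lambda s: s.key))
    codes = solution_codes(canon, alphabet)
    if len(set(codes.values())) != len(alphabet):
        raise SearchError("separation set does not classify residues uniquely")
    f = len(canon)
    assigned = set(codes.values())
    empty = frozenset(
        format(i, f"0{f}b") for i in range(2**f) if format(i, f"0{f}b") not in assigned
    )
    return Solution(
        separations=canon,
        codes=codes,
        cumulative_score=sum(s.score for s in canon),
        empty_codes=empty,
    )


def _sorted_output(solutions: list[Solution]) -> list[Solution]:
    return sorted(solutions, key=lambda s: (-s.cumulative_score, s.key))


def find_solutions(
    pool: Sequence[Separation],
    alphabet: Sequence[str],
    f: int = 5,
    distinct_features: bool = True,
    stats: dict[str, int] | None = None,
) -> list[Solution]:
    """Enumerate every f-separation solution over ``pool``.

    Depth-first backtracking over the pool in canonical order, with an
    explicit stack (recursion depth never exceeds f, and the stack keeps
    pools of hundreds of separations safe).  A branch extends only while
    the capacity criterion holds; when it fails, the last separation is
    revoked and the next pool entry is tried.  With ``distinct_features``
    at most one separation per accession joins a branch.

    Output is sorted by descending cumulative score, then canonical key.
    ``stats``, if given, receives ``expanded`` / ``pruned`` counters.
    """
    n = len(alphabet)
    if 2**f < n:
        raise SearchError(
            f"{f} features can separate at most 2**{f} = {2**f} elements, "
            f"fewer than the {n} residues requested"
        )
    canon = sorted(pool, key=lambda s: s.key)
    for sep in canon:
        if len(sep.membership) != n:
            raise SearchError(
                f"separation {sep.key} is over a different alphabet"
            )
    index = {r: j for j, r in enumerate(alphabet)}
    expanded = 0
    pruned = 0
    solutions: list[Solution] = []
    # Cells are kept as a tuple of nonempty member-sets: empty cells can
    # never violate capacity and the uniqueness test only needs sizes.
    root = (frozenset(alphabet),)
    stack: list[tuple[int, tuple[Separation, ...], tuple[frozenset[str], ...]]]
    stack = [(0, (), root)]
    while stack:
        start, chosen, cells = stack.pop()
        depth = len(chosen)
        if depth == f:
            if all(len(c) <= 1 for c in cells):
                solutions.append(make_solution(chosen, alphabet))
            continue
        used = {s.accession for s in chosen} if distinct_features else None
        cap = 2 ** (f - depth - 1)
        # reversed push order -> children explored in canonical order
        for i in range(len(canon) - (f - depth - 1) - 1, start - 1, -1):
            sep = canon[i]
            if used is not None and sep.accession in used:
                continue
            expanded += 1
            new_cells: list[frozenset[str]] = []
            ok = True
            for cell in cells:
                low = frozenset(
                    r for r in cell if sep.membership[index[r]] == 0
                )
                high = cell - low
                if len(low) > cap or len(high) > cap:
                    ok = False
                    break
                if low:
                    new_cells.append(low)
                if high:
                    new_cells.append(high)
            if not ok:
                pruned += 1
                continue
            stack.append((i + 1, chosen + (sep,), tuple(new_cells)))
    if stats is not None:
        stats.update(expanded=expanded, pruned=pruned)
    logger.info(
        "search over %d separations: %d solutions (%d branches expanded, "
        "%d pruned by capacity)",
        len(canon),
        len(solutions),
        expanded,
        pruned,
    )
    return _sorted_output(solutions)


def brute_force_solutions(
    pool: Sequence[Separation],
    alphabet: Sequence[str],
    f: int = 5,
    distinct_features: bool = True,
) -> list[Solution]:
    """Exhaustive f-subset check with no pruning; the verification
    oracle for :func:`find_solutions`.  Guarded to C(|pool|, f) <= 1e7."""
    n = len(alphabet)
    if 2**f < n:
        raise SearchError(f"{f} features cannot separate {n} residues")
    if math.comb(len(pool), f) > BRUTE_FORCE_GUARD:
        raise SearchError(
            f"brute force over C({len(pool)}, {f}) subsets exceeds the "
            f"{BRUTE_FORCE_GUARD} guard"
        )
    canon = sorted(pool, key=lambda s: s.key)
    solutions: list[Solution] = []
    for subset in combinations(canon, f):
        if distinct_features and len({s.accession for s in subset}) < f:
            continue
        codes = set(
            zip(*(s.membership for s in subset))
        )
        if len(codes) == n:
            solutions.append(make_solution(subset, alphabet))
    return _sorted_output(solutions)


def cumulative_score(solution: Solution) -> int:
    """Sum of the gap-rank scores of the solution's separations (max
    f * (n - 2) = 90 for f = 5, n = 20 all-distinct values)."""
    return sum(s.score for s in solution.separations)


def empty_codes(solution: Solution) -> frozenset[str]:
    """The 2**f - n codes no residue occupies: candidate niches for
    amino acids outside the canonical set."""
    return solution.empty_codes
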
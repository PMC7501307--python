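"""Downstream analyses on solution sets.

* leave-one-residue-out redundancy profiling — how many additional
  classifications appear when one residue is excluded before the search;
  a large gain marks a residue whose properties are well covered by the
  remaining nineteen;
* empty-niche assessment — where a candidate (typically non-canonical)
  amino acid lands in each solution's code space, and how often it
  occupies a code no canonical residue uses, a proxy for how much
  chemical novelty it would add to an expanded genetic code;
* adjective labelling of solution groups ("small", "hydrophobic", ...);
* the identical-separation check used when screening correlated
  features as substitutes for hard-to-measure ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .aaindex_io import FeatureTable, restrict_residues
from .separations import Separation, SeparationError, candidate_pool
from .search import Solution, find_solutions

__all__ = [
    "AnalysisError",
    "RedundancyProfile",
    "NicheReport",
    "redundancy_profile",
    "niche_assessment",
    "label_groups",
    "separation_identity",
]


class AnalysisError(ValueError):
    pass


@dataclass
class RedundancyProfile:
    """Solution counts with each residue left out of the search.

    ``per_residue[r]`` is the count on the 19-residue alphabet minus the
    full-alphabet ``baseline_count``.  Under pool recomputation (medians
    and cut points shift on the reduced alphabet) the difference is
    almost always >= 0 but is not clamped here.
    """

    baseline_count: int
    per_residue: dict[str, int]


@dataclass
class NicheReport:
    """Per-solution placement of one candidate amino acid.

    ``per_solution`` rows are ``(solution id, code, was_empty,
    skipped)``; a solution is skipped when the candidate lacks a value
    for one of its features (e.g. helix propensities, which cannot be
    measured directly for non-canonical amino acids), in which case
    ``code`` is the empty string.
    """

    candidate: str
    per_solution: list[tuple[str, str, bool, bool]]
    empty_niche_count: int
    skipped_count: int


def redundancy_profile(
    table: FeatureTable,
    mode: str = "median",
    k: int = 3,
    f: int = 5,
    size_bounds: tuple[int, int] | None = None,
    distinct_features: bool = True,
) -> RedundancyProfile:
    """Leave-one-residue-out redundancy counts.

    For every residue the pool is rebuilt from scratch on the reduced
    alphabet (median splits and gap ranks are recomputed on 19 values;
    uniqueness means cells of at most one residue out of 19) and the
    search re-run with the same configuration.
    """
    if len(table.alphabet) < 2:
        raise AnalysisError("redundancy profiling needs at least 2 residues")

    def count(t: FeatureTable) -> int:
        try:
            pool = candidate_pool(t, mode=mode, k=k, size_bounds=size_bounds, f=f)
        except SeparationError:
            return 0
        return len(
            find_solutions(pool, t.alphabet, f=f, distinct_features=distinct_features)
        )

    baseline = count(table)
    per_residue: dict[str, int] = {}
    for residue in table.alphabet:
        reduced = restrict_residues(
            table, [r for r in table.alphabet if r != residue]
        )
        per_residue[residue] = count(reduced) - baseline
    return RedundancyProfile(baseline_count=baseline, per_residue=per_residue)


def niche_assessment(
    solutions: Sequence[Solution],
    candidate_values: Mapping[str, float],
    candidate: str = "X",
) -> NicheReport:
    """Place a candidate amino acid into every solution's code space.

    The candidate's bit for each separation follows the canonical
    threshold rule learned from the 20 residues (low iff value <=
    threshold); the candidate never shifts the thresholds.  A code is
    *empty* when no canonical residue occupies it.
    """
    if not solutions:
        raise AnalysisError("niche assessment needs at least one solution")
    rows: list[tuple[str, str, bool, bool]] = []
    empty_count = 0
    skipped = 0
    for sol in solutions:
        accs = [s.accession for s in sol.separations]
        if any(a not in candidate_values for a in accs):
            rows.append((sol.id(), "", False, True))
            skipped += 1
            continue
        code = "".join(
            "0" if candidate_values[s.accession] <= s.threshold else "1"
            for s in sol.separations
        )
        was_empty = code in sol.empty_codes
        rows.append((sol.id(), code, was_empty, False))
        empty_count += was_empty
    return NicheReport(
        candidate=candidate,
        per_solution=rows,
        empty_niche_count=empty_count,
        skipped_count=skipped,
    )


def label_groups(
    solution: Solution,
    label_config: Mapping[str, tuple[str, str]],
) -> dict[str, tuple[str, ...]]:
    """Adjective sets per residue, e.g. {"G": ("small",), ...}.

    ``label_config`` maps each accession to ``(adjective, side)`` with
    side "low" or "high"; a residue carries the adjective iff its
    membership bit falls on the labelled side.  In the classical naming,
    the low side of a volume index is "small" and the high side of an
    interaction-potential index is "electrostatically interactive".
    """
    missing = [
        s.accession for s in solution.separations if s.accession not in label_config
    ]
    if missing:
        raise AnalysisError(f"label config missing accessions: {missing}")
    alphabet = solution.alphabet
    out: dict[str, tuple[str, ...]] = {}
    for i, residue in enumerate(alphabet):
        adjectives = []
        for sep in solution.separations:
            adjective, side = label_config[sep.accession]
            if side not in ("low", "high"):
                raise AnalysisError(f"bad side {side!r} for {sep.accession}")
            if sep.membership[i] == (0 if side == "low" else 1):
                adjectives.append(adjective)
        out[residue] = tuple(adjectives)
    return out


def separation_identity(sep_a: Separation, sep_b: Separation) -> bool:
    """Whether two separations classify the residues identically."""
    if len(sep_a.membership) != len(sep_b.membership):
        raise AnalysisError("separations are over different alphabets")
    return sep_a.membership == sep_b.membership
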
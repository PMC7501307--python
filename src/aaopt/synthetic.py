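"""Synthetic residue-by-feature tables with known ground truth.

`generate_planted_table` plants a perfect f-feature classification: each
planted feature's values fall in two disjoint bands (low [0, 1), high
[2, 3)) whose gap dwarfs every within-band gap, so the planted cut is
simultaneously the top-gap cut and — when the bit-plane is balanced —
the median cut.  Noise features are built so that every realizable cut
fails the capacity size filter (n-2 exactly tied values plus two low
outliers), so they can never enter a cuts-mode solution and are skipped
as degenerate in median mode.

`generate_random_table` draws unstructured values with a controllable
fraction of exact ties, to exercise tie handling and to feed the
brute-force search oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .aaindex_io import CANONICAL_ALPHABET, FeatureRecord, FeatureTable

__all__ = [
    "PlantedDesign",
    "generate_planted_table",
    "generate_random_table",
    "default_labels",
]

_MAX_CODE_TRIES = 2000


@dataclass
class PlantedDesign:
    """Ground truth of a planted table: the code of every residue and
    the accessions whose cuts realize those codes."""

    n_residues: int
    f: int
    codes: dict[str, str]
    planted_accessions: tuple[str, ...]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_residues": self.n_residues,
                "f": self.f,
                "codes": self.codes,
                "planted_accessions": list(self.planted_accessions),
                "seed": self.seed,
            },
            indent=2,
        )


def default_labels(n_residues: int) -> tuple[str, ...]:
    """Residue labels: the canonical alphabet, extended with X1, X2, ...
    beyond 20 residues."""
    if n_residues <= 20:
        return CANONICAL_ALPHABET[:n_residues]
    extra = tuple(f"X{i}" for i in range(1, n_residues - 19))
    return CANONICAL_ALPHABET + extra


def _balanced_codes(
    rng: np.random.Generator, n: int, f: int
) -> list[int] | None:
    # complement pairs: {c, ~c} contribute one 0 and one 1 to every
    # plane, so n/2 pairs give perfectly balanced bit-planes
    if n % 2 or n // 2 > 2 ** (f - 1):
        return None
    mask = 2**f - 1
    halves = rng.choice(2 ** (f - 1), size=n // 2, replace=False)
    codes: list[int] = []
    for c in halves:
        codes.extend((int(c), int(c) ^ mask))
    return codes


def _capacity_codes(rng: np.random.Generator, n: int, f: int) -> list[int]:
    half = 2 ** (f - 1)
    lo, hi = max(1, n - half), min(n - 1, half)
    for _ in range(_MAX_CODE_TRIES):
        codes = [int(c) for c in rng.choice(2**f, size=n, replace=False)]
        zeros = [
            sum(1 for c in codes if not (c >> (f - 1 - bit)) & 1)
            for bit in range(f)
        ]
        if all(lo <= z <= hi for z in zeros):
            return codes
    raise ValueError(
        f"could not sample {n} codes with capacity-bounded bit-planes "
        f"for f={f}"
    )


def _band_values(
    rng: np.random.Generator, start: float, count: int
) -> list[float]:
    if count == 1:
        return [round(start, 6)]
    vals = np.round(np.linspace(start, start + 0.9, count), 6)
    return [float(v) for v in rng.permutation(vals)]


def generate_planted_table(
    n_residues: int = 20,
    n_noise_features: int = 0,
    seed: int = 0,
    f: int = 5,
    balanced: bool = True,
) -> tuple[FeatureTable, PlantedDesign]:
    """A table whose unique f-feature solution is known by construction.

    ``balanced=True`` (possible when n is even and n/2 <= 2**(f-1))
    samples codes as complement pairs so every planted bit-plane splits
    the residues evenly and the planted cut is also the median cut;
    otherwise codes are sampled subject only to the capacity bounds.
    Bit-for-bit reproducible from ``seed``.
    """
    if n_residues > 2**f:
        raise ValueError(f"{f} features cannot encode {n_residues} residues")
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if n_noise_features > 0 and n_residues - 2 ** (f - 1) < 3:
        # noise cuts have side sizes 1 and 2; the capacity size filter
        # only rejects them when its lower bound is >= 3
        raise ValueError(
            "noise features need n_residues >= 2**(f-1) + 3 so the "
            "capacity size filter excludes them"
        )
    rng = np.random.default_rng(seed)
    alphabet = default_labels(n_residues)
    codes_int = _balanced_codes(rng, n_residues, f) if balanced else None
    if codes_int is None:
        codes_int = _capacity_codes(rng, n_residues, f)
    codes = {
        r: format(c, f"0{f}b") for r, c in zip(alphabet, codes_int)
    }

    records: list[FeatureRecord] = []
    planted_accs = tuple(f"PLANT{i + 1:02d}" for i in range(f))
    for bit, acc in enumerate(planted_accs):
        low = [r for r in alphabet if codes[r][bit] == "0"]
        high = [r for r in alphabet if codes[r][bit] == "1"]
        values = dict(zip(low, _band_values(rng, 0.0, len(low))))
        values.update(zip(high, _band_values(rng, 2.0, len(high))))
        records.append(FeatureRecord(accession=acc, values=values))

    for j in range(n_noise_features):
        # n-2 exact ties + 2 low outliers: realizable cuts have side
        # sizes 1 and 2 only, outside the [4, 16] capacity filter, and
        # the median lands inside the tied block (degenerate split)
        base = round(float(rng.uniform(5.0, 10.0)), 6)
        outliers = rng.choice(n_residues, size=2, replace=False)
        values = {r: base for r in alphabet}
        values[alphabet[int(outliers[0])]] = round(base - 2.0, 6)
        values[alphabet[int(outliers[1])]] = round(base - 1.0, 6)
        records.append(
            FeatureRecord(accession=f"NOISE{j + 1:02d}", values=values)
        )

    table = FeatureTable(alphabet=alphabet, records=records)
    design = PlantedDesign(
        n_residues=n_residues,
        f=f,
        codes=codes,
        planted_accessions=planted_accs,
        seed=seed,
    )
    return table, design


def generate_random_table(
    n_residues: int = 20,
    n_features: int = 8,
    seed: int = 0,
    tie_fraction: float = 0.0,
    alphabet: Sequence[str] | None = None,
) -> FeatureTable:
    """Unstructured uniform values, with ``tie_fraction`` of each
    feature's entries overwritten by copies of other entries.

    After construction each feature has exactly
    ``n_residues - round(tie_fraction * n_residues)`` distinct values.
    """
    if not 0.0 <= tie_fraction <= 1.0:
        raise ValueError("tie_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = tuple(alphabet) if alphabet is not None else default_labels(n_residues)
    n_ties = int(round(tie_fraction * n_residues))
    if n_ties > n_residues - 1:
        n_ties = n_residues - 1
    records: list[FeatureRecord] = []
    for j in range(n_features):
        while True:
            vals = np.round(rng.uniform(0.0, 10.0, size=n_residues), 6)
            if len(set(vals.tolist())) == n_residues:
                break
        vals = [float(v) for v in vals]
        if n_ties:
            targets = rng.choice(n_residues, size=n_ties, replace=False)
            others = [i for i in range(n_residues) if i not in set(targets.tolist())]
            for t in targets:
                vals[int(t)] = vals[int(rng.choice(others))]
        records.append(
            FeatureRecord(
                accession=f"RAND{j + 1:03d}",
                values=dict(zip(labels, vals)),
            )
        )
    return FeatureTable(alphabet=labels, records=records)
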
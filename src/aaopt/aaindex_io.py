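"""Reading and writing amino-acid feature tables.

Two on-disk dialects are supported:

* the **AAindex1 flat file** — the standard exchange format for numeric
  amino-acid indices (one value per canonical residue per index), with
  keyed record lines (``H`` accession, ``D`` description, ``C`` correlated
  accessions, ``I`` the value block) and entries terminated by ``//``;
* a plain **tab-separated table** (``residue`` column + one column per
  accession), convenient for synthetic data and spreadsheets.

Values that the database marks ``NA`` (missing or undefined) are imputed
to 0 at parse time and flagged in :attr:`FeatureRecord.missing`, so
downstream analyses can drop or keep them explicitly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

__all__ = [
    "CANONICAL_ALPHABET",
    "AAindexParseError",
    "FeatureRecord",
    "FeatureTable",
    "parse_aaindex1",
    "write_feature_table",
    "read_feature_table_tsv",
    "read_accession_list",
    "filter_features",
    "restrict_residues",
]

#: The 20 canonical residues in AAindex I-line order.  Every membership
#: bit vector in this package indexes residues in this order.
CANONICAL_ALPHABET: tuple[str, ...] = (
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V",
)

#: The exact I-line header of an AAindex1 entry.
I_LINE_HEADER = "A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V"

#: Row-to-residue mapping implied by the I-line header: the first value
#: row carries A R N D C Q E G H I, the second L K M F P S T W Y V.
_ROW1 = CANONICAL_ALPHABET[:10]
_ROW2 = CANONICAL_ALPHABET[10:]


class AAindexParseError(ValueError):
    """Raised when an AAindex1 entry or feature TSV is malformed."""


@dataclass
class FeatureRecord:
    """One numeric index: a value for every residue in the alphabet.

    Parameters
    ----------
    accession:
        Short identifier, e.g. an AAindex H-line code such as
        ``GRAR740102``.  Unique within a table.
    description:
        Free-text description (D-line).
    values:
        Mapping residue label -> value.  Units vary per index and are
        treated as dimensionless here.
    missing:
        Residues whose value was absent in the source (``NA``) and was
        imputed to exactly 0.
    correlated:
        ``(accession, correlation coefficient)`` pairs from the C-line.
        Metadata only; never used in computation.
    """

    accession: str
    values: dict[str, float]
    description: str = ""
    missing: frozenset[str] = frozenset()
    correlated: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        for residue in self.missing:
            if self.values.get(residue) != 0.0:
                raise ValueError(
                    f"{self.accession}: residue {residue} flagged missing "
                    "but its imputed value is not 0"
                )


@dataclass
class FeatureTable:
    """An ordered residue-by-feature numeric matrix.

    ``alphabet`` fixes the residue order used by every bit vector derived
    from the table; ``records`` preserve input order.  ``warnings`` carry
    non-fatal notes (e.g. unknown accessions requested in a filter).
    """

    alphabet: tuple[str, ...]
    records: list[FeatureRecord] = field(default_factory=list)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.alphabet = tuple(self.alphabet)
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet labels must be unique")
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
            if set(rec.values) != set(self.alphabet):
                raise ValueError(
                    f"record {rec.accession!r} does not cover the alphabet"
                )

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(rec.accession for rec in self.records)

    def record(self, accession: str) -> FeatureRecord:
        for rec in self.records:
            if rec.accession == accession:
                return rec
        raise KeyError(accession)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.alphabet == other.alphabet
            and len(self.records) == len(other.records)
            and all(
                a.accession == b.accession
                and a.values == b.values
                and a.missing == b.missing
                for a, b in zip(self.records, other.records)
            )
        )


def _as_text_lines(stream: IO[str] | str) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream.read().splitlines()


def parse_aaindex1(stream: IO[str] | str) -> FeatureTable:
    """Parse zero or more AAindex1 entries into a :class:`FeatureTable`.

    The I-line header maps the first value row to residues
    ``A R N D C Q E G H I`` and the second to ``L K M F P S T W Y V``.
    ``NA`` tokens become value 0 with the residue recorded in
    :attr:`FeatureRecord.missing`.  Record order follows entry order.

    Raises
    ------
    AAindexParseError
        On a wrong count of value tokens, a non-numeric token other than
        ``NA``, or a duplicate accession.
    """
    lines = _as_text_lines(stream)
    records: list[FeatureRecord] = []
    entry: list[str] = []
    for line in lines:
        if line.strip() == "//":
            if any(l.strip() for l in entry):
                records.append(_parse_entry(entry))
            entry = []
        else:
            entry.append(line)
    if any(l.strip() for l in entry):
        records.append(_parse_entry(entry))
    return FeatureTable(alphabet=CANONICAL_ALPHABET, records=records)


def _parse_entry(lines: list[str]) -> FeatureRecord:
    accession = ""
    description = ""
    correlated: list[tuple[str, float]] = []
    value_tokens: list[str] = []
    key = ""
    in_values = False
    for line in lines:
        if not line.strip():
            continue
        if line[0] not in " \t":
            key = line[0]
            body = line[1:].strip()
            in_values = False
        else:
            body = line.strip()
            if in_values:
                value_tokens.extend(body.split())
                continue
        if key == "H" and line[0] == "H":
            accession = body
        elif key == "D" and line[0] == "D":
            description = body
        elif key == "C":
            tokens = body.split()
            if len(tokens) % 2:
                raise AAindexParseError(
                    f"{accession or '<no accession>'}: odd C-line token count"
                )
            for acc, coef in zip(tokens[::2], tokens[1::2]):
                try:
                    correlated.append((acc, float(coef)))
                except ValueError as exc:
                    raise AAindexParseError(
                        f"{accession}: bad C-line coefficient {coef!r}"
                    ) from exc
        elif key == "I":
            if line[0] == "I":
                header = " ".join(body.split())
                if header != I_LINE_HEADER:
                    raise AAindexParseError(
                        f"{accession or '<no accession>'}: unexpected "
                        f"I-line header {header!r}"
                    )
                in_values = True
    if not accession:
        raise AAindexParseError("entry without an H (accession) line")
    if len(value_tokens) != 20:
        raise AAindexParseError(
            f"{accession}: expected 20 value tokens on the I-line block, "
            f"got {len(value_tokens)}"
        )
    values: dict[str, float] = {}
    missing: set[str] = set()
    order = _ROW1 + _ROW2
    for residue, token in zip(order, value_tokens):
        if token.upper() == "NA" or token == "-":
            values[residue] = 0.0
            missing.add(residue)
        else:
            try:
                values[residue] = float(token)
            except ValueError as exc:
                raise AAindexParseError(
                    f"{accession}: non-numeric value token {token!r}"
                ) from exc
    return FeatureRecord(
        accession=accession,
        description=description,
        values=values,
        missing=frozenset(missing),
        correlated=tuple(correlated),
    )


def _format_value(record: FeatureRecord, residue: str) -> str:
    if residue in record.missing:
        return "NA"
    return repr(record.values[residue])


def write_feature_table(
    table: FeatureTable, sink: IO[str], format: str = "tsv"
) -> None:
    """Serialize ``table`` to ``sink`` as ``tsv`` or ``aaindex1``.

    Both formats round-trip losslessly with the matching reader (values
    are written as shortest-repr decimal text; missing entries as
    ``NA``).  The AAindex1 dialect is defined for the canonical
    20-residue alphabet only.
    """
    if format == "tsv":
        _write_tsv(table, sink)
    elif format == "aaindex1":
        _write_aaindex1(table, sink)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_tsv(table: FeatureTable, sink: IO[str]) -> None:
    sink.write("\t".join(("residue",) + table.accessions) + "\n")
    if not table.records:
        return
    for residue in table.alphabet:
        row = [residue] + [_format_value(rec, residue) for rec in table.records]
        sink.write("\t".join(row) + "\n")


def _write_aaindex1(table: FeatureTable, sink: IO[str]) -> None:
    if table.alphabet != CANONICAL_ALPHABET:
        raise ValueError(
            "AAindex1 output is defined for the canonical 20-residue "
            "alphabet only; use format='tsv' for other alphabets"
        )
    for rec in table.records:
        sink.write(f"H {rec.accession}\n")
        if rec.description:
            sink.write(f"D {rec.description}\n")
        if rec.correlated:
            pairs = "  ".join(f"{acc} {coef:g}" for acc, coef in rec.correlated)
            sink.write(f"C {pairs}\n")
        sink.write("I    " + I_LINE_HEADER.replace(" ", "     ") + "\n")
        for row in (_ROW1, _ROW2):
            sink.write(
                "  " + "  ".join(_format_value(rec, r) for r in row) + "\n"
            )
        sink.write("//\n")


def read_feature_table_tsv(stream: IO[str] | str) -> FeatureTable:
    """Inverse of the TSV writer; the alphabet is taken from row order."""
    lines = [l for l in _as_text_lines(stream) if l.strip()]
    if not lines:
        raise AAindexParseError("empty feature TSV")
    header = lines[0].split("\t")
    if header[0] != "residue":
        raise AAindexParseError("feature TSV must start with a 'residue' column")
    accessions = header[1:]
    alphabet: list[str] = []
    columns: list[list[float]] = [[] for _ in accessions]
    missing: list[set[str]] = [set() for _ in accessions]
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(header):
            raise AAindexParseError(f"ragged TSV row: {line!r}")
        residue = cells[0]
        if residue in alphabet:
            raise AAindexParseError(f"duplicate residue label {residue!r}")
        alphabet.append(residue)
        for j, cell in enumerate(cells[1:]):
            if cell.upper() == "NA":
                columns[j].append(0.0)
                missing[j].add(residue)
            else:
                try:
                    columns[j].append(float(cell))
                except ValueError as exc:
                    raise AAindexParseError(
                        f"non-numeric cell {cell!r} in column "
                        f"{accessions[j]!r}"
                    ) from exc
    records = [
        FeatureRecord(
            accession=acc,
            values=dict(zip(alphabet, col)),
            missing=frozenset(miss),
        )
        for acc, col, miss in zip(accessions, columns, missing)
    ]
    return FeatureTable(alphabet=tuple(alphabet), records=records)


def read_accession_list(stream: IO[str] | str) -> list[str]:
    """Read a plain accession list: one per line, ``#`` comments allowed."""
    out: list[str] = []
    for line in _as_text_lines(stream):
        body = line.split("#", 1)[0].strip()
        if body:
            out.append(body)
    return out


def filter_features(
    table: FeatureTable, accessions: Sequence[str]
) -> FeatureTable:
    """Restrict ``table`` to ``accessions``, preserving list order.

    This implements curation: e.g. keeping a hand-picked subset of
    biologically interpretable indices out of a full database dump.
    Unknown accessions are not fatal; they are reported in the result's
    ``warnings``.
    """
    if not accessions:
        raise ValueError("accession list must be non-empty")
    by_acc = {rec.accession: rec for rec in table.records}
    kept: list[FeatureRecord] = []
    warnings: list[str] = []
    for acc in accessions:
        if acc in by_acc:
            kept.append(by_acc[acc])
        else:
            warnings.append(f"unknown accession {acc!r}")
    return FeatureTable(
        alphabet=table.alphabet, records=kept, warnings=tuple(warnings)
    )


def restrict_residues(
    table: FeatureTable, residues: Iterable[str]
) -> FeatureTable:
    """Restrict ``table`` to a residue subset (alphabet order preserved).

    Used by leave-one-residue-out analyses, where medians and cut points
    are recomputed on the reduced alphabet.
    """
    keep = set(residues)
    unknown = keep - set(table.alphabet)
    if unknown:
        raise ValueError(f"residues not in alphabet: {sorted(unknown)}")
    alphabet = tuple(r for r in table.alphabet if r in keep)
    records = [
        FeatureRecord(
            accession=rec.accession,
            description=rec.description,
            values={r: rec.values[r] for r in alphabet},
            missing=frozenset(m for m in rec.missing if m in keep),
            correlated=rec.correlated,
        )
        for rec in table.records
    ]
    return FeatureTable(alphabet=alphabet, records=records)


def table_from_text(text: str) -> FeatureTable:
    """Parse a feature table from text, sniffing AAindex1 vs TSV."""
    stripped = text.lstrip()
    if stripped.startswith("residue\t"):
        return read_feature_table_tsv(io.StringIO(text))
    return parse_aaindex1(io.StringIO(text))
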
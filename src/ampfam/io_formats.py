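"""Readers and writers for the external artifacts of the pipeline.

Formats handled here:

* peptide FASTA (via Biopython :mod:`Bio.SeqIO`),
* two-column family-label tables (tab-separated, no header),
* AAIndex1 flat files of amino-acid property scales,
* feature-matrix TSV with region-tagged column descriptors,
* YAML run configuration.

Peptides carrying non-canonical letters (B, Z, J, X, U, O or anything
outside the 20 one-letter codes) are skipped on input with a warning:
per-residue masking would corrupt the fixed-length region layout, so the
whole record is dropped instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Residue order of the two value rows in an AAIndex1 record:
#: "I    A/L  R/K  N/M  D/F  C/P  Q/S  E/T  G/W  H/Y  I/V".
AAINDEX_ROW1 = "ARNDCQEGHI"
AAINDEX_ROW2 = "LKMFPSTWYV"


class ParseError(ValueError):
    """A file did not conform to its declared format."""


@dataclass(frozen=True)
class Peptide:
    """An identified amino-acid sequence with an optional family label."""

    id: str
    sequence: str
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise ValueError(
                f"peptide {self.id!r}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_family(self, family: str | None) -> "Peptide":
        return Peptide(self.id, self.sequence, family)


@dataclass(frozen=True)
class AAIndexProperty:
    """One amino-acid property scale: a real value per canonical residue."""

    accession: str
    description: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != _CANONICAL_SET:
            raise ValueError(
                f"property {self.accession}: needs exactly one value per "
                f"canonical residue, got {len(self.values)}"
            )

    def value_array(self, order: str = CANONICAL_AA):
        import numpy as np

        return np.array([self.values[a] for a in order], dtype=float)


@dataclass
class AAIndexTable:
    """An ordered collection of property scales with unique accessions."""

    properties: list[AAIndexProperty]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        accs = [p.accession for p in self.properties]
        if len(set(accs)) != len(accs):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions: {dupes}")

    def __len__(self) -> int:
        return len(self.properties)

    def __iter__(self):
        return iter(self.properties)

    def __getitem__(self, accession: str) -> AAIndexProperty:
        for p in self.properties:
            if p.accession == accession:
                return p
        raise KeyError(accession)

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.properties]


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature column: what it measures and in which region."""

    name: str
    region: str  # one of n1..n4, M, C, FULL
    category: str  # composition | twin | distance_basic | distance_hydrophobic
    #              | distance_other | physchem

    @property
    def column(self) -> str:
        return f"{self.category}:{self.region}:{self.name}"

    @staticmethod
    def from_column(column: str) -> "FeatureDescriptor":
        try:
            category, region, name = column.split(":", 2)
        except ValueError as exc:
            raise ParseError(f"malformed feature column {column!r}") from exc
        return FeatureDescriptor(name=name, region=region, category=category)


@dataclass
class FeatureMatrix:
    """Peptides x named, region-tagged features, with optional family labels.

    ``data`` is a :class:`pandas.DataFrame` indexed by peptide id whose
    columns are ``category:region:name`` descriptor strings.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and not self.data.index.equals(self.labels.index):
            raise ValueError("labels index must match the peptide-id index")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature columns")

    @property
    def descriptors(self) -> list[FeatureDescriptor]:
        return [FeatureDescriptor.from_column(c) for c in self.data.columns]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_columns(self, columns: Iterable[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[:, list(columns)].copy(), self.labels)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Peptide]:
    """Read peptides from a FASTA file.

    Sequences are uppercased.  Records containing letters outside the 20
    canonical amino-acid codes are skipped with a warning.  An empty or
    record-free file raises :class:`ParseError`.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    seen: set[str] = set()
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(record.seq).upper()
        bad = set(seq) - _CANONICAL_SET
        if bad or not seq:
            warnings.warn(
                f"{path.name}: skipping record {record.id!r} with "
                f"non-canonical residues {sorted(bad)}",
                stacklevel=2,
            )
            continue
        if record.id in seen:
            raise ParseError(f"{path}: duplicate id {record.id!r}")
        seen.add(record.id)
        peptides.append(Peptide(id=record.id, sequence=seq))
    if n_records == 0:
        raise ParseError(f"{path}: no FASTA records found")
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# family-label table
# ---------------------------------------------------------------------------

def read_family_table(path: str | Path) -> dict[str, str]:
    """Read a tab-separated ``id<TAB>family`` table into a dict.

    A duplicated id is tolerated when the label agrees and rejected when it
    conflicts.  An empty file yields an empty mapping.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            pid, family = parts
            if pid in mapping and mapping[pid] != family:
                raise ParseError(
                    f"{path}:{lineno}: id {pid!r} maps to both "
                    f"{mapping[pid]!r} and {family!r}"
                )
            mapping[pid] = family
    return mapping


def write_family_table(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, family in mapping.items():
            fh.write(f"{pid}\t{family}\n")


def attach_families(
    peptides: Iterable[Peptide], mapping: dict[str, str]
) -> list[Peptide]:
    """Return peptides with family labels filled in from ``mapping``."""
    return [p.with_family(mapping.get(p.id)) for p in peptides]


# ---------------------------------------------------------------------------
# AAIndex1 flat file
# ---------------------------------------------------------------------------

def parse_aaindex(path: str | Path) -> AAIndexTable:
    """Parse an AAIndex1 flat file of amino-acid property scales.

    Each record starts with ``H <accession>``, carries an ``I`` header line
    followed by two rows of ten whitespace-separated values (residue order
    A R N D C Q E G H I / L K M F P S T W Y V) and ends with ``//``.

    Records with any ``NA`` value are excluded (their accessions are listed
    in :attr:`AAIndexTable.excluded`); a record with the wrong number of
    values raises :class:`ParseError` naming the accession.
    """
    properties: list[AAIndexProperty] = []
    excluded: list[str] = []
    accession = ""
    description = ""
    value_tokens: list[str] = []
    in_values = False

    def finish_record() -> None:
        nonlocal accession, description, value_tokens, in_values
        if not accession:
            raise ParseError(f"{path}: record terminator without 'H' line")
        if len(value_tokens) != 20:
            raise ParseError(
                f"{path}: record {accession}: expected 20 values, "
                f"got {len(value_tokens)}"
            )
        if any(t.upper() == "NA" for t in value_tokens):
            excluded.append(accession)
        else:
            order = AAINDEX_ROW1 + AAINDEX_ROW2
            try:
                values = {
                    aa: float(tok) for aa, tok in zip(order, value_tokens)
                }
            except ValueError as exc:
                raise ParseError(
                    f"{path}: record {accession}: non-numeric value"
                ) from exc
            properties.append(
                AAIndexProperty(accession, description.strip(), values)
            )
        accession, description, value_tokens, in_values = "", "", [], False

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("//"):
                finish_record()
            elif line.startswith("H "):
                accession = line[2:].strip()
                in_values = False
            elif line.startswith("D "):
                description = line[2:].strip()
                in_values = False
            elif line.startswith("I "):
                in_values = True
            elif line.startswith(" ") and in_values:
                value_tokens.extend(line.split())
            elif line and not line[0].isspace():
                # other AAIndex sections (R, A, T, J, C ...) end the value block
                in_values = False
    if accession:
        raise ParseError(f"{path}: record {accession} missing '//' terminator")
    return AAIndexTable(properties=properties, excluded=excluded)


def write_aaindex(table: AAIndexTable, path: str | Path) -> None:
    """Write property scales in the AAIndex1 flat-file dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for prop in table.properties:
            fh.write(f"H {prop.accession}\n")
            fh.write(f"D {prop.description}\n")
            fh.write(
                "I    A/L     R/K     N/M     D/F     C/P     "
                "Q/S     E/T     G/W     H/Y     I/V\n"
            )
            for row in (AAINDEX_ROW1, AAINDEX_ROW2):
                fh.write(
                    "  "
                    + " ".join(repr(prop.values[aa]) for aa in row)
                    + "\n"
                )
            fh.write("//\n")


# ---------------------------------------------------------------------------
# feature-matrix TSV
# ---------------------------------------------------------------------------

_ID_COL = "peptide_id"
_LABEL_COL = "family"


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as TSV (exact float round-trip via ``repr``)."""
    with open(path, "w", encoding="utf-8") as fh:
        header = [_ID_COL]
        if matrix.labels is not None:
            header.append(_LABEL_COL)
        header.extend(matrix.data.columns)
        fh.write("\t".join(header) + "\n")
        for pid in matrix.data.index:
            row = [str(pid)]
            if matrix.labels is not None:
                row.append(str(matrix.labels.loc[pid]))
            row.extend(repr(v) for v in matrix.data.loc[pid].to_list())
            fh.write("\t".join(row) + "\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise ParseError(f"{path}: empty file")
        header = header_line.split("\t")
        if header[0] != _ID_COL:
            raise ParseError(f"{path}: first column must be {_ID_COL!r}")
        has_labels = len(header) > 1 and header[1] == _LABEL_COL
        feat_start = 2 if has_labels else 1
        columns = header[feat_start:]
        for col in columns:
            FeatureDescriptor.from_column(col)  # validates
        ids: list[str] = []
        labels: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: {len(parts)} columns, header has "
                    f"{len(header)}"
                )
            ids.append(parts[0])
            if has_labels:
                labels.append(parts[1])
            rows.append([float(v) for v in parts[feat_start:]])
    data = pd.DataFrame(rows, index=ids, columns=columns, dtype=float)
    label_series = pd.Series(labels, index=ids) if has_labels else None
    return FeatureMatrix(data=data, labels=label_series)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    return cfg
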
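"""Readers and writers for every external representation the pipeline touches.

Formats are deliberately plain: multi-record FASTA for genomes, Newick with
branch lengths for trees, tab-separated tables for metadata, similarity /
distance matrices and host–phage association lists.  Readers validate, and
every reader/writer pair round-trips bit-faithfully on valid input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SequenceRecord",
    "LabeledMatrix",
    "AssociationTable",
    "MISSING",
    "METADATA_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "load_newick",
    "save_newick",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_associations_tsv",
    "write_associations_tsv",
    "check_id_overlap",
]

#: Sentinel used for any missing categorical metadata value.
MISSING = "N/A"

METADATA_COLUMNS = ("genome_id", "host_species", "country", "isolation_source")

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A single DNA sequence with a whitespace-free identifier.

    ``description`` keeps the full FASTA header; ``id`` is the header
    truncated at the first whitespace, matching common tool behaviour.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledMatrix:
    """Square numeric matrix aligned to an ordered list of unique labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("matrix labels are not unique")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-6, rtol=0.0):
            raise ValueError("matrix is not symmetric within 1e-6")
        # store the exactly symmetrised form so downstream algebra is clean
        self.values = (self.values + self.values.T) / 2.0
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def value(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"unknown label: {exc.args[0]!r}") from None

    def reorder(self, labels: Sequence[str]) -> "LabeledMatrix":
        """Return a copy with rows/columns aligned to ``labels``."""
        try:
            idx = [self._index[lab] for lab in labels]
        except KeyError as exc:
            raise KeyError(f"unknown label: {exc.args[0]!r}") from None
        return LabeledMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class AssociationTable:
    """Unique (host_id, phage_id) links, optionally annotated with
    Procrustes squared residuals and host-jump flags."""

    links: list[tuple[str, str]]
    residual_sq: list[float] | None = None
    jump_flag: list[bool] | None = None

    def __post_init__(self) -> None:
        self.links = [(str(h), str(p)) for h, p in self.links]
        if len(set(self.links)) != len(self.links):
            raise ValueError("association links are not unique")
        for attr in ("residual_sq", "jump_flag"):
            vals = getattr(self, attr)
            if vals is not None and len(vals) != len(self.links):
                raise ValueError(f"{attr} length does not match links")

    @property
    def hosts(self) -> list[str]:
        return [h for h, _ in self.links]

    @property
    def phages(self) -> list[str]:
        return [p for _, p in self.links]

    def validate_against(self, host_ids: Iterable[str], phage_ids: Iterable[str]) -> None:
        hosts, phages = set(host_ids), set(phage_ids)
        for h, p in self.links:
            if h not in hosts:
                raise KeyError(f"association host {h!r} not resolvable")
            if p not in phages:
                raise KeyError(f"association phage {p!r} not resolvable")

    def __len__(self) -> int:
        return len(self.links)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Lowercase bases are uppercased; multi-line sequences are concatenated;
    the record id is the header truncated at the first whitespace.  Raises
    on empty files, duplicate ids and characters outside {A,C,G,T,N}.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        rec_id = header.split()[0] if header.split() else ""
        records.append(SequenceRecord(rec_id, seq, description=header))

    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate record ids {dupes}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick

def read_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick string with branch lengths.

    Polytomies are allowed; duplicate leaf labels and malformed strings
    raise ``ValueError``.
    """
    if not text.strip().endswith(";"):
        raise ValueError("Newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed Newick: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in Newick string")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to Newick; round-trips labels, topology and branch
    lengths to at least 10 significant decimal digits."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    ).strip()


def load_newick(path: str | Path) -> dendropy.Tree:
    return read_newick(Path(path).read_text())


def save_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Labeled matrices (TSV: first row and first column are labels)

def read_matrix_tsv(path: str | Path) -> LabeledMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = header[1:]
        rows: list[list[float]] = []
        row_labels: list[str] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(labels) + 1:
                raise ValueError(f"{path}: ragged row for label {parts[0]!r}")
            row_labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if row_labels != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return LabeledMatrix(labels, np.array(rows))


def write_matrix_tsv(matrix: LabeledMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(["id"] + matrix.labels) + "\n")
        for lab, row in zip(matrix.labels, matrix.values):
            fh.write(lab + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# Metadata

def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-phage metadata keyed by ``phage_id``.

    Required columns: genome_id, host_species, country, isolation_source.
    Missing values (empty cells, NaN) are normalised to the single sentinel
    ``"N/A"``; categories are treated as opaque strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "phage_id" not in df.columns:
        raise ValueError(f"{path}: missing 'phage_id' column")
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if df["phage_id"].duplicated().any():
        dupes = sorted(df.loc[df["phage_id"].duplicated(), "phage_id"].unique())
        raise ValueError(f"{path}: duplicate phage_id values {dupes}")
    df = df.set_index("phage_id")
    for col in METADATA_COLUMNS:
        df[col] = df[col].replace("", MISSING).fillna(MISSING)
    if (df["genome_id"] == MISSING).any():
        bad = sorted(df.index[df["genome_id"] == MISSING])
        raise ValueError(f"{path}: empty genome_id for phages {bad}")
    return df


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="phage_id")


# ---------------------------------------------------------------------------
# Associations

def read_associations_tsv(path: str | Path) -> AssociationTable:
    df = pd.read_csv(path, sep="\t", dtype={"host_id": str, "phage_id": str})
    links = list(zip(df["host_id"], df["phage_id"]))
    residual = df["residual_sq"].tolist() if "residual_sq" in df.columns else None
    flags = None
    if "jump_flag" in df.columns:
        flags = [bool(int(v)) for v in df["jump_flag"]]
    return AssociationTable(links, residual_sq=residual, jump_flag=flags)


def write_associations_tsv(assoc: AssociationTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        cols = ["host_id", "phage_id"]
        if assoc.residual_sq is not None:
            cols.append("residual_sq")
        if assoc.jump_flag is not None:
            cols.append("jump_flag")
        fh.write("\t".join(cols) + "\n")
        for i, (h, p) in enumerate(assoc.links):
            row = [h, p]
            if assoc.residual_sq is not None:
                row.append(format(assoc.residual_sq[i], ".10g"))
            if assoc.jump_flag is not None:
                row.append(str(int(assoc.jump_flag[i])))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------

def check_id_overlap(metadata_ids: Iterable[str], matrix_labels: Iterable[str]) -> dict:
    """Report (never silently drop) id differences between a metadata table
    and a similarity matrix."""
    meta, mat = set(metadata_ids), set(matrix_labels)
    return {
        "shared": sorted(meta & mat),
        "metadata_only": sorted(meta - mat),
        "matrix_only": sorted(mat - meta),
    }
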
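"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as a TSV (first column = feature id, header =
sample ids) plus a sidecar labels TSV mapping sample id -> group.  FASTA
is parsed with Biopython and normalised to the RNA alphabet (T -> U,
upper case).  Gene sets use the standard GMT layout.  All writers emit
UTF-8 with LF endings; readers are insensitive to CRLF and trailing
whitespace.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import ExpressionDataset, FormatError, GeneSetCollection

RNA_ALPHABET = frozenset("ACGU")


# ---------------------------------------------------------------------------
# expression TSV


def read_expression_tsv(
    matrix_path: str | Path,
    labels_path: str | Path,
    biotype: str | Path | pd.Series = "mRNA",
    cohort_id: str | None = None,
    is_log: bool = True,
) -> ExpressionDataset:
    """Read an expression matrix TSV plus its sample-labels sidecar.

    ``biotype`` may be a single biotype applied to every feature, a
    per-feature :class:`pandas.Series`, or the path of a two-column TSV
    (feature id, biotype).
    """
    matrix_path = Path(matrix_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise FormatError(f"{matrix_path}: empty expression matrix")
    values.index = values.index.astype(str).str.strip()
    values.columns = values.columns.astype(str).str.strip()
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any():
            row = values.index[bad][0]
            raise FormatError(
                f"{matrix_path}: non-numeric value at feature {row!r}, sample {col!r}"
            )
        values[col] = coerced
    labels = _read_two_column_tsv(labels_path, "sample", "group")
    if isinstance(biotype, pd.Series):
        biotypes = biotype
    elif isinstance(biotype, (str,)) and biotype in ("mRNA", "lncRNA", "miRNA"):
        biotypes = pd.Series(biotype, index=values.index)
    else:
        biotypes = _read_two_column_tsv(biotype, "feature", "biotype")
    return ExpressionDataset(
        values=values,
        biotype=biotypes,
        group=labels,
        cohort_id=cohort_id or matrix_path.stem,
        is_log=is_log,
    )


def write_expression_tsv(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
    header_comment: str | None = None,
) -> None:
    matrix_path = Path(matrix_path)
    with open(matrix_path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        dataset.values.to_csv(fh, sep="\t", index_label="feature", lineterminator="\n")
    with open(labels_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in dataset.group.items():
            fh.write(f"{sample}\t{group}\n")


def write_biotype_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature\tbiotype\n")
        for feature, biotype in dataset.biotype.items():
            fh.write(f"{feature}\t{biotype}\n")


def _read_two_column_tsv(path: str | Path, key_name: str, value_name: str) -> pd.Series:
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n").strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            key, value = parts[0], parts[1]
            if lineno == 1 and key.lower() in (key_name, "sample", "feature", "id"):
                continue  # header row
            if key in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate {key_name} {key!r}")
            mapping[key] = value
    return pd.Series(mapping, name=value_name)


# ---------------------------------------------------------------------------
# FASTA


def normalize_rna(seq: str) -> str:
    """Upper-case and map DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def check_unambiguous(seq: str, seq_id: str = "sequence") -> None:
    for pos, base in enumerate(seq):
        if base not in RNA_ALPHABET:
            raise FormatError(
                f"{seq_id}: ambiguous or invalid base {base!r} at position {pos}"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: RNA sequence} mapping.

    T is mapped to U and case is folded; ambiguous bases are *kept*
    here and rejected with a clear error by the sequence-analysis
    stages that cannot handle them.
    """
    records: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in records:
            raise FormatError(f"{path}: duplicate sequence id {record.id!r}")
        seq = normalize_rna(str(record.seq))
        if len(seq) == 0:
            raise FormatError(f"{path}: empty record {record.id!r}")
        records[record.id] = seq
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, members; tab-separated)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n").rstrip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = parts[0], parts[1]
            members: list[str] = []
            seen: set[str] = set()
            for member in parts[2:]:
                member = member.strip()
                if member and member not in seen:
                    members.append(member)
                    seen.add(member)
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, (desc, members) in collection:
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# edge lists / generic tables


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None,
                index: bool = False) -> None:
    """Write a TSV with an optional leading ``#`` comment line."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
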
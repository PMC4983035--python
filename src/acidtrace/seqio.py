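"""Sequence, alignment, tree and RSA-table I/O with strict validation.

All residue coordinates in this package are 1-based inclusive, matching the
convention used for protein domain annotations (e.g. "amino acids 36-50").

File formats are delegated to established parsers — FASTA through
:mod:`Bio.SeqIO`, Newick through :mod:`dendropy` — and wrapped with the
validation and normalisation rules this pipeline needs: uppercase residues,
terminal-stop stripping, ambiguity codes collapsed to ``X``, unique ids,
rectangular alignments, contiguous 1..L RSA tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

from .errors import LookupError_, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: the 20 standard amino acids plus X (unknown/ambiguous)
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = STANDARD_AA | {"X"}
#: ambiguity codes occasionally emitted by databases, collapsed to X
AMBIGUOUS_AA = set("UBZJO")
GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """One named, ungapped protein sequence.

    Parameters
    ----------
    id : str
        Unique identifier (within any collection this record joins).
    residues : str
        Uppercase residues over the 20 standard amino acids plus ``X``.
    species : str
        Free-text species annotation; empty string when unknown.
    """

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record id must be non-empty")
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = [(i + 1, c) for i, c in enumerate(self.residues) if c not in ALPHABET]
        if bad:
            pos, char = bad[0]
            raise ValidationError(
                f"record {self.id!r}: illegal residue {char!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase, strip one terminal '*', map ambiguity codes to X.

    U/B/Z/J/O are mapped to ``X`` with a logged warning; any other
    non-standard character raises :class:`ValidationError` with its 1-based
    position.
    """
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise ParseError(f"record {record_id!r}: empty sequence")
    out = []
    for i, c in enumerate(seq):
        if c in STANDARD_AA or c == "X":
            out.append(c)
        elif c in AMBIGUOUS_AA:
            logger.warning(
                "record %r: ambiguity code %r at position %d mapped to X",
                record_id, c, i + 1,
            )
            out.append("X")
        else:
            raise ValidationError(
                f"record {record_id!r}: illegal residue {c!r} at position {i + 1}"
            )
    return "".join(out)


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for rid in ids:
        if rid in seen:
            raise ValidationError(f"duplicate record id {rid!r}")
        seen.add(rid)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read ungapped protein FASTA into validated records, in file order."""
    path = Path(path)
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Bio.SeqIO warns on odd headers
        parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise ParseError(f"{path}: no FASTA records found")
    for rec in parsed:
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        seq = str(rec.seq)
        if GAP in seq:
            raise ValidationError(
                f"record {rec.id!r}: gap characters in ungapped FASTA "
                f"(use read_alignment for aligned input)"
            )
        residues = normalize_residues(seq, rec.id)
        records.append(ProteinRecord(id=rec.id, residues=residues,
                                     species=_species_from_description(rec.description)))
    _check_unique_ids([r.id for r in records])
    return records


def _species_from_description(description: str) -> str:
    """Pull a bracketed [species name] out of an NCBI-style description."""
    if "[" in description and description.rstrip().endswith("]"):
        return description[description.rindex("[") + 1:].rstrip().rstrip("]")
    return ""


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")
    return path


@dataclass
class FamilyAlignment:
    """A rectangular gapped protein alignment (gap character ``-``).

    ``records`` preserves input order; degapping any row must yield a valid
    :class:`ProteinRecord` sequence and no row may be entirely gaps.
    """

    records: list[tuple[str, str]]
    n_cols: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment has no rows")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            offenders = sorted({rid for rid, seq in self.records
                                if len(seq) != len(self.records[0][1])})
            raise ValidationError(
                f"ragged alignment: rows differ in length (e.g. {offenders})"
            )
        self.n_cols = lengths.pop()
        if self.n_cols == 0:
            raise ValidationError("alignment has zero columns")
        _check_unique_ids([rid for rid, _ in self.records])
        for rid, seq in self.records:
            degapped = seq.replace(GAP, "")
            if not degapped:
                raise ValidationError(f"row {rid!r} is entirely gaps")
            # constructor validates the alphabet
            ProteinRecord(id=rid, residues=degapped)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise LookupError_(f"id {rid!r} not in alignment")

    def degapped(self, rid: str) -> ProteinRecord:
        return ProteinRecord(id=rid, residues=self.row(rid).replace(GAP, ""))


def read_alignment(path: str | Path) -> FamilyAlignment:
    """Read gapped FASTA into a validated rectangular alignment."""
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise ParseError(f"{path}: no FASTA records found")
    rows = []
    for rec in parsed:
        seq = str(rec.seq).upper()
        # normalise residues but keep gap positions in place
        cleaned = []
        for c in seq:
            if c == GAP:
                cleaned.append(c)
            elif c in STANDARD_AA or c == "X":
                cleaned.append(c)
            elif c in AMBIGUOUS_AA:
                logger.warning("row %r: ambiguity code %r mapped to X", rec.id, c)
                cleaned.append("X")
            elif c == "*":
                continue
            else:
                raise ValidationError(f"row {rec.id!r}: illegal character {c!r}")
        rows.append((rec.id, "".join(cleaned)))
    return FamilyAlignment(records=rows)


def write_alignment(aln: FamilyAlignment, path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Trees


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree.

    Accepts a path or a Newick string. Quoted labels and internal-node labels
    are accepted; branch lengths are parsed but ignored by the parsimony
    stage. Leaf labels must be unique.
    """
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
        data, kind = str(source), "path"
    else:
        data, kind = str(source), "string"
    try:
        tree = dendropy.Tree.get(
            **({"path": data} if kind == "path" else {"data": data}),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse exception types
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise ParseError(f"invalid Newick: {exc}") from exc
    tree.is_rooted = True
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValidationError("tree must have at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        dupes = sorted({l for l in leaves if leaves.count(l) > 1})
        raise ValidationError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return path


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# RSA profiles


@dataclass(frozen=True)
class RSAProfile:
    """Per-residue relative solvent accessibility for one protein.

    Values are fractions of surface exposure in [0, 1], one per residue,
    in N-to-C order.
    """

    id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValidationError(f"RSA profile {self.id!r}: no values")
        for i, v in enumerate(self.values):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"RSA profile {self.id!r}: value {v} at position {i + 1} "
                    f"outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.values)


def read_rsa_table(path: str | Path, record: ProteinRecord | None = None,
                   profile_id: str | None = None) -> RSAProfile:
    """Read a minimal NetSurfP-like tab-separated RSA table.

    Layout: comment lines start with ``#``; each data row carries at least
    three tab-separated columns ``residue<TAB>position<TAB>rsa``. Positions
    must run contiguously 1..L. When ``record`` is given, the residue column
    is cross-checked against it and the profile takes the record's id.
    """
    path = Path(path)
    rows: list[tuple[str, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns "
                    f"(residue, position, rsa)"
                )
            residue = parts[0].strip()
            try:
                position = int(parts[1])
                rsa = float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if not (0.0 <= rsa <= 1.0):
                raise ValidationError(
                    f"{path}:{lineno}: RSA {rsa} outside [0, 1]"
                )
            rows.append((residue, position, rsa))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    for i, (_, position, _) in enumerate(rows, start=1):
        if position != i:
            raise ValidationError(
                f"{path}: positions must be contiguous 1..L; "
                f"expected {i}, found {position}"
            )
    if record is not None:
        if len(rows) != record.length:
            raise ValidationError(
                f"{path}: {len(rows)} rows but record {record.id!r} has "
                f"{record.length} residues"
            )
        for i, (residue, _, _) in enumerate(rows):
            if residue.upper() != record.residues[i]:
                raise ValidationError(
                    f"{path}: residue mismatch at position {i + 1}: table has "
                    f"{residue!r}, record {record.id!r} has {record.residues[i]!r}"
                )
    pid = profile_id or (record.id if record is not None else path.stem)
    return RSAProfile(id=pid, values=tuple(r[2] for r in rows))


def write_rsa_table(profile: RSAProfile, path: str | Path,
                    residues: str | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# RSA profile {profile.id}\n")
        fh.write("# residue\tposition\trsa\n")
        for i, v in enumerate(profile.values):
            res = residues[i] if residues else "X"
            fh.write(f"{res}\t{i + 1}\t{v:.6g}\n")
    return path


# ---------------------------------------------------------------------------
# Report tables


def write_report_tables(tables: dict[str, "object"], out_dir: str | Path) -> list[Path]:
    """Write a dict of name -> pandas DataFrame as TSV files with headers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in tables.items():
        p = out_dir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths
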
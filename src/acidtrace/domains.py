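"""Domain projection through a family alignment, conservation symbols,
presence/absence calling and in-silico construct editing.

Reference domain coordinates (1-based inclusive, e.g. RD1 = 36-50 on mouse
Dbx1) are mapped to alignment columns by walking the reference row and
counting non-gap residues. Each taxon's slice at those columns is then
summarised by coverage (fraction of non-gap positions) and similarity to the
reference (identity or shared ClustalX strong group, over mutually ungapped
positions).

Column conservation uses the ClustalX nomenclature: ``*`` full identity,
``:`` all residues within one strong group, ``.`` within one weak group,
space otherwise. A gap anywhere in the column suppresses all three symbols.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import CoordinateError, InputError, LookupError_
from .seqio import GAP, FamilyAlignment, ProteinRecord

# ClustalX residue groups (Gonnet-PAM250-derived; strong > 0.5, weak > 0.2)
CLUSTALX_STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in
    ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)
CLUSTALX_WEAK_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in
    ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
     "NEQHRK", "FVLIM", "HFY")
)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named interval on a reference sequence (1-based inclusive)."""

    name: str
    ref_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"domain {self.name!r}: invalid interval {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TaxonSlice:
    """One taxon's extract over a projected domain's columns."""

    taxon: str
    residues: str          # gapped slice, one char per domain column
    n_nongap: int
    similarity_to_ref: float


@dataclass(frozen=True)
class ProjectedDomain:
    """A domain annotation mapped onto alignment columns (1-based)."""

    domain: DomainAnnotation
    columns: tuple[int, ...]
    per_taxon: dict[str, TaxonSlice]


@dataclass(frozen=True)
class DomainPresenceCall:
    taxon: str
    domain: str
    present: bool
    coverage: float
    similarity: float
    min_coverage: float
    min_similarity: float


def _strong_group_match(a: str, b: str) -> bool:
    if a == b:
        return True
    return any(a in g and b in g for g in CLUSTALX_STRONG_GROUPS)


def project_domain(aln: FamilyAlignment, domain: DomainAnnotation) -> ProjectedDomain:
    """Map a reference-sequence interval to alignment columns and extract
    every taxon's slice at those columns.

    The columns are exactly those where the reference row carries its
    ``start``-th through ``end``-th residues; gap columns of the reference
    inside that span are not part of the domain.
    """
    if domain.ref_id not in aln.ids:
        raise LookupError_(f"reference {domain.ref_id!r} not in alignment")
    ref_row = aln.row(domain.ref_id)
    columns: list[int] = []
    residue_idx = 0
    for col, c in enumerate(ref_row, start=1):
        if c != GAP:
            residue_idx += 1
            if domain.start <= residue_idx <= domain.end:
                columns.append(col)
    if residue_idx < domain.end:
        raise CoordinateError(
            f"domain {domain.name!r} ends at {domain.end} but reference "
            f"{domain.ref_id!r} has only {residue_idx} residues"
        )
    ref_slice = "".join(ref_row[c - 1] for c in columns)
    per_taxon: dict[str, TaxonSlice] = {}
    for taxon, row in aln.records:
        sl = "".join(row[c - 1] for c in columns)
        n_nongap = sum(1 for c in sl if c != GAP)
        if taxon == domain.ref_id:
            sim = 1.0
        else:
            mutual = [(x, y) for x, y in zip(sl, ref_slice)
                      if x != GAP and y != GAP]
            if mutual:
                sim = sum(_strong_group_match(x, y) for x, y in mutual) / len(mutual)
            else:
                sim = 0.0
        per_taxon[taxon] = TaxonSlice(taxon=taxon, residues=sl,
                                      n_nongap=n_nongap, similarity_to_ref=sim)
    return ProjectedDomain(domain=domain, columns=tuple(columns),
                           per_taxon=per_taxon)


def conservation_symbols(aln: FamilyAlignment) -> str:
    """ClustalX-style conservation line, one symbol per column."""
    if len(aln.records) < 2:
        raise InputError("conservation requires at least 2 rows")
    symbols = []
    for col in range(aln.n_cols):
        chars = [seq[col] for _, seq in aln.records]
        if GAP in chars:
            symbols.append(" ")
            continue
        residues = set(chars)
        if len(residues) == 1:
            symbols.append("*")
        elif any(residues <= g for g in CLUSTALX_STRONG_GROUPS):
            symbols.append(":")
        elif any(residues <= g for g in CLUSTALX_WEAK_GROUPS):
            symbols.append(".")
        else:
            symbols.append(" ")
    return "".join(symbols)


def call_domain_presence(proj: ProjectedDomain,
                         min_coverage: float = 0.6,
                         min_similarity: float = 0.4,
                         ) -> list[DomainPresenceCall]:
    """Presence/absence call per taxon from coverage and similarity.

    present iff coverage >= min_coverage and similarity >= min_similarity;
    the thresholds are recorded in each call. The reference taxon is always
    present with similarity 1.0.
    """
    length = proj.domain.length
    calls = []
    for taxon, sl in proj.per_taxon.items():
        coverage = sl.n_nongap / length
        present = (coverage >= min_coverage
                   and sl.similarity_to_ref >= min_similarity)
        calls.append(DomainPresenceCall(
            taxon=taxon, domain=proj.domain.name, present=present,
            coverage=coverage, similarity=sl.similarity_to_ref,
            min_coverage=min_coverage, min_similarity=min_similarity,
        ))
    return calls


def presence_table(calls: list[DomainPresenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"taxon": c.taxon, "domain": c.domain, "present": c.present,
          "coverage": c.coverage, "similarity": c.similarity,
          "min_coverage": c.min_coverage, "min_similarity": c.min_similarity}
         for c in calls],
        columns=["taxon", "domain", "present", "coverage", "similarity",
                 "min_coverage", "min_similarity"])


# ---------------------------------------------------------------------------
# Construct editor


def delete_interval(seq: ProteinRecord, start: int, end: int) -> ProteinRecord:
    """Remove residues start..end (1-based inclusive); id gains a suffix."""
    if not (1 <= start <= end <= seq.length):
        raise CoordinateError(
            f"delete {start}-{end} outside 1-{seq.length} of {seq.id!r}"
        )
    residues = seq.residues[:start - 1] + seq.residues[end:]
    return ProteinRecord(id=f"{seq.id}_del{start}-{end}", residues=residues,
                         species=seq.species)


def truncate_cterm(seq: ProteinRecord, n: int) -> ProteinRecord:
    """Remove the last ``n`` residues; n = 0 is the identity edit."""
    if n < 0 or n >= seq.length:
        raise CoordinateError(
            f"cannot truncate {n} residues from {seq.id!r} (length {seq.length})"
        )
    if n == 0:
        return seq
    return ProteinRecord(id=f"{seq.id}_dC{n}", residues=seq.residues[:-n],
                         species=seq.species)


def append_cterm(seq: ProteinRecord, donor: ProteinRecord, n: int) -> ProteinRecord:
    """Append the donor's last ``n`` residues to the C-terminus."""
    if not (1 <= n <= donor.length):
        raise CoordinateError(
            f"cannot take last {n} residues of {donor.id!r} (length {donor.length})"
        )
    return ProteinRecord(id=f"{seq.id}_plusC{n}of{donor.id}",
                         residues=seq.residues + donor.residues[-n:],
                         species=seq.species)
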
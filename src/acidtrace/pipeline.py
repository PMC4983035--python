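"""End-to-end analysis driver: one config in, one report directory out.

The pipeline chains the stages — sequence/alignment/tree loading, windowed
acidity scanning, domain projection and presence calling, gain/loss
scenario comparison, RSA summaries, pairwise identity — skipping (and
logging) any stage whose inputs are absent from the config. Stages are pure
functions over files: rerunning an identical config on identical inputs
produces byte-identical report tables. A provenance block records
parameters, package version and input checksums so a report fully
determines its own re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .acidic import AcidicScanParams, classify_family
from .domains import (DomainAnnotation, call_domain_presence,
                      conservation_symbols, presence_table, project_domain)
from .errors import InputError, ValidationError
from .pairwise import AlignParams, global_align
from .parsimony import (BinaryCharacterMatrix, compare_scenarios,
                        scenario_table)
from .rsa import compare_all_domains, domain_rsa_summary, summary_table
from .seqio import (read_alignment, read_fasta, read_newick, read_rsa_table,
                    write_report_tables)

logger = logging.getLogger(__name__)


def parse_domain_spec(spec: str, ref_id: str) -> DomainAnnotation:
    """Parse ``NAME:START-END`` (1-based inclusive) into an annotation."""
    try:
        name, interval = spec.split(":")
        start_s, end_s = interval.split("-")
        return DomainAnnotation(name=name, ref_id=ref_id,
                                start=int(start_s), end=int(end_s))
    except ValueError as exc:
        raise InputError(f"bad domain spec {spec!r}; expected NAME:START-END") from exc


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    alignment: str | None = None
    tree: str | None = None
    fasta: str | None = None
    rsa_tables: dict[str, str] = field(default_factory=dict)
    reference: str | None = None
    domains: list[str] = field(default_factory=list)  # NAME:START-END specs
    scan: dict = field(default_factory=dict)
    presence: dict = field(default_factory=dict)
    identity: dict = field(default_factory=dict)
    identity_pairs: list[list[str]] = field(default_factory=list)
    alpha: float = 0.01
    out_dir: str = "acidtrace_report"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def scan_params(self) -> AcidicScanParams:
        kwargs = dict(self.scan)
        if "residues" in kwargs:
            kwargs["acidic_set"] = frozenset(kwargs.pop("residues"))
        if "tail" in kwargs:
            kwargs["tail_len"] = kwargs.pop("tail")
        return AcidicScanParams(**kwargs)

    def align_params(self) -> AlignParams:
        kwargs = dict(self.identity)
        kwargs.pop("denominator", None)
        if "matrix" in kwargs:
            kwargs["matrix_name"] = kwargs.pop("matrix")
        return AlignParams(**kwargs)


@dataclass
class AnalysisReport:
    """All tables produced by one run, plus provenance."""

    cter_calls: pd.DataFrame | None = None
    presence: pd.DataFrame | None = None
    presence_matrix: pd.DataFrame | None = None
    conservation: str | None = None
    scenarios: pd.DataFrame | None = None
    rsa_summaries: pd.DataFrame | None = None
    rsa_comparisons: pd.DataFrame | None = None
    identities: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tables = {}
        for name in ("cter_calls", "presence", "scenarios", "rsa_summaries",
                     "rsa_comparisons", "identities"):
            frame = getattr(self, name)
            if frame is not None:
                tables[name] = frame
        if self.presence_matrix is not None:
            tables["presence_matrix"] = self.presence_matrix.reset_index()
        paths = {p.stem: p for p in write_report_tables(tables, out_dir)}
        if self.conservation is not None:
            cons_path = out_dir / "conservation.txt"
            cons_path.write_text(self.conservation + "\n")
            paths["conservation"] = cons_path
        rollup = {
            "provenance": self.provenance,
            "skipped": self.skipped,
            "tables": {name: str(path.name) for name, path in paths.items()},
        }
        json_path = out_dir / "report.json"
        json_path.write_text(json.dumps(rollup, indent=2, sort_keys=True) + "\n")
        paths["report"] = json_path
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage whose inputs the config provides."""
    report = AnalysisReport()
    provenance: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "domains": list(config.domains),
            "scan": dict(config.scan),
            "presence": dict(config.presence),
            "identity": dict(config.identity),
            "alpha": config.alpha,
            "reference": config.reference,
        },
        "inputs": {},
    }
    for label, path in (("alignment", config.alignment), ("tree", config.tree),
                        ("fasta", config.fasta)):
        if path:
            provenance["inputs"][label] = {"path": str(path),
                                           "sha256": _sha256(path)}
    for rid, path in sorted(config.rsa_tables.items()):
        provenance["inputs"][f"rsa:{rid}"] = {"path": str(path),
                                              "sha256": _sha256(path)}
    report.provenance = provenance
    scan_params = config.scan_params()

    aln = read_alignment(config.alignment) if config.alignment else None
    tree = read_newick(config.tree) if config.tree else None

    # --- Cter scan over the family (degapped alignment rows) --------------
    if aln is not None:
        family = [aln.degapped(rid) for rid in aln.ids]
        report.cter_calls = classify_family(family, scan_params)
    else:
        report.skipped.append("cter_scan: no alignment input")
        logger.info("skipping Cter scan: no alignment")

    # --- domain projection and presence ------------------------------------
    domain_annotations: list[DomainAnnotation] = []
    if aln is not None and config.reference and config.domains:
        domain_annotations = [parse_domain_spec(s, config.reference)
                              for s in config.domains]
        calls = []
        for dom in domain_annotations:
            proj = project_domain(aln, dom)
            calls.extend(call_domain_presence(proj, **config.presence))
        report.presence = presence_table(calls)
        report.conservation = conservation_symbols(aln)
    else:
        report.skipped.append("domain_architecture: needs alignment, "
                              "reference and domain list")
        logger.info("skipping domain projection")

    # --- presence matrix: projected domains + scanner-driven Cter ----------
    if report.presence is not None or report.cter_calls is not None:
        columns = {}
        if report.presence is not None:
            wide = report.presence.pivot(index="taxon", columns="domain",
                                         values="present").astype(int)
            for name in wide.columns:
                columns[name] = wide[name]
        if report.cter_calls is not None:
            cter = report.cter_calls.set_index("seq_id")["positive"].astype(int)
            cter.index.name = "taxon"
            columns["Cter"] = cter  # scanner call defines the Cter character
        matrix = pd.DataFrame(columns).dropna().astype(int)
        matrix.index.name = "taxon"
        report.presence_matrix = matrix.sort_index()

    # --- gain/loss scenarios ------------------------------------------------
    if tree is not None and report.presence_matrix is not None:
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        matrix_taxa = set(report.presence_matrix.index)
        if leaves != matrix_taxa:
            raise ValidationError(
                f"tree leaves and presence taxa differ: "
                f"only-in-tree={sorted(leaves - matrix_taxa)}, "
                f"only-in-matrix={sorted(matrix_taxa - leaves)}"
            )
        matrix = BinaryCharacterMatrix.from_dataframe(report.presence_matrix)
        report.scenarios = scenario_table(compare_scenarios(tree, matrix))
    else:
        report.skipped.append("character_parsimony: needs tree and presence")
        logger.info("skipping scenario comparison")

    # --- RSA ----------------------------------------------------------------
    if config.rsa_tables and domain_annotations:
        summaries = []
        comparisons = []
        for rid, path in sorted(config.rsa_tables.items()):
            profile = read_rsa_table(path, profile_id=rid)
            doms = [d for d in domain_annotations if d.end <= len(profile)]
            table = summary_table(domain_rsa_summary(profile, doms))
            table.insert(0, "profile", rid)
            summaries.append(table)
            cmp_table = compare_all_domains(profile, doms, alpha=config.alpha)
            cmp_table.insert(0, "profile", rid)
            comparisons.append(cmp_table)
        report.rsa_summaries = pd.concat(summaries, ignore_index=True)
        report.rsa_comparisons = pd.concat(comparisons, ignore_index=True)
    else:
        report.skipped.append("rsa_summary: no RSA tables")
        logger.info("skipping RSA summaries")

    # --- pairwise identity --------------------------------------------------
    if config.fasta:
        records = {r.id: r for r in read_fasta(config.fasta)}
        pairs = [tuple(p) for p in config.identity_pairs]
        if not pairs:
            ids = list(records)
            pairs = [(ids[i], ids[j]) for i in range(len(ids))
                     for j in range(i + 1, len(ids))]
        params = config.align_params()
        denominator = config.identity.get("denominator", "ungapped")
        rows = []
        for ida, idb in pairs:
            res = global_align(records[ida], records[idb], params,
                               denominator=denominator)
            rows.append({"id_a": ida, "id_b": idb, "score": res.score,
                         "n_identical": res.n_identical,
                         "n_scored_cols": res.n_scored_cols,
                         "identity_pct": res.identity_pct,
                         "denominator": res.denominator})
        report.identities = pd.DataFrame(
            rows, columns=["id_a", "id_b", "score", "n_identical",
                           "n_scored_cols", "identity_pct", "denominator"])
    else:
        report.skipped.append("pairwise_identity: no FASTA input")
        logger.info("skipping pairwise identity")

    report.write(config.out_dir)
    return report
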
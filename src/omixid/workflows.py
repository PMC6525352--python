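"""Workflow orchestration: config validation, bundle wiring, run reports.

Binds the identifier, table and miRNA layers into five named workflows —
``add-ids``, ``integrate``, ``mirna-targets``, ``mirna-reverse``,
``mirna-convert`` — each consuming tab-separated user tables and a reference
bundle directory, and writing an output table *atomically* (temp file +
rename, so an interrupted run never leaves a partial file) together with a
small run report (``<output>.report.tsv``: rows in/out, resolved/unresolved
counts, a support histogram for miRNA queries, and the bundle release label
so results are traceable to a reference snapshot — counts from one snapshot
are artifacts of that snapshot).

Exit convention: 0 success, 2 configuration/validation error, 1 runtime
error.  Two end-to-end drivers reproduce the canonical pipelines: a
cross-species expression integration, and a miRNA pipeline (normalize →
consensus target query → merge with expression).
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import idmap, mirna, refdata, tables
from .idmap import ColumnSpec, MatchPolicy
from .tables import DataTable

log = logging.getLogger(__name__)

__all__ = [
    "WorkflowConfig",
    "WorkflowValidationError",
    "RunResult",
    "BundleStores",
    "load_bundle_stores",
    "run_workflow",
    "run_cross_species_integration",
    "run_mirna_pipeline",
]

WORKFLOW_NAMES = ("add-ids", "integrate", "mirna-targets", "mirna-reverse", "mirna-convert")

_ALLOWED_PARAMS = {
    "add-ids": {"input", "id_cols", "out_types", "in_tax", "out_tax", "policy"},
    "integrate": {"a", "b", "keys_a", "keys_b", "mode", "out_tax", "intersection_only"},
    "mirna-targets": {"input", "column", "species", "dbs", "min_support",
                      "append_gene_ids", "merge_expression", "expression_keys",
                      "intersection_only"},
    "mirna-reverse": {"input", "keys", "dbs", "min_support", "policy"},
    "mirna-convert": {"input", "column", "species"},
}


class WorkflowValidationError(ValueError):
    """Configuration rejected before any file is read (exit code 2)."""


@dataclass
class WorkflowConfig:
    """One workflow invocation: name, bundle, parameter block, output path.

    Validated eagerly on construction; unknown parameter keys are fatal so a
    typo never silently changes a run.
    """

    workflow: str
    bundle: Path
    output: Path
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOW_NAMES:
            raise WorkflowValidationError(
                f"unknown workflow {self.workflow!r}; expected one of {WORKFLOW_NAMES}")
        allowed = _ALLOWED_PARAMS[self.workflow]
        unknown = set(self.params) - allowed
        if unknown:
            raise WorkflowValidationError(
                f"{self.workflow}: unknown parameter keys {sorted(unknown)}; "
                f"allowed: {sorted(allowed)}")
        self.bundle = Path(self.bundle)
        self.output = Path(self.output)


@dataclass
class RunResult:
    exit_code: int
    output_path: Optional[Path] = None
    report_path: Optional[Path] = None
    report: dict = field(default_factory=dict)
    error: str = ""


@dataclass
class BundleStores:
    """All in-memory stores loaded from one reference bundle."""

    xref: refdata.XrefStore
    names: Optional[mirna.MirnaNameStore] = None
    targets: Optional[mirna.TargetStore] = None
    release: str = "unknown"


def load_bundle_stores(bundle_dir: str | Path, *, need_mirna: bool = True) -> BundleStores:
    """Load gene xrefs (backfilled) and, when present, the miRNA stores."""
    d = Path(bundle_dir)
    xref = refdata.load_bundle(d)
    release = "unknown"
    if xref.manifest:
        release = str(xref.manifest.get("release", "unknown"))
    names = targets = None
    mature = d / "mirna_mature.tsv"
    aliases = d / "mirna_aliases.tsv"
    if need_mirna and mature.exists():
        names = mirna.load_mirbase(aliases, mature)
        db_paths = {db: d / f"targets_{db}.tsv" for db in mirna.TARGET_DBS
                    if (d / f"targets_{db}.tsv").exists()}
        if db_paths:
            targets = mirna.load_target_dbs(db_paths, names, xref_store=xref)
    return BundleStores(xref=xref, names=names, targets=targets, release=release)


def _atomic_write(table: DataTable, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        tables.write_table(table, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_report(report: dict, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("metric\tvalue\n")
        for k, v in report.items():
            fh.write(f"{k}\t{v}\n")


def _parse_specs(raw: list) -> list[ColumnSpec]:
    out = []
    for item in raw:
        if isinstance(item, ColumnSpec):
            out.append(item)
        elif isinstance(item, str):
            if ":" in item:
                label, id_type = item.rsplit(":", 1)
                out.append(ColumnSpec(label, id_type))
            else:
                out.append(ColumnSpec(item))
        else:
            label, id_type = item
            out.append(ColumnSpec(label, id_type))
    return out


def run_workflow(config: WorkflowConfig) -> RunResult:
    """Execute one configured workflow; never raises for expected failures.

    Returns exit code 0 with output and report paths on success, 2 for
    validation problems, 1 for runtime errors; the output file is written
    atomically so failures leave nothing at the target path.
    """
    report: dict = {"workflow": config.workflow, "bundle": str(config.bundle)}
    try:
        out_table, extra = _dispatch(config)
    except (WorkflowValidationError, tables.TableError, refdata.RefDataError) as exc:
        log.error("%s: validation error: %s", config.workflow, exc)
        return RunResult(exit_code=2, error=f"{config.workflow}: {exc}")
    except Exception as exc:  # runtime error
        log.error("%s: runtime error: %s", config.workflow, exc)
        return RunResult(exit_code=1, error=f"{config.workflow}: {exc}")
    report.update(extra)
    _atomic_write(out_table, config.output)
    report_path = config.output.with_name(config.output.name + ".report.tsv")
    _write_report(report, report_path)
    return RunResult(exit_code=0, output_path=config.output,
                     report_path=report_path, report=report)


def _dispatch(config: WorkflowConfig) -> tuple[DataTable, dict]:
    p = config.params
    name = config.workflow
    need_mirna = name.startswith("mirna")
    stores = load_bundle_stores(config.bundle, need_mirna=need_mirna)
    extra: dict = {"bundle_release": stores.release}

    if name == "add-ids":
        table = tables.read_table(p["input"])
        specs = _parse_specs(p["id_cols"])
        policy = MatchPolicy(p.get("policy", MatchPolicy.FIRST))
        out = idmap.add_identifiers(
            stores.xref, table, specs, p["out_types"],
            in_tax=p.get("in_tax"), out_tax=p.get("out_tax"), policy=policy)
        first_type = p["out_types"][0]
        appended = out.column(out.header[len(table.header)])
        resolved = sum(1 for v in appended if v)
        extra.update(rows_in=table.n_rows, rows_out=out.n_rows,
                     resolved_rows=resolved, unresolved_rows=out.n_rows - resolved,
                     first_output_type=first_type)
        return out, extra

    if name == "integrate":
        ta, tb = tables.read_table(p["a"]), tables.read_table(p["b"])
        out = idmap.integrate_tables(
            stores.xref, ta, tb, _parse_specs(p["keys_a"]), _parse_specs(p["keys_b"]),
            mode=p.get("mode", "conversion"), out_tax=p.get("out_tax"),
            intersection_only=bool(p.get("intersection_only", False)))
        extra.update(rows_in_a=ta.n_rows, rows_in_b=tb.n_rows, rows_out=out.n_rows)
        return out, extra

    if name == "mirna-convert":
        table = tables.read_table(p["input"])
        out = mirna.convert_mirna_column(stores.names, table, p["column"],
                                         species_restrict=p.get("species"))
        statuses = out.column("mirna_status")
        extra.update(rows_in=table.n_rows, rows_out=out.n_rows,
                     resolved_rows=sum(s in ("exact", "alias") for s in statuses),
                     unresolved_rows=sum(s == "unresolved" for s in statuses),
                     ambiguous_rows=sum(s == "ambiguous" for s in statuses))
        return out, extra

    if name == "mirna-targets":
        table = tables.read_table(p["input"])
        names_in = table.column(p["column"])
        dbs = tuple(p.get("dbs", mirna.TARGET_DBS))
        k = int(p.get("min_support", 1))
        out = mirna.query_targets(
            stores.targets, stores.names, names_in, selected_dbs=dbs,
            min_support=k, species=p.get("species"),
            append_gene_ids=bool(p.get("append_gene_ids", True)),
            xref_store=stores.xref)
        support = [int(s) for s in out.column("support") if s]
        hist = {f"support_{i}": support.count(i)
                for i in range(1, len(dbs) + 1)}
        extra.update(rows_in=table.n_rows, rows_out=out.n_rows,
                     unresolved_rows=sum(s in ("unresolved", "ambiguous")
                                         for s in out.column("status")),
                     min_support=k, **hist)
        if p.get("merge_expression"):
            expr = tables.read_table(p["merge_expression"])
            out = mirna.merge_with_expression(
                out, expr,
                _parse_specs(["gene_ensembl:ensembl_gene", "gene_entrez:entrez",
                              "gene_symbol:symbol"]),
                _parse_specs(p["expression_keys"]), stores.xref,
                intersection_only=bool(p.get("intersection_only", False)))
            extra.update(rows_out_after_merge=out.n_rows)
        return out, extra

    if name == "mirna-reverse":
        table = tables.read_table(p["input"])
        dbs = tuple(p.get("dbs", mirna.TARGET_DBS))
        k = int(p.get("min_support", 1))
        out = mirna.reverse_lookup(
            stores.targets, stores.names, table, _parse_specs(p["keys"]),
            selected_dbs=dbs, min_support=k, xref_store=stores.xref,
            policy=MatchPolicy(p.get("policy", MatchPolicy.EXPAND_ROWS)))
        hit = sum(1 for v in out.column("mirna_accession") if v)
        extra.update(rows_in=table.n_rows, rows_out=out.n_rows,
                     rows_with_hits=hit, min_support=k)
        return out, extra

    raise WorkflowValidationError(f"unhandled workflow {name!r}")


# ---------------------------------------------------------------------------
# end-to-end drivers


def run_cross_species_integration(
    bundle_dir: str | Path,
    table_a_path: str | Path,
    table_b_path: str | Path,
    key_a: tuple[str, str] = ("GeneID", "ensembl_gene"),
    key_b: tuple[str, str] = ("GeneID", "ensembl_gene"),
    intersection_only: bool = True,
) -> DataTable:
    """Two-species expression integration via the Ensembl ortholog pivot.

    Reads both differential-expression tables, merges them in conversion
    mode (identifier retrievals and ortholog bridging happen in the
    background), and returns the merged table — by default the intersection,
    the genes regulated in common across the two species.
    """
    stores = load_bundle_stores(bundle_dir, need_mirna=False)
    ta = tables.read_table(table_a_path)
    tb = tables.read_table(table_b_path)
    return idmap.integrate_tables(
        stores.xref, ta, tb,
        [ColumnSpec(*key_a)], [ColumnSpec(*key_b)],
        mode="conversion", intersection_only=intersection_only)


def run_mirna_pipeline(
    bundle_dir: str | Path,
    mirna_table_path: str | Path,
    expression_table_path: Optional[str | Path] = None,
    mirna_column: str = "miRNA",
    min_support: int = 2,
    expression_key: tuple[str, str] = ("GeneID", "ensembl_gene"),
    species: Optional[list[int]] = None,
) -> dict[str, DataTable]:
    """miRNA pipeline: normalize names → consensus target query → merge.

    Step 1 normalizes the user's miRNA names to current miRBase-style names;
    step 2 queries all four target databases and keeps (miRNA, gene) pairs
    supported by at least ``min_support`` of them; step 3 (optional) merges
    the predicted targets with an experimental expression table on gene
    identifiers, keeping the intersection.  Returns the intermediate and
    final tables keyed ``converted``, ``targets``, ``merged``.
    """
    stores = load_bundle_stores(bundle_dir)
    table = tables.read_table(mirna_table_path)
    converted = mirna.convert_mirna_column(stores.names, table, mirna_column,
                                           species_restrict=species)
    targets = mirna.query_targets(
        stores.targets, stores.names, table.column(mirna_column),
        min_support=min_support, species=species,
        append_gene_ids=True, xref_store=stores.xref)
    out = {"converted": converted, "targets": targets}
    if expression_table_path is not None:
        expr = tables.read_table(expression_table_path)
        out["merged"] = mirna.merge_with_expression(
            targets, expr,
            [ColumnSpec("gene_ensembl", "ensembl_gene"),
             ColumnSpec("gene_entrez", "entrez"),
             ColumnSpec("gene_symbol", "symbol")],
            [ColumnSpec(*expression_key)], stores.xref, intersection_only=True)
    return out
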
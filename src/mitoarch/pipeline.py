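"""Orchestration: full comparative architecture report over input genomes.

``run_compare`` composes the library modules into one deterministic report:
per-taxon architecture summaries (length, GC, gene counts, NCR size bins,
largest NCR, overlaps), the cluster-orientation table against the
lophotrochozoan ground pattern, the motif position table, the shared-NCR
matrix and pairwise adjacency differences, plus cox1-anchored linearized
arrangement strings.  The report regenerates byte-identically from the same
inputs (no randomness anywhere in the comparison path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import EmptyRecordError, NotFoundError, UndefinedGCError
from .gene_order import (
    REFERENCE_CLUSTERS,
    arrangement_table,
    canonicalize,
    classify_clusters,
    diff_orders,
    extract_gene_order,
)
from .motifs import DEFAULT_MOTIFS, motif_position_table, motif_table_tsv
from .nomenclature import PCG, RRNA, TRNA
from .noncoding import (
    bin_ncrs,
    extract_ncrs,
    gc_content,
    ncr_table,
    overlap_table,
    shared_ncr_boundaries,
)
from .records import MitogenomeRecord


@dataclass
class ComparisonReport:
    summaries: list[dict]
    cluster_table: list[dict]
    motif_rows: list
    shared_ncrs: dict | None
    adjacency_diffs: list[dict]
    arrangements: dict[str, str]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "summaries": self.summaries,
            "cluster_table": self.cluster_table,
            "motifs": [
                {"motif": h.motif_id, "taxon": h.taxon,
                 "ncr": f"{h.ncr[0]}/{h.ncr[1]}",
                 "start_in_ncr": h.start_in_ncr, "matched": h.matched}
                for h in self.motif_rows
            ],
            "shared_ncrs": _jsonable_shared(self.shared_ncrs),
            "adjacency_diffs": self.adjacency_diffs,
            "arrangements": self.arrangements,
            "warnings": self.warnings,
        }


def _jsonable_shared(shared: dict | None) -> dict | None:
    if shared is None:
        return None
    return {
        "all_taxa": shared["all_taxa"],
        "pairwise": {f"{a}|{b}": v for (a, b), v in shared["pairwise"].items()},
        "per_ncr": {f"{f5}/{f3}": taxa
                    for (f5, f3), taxa in sorted(shared["per_ncr"].items())},
    }


def summarize_record(record: MitogenomeRecord) -> dict:
    counts = {
        "PCG": len(record.genes({PCG})),
        "rRNA": len(record.genes({RRNA})),
        "tRNA": len(record.genes({TRNA})),
    }
    summary = {
        "taxon": record.taxon,
        "accession": record.accession,
        "length_bp": record.length,
        "circular": record.circular,
        "gene_counts": counts,
        "gene_total": sum(counts.values()),
    }
    if record.sequence is not None:
        try:
            summary["gc_percent"] = round(100 * gc_content(record.sequence), 1)
        except UndefinedGCError:
            summary["gc_percent"] = None
    try:
        ncrs, overlaps = extract_ncrs(record)
    except NotFoundError:
        return summary
    bins = bin_ncrs(ncrs)
    summary["ncr_count"] = bins.total
    summary["ncr_bins"] = {"lt10": bins.n_small, "10_100": bins.n_mid,
                           "gt100": bins.n_large}
    if ncrs:
        big = max(ncrs, key=lambda r: (r.length, -r.start))
        summary["largest_ncr"] = {"flank5": big.flank5, "flank3": big.flank3,
                                  "length": big.length}
    summary["overlaps"] = [
        {"gene_a": o.gene_a, "gene_b": o.gene_b, "bp": o.overlap_length}
        for o in overlaps
    ]
    return summary


def run_compare(records: list[MitogenomeRecord],
                motifs=DEFAULT_MOTIFS,
                anchor: str = "cox1",
                mode: str = "strict",
                include_kinds: set[str] | None = None,
                out_dir: str | Path | None = None) -> ComparisonReport:
    """Run the full comparison; optionally write all tables to ``out_dir``."""
    if not records:
        raise EmptyRecordError("no input genomes")
    warnings: list[str] = []

    summaries = [summarize_record(r) for r in records]

    cluster_table = []
    for rec in records:
        order = extract_gene_order(rec, {PCG, RRNA})
        calls = classify_clusters(order)
        row = {"taxon": rec.taxon}
        for p in REFERENCE_CLUSTERS:
            c = calls[p.id]
            row[p.id] = c.call
            row[f"{p.id}_arrow"] = c.arrow
            row[f"{p.id}_missing"] = list(c.genes_missing)
        cluster_table.append(row)

    sequenced = [r for r in records if r.sequence is not None]
    if sequenced and len(sequenced) < len(records):
        warnings.append(
            "motif/GC sections restricted to sequenced taxa: "
            + ", ".join(r.taxon for r in sequenced))
    motif_rows = motif_position_table(sequenced, motifs) if sequenced else []

    shared = (shared_ncr_boundaries(records, mode=mode)
              if len(records) >= 2 else None)

    diffs = []
    orders = {r.taxon: canonicalize(extract_gene_order(r, include_kinds),
                                    anchor)
              for r in records}
    names = [r.taxon for r in records]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = diff_orders(orders[names[i]], orders[names[j]])
            diffs.append({"taxon_a": names[i], "taxon_b": names[j],
                          "breakpoints": d.breakpoints,
                          "differing_genes": list(d.differing_genes)})

    arrangements = {t: o.arrangement_string() for t, o in orders.items()}

    report = ComparisonReport(summaries, cluster_table, motif_rows, shared,
                              diffs, arrangements, warnings)
    if out_dir is not None:
        _write_report(report, records, Path(out_dir))
    return report


def _write_report(report: ComparisonReport,
                  records: list[MitogenomeRecord], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    (out / "motifs.tsv").write_text(motif_table_tsv(report.motif_rows))

    lines = ["taxon\tcluster1\tcluster2\tcluster1_missing\tcluster2_missing"]
    for row in report.cluster_table:
        lines.append(
            f"{row['taxon']}\t{row['cluster1_arrow']}\t{row['cluster2_arrow']}"
            f"\t{','.join(row['cluster1_missing']) or '-'}"
            f"\t{','.join(row['cluster2_missing']) or '-'}")
    (out / "clusters.tsv").write_text("\n".join(lines) + "\n")

    for rec in records:
        slug = rec.taxon.replace(" ", "_").replace("/", "_")
        try:
            (out / f"ncrs_{slug}.tsv").write_text(ncr_table(rec))
            (out / f"overlaps_{slug}.tsv").write_text(overlap_table(rec))
        except NotFoundError:
            pass
        order = extract_gene_order(rec)
        (out / f"arrangement_{slug}.tsv").write_text(
            arrangement_table(canonicalize(order)))

    txt = [f"{t}: {s}" for t, s in sorted(report.arrangements.items())]
    (out / "arrangements.txt").write_text("\n".join(txt) + "\n")
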
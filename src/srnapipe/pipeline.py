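"""End-to-end orchestration: preprocess -> annotate -> hairpin -> expression
-> targets -> enrichment, with a run manifest and report tables.

Every stage is also usable standalone; this module wires them together on
either simulated data (in memory or on disk) or user-supplied inputs, and
applies presentation rounding only when rendering report tables — all
intermediate files carry full precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotate, enrichment, expression, hairpin, preprocess, targets
from .simulate import SimulatedData, SimulationConfig, simulate_all

log = logging.getLogger("srnapipe")

FLANK = 80


@dataclass
class RunManifest:
    seed: int
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    failed_stage: str = ""
    pvalue_mode: str = "raw"
    notes: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


@dataclass
class RunResult:
    clean_sets: list[preprocess.CleanReadSet]
    unique_reads: list[preprocess.UniqueRead]
    records: list[annotate.AnnotationRecord]
    novel: list[hairpin.NovelRecord]
    mirna_rows: list[expression.ExpressionRow]
    gene_rows: list[expression.ExpressionRow]
    target_map: dict[str, list[str]]
    enrichment_rows: list[enrichment.EnrichmentRow]
    target_enrichment_rows: list[enrichment.EnrichmentRow]
    manifest: RunManifest


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def novel_candidates(records: Sequence[annotate.AnnotationRecord],
                     unique_reads: Sequence[preprocess.UniqueRead],
                     genome: Mapping[str, str], flank: int = FLANK,
                     ) -> list[tuple[tuple[str, int, int, str],
                                     list[hairpin.HairpinCandidate]]]:
    """Flank windows for every novel-candidate locus, ordered by read
    support (descending total count, then sequence) so that novel names are
    assigned to the best-supported loci first."""
    totals = {u.sequence: u.total() for u in unique_reads}
    cand_records = [r for r in records if r.tier == "novel_candidate"]
    cand_records.sort(key=lambda r: (-totals.get(r.sequence, 0), r.sequence))
    out = []
    for rec in cand_records:
        for locus in rec.loci:
            windows = annotate.extract_flanks(locus, genome, flank)
            cands = [hairpin.HairpinCandidate.from_sequence(
                         w.sequence, w.mature_offset, w.mature_length)
                     for w in windows if len(w.sequence) >= 20]
            if cands:
                out.append((locus, cands))
    return out


def dedupe_novel(novel: Sequence[hairpin.NovelRecord], flank: int = FLANK,
                 ) -> list[hairpin.NovelRecord]:
    """Collapse novel calls whose precursor windows overlap on the genome.

    Reads from the two arms of one hairpin (mature and star) map within one
    window of each other; only the first (best-supported, already ordered)
    call per overlapping cluster is kept.
    """
    kept: list[hairpin.NovelRecord] = []
    spans: list[tuple[str, int, int]] = []
    for rec in novel:
        contig, start, end, _strand = rec.locus
        lo, hi = start - flank, end + flank
        if any(c == contig and lo < s_hi and s_lo < hi
               for c, s_lo, s_hi in spans):
            continue
        kept.append(rec)
        spans.append((contig, lo, hi))
    return kept


def run_from_data(data: SimulatedData, *, pvalue_mode: str = "raw",
                  thresholds: hairpin.Thresholds | None = None,
                  ) -> RunResult:
    """Execute the full pipeline on an in-memory simulated dataset."""
    cfg = data.config
    manifest = RunManifest(seed=cfg.seed, config=dataclasses.asdict(cfg),
                           pvalue_mode=pvalue_mode)

    # --- preprocess ---------------------------------------------------
    clean_sets = [
        preprocess.clean_records(data.library_control, "control",
                                 cfg.adapter3),
        preprocess.clean_records(data.library_treated, "treated",
                                 cfg.adapter3),
    ]
    unique_reads = preprocess.collapse_unique(clean_sets)
    manifest.row_counts["clean_control"] = clean_sets[0].total_clean
    manifest.row_counts["clean_treated"] = clean_sets[1].total_clean
    manifest.row_counts["unique_reads"] = len(unique_reads)
    manifest.stages_completed.append("preprocess")

    # --- annotate ------------------------------------------------------
    refs = data.references
    records = annotate.annotate_cascade(
        unique_reads, refs.known_mature, refs.other_mature, refs.ncrna,
        data.genome, mature_to_precursors=refs.mature_to_precursors)
    manifest.row_counts["annotated"] = len(records)
    manifest.stages_completed.append("annotate")

    # --- hairpin / novel prediction -------------------------------------
    cands = novel_candidates(records, unique_reads, data.genome)
    novel = dedupe_novel(hairpin.call_novel(cands, thresholds))
    manifest.row_counts["novel_mirnas"] = len(novel)
    manifest.stages_completed.append("hairpin")

    # --- miRNA expression -----------------------------------------------
    names: dict[str, str] = {}
    for rec in records:
        if rec.tier in ("known", "homolog"):
            names[rec.sequence] = rec.matched_name
    for nov in novel:
        names.setdefault(nov.mature_sequence, nov.name)
    counts = preprocess.counts_by_name(unique_reads, names)
    totals = (clean_sets[0].total_clean, clean_sets[1].total_clean)
    mirna_rows = expression.call_dem(expression.build_rows(
        counts[["control", "treated"]] if set(counts.columns) >= {"control", "treated"}
        else counts, totals, kind="miRNA", pvalue_mode=pvalue_mode))
    manifest.row_counts["mirna_rows"] = len(mirna_rows)
    manifest.stages_completed.append("expression_mirna")

    # --- gene expression -------------------------------------------------
    lengths = pd.Series(data.ground_truth.gene_lengths)
    gene_totals = (int(data.gene_counts["count_control"].sum()),
                   int(data.gene_counts["count_treated"].sum()))
    gene_rows = expression.call_deg(expression.build_rows(
        data.gene_counts, gene_totals, kind="gene", gene_lengths=lengths,
        pvalue_mode=pvalue_mode))
    manifest.row_counts["gene_rows"] = len(gene_rows)
    manifest.stages_completed.append("expression_gene")

    # --- reciprocal target prediction ------------------------------------
    dem_calls = {r.entity_id: r.call for r in mirna_rows
                 if r.entity_id in refs.known_mature and r.call in ("up", "down")}
    deg_calls = {r.entity_id: r.call for r in gene_rows
                 if r.call in ("up", "down")}
    target_map = targets.reciprocal_predict(dem_calls, deg_calls,
                                            refs.known_mature, data.utrs)
    manifest.row_counts["target_pairs"] = sum(len(v)
                                              for v in target_map.values())
    manifest.stages_completed.append("targets")

    # --- enrichment -------------------------------------------------------
    deg_set = sorted(deg_calls)
    background = len(data.gene_counts)         # all genes in the experiment
    enr = enrichment.enrich(deg_set, data.term_table, background)
    tenr = enrichment.enrich_targets(target_map, data.term_table, background)
    manifest.row_counts["enriched_terms"] = len(enr)
    manifest.stages_completed.append("enrichment")

    return RunResult(clean_sets=clean_sets, unique_reads=unique_reads,
                     records=records, novel=novel, mirna_rows=mirna_rows,
                     gene_rows=gene_rows, target_map=target_map,
                     enrichment_rows=enr, target_enrichment_rows=tenr,
                     manifest=manifest)


def run_all(config: SimulationConfig | str | Path, outdir: str | Path,
            *, pvalue_mode: str = "raw") -> RunResult:
    """Simulate (writing all inputs), run every stage and write all outputs.

    ``config`` is a :class:`SimulationConfig` or a path to its YAML form.
    """
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_yaml(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = out / "inputs"
    data = simulate_all(config, sim_dir)
    result = run_from_data(data, pvalue_mode=pvalue_mode)
    manifest = result.manifest
    for f in sorted(sim_dir.iterdir()):
        manifest.input_digests[f.name] = _digest(f)

    preprocess.write_collapsed(result.unique_reads, out / "collapsed.fa",
                               out / "collapsed_counts.tsv")
    preprocess.length_histogram(result.unique_reads).to_csv(
        out / "length_histogram.tsv", sep="\t")
    annotation_table(result.records).to_csv(out / "annotation.tsv",
                                            sep="\t", index=False)
    annotate.tier_tally(result.records, result.unique_reads).to_csv(
        out / "tier_tally.tsv", sep="\t", index=False)
    annotate.known_summary(result.records, result.unique_reads).to_csv(
        out / "known_summary.tsv", sep="\t", index=False)
    novel_table(result.novel).to_csv(out / "novel_mirnas.tsv", sep="\t",
                                     index=False)
    with open(out / "novel_reports.txt", "w") as fh:
        for rec in result.novel:
            fh.write(hairpin.candidate_report(rec))
    expression.rows_to_frame(result.mirna_rows).to_csv(
        out / "mirna_expression.tsv", sep="\t")
    expression.rows_to_frame(result.gene_rows).to_csv(
        out / "gene_expression.tsv", sep="\t")
    per_mirna, per_gene = targets.summarize_targets(result.target_map)
    per_mirna.to_csv(out / "targets_per_mirna.tsv", sep="\t", index=False)
    per_gene.to_csv(out / "targets_per_gene.tsv", sep="\t", index=False)
    enrichment.rows_to_frame(result.enrichment_rows).to_csv(
        out / "enrichment_deg.tsv", sep="\t", index=False)
    enrichment.rows_to_frame(result.target_enrichment_rows).to_csv(
        out / "enrichment_targets.tsv", sep="\t", index=False)
    manifest.write(out / "manifest.json")
    return result


def annotation_table(records: Sequence[annotate.AnnotationRecord],
                     ) -> pd.DataFrame:
    return pd.DataFrame([{
        "sequence": r.sequence, "tier": r.tier,
        "matched_name": r.matched_name, "ncrna_class": r.ncrna_class,
        "mismatches": r.mismatches,
        "loci": ";".join(f"{c}:{s}-{e}({st})" for c, s, e, st in r.loci),
    } for r in records])


def novel_table(novel: Sequence[hairpin.NovelRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": n.name, "mature": n.mature_sequence, "arm": n.arm,
        "contig": n.locus[0], "start": n.locus[1], "end": n.locus[2],
        "strand": n.locus[3], "score": n.score,
        "norm_score": round(n.norm_score, 3),
        "star": n.star.sequence if n.star.defined else "",
    } for n in novel], columns=["name", "mature", "arm", "contig", "start",
                                "end", "strand", "score", "norm_score",
                                "star"])


def _round_fold(f: float) -> str:
    """The mixed presentation precision used in differential tables: one
    decimal above 0.1, three decimals below (round-half-even)."""
    return f"{f:.1f}" if f >= 0.1 else f"{f:.3f}"


def dem_report(rows: Sequence[expression.ExpressionRow]) -> pd.DataFrame:
    """Differential-miRNA table with presentation rounding: RPM to one
    decimal, fold change at mixed precision, P-values in scientific
    notation below 1e-3."""
    out = []
    for r in rows:
        if r.call not in ("up", "down"):
            continue
        out.append({
            "miRNA": r.entity_id,
            "RPM_control": f"{r.norm_control:.1f}",
            "RPM_treated": f"{r.norm_treated:.1f}",
            "fold_change": _round_fold(r.fold),
            "p_value": (f"{r.p_value:.2E}" if r.p_value < 1e-3
                        else f"{r.p_value:.3f}"),
            "call": r.call,
        })
    return pd.DataFrame(out, columns=["miRNA", "RPM_control", "RPM_treated",
                                      "fold_change", "p_value", "call"])


def make_report(result: RunResult, outdir: str | Path) -> dict[str, Path]:
    """Write the summary report tables; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    dem = dem_report(result.mirna_rows)
    paths["dem"] = out / "report_dem.tsv"
    dem.to_csv(paths["dem"], sep="\t", index=False)
    if dem.empty:
        log.warning("no differentially expressed miRNAs to report")

    deg = dem_report(result.gene_rows).rename(columns={
        "miRNA": "gene", "RPM_control": "RPKM_control",
        "RPM_treated": "RPKM_treated"})
    paths["deg"] = out / "report_deg.tsv"
    deg.to_csv(paths["deg"], sep="\t", index=False)

    paths["overview"] = out / "report_overview.tsv"
    pd.DataFrame([result.manifest.row_counts]).T.rename(
        columns={0: "count"}).to_csv(paths["overview"], sep="\t")
    paths["length_histogram"] = out / "report_length_histogram.tsv"
    preprocess.length_histogram(result.unique_reads).to_csv(
        paths["length_histogram"], sep="\t")
    return paths
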
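"""End-to-end pipeline: process -> annotate -> DE -> targets -> degradome
-> report, with stage TSV outputs and a reproducible JSON manifest.

Re-running with the same configuration and inputs is byte-identical:
outputs carry no timestamps and all iteration orders are deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotate as ann
from . import de as de_mod
from ._seq import read_fasta, read_fastq_seqs
from .config import RunConfig
from .degradome import DegradomeSupport, support_count
from .fold import FoldThresholds
from .readproc import MatchPolicy, ReferenceMature, UniqueTag, process_libraries
from .report import assign_bins
from .targets import ConsensusTarget, TargetAlignment, intersect_predictions, \
    scan_transcriptome, upe_proxy

__all__ = ["PipelineResult", "run_pipeline", "load_degradome_tsv"]


@dataclass
class PipelineResult:
    outdir: Path
    config: RunConfig
    tags: list[UniqueTag] = field(default_factory=list)
    ledger: dict = field(default_factory=dict)
    lib_totals: dict[str, int] = field(default_factory=dict)
    records: list[ann.MiRNARecord] = field(default_factory=list)
    drops: dict[str, str] = field(default_factory=dict)
    de_results: dict[str, list[de_mod.DEResult]] = field(default_factory=dict)
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    hits_a: list[TargetAlignment] = field(default_factory=list)
    hits_b: list[TargetAlignment] = field(default_factory=list)
    consensus: list[ConsensusTarget] = field(default_factory=list)
    supports: list[DegradomeSupport] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_references(mature_path, hairpin_path, priority: int) -> list[ReferenceMature]:
    matures = {h.split()[0]: s for h, s in read_fasta(mature_path)} if mature_path else {}
    hairpins = {h.split()[0]: s for h, s in read_fasta(hairpin_path)} if hairpin_path else {}
    refs = []
    for rid in sorted(matures):
        prec = hairpins.get(rid)
        mstart = prec.find(matures[rid]) + 1 if prec else None
        if mstart == 0:
            mstart = None
        refs.append(ReferenceMature(id=rid, mature=matures[rid], precursor=prec,
                                    mature_start=mstart, priority=priority))
    return refs


def load_degradome_tsv(path: str | Path) -> dict[str, dict[str, dict[int, int]]]:
    """Read a degradome count TSV (transcript_id, position, count,
    library_id) into the nested mapping the evidence stage consumes."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, dict[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.library_id), {}).setdefault(
            str(row.transcript_id), {})[int(row.position)] = int(row.count)
    return out


def _read_reads(path: str) -> list[str]:
    if any(str(path).endswith(ext) for ext in (".fa", ".fasta", ".fa.gz", ".fasta.gz")):
        # count-header FASTA: ">tag_N x COUNT"
        reads = []
        for header, seq in read_fasta(path):
            parts = header.split()
            count = int(parts[-1]) if len(parts) >= 3 and parts[-2] == "x" else 1
            reads.extend([seq] * count)
        return reads
    return list(read_fastq_seqs(path))


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Execute all stages; each stage writes its TSV and a manifest entry
    (input hashes, thresholds, counts in/out).  Any stage failure aborts
    with the stage name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(outdir=outdir, config=config)
    manifest: dict = {"config": config.to_dict(), "inputs": {}, "stages": {}}
    for name, path in sorted(
        {**{f"reads_{k}": v for k, v in config.paths.reads.items()},
         **{k: v for k, v in vars(config.paths).items() if k != "reads" and v}}.items()
    ):
        manifest["inputs"][name] = _sha256(path)

    stage = "process"
    try:
        raw = {lib: _read_reads(path) for lib, path in sorted(config.paths.reads.items())}
        contaminants = [s for _h, s in read_fasta(config.paths.contaminants)] \
            if config.paths.contaminants else []
        tags, ledger = process_libraries(
            raw, adapter=config.adapter, min_overlap=config.min_overlap,
            max_mismatch_rate=config.max_mismatch_rate,
            contaminant_refs=contaminants, length_range=config.length_range)
        del raw
        totals = {lib: led["kept"] for lib, led in ledger.items()}
        for tag in tags:
            tag.norm_counts = {
                lib: tag.raw_counts.get(lib, 0) * config.norm_scale / totals[lib]
                for lib in config.library_ids if totals.get(lib)
            }
        res.tags, res.ledger, res.lib_totals = tags, ledger, totals
        _write_tags(outdir / "tags.tsv", tags, config.library_ids)
        pd.DataFrame(ledger).T.rename_axis("library").to_csv(
            outdir / "filter_ledger.tsv", sep="\t")
        manifest["stages"][stage] = {
            "reads_in": {k: v["reads_in"] for k, v in ledger.items()},
            "tags_out": len(tags), "lib_totals": totals,
        }

        stage = "annotate"
        own = _load_references(config.paths.refs_mature, config.paths.refs_hairpin, 0)
        monocot = _load_references(config.paths.monocot_mature,
                                   config.paths.monocot_hairpin, 1)
        genome = dict(sorted((h.split()[0], s) for h, s in
                             read_fasta(config.paths.genome))) \
            if config.paths.genome else None
        policy = ann.AnnotatePolicy(
            length_range=config.annotate_length_range,
            match=MatchPolicy(config.max_shift, config.max_subs),
            flank=config.flank,
            fold_thresholds=FoldThresholds(config.max_mfe, config.min_mfei,
                                           config.max_duplex_unpaired,
                                           config.max_asym_bulge))
        in_range = [t for t in tags
                    if config.annotate_length_range[0] <= t.length
                    <= config.annotate_length_range[1]]
        records, drops = ann.classify_tags(in_range, own, own, monocot, genome, policy)
        res.records, res.drops = records, drops
        _write_annotation(outdir / "annotation.tsv", records, config.library_ids)
        with open(outdir / "annotation_drops.tsv", "w") as fh:
            fh.write("sequence\treason\n")
            for seq in sorted(drops):
                fh.write(f"{seq}\t{drops[seq]}\n")
        by_class: dict[str, int] = {}
        for r in records:
            by_class[r.mclass] = by_class.get(r.mclass, 0) + 1
        manifest["stages"][stage] = {"tags_in": len(in_range), "records": len(records),
                                     "by_class": by_class, "dropped": len(drops)}

        stage = "de"
        counts = {r.name: r.tag.raw_counts for r in records}
        th = de_mod.DEThresholds(alpha=config.alpha,
                                 min_abs_log2fc=config.min_abs_log2fc,
                                 pseudocount=config.pseudocount,
                                 method=config.de_method)
        pairs = [(a, b) for i, a in enumerate(config.library_ids)
                 for b in config.library_ids[i + 1:]]
        for a, b in pairs:
            results = de_mod.pairwise_de(counts, a, b, totals, th, config.norm_scale)
            res.de_results[f"{a}_vs_{b}"] = results
            for r, rec in zip(results, records):
                rec.p_values[f"{a}_vs_{b}"] = r.p_value
        main_key = f"{config.comparison[0]}_vs_{config.comparison[1]}"
        main = res.de_results.get(main_key, [])
        res.up, res.down = de_mod.classify_regulation(main)
        _write_de(outdir / "de.tsv", main, records)
        manifest["stages"][stage] = {"comparisons": [f"{a}_vs_{b}" for a, b in pairs],
                                     "up": len(res.up), "down": len(res.down)}

        stage = "targets"
        if config.paths.transcripts:
            transcripts = dict(sorted((h.split()[0], s) for h, s in
                                      read_fasta(config.paths.transcripts)))
            selected = _select_target_mirnas(records, config)
            mirnas = {r.name: r.tag.sequence for r in selected}
            res.hits_a, res.hits_b = scan_transcriptome(
                mirnas, transcripts, config.cutoff_a, config.max_gaps, config.cutoff_b)
            gene_map = None
            if config.paths.gene_map:
                gm = pd.read_csv(config.paths.gene_map, sep="\t", header=None)
                gene_map = dict(zip(gm[0].astype(str), gm[1].astype(str)))
            res.consensus = intersect_predictions(res.hits_a, res.hits_b, gene_map,
                                                  config.min_site_overlap)
            if config.compute_upe:
                for c in res.consensus:
                    c_upe = upe_proxy(transcripts[c.transcript_id],
                                      (c.site_start, c.site_end))
                    for h in (h for h in res.hits_a
                              if h.transcript_id == c.transcript_id
                              and h.site_start == c.site_start and h.mirna == c.mirna):
                        h.upe_proxy = c_upe
            _write_hits(outdir / "targets_a.tsv", res.hits_a)
            _write_hits(outdir / "targets_b.tsv", res.hits_b)
            _write_consensus(outdir / "consensus.tsv", res.consensus)
            manifest["stages"][stage] = {
                "mirnas_scanned": len(mirnas), "hits_a": len(res.hits_a),
                "hits_b": len(res.hits_b), "consensus": len(res.consensus)}

        stage = "degradome"
        if config.paths.degradome and res.consensus:
            libraries = load_degradome_tsv(config.paths.degradome)
            for c in res.consensus:
                site = TargetAlignment(
                    mirna=c.mirna, transcript_id=c.transcript_id,
                    site_start=c.site_start, site_end=c.site_end,
                    pairing=c.pairing, expectation=c.expectation,
                    penalty_b=c.penalty_b, inhibition=c.inhibition,
                    mirna_seq=c.mirna_seq)
                res.supports.append(support_count(site, libraries,
                                                  config.category_max,
                                                  config.pos_tolerance))
            _write_supports(outdir / "degradome_support.tsv", res.supports)
            manifest["stages"][stage] = {
                "sites": len(res.supports),
                "confirmed": sum(1 for s in res.supports if s.deg_count >= 1)}

        stage = "report"
        _write_reports(outdir, res, config)
        manifest["stages"][stage] = {"done": True}
    except Exception as err:
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    res.manifest = manifest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return res


def _select_target_mirnas(records, config: RunConfig):
    if config.targets_from == "significant":
        return ann.select_significant(records, config.alpha)
    if config.targets_from == "high_confidence":
        return ann.high_confidence_filter(records, config.hc_min_reads,
                                          config.min_mfei, config.hc_min_libraries)
    return records


def _write_tags(path, tags, lib_ids):
    with open(path, "w") as fh:
        cols = "\t".join([f"raw_{lib}" for lib in lib_ids]
                         + [f"norm_{lib}" for lib in lib_ids])
        fh.write(f"sequence\tlength\t{cols}\n")
        for t in tags:
            raw = "\t".join(str(t.raw_counts.get(lib, 0)) for lib in lib_ids)
            norm = "\t".join(f"{t.norm_counts.get(lib, 0.0):.4f}" for lib in lib_ids)
            fh.write(f"{t.sequence}\t{t.length}\t{raw}\t{norm}\n")


def _write_annotation(path, records, lib_ids):
    with open(path, "w") as fh:
        norm_cols = "\t".join(f"norm_{lib}" for lib in lib_ids)
        fh.write(f"name\tclass\tsequence\tsize\t{norm_cols}\tchrom\tstrand\tstart\tend"
                 "\tmfe\tmfei\n")
        for r in records:
            norm = "\t".join(f"{r.tag.norm_counts.get(lib, 0.0):.2f}" for lib in lib_ids)
            loc = (f"{r.locus.chrom}\t{r.locus.strand}\t{r.locus.start}\t{r.locus.end}"
                   if r.locus else ".\t.\t.\t.")
            ev = (f"{r.evaluation.mfe:.1f}\t{r.evaluation.mfei:.2f}"
                  if r.evaluation else ".\t.")
            fh.write(f"{r.name}\t{r.mclass}\t{r.tag.sequence}\t{r.tag.length}\t{norm}\t"
                     f"{loc}\t{ev}\n")


def _write_de(path, results, records):
    loci = {r.name: r.locus for r in records}
    with open(path, "w") as fh:
        fh.write("name\tnorm_a\tnorm_b\tlog2fc\tp_value\tmethod\tstatus\t"
                 "chrom\tstrand\tstart\tend\n")
        for r in results:
            locus = loci.get(r.name)
            loc = (f"{locus.chrom}\t{locus.strand}\t{locus.start}\t{locus.end}"
                   if locus else ".\t.\t.\t.")
            fh.write(f"{r.name}\t{r.norm_a:.2f}\t{r.norm_b:.2f}\t{r.log2fc:.4f}\t"
                     f"{r.p_value:.3e}\t{r.method}\t{r.status}\t{loc}\n")


def _write_hits(path, hits):
    with open(path, "w") as fh:
        fh.write("mirna\ttranscript_id\tsite_start\tsite_end\texpectation\tpenalty_b\t"
                 "inhibition\tpairing\tupe_proxy\n")
        for h in sorted(hits, key=lambda x: (x.mirna, x.transcript_id, x.site_start)):
            pb = f"{h.penalty_b:.1f}" if h.penalty_b is not None else "."
            upe = f"{h.upe_proxy:.1f}" if h.upe_proxy is not None else "."
            fh.write(f"{h.mirna}\t{h.transcript_id}\t{h.site_start}\t{h.site_end}\t"
                     f"{h.expectation:.1f}\t{pb}\t{h.inhibition}\t{h.pairing}\t{upe}\n")


def _write_consensus(path, consensus):
    with open(path, "w") as fh:
        fh.write("mirna\ttranscript_id\tgene\tsite_start\tsite_end\texpectation\t"
                 "penalty_b\tinhibition\n")
        for c in consensus:
            fh.write(f"{c.mirna}\t{c.transcript_id}\t{c.gene or '.'}\t{c.site_start}\t"
                     f"{c.site_end}\t{c.expectation:.1f}\t{c.penalty_b:.1f}\t"
                     f"{c.inhibition}\n")


def _write_supports(path, supports):
    with open(path, "w") as fh:
        fh.write("mirna\ttranscript_id\tcleavage_pos\tdeg_count\tper_library\n")
        for s in sorted(supports, key=lambda x: (x.mirna, x.transcript_id)):
            per = ";".join(f"{lib}:{cat if cat is not None else 'na'}"
                           for lib, (_cnt, cat) in sorted(s.per_library.items()))
            fh.write(f"{s.mirna}\t{s.transcript_id}\t{s.cleavage_pos}\t{s.deg_count}\t"
                     f"{per}\n")


def _write_reports(outdir: Path, res: PipelineResult, config: RunConfig):
    # table of high-confidence novel miRNAs (counts, sequence, size, MFEI)
    novel = [r for r in res.records if r.mclass != "known"]
    try:
        hc = ann.high_confidence_filter(novel, config.hc_min_reads, config.min_mfei,
                                        config.hc_min_libraries)
    except ValueError:
        hc = []
    with open(outdir / "table_high_confidence.tsv", "w") as fh:
        cols = "\t".join(config.library_ids)
        fh.write(f"mirna\t{cols}\tsequence\tsize\tmfei\n")
        for r in hc:
            counts = "\t".join(f"{r.tag.norm_counts.get(lib, 0.0):.0f}"
                               for lib in config.library_ids)
            mfei = f"{r.evaluation.mfei:.2f}" if r.evaluation else "."
            fh.write(f"{r.name}\t{counts}\t{r.tag.sequence}\t{r.tag.length}\t{mfei}\n")
    # Cd-responsive table
    main_key = f"{config.comparison[0]}_vs_{config.comparison[1]}"
    de_rows = [r for r in res.de_results.get(main_key, []) if r.status != "none"]
    loci = {r.name: r.locus for r in res.records}
    with open(outdir / "table_cd_responsive.tsv", "w") as fh:
        fh.write("mirna\tnorm_c1\tnorm_cd1\tlog2fc\tp_value\tstatus\tchrom\tstrand\t"
                 "start\tend\n")
        for r in sorted(de_rows, key=lambda x: (-x.log2fc, x.name)):
            locus = loci.get(r.name)
            loc = (f"{locus.chrom}\t{locus.strand}\t{locus.start}\t{locus.end}"
                   if locus else ".\t.\t.\t.")
            fh.write(f"{r.name}\t{r.norm_a:.0f}\t{r.norm_b:.0f}\t{r.log2fc:.2f}\t"
                     f"{r.p_value:.3e}\t{r.status}\t{loc}\n")
    # cleavable-target table with degradome support
    deg = {(s.mirna, s.transcript_id): s for s in res.supports}
    with open(outdir / "table_targets.tsv", "w") as fh:
        fh.write("mirna\ttranscript_id\tgene\texpectation\tpenalty_b\tinhibition\tdeg\n")
        for c in res.consensus:
            s = deg.get((c.mirna, c.transcript_id))
            fh.write(f"{c.mirna}\t{c.transcript_id}\t{c.gene or '.'}\t"
                     f"{c.expectation:.1f}\t{c.penalty_b:.1f}\t{c.inhibition}\t"
                     f"{s.deg_count if s else 0}\n")
    # functional bins of consensus target genes
    annotations: dict[str, str] = {}
    if config.paths.gene_annotations:
        df = pd.read_csv(config.paths.gene_annotations, sep="\t", header=None)
        annotations = dict(zip(df[0].astype(str), df[1].astype(str)))
    genes = sorted({c.gene for c in res.consensus if c.gene})
    bins = assign_bins({g: annotations.get(g, "") for g in genes})
    with open(outdir / "table_bins.tsv", "w") as fh:
        fh.write("gene\tbin\n")
        for b in bins:
            fh.write(f"{b.gene_id}\t{b.bin}\n")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"unique tags: {len(res.tags)}\n")
        fh.write(f"annotated miRNA records: {len(res.records)}\n")
        fh.write(f"high-confidence novel: {len(hc)}\n")
        fh.write(f"Cd-responsive ({main_key}): {len(de_rows)} "
                 f"(up {len(res.up)}, down {len(res.down)})\n")
        fh.write(f"consensus targets: {len(res.consensus)}\n")
        fh.write(f"degradome-confirmed: "
                 f"{sum(1 for s in res.supports if s.deg_count >= 1)}\n")
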
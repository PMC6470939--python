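"""Run the full pipeline on a freshly simulated study and score the
outputs against the planted ground truth (recovery of planted miRNAs,
detection of planted Cd fold changes, and exactness of the
degradome-confirmed consensus target set)."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

from .annotate import base_name
from .config import Paths, RunConfig
from .pipeline import PipelineResult, run_pipeline
from .synth import SimulatedStudy, simulate_study, write_study

__all__ = ["run_synthetic_study", "compare_to_truth"]


def run_synthetic_study(
    seed: int = 0,
    outdir: str | Path = "synthetic_run",
    depth: int = 1_000_000,
    n_hairpins: int = 10,
    sites_per_mirna: int = 5,
    dispersion: float = 0.1,
    degradome_depth: int = 30_000,
    peak_fraction: float = 0.8,
    config: Optional[RunConfig] = None,
    **simulate_kwargs,
) -> tuple[PipelineResult, SimulatedStudy, dict]:
    """Simulate, write, analyse, and score one synthetic study."""
    outdir = Path(outdir)
    study = simulate_study(seed=seed, depth=depth, n_hairpins=n_hairpins,
                           sites_per_mirna=sites_per_mirna, dispersion=dispersion,
                           degradome_depth=degradome_depth,
                           peak_fraction=peak_fraction, **simulate_kwargs)
    simdir = outdir / "sim"
    paths = write_study(study, simdir)
    cfg = config or RunConfig()
    cfg.rng_seed = seed
    cfg.paths = Paths(
        reads={lib: str(paths[f"reads_{lib}.fastq"]) for lib in study.libraries},
        contaminants=str(paths["contaminants.fa"]),
        refs_mature=str(paths["refs_mature.fa"]),
        refs_hairpin=str(paths["refs_hairpin.fa"]),
        genome=str(paths["genome.fa"]),
        transcripts=str(paths["transcripts.fa"]),
        degradome=str(paths["degradome_counts.tsv"]),
    )
    result = run_pipeline(cfg, outdir / "run")
    metrics = compare_to_truth(result, study)
    return result, study, metrics


def _map_records_to_truth(result: PipelineResult, study: SimulatedStudy) -> dict[str, str]:
    """record name -> planted miRNA name, via genomic locus overlap with
    the planted precursor (sequence identity as fallback)."""
    mapping: dict[str, str] = {}
    for rec in result.records:
        target = None
        for pm in study.truth.planted_mirnas:
            if base_name(rec.name) == pm.name or rec.tag.sequence == pm.mature_seq:
                target = pm.name
                break
            if rec.locus is not None and rec.locus.chrom == pm.precursor_locus.chrom \
                    and not (rec.locus.end < pm.precursor_locus.start
                             or rec.locus.start > pm.precursor_locus.end):
                target = pm.name
                break
        if target:
            mapping[rec.name] = target
    return mapping


def compare_to_truth(result: PipelineResult, study: SimulatedStudy) -> dict:
    """Score pipeline outputs against the planted truth."""
    truth = study.truth
    rec2pm = _map_records_to_truth(result, study)
    recovered = set(rec2pm.values())
    planted = [pm.name for pm in truth.planted_mirnas]

    # planted DE recall: strong planted fold changes must be flagged with
    # the right sign in the Cd contrast
    main_key = f"{result.config.comparison[0]}_vs_{result.config.comparison[1]}"
    status_by_rec = {r.name: r.status for r in result.de_results.get(main_key, [])}
    de_expected = {name: fc for name, (b, fc) in truth.de_truth.items()
                   if abs(math.log2(fc)) >= 2.0 and b >= 50.0}
    de_hits = {}
    for name, fc in de_expected.items():
        want = "up" if fc > 1 else "down"
        de_hits[name] = any(
            status_by_rec.get(rname) == want
            for rname, pname in rec2pm.items() if pname == name)

    # degradome-confirmed consensus pairs vs planted target pairs
    confirmed = {(rec2pm.get(s.mirna, s.mirna), s.transcript_id)
                 for s in result.supports if s.deg_count >= 1}
    truth_pairs = {(t.mirna, t.transcript_id) for t in truth.planted_targets}
    inter = confirmed & truth_pairs
    union = confirmed | truth_pairs

    null_names = {name for name, (b, fc) in truth.de_truth.items() if fc == 1.0}
    return {
        "planted_mirnas": len(planted),
        "planted_recovered": len(recovered),
        "mirna_recovery_rate": len(recovered) / len(planted) if planted else 1.0,
        "true_de_expected": len(de_expected),
        "true_de_flagged": sum(de_hits.values()),
        "de_recall": (sum(de_hits.values()) / len(de_expected)) if de_expected else 1.0,
        "planted_targets": len(truth_pairs),
        "confirmed_pairs": len(confirmed),
        "confirmed_equals_truth": confirmed == truth_pairs,
        "target_jaccard": len(inter) / len(union) if union else 1.0,
        "null_mirnas": len(null_names),
    }
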
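"""Pipeline orchestration: ingest -> classes -> hotspots -> hybrids -> mods.

One JSON config drives all stages; every stage writes plain TSV/BED and the
run ends with a consolidated machine-readable ``report.json``.  Outputs are
deterministic for a fixed config and seed (no timestamps in any output).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from . import __version__
from .core_io import GenomeModel, load_genome, read_alignments, split_strands
from .hotspots import ag_richness_test, annotate_codons, call_hotspots, window_site_stats
from .hybrids import calls_to_frame, detect_hybrids, hybrid_length_histogram, hybrid_summary
from .mod_dynamics import (ivt_subtract, site_context, site_significance,
                           site_stoichiometry, temporal_classification)
from .read_classes import class_proportions, classify_reads, count_orf_containment

logger = logging.getLogger("ms2drs")

DEFAULT_TIMEPOINT_ORDER = ["0h", "20min", "40min", "3h", "6h"]


@dataclass
class RunConfig:
    """Paths, per-stage parameters, seed and timepoint ordering for one run."""

    genome_fasta: str
    annotation: str
    outdir: str
    alignments: str | None = None           # SAM/BAM with primary (+supplementary) records
    reads: str | None = None                # FASTA/FASTQ for the chimera stage
    mod_calls_test: str | None = None       # per-read mod-call TSV, test samples
    mod_calls_ivt: str | None = None        # per-read mod-call TSV, IVT control
    seed: int = 0
    timepoints: list[str] = field(default_factory=lambda: list(DEFAULT_TIMEPOINT_ORDER))
    min_phred: float = 10.0
    class_delta: int = 25
    window: int = 5
    min_depth: float = 50
    fold_threshold: float = 5.0
    hybrid_min_score: float = 60
    prob_threshold: float = 0.8
    min_cov: int = 30
    alpha: float = 0.05

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _stage(name: str):
    logger.info("[%s] running", name)


def run_pipeline(config: RunConfig) -> dict:
    """Run all requested stages in order; returns the report dict.

    Stages whose inputs are absent from the config are skipped and noted
    in the report.  Any stage error propagates with the stage named.
    """
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config": {k: v for k, v in vars(config).items()},
                    "stages": {}}

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    _stage("ingest")
    try:
        genome = load_genome(config.genome_fasta, config.annotation)
    except Exception as exc:
        raise RuntimeError(f"stage ingest failed: {exc}") from exc
    report["stages"]["ingest"] = {"genome": genome.name, "length": genome.length,
                                  "n_orfs": len(genome.orfs)}

    reads = []
    if config.alignments:
        try:
            reads, _supp = read_alignments(config.alignments, min_phred=config.min_phred)
        except Exception as exc:
            raise RuntimeError(f"stage ingest failed: {exc}") from exc
        pos, neg = split_strands(reads)
        report["stages"]["ingest"].update(
            {"n_reads": len(reads), "n_positive": len(pos), "n_negative": len(neg)})

    classified = None
    if reads:
        _stage("classes")
        classified = classify_reads(reads, genome, delta=config.class_delta)
        classified.to_csv(out("read_classes.tsv"), sep="\t", index=False)
        summary = class_proportions(classified)
        summary.to_csv(out("class_summary.tsv"), sep="\t", index=False)
        orf_counts = count_orf_containment(reads, genome.orfs)
        orf_counts.to_csv(out("orf_containment.tsv"), sep="\t", index=False)
        report["stages"]["classes"] = {
            "n_classified": len(classified),
            "classes": classified["read_class"].value_counts().to_dict()}

        _stage("hotspots")
        stats = window_site_stats(reads, genome, window=config.window,
                                  min_depth=config.min_depth)
        stats.to_csv(out("window_stats.tsv"), sep="\t", index=False)
        hs = call_hotspots(stats, fold_threshold=config.fold_threshold,
                           window=config.window)
        hs_ann = annotate_codons(genome, hs)
        if len(hs):
            ag = ag_richness_test(genome, hs, strand="-")
            hs_ann = hs_ann.merge(
                ag[["window_start", "window_end", "purine_fraction", "p_value", "q_value"]],
                on=["window_start", "window_end"], how="left")
        hs_ann.to_csv(out("hotspots_annotated.tsv"), sep="\t", index=False)
        with open(out("hotspots.bed"), "w") as fh:
            for _, h in hs.iterrows():
                fh.write(f"{genome.name}\t{int(h['window_start']) - 1}\t"
                         f"{int(h['window_end'])}\t{h['kind']}\t"
                         f"{h['fold']:.3f}\t{h['strand']}\n")
        report["stages"]["hotspots"] = {"n_windows": len(stats), "n_hotspots": len(hs)}
    else:
        report["stages"]["classes"] = "skipped (no alignments)"
        report["stages"]["hotspots"] = "skipped (no alignments)"

    if config.reads:
        _stage("hybrids")
        fmt = "fastq" if config.reads.endswith(("q", ".fastq.gz")) else "fasta"
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(config.reads, fmt)}
        calls = detect_hybrids(seqs, genome, min_score=config.hybrid_min_score)
        calls_to_frame(calls).to_csv(out("hybrid_calls.tsv"), sep="\t", index=False)
        summary, breakdown = hybrid_summary(calls, reads or [])
        summary.to_csv(out("hybrid_summary.tsv"), sep="\t", index=False)
        breakdown.to_csv(out("hybrid_breakdown.tsv"), sep="\t", index=False)
        hybrid_length_histogram(calls).to_csv(out("hybrid_lengths.tsv"),
                                              sep="\t", index=False)
        report["stages"]["hybrids"] = {"n_reads": len(seqs), "n_hybrid": len(calls)}
    else:
        report["stages"]["hybrids"] = "skipped (no reads)"

    if config.mod_calls_test:
        _stage("mods")
        from .core_io import read_modcall_table

        test_calls = read_modcall_table(config.mod_calls_test)
        if "length_fraction" not in test_calls.columns and classified is not None:
            frac = classified.set_index("read_id")["length_fraction"]
            test_calls["length_fraction"] = test_calls["read_id"].map(frac).fillna("all")
        test_sites = site_stoichiometry(test_calls, prob_threshold=config.prob_threshold,
                                        min_cov=config.min_cov)
        if config.mod_calls_ivt:
            ivt_calls = read_modcall_table(config.mod_calls_ivt)
            if "length_fraction" not in ivt_calls.columns:
                ivt_calls["length_fraction"] = "all"
            ivt_sites = site_stoichiometry(ivt_calls, prob_threshold=config.prob_threshold,
                                           min_cov=0)
            if set(ivt_sites["length_fraction"]) == {"all"}:
                # an IVT run has no biological length fractions; match on site only
                frames = []
                for lf in test_sites["length_fraction"].unique():
                    tmp = ivt_sites.copy()
                    tmp["length_fraction"] = lf
                    frames.append(tmp)
                ivt_sites = pd.concat(frames, ignore_index=True)
            retained = ivt_subtract(test_sites[~test_sites["low_coverage"]], ivt_sites)
            tested = site_significance(retained, family_keys=["timepoint", "mod_type",
                                                              "length_fraction"],
                                       alpha=config.alpha)
        else:
            retained = test_sites[~test_sites["low_coverage"]].reset_index(drop=True)
            tested = retained
        tested = tested.copy()
        tested["context"] = site_context(genome, tested)
        out_sites = tested.copy()
        out_sites["ref_pos"] = out_sites["ref_pos"] + 1  # 1-based report
        out_sites.to_csv(out("mod_sites.tsv"), sep="\t", index=False)
        dynamics = temporal_classification(tested, config.timepoints, alpha=config.alpha)
        dyn_out = dynamics.copy()
        dyn_out["ref_pos"] = dyn_out["ref_pos"] + 1
        dyn_out.to_csv(out("mod_dynamics.tsv"), sep="\t", index=False)
        report["stages"]["mods"] = {"n_sites_tested": len(tested),
                                    "n_sites_dynamic": int(
                                        (dynamics["dynamic_label"] != "static_insufficient").sum()
                                        if len(dynamics) else 0)}
    else:
        report["stages"]["mods"] = "skipped (no mod tables)"

    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def compare_timepoints(class_summary: pd.DataFrame, orf_counts: pd.DataFrame,
                       timepoint_order: list[str] | None = None) -> pd.DataFrame:
    """Fold-change of class and ORF counts relative to the first timepoint.

    Reports both the raw ratio and a pseudo-count-adjusted ratio
    (count+1)/(baseline+1), which stays finite when the baseline is zero
    (early timepoints can lack whole classes).
    """
    frames = []
    for df, key in ((class_summary, "read_class"), (orf_counts, "orf")):
        if df is None or not len(df):
            continue
        tps = [t for t in (timepoint_order or sorted(df["timepoint"].unique()))
               if t in set(df["timepoint"])]
        if len(tps) < 2:
            continue
        base_tp = tps[0]
        counts = df.groupby(["timepoint", key])["count"].sum().reset_index()
        base = counts[counts["timepoint"] == base_tp].set_index(key)["count"]
        for tp in tps[1:]:
            cur = counts[counts["timepoint"] == tp]
            for _, row in cur.iterrows():
                b = int(base.get(row[key], 0))
                c = int(row["count"])
                frames.append({"feature_type": key, "feature": row[key],
                               "timepoint": tp, "baseline_timepoint": base_tp,
                               "count": c, "baseline_count": b,
                               "raw_fold": c / b if b else float("inf"),
                               "adjusted_fold": (c + 1) / (b + 1)})
    return pd.DataFrame(frames, columns=["feature_type", "feature", "timepoint",
                                         "baseline_timepoint", "count", "baseline_count",
                                         "raw_fold", "adjusted_fold"])
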
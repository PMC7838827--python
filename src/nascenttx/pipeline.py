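"""End-to-end orchestration: simulate -> segment -> annotate -> score ->
pair -> enrich, driven by a single config with mandatory seeds.

Every stage is a pure function of (inputs, config, seed); outputs are
written under the run directory and hash-logged, so a rerun with identical
config and seeds reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotation, enrichment, normalization, pairing, scores, segmentation
from . import synthetic
from .annotation import ClassificationRules
from .genomic_io import BinnedCoverage, count_fragments, write_bed


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the study's printed constants."""

    # synthetic genome
    n_chrom: int = 1
    chrom_length_bp: int = 10_000_000
    n_genes: int = 100
    n_enhancer_states: int = 150
    n_cell_lines: int = 14
    n_replicates: int = 2
    frac_specific: float = 0.37
    coupling: float = 0.8
    noise: str = "poisson-lognormal"
    # activity thresholds (normalized FPK)
    fpk_active_mean: float = 20.0
    fpk_active_replicate: float = 15.0
    fpk_promoter_pairing: float = 30.0
    # pairing
    correlation_cutoff: float = 0.6
    pairing_window: int = 500_000
    # enrichment resampling
    n_ep_null_sets: int = 100
    n_snp_null_sets: int = 1_000
    # segmentation
    hmm_max_iter: int = 50
    hmm_tol: float = 1e-2
    # seeds (mandatory, documented defaults)
    seed_genome: int = 1
    seed_programs: int = 2
    seed_coverage: int = 3
    seed_ancillary: int = 4
    seed_enrichment: int = 5
    rules: ClassificationRules = field(default_factory=ClassificationRules)

    def __post_init__(self):
        for name in ("fpk_active_mean", "fpk_active_replicate",
                     "fpk_promoter_pairing", "correlation_cutoff",
                     "pairing_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str):
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        rules = d.pop("rules", None)
        cfg = cls(**d)
        if rules is not None:
            cfg.rules = ClassificationRules(**rules)
        return cfg

    def reseed(self, seed: int) -> "PipelineConfig":
        """Derive all stage seeds deterministically from one master seed."""
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(5)
        out = dataclasses.replace(self)
        for name, child in zip(("seed_genome", "seed_programs", "seed_coverage",
                                "seed_ancillary", "seed_enrichment"), children):
            setattr(out, name, int(child.generate_state(1)[0] % (2 ** 31)))
        return out


def _log(log_path, stage, **kv):
    rec = {"ts": time.time(), "stage": stage, **kv}
    with open(log_path, "a") as fh:
        fh.write(json.dumps(rec) + "\n")


def file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def pooled_line_coverage(coverage: dict[str, dict[str, BinnedCoverage]],
                         sample_to_line: dict[str, str],
                         line: str) -> dict[str, BinnedCoverage]:
    """Sum replicate coverage of one cell line, per strand."""
    pooled = None
    for sample, strands in coverage.items():
        if sample_to_line.get(sample) != line:
            continue
        if pooled is None:
            pooled = {
                s: BinnedCoverage(line, s, strands[s].bin_width,
                                  {c: v.copy() for c, v in strands[s].data.items()})
                for s in strands
            }
        else:
            for s in strands:
                for c in strands[s].data:
                    pooled[s].data[c] = pooled[s].data[c] + strands[s].data[c]
    if pooled is None:
        raise ValueError(f"no samples for cell line {line}")
    return pooled


def annotate_cell_line(tus_raw: pd.DataFrame, genome, line_samples: list[str],
                       coverage: dict[str, dict[str, BinnedCoverage]],
                       factors: pd.Series, cfg: PipelineConfig,
                       line: str) -> dict:
    """Per-cell-line classification, expression filtering, eRNA calling and
    enhancer construction."""
    rules = cfg.rules
    genes = genome.genes

    tus = annotation.classify_tus(tus_raw, genes, rules)
    tus = segmentation.merge_gaps(tus, max_gap_bp=genome.layout.bin_width)
    tus = annotation.classify_tus(
        tus.drop(columns=["klass", "host_gene"]), genes, rules)

    # expression filter: replicate-averaged FPK >= 20 and each replicate >= 15
    lengths = pd.Series((tus["end"] - tus["start"]).to_numpy(),
                        index=tus["tu_id"])
    counts = pd.DataFrame({
        s: count_fragments(tus, coverage[s], "sense") for s in line_samples
    }, index=tus["tu_id"])
    fpk = normalization.fpk(counts, factors[line_samples], lengths)
    active = (fpk.mean(axis=1) >= cfg.fpk_active_mean) & \
             (fpk >= cfg.fpk_active_replicate).all(axis=1)
    tus_expressed = tus[tus["tu_id"].map(active)].reset_index(drop=True)

    ernas = annotation.call_ernas(tus_expressed, genome.enhancer_states,
                                  genes, rules)

    pooled = pooled_line_coverage(coverage, dict.fromkeys(line_samples, line), line)
    line_factor = float(factors[line_samples].mean())

    def end_fpk(head_row) -> float:
        w = rules.upstream_end_window
        if head_row["strand"] == "+":
            iv = pd.DataFrame([{**head_row,
                                "start": max(head_row["end"] - w, head_row["start"]),
                                "end": head_row["end"]}])
        else:
            iv = pd.DataFrame([{**head_row, "start": head_row["start"],
                                "end": min(head_row["start"] + w, head_row["end"])}])
        n = float(count_fragments(iv, pooled, "sense")[0]) / line_factor
        return n / (w / 1000.0)

    tu_fpk = fpk.mean(axis=1)
    ernas = annotation.filter_antisense(ernas, tus, tu_fpk, end_fpk, rules)
    pairs = annotation.pair_bidirectional(ernas, tus, rules)
    # intergenic eRNAs that found no divergent partner are discarded
    paired_ids = set(pairs["erna_id"]) | set(pairs["plus_id"]) | set(pairs["minus_id"])
    keep = (ernas["erna_kind"] == "antisense") | ernas["tu_id"].isin(paired_ids)
    ernas = ernas[keep].reset_index(drop=True)
    enhancers = annotation.define_enhancers(pairs, ernas, genome.layout,
                                            rules, cell_line=line)
    return {"tus": tus, "tus_expressed": tus_expressed, "ernas": ernas,
            "divergent_pairs": pairs, "enhancers": enhancers}


def run(cfg: PipelineConfig, outdir: str) -> dict:
    """Execute the full pipeline; returns the result bundle."""
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "pipeline.log.jsonl")
    open(log_path, "w").close()
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))

    # --- simulate -----------------------------------------------------
    genome = synthetic.generate_genome(
        cfg.n_chrom, cfg.chrom_length_bp, cfg.n_genes, cfg.n_enhancer_states,
        seed=cfg.seed_genome)
    truth = synthetic.generate_programs(
        genome, cfg.n_cell_lines, cfg.frac_specific, seed=cfg.seed_programs,
        n_replicates=cfg.n_replicates, coupling=cfg.coupling)
    coverage = synthetic.simulate_coverage(genome, truth,
                                           seed=cfg.seed_coverage,
                                           noise=cfg.noise)
    interactions, snps, peaks = synthetic.simulate_ancillary(
        genome, truth, seed=cfg.seed_ancillary)
    synthetic.write_dataset(outdir, genome, coverage=None,
                            interactions=interactions, snps=snps, peaks=peaks)
    _log(log_path, "simulate", n_genes=len(genome.genes.genes),
         n_states=len(genome.enhancer_states), n_samples=len(truth.samples))

    # --- normalization ------------------------------------------------
    gene_counts = pd.DataFrame({
        s: count_fragments(genome.genes.genes, coverage[s], "sense")
        for s in truth.samples
    }, index=genome.genes.genes["gene_id"])
    factors = normalization.size_factors(gene_counts)
    lines = sorted(set(truth.sample_to_line.values()))
    _log(log_path, "normalize", size_factors=factors.round(4).to_dict())

    # --- segment + annotate per cell line ------------------------------
    per_line = {}
    for line in lines:
        line_samples = [s for s in truth.samples
                        if truth.sample_to_line[s] == line]
        pooled = pooled_line_coverage(coverage, truth.sample_to_line, line)
        model = segmentation.fit_hmm(pooled, max_iter=cfg.hmm_max_iter,
                                     tol=cfg.hmm_tol, seed=cfg.seed_coverage)
        model.to_yaml(os.path.join(outdir, f"hmm_{line}.yaml"))
        tus_raw = segmentation.decode_tus(pooled, model, prefix=f"TU_{line}")
        per_line[line] = annotate_cell_line(tus_raw, genome, line_samples,
                                            coverage, factors, cfg, line)
        _log(log_path, "segment+annotate", line=line,
             n_tus=len(per_line[line]["tus"]),
             n_ernas=len(per_line[line]["ernas"]),
             n_enhancers=len(per_line[line]["enhancers"]))

    # --- union annotation and quantification ---------------------------
    merged_enh = annotation.merge_across_cell_lines(
        {ln: r["enhancers"] for ln, r in per_line.items()})
    enh_fpk = annotation.quantify_enhancers(merged_enh, coverage, factors,
                                            cfg.rules)
    enh_activity = normalization.replicate_average(enh_fpk, truth.sample_to_line)
    gene_lengths = pd.Series(
        (genome.genes.genes["end"] - genome.genes.genes["start"]).to_numpy(),
        index=genome.genes.genes["gene_id"])
    gene_fpk = normalization.fpk(gene_counts, factors, gene_lengths)
    gene_activity = normalization.replicate_average(gene_fpk, truth.sample_to_line)
    write_bed(merged_enh.assign(name=merged_enh["enhancer_id"], score=0),
              os.path.join(outdir, "enhancers_union.bed"))
    _log(log_path, "quantify", n_merged_enhancers=len(merged_enh))

    # --- scores ---------------------------------------------------------
    spec_enh = scores.specificity_table(enh_activity)
    spec_gene = scores.specificity_table(gene_activity)
    spec_enh.to_csv(os.path.join(outdir, "enhancer_specificity.tsv"), sep="\t")
    spec_gene.to_csv(os.path.join(outdir, "gene_specificity.tsv"), sep="\t")
    _log(log_path, "score", n_enh_scored=len(spec_enh))

    # --- pairing --------------------------------------------------------
    promoters = pairing.promoter_anchors(genome.genes, gene_activity,
                                         cfg.fpk_promoter_pairing)
    p_n = pairing.pair_nearest(merged_enh, promoters, cfg.pairing_window)
    p_cn = pairing.pair_correlated_neighboring(
        merged_enh, promoters, enh_activity, gene_activity,
        cfg.correlation_cutoff, cfg.pairing_window)
    p_cw = pairing.pair_correlated_window(
        merged_enh, promoters, enh_activity, gene_activity,
        cfg.pairing_window, cfg.correlation_cutoff)
    enh_active = normalization.classify_active(
        enh_fpk, truth.sample_to_line, cfg.fpk_active_mean,
        cfg.fpk_active_replicate)
    prom_active = gene_activity >= cfg.fpk_promoter_pairing
    p_n, p_cn, p_cw = (
        pairing.attribute_cell_lines(df, enh_active, prom_active)
        for df in (p_n, p_cn, p_cw))
    all_pairs = pd.concat([p_n, p_cn, p_cw], ignore_index=True)
    for df in (p_n, p_cn, p_cw):
        pairing.audit_pairs(df, cfg.pairing_window, cfg.correlation_cutoff)
    all_pairs.to_csv(os.path.join(outdir, "ep_pairs.tsv"), sep="\t", index=False)
    summaries = pairing.pairing_summaries(p_cw)
    _log(log_path, "pair", n_N=len(p_n), n_CN=len(p_cn), n_CW=len(p_cw))

    # --- enrichment ------------------------------------------------------
    se = enrichment.call_super_enhancers(peaks)
    se_path = os.path.join(outdir, "super_enhancers.bed")
    write_bed(se.assign(name=np.where(se["is_super"], "SE", "TE"),
                        score=se["rank"], strand="."), se_path)
    chic_pairs, chic_frac = enrichment.chic_support(
        p_cn, interactions, promoters, merged_enh)
    trait = snps[snps["set"] == "trait"].reset_index(drop=True)
    background = snps[snps["set"] == "background"].reset_index(drop=True)
    snp_null = enrichment.sample_matched_snp_nulls(
        trait, background, merged_enh, n_sets=cfg.n_snp_null_sets,
        seed=cfg.seed_enrichment)
    linked_genes = {g for _, g in truth.ep_links}
    paired_genes = set(p_cn["gene_id"])
    all_genes = set(genome.genes.genes["gene_id"])
    a = len(linked_genes & paired_genes)
    b = len(linked_genes - paired_genes)
    c = len(paired_genes - linked_genes)
    d = len(all_genes - linked_genes - paired_genes)
    odds, fisher_p = enrichment.fisher_enrichment(a, b, c, d)
    report = {
        "n_merged_enhancers": len(merged_enh),
        "n_pairs": {"N": len(p_n), "CN": len(p_cn), "CW": len(p_cw)},
        "pairing_summaries": summaries,
        "n_super_enhancers": int(se["is_super"].sum()) if len(se) else 0,
        "chic_supported_fraction": chic_frac,
        "snp_enrichment": snp_null.summary(),
        "linked_gene_fisher": {"odds_ratio": odds, "p": fisher_p},
    }
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    _log(log_path, "enrich", **{k: v for k, v in report.items()
                                if not isinstance(v, dict)})

    hashes = {
        f: file_hash(os.path.join(outdir, f))
        for f in sorted(os.listdir(outdir))
        if f.endswith((".bed", ".tsv", ".gtf", ".json", ".yaml"))
        and f != "pipeline.log.jsonl"
    }
    _log(log_path, "done", hashes=hashes)
    return {
        "genome": genome, "truth": truth, "factors": factors,
        "per_line": per_line, "merged_enhancers": merged_enh,
        "enhancer_activity": enh_activity, "gene_activity": gene_activity,
        "pairs": {"N": p_n, "CN": p_cn, "CW": p_cw},
        "super_enhancers": se, "report": report, "hashes": hashes,
    }
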
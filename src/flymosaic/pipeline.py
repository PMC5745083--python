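"""End-to-end synthetic pipeline runner with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List

import numpy as np
import yaml

from . import behavior, gwas, io, kmers, popgen, segmentation, synthetic

logger = logging.getLogger(__name__)

_KNOWN_SECTIONS = {"seed", "outdir", "log_level", "segmentation", "gwas",
                   "kmer", "popgen", "behavior", "synthetic"}


@dataclass
class PipelineConfig:
    """Per-module parameter blocks plus the global seed and output dir."""

    seed: int = 0
    outdir: str = "pipeline_out"
    log_level: str = "INFO"
    segmentation: Dict[str, Any] = field(default_factory=dict)
    gwas: Dict[str, Any] = field(default_factory=dict)
    kmer: Dict[str, Any] = field(default_factory=dict)
    popgen: Dict[str, Any] = field(default_factory=dict)
    behavior: Dict[str, Any] = field(default_factory=dict)
    synthetic: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: Dict[str, Any]) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict[str, Any]:
    """Run every stage on small synthetic inputs and write a manifest.

    Stages run in dependency order (generate, then analyse); every output
    file is listed in manifest.json with its sha256 so identical configs
    can be verified to reproduce identical artifacts.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Any] = {"seed": config.seed, "stages": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].setdefault(stage, [])
        for p in paths:
            manifest["stages"][stage].append(
                {"path": str(p.relative_to(out)), "sha256": _sha256(p)})

    # --- retina: simulate, count -------------------------------------------
    syn = config.synthetic
    cfg = synthetic.SimulationConfig(seed=config.seed,
                                     **syn.get("retina", {}))
    image, truth = synthetic.generate_retina_image(cfg)
    img_path, truth_path = out / "retina.tif", out / "retina_truth.json"
    io.write_image(image, img_path)
    io.write_ground_truth_json(truth, truth_path)
    params = segmentation.SegmentationParams(**config.segmentation)
    count = segmentation.count_mosaic(io.read_image_pair(img_path), params)
    summary_path = out / "retina_summary.tsv"
    summary_path.write_text(
        "n_rh3\tn_rh4\tn_ambiguous\tpct_on\ttrue_pct_on\n"
        f"{count.n_rh3}\t{count.n_rh4}\t{count.n_ambiguous}\t"
        f"{count.pct_on:.4f}\t{truth.pct_on_true:.4f}\n")
    record("retina", img_path, truth_path, summary_path)

    # --- cross + GWAS -------------------------------------------------------
    g = config.gwas
    deficiency = gwas.DeficiencyInterval(g.get("chrom", "3R"),
                                         g.get("def_start", 16_200_000),
                                         g.get("def_end", 16_400_000))
    genotypes, phenotype, _ = synthetic.generate_cross_cohort(
        n_lines=g.get("n_lines", 60), n_variants=g.get("n_variants", 80),
        causal_index=g.get("causal_index", 40),
        effect_size=g.get("effect_size", -2.0),
        deficiency=deficiency, seed=config.seed)
    vcf_path, pheno_path = out / "cohort.vcf", out / "phenotype.tsv"
    io.write_vcf(genotypes, vcf_path)
    io.write_phenotype_tsv(phenotype, pheno_path)
    progeny = gwas.simulate_cross(io.read_vcf(vcf_path), deficiency)
    pcs = gwas.compute_relationship_pcs(progeny, g.get("n_pcs", 5))
    scan = gwas.association_scan(progeny, io.read_phenotype_tsv(pheno_path),
                                 pcs)
    perm = gwas.maxT_permutation(progeny, phenotype, pcs,
                                 n_perm=g.get("n_perm", 100),
                                 seed=config.seed)
    scan["emp_p"] = perm["emp_p"]
    threshold, flags = gwas.bonferroni_threshold(scan["p"].to_numpy())
    scan["significant"] = flags
    assoc_path = out / "association.tsv"
    scan.to_csv(assoc_path, sep="\t", index=False)
    record("gwas", vcf_path, pheno_path, assoc_path)

    # --- SELEX k-mers -------------------------------------------------------
    k = config.kmer
    sites = kmers.BindingSiteSet()
    pwm = kmers.PWM.from_consensus(k.get("consensus", sites.optimal_site))
    cycles = synthetic.generate_selex_reads(
        pwm, n_reads=k.get("n_reads", 800),
        read_length=k.get("read_length", 24),
        n_cycles=k.get("n_cycles", 2),
        temperature=k.get("temperature", 2.0), seed=config.seed,
        site=sites.site_with_sin, site_freq=k.get("site_freq", 0.02))
    fasta_paths = []
    for i, reads in enumerate(cycles):
        p = out / f"selex_cycle{i}.fasta"
        io.write_fasta(reads, p)
        fasta_paths.append(p)
    table = kmers.canonical_kmer_counts(io.read_fasta(fasta_paths[-1]),
                                        k.get("k", 10), cycle="last")
    kmer_path = out / "kmer_counts.tsv"
    with open(kmer_path, "w") as fh:
        fh.write("kmer\tcount\tcycle\n")
        for kmer, count in sorted(table.counts.items(),
                                  key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{kmer}\t{count}\t{table.cycle}\n")
    counts = kmers.count_site_reads(cycles[-1], sites)
    site_path = out / "site_counts.json"
    payload = dataclasses.asdict(counts)
    if counts.n_with_only + counts.n_without_only > 0:
        stat, p_chi2, p_exact = kmers.mcnemar_test(counts)
        payload.update({"mcnemar_statistic": stat, "mcnemar_p": p_chi2,
                        "exact_p": p_exact})
    site_path.write_text(json.dumps(payload, indent=1))
    record("kmer", *fasta_paths, kmer_path, site_path)

    # --- haplotype scan -----------------------------------------------------
    pg = config.popgen
    haps = synthetic.generate_haplotypes(
        n_haps=pg.get("n_haps", 60), n_sites=pg.get("n_sites", 81),
        focal_index=pg.get("focal_index", 40),
        derived_freq=pg.get("derived_freq", 0.25),
        sweep_strength=pg.get("sweep_strength", 20.0), seed=config.seed)
    hap_path = out / "haplotypes.vcf"
    io.write_haplotype_vcf(haps, hap_path)
    haps_rt = io.read_haplotype_vcf(hap_path)
    rows = []
    iehh_by_class = {}
    for cls, name in ((popgen.DERIVED, "derived"),
                      (popgen.ANCESTRAL, "ancestral")):
        profile = popgen.ehh(haps_rt, cls)
        iehh_by_class[name] = popgen.iehh(profile,
                                          pg.get("threshold", 0.05))
        for d, v in zip(profile.left_distances, profile.left_ehh):
            rows.append((name, "left", int(d), v))
        for d, v in zip(profile.right_distances, profile.right_ehh):
            rows.append((name, "right", int(d), v))
    ehh_path = out / "ehh_profile.tsv"
    with open(ehh_path, "w") as fh:
        fh.write("allele\tdirection\tdistance_bp\tehh\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    ihs_path = out / "ihs.json"
    ihs_path.write_text(json.dumps(
        {"iehh_derived": iehh_by_class["derived"],
         "iehh_ancestral": iehh_by_class["ancestral"],
         "ihs": popgen.ihs(iehh_by_class["derived"],
                           iehh_by_class["ancestral"])}, indent=1))
    record("popgen", hap_path, ehh_path, ihs_path)

    # --- behavior -----------------------------------------------------------
    b = config.behavior
    trials: List[behavior.TrialCounts] = []
    for i in range(b.get("n_lines_sin", 4)):
        trials += synthetic.generate_tmaze_trials(
            b.get("n_trials", 5), b.get("n_flies", 100),
            b.get("green_prob_sin", 0.45), seed=config.seed + i,
            line_id=f"sin_{i}", has_insertion=True)
    for i in range(b.get("n_lines_nosin", 4)):
        trials += synthetic.generate_tmaze_trials(
            b.get("n_trials", 5), b.get("n_flies", 100),
            b.get("green_prob_nosin", 0.55), seed=config.seed + 1000 + i,
            line_id=f"nosin_{i}", has_insertion=False)
    trials_path = out / "trials.tsv"
    io.write_trials_tsv(trials, trials_path)
    loaded = io.read_trials_tsv(trials_path)
    by_line: Dict[str, list] = {}
    for t in loaded:
        by_line.setdefault(t.line_id, []).append(t)
    line_rows = []
    import warnings as _warnings
    for line_id, line_trials in sorted(by_line.items()):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            pi = behavior.line_mean_pi(line_trials)
        line_rows.append((line_id, line_trials[0].has_insertion, pi.value,
                          pi.sem, pi.n_trials))
    means_sin = [r[2] for r in line_rows if r[1]]
    means_nosin = [r[2] for r in line_rows if r[1] is False]
    diff, p = behavior.group_compare(means_sin, means_nosin)
    pi_path = out / "preference.tsv"
    with open(pi_path, "w") as fh:
        fh.write("line_id\thas_insertion\tmean_pi\tsem\tn_trials\n")
        for r in line_rows:
            fh.write("\t".join(map(str, r)) + "\n")
        fh.write(f"# group_difference={diff}\tp={p}\n")
    record("behavior", trials_path, pi_path)

    # resolved config + manifest beside the outputs
    config_path = out / "resolved_config.yaml"
    config_path.write_text(yaml.safe_dump(config.to_dict()))
    record("config", config_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
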
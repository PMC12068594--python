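"""End-to-end orchestration: config validation, staged runs, manifest.

The demo run is fully synthetic and deterministic under its seed; every
stage writes plain-text outputs plus a JSON manifest with parameters and
SHA-256 checksums, so identical configs yield identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from regconverge import __version__, convergence, expression, motifs, sexchrom
from regconverge import promoters as prom
from regconverge import synthetic
from regconverge.errors import InputError

log = logging.getLogger("regconverge")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    upstream: int = 2000
    downstream: int = 1000
    fdr_alpha: float = 0.05
    lfc_cut: float = 1.0
    alpha: float = 0.05
    min_mean_tpm: float = 1.0
    n_perm: int = 10_000
    k_clusters: int = 9
    reference_species: str = ""
    genome: str = ""
    gff: str = ""
    motifs: str = ""
    motif_dialect: str = "jaspar"
    counts: str = ""
    tree: str = ""
    color_genes: str = ""

    def validate(self) -> None:
        if not 0 < self.fdr_alpha <= 1:
            raise InputError(f"fdr_alpha {self.fdr_alpha} outside (0,1]")
        if not 0 < self.alpha <= 1:
            raise InputError(f"alpha {self.alpha} outside (0,1]")
        if self.lfc_cut < 0:
            raise InputError("lfc_cut must be >= 0")
        if self.upstream < 0 or self.downstream < 1:
            raise InputError("bad promoter window")
        if self.n_perm < 1:
            raise InputError("n_perm must be >= 1")
        if self.k_clusters < 1:
            raise InputError("k_clusters must be >= 1")
        if self.motif_dialect not in ("jaspar", "meme"):
            raise InputError(f"unknown motif dialect {self.motif_dialect!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class Manifest:
    version: str
    seed: int
    parameters: dict
    outputs: dict = field(default_factory=dict)

    def add(self, name: str, path: Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def run_demo(out_dir, seed: int = 0, n_perm: int = 2000) -> Manifest:
    """Fully synthetic end-to-end run; returns the output manifest."""
    cfg = RunConfig(out_dir=str(out_dir), seed=seed, n_perm=n_perm)
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = seed
    manifest = Manifest(
        version=__version__, seed=seed, parameters={**asdict(cfg)}
    )

    # --- synthetic inputs -------------------------------------------------
    log.info("stage=synthetic generating genome/annotation/motifs/counts")
    genome = synthetic.generate_genome(
        n_contigs=2, contig_lengths=[60_000, 60_000], gc_fraction=0.45, seed=rng_seed
    )
    models = synthetic.generate_gene_models(
        genome, n_genes=8, isoforms_per_gene=2, strand_mix=0.5, seed=rng_seed + 1
    )
    pwm = motifs.PWM(
        tf_id="TF_demo",
        matrix=np.eye(4)[[0, 1, 2, 3, 0, 0, 2, 3, 1, 0]] * 100,
        pseudocount=0.5,
    )
    copies = {("gene_1", "TF_demo"): 3, ("gene_2", "TF_demo"): 1}
    genome, truth = synthetic.plant_motifs(
        genome, models, {"TF_demo": pwm}, copies, seed=rng_seed + 2
    )
    counts, lengths, chroms, de_truth = synthetic.generate_counts(
        n_genes=400,
        groups={"grp1": 3, "grp2": 3},
        de_fraction=0.1,
        dispersion=0.05,
        seed=rng_seed + 3,
    )
    synthetic.write_fasta(genome, out / "genome.fa")
    synthetic.write_gff3(models, out / "annotation.gff3")
    synthetic.write_counts_tsv(counts, lengths, chroms, out / "counts.tsv")
    truth.to_json(out / "truth_motifs.json")
    de_truth.to_json(out / "truth_de.json")
    for n in ("genome.fa", "annotation.gff3", "counts.tsv",
              "truth_motifs.json", "truth_de.json"):
        manifest.add(n, out / n)

    # --- promoters + scan -------------------------------------------------
    log.info("stage=promoters extracting windows")
    regions = prom.extract_promoters(
        genome, models, upstream=cfg.upstream, downstream=cfg.downstream
    )
    prom.write_promoter_fasta(regions, out / "promoters.fa")
    prom.write_promoter_bed(regions, out / "promoters.bed")
    manifest.add("promoters.fa", out / "promoters.fa")
    manifest.add("promoters.bed", out / "promoters.bed")

    log.info("stage=scan scoring %d promoters", len(regions))
    hits = motifs.scan_promoters(
        regions, [pwm], alpha_raw=1e-3, background="uniform"
    )
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    manifest.add("hits.tsv", out / "hits.tsv")
    gene_ids = sorted({m.gene_id for m in models})
    bsm = motifs.binding_strength(
        hits, tf_ids=[pwm.tf_id], gene_ids=gene_ids, fdr_alpha=cfg.fdr_alpha
    )
    bsm.to_tsv(out / "binding_counts.tsv", out / "binding_mask.tsv")
    manifest.add("binding_counts.tsv", out / "binding_counts.tsv")
    manifest.add("binding_mask.tsv", out / "binding_mask.tsv")

    # --- expression -------------------------------------------------------
    log.info("stage=expression TPM/UQ/DEG")
    tpm_tab = expression.tpm(counts, lengths)
    norm = expression.upper_quartile_normalize(tpm_tab)
    expressed = expression.filter_expressed(norm, cfg.min_mean_tpm)
    groups = {s: s.rsplit("_", 1)[0] for s in counts.columns}
    deg_table = expression.de_test_standin(counts, groups, chromosome=chroms)
    degs = expression.deg_filter(deg_table, cfg.lfc_cut, cfg.alpha)
    deg_table.to_csv(out / "deg_table.tsv", sep="\t", index=False)
    manifest.add("deg_table.tsv", out / "deg_table.tsv")
    log.info("stage=expression expressed=%d degs=%d", len(expressed), len(degs))

    # --- sex chromosomes --------------------------------------------------
    universe = pd.DataFrame(
        {"gene_id": counts.index, "chromosome": chroms.reindex(counts.index)}
    )
    universe = universe[universe["gene_id"].isin(expressed)]
    deg_in_universe = [g for g in degs if g in set(universe["gene_id"])]
    ratio_report = sexchrom.chromosome_ratios(deg_in_universe, universe)
    perm = sexchrom.permutation_enrichment_test(
        ratio_report, n_perm=cfg.n_perm, seed=rng_seed + 4
    )
    ratio_report.as_frame().to_csv(out / "chrom_ratios.tsv", sep="\t", index=False)
    with open(out / "sexchrom_test.json", "w") as fh:
        json.dump(asdict(perm), fh, indent=2)
    manifest.add("chrom_ratios.tsv", out / "chrom_ratios.tsv")
    manifest.add("sexchrom_test.json", out / "sexchrom_test.json")

    # --- convergence ------------------------------------------------------
    log.info("stage=convergence species set + report")
    newick = "((zf:0.2,sf:0.2):1.0,((sp1:0.2,sp2:0.2):1.0,(sp3:0.2,sp4:0.2):1.0):1.0);"
    mats, conv_truth = synthetic.generate_species_set(
        newick,
        profile_noise=1.0,
        convergent_pair=("zf", "sp1"),
        convergence_strength=0.9,
        seed=rng_seed + 5,
        n_genes=20,
    )
    report = convergence.convergence_report(
        mats,
        newick,
        phenotype_labels={"zf": "bright", "sp1": "bright", "sf": "dull",
                          "sp2": "dull", "sp3": "dull", "sp4": "dull"},
        reference_species="zf",
    )
    report["species_table"].to_csv(out / "convergence_species.tsv", sep="\t",
                                   index=False)
    payload = {
        "reference": report["reference"],
        "pcc_distance_spearman": report["pcc_distance_spearman"],
        "pairwise_spearman": report["pairwise_spearman"],
        "top_nonsister_pair": list(report["top_nonsister_pair"] or ()),
        "convergent_pair_flagged": report["convergent_pair_flagged"],
        "phenotype_pattern": report["phenotype_pattern"],
        "planted_pair": list(conv_truth.convergent_pair or ()),
    }
    with open(out / "convergence_report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    manifest.add("convergence_species.tsv", out / "convergence_species.tsv")
    manifest.add("convergence_report.json", out / "convergence_report.json")

    manifest.write(out / "manifest.json")
    return manifest


def run_all(config: RunConfig) -> Manifest:
    """Run the configured stages on user inputs; currently the synthetic demo
    path is the reference implementation, used when no inputs are supplied."""
    config.validate()
    if not (config.genome or config.counts):
        return run_demo(config.out_dir, seed=config.seed, n_perm=config.n_perm)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(version=__version__, seed=config.seed,
                        parameters=asdict(config))
    regions = None
    if config.genome and config.gff:
        log.info("stage=promoters")
        import pyfaidx

        genome = pyfaidx.Fasta(config.genome)
        models = prom.parse_annotation(config.gff)
        regions = prom.extract_promoters(
            genome, models, config.upstream, config.downstream
        )
        prom.write_promoter_fasta(regions, out / "promoters.fa")
        manifest.add("promoters.fa", out / "promoters.fa")
        if config.motifs:
            log.info("stage=scan")
            pwms = motifs.load_pwms(config.motifs, config.motif_dialect)
            hits = motifs.scan_promoters(regions, pwms, alpha_raw=1e-3)
            hits.to_csv(out / "hits.tsv", sep="\t", index=False)
            manifest.add("hits.tsv", out / "hits.tsv")
            bsm = motifs.binding_strength(
                hits,
                tf_ids=[p.tf_id for p in pwms],
                gene_ids=sorted({m.gene_id for m in models}),
                fdr_alpha=config.fdr_alpha,
            )
            bsm.to_tsv(out / "binding_counts.tsv", out / "binding_mask.tsv")
            manifest.add("binding_counts.tsv", out / "binding_counts.tsv")
            manifest.add("binding_mask.tsv", out / "binding_mask.tsv")
    if config.counts:
        log.info("stage=expression")
        counts, lengths, chroms = synthetic.read_counts_tsv(config.counts)
        tpm_tab = expression.tpm(counts, lengths)
        norm = expression.upper_quartile_normalize(tpm_tab)
        expressed = expression.filter_expressed(norm, config.min_mean_tpm)
        pd.Series(expressed, name="gene_id").to_csv(
            out / "expressed_genes.tsv", sep="\t", index=False
        )
        manifest.add("expressed_genes.tsv", out / "expressed_genes.tsv")
    manifest.write(out / "manifest.json")
    return manifest
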
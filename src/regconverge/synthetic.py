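"""Synthetic genomes, annotations, counts, and species sets with planted truth.

Every generator is deterministic under its seed and records what it planted
(:class:`SyntheticTruth`), so each downstream stage has a closed-loop test:
planted motif copies must be recovered by the scanner, planted fold changes
by the DE filter, and the planted convergent species pair by the
convergence report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from regconverge.convergence import load_tree, sister_pairs
from regconverge.errors import GenerationError, InputError
from regconverge.motifs import PWM, BindingStrengthMatrix
from regconverge.promoters import GeneModel
from regconverge.seq import revcomp

NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedHit:
    gene_id: str
    transcript_id: str
    tf_id: str
    offset: int  # 0-based within the sense-oriented promoter window
    strand: str


@dataclass
class SyntheticTruth:
    seed: int
    planted_hits: list[PlantedHit] = field(default_factory=list)
    true_de_genes: dict[str, float] = field(default_factory=dict)
    chromosome_assignment: dict[str, str] = field(default_factory=dict)
    convergent_pair: tuple[str, str] | None = None

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["planted_hits"] = [asdict(h) for h in self.planted_hits]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def generate_genome(
    n_contigs: int,
    contig_lengths: Sequence[int],
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, str]:
    """I.i.d. nucleotide contigs with expected GC content ``gc_fraction``."""
    if n_contigs < 1 or len(contig_lengths) != n_contigs:
        raise InputError("need one positive length per contig")
    if any(length < 1 for length in contig_lengths):
        raise InputError("contig lengths must be >= 1")
    if not 0 < gc_fraction < 1:
        raise InputError("gc_fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    probs = [at, gc, gc, at]  # A C G T
    return {
        f"contig_{i + 1}": "".join(rng.choice(NUCS, size=length, p=probs))
        for i, length in enumerate(contig_lengths)
    }


def generate_gene_models(
    genome: Mapping[str, str],
    n_genes: int,
    isoforms_per_gene: int = 1,
    strand_mix: float = 0.5,
    seed: int = 0,
    gene_length: int = 600,
    margin: int = 3200,
    tss_jitter: int = 150,
) -> list[GeneModel]:
    """Place non-overlapping gene/mRNA records on the contigs.

    ``margin`` keeps each gene at least that far from both contig ends so
    default 2 kb / 1 kb promoter windows stay untruncated; spacing between
    genes is at least two margins so promoter windows never overlap.
    Isoform TSSs are jittered within ``tss_jitter`` of the gene start,
    mirroring multi-isoform promoter inclusion. Returns one
    :class:`GeneModel` per transcript.
    """
    if n_genes < 1 or isoforms_per_gene < 1:
        raise InputError("n_genes and isoforms_per_gene must be >= 1")
    if not 0 <= strand_mix <= 1:
        raise InputError("strand_mix must be a proportion")
    rng = np.random.default_rng(seed)
    slot = gene_length + 2 * margin
    slots: list[tuple[str, int]] = []  # (contig, 1-based gene start)
    for contig in sorted(genome):
        clen = len(genome[contig])
        pos = margin + 1
        while pos + gene_length - 1 + margin <= clen:
            slots.append((contig, pos))
            pos += slot
    if len(slots) < n_genes:
        raise GenerationError(
            f"cannot pack {n_genes} genes: only {len(slots)} slots with "
            f"margin={margin}, gene_length={gene_length}"
        )
    models: list[GeneModel] = []
    for gi in range(n_genes):
        contig, gstart = slots[gi]
        strand = "+" if rng.random() < strand_mix else "-"
        gend = gstart + gene_length - 1
        jitters = [0] + sorted(
            rng.integers(1, max(tss_jitter, 2), size=isoforms_per_gene - 1).tolist()
        )
        gene_id = f"gene_{gi + 1}"
        for ti, j in enumerate(jitters):
            if strand == "+":
                start, end = gstart + j, gend
            else:
                start, end = gstart, gend - j
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t{ti + 1}",
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    chromosome=contig,
                )
            )
    return models


def plant_motifs(
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    tf_pwms: Mapping[str, PWM],
    copies: Mapping[tuple[str, str], int],
    seed: int = 0,
    upstream: int = 2000,
    downstream: int = 1000,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Write PWM consensus sequences at recorded offsets inside promoters.

    Copies are planted in the promoter window of the FIRST transcript of
    each requested gene, on the transcript's sense strand, at offsets drawn
    without overlap (against all plants in that window). Returns the edited
    genome and the truth log.
    """
    by_gene: dict[str, GeneModel] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, m)
    contigs = {c: list(s) for c, s in genome.items()}
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    occupied: dict[str, list[tuple[int, int]]] = {}

    for (gene_id, tf_id), n_copies in sorted(copies.items()):
        if n_copies < 0:
            raise InputError("copy counts must be >= 0")
        if n_copies == 0:
            continue
        if gene_id not in by_gene:
            raise InputError(f"unknown gene {gene_id!r}")
        if tf_id not in tf_pwms:
            raise InputError(f"unknown TF {tf_id!r}")
        m = by_gene[gene_id]
        pwm = tf_pwms[tf_id]
        cons = pwm.consensus
        L = len(cons)
        clen = len(contigs[m.contig])
        t = m.tss0
        if m.strand == "+":
            lo, hi = t - upstream, t + downstream
        else:
            lo, hi = t - downstream + 1, t + upstream + 1
        lo, hi = max(lo, 0), min(hi, clen)
        wlen = hi - lo
        if wlen < L:
            raise GenerationError(f"{gene_id}: promoter window shorter than motif")
        taken = occupied.setdefault(m.transcript_id, [])
        placed = 0
        attempts = 0
        while placed < n_copies:
            attempts += 1
            if attempts > 200 * n_copies:
                raise GenerationError(
                    f"{gene_id}/{tf_id}: cannot place {n_copies} non-overlapping "
                    f"copies of a {L}-mer in a {wlen}-nt window"
                )
            off = int(rng.integers(0, wlen - L + 1))
            if any(off < e and o < off + L for o, e in taken):
                continue
            taken.append((off, off + L))
            if m.strand == "+":
                gstart = lo + off
                contigs[m.contig][gstart : gstart + L] = list(cons)
            else:
                gstart = hi - off - L
                contigs[m.contig][gstart : gstart + L] = list(revcomp(cons))
            truth.planted_hits.append(
                PlantedHit(
                    gene_id=gene_id,
                    transcript_id=m.transcript_id,
                    tf_id=tf_id,
                    offset=off,
                    strand="+",
                )
            )
            placed += 1
    return {c: "".join(s) for c, s in contigs.items()}, truth


def generate_counts(
    n_genes: int,
    groups: Mapping[str, int],
    base_mean: float = 100.0,
    dispersion: float = 0.1,
    de_fraction: float = 0.0,
    true_lfc_magnitude: float = 2.0,
    chrom_labels: Sequence[str] | None = None,
    chrom_probs: Sequence[float] | None = None,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (500, 3000),
) -> tuple[pd.DataFrame, pd.Series, pd.Series, SyntheticTruth]:
    """Negative-binomial count matrix with planted group-2 fold changes.

    Variance follows mean/dispersion: var = mu + dispersion * mu^2. A
    ``de_fraction`` of genes get their second-group mean scaled by
    2^(+-true_lfc_magnitude) (random sign). Returns (counts, lengths,
    chromosomes, truth).
    """
    if dispersion <= 0:
        raise InputError("dispersion must be positive")
    if base_mean <= 0:
        raise InputError("base_mean must be positive")
    if not 0 <= de_fraction <= 1:
        raise InputError("de_fraction must be a proportion")
    group_names = sorted(groups)
    if len(group_names) != 2:
        raise InputError("generate_counts expects exactly 2 groups")
    if any(groups[g] < 1 for g in group_names):
        raise InputError("each group needs >= 1 replicate")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i + 1}" for i in range(n_genes)]
    labels = (
        list(chrom_labels)
        if chrom_labels is not None
        else [str(i) for i in range(1, 11)] + ["Z", "W"]
    )
    probs = None
    if chrom_probs is not None:
        probs = np.asarray(chrom_probs, dtype=float)
        probs = probs / probs.sum()
    chroms = pd.Series(
        rng.choice(labels, size=n_genes, p=probs), index=genes, name="chromosome"
    )
    lengths = pd.Series(
        rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=n_genes),
        index=genes,
        name="length",
    )
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = signs * true_lfc_magnitude

    r = 1.0 / dispersion  # NB shape; var = mu + mu^2/r
    cols = {}
    for g in group_names:
        mu = base_mean * (2.0**lfc if g == group_names[1] else np.ones(n_genes))
        for rep in range(groups[g]):
            p = r / (r + mu)
            cols[f"{g}_{rep + 1}"] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(cols, index=genes)
    truth = SyntheticTruth(
        seed=seed,
        true_de_genes={genes[i]: float(lfc[i]) for i in de_idx},
        chromosome_assignment=dict(chroms),
    )
    return counts, lengths, chroms, truth


def generate_species_set(
    tree: str | dendropy.Tree,
    profile_noise: float = 1.0,
    convergent_pair: tuple[str, str] | None = None,
    convergence_strength: float = 0.0,
    seed: int = 0,
    n_tfs: int = 3,
    n_genes: int = 10,
    base_scale: float = 10.0,
) -> tuple[dict[str, BindingStrengthMatrix], SyntheticTruth]:
    """Per-species binding matrices evolved by Brownian motion along the tree.

    Matrix cells start from a root profile ~ Uniform(0, base_scale) and gain
    Normal(0, profile_noise^2 * branch_length) increments along each edge.
    The convergent pair's leaves are additionally pulled toward one shared
    profile: leaf = (1-w) * evolved + w * shared, w = convergence_strength.
    Final matrices are rounded and clipped to non-negative integer counts.
    """
    if profile_noise < 0:
        raise InputError("profile_noise must be >= 0")
    if not 0 <= convergence_strength <= 1:
        raise InputError("convergence_strength must be in [0,1]")
    t = load_tree(tree)
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    if len(leaves) != len(set(leaves)):
        raise InputError("tree leaves must be uniquely named")
    if convergent_pair is not None:
        a, b = convergent_pair
        if a not in leaves or b not in leaves:
            raise InputError(f"convergent pair {convergent_pair} not in tree")
        if frozenset({a, b}) in sister_pairs(t):
            raise InputError("convergent pair must be non-sister leaves")
    rng = np.random.default_rng(seed)
    shape = (n_tfs, n_genes)
    root_profile = rng.uniform(0, base_scale, size=shape)
    shared = rng.uniform(0, base_scale, size=shape)

    evolved: dict[int, np.ndarray] = {id(t.seed_node): root_profile}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        blen = node.edge.length if node.edge.length is not None else 1.0
        parent = evolved[id(node.parent_node)]
        step = rng.normal(0.0, profile_noise * np.sqrt(max(blen, 0.0)), size=shape)
        evolved[id(node)] = parent + step

    tf_ids = [f"TF{i + 1}" for i in range(n_tfs)]
    gene_ids = [f"cg_{j + 1}" for j in range(n_genes)]
    matrices: dict[str, BindingStrengthMatrix] = {}
    pair = set(convergent_pair or ())
    for lf in t.leaf_node_iter():
        prof = evolved[id(lf)]
        if lf.taxon.label in pair:
            prof = (1 - convergence_strength) * prof + convergence_strength * shared
        counts = np.clip(np.round(prof), 0, None).astype(int)
        matrices[lf.taxon.label] = BindingStrengthMatrix(
            counts=pd.DataFrame(counts, index=tf_ids, columns=gene_ids),
            annotated=pd.Series(True, index=gene_ids),
        )
    truth = SyntheticTruth(seed=seed, convergent_pair=convergent_pair)
    return matrices, truth


# ---------------------------------------------------------------------------
# Writers (plain-text interchange)


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            s = genome[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gff3(models: Sequence[GeneModel], path) -> None:
    """GFF3 with gene features spanning their transcripts plus mRNA children."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(by_gene):
            txs = by_gene[gid]
            contig, strand = txs[0].contig, txs[0].strand
            gstart = min(m.start for m in txs)
            gend = max(m.end for m in txs)
            fh.write(
                f"{contig}\tsynthetic\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                f"ID={gid}\n"
            )
            for m in txs:
                fh.write(
                    f"{m.contig}\tsynthetic\tmRNA\t{m.start}\t{m.end}\t.\t"
                    f"{m.strand}\t.\tID={m.transcript_id};Parent={gid}\n"
                )


def write_counts_tsv(
    counts: pd.DataFrame, lengths: pd.Series, chroms: pd.Series, path
) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index))
    out.insert(1, "chromosome", chroms.reindex(counts.index))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("length")
    chroms = df.pop("chromosome").astype(str)
    return df, lengths, chroms


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")
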
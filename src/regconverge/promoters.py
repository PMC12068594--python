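"""Genome + annotation parsing and strand-aware promoter-window extraction.

Promoter windows span ``upstream`` bases 5' of the transcription start site
through ``downstream`` bases 3' of it (TSS included in the downstream
segment), defaulting to 2000/1000 so an untruncated window is 3000 nt.
Coordinates follow two conventions, deliberately kept apart:

* GFF3 / :class:`GeneModel` — 1-based, inclusive.
* :class:`PromoterRegion` windows — 0-based, half-open, on the genomic
  forward strand; the stored sequence is oriented 5'->3' on the
  transcript's sense strand (reverse-complemented for '-' genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils

from regconverge.errors import InputError, LookupError_, ParseError
from regconverge.seq import contig_length, fetch, revcomp


@dataclass(frozen=True)
class GeneModel:
    """One transcript (or bare gene) from the annotation."""

    gene_id: str
    transcript_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    chromosome: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ParseError(
                f"{self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def tss0(self) -> int:
        """0-based genomic coordinate of the transcription start site."""
        return self.start - 1 if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    transcript_id: str
    contig: str
    window_start: int  # 0-based half-open, forward strand
    window_end: int
    strand: str
    sequence: str  # sense-strand oriented
    truncated: bool

    def __post_init__(self):
        if len(self.sequence) != self.window_end - self.window_start:
            raise InputError("sequence length != window length")

    @property
    def header(self) -> str:
        return (
            f"{self.gene_id}|{self.transcript_id}|"
            f"{self.contig}:{self.window_start}-{self.window_end}({self.strand})"
        )

    def genomic_position(self, offset: int, length: int = 1) -> int:
        """Map a 0-based offset in the sense-oriented sequence to the 0-based
        genomic start of the ``length``-nt segment it begins."""
        if self.strand == "+":
            return self.window_start + offset
        return self.window_end - offset - length


@dataclass(frozen=True)
class AssemblyStats:
    scaffold_n50: int
    n_scaffolds: int

    def __post_init__(self):
        if self.scaffold_n50 <= 0 or self.n_scaffolds <= 0:
            raise InputError("assembly stats must be positive")


@dataclass
class FilterDecision:
    passed: bool
    reasons: list[str] = field(default_factory=list)


def parse_annotation(
    gff3,
    chromosome_map: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Parse GFF3 into one :class:`GeneModel` per transcript.

    ``gff3`` may be a path, a file object, or the raw GFF3 text. Genes with
    no mRNA/transcript children yield a single model from the gene feature
    itself. A transcript whose ``Parent`` is not a gene in the file is a
    :class:`ParseError`; so are inverted coordinates.

    ``chromosome_map`` maps contig names to chromosome labels (autosome
    number, 'Z', 'W'); by default the contig name is used verbatim.
    """
    if hasattr(gff3, "read"):
        text = gff3.read()
    elif isinstance(gff3, str) and "\n" in gff3:
        text = gff3
    else:
        with open(gff3) as fh:
            text = fh.read()

    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types
        raise ParseError(f"could not parse GFF3: {exc}") from exc

    cmap = dict(chromosome_map or {})
    genes = {f.id: f for f in db.features_of_type("gene")}
    models: list[GeneModel] = []
    seen_tx: set[str] = set()
    errors: list[str] = []
    genes_with_tx: set[str] = set()

    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            parents = tx.attributes.get("Parent", [])
            if not parents or parents[0] not in genes:
                errors.append(
                    f"{tx.id}: Parent {parents or '(none)'} not a gene in this file"
                )
                continue
            gene = genes[parents[0]]
            if tx.start > tx.end:
                errors.append(f"{tx.id}: start {tx.start} > end {tx.end}")
                continue
            if tx.id in seen_tx:
                errors.append(f"{tx.id}: duplicate transcript id")
                continue
            seen_tx.add(tx.id)
            genes_with_tx.add(gene.id)
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    transcript_id=tx.id,
                    contig=tx.seqid,
                    start=tx.start,
                    end=tx.end,
                    strand=tx.strand,
                    chromosome=cmap.get(tx.seqid, tx.seqid),
                )
            )

    if errors:
        raise ParseError("annotation errors:\n" + "\n".join(errors))

    for gid, gene in genes.items():
        if gid in genes_with_tx:
            continue
        models.append(
            GeneModel(
                gene_id=gid,
                transcript_id=gid,
                contig=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                chromosome=cmap.get(gene.seqid, gene.seqid),
            )
        )
    return models


def extract_promoters(
    genome,
    models: Iterable[GeneModel],
    upstream: int = 2000,
    downstream: int = 1000,
) -> list[PromoterRegion]:
    """Extract the promoter window of every model, clipping at contig bounds.

    For a '+' transcript with 0-based TSS t the window is
    ``[t - upstream, t + downstream)``; for a '-' transcript it is
    ``[t - downstream + 1, t + upstream + 1)`` and the sequence is
    reverse-complemented, so both strands see the same 5'->3' layout:
    ``upstream`` bases, then the TSS, then ``downstream - 1`` more bases.
    """
    if upstream < 0 or downstream < 1:
        raise InputError("need upstream >= 0 and downstream >= 1")
    regions = []
    for m in models:
        try:
            clen = contig_length(genome, m.contig)
        except KeyError as exc:
            raise LookupError_(f"contig {m.contig!r} not in genome") from exc
        t = m.tss0
        if m.strand == "+":
            lo, hi = t - upstream, t + downstream
        else:
            lo, hi = t - downstream + 1, t + upstream + 1
        clo, chi = max(lo, 0), min(hi, clen)
        if chi <= clo:
            raise InputError(
                f"{m.transcript_id}: promoter window [{lo},{hi}) misses contig"
            )
        seq = fetch(genome, m.contig, clo, chi)
        if m.strand == "-":
            seq = revcomp(seq)
        regions.append(
            PromoterRegion(
                gene_id=m.gene_id,
                transcript_id=m.transcript_id,
                contig=m.contig,
                window_start=clo,
                window_end=chi,
                strand=m.strand,
                sequence=seq,
                truncated=(clo != lo or chi != hi),
            )
        )
    return regions


def assembly_filter(stats: AssemblyStats) -> FilterDecision:
    """Strict assembly-quality gate: N50 > 500 kb AND scaffolds < 30,000."""
    reasons = []
    if not stats.scaffold_n50 > 500_000:
        reasons.append(f"scaffold N50 {stats.scaffold_n50} not > 500000")
    if not stats.n_scaffolds < 30_000:
        reasons.append(f"{stats.n_scaffolds} scaffolds not < 30000")
    return FilterDecision(passed=not reasons, reasons=reasons)


def write_promoter_fasta(regions: Sequence[PromoterRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.header}\n{r.sequence}\n")


def write_promoter_bed(regions: Sequence[PromoterRegion], path) -> None:
    """BED6 of the genomic windows (score column = 0)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.contig}\t{r.window_start}\t{r.window_end}\t"
                f"{r.gene_id}|{r.transcript_id}\t0\t{r.strand}\n"
            )


def read_promoter_fasta(path_or_handle) -> list[PromoterRegion]:
    """Read promoters back from the FASTA written by :func:`write_promoter_fasta`."""
    if hasattr(path_or_handle, "read"):
        fh = path_or_handle
        close = False
    else:
        fh = open(path_or_handle)
        close = True
    try:
        regions = []
        header, chunks = None, []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    regions.append(_region_from_header(header, "".join(chunks)))
                header, chunks = line[1:], []
            else:
                chunks.append(line)
        if header is not None:
            regions.append(_region_from_header(header, "".join(chunks)))
        return regions
    finally:
        if close:
            fh.close()


def _region_from_header(header: str, seq: str) -> PromoterRegion:
    try:
        gene_id, transcript_id, loc = header.split("|")
        contig, rest = loc.rsplit(":", 1)
        span, strand = rest.rstrip(")").rsplit("(", 1)
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except (ValueError, IndexError) as exc:
        raise ParseError(f"bad promoter FASTA header: {header!r}") from exc
    return PromoterRegion(
        gene_id=gene_id,
        transcript_id=transcript_id,
        contig=contig,
        window_start=start,
        window_end=end,
        strand=strand,
        sequence=seq,
        truncated=False,  # not recoverable from the FASTA; callers needing it keep BED
    )
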
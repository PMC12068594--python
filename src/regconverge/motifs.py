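"""PWM motif scanning with exact background p-values and FDR-counted hits.

The scan scores every offset of a promoter on both strands with a log-odds
(bits) position weight matrix. Per-position scores are discretized onto a
fixed grid (default 1e-4 bits) so window scores are exact integers; the
null score distribution of a random background window is then obtained by
dynamic programming (one convolution per motif position), giving an exact
p-value P[S >= s] for every attainable score. Benjamini-Hochberg adjustment
is applied over the family of all scored windows of a scan run, and the
binding-strength matrix counts, per (TF, gene), the hits with padj below
the FDR threshold.

Positions containing N score -infinity and can never become hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from regconverge.errors import InputError, ParseError
from regconverge.promoters import PromoterRegion

ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}
UNIFORM_BG = np.full(4, 0.25)

#: sentinel integer for a -infinity per-position score (N or zero probability)
NEG_SENTINEL = np.int64(-(10**12))


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over ACGT.

    ``matrix`` holds one row per motif position (shape L x 4) of counts or
    probabilities; ``pseudocount`` is added per cell before normalization;
    ``background`` is the null nucleotide distribution.
    """

    tf_id: str
    matrix: np.ndarray
    pseudocount: float = 0.0
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ParseError(f"{self.tf_id}: PWM must be L x 4, got {m.shape}")
        if np.any(m < 0):
            raise ParseError(f"{self.tf_id}: negative PWM entries")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be >= 0")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1) > 1e-8:
            raise InputError("background must be a strictly positive 4-simplex point")
        col_tot = m.sum(axis=1) + 4 * self.pseudocount
        if np.any(col_tot <= 0):
            raise ParseError(
                f"{self.tf_id}: all-zero PWM column with zero pseudocount"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Pseudocount-regularized per-position probabilities (rows sum to 1)."""
        m = self.matrix + self.pseudocount
        return m / m.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probabilities, axis=1))

    def reverse_complement(self) -> "PWM":
        return replace(self, matrix=self.matrix[::-1, ::-1].copy())

    def with_background(self, background: np.ndarray) -> "PWM":
        return replace(self, background=np.asarray(background, dtype=float))


@dataclass
class MotifHit:
    tf_id: str
    gene_id: str
    transcript_id: str
    offset: int  # 0-based in the sense-oriented promoter sequence
    strand: str  # strand within the window: '+' sense, '-' antisense
    score: float  # log-odds bits
    pvalue: float
    padj: float | None = None
    contig: str = ""
    genomic_start: int = -1  # 0-based forward-strand start, -1 if unknown


@dataclass
class BindingStrengthMatrix:
    """TF x gene matrix of FDR-passing hit counts plus an annotation mask.

    ``annotated[g]`` is False for genes absent from the species' annotation:
    their cells carry no information (mask), which is different from a
    scanned gene with zero hits.
    """

    counts: pd.DataFrame  # index: tf_ids, columns: gene_ids, int
    annotated: pd.Series  # index: gene_ids, bool

    def __post_init__(self):
        self.counts = self.counts.astype(int)
        self.annotated = self.annotated.astype(bool).reindex(
            self.counts.columns, fill_value=False
        )
        if (self.counts.values < 0).any():
            raise InputError("negative binding counts")
        masked = ~self.annotated
        if masked.any() and self.counts.loc[:, masked].to_numpy().any():
            raise InputError("unannotated gene carries nonzero counts")

    def to_tsv(self, counts_path, mask_path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.annotated.rename("annotated").to_csv(mask_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, mask_path) -> "BindingStrengthMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        mask = pd.read_csv(mask_path, sep="\t", index_col=0)["annotated"]
        return cls(counts=counts, annotated=mask)


# ---------------------------------------------------------------------------
# PWM loading


def load_pwms(stream, dialect: str, pseudocount: float = 0.5,
              background: np.ndarray | None = None) -> list[PWM]:
    """Load all motifs from a JASPAR (.jaspar/.pfm) or MEME-minimal stream."""
    if dialect not in ("jaspar", "meme"):
        raise InputError(f"unknown motif dialect {dialect!r}")
    if hasattr(stream, "read"):
        handle = stream
    else:
        handle = open(stream)
    fmt = "jaspar" if dialect == "jaspar" else "minimal"
    try:
        records = bio_motifs.parse(handle, fmt)
        parsed = list(records)
    except Exception as exc:
        raise ParseError(f"could not parse {dialect} motifs: {exc}") from exc
    finally:
        if handle is not stream:
            handle.close()
    if not parsed:
        raise ParseError("no motifs found in input")
    bg = UNIFORM_BG if background is None else background
    out = []
    for m in parsed:
        counts = np.array(
            [[float(m.counts[b][i]) for b in ALPHABET] for i in range(m.length)]
        )
        name = m.matrix_id if getattr(m, "matrix_id", None) else m.name
        out.append(PWM(tf_id=str(name), matrix=counts, pseudocount=pseudocount,
                       background=np.asarray(bg, dtype=float)))
    return out


def load_pwm(stream, dialect: str, pseudocount: float = 0.5,
             background: np.ndarray | None = None) -> PWM:
    """Load a single motif; error if the stream holds more than one."""
    pwms = load_pwms(stream, dialect, pseudocount, background)
    if len(pwms) != 1:
        raise ParseError(f"expected exactly one motif, found {len(pwms)}")
    return pwms[0]


# ---------------------------------------------------------------------------
# Scoring


def log_odds(pwm: PWM) -> np.ndarray:
    """Per-position log2-odds scores in bits; -inf where probability is 0."""
    p = pwm.probabilities
    with np.errstate(divide="ignore"):
        return np.log2(p / pwm.background)


class ScoreModel:
    """Discretized log-odds scores plus the exact null score distribution.

    Scores are rounded to multiples of ``precision`` bits; the distribution
    of the integer window score under i.i.d. background draws is built by
    convolving the four-point per-position distributions. ``pvalue`` is the
    exact survival function P[S >= s] on that grid.
    """

    def __init__(self, pwm: PWM, precision: float = 1e-4):
        if precision <= 0:
            raise InputError("precision must be positive")
        self.pwm = pwm
        self.precision = precision
        lo = log_odds(pwm)
        finite = np.isfinite(lo)
        iscores = np.full(lo.shape, NEG_SENTINEL, dtype=np.int64)
        iscores[finite] = np.round(lo[finite] / precision).astype(np.int64)
        self.int_scores = iscores
        self._build_null()

    def _build_null(self) -> None:
        bg = self.pwm.background
        # dist over integer scores, kept as (offset, probs array)
        probs = np.array([1.0])
        base = 0
        finite_mass = 1.0
        for row in self.int_scores:
            fin = row != NEG_SENTINEL
            if not fin.any():
                finite_mass = 0.0
                break
            vals = row[fin]
            ps = bg[fin]
            finite_mass *= ps.sum()
            lo_v, hi_v = int(vals.min()), int(vals.max())
            new = np.zeros(len(probs) + (hi_v - lo_v), dtype=float)
            for v, p in zip(vals, ps):
                sh = int(v) - lo_v
                new[sh : sh + len(probs)] += p * probs
            probs = new
            base += lo_v
        if finite_mass == 0.0:
            self._support_min = 0
            self._sf = np.array([0.0])
        else:
            self._support_min = base
            # survival function: sf[i] = P[S >= base + i]
            self._sf = probs[::-1].cumsum()[::-1]
        self._finite_mass = finite_mass

    @property
    def max_int_score(self) -> int:
        return self._support_min + len(self._sf) - 1

    def pvalue(self, int_score: int) -> float:
        """Exact P[S >= int_score] for a background window; 1.0 at -inf."""
        if int_score <= NEG_SENTINEL:
            return 1.0
        # finite thresholds below the support floor keep the whole finite mass
        i = max(int(int_score) - self._support_min, 0)
        if i >= len(self._sf):
            return 0.0
        return float(min(self._sf[i], 1.0))

    def pvalues(self, int_scores: np.ndarray) -> np.ndarray:
        out = np.ones(len(int_scores), dtype=float)
        s = np.asarray(int_scores, dtype=np.int64)
        valid = s > NEG_SENTINEL
        idx = s[valid] - self._support_min
        idx = np.clip(idx, 0, None)
        vals = np.empty(idx.shape, dtype=float)
        vals[idx >= len(self._sf)] = 0.0
        mid = idx < len(self._sf)
        vals[mid] = np.minimum(self._sf[idx[mid]], 1.0)
        out[valid] = vals
        return out


def score_pvalue(pwm: PWM, score_bits: float, precision: float = 1e-4) -> float:
    """Exact background p-value of a window score given in bits."""
    model = ScoreModel(pwm, precision)
    if score_bits == -np.inf:
        return 1.0
    return model.pvalue(int(np.round(score_bits / precision)))


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for c, i in _IDX.items():
        out[arr == ord(c)] = i
    return out


def _window_int_scores(enc: np.ndarray, iscores: np.ndarray) -> np.ndarray:
    """Integer score of every offset; windows touching N get the sentinel."""
    L = iscores.shape[0]
    n = len(enc) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    # pad score table with a sentinel column for N (index 4)
    table = np.hstack([iscores, np.full((L, 1), NEG_SENTINEL)])
    win = np.lib.stride_tricks.sliding_window_view(enc, L)  # (n, L)
    per_pos = table[np.arange(L)[None, :], win]  # (n, L)
    bad = (per_pos == NEG_SENTINEL).any(axis=1)
    total = per_pos.sum(axis=1)
    total[bad] = NEG_SENTINEL
    return total


def scan(
    promoter: PromoterRegion,
    pwm: PWM,
    alpha_raw: float = 1.0,
    model: ScoreModel | None = None,
    precision: float = 1e-4,
) -> list[MotifHit]:
    """Score every offset on both strands; return windows with p <= alpha_raw.

    A motif longer than the window yields an empty list with a warning.
    N-containing windows never hit regardless of ``alpha_raw``.
    """
    if not 0 <= alpha_raw <= 1:
        raise InputError("alpha_raw must be in [0,1]")
    if model is None:
        model = ScoreModel(pwm, precision)
    L = len(pwm)
    if L > len(promoter.sequence):
        warnings.warn(
            f"motif {pwm.tf_id} (len {L}) longer than window "
            f"{promoter.transcript_id} (len {len(promoter.sequence)})",
            stacklevel=2,
        )
        return []
    enc = _encode(promoter.sequence)
    rc_iscores = model.int_scores[::-1, ::-1]
    hits: list[MotifHit] = []
    for strand, iscores in (("+", model.int_scores), ("-", rc_iscores)):
        totals = _window_int_scores(enc, iscores)
        pvals = model.pvalues(totals)
        keep = (totals > NEG_SENTINEL) & (pvals <= alpha_raw)
        for off in np.nonzero(keep)[0]:
            hits.append(
                MotifHit(
                    tf_id=pwm.tf_id,
                    gene_id=promoter.gene_id,
                    transcript_id=promoter.transcript_id,
                    offset=int(off),
                    strand=strand,
                    score=float(totals[off]) * model.precision,
                    pvalue=float(pvals[off]),
                    contig=promoter.contig,
                    genomic_start=promoter.genomic_position(int(off), L),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Multiple testing and aggregation


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("pvalues must be 1-D")
    if len(p) == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("pvalues must lie in [0,1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def promoter_background(promoters: Iterable[PromoterRegion]) -> np.ndarray:
    """Nucleotide composition of the promoter set (N excluded), as the scan null."""
    counts = np.zeros(4)
    for p in promoters:
        enc = _encode(p.sequence)
        for i in range(4):
            counts[i] += int((enc == i).sum())
    if counts.sum() == 0:
        raise InputError("promoter set has no ACGT content")
    bg = counts / counts.sum()
    return np.clip(bg, 1e-9, None) / np.clip(bg, 1e-9, None).sum()


def scan_promoters(
    promoters: Sequence[PromoterRegion],
    pwms: Sequence[PWM],
    alpha_raw: float = 1.0,
    background: str | np.ndarray = "promoters",
    precision: float = 1e-4,
) -> pd.DataFrame:
    """Scan every promoter with every PWM and BH-adjust per-TF over all windows.

    The FDR family for each TF is *every scored window of the run* (both
    strands, all promoters, N-windows included at p=1), the most conservative
    reproducible choice. Returns a hit table (rows: windows with
    ``pvalue <= alpha_raw``) with a ``padj`` column.
    """
    if isinstance(background, str):
        if background == "promoters":
            bg = promoter_background(promoters)
        elif background == "uniform":
            bg = UNIFORM_BG
        else:
            raise InputError(f"unknown background {background!r}")
    else:
        bg = np.asarray(background, dtype=float)

    frames = []
    for pwm in pwms:
        pwm_bg = pwm.with_background(bg)
        model = ScoreModel(pwm_bg, precision)
        all_pvals: list[np.ndarray] = []
        all_hits: list[MotifHit] = []
        hit_pos: list[int] = []  # index of each hit within the family
        cursor = 0
        for prom in promoters:
            if len(pwm_bg) > len(prom.sequence):
                continue
            hits = scan(prom, pwm_bg, alpha_raw=1.0, model=model)
            enc_n = (len(prom.sequence) - len(pwm_bg) + 1) * 2
            # rebuild the full family of window p-values for this promoter
            enc = _encode(prom.sequence)
            fam = np.concatenate(
                [
                    model.pvalues(_window_int_scores(enc, model.int_scores)),
                    model.pvalues(
                        _window_int_scores(enc, model.int_scores[::-1, ::-1])
                    ),
                ]
            )
            assert len(fam) == enc_n
            all_pvals.append(fam)
            for h in hits:
                if h.pvalue <= alpha_raw:
                    base = cursor if h.strand == "+" else cursor + enc_n // 2
                    hit_pos.append(base + h.offset)
                    all_hits.append(h)
            cursor += enc_n
        if not all_pvals:
            continue
        family = np.concatenate(all_pvals)
        padj = bh_fdr(family)
        rows = []
        for h, i in zip(all_hits, hit_pos):
            h.padj = float(padj[i])
            rows.append(vars(h))
        if rows:
            frames.append(pd.DataFrame(rows))
    if not frames:
        return pd.DataFrame(
            columns=[
                "tf_id", "gene_id", "transcript_id", "offset", "strand",
                "score", "pvalue", "padj", "contig", "genomic_start",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def binding_strength(
    hits: pd.DataFrame,
    tf_ids: Sequence[str],
    gene_ids: Sequence[str],
    annotated: Mapping[str, bool] | None = None,
    fdr_alpha: float = 0.05,
    dedupe_genomic: bool = True,
) -> BindingStrengthMatrix:
    """Count FDR-passing hits into a TF x gene matrix.

    Hits from isoform promoters that share genomic sequence are deduplicated
    by genomic coordinate (same contig/start/strand counted once per gene)
    when ``dedupe_genomic`` and coordinates are available. Genes with
    ``annotated[g]`` False are masked, not zero.
    """
    if not 0 < fdr_alpha <= 1:
        raise InputError("fdr_alpha must be in (0,1]")
    ann = pd.Series(
        {g: (annotated.get(g, True) if annotated else True) for g in gene_ids}
    )
    counts = pd.DataFrame(0, index=list(tf_ids), columns=list(gene_ids), dtype=int)
    if len(hits):
        kept = hits[hits["padj"] < fdr_alpha].copy()
        kept = kept[kept["gene_id"].isin(gene_ids) & kept["tf_id"].isin(tf_ids)]
        if dedupe_genomic and "genomic_start" in kept.columns:
            with_coord = kept[kept["genomic_start"] >= 0]
            without = kept[kept["genomic_start"] < 0]
            with_coord = with_coord.drop_duplicates(
                subset=["tf_id", "gene_id", "contig", "genomic_start", "strand"]
            )
            kept = pd.concat([with_coord, without])
        tab = kept.groupby(["tf_id", "gene_id"]).size()
        for (tf, g), n in tab.items():
            counts.loc[tf, g] = int(n)
    counts.loc[:, ~ann.reindex(counts.columns, fill_value=False)] = 0
    return BindingStrengthMatrix(counts=counts, annotated=ann)
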
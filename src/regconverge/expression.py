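"""Expression-side processing: TPM, upper-quartile normalization, expressed-gene
filter, DEG thresholding, set intersections, and Ward.D2 clustering.

All threshold comparisons are strict (mean TPM > 1, |log2FC| > 1,
padj < 0.05): boundary rows are excluded.

The differential-expression test here is an explicitly labeled stand-in
(t-test on log-transformed normalized counts with BH adjustment) so the
pipeline runs end-to-end; externally produced DEG tables are first-class
inputs and take precedence when supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from regconverge.errors import InputError

DEG_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj", "chromosome"]


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: per sample, rate = count / length_kb, scaled to 1e6.

    ``counts`` is genes x samples; ``lengths`` is bp per gene.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise InputError(f"genes without lengths: {missing} ...")
    if (lengths <= 0).any():
        raise InputError("gene lengths must be positive bp")
    if (counts.values < 0).any():
        raise InputError("negative counts")
    rate = counts.div(lengths / 1e3, axis=0)
    totals = rate.sum(axis=0)
    dead = totals[totals == 0]
    if len(dead):
        raise InputError(f"all-zero samples, TPM undefined: {list(dead.index)}")
    return rate.div(totals, axis=1) * 1e6


def upper_quartile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample so its upper quartile over its nonzero genes equals
    the geometric mean of the per-sample upper quartiles."""
    uqs = {}
    for s in matrix.columns:
        col = matrix[s]
        nz = col[col > 0]
        if len(nz) < 4:
            raise InputError(f"sample {s!r} has <4 nonzero genes; UQ undefined")
        uqs[s] = float(np.percentile(nz, 75))
    uq = pd.Series(uqs)
    if (uq <= 0).any():
        raise InputError("non-positive upper quartile")
    target = float(np.exp(np.mean(np.log(uq))))
    return matrix.mul(target / uq, axis=1)


def filter_expressed(matrix: pd.DataFrame, min_mean_tpm: float = 1.0) -> list[str]:
    """Genes whose mean across libraries is strictly above the threshold."""
    means = matrix.mean(axis=1)
    return list(matrix.index[means > min_mean_tpm])


def de_test_standin(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    chromosome: Mapping[str, str] | pd.Series | None = None,
    pseudocount: float = 1.0,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Two-group differential-expression stand-in (NOT a negative-binomial
    Wald model): upper-quartile normalize, log2(x+pseudocount), then a
    moderated two-sided t-test whose per-gene variance is shrunk toward the
    mean gene variance with ``prior_df`` pseudo-degrees of freedom (needed
    for usable power at 2-3 replicates), BH adjustment. log2fc is the log2
    ratio of normalized group means (group 2 over group 1,
    pseudocount-stabilized).

    ``groups`` maps sample -> group label; exactly two labels, each with >= 2
    replicates (otherwise an error advising external statistics).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise InputError("every sample needs a group label")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise InputError(f"need exactly 2 groups, got {labels}")
    g1 = counts.columns[groups == labels[0]]
    g2 = counts.columns[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise InputError(
            "single-replicate group: the stand-in t-test needs >=2 replicates "
            "per group; supply an externally computed DEG table instead"
        )
    norm = upper_quartile_normalize(counts.astype(float))
    logm = np.log2(norm + pseudocount)
    x1, x2 = logm[g1].to_numpy(), logm[g2].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    df_resid = n1 + n2 - 2
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    s2_prior = float(np.mean(s2))
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    se = np.sqrt(s2_mod * (1 / n1 + 1 / n2))
    delta = x2.mean(axis=1) - x1.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, delta / se, 0.0)
    pval = 2 * sps.t.sf(np.abs(tstat), df=prior_df + df_resid)
    pval = np.where(np.isnan(pval), 1.0, pval)
    m1 = norm[g1].mean(axis=1)
    m2 = norm[g2].mean(axis=1)
    lfc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    from regconverge.motifs import bh_fdr

    padj = bh_fdr(pval)
    chrom = pd.Series(dict(chromosome)) if chromosome is not None else None
    table = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": lfc.to_numpy(),
            "pvalue": pval,
            "padj": padj,
            "chromosome": (
                chrom.reindex(counts.index).fillna("").to_numpy()
                if chrom is not None
                else ""
            ),
        }
    ).reset_index(drop=True)
    return table


def deg_filter(
    table: pd.DataFrame, lfc_cut: float = 1.0, alpha: float = 0.05
) -> list[str]:
    """DEGs: (log2fc > lfc_cut or log2fc < -lfc_cut) and padj < alpha, all strict."""
    if len(table) == 0:
        return []
    lfc = table["log2fc"].to_numpy(dtype=float)
    padj = table["padj"].to_numpy(dtype=float)
    keep = ((lfc > lfc_cut) | (lfc < -lfc_cut)) & (padj < alpha)
    return list(table.loc[keep, "gene_id"])


def intersect_gene_sets(sets: Mapping[str, set]) -> dict:
    """Pairwise and full intersections with cardinalities, deterministically ordered."""
    names = sorted(sets)
    report = {
        "sets": {n: sorted(sets[n]) for n in names},
        "sizes": {n: len(sets[n]) for n in names},
        "pairwise": {},
        "full_intersection": sorted(set.intersection(*map(set, sets.values())))
        if sets
        else [],
    }
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = sorted(set(sets[a]) & set(sets[b]))
            report["pairwise"][f"{a}&{b}"] = {"genes": inter, "size": len(inter)}
    return report


def transform_for_clustering(
    counts: pd.DataFrame, pseudocount: float = 1.0, normalize: bool = True
) -> pd.DataFrame:
    """Shifted-log stand-in for a regularized-log transform:
    log2(UQ-normalized count + pseudocount). Flagged via .attrs."""
    if (counts.values < 0).any():
        raise InputError("negative counts")
    mat = upper_quartile_normalize(counts.astype(float)) if normalize else counts
    out = np.log2(mat + pseudocount)
    out.attrs["transform"] = "shifted-log2 (stand-in for regularized-log)"
    return out


@dataclass
class ClusterAssignment:
    labels: pd.Series  # item -> 1..k
    k: int
    axis: str
    method: str = "ward.d2"
    linkage_matrix: np.ndarray | None = None

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def ward_cluster(
    matrix: pd.DataFrame, k: int, axis: str = "genes"
) -> ClusterAssignment:
    """Agglomerative clustering with the Ward.D2 criterion (squared-Euclidean
    merge cost, Lance-Williams update), cut into k flat clusters.

    ``axis='genes'`` clusters rows, ``axis='samples'`` clusters columns.
    """
    if axis not in ("genes", "samples"):
        raise InputError("axis must be 'genes' or 'samples'")
    X = matrix.to_numpy(dtype=float) if axis == "genes" else matrix.to_numpy().T
    names = matrix.index if axis == "genes" else matrix.columns
    n = X.shape[0]
    if k < 1 or k > n:
        raise InputError(f"k={k} outside 1..{n}")
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber clusters by first appearance so labels are order-deterministic
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    return ClusterAssignment(
        labels=pd.Series(labels, index=names),
        k=k,
        axis=axis,
        linkage_matrix=Z,
    )


def read_deg_table(path) -> pd.DataFrame:
    """Read an externally produced DEG TSV (gene, log2fc, pvalue, padj[, chromosome])."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want, aliases in {
        "gene_id": ("gene_id", "gene"),
        "log2fc": ("log2fc", "log2foldchange", "lfc"),
        "pvalue": ("pvalue", "p"),
        "padj": ("padj", "fdr", "qvalue"),
        "chromosome": ("chromosome", "chrom", "chr"),
    }.items():
        for a in aliases:
            if a in cols:
                rename[cols[a]] = want
                break
    df = df.rename(columns=rename)
    missing = {"gene_id", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise InputError(f"DEG table missing columns: {sorted(missing)}")
    if "pvalue" not in df.columns:
        df["pvalue"] = df["padj"]
    if "chromosome" not in df.columns:
        df["chromosome"] = ""
    return df[DEG_COLUMNS]
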
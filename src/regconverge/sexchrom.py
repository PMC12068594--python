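"""Per-chromosome DEG ratios, label-permutation enrichment test, and
dosage-effect classification of Z-linked male-biased DEGs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from regconverge.errors import InputError

SEX_CHROMOSOMES = frozenset({"Z", "W"})


@dataclass(frozen=True)
class ChromRatio:
    chromosome: str
    n_genes: int
    n_degs: int
    ratio: float
    chrom_class: str  # 'sex' or 'autosome'


@dataclass
class RatioReport:
    ratios: list[ChromRatio]
    excluded_chromosomes: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.ratios])


@dataclass
class PermutationResult:
    statistic: float
    pvalue: float
    n_perm: int
    seed: int
    alternative: str


def _classify_chrom(label: str) -> str | None:
    """'sex' for Z/W, 'autosome' for numeric labels, None for unplaced."""
    lab = str(label).strip()
    if lab.upper() in SEX_CHROMOSOMES:
        return "sex"
    if lab.isdigit():
        return "autosome"
    return None


def chromosome_ratios(degs, universe: pd.DataFrame) -> RatioReport:
    """Per-chromosome DEG fraction over the expressed-gene universe.

    ``universe`` needs columns gene_id and chromosome (every expressed gene).
    DEGs absent from the universe are an error; genes on unplaced scaffolds
    are excluded and reported.
    """
    if not {"gene_id", "chromosome"} <= set(universe.columns):
        raise InputError("universe needs gene_id and chromosome columns")
    deg_set = set(degs)
    missing = deg_set - set(universe["gene_id"])
    if missing:
        raise InputError(f"DEGs missing from universe: {sorted(missing)[:10]}")
    ratios: list[ChromRatio] = []
    excluded: list[str] = []
    for chrom, sub in universe.groupby("chromosome", sort=True):
        cls = _classify_chrom(chrom)
        if cls is None:
            excluded.append(str(chrom))
            continue
        n = len(sub)
        d = int(sub["gene_id"].isin(deg_set).sum())
        ratios.append(
            ChromRatio(
                chromosome=str(chrom),
                n_genes=n,
                n_degs=d,
                ratio=d / n,
                chrom_class=cls,
            )
        )
    return RatioReport(ratios=ratios, excluded_chromosomes=excluded)


def permutation_enrichment_test(
    ratios: list[ChromRatio] | RatioReport,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationResult:
    """Label-permutation test of mean(sex ratios) - mean(autosome ratios).

    The null reassigns the sex/autosome class labels across chromosomes.
    When the number of distinct label assignments C(n, n_sex) is at most
    ``n_perm`` the null is enumerated exactly and
    p = #{assignments with stat as or more extreme} / #assignments (the
    observed labeling is one of them, so p > 0). Otherwise ``n_perm``
    random assignments are drawn and p = (1 + #extreme) / (1 + n_perm).
    One-sided 'greater' (sex > autosome) by default; 'two-sided' available.
    """
    if isinstance(ratios, RatioReport):
        ratios = ratios.ratios
    if alternative not in ("greater", "two-sided"):
        raise InputError("alternative must be 'greater' or 'two-sided'")
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value grid", stacklevel=2)
    vals = np.array([r.ratio for r in ratios], dtype=float)
    is_sex = np.array([r.chrom_class == "sex" for r in ratios])
    n_sex = int(is_sex.sum())
    n_auto = len(vals) - n_sex
    if n_sex < 1 or n_auto < 1:
        raise InputError("need at least one sex and one autosome chromosome")
    observed = float(vals[is_sex].mean() - vals[~is_sex].mean())
    n = len(vals)

    n_exact = comb(n, n_sex)
    if n_exact <= n_perm:
        sex_idx = np.array(list(combinations(range(n), n_sex)))
        exact = True
    else:
        rng = np.random.default_rng(seed)
        # first n_sex positions of each random shuffle
        sex_idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_sex]
        exact = False
    sex_means = vals[sex_idx].mean(axis=1)
    auto_means = (vals.sum() - vals[sex_idx].sum(axis=1)) / n_auto
    null = sex_means - auto_means
    tol = 1e-12 * max(1.0, abs(observed))
    if alternative == "greater":
        hits = int((null >= observed - tol).sum())
    else:
        hits = int((np.abs(null) >= abs(observed) - tol).sum())
    if exact:
        p = hits / n_exact
    else:
        p = (1 + hits) / (1 + n_perm)
    return PermutationResult(
        statistic=observed,
        pvalue=float(min(p, 1.0)),
        n_perm=int(n_exact if exact else n_perm),
        seed=seed,
        alternative=alternative,
    )


def classify_dosage(
    z_degs: pd.DataFrame,
    lower: float = 1.0,
    upper: float = 1.5,
    strong_cut: float = 2.0,
) -> pd.DataFrame:
    """Classify Z-linked male-biased DEGs by |log2FC|.

    dosage: lower < |lfc| <= upper; exceeds_dosage: |lfc| > upper;
    strong_male_biased flag additionally marks |lfc| > strong_cut.
    Non-Z rows (when a chromosome column is present) and rows with
    |lfc| <= lower (not male-biased DEGs) are errors.
    """
    if "chromosome" in z_degs.columns:
        bad = z_degs[~z_degs["chromosome"].astype(str).str.upper().eq("Z")]
        if len(bad):
            raise InputError(
                f"non-Z genes in dosage input: {list(bad['gene_id'])[:10]}"
            )
    lfc = z_degs["log2fc"].to_numpy(dtype=float)
    a = np.abs(lfc)
    if (a <= lower).any():
        offenders = list(z_degs.loc[a <= lower, "gene_id"])[:10]
        raise InputError(f"|log2fc| <= {lower} rows are not DEGs: {offenders}")
    cls = np.where(a > upper, "exceeds_dosage", "dosage")
    return pd.DataFrame(
        {
            "gene_id": z_degs["gene_id"].to_numpy(),
            "abs_log2fc": a,
            "dosage_class": cls,
            "strong_male_biased": a > strong_cut,
        }
    )
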
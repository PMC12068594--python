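"""Cross-species comparison of binding-strength matrices on a phylogeny.

Species profiles are compared by Pearson correlation over the (TF, gene)
cells annotated in both species, flattened TF-major/gene-minor. The
convergence report attaches each species' correlation-to-reference and
patristic distance, computes the rank correlation between similarity and
distance, and flags the signature of convergent regulatory evolution: a
non-sister pair whose mutual correlation exceeds that of every sister
(cherry) pair — similarity that phylogeny alone does not predict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from regconverge.errors import InputError, LookupError_
from regconverge.motifs import BindingStrengthMatrix

MIN_COMMON_CELLS = 3


@dataclass
class AlignmentReport:
    n_cells: int
    n_common: int
    dropped_cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.n_cells - self.n_common


@dataclass
class SpeciesProfile:
    species: str
    matrix: BindingStrengthMatrix
    pcc_vs_reference: float | None = None
    n_common_cells: int = 0
    note: str = ""


def align_profiles(
    reference: BindingStrengthMatrix, other: BindingStrengthMatrix
) -> tuple[np.ndarray, np.ndarray, AlignmentReport]:
    """Flatten both matrices over cells unmasked in BOTH species.

    Cells run TF-major, gene-minor over the shared TFs and the union of
    genes; a gene missing or unannotated in either species drops all its
    cells, tallied in the report.
    """
    tfs = [t for t in reference.counts.index if t in other.counts.index]
    if not tfs:
        raise InputError("no shared TFs between profiles")
    genes = sorted(set(reference.counts.columns) | set(other.counts.columns))
    ok_ref = {
        g for g in reference.counts.columns if bool(reference.annotated.get(g, False))
    }
    ok_other = {
        g for g in other.counts.columns if bool(other.annotated.get(g, False))
    }
    common_genes = [g for g in genes if g in ok_ref and g in ok_other]
    dropped = [
        (t, g) for t in tfs for g in genes if g not in ok_ref or g not in ok_other
    ]
    x = reference.counts.loc[tfs, common_genes].to_numpy(dtype=float).ravel()
    y = other.counts.loc[tfs, common_genes].to_numpy(dtype=float).ravel()
    report = AlignmentReport(
        n_cells=len(tfs) * len(genes),
        n_common=len(tfs) * len(common_genes),
        dropped_cells=dropped,
    )
    return x, y, report


def _pcc(x: np.ndarray, y: np.ndarray) -> tuple[float | None, str]:
    if len(x) < MIN_COMMON_CELLS:
        return None, f"only {len(x)} common cells (< {MIN_COMMON_CELLS})"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, "constant vector"
    r = float(np.corrcoef(x, y)[0, 1])
    return r, ""


def pairwise_pcc(
    matrices: Mapping[str, BindingStrengthMatrix], log1p: bool = False
) -> pd.DataFrame:
    """Symmetric species x species Pearson-correlation table (NaN when undefined)."""
    names = sorted(matrices)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        out.loc[a, a] = 1.0
    for a, b in combinations(names, 2):
        x, y, _ = align_profiles(matrices[a], matrices[b])
        if log1p:
            x, y = np.log1p(x), np.log1p(y)
        r, _note = _pcc(x, y)
        out.loc[a, b] = out.loc[b, a] = np.nan if r is None else r
    return out


def pcc_vs_reference(
    matrices: Mapping[str, BindingStrengthMatrix],
    reference_species: str,
    log1p: bool = False,
) -> list[SpeciesProfile]:
    """Pearson correlation of every species' profile against the reference."""
    if reference_species not in matrices:
        raise LookupError_(f"reference species {reference_species!r} missing")
    ref = matrices[reference_species]
    profiles = []
    for sp in sorted(matrices):
        if sp == reference_species:
            profiles.append(
                SpeciesProfile(
                    species=sp,
                    matrix=ref,
                    pcc_vs_reference=1.0,
                    n_common_cells=int(ref.annotated.sum()) * len(ref.counts.index),
                )
            )
            continue
        x, y, rep = align_profiles(ref, matrices[sp])
        if log1p:
            x, y = np.log1p(x), np.log1p(y)
        r, note = _pcc(x, y)
        profiles.append(
            SpeciesProfile(
                species=sp,
                matrix=matrices[sp],
                pcc_vs_reference=r,
                n_common_cells=rep.n_common,
                note=note,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Phylogeny helpers


def load_tree(newick: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(newick, dendropy.Tree):
        return newick
    if "(" in newick:
        return dendropy.Tree.get(data=newick, schema="newick")
    return dendropy.Tree.get(path=newick, schema="newick")


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf x leaf branch-length distances; topological (edge-count) fallback
    with a warning when the tree carries no branch lengths."""
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    has_lengths = any(
        e.length is not None for e in tree.preorder_edge_iter() if e.head_node.parent_node
    )
    if not has_lengths:
        warnings.warn("tree has no branch lengths; using topological distances",
                      stacklevel=2)
    pdm = tree.phylogenetic_distance_matrix()
    out = pd.DataFrame(0.0, index=sorted(taxa), columns=sorted(taxa))
    for a, b in combinations(sorted(taxa), 2):
        ta = tree.taxon_namespace.get_taxon(a)
        tb = tree.taxon_namespace.get_taxon(b)
        d = (
            pdm.patristic_distance(ta, tb)
            if has_lengths
            else pdm.path_edge_count(ta, tb)
        )
        out.loc[a, b] = out.loc[b, a] = float(d)
    return out


def sister_pairs(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Leaf pairs that form cherries (share an immediate parent node)."""
    pairs = set()
    for node in tree.preorder_node_iter():
        leaves = [c for c in node.child_nodes() if c.is_leaf()]
        for a, b in combinations(leaves, 2):
            pairs.add(frozenset({a.taxon.label, b.taxon.label}))
    return pairs


# ---------------------------------------------------------------------------
# Report


def convergence_report(
    matrices: Mapping[str, BindingStrengthMatrix],
    tree: str | dendropy.Tree,
    phenotype_labels: Mapping[str, str] | None = None,
    reference_species: str | None = None,
    log1p: bool = False,
) -> dict:
    """Rank species by profile similarity and flag phylogeny-discordant pairs.

    Returns a dict with: per-species table (PCC to reference, patristic
    distance to reference, phenotype), the Spearman rank correlation between
    PCC and distance, the full pairwise PCC matrix, the top-correlated
    non-sister pair and whether it is flagged as convergent (its mutual PCC
    beats every sister pair's), and a descriptive note on the
    phenotype/distance pattern.
    """
    t = load_tree(tree)
    dist = patristic_distances(t)
    missing = sorted(set(matrices) - set(dist.index))
    if missing:
        raise LookupError_(f"species missing from tree: {missing}")
    species = sorted(matrices)
    if reference_species is None:
        reference_species = species[0]
    pheno = dict(phenotype_labels or {})

    profiles = pcc_vs_reference(matrices, reference_species, log1p=log1p)
    rows = []
    for p in profiles:
        rows.append(
            {
                "species": p.species,
                "pcc_vs_reference": p.pcc_vs_reference,
                "distance_to_reference": float(
                    dist.loc[reference_species, p.species]
                ),
                "phenotype": pheno.get(p.species, ""),
                "n_common_cells": p.n_common_cells,
                "note": p.note,
            }
        )
    table = pd.DataFrame(rows)

    others = table[table["species"] != reference_species].dropna(
        subset=["pcc_vs_reference"]
    )
    if (
        len(others) >= 3
        and others["distance_to_reference"].nunique() > 1
        and others["pcc_vs_reference"].nunique() > 1
    ):
        rho, rho_p = sps.spearmanr(
            others["pcc_vs_reference"], others["distance_to_reference"]
        )
    else:
        rho, rho_p = float("nan"), float("nan")

    pcc_mat = pairwise_pcc(matrices, log1p=log1p)
    sisters = sister_pairs(t)
    pair_rows = []
    for a, b in combinations(species, 2):
        r = pcc_mat.loc[a, b]
        pair_rows.append(
            {
                "a": a,
                "b": b,
                "pcc": float(r) if pd.notna(r) else None,
                "distance": float(dist.loc[a, b]),
                "sister": frozenset({a, b}) in sisters,
            }
        )
    pairs = pd.DataFrame(pair_rows)
    # pooled rank correlation over all pairs (distance vs similarity)
    defined = pairs.dropna(subset=["pcc"])
    if (
        len(defined) >= 3
        and defined["distance"].nunique() > 1
        and defined["pcc"].nunique() > 1
    ):
        pair_rho, pair_rho_p = sps.spearmanr(defined["pcc"], defined["distance"])
    else:
        pair_rho, pair_rho_p = float("nan"), float("nan")

    nonsister = defined[~defined["sister"]]
    sister_df = defined[defined["sister"]]
    flagged = False
    top_pair = None
    if len(nonsister):
        best = nonsister.loc[nonsister["pcc"].idxmax()]
        top_pair = (best["a"], best["b"])
        if len(sister_df):
            flagged = bool(best["pcc"] > sister_df["pcc"].max())
        else:
            close = defined[defined["distance"] <= defined["distance"].median()]
            flagged = bool(len(close) and best["pcc"] > close["pcc"].max())

    note = _phenotype_pattern_note(table, reference_species)
    return {
        "reference": reference_species,
        "species_table": table,
        "pcc_distance_spearman": {"rho": float(rho), "pvalue": float(rho_p)},
        "pairwise_spearman": {"rho": float(pair_rho), "pvalue": float(pair_rho_p)},
        "pairwise_pcc": pcc_mat,
        "pair_table": pairs,
        "top_nonsister_pair": top_pair,
        "convergent_pair_flagged": flagged,
        "phenotype_pattern": note,
    }


def _phenotype_pattern_note(table: pd.DataFrame, reference: str) -> str:
    """Describe whether phenotype-matched distant species correlate worse with
    the reference than phenotype-mismatched close relatives (the pattern read
    as convergence of phenotype via divergent regulation)."""
    ref_pheno = table.loc[table["species"] == reference, "phenotype"]
    if not len(ref_pheno) or not ref_pheno.iloc[0]:
        return "no phenotype labels supplied"
    rp = ref_pheno.iloc[0]
    others = table[
        (table["species"] != reference) & table["pcc_vs_reference"].notna()
    ]
    matched = others[others["phenotype"] == rp]
    mismatched = others[(others["phenotype"] != rp) & (others["phenotype"] != "")]
    if not len(matched) or not len(mismatched):
        return "phenotype classes not both represented"
    cases = []
    for _, m in matched.iterrows():
        closer_mismatch = mismatched[
            mismatched["distance_to_reference"] < m["distance_to_reference"]
        ]
        if len(closer_mismatch) and (
            m["pcc_vs_reference"] < closer_mismatch["pcc_vs_reference"].max()
        ):
            cases.append(m["species"])
    if cases:
        return (
            "phenotype-matched distant species with lower similarity than "
            f"phenotype-mismatched close relatives: {sorted(cases)}"
        )
    return "no phenotype-discordant similarity pattern detected"
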
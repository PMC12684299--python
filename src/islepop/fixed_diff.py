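"""Differentially fixed variants between island and mainland populations.

A protein-coding site is differentially fixed when every non-missing island
genotype is homozygous for one allele, every non-missing mainland genotype
is homozygous for the other, and both populations have at least one
genotyped individual.  Genes containing any LoF variant anywhere in the
dataset are then removed, since putative pseudogenes accumulate alternative
alleles through drift alone.  Gene sets from several species can finally be
intersected to find repeatedly affected genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, DerivedMatrix, GenotypeMatrix

CODING_CATEGORIES = ("lof", "missense_deleterious", "missense_tolerated", "synonymous")

FIXED_DIFF_COLUMNS = [
    "chrom",
    "pos",
    "island_allele",
    "mainland_allele",
    "gene_id",
    "consequence",
]


def _genotype_view(mat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(codes, allele0, allele2): genotype matrix plus per-site alleles."""
    if isinstance(mat, DerivedMatrix):
        return (
            mat.dc,
            mat.sites["ancestral"].to_numpy(),
            mat.sites["derived"].to_numpy(),
        )
    if isinstance(mat, GenotypeMatrix):
        return mat.gt, mat.sites["ref"].to_numpy(), mat.sites["alt"].to_numpy()
    raise TypeError("expected GenotypeMatrix or DerivedMatrix")


def _fixed_code(sub: np.ndarray) -> np.ndarray:
    """Per-site fixation code of a population block: 0, 2, or -9 (not fixed)."""
    called = sub != MISSING
    any_called = called.any(axis=0)
    hom0 = ((sub == 0) | ~called).all(axis=0) & any_called
    hom2 = ((sub == 2) | ~called).all(axis=0) & any_called
    code = np.full(sub.shape[1], -9, dtype=np.int8)
    code[hom0] = 0
    code[hom2] = 2
    return code


def differentially_fixed(
    mat,
    island_samples: Sequence[str],
    mainland_samples: Sequence[str],
    site_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sites fixed for alternative alleles between the two populations.

    ``site_mask`` (boolean, e.g. coding sites only) restricts the scan.
    Missing genotypes do not disqualify a site; fixation is judged on the
    observed genotypes, but each population needs >= 1 called genotype.
    """
    if not island_samples or not mainland_samples:
        raise ValueError("both populations need at least one sample")
    codes, a0, a2 = _genotype_view(mat)
    isl = codes[[mat.sample_index(s) for s in island_samples]]
    mnl = codes[[mat.sample_index(s) for s in mainland_samples]]
    keep = np.ones(codes.shape[1], dtype=bool) if site_mask is None else np.asarray(site_mask, dtype=bool)

    ci = _fixed_code(isl)
    cm = _fixed_code(mnl)
    qual = keep & (ci >= 0) & (cm >= 0) & (ci != cm)
    idx = np.flatnonzero(qual)

    sites = mat.sites
    gene = sites["gene_id"].to_numpy() if "gene_id" in sites.columns else np.full(len(sites), "", object)
    cons = sites["consequence"].to_numpy() if "consequence" in sites.columns else np.full(len(sites), "", object)
    rows = {
        "chrom": sites["chrom"].to_numpy()[idx],
        "pos": sites["pos"].to_numpy()[idx],
        "island_allele": np.where(ci[idx] == 0, a0[idx], a2[idx]),
        "mainland_allele": np.where(cm[idx] == 0, a0[idx], a2[idx]),
        "gene_id": gene[idx],
        "consequence": cons[idx],
    }
    return pd.DataFrame(rows, columns=FIXED_DIFF_COLUMNS)


@dataclass
class LoFGeneFilterResult:
    """Fixed differences surviving pseudogene (LoF-containing gene) removal."""

    fixed: pd.DataFrame
    genes: set[str]
    lof_genes: set[str]


def filter_lof_genes(
    fixed: pd.DataFrame,
    site_gene_ids: Sequence[str],
    site_categories: Sequence[str],
) -> LoFGeneFilterResult:
    """Drop fixed differences in genes containing any LoF variant.

    LoF presence is judged on the combined dataset (both populations),
    matching the pseudogene rationale.  Returns the surviving fixed
    differences and their gene ids.
    """
    gene_ids = np.asarray(site_gene_ids, dtype=object)
    cats = np.asarray(site_categories, dtype=object)
    lof_genes = {str(g) for g in gene_ids[cats == "lof"]}
    keep = ~fixed["gene_id"].astype(str).isin(lof_genes)
    surviving = fixed.loc[keep].reset_index(drop=True)
    return LoFGeneFilterResult(
        fixed=surviving,
        genes=set(surviving["gene_id"].astype(str)),
        lof_genes=lof_genes,
    )


@dataclass
class OverlapTable:
    """Cross-species gene-set overlap."""

    table: pd.DataFrame  # one row per gene, one bool column per species, n_species
    shared: set[str]  # genes present in >= 2 sets
    core: set[str]  # genes present in every set


def cross_species_overlap(gene_sets: Mapping[str, Sequence[str]]) -> OverlapTable:
    """Membership table across species gene sets; >= 2 sets required."""
    if len(gene_sets) < 2:
        raise ValueError("need gene sets from at least two species")
    species = list(gene_sets)
    all_genes = sorted({str(g) for s in species for g in gene_sets[s]})
    data = {
        sp: [str(g) in {str(x) for x in gene_sets[sp]} for g in all_genes]
        for sp in species
    }
    table = pd.DataFrame(data, index=pd.Index(all_genes, name="gene_id"))
    table["n_species"] = table[species].sum(axis=1).astype(int)
    shared = set(table.index[table["n_species"] >= 2])
    core = set(table.index[table["n_species"] == len(species)])
    return OverlapTable(table=table, shared=shared, core=core)
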
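"""Mutational-effect classification and genetic-load statistics.

Derived variants are binned into four effect categories — loss-of-function
(LoF), likely-deleterious missense, tolerated missense and synonymous —
from VEP-style consequence strings, with the missense split taken at an
amino-acid experimental exchangeability (EX) score of 0.256 (inclusive on
the deleterious side).

Per-individual load is summarised two ways:

* the relative abundance of derived alleles,
  ``RA = (n_het + 2 n_hom) / (2 n_p)``, where ``n_p`` is the species-wide
  (island and mainland pooled) count of derived positions in the category.
  Under pure drift the expectation of RA is conserved through a
  bottleneck, so island/mainland RA differences diagnose selection;
* derived homozygosity ``n_hom / (n_het + n_hom)``, which rises with
  inbreeding as masked load is converted into realised load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, DerivedMatrix

#: consequence strings treated as loss-of-function
LOF_CONSEQUENCES = frozenset(
    {
        "transcript_ablation",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_region_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)

SYNONYMOUS_CONSEQUENCES = frozenset({"synonymous_variant"})
MISSENSE_CONSEQUENCES = frozenset({"missense_variant"})

#: EX score at or below which a missense variant is called deleterious
EX_DELETERIOUS_MAX = 0.256

CATEGORIES = ("lof", "missense_deleterious", "missense_tolerated", "synonymous")
EXCLUDED = "excluded"


def classify_effect(consequence: str, ex_score: float | None = None) -> str:
    """Map one picked consequence (plus EX score for missense) to a category.

    Returns one of ``CATEGORIES`` or ``"excluded"`` for consequences outside
    the coding classes of interest (UTR, intronic, intergenic, ...).
    Missense classification requires an EX score; the deleterious side of
    the split is inclusive (EX <= 0.256).
    """
    norm = consequence.strip().lower().replace(" ", "_")
    if norm in LOF_CONSEQUENCES:
        return "lof"
    if norm in SYNONYMOUS_CONSEQUENCES:
        return "synonymous"
    if norm in MISSENSE_CONSEQUENCES:
        if ex_score is None or (isinstance(ex_score, float) and math.isnan(ex_score)):
            raise ValueError(f"missense consequence {consequence!r} lacks an EX score")
        if not 0.0 <= ex_score <= 1.0:
            raise ValueError("EX score must be in [0, 1]")
        return "missense_deleterious" if ex_score <= EX_DELETERIOUS_MAX else "missense_tolerated"
    return EXCLUDED


def classify_sites(sites: pd.DataFrame) -> np.ndarray:
    """Vectorised :func:`classify_effect` over a site table.

    Expects ``consequence`` and (for missense rows) ``ex_score`` columns.
    """
    cons = sites["consequence"].astype(str)
    ex = sites["ex_score"] if "ex_score" in sites.columns else pd.Series(np.nan, index=sites.index)
    return np.array(
        [classify_effect(c, None if pd.isna(e) else float(e)) for c, e in zip(cons, ex)],
        dtype=object,
    )


def load_counts(
    dm: DerivedMatrix,
    categories: np.ndarray,
    sample: str,
    category: str,
) -> tuple[int, int, int]:
    """(n_het, n_hom, n_p) for one sample in one effect category.

    ``n_het``/``n_hom`` count the sample's non-missing derived het/hom
    genotypes; ``n_p`` counts category sites carrying a derived allele in
    *any* genome of the species (island and mainland pooled), independent
    of the focal sample.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    categories = np.asarray(categories)
    if categories.shape[0] != dm.n_sites:
        raise ValueError("category vector length != number of sites")
    in_cat = categories == category
    dc = dm.dc[:, in_cat]
    row = dc[dm.sample_index(sample)]
    n_het = int((row == 1).sum())
    n_hom = int((row == 2).sum())
    n_p = int(((dc == 1) | (dc == 2)).any(axis=0).sum())
    return n_het, n_hom, n_p


def relative_abundance(n_het: int, n_hom: int, n_p: int) -> float:
    """RA = (n_het + 2 n_hom) / (2 n_p)."""
    if n_p < 1:
        raise ValueError("n_p must be >= 1 for relative abundance")
    if n_het < 0 or n_hom < 0:
        raise ValueError("counts must be non-negative")
    return (n_het + 2 * n_hom) / (2 * n_p)


def derived_homozygosity(n_het: int, n_hom: int) -> float:
    """n_hom / (n_het + n_hom); NaN when the sample carries no derived allele."""
    if n_het < 0 or n_hom < 0:
        raise ValueError("counts must be non-negative")
    tot = n_het + n_hom
    if tot == 0:
        return float("nan")
    return n_hom / tot


def load_summary(
    dm: DerivedMatrix,
    categories: np.ndarray,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per sample x category table of load counts and statistics."""
    samples = list(dm.samples) if samples is None else list(samples)
    rows = []
    for cat in CATEGORIES:
        for s in samples:
            n_het, n_hom, n_p = load_counts(dm, categories, s, cat)
            rows.append(
                {
                    "sample": s,
                    "category": cat,
                    "n_het": n_het,
                    "n_hom": n_hom,
                    "n_p": n_p,
                    "ra": relative_abundance(n_het, n_hom, n_p) if n_p else float("nan"),
                    "derived_homozygosity": derived_homozygosity(n_het, n_hom),
                }
            )
    return pd.DataFrame(rows)


def fixed_homozygous_lof_genes(
    dm: DerivedMatrix,
    categories: np.ndarray,
    population_samples: Sequence[str],
) -> set[str]:
    """Genes with >= 1 LoF site fixed homozygous-derived in the population.

    A site qualifies when at least one population member is genotyped there
    and every non-missing genotype is homozygous derived.
    """
    if "gene_id" not in dm.sites.columns:
        raise ValueError("site table lacks gene_id column")
    idx = [dm.sample_index(s) for s in population_samples]
    if not idx:
        raise ValueError("empty population")
    categories = np.asarray(categories)
    lof_sites = np.flatnonzero(categories == "lof")
    genes: set[str] = set()
    gene_ids = dm.sites["gene_id"].to_numpy()
    sub = dm.dc[np.asarray(idx)][:, lof_sites]
    called = sub != MISSING
    any_called = called.any(axis=0)
    all_hom = ((sub == 2) | ~called).all(axis=0)
    for j in np.flatnonzero(any_called & all_hom):
        genes.add(str(gene_ids[lof_sites[j]]))
    return genes


@dataclass(frozen=True)
class GroupComparison:
    """Welch's t-test outcome, or the reason it was not testable."""

    testable: bool
    n_a: int
    n_b: int
    statistic: float = float("nan")
    pvalue: float = float("nan")
    reason: str = ""


def compare_groups(values_a: Iterable[float], values_b: Iterable[float]) -> GroupComparison:
    """Welch's unequal-variance t-test; requires N >= 3 in both groups.

    Groups smaller than three genomes are reported as not testable, with
    the reason, rather than producing an unstable test.
    """
    a = np.asarray([v for v in values_a if not math.isnan(v)], dtype=float)
    b = np.asarray([v for v in values_b if not math.isnan(v)], dtype=float)
    if len(a) < 3 or len(b) < 3:
        return GroupComparison(
            testable=False,
            n_a=len(a),
            n_b=len(b),
            reason="N < 3 genomes in one of the groups",
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        testable=True,
        n_a=len(a),
        n_b=len(b),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )
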
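"""Genotype-quality masking and outgroup-based allele polarisation.

Masking follows two per-genotype rules applied to the raw depth fields
(so the two masks commute):

* *allelic balance* — a heterozygous call whose minor-allele read fraction
  ``min(AD)/DP`` is strictly below 0.25 becomes missing;
* *depth* — any call with depth strictly below half or strictly above
  double the sample's genome-wide mean depth becomes missing, with the
  mean computed over non-missing genotypes before any masking.

Polarisation assigns ancestral/derived status from three outgroup species:
a site is kept only when all three outgroups are genotyped, homozygous,
mutually identical, and carry the site's ref or alt allele; that shared
allele is the ancestral one.  Sites with no derived allele observed in the
ingroup are then removed (sites fixed for the derived allele are kept —
they are variable relative to the ancestor and carry load information).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import MISSING, DerivedMatrix, GenotypeMatrix

OUTGROUP_COLUMNS = ("out1", "out2", "out3")


def mask_allelic_balance(
    gm: GenotypeMatrix, min_support_fraction: float = 0.25
) -> GenotypeMatrix:
    """Mask heterozygous genotypes with skewed allelic balance.

    Hets whose minor-allele read fraction is strictly below the threshold
    become missing; homozygous calls are untouched.  Idempotent.
    """
    if not 0.0 <= min_support_fraction <= 0.5:
        raise ValueError("min_support_fraction must be in [0, 0.5]")
    out = gm.copy()
    if gm.dp is None or gm.minor_ad is None:
        n_het = int((gm.gt == 1).sum())
        warnings.warn(
            f"no depth/AD fields; {n_het} heterozygous genotypes left unmasked",
            stacklevel=2,
        )
        return out
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(gm.dp > 0, gm.minor_ad / np.maximum(gm.dp, 1), np.nan)
    bad = (gm.gt == 1) & (gm.dp > 0) & (frac < min_support_fraction)
    out.gt[bad] = MISSING
    return out


def mask_depth(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Mask genotypes outside (0.5x, 2x) of the sample's mean depth.

    The per-sample genome-wide mean is computed from the raw depth field
    over sequenced genotypes (depth > 0), so it is unaffected by any other
    masking and the two masks commute.  Bounds are strict: boundary depths
    are kept.
    """
    if gm.dp is None:
        raise ValueError("depth masking requires per-genotype depths")
    out = gm.copy()
    sequenced = gm.dp > 0
    n_seq = sequenced.sum(axis=1)
    for i, n in enumerate(n_seq):
        if n == 0:
            raise ValueError(f"sample {gm.samples[i]!r} has no sequenced genotypes")
    mean = (gm.dp * sequenced).sum(axis=1) / n_seq
    lo = 0.5 * mean[:, None]
    hi = 2.0 * mean[:, None]
    bad = (gm.gt != MISSING) & ((gm.dp < lo) | (gm.dp > hi))
    out.gt[bad] = MISSING
    return out


def _parse_outgroup(col: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split 'A/A'-style genotype strings into allele arrays + validity."""
    s = col.astype(str).str.strip()
    parts = s.str.split("/", expand=True)
    if parts.shape[1] != 2:
        raise ValueError("outgroup genotypes must be 'X/Y' strings")
    a1 = parts[0].to_numpy(dtype=object)
    a2 = parts[1].to_numpy(dtype=object)
    ok = np.array(
        [x not in (".", "", "N", "nan") and y not in (".", "", "N", "nan") for x, y in zip(a1, a2)]
    )
    return a1, a2, ok


def polarize(
    gm: GenotypeMatrix,
    outgroups: pd.DataFrame,
    outgroup_columns: tuple[str, str, str] = OUTGROUP_COLUMNS,
) -> DerivedMatrix:
    """Recode reference-coded genotypes as derived-allele counts.

    ``outgroups`` must hold ``chrom``, ``pos`` and three genotype-string
    columns.  Sites without a usable outgroup consensus are silently
    dropped (this is a filter, not a failure).
    """
    for c in ("chrom", "pos", *outgroup_columns):
        if c not in outgroups.columns:
            raise ValueError(f"outgroup table lacks column {c!r}")
    key = gm.sites[["chrom", "pos"]].copy()
    key["_site_order"] = np.arange(len(key))
    merged = key.merge(outgroups, on=["chrom", "pos"], how="left", validate="one_to_one")
    merged = merged.sort_values("_site_order")

    alleles = []
    valid = np.ones(len(merged), dtype=bool)
    for c in outgroup_columns:
        col = merged[c].fillna(".")
        a1, a2, ok = _parse_outgroup(col)
        hom = ok & (a1 == a2)
        valid &= hom
        alleles.append(a1)
    a, b, c3 = alleles
    concordant = valid & (a == b) & (b == c3)

    ref = gm.sites["ref"].to_numpy(dtype=object)
    alt = gm.sites["alt"].to_numpy(dtype=object)
    shared = np.where(concordant, a, None)
    is_ref = concordant & (shared == ref)
    is_alt = concordant & (shared == alt)
    retained = is_ref | is_alt

    idx = np.flatnonzero(retained)
    anc = np.where(is_ref[idx], ref[idx], alt[idx])
    der = np.where(is_ref[idx], alt[idx], ref[idx])

    gt = gm.gt[:, idx]
    dc = gt.copy()
    flip = is_alt[idx]  # ancestral is the alt allele: derived count = 2 - gt
    flipped = 2 - gt[:, flip]
    flipped[gt[:, flip] == MISSING] = MISSING
    dc[:, flip] = flipped

    sites = gm.sites.iloc[idx].reset_index(drop=True).copy()
    sites["ancestral"] = anc
    sites["derived"] = der
    return DerivedMatrix(samples=list(gm.samples), sites=sites, dc=dc)


def drop_invariant(dm: DerivedMatrix) -> DerivedMatrix:
    """Remove sites with no derived allele observed in the ingroup.

    Sites fixed homozygous-derived across all genotyped samples are kept:
    they are variable relative to the ancestor and enter the load counts.
    """
    observed = ((dm.dc == 1) | (dm.dc == 2)).any(axis=0)
    return dm.take_sites(observed)
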
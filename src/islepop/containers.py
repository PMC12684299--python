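"""In-memory containers shared by all pipeline stages.

Genotypes are held as dense ``(n_samples, n_sites)`` integer matrices with
sites described by a parallel :class:`pandas.DataFrame`.  Two codings are
used: reference-coded (:class:`GenotypeMatrix`, the VCF view) and
derived-coded (:class:`DerivedMatrix`, after outgroup polarisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: genotype / derived-count code for a missing call
MISSING = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


def _check_sites(sites: pd.DataFrame, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks required columns: {missing}")


@dataclass
class GenotypeMatrix:
    """Reference-coded diploid genotypes at biallelic autosomal SNP sites.

    Parameters
    ----------
    samples
        Sample identifiers, one per matrix row.
    sites
        Per-site table with at least ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt``; extra columns (gene ids, annotations) travel along.
    gt
        ``(n_samples, n_sites)`` int8 matrix: 0 hom-ref, 1 het, 2 hom-alt,
        ``MISSING`` (-1) for no-calls.
    dp
        Per-genotype read depth, same shape as ``gt`` (optional; ``None``
        for noiseless truth genotypes straight out of the simulator).
    minor_ad
        Per-genotype minor-allele read support, ``min(AD)`` of the biallelic
        allele-depth pair (optional, paired with ``dp``).
    """

    samples: list[str]
    sites: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray | None = None
    minor_ad: np.ndarray | None = None

    def __post_init__(self) -> None:
        _check_sites(self.sites, SITE_COLUMNS)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"gt shape {self.gt.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        for name in ("dp", "minor_ad"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int32)
                if arr.shape != self.gt.shape:
                    raise ValueError(f"{name} shape {arr.shape} != gt shape")
                setattr(self, name, arr)
        if self.dp is not None and self.minor_ad is not None:
            ok = (self.minor_ad <= self.dp) | (self.gt == MISSING)
            if not ok.all():
                raise ValueError("minor allele support exceeds depth")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.copy(),
            gt=self.gt.copy(),
            dp=None if self.dp is None else self.dp.copy(),
            minor_ad=None if self.minor_ad is None else self.minor_ad.copy(),
        )

    def take_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer index array."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[keep if keep.dtype != bool else np.flatnonzero(keep)]
            .reset_index(drop=True),
            gt=self.gt[:, keep],
            dp=None if self.dp is None else self.dp[:, keep],
            minor_ad=None if self.minor_ad is None else self.minor_ad[:, keep],
        )


@dataclass
class DerivedMatrix:
    """Derived-allele-coded genotypes after outgroup polarisation.

    ``dc`` counts derived alleles per genotype (0, 1, 2, or ``MISSING``).
    ``sites`` carries ``ancestral`` and ``derived`` alleles in addition to
    the usual columns; every retained site has exactly one of each.
    """

    samples: list[str]
    sites: pd.DataFrame
    dc: np.ndarray

    def __post_init__(self) -> None:
        _check_sites(self.sites, SITE_COLUMNS + ("ancestral", "derived"))
        self.dc = np.asarray(self.dc, dtype=np.int8)
        if self.dc.shape != (len(self.samples), len(self.sites)):
            raise ValueError("dc shape inconsistent with samples x sites")
        anc = self.sites["ancestral"].to_numpy()
        der = self.sites["derived"].to_numpy()
        if (anc == der).any():
            raise ValueError("site with identical ancestral and derived allele")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def take_sites(self, keep: np.ndarray) -> "DerivedMatrix":
        keep = np.asarray(keep)
        rows = keep if keep.dtype != bool else np.flatnonzero(keep)
        return DerivedMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[rows].reset_index(drop=True),
            dc=self.dc[:, keep],
        )
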
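"""Reading and writing the pipeline's file formats.

VCF 4.2 with ``GT:DP:AD`` genotypes is the variant interchange format
(parsed with cyvcf2; written as plain text).  Site annotations, outgroup
genotypes and sample metadata travel as tab-separated tables.  Only
biallelic SNPs are accepted at read time; indels and multi-allelic
records are counted and skipped.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, DerivedMatrix, GenotypeMatrix

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

# cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_CYVCF2_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def write_vcf(
    path: str | Path,
    samples: Sequence[str],
    sites: pd.DataFrame,
    gt: np.ndarray,
    dp: np.ndarray | None = None,
    alt_ad: np.ndarray | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a VCF 4.2 file with GT (and DP/AD when depths are given).

    ``alt_ad`` is the number of reads supporting the alternative allele;
    reference support is ``dp - alt_ad``.  An ``AA`` INFO tag is written
    when the site table has an ``ancestral`` column.
    """
    path = Path(path)
    n_samples, n_sites = len(samples), len(sites)
    if gt.shape != (n_samples, n_sites):
        raise ValueError("gt shape inconsistent with samples/sites")
    with_depth = dp is not None and alt_ad is not None

    chrom = sites["chrom"].astype(str).to_numpy()
    pos = sites["pos"].to_numpy()
    ref = sites["ref"].astype(str).to_numpy()
    alt = sites["alt"].astype(str).to_numpy()
    if contig_lengths is None:
        contig_lengths = {
            c: int(pos[chrom == c].max()) for c in dict.fromkeys(chrom)
        }
    has_aa = "ancestral" in sites.columns
    info = (
        ("AA=" + sites["ancestral"].astype(str)).to_numpy()
        if has_aa
        else np.full(n_sites, ".", dtype=object)
    )

    lines = [
        "##fileformat=VCFv4.2",
        "##source=islepop",
    ]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in contig_lengths.items()]
    if has_aa:
        lines.append('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_depth:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )

    fmt = "GT:DP:AD" if with_depth else "GT"
    gt_str = np.empty(gt.shape, dtype=object)
    for code, s in _GT_STRINGS.items():
        gt_str[gt == code] = s
    if with_depth:
        ref_ad = dp - alt_ad
        cells = np.char.add(
            np.char.add(gt_str.astype(str), ":" + dp.astype(str) + ":"),
            np.char.add(np.char.add(ref_ad.astype(str), ","), alt_ad.astype(str)),
        )
    else:
        cells = gt_str.astype(str)

    body = []
    for j in range(n_sites):
        fixed = f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t{info[j]}\t{fmt}\t"
        body.append(fixed + "\t".join(cells[:, j]))
    path.write_text("\n".join(lines + body) + "\n")


def emit_vcf(
    gm: GenotypeMatrix,
    sites: pd.DataFrame,
    path: str | Path,
    mean_depth: float = 30.0,
    seed: int | np.random.Generator = 0,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write truth genotypes to VCF with a sequencing-noise model.

    Depth per genotype is Poisson(``mean_depth``); for heterozygotes the
    allele depth is split Binomial(DP, 0.5), homozygotes get all reads on
    their allele (so AD always sums to DP).  Truth genotype calls are
    written unchanged — the noise lives in DP/AD only.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    gt = gm.gt
    dp = rng.poisson(mean_depth, size=gt.shape).astype(np.int32)
    alt_ad = np.zeros_like(dp)
    het = gt == 1
    alt_ad[het] = rng.binomial(dp[het], 0.5)
    alt_ad[gt == 2] = dp[gt == 2]
    write_vcf(
        path,
        gm.samples,
        sites if "ref" in sites.columns else gm.sites,
        gt,
        dp=dp,
        alt_ad=alt_ad,
        contig_lengths=contig_lengths,
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Indels and multi-allelic records are rejected (counted, reported via a
    warning).  Minor-allele support is ``min(AD)`` of the biallelic pair;
    depth comes from the DP field.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt = [], [], [], []
    gts, dps, minors = [], [], []
    n_rejected = 0
    has_depth = True
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_rejected += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        gts.append(_CYVCF2_CODE[np.asarray(v.gt_types)])
        try:
            d = v.format("DP")
            a = v.format("AD")
        except KeyError:
            d = a = None
        if d is None or a is None:
            has_depth = False
        else:
            dps.append(d[:, 0])
            minors.append(a[:, :2].min(axis=1))
    vcf.close()
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} non-biallelic-SNP records", stacklevel=2)
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
    n_sites = len(sites)
    gt = (
        np.stack(gts, axis=1)
        if n_sites
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    dp = minor = None
    if has_depth and dps:
        dp = np.stack(dps, axis=1).astype(np.int32)
        minor = np.stack(minors, axis=1).astype(np.int32)
        np.clip(minor, 0, None, out=minor)  # cyvcf2 encodes missing AD as negative
        minor = np.minimum(minor, dp)
    return GenotypeMatrix(samples=samples, sites=sites, gt=gt, dp=dp, minor_ad=minor)


def write_derived_vcf(dm: DerivedMatrix, path: str | Path) -> None:
    """Write a polarised matrix as VCF with the AA (ancestral allele) tag."""
    anc_is_ref = (dm.sites["ancestral"] == dm.sites["ref"]).to_numpy()
    gt = dm.dc.copy()
    flip = ~anc_is_ref
    flipped = 2 - dm.dc[:, flip]
    flipped[dm.dc[:, flip] == MISSING] = MISSING
    gt[:, flip] = flipped
    write_vcf(path, dm.samples, dm.sites, gt)


def merge_site_annotations(sites: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Left-join VEP-style annotations (gene_id, consequence, ex_score)."""
    cols = [c for c in ("gene_id", "consequence", "ex_score") if c in annotations.columns]
    return sites.merge(
        annotations[["chrom", "pos", *cols]], on=["chrom", "pos"], how="left", validate="one_to_one"
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"sample_id", "species", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample metadata must have columns {sorted(required)}")
    bad = set(df["population"]) - {"island", "mainland"}
    if bad:
        raise ValueError(f"unknown populations in metadata: {sorted(bad)}")
    return df
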
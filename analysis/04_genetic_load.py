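#!/usr/bin/env python
"""Per-individual genetic load across mutational-effect categories.

From the derived-coded matrix: counts of derived het/hom genotypes,
relative abundance RA = (n_het + 2 n_hom) / (2 n_p) with n_p pooled
species-wide, derived homozygosity, Welch island-vs-mainland comparisons
per category, and genes carrying LoF variants fixed homozygous on the
island.
"""

import argparse
from pathlib import Path

import pandas as pd

from islepop import genetic_load as gl
from islepop.variant_prep import drop_invariant, polarize
from islepop.vcfio import read_table, read_vcf, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/load"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    gm = read_vcf(args.simdir / "simulated.vcf")
    annotations = read_table(args.simdir / "annotations.tsv")
    gm.sites = gm.sites.merge(
        annotations[["chrom", "pos", "gene_id", "consequence", "ex_score"]],
        on=["chrom", "pos"], how="left",
    )
    dm = drop_invariant(polarize(gm, read_table(args.simdir / "outgroups.tsv")))
    cats = gl.classify_sites(dm.sites)

    summary = gl.load_summary(dm, cats)
    write_table(summary, args.outdir / "load_summary.tsv")

    meta = read_table(args.simdir / "samples.tsv")
    pop = dict(zip(meta["sample_id"], meta["population"]))
    summary["population"] = summary["sample"].map(pop)
    rows = []
    for cat in gl.CATEGORIES:
        sub = summary[summary["category"] == cat]
        for stat in ("ra", "derived_homozygosity"):
            isl = sub.loc[sub.population == "island", stat]
            mnl = sub.loc[sub.population == "mainland", stat]
            cmp = gl.compare_groups(isl, mnl)
            rows.append({"category": cat, "statistic": stat,
                         "mean_island": isl.mean(), "mean_mainland": mnl.mean(),
                         "welch_t": cmp.statistic, "welch_p": cmp.pvalue,
                         "testable": cmp.testable})
    tests = pd.DataFrame(rows)
    write_table(tests, args.outdir / "group_tests.tsv")

    island = [s for s in dm.samples if pop.get(s) == "island"]
    genes = gl.fixed_homozygous_lof_genes(dm, cats, island)
    (args.outdir / "fixed_lof_genes_island.txt").write_text(
        "\n".join(sorted(genes)) + ("\n" if genes else "")
    )
    print(tests.round(4).to_string(index=False))
    print(f"{len(genes)} genes carry island-fixed homozygous LoF variants")


if __name__ == "__main__":
    main()
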
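#!/usr/bin/env python
"""Differentially fixed coding variants and the pseudogene filter.

Scans coding sites for reciprocal fixation between island and mainland,
removes genes containing any LoF variant (drift in putative pseudogenes),
and — using two replicate simulated species — demonstrates the
cross-species overlap of affected gene sets.
"""

import argparse
from pathlib import Path

import numpy as np

from islepop import genetic_load as gl
from islepop.experiments import neutral_config
from islepop.fixed_diff import cross_species_overlap, differentially_fixed, filter_lof_genes
from islepop.pipeline import PipelineConfig, run_pipeline
from islepop.variant_prep import drop_invariant, polarize
from islepop.vcfio import read_table, read_vcf, write_table


def gene_set_for_simdir(simdir: Path):
    gm = read_vcf(simdir / "simulated.vcf")
    annotations = read_table(simdir / "annotations.tsv")
    gm.sites = gm.sites.merge(
        annotations[["chrom", "pos", "gene_id", "consequence", "ex_score"]],
        on=["chrom", "pos"], how="left",
    )
    dm = drop_invariant(polarize(gm, read_table(simdir / "outgroups.tsv")))
    meta = read_table(simdir / "samples.tsv")
    pop = dict(zip(meta["sample_id"], meta["population"]))
    island = [s for s in dm.samples if pop.get(s) == "island"]
    mainland = [s for s in dm.samples if pop.get(s) == "mainland"]
    cats = gl.classify_sites(dm.sites)
    fixed = differentially_fixed(dm, island, mainland, site_mask=np.isin(cats, gl.CATEGORIES))
    filt = filter_lof_genes(fixed, dm.sites["gene_id"].to_numpy(), cats)
    return filt, len(fixed)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/fixdiff"))
    ap.add_argument("--replicate-seeds", type=int, nargs="*", default=[31, 32],
                    help="extra seeds simulated as replicate species for the overlap")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    filt, n_raw = gene_set_for_simdir(args.simdir)
    write_table(filt.fixed, args.outdir / "fixed_differences.tsv")
    print(f"{n_raw} fixed differences; {len(filt.fixed)} in {len(filt.genes)} genes "
          f"after removing {len(filt.lof_genes)} LoF-containing genes")

    gene_sets = {"species_ref": filt.genes}
    for seed in args.replicate_seeds:
        rep_dir = args.outdir / f"replicate_{seed}"
        run_pipeline(PipelineConfig(outdir=str(rep_dir), seed=seed, sim=neutral_config()))
        rep_filt, _ = gene_set_for_simdir(rep_dir / "sim")
        gene_sets[f"species_{seed}"] = rep_filt.genes
    overlap = cross_species_overlap(gene_sets)
    write_table(overlap.table.reset_index(), args.outdir / "gene_overlap.tsv")
    print(f"genes with fixed differences in >= 2 simulated species: {len(overlap.shared)}")


if __name__ == "__main__":
    main()
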
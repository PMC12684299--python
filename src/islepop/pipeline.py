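"""End-to-end pipeline: simulate/read -> mask -> polarise -> ROH -> load -> fixed diffs.

Stages are pure functions of their inputs and the configuration; a JSON
manifest with input/output hashes and all parameters is written so a
re-run with the same config is byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import genetic_load as gl
from . import roh_diversity as roh
from . import simdata, vcfio
from .containers import MISSING, DerivedMatrix, GenotypeMatrix
from .fixed_diff import differentially_fixed, filter_lof_genes
from .variant_prep import drop_invariant, mask_allelic_balance, mask_depth, polarize


@dataclass(frozen=True)
class PipelineConfig:
    """One run: either a synthetic scenario or real input paths.

    Exactly one of ``sim`` and ``vcf`` must be set.  The scalar constants
    carried here (recombination rate 0.448 cM/Mb, generation time 11 y,
    mutation rate 4.65e-9, ROH false-positive alpha 0.05, allelic-balance
    threshold 0.25, EX threshold 0.256) surface in the report.
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    sim: simdata.SimConfig | None = None
    vcf: str | None = None
    sample_metadata: str | None = None
    site_annotations: str | None = None
    outgroups: str | None = None
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    clock: roh.RecombClock = field(default_factory=roh.RecombClock)
    calibrate_roh: bool = True
    min_support_fraction: float = 0.25
    mutation_rate: float = 4.65e-9

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.vcf is None):
            raise ValueError("set exactly one of sim (synthetic mode) or vcf (file mode)")
        if self.vcf is not None:
            for name in ("sample_metadata", "site_annotations", "outgroups"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"file mode requires {name}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
            if not Path(self.vcf).exists():
                raise FileNotFoundError(f"vcf file not found: {self.vcf}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = simdata.SimConfig(**raw["sim"])
        if "roh_params" in raw:
            raw["roh_params"] = roh.ROHParams(**raw["roh_params"])
        if "clock" in raw:
            raw["clock"] = roh.RecombClock(**raw["clock"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    metadata: pd.DataFrame
    roh_segments: pd.DataFrame
    roh_summary: pd.DataFrame
    load_summary: pd.DataFrame
    group_tests: pd.DataFrame
    fixed_differences: pd.DataFrame
    fixdiff_genes: set[str]
    fixed_lof_genes_island: set[str]
    counts: dict
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return obj


def prepare_inputs(config: PipelineConfig, outdir: Path):
    """Synthesise (synthetic mode) or load (file mode) the four inputs."""
    if config.sim is not None:
        sim_cfg = replace(config.sim, seed=config.seed)
        gm_truth, sites, truth = simdata.simulate(sim_cfg)
        metadata = simdata.sample_metadata(truth)
        outgroups = simdata.emit_outgroups(
            sites, seed=np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
        )
        simdir = outdir / "sim"
        simdir.mkdir(parents=True, exist_ok=True)
        contigs = {
            f"chr{i + 1}": sim_cfg.chrom_length_bp for i in range(sim_cfg.n_chromosomes)
        }
        vcf_path = simdir / "simulated.vcf"
        vcfio.emit_vcf(
            gm_truth,
            sites,
            vcf_path,
            mean_depth=sim_cfg.mean_depth,
            seed=np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1]),
            contig_lengths=contigs,
        )
        vcfio.write_table(metadata, simdir / "samples.tsv")
        vcfio.write_table(sites, simdir / "annotations.tsv")
        vcfio.write_table(outgroups, simdir / "outgroups.tsv")
        vcfio.write_table(truth.sites, simdir / "truth_sites.tsv")
        vcfio.write_table(truth.pedigree_f, simdir / "truth_pedigree_f.tsv")
        gm = vcfio.read_vcf(vcf_path)
        annotations = sites.drop(columns=["ancestral"])
    else:
        gm = vcfio.read_vcf(config.vcf)
        metadata = vcfio.read_sample_metadata(config.sample_metadata)
        annotations = vcfio.read_table(config.site_annotations)
        outgroups = vcfio.read_table(config.outgroups)
    gm.sites = vcfio.merge_site_annotations(gm.sites, annotations)
    return gm, metadata, outgroups


def roh_stage(
    gm: GenotypeMatrix,
    params: roh.ROHParams,
    clock: roh.RecombClock,
    calibrate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, roh.ROHParams]:
    """Heterozygosity, calibrated ROH detection, F_ROH and age classes."""
    hets = {s: roh.heterozygosity(gm.gt[i]) for i, s in enumerate(gm.samples)}
    if calibrate:
        mean_het = float(np.mean(list(hets.values())))
        L = roh.min_roh_snps(gm.n_sites, gm.n_samples, params.alpha, mean_het)
        L = max(L, 2)
        params = replace(params, min_snps=L, window_snps=L)
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    seg_rows, sum_rows = [], []
    for i, s in enumerate(gm.samples):
        segs = roh.assign_age_classes(
            roh.detect_roh(chrom, pos, gm.gt[i], params, sample=s), clock
        )
        hom_gt = roh.synthetic_homozygous(gm.gt[i])
        segs_hom = roh.detect_roh(chrom, pos, hom_gt, params, sample=s)
        l_roh = roh.total_length(segs)
        l_hom = roh.total_length(segs_hom)
        l_cont = sum(x.length_bp for x in segs if x.age_class == roh.CONTEMPORARY)
        l_hist = sum(x.length_bp for x in segs if x.age_class == roh.HISTORICAL)
        froh = roh.f_roh(segs, segs_hom)
        sum_rows.append(
            {
                "sample": s,
                "het": hets[s],
                "n_roh": len(segs),
                "l_roh_bp": l_roh,
                "l_roh_hom_bp": l_hom,
                "f_roh": froh,
                "f_roh_contemporary": l_cont / l_hom if l_hom else 0.0,
                "f_roh_historical": l_hist / l_hom if l_hom else 0.0,
            }
        )
        seg_rows += [
            {
                "sample": x.sample,
                "chrom": x.chrom,
                "start": x.start,
                "end": x.end,
                "n_snps": x.n_snps,
                "length_bp": x.length_bp,
                "age_class": x.age_class,
            }
            for x in segs
        ]
    seg_cols = ["sample", "chrom", "start", "end", "n_snps", "length_bp", "age_class"]
    return (
        pd.DataFrame(seg_rows, columns=seg_cols),
        pd.DataFrame(sum_rows),
        params,
    )


def group_test_table(
    roh_summary: pd.DataFrame,
    load_summary: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Welch island-vs-mainland comparisons for every reported statistic."""
    pop = dict(zip(metadata["sample_id"], metadata["population"]))
    rows = []

    def add(name: str, series: pd.Series, samples: pd.Series):
        a = [v for v, s in zip(series, samples) if pop.get(s) == "island"]
        b = [v for v, s in zip(series, samples) if pop.get(s) == "mainland"]
        cmp = gl.compare_groups(a, b)
        rows.append(
            {
                "statistic": name,
                "mean_island": float(np.nanmean(a)) if a else float("nan"),
                "mean_mainland": float(np.nanmean(b)) if b else float("nan"),
                "testable": cmp.testable,
                "t": cmp.statistic,
                "p": cmp.pvalue,
                "reason": cmp.reason,
            }
        )

    add("heterozygosity", roh_summary["het"], roh_summary["sample"])
    add("f_roh", roh_summary["f_roh"], roh_summary["sample"])
    add("f_roh_contemporary", roh_summary["f_roh_contemporary"], roh_summary["sample"])
    for cat in gl.CATEGORIES:
        sub = load_summary[load_summary["category"] == cat]
        add(f"ra_{cat}", sub["ra"], sub["sample"])
        add(f"derived_homozygosity_{cat}", sub["derived_homozygosity"], sub["sample"])
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages, write per-stage tables, manifest and report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    gm, metadata, outgroups = prepare_inputs(config, outdir)
    counts["sites_read"] = gm.n_sites
    counts["samples"] = gm.n_samples

    gm_ab = mask_allelic_balance(gm, config.min_support_fraction)
    counts["masked_allelic_balance"] = int(((gm_ab.gt == MISSING) & (gm.gt != MISSING)).sum())
    gm_masked = mask_depth(gm_ab)
    counts["masked_depth"] = int(
        ((gm_masked.gt == MISSING) & (gm_ab.gt != MISSING)).sum()
    )

    dm = polarize(gm_masked, outgroups)
    counts["sites_polarised"] = dm.n_sites
    counts["sites_dropped_polarisation"] = gm.n_sites - dm.n_sites
    dm = drop_invariant(dm)
    counts["sites_after_invariant_filter"] = dm.n_sites

    roh_segments, roh_summary, roh_params_used = roh_stage(
        gm_masked, config.roh_params, config.clock, config.calibrate_roh
    )
    counts["roh_min_snps_L"] = roh_params_used.min_snps

    categories = gl.classify_sites(dm.sites)
    load_summary = gl.load_summary(dm, categories)
    pop = dict(zip(metadata["sample_id"], metadata["population"]))
    island = [s for s in dm.samples if pop.get(s) == "island"]
    mainland = [s for s in dm.samples if pop.get(s) == "mainland"]
    fixed_lof_island = gl.fixed_homozygous_lof_genes(dm, categories, island) if island else set()

    coding = np.isin(categories, gl.CATEGORIES)
    fixed = differentially_fixed(dm, island, mainland, site_mask=coding)
    counts["fixed_differences"] = len(fixed)
    filt = filter_lof_genes(
        fixed, dm.sites["gene_id"].to_numpy(), categories
    )
    counts["fixed_differences_after_lof_gene_filter"] = len(filt.fixed)

    tests = group_test_table(roh_summary, load_summary, metadata)

    outputs = {
        "roh_segments.tsv": roh_segments,
        "roh_summary.tsv": roh_summary,
        "load_summary.tsv": load_summary,
        "group_tests.tsv": tests,
        "fixed_differences.tsv": filt.fixed,
    }
    for name, df in outputs.items():
        vcfio.write_table(df, outdir / name)
    (outdir / "fixed_lof_genes_island.txt").write_text(
        "\n".join(sorted(fixed_lof_island)) + ("\n" if fixed_lof_island else "")
    )
    vcfio.write_derived_vcf(dm, outdir / "derived.vcf")

    cfg_record = _jsonable(config)
    cfg_record.pop("outdir", None)  # location is environment, not a parameter
    manifest = {
        "config": cfg_record,
        "counts": _jsonable(counts),
        "roh_params_used": _jsonable(roh_params_used),
        "outputs": {
            name: _sha256(outdir / name)
            for name in [*outputs, "fixed_lof_genes_island.txt", "derived.vcf"]
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _write_report(outdir / "report.txt", config, counts, roh_summary, load_summary, tests, metadata)

    return PipelineResult(
        config=config,
        metadata=metadata,
        roh_segments=roh_segments,
        roh_summary=roh_summary,
        load_summary=load_summary,
        group_tests=tests,
        fixed_differences=filt.fixed,
        fixdiff_genes=filt.genes,
        fixed_lof_genes_island=fixed_lof_island,
        counts=counts,
        manifest=manifest,
    )


def _write_report(path, config, counts, roh_summary, load_summary, tests, metadata):
    clock = config.clock
    lines = [
        "islepop pipeline report",
        "=======================",
        "",
        "Parameters",
        f"  seed: {config.seed}",
        f"  allelic-balance minimum minor fraction: {config.min_support_fraction}",
        f"  ROH false-positive alpha: {config.roh_params.alpha}",
        f"  recombination rate: {clock.r_cm_per_mb} cM/Mb",
        f"  generation time: {clock.generation_time_years} y",
        f"  ROH age boundary: {clock.length_threshold_mb} Mb "
        f"(~{clock.generation_threshold} generations, ~{clock.boundary_years:.0f} y)",
        f"  missense EX deleterious threshold: {gl.EX_DELETERIOUS_MAX}",
        f"  mutation rate (reporting): {config.mutation_rate}",
        "",
        "Record counts",
    ]
    lines += [f"  {k}: {v}" for k, v in counts.items()]
    lines += ["", "Per-sample ROH / heterozygosity", roh_summary.to_string(index=False)]
    lines += ["", "Group comparisons (Welch)", tests.to_string(index=False)]
    Path(path).write_text("\n".join(lines) + "\n")
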
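"""Forward-time Wright-Fisher simulator of an island bottleneck.

Simulates a large mainland population from which a small island population
splits (no migration afterwards), with four mutational-effect classes
(synonymous, tolerated/deleterious missense, loss-of-function), selection
and dominance per class, Haldane-model recombination at marker positions,
and infinite-sites mutation so every variant has an unambiguous founder
(ancestral) allele.  Pedigree-level inbreeding of every individual is
tracked exactly through a forward kinship recursion.

Genotypes stay noiseless inside the simulator; sequencing-style noise
(Poisson depth, binomial allele-depth split for hets) is only applied when
emitting VCF, so masking stages can be tested against clean truth.

Standing variation at generation zero is seeded from the neutral
equilibrium frequency spectrum (expected site count ``theta * H_{2N-1}``,
allele-count distribution ``p(i) ~ 1/i``) and then propagated forward; a
short forward burn-in (``total_generations - split_generation``) precedes
the split.  With ``mu = 0`` the seeding intensity is zero and the founders
are monomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

CLASS_NAMES = ("synonymous", "missense_tolerated", "missense_deleterious", "lof")

#: consequence strings the toy annotator can assign to simulated LoF sites
LOF_CONSEQUENCE_CHOICES = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_region_variant",
)

BASES = np.array(["A", "C", "G", "T"])

MAINLAND, ISLAND = 0, 1
POP_NAMES = ("mainland", "island")


def _class_dict(values, default: float) -> dict[str, float]:
    if values is None:
        return {c: default for c in CLASS_NAMES}
    return {c: float(values[c]) for c in CLASS_NAMES}


@dataclass(frozen=True)
class SimConfig:
    """Two-population bottleneck scenario and sequencing-noise parameters.

    ``split_generation`` counts generations before present;
    ``total_generations`` is the full run length, so the pre-split burn-in
    lasts ``total_generations - split_generation`` generations.
    """

    n_mainland: int = 500
    n_island: int = 50
    split_generation: int = 200
    total_generations: int = 250
    chrom_length_bp: int = 5_000_000
    n_chromosomes: int = 4
    mu: float = 1e-8
    r_cm_per_mb: float = 1.0
    class_fractions: dict = field(
        default_factory=lambda: {
            "synonymous": 0.40,
            "missense_tolerated": 0.25,
            "missense_deleterious": 0.20,
            "lof": 0.15,
        }
    )
    sel_coeff: dict = field(default_factory=lambda: _class_dict(None, 0.0))
    dominance: dict = field(default_factory=lambda: _class_dict(None, 0.5))
    mean_depth: float = 30.0
    n_sample_mainland: int = 8
    n_sample_island: int = 8
    gene_length_bp: int = 50_000
    ref_derived_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_island < 2 or self.n_mainland < 2:
            raise ValueError("population sizes must be >= 2")
        if self.n_island > self.n_mainland:
            raise ValueError("island population must not exceed the mainland")
        if self.split_generation > self.total_generations:
            raise ValueError("split_generation cannot exceed total_generations")
        if self.split_generation < 1:
            raise ValueError("split_generation must be >= 1")
        fr = self.class_fractions
        if set(fr) != set(CLASS_NAMES):
            raise ValueError(f"class_fractions must have keys {CLASS_NAMES}")
        if abs(sum(fr.values()) - 1.0) > 1e-9 or any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be non-negative and sum to 1")
        for name, d in (("sel_coeff", self.sel_coeff), ("dominance", self.dominance)):
            if set(d) != set(CLASS_NAMES):
                raise ValueError(f"{name} must have keys {CLASS_NAMES}")
            if any(not 0.0 <= v <= 1.0 for v in d.values()):
                raise ValueError(f"{name} values must be in [0, 1]")
        if self.mu < 0 or self.mean_depth <= 0:
            raise ValueError("mu must be >= 0 and mean_depth > 0")
        if self.r_cm_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")
        if self.n_sample_mainland > self.n_mainland or self.n_sample_island > self.n_island:
            raise ValueError("cannot sample more individuals than the population holds")
        if not 0.0 <= self.ref_derived_fraction <= 1.0:
            raise ValueError("ref_derived_fraction must be in [0, 1]")

    @property
    def genome_length_bp(self) -> int:
        return self.chrom_length_bp * self.n_chromosomes


@dataclass
class SimTruth:
    """Simulator ground truth for recovery tests.

    ``sites`` holds one record per emitted variant site (mutation class,
    selection/dominance coefficients, origin population and generation
    before present, whether the site is fixed species-wide).
    ``pedigree_f`` holds the realised pedigree inbreeding coefficient of
    every sampled individual relative to the generation-zero founders.
    """

    config: SimConfig
    sites: pd.DataFrame
    pedigree_f: pd.DataFrame


class _Registry:
    """Global site registry shared by both populations, position-sorted."""

    __slots__ = ("gpos", "cls", "origin_pop", "origin_gen")

    def __init__(self, gpos, cls, origin_pop, origin_gen):
        self.gpos = np.asarray(gpos, dtype=np.int64)
        self.cls = np.asarray(cls, dtype=np.int8)
        self.origin_pop = np.asarray(origin_pop, dtype=np.int8)
        self.origin_gen = np.asarray(origin_gen, dtype=np.int32)

    @property
    def n(self) -> int:
        return self.gpos.size

    def insert(self, ins, gpos, cls, origin_pop, origin_gen) -> None:
        self.gpos = np.insert(self.gpos, ins, gpos)
        self.cls = np.insert(self.cls, ins, cls)
        self.origin_pop = np.insert(self.origin_pop, ins, origin_pop)
        self.origin_gen = np.insert(self.origin_gen, ins, origin_gen)

    def take(self, keep: np.ndarray) -> None:
        self.gpos = self.gpos[keep]
        self.cls = self.cls[keep]
        self.origin_pop = self.origin_pop[keep]
        self.origin_gen = self.origin_gen[keep]


class _Population:
    __slots__ = ("H", "kin", "f")

    def __init__(self, H, kin, f):
        self.H = H  # (2N, S) uint8 haplotypes
        self.kin = kin  # (N, N) float32 pedigree kinship
        self.f = f  # (N,) pedigree inbreeding of current individuals


def _harmonic(n: int) -> float:
    if n < 1:
        return 0.0
    if n > 100:
        return float(np.log(n) + 0.5772156649015329 + 1.0 / (2 * n))
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def _seed_standing_variation(cfg: SimConfig, rng: np.random.Generator):
    """Stationary-spectrum standing variation for the founding population.

    Each class is seeded as a Poisson random field over allele counts with
    intensity proportional to the neutral 1/i spectrum weighted by Wright's
    stationary density ``w_bar(q)^{2N}`` for that class's selection regime
    (``w_bar(q) = 1 - 2hs q(1-q) - s q^2``); for a neutral class this is
    exactly the 1/i spectrum.  Seeding intensity scales with mu, so
    ``mu = 0`` leaves the founders monomorphic.
    """
    two_n = 2 * cfg.n_mainland
    theta = 2.0 * two_n * cfg.mu * cfg.genome_length_bp
    i_vals = np.arange(1, two_n)
    neutral = all(cfg.sel_coeff[c] == 0.0 for c in CLASS_NAMES)
    if neutral:
        expected = theta * _harmonic(two_n - 1)
        n_sites = int(rng.poisson(expected)) if expected > 0 else 0
        gpos = _draw_unique_positions(
            rng, n_sites, np.empty(0, dtype=np.int64), cfg.genome_length_bp
        )
        p = (1.0 / i_vals) / np.sum(1.0 / i_vals) if n_sites else None
        counts = rng.choice(i_vals, size=n_sites, p=p) if n_sites else np.empty(0, int)
        cls = rng_class_draw = None  # classes drawn after placement, below
    else:
        q = i_vals / two_n
        per_class_counts, per_class_cls = [], []
        n_sites = 0
        for k, cname in enumerate(CLASS_NAMES):
            s = cfg.sel_coeff[cname]
            h = cfg.dominance[cname]
            # log mean fitness of a random individual given allele freq q
            with np.errstate(divide="ignore"):
                log_wbar = np.log1p(-np.minimum(2 * h * s * q * (1 - q) + s * q * q, 1.0 - 1e-12))
            weight = (1.0 / i_vals) * np.exp(2 * cfg.n_mainland * log_wbar)
            theta_c = theta * cfg.class_fractions[cname]
            expected_c = theta_c * weight.sum()
            n_c = int(rng.poisson(expected_c)) if expected_c > 0 else 0
            if n_c:
                per_class_counts.append(
                    rng.choice(i_vals, size=n_c, p=weight / weight.sum())
                )
                per_class_cls.append(np.full(n_c, k, dtype=np.int8))
            n_sites += n_c
        counts = (
            np.concatenate(per_class_counts) if per_class_counts else np.empty(0, int)
        )
        cls = (
            np.concatenate(per_class_cls)
            if per_class_cls
            else np.empty(0, dtype=np.int8)
        )
        gpos = _draw_unique_positions(
            rng, n_sites, np.empty(0, dtype=np.int64), cfg.genome_length_bp
        )
    order = np.argsort(gpos)
    gpos, counts = gpos[order], counts[order]
    if cls is not None:
        cls = cls[order]
    H = np.zeros((two_n, n_sites), dtype=np.uint8)
    for j, c in enumerate(counts):
        H[rng.choice(two_n, size=int(c), replace=False), j] = 1
    if cls is None:
        cls = rng.choice(
            len(CLASS_NAMES),
            size=n_sites,
            p=[cfg.class_fractions[c] for c in CLASS_NAMES],
        ).astype(np.int8)
    reg = _Registry(
        gpos=gpos,
        cls=cls,
        origin_pop=np.full(n_sites, MAINLAND, dtype=np.int8),
        origin_gen=np.zeros(n_sites, dtype=np.int32),
    )
    return H, reg


def _draw_unique_positions(
    rng: np.random.Generator, n: int, existing_sorted: np.ndarray, genome_len: int
) -> np.ndarray:
    """Sample n genome coordinates absent from `existing_sorted` (infinite sites)."""
    out: list[np.ndarray] = []
    have = 0
    taken = existing_sorted
    while have < n:
        cand = rng.integers(0, genome_len, size=n - have)
        cand = np.unique(cand)
        if taken.size:
            pos = np.searchsorted(taken, cand)
            pos = np.clip(pos, 0, taken.size - 1)
            cand = cand[taken[pos] != cand]
        out.append(cand)
        taken = np.sort(np.concatenate([taken, cand]))
        have += cand.size
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def _recomb_boundaries(reg: _Registry, cfg: SimConfig):
    """Per-boundary crossover probabilities between adjacent marker sites."""
    chrom = reg.gpos // cfg.chrom_length_bp
    r_per_bp = cfg.r_cm_per_mb / 100.0 / 1e6  # Morgans per bp
    d = np.diff(reg.gpos)
    same = chrom[1:] == chrom[:-1]
    within_idx = np.flatnonzero(same)
    c = np.minimum(d[within_idx] * r_per_bp, 0.5)
    chrom_bound_idx = np.flatnonzero(~same)
    total = float(c.sum())
    p = c / total if total > 0 else None
    return within_idx, p, total, chrom_bound_idx


def _fitness(H: np.ndarray, s: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Multiplicative per-individual fitness: 1, 1-hs, 1-s per genotype."""
    N = H.shape[0] // 2
    sel = np.flatnonzero(s > 0)
    if sel.size == 0:
        return np.ones(N)
    G = H[0::2][:, sel].astype(np.int8) + H[1::2][:, sel]
    with np.errstate(divide="ignore"):
        lhet = np.log1p(-(h[sel] * s[sel]).astype(float))
        lhom = np.log1p(-s[sel].astype(float))
    logw = (G == 1) @ lhet + (G == 2) @ lhom
    m = logw.max()
    if not np.isfinite(m):
        raise RuntimeError("all individuals have zero fitness")
    return np.exp(logw - m)


def _gametes(H, parents, rng, within_idx, within_p, within_total, chrom_bound_idx):
    """One recombinant gamete per entry of `parents` (haplotype rows 2p, 2p+1)."""
    G = parents.size
    S = H.shape[1]
    if S == 0:
        return np.zeros((G, 0), dtype=np.uint8)
    sw = np.zeros((G, S), dtype=np.int8)
    sw[:, 0] = rng.integers(0, 2, size=G, dtype=np.int8)
    if chrom_bound_idx.size:
        sw[:, chrom_bound_idx + 1] += rng.integers(
            0, 2, size=(G, chrom_bound_idx.size), dtype=np.int8
        )
    if within_total > 0 and within_idx.size:
        k = rng.poisson(within_total, size=G)
        tot = int(k.sum())
        if tot:
            bidx = rng.choice(within_idx, size=tot, p=within_p)
            gidx = np.repeat(np.arange(G), k)
            np.add.at(sw, (gidx, bidx + 1), 1)
    # parity scan of switch events = which parental haplotype contributes
    choice = np.bitwise_xor.accumulate((sw & 1).astype(bool), axis=1)
    A = H[2 * parents]
    B = H[2 * parents + 1]
    return A ^ ((A ^ B) & choice)


def _next_generation(pop: _Population, s, h, n_off, rng, bounds) -> _Population:
    N = pop.kin.shape[0]
    w = _fitness(pop.H, s, h)
    if (w > 0).sum() < 2:
        raise RuntimeError("fewer than two viable parents")
    p = w / w.sum()
    fathers = rng.choice(N, size=n_off, p=p)
    mothers = rng.choice(N, size=n_off, p=p)
    for _ in range(1000):  # monogamous pairs not enforced, selfing is
        same = fathers == mothers
        if not same.any():
            break
        mothers[same] = rng.choice(N, size=int(same.sum()), p=p)
    gpar = np.empty(2 * n_off, dtype=np.int64)
    gpar[0::2] = fathers
    gpar[1::2] = mothers
    H_new = _gametes(pop.H, gpar, rng, *bounds)
    kin = pop.kin
    K2 = 0.25 * (
        kin[np.ix_(fathers, fathers)]
        + kin[np.ix_(fathers, mothers)]
        + kin[np.ix_(mothers, fathers)]
        + kin[np.ix_(mothers, mothers)]
    )
    f_off = kin[fathers, mothers].astype(np.float64)
    np.fill_diagonal(K2, 0.5 * (1.0 + f_off))
    return _Population(H=H_new, kin=K2.astype(np.float32), f=f_off)


def _mutate(
    pops, reg: _Registry, cfg: SimConfig, rng, abs_gen: int, pop_ids, taken_gpos
) -> None:
    """Add new infinite-sites mutations to this generation's gametes.

    ``taken_gpos`` holds every coordinate ever used (including sites that
    fixed and left the registry), keeping the infinite-sites guarantee.
    """
    new_gpos, new_cls, new_pop, owner_rows = [], [], [], []
    for pid, pop in zip(pop_ids, pops):
        lam = pop.H.shape[0] * cfg.mu * cfg.genome_length_bp
        n_mut = int(rng.poisson(lam)) if lam > 0 else 0
        if n_mut == 0:
            continue
        gpos = _draw_unique_positions(
            rng,
            n_mut,
            np.sort(np.concatenate([taken_gpos] + new_gpos)),
            cfg.genome_length_bp,
        )
        new_gpos.append(gpos)
        new_cls.append(
            rng.choice(
                len(CLASS_NAMES), size=n_mut, p=[cfg.class_fractions[c] for c in CLASS_NAMES]
            )
        )
        new_pop.append(np.full(n_mut, pid))
        owner_rows.append(rng.integers(0, pop.H.shape[0], size=n_mut))
    if not new_gpos:
        return
    gpos = np.concatenate(new_gpos)
    cls = np.concatenate(new_cls)
    pop_of = np.concatenate(new_pop)
    rows = np.concatenate(owner_rows)
    order = np.argsort(gpos)
    gpos, cls, pop_of, rows = gpos[order], cls[order], pop_of[order], rows[order]
    ins = np.searchsorted(reg.gpos, gpos)
    reg.insert(ins, gpos, cls, pop_of, np.full(gpos.size, abs_gen, dtype=np.int32))
    for pid, pop in zip(pop_ids, pops):
        cols = np.zeros((pop.H.shape[0], gpos.size), dtype=np.uint8)
        mine = np.flatnonzero(pop_of == pid)
        cols[rows[mine], mine] = 1
        pop.H = np.insert(pop.H, ins, cols.T if cols.ndim == 1 else cols, axis=1)


def _prune(pops, reg: _Registry, fixed_records: list) -> None:
    """Drop sites lost everywhere; move species-wide fixed sites aside."""
    if reg.n == 0:
        return
    counts = [p.H.sum(axis=0, dtype=np.int64) for p in pops]
    total = np.sum(counts, axis=0)
    lost = total == 0
    fixed = np.ones(reg.n, dtype=bool)
    for pop, c in zip(pops, counts):
        fixed &= c == pop.H.shape[0]
    for j in np.flatnonzero(fixed):
        fixed_records.append(
            (reg.gpos[j], reg.cls[j], reg.origin_pop[j], reg.origin_gen[j])
        )
    keep = ~(lost | fixed)
    if keep.all():
        return
    reg.take(keep)
    for pop in pops:
        pop.H = pop.H[:, keep]


def _sample_names(cfg: SimConfig) -> tuple[list[str], list[str]]:
    mnl = [f"mnl{i + 1:02d}" for i in range(cfg.n_sample_mainland)]
    isl = [f"isl{i + 1:02d}" for i in range(cfg.n_sample_island)]
    return mnl, isl


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Run the scenario; return truth genotypes, site annotations and truth.

    The returned :class:`GenotypeMatrix` holds noiseless genotypes
    (``dp``/``minor_ad`` are ``None``); the site table carries reference,
    alternative and true ancestral alleles, gene ids, toy VEP-style
    consequences and EX scores for missense sites.  Identical configs
    (including seed) give identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H0, reg = _seed_standing_variation(cfg, rng)
    mainland = _Population(
        H=H0,
        kin=np.zeros((cfg.n_mainland, cfg.n_mainland), dtype=np.float32),
        f=np.zeros(cfg.n_mainland),
    )
    island: _Population | None = None
    fixed_records: list = []
    fixed_gpos = np.empty(0, dtype=np.int64)
    s_by_cls = np.array([cfg.sel_coeff[c] for c in CLASS_NAMES])
    h_by_cls = np.array([cfg.dominance[c] for c in CLASS_NAMES])
    split_at = cfg.total_generations - cfg.split_generation

    for abs_gen in range(1, cfg.total_generations + 1):
        if abs_gen == split_at + 1 and island is None:
            founders = rng.choice(cfg.n_mainland, size=cfg.n_island, replace=False)
            hap_rows = np.empty(2 * cfg.n_island, dtype=np.int64)
            hap_rows[0::2] = 2 * founders
            hap_rows[1::2] = 2 * founders + 1
            island = _Population(
                H=mainland.H[hap_rows].copy(),
                kin=mainland.kin[np.ix_(founders, founders)].copy(),
                f=mainland.f[founders].copy(),
            )
        pops = [mainland] if island is None else [mainland, island]
        pop_ids = [MAINLAND] if island is None else [MAINLAND, ISLAND]
        s = s_by_cls[reg.cls] if reg.n else np.empty(0)
        h = h_by_cls[reg.cls] if reg.n else np.empty(0)
        bounds = _recomb_boundaries(reg, cfg)
        mainland = _next_generation(mainland, s, h, cfg.n_mainland, rng, bounds)
        new_pops = [mainland]
        if island is not None:
            island = _next_generation(island, s, h, cfg.n_island, rng, bounds)
            new_pops.append(island)
        _mutate(
            new_pops, reg, cfg, rng, abs_gen, pop_ids,
            np.concatenate([reg.gpos, fixed_gpos]),
        )
        n_fixed_before = len(fixed_records)
        _prune(new_pops, reg, fixed_records)
        if len(fixed_records) > n_fixed_before:
            fixed_gpos = np.concatenate(
                [
                    fixed_gpos,
                    np.array(
                        [r[0] for r in fixed_records[n_fixed_before:]], dtype=np.int64
                    ),
                ]
            )
        if island is not None:
            island = new_pops[1]
        mainland = new_pops[0]

    if island is None:  # split_generation == total_generations edge: split at start
        raise RuntimeError("island was never founded; check split/total generations")

    mnl_names, isl_names = _sample_names(cfg)
    mnl_idx = np.sort(rng.choice(cfg.n_mainland, size=cfg.n_sample_mainland, replace=False))
    isl_idx = np.sort(rng.choice(cfg.n_island, size=cfg.n_sample_island, replace=False))

    def _genotypes(pop: _Population, idx: np.ndarray) -> np.ndarray:
        return (pop.H[2 * idx] + pop.H[2 * idx + 1]).astype(np.int8)

    g_mnl = _genotypes(mainland, mnl_idx)
    g_isl = _genotypes(island, isl_idx)
    derived = np.vstack([g_mnl, g_isl]) if reg.n else np.zeros((len(mnl_names) + len(isl_names), 0), np.int8)

    seg_keep = derived.sum(axis=0) > 0 if reg.n else np.zeros(0, dtype=bool)
    derived = derived[:, seg_keep]
    seg = _Registry(
        reg.gpos[seg_keep], reg.cls[seg_keep], reg.origin_pop[seg_keep], reg.origin_gen[seg_keep]
    )

    # merge species-wide fixed sites back in as all-homozygous-derived records
    if fixed_records:
        fg = np.array([r[0] for r in fixed_records], dtype=np.int64)
        fc = np.array([r[1] for r in fixed_records], dtype=np.int8)
        fp = np.array([r[2] for r in fixed_records], dtype=np.int8)
        fo = np.array([r[3] for r in fixed_records], dtype=np.int32)
        forder = np.argsort(fg)  # records accrue in fixation order, not position order
        fg, fc, fp, fo = fg[forder], fc[forder], fp[forder], fo[forder]
        ins = np.searchsorted(seg.gpos, fg)
        seg.insert(ins, fg, fc, fp, fo)
        derived = np.insert(derived, ins, np.full((fg.size, derived.shape[0]), 2, np.int8).T, axis=1)
        fixed_flag = np.zeros(seg.n, dtype=bool)
        fixed_flag[np.searchsorted(seg.gpos, fg)] = True
    else:
        fixed_flag = np.zeros(seg.n, dtype=bool)

    samples = mnl_names + isl_names
    n_sites = seg.n
    chrom_i = (seg.gpos // cfg.chrom_length_bp).astype(int)
    pos = (seg.gpos % cfg.chrom_length_bp + 1).astype(np.int64)
    chrom = np.array([f"chr{c + 1}" for c in chrom_i], dtype=object)

    anc_base = BASES[rng.integers(0, 4, size=n_sites)]
    shift = rng.integers(1, 4, size=n_sites)
    der_base = BASES[(np.searchsorted(BASES, anc_base) + shift) % 4]
    ref_is_derived = rng.random(n_sites) < cfg.ref_derived_fraction
    ref = np.where(ref_is_derived, der_base, anc_base)
    alt = np.where(ref_is_derived, anc_base, der_base)

    gt = derived.copy()
    flip = np.flatnonzero(ref_is_derived)
    gt[:, flip] = 2 - derived[:, flip]  # truth genotypes have no missing calls

    cls_names = np.array(CLASS_NAMES, dtype=object)[seg.cls]
    gene_id = np.array(
        [f"gene_{c + 1}_{(p - 1) // cfg.gene_length_bp}" for c, p in zip(chrom_i, pos)],
        dtype=object,
    )
    consequence = np.empty(n_sites, dtype=object)
    ex_score = np.full(n_sites, np.nan)
    for j in range(n_sites):
        cn = cls_names[j]
        if cn == "synonymous":
            consequence[j] = "synonymous_variant"
        elif cn == "lof":
            consequence[j] = LOF_CONSEQUENCE_CHOICES[rng.integers(0, len(LOF_CONSEQUENCE_CHOICES))]
        elif cn == "missense_deleterious":
            consequence[j] = "missense_variant"
            ex_score[j] = rng.uniform(0.01, 0.256)
        else:
            consequence[j] = "missense_variant"
            ex_score[j] = rng.uniform(0.30, 0.95)

    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "ancestral": anc_base,
            "gene_id": gene_id,
            "consequence": consequence,
            "ex_score": ex_score,
        }
    )

    gm = GenotypeMatrix(
        samples=samples,
        sites=sites.drop(columns=["ancestral"]),
        gt=gt,
    )

    truth_sites = sites[["chrom", "pos", "ancestral"]].copy()
    truth_sites["mutation_class"] = cls_names
    truth_sites["s"] = s_by_cls[seg.cls]
    truth_sites["h"] = h_by_cls[seg.cls]
    truth_sites["origin_pop"] = np.array(POP_NAMES, dtype=object)[seg.origin_pop]
    truth_sites["origin_gen_before_present"] = cfg.total_generations - seg.origin_gen
    truth_sites["fixed_in_species"] = fixed_flag

    pedigree_f = pd.DataFrame(
        {
            "sample": samples,
            "population": ["mainland"] * len(mnl_names) + ["island"] * len(isl_names),
            "pedigree_f": np.concatenate([mainland.f[mnl_idx], island.f[isl_idx]]),
        }
    )
    truth = SimTruth(config=cfg, sites=truth_sites, pedigree_f=pedigree_f)
    return gm, sites, truth


def sample_metadata(truth: SimTruth, species: str = "sim_guenon") -> pd.DataFrame:
    """Sample metadata table (sample_id, species, population)."""
    return pd.DataFrame(
        {
            "sample_id": truth.pedigree_f["sample"],
            "species": species,
            "population": truth.pedigree_f["population"],
        }
    )


def emit_outgroups(
    sites: pd.DataFrame,
    discordant_fraction: float = 0.0,
    het_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Three-outgroup genotype table for the polarisation stage.

    By default all three outgroups are homozygous for the true ancestral
    allele.  ``discordant_fraction`` of sites get one outgroup homozygous
    for the derived allele; a further ``het_fraction`` get one outgroup
    heterozygous — both make the polarisation filter drop the site.
    """
    for frac in (discordant_fraction, het_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    if discordant_fraction + het_fraction > 1.0 + 1e-12:
        raise ValueError("discordant and het fractions overlap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(sites)
    anc = sites["ancestral"].to_numpy(dtype=object)
    ref = sites["ref"].to_numpy(dtype=object)
    alt = sites["alt"].to_numpy(dtype=object)
    der = np.where(anc == ref, alt, ref)

    og = np.empty((n, 3), dtype=object)
    for k in range(3):
        og[:, k] = anc + "/" + anc

    perm = rng.permutation(n)
    n_disc = int(round(discordant_fraction * n))
    n_het = int(round(het_fraction * n))
    disc_idx = perm[:n_disc]
    het_idx = perm[n_disc : n_disc + n_het]
    which_d = rng.integers(0, 3, size=disc_idx.size)
    which_h = rng.integers(0, 3, size=het_idx.size)
    for i, k in zip(disc_idx, which_d):
        og[i, k] = f"{der[i]}/{der[i]}"
    for i, k in zip(het_idx, which_h):
        og[i, k] = f"{anc[i]}/{der[i]}"
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "out1": og[:, 0],
            "out2": og[:, 1],
            "out3": og[:, 2],
        }
    )
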
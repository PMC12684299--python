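"""Literal brute-force re-implementation of the sliding-window ROH rules.

Enumerates every window and applies each rule with plain Python loops;
deliberately shares no code with islepop.roh_diversity so it can serve as
an independent oracle.
"""

from islepop.roh_diversity import ROHParams, ROHSegment


def brute_force_roh(chrom, pos, gt, params: ROHParams, sample=""):
    segments = []
    seen = []
    for c in chrom:
        if c not in seen:
            seen.append(c)
    for c in seen:
        idx = [i for i, x in enumerate(chrom) if x == c]
        p = [int(pos[i]) for i in idx]
        g = [int(gt[i]) for i in idx]
        n = len(p)
        w = params.effective_window

        windows = [(a, a + w - 1) for a in range(0, n - w + 1)]
        hits = []
        for a, b in windows:
            n_het = sum(1 for j in range(a, b + 1) if g[j] == 1)
            n_mis = sum(1 for j in range(a, b + 1) if g[j] == -1)
            hits.append(
                n_het <= params.window_het_allowance
                and n_mis <= params.window_missing_allowance
            )

        eligible = []
        for j in range(n):
            containing = [k for k, (a, b) in enumerate(windows) if a <= j <= b]
            if not containing:
                eligible.append(False)
                continue
            frac = sum(1 for k in containing if hits[k]) / len(containing)
            eligible.append(frac > params.window_hit_threshold)

        # maximal runs of eligible SNPs, split at large gaps
        j = 0
        while j < n:
            if not eligible[j]:
                j += 1
                continue
            k = j
            while k + 1 < n and eligible[k + 1]:
                k += 1
            # split [j, k] at gaps
            pieces = []
            a = j
            for t in range(j, k):
                if p[t + 1] - p[t] > params.max_gap_kb * 1000:
                    pieces.append((a, t))
                    a = t + 1
            pieces.append((a, k))
            for a, b in pieces:
                n_snps = b - a + 1
                length = p[b] - p[a] + 1
                if n_snps < params.min_snps:
                    continue
                if length < params.min_length_kb * 1000:
                    continue
                if length / n_snps > params.max_density_kb_per_snp * 1000:
                    continue
                segments.append(
                    ROHSegment(
                        sample=sample,
                        chrom=str(c),
                        start=p[a],
                        end=p[b],
                        n_snps=n_snps,
                    )
                )
            j = k + 1
    return segments


def random_roh_instance(rng, max_snps=1000):
    """A random genotype track designed to stress the ROH rules."""
    n = int(rng.integers(10, max_snps + 1))
    n_chrom = int(rng.integers(1, 3))
    chrom = [f"chr{1 + (i * n_chrom) // n}" for i in range(n)]
    # spacing mixes dense runs and occasional huge gaps (to hit the gap rule)
    steps = rng.choice(
        [200, 2000, 8000, 60_000, 1_200_000], size=n, p=[0.3, 0.35, 0.2, 0.13, 0.02]
    )
    pos = []
    cur = 0
    last_c = None
    for i in range(n):
        if chrom[i] != last_c:
            cur = int(rng.integers(1, 10_000))
            last_c = chrom[i]
        else:
            cur += int(steps[i])
        pos.append(cur)
    # genotype: mostly homozygous stretches with het/missing clusters
    gt = []
    state = int(rng.integers(0, 2))
    for i in range(n):
        if rng.random() < 0.05:
            state = 1 - state
        if state == 0:
            gt.append(int(rng.choice([0, 2])))
        else:
            gt.append(int(rng.choice([0, 1, 2, -1], p=[0.3, 0.5, 0.1, 0.1])))
    params = ROHParams(
        min_snps=int(rng.integers(5, 40)),
        window_het_allowance=int(rng.integers(0, 3)),
        window_missing_allowance=int(rng.integers(0, 6)),
        window_hit_threshold=float(rng.choice([0.05, 0.2, 0.5])),
        min_length_kb=float(rng.choice([10.0, 100.0, 500.0])),
        max_gap_kb=float(rng.choice([100.0, 1000.0])),
        max_density_kb_per_snp=float(rng.choice([5.0, 50.0, 5000.0])),
    )
    return chrom, pos, gt, params
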
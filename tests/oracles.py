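"""Independently coded brute-force oracles.

Everything here is deliberately naive — exhaustive enumeration, scalar
arithmetic, quadratic scans — and shares no code with the package, so a
bug in the fast implementations cannot hide in its own reference.
"""

from itertools import combinations
import math

import numpy as np


def site_alleles(genotypes):
    """Expand diploid calls (0/1/2, -1 missing) into a haploid allele list."""
    out = []
    for g in genotypes:
        if g >= 0:
            out.extend([1] * int(g) + [0] * (2 - int(g)))
    return out


def pi_site(genotypes):
    """Mean pairwise difference over all allele pairs at one site."""
    alleles = site_alleles(genotypes)
    n = len(alleles)
    if n < 2:
        return float("nan")
    diffs = sum(abs(a - b) for a, b in combinations(alleles, 2))
    return diffs / math.comb(n, 2)


def windowed_pi(G, positions, start, end):
    """Per-bp pi over a half-open window from raw genotype columns."""
    total = 0.0
    for g_row, pos in zip(G, positions):
        if start <= pos < end:
            v = pi_site(g_row)
            if not math.isnan(v):
                total += v
    return total / (end - start)


def tajimas_d(pi_sum, S, n):
    """Tajima's D from summed pairwise diversity, S segregating sites, n alleles."""
    if S == 0 or n < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def tajimas_d_from_derived_counts(derived_counts, n):
    """D for one window given per-site derived allele counts (no missing)."""
    S = sum(1 for d in derived_counts if 0 < d < n)
    pi_sum = sum(
        d * (n - d) / math.comb(n, 2) for d in derived_counts if 0 < d < n
    )
    return tajimas_d(pi_sum, S, n)


def wc_theta(genotypes_a, genotypes_b):
    """Weir-Cockerham theta-hat for one site, two diploid populations.

    Scalar transcription of the 1984 variance components (r=2, observed
    heterozygosity, unequal sample sizes).  Returns (a, b, c, theta).
    """
    r = 2
    stats = []
    for gts in (genotypes_a, genotypes_b):
        called = [g for g in gts if g >= 0]
        n = len(called)
        if n < 2:
            return float("nan"), float("nan"), float("nan"), float("nan")
        p = sum(called) / (2.0 * n)
        h = sum(1 for g in called if g == 1) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return a, b, c, theta


def closest_genes(pos, intervals):
    """All nearest intervals for one SNP by quadratic scan.

    ``intervals``: (start, end, name) half-open 1-based.  Returns
    [(name, distance), ...] for every interval at the minimum distance.
    """
    dists = []
    for start, end, name in intervals:
        if start <= pos < end:
            d = 0
        elif pos < start:
            d = start - pos
        else:
            d = pos - (end - 1)
        dists.append((name, d))
    dmin = min(d for _, d in dists)
    return [(name, d) for name, d in dists if d == dmin]


def collapse_partition(segments, min_overlap):
    """Single-linkage clusters of (start, end) intervals; overlap fraction
    over the LONGER segment must exceed min_overlap.  Returns a list of
    frozensets of segment indices."""
    n = len(segments)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = segments[i][:2], segments[j][:2]
            ov = min(e1, e2) - max(s1, s2) + 1
            longer = max(e1 - s1 + 1, e2 - s2 + 1)
            if ov > 0 and ov / longer > min_overlap:
                adj[i].add(j)
                adj[j].add(i)
    seen, clusters = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        clusters.append(frozenset(comp))
    return clusters


def occupancy(genotypes, locations, minor_is_alt):
    """Exhaustive per-site occupancy: (n_carriers, any_hom, n_locations)."""
    carriers, homs, locs = 0, 0, set()
    for g, loc in zip(genotypes, locations):
        if g < 0:
            continue
        copies = g if minor_is_alt else 2 - g
        if copies >= 1:
            carriers += 1
            locs.add(loc)
        if copies == 2:
            homs += 1
    return carriers, homs > 0, len(locs)


def sharing_counts(carrier_location_lists, locations):
    """Location x location sharing by explicit double loop over ROHs."""
    idx = {l: i for i, l in enumerate(locations)}
    M = np.zeros((len(locations), len(locations)))
    for carrier_locs in carrier_location_lists:
        counts = np.zeros(len(locations))
        for l in carrier_locs:
            counts[idx[l]] += 1
        for i in range(len(locations)):
            for j in range(len(locations)):
                M[i, j] += counts[i] * counts[j]
    return M
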
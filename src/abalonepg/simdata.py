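"""Forward-time Wright-Fisher diploid simulator.

Generates desk-scale genotype data with the statistical structure the
analyses assume: two demes whose differentiation concentrates at designated
selected loci over a low genome-wide background, a severe recent bottleneck
followed by modest re-expansion (genome-wide negative Tajima's D, excess of
single-individual variants), and plantable long homozygous tracts.

Model summary
-------------
* Initialization from the neutral equilibrium site-frequency spectrum
  instead of burn-in: segregating site count ~ Poisson(theta*L*a_n) with
  theta = 4*N0*mu and a_n = sum 1/i, derived-allele copy numbers drawn
  with P(i) proportional to 1/i, alleles placed on random chromosomes.
  This seeds correct diversity instantly but NOT haplotype structure, so
  analyses that depend on LD must let the simulation run (>= ~100
  generations, or ~1/(2c) for the map distances of interest) before the
  measured epochs.
* Each generation, per deme: Wright-Fisher binomial resampling with
  fitness-weighted parent choice; an offspring is a migrant (both parents
  drawn from the other deme) with probability m.  Selection is additive
  within the advantaged deme: genotype fitness 1, 1+s/2, 1+s in copies of
  the advantaged allele (alt by default; a ref-allele entry at the same
  position expresses antagonistic local adaptation, the regime that keeps
  demes differentiated at a locus despite migration).
* Recombination: crossover count ~ Poisson(rate*L) per gamete per
  scaffold with uniform breakpoints; scaffolds assort independently.
* Mutation: infinite sites -- new mutations only at unused positions;
  sites fixed in the whole metapopulation are pruned each generation
  (counted), except selected loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from . import vcfio

MAX_TOTAL_DEMESIZE = 5_000
MAX_TOTAL_GENOME = 10_000_000


@dataclass
class SelectedLocus:
    scaffold: str
    pos: int
    s: float
    deme: int
    allele: str = "alt"  # which allele is advantaged in `deme`


@dataclass
class SimConfig:
    """Full parameterization of one simulation run.

    ``schedule`` lists (start_generation, per-deme diploid sizes); epochs
    are contiguous and the last one runs to ``n_generations``.  Rates are
    per bp per generation (``recomb`` 1e-8 == 1 cM/Mb).
    """

    scaffolds: list[tuple[str, int]]
    schedule: list[tuple[int, tuple[int, ...]]]
    n_generations: int
    mu: float
    recomb: float
    migration: float = 0.0
    selected: list[SelectedLocus] = field(default_factory=list)
    sample_sizes: tuple[int, ...] = (20,)
    seed: int = 0
    sfs_init: bool = True
    init_selected_freq: float = 0.5
    group_names: tuple[str, ...] = ("southeast", "northwest")
    locations_per_deme: int = 3
    depth_mean: float | None = 10.0

    def __post_init__(self) -> None:
        if sum(l for _, l in self.scaffolds) > MAX_TOTAL_GENOME:
            raise ValueError("total genome length exceeds desk-scale bound (10 Mb)")
        for _, sizes in self.schedule:
            if sum(sizes) > MAX_TOTAL_DEMESIZE:
                raise ValueError("total deme size exceeds desk-scale bound (5000)")
        if self.schedule[0][0] != 0:
            raise ValueError("schedule must start at generation 0")
        starts = [g for g, _ in self.schedule]
        if starts != sorted(starts):
            raise ValueError("schedule epochs must be in increasing order")
        lengths = dict(self.scaffolds)
        for loc in self.selected:
            if loc.scaffold not in lengths or not 1 <= loc.pos <= lengths[loc.scaffold]:
                raise ValueError(f"selected locus {loc} outside scaffold bounds")
        final_sizes = self.sizes_at(self.n_generations)
        if len(self.sample_sizes) != len(final_sizes):
            raise ValueError("one sample size per deme required")
        for n, N in zip(self.sample_sizes, final_sizes):
            if n > N:
                raise ValueError(f"sample of {n} exceeds final deme size {N}")

    @property
    def n_demes(self) -> int:
        return len(self.schedule[0][1])

    def sizes_at(self, gen: int) -> tuple[int, ...]:
        sizes = self.schedule[0][1]
        for g, s in self.schedule:
            if gen >= g:
                sizes = s
        return sizes


@dataclass
class SimResult:
    gm: GenotypeMatrix
    config: SimConfig
    selected_freqs: pd.DataFrame  # generation, deme, scaffold, pos, freq
    planted_tracts: list[dict] = field(default_factory=list)
    n_fixed_pruned: int = 0

    def true_ne_schedule(self) -> list[tuple[int, int]]:
        """(start_generation, total diploid size) per epoch."""
        return [(g, int(sum(s))) for g, s in self.config.schedule]


class _Scaffold:
    __slots__ = ("name", "length", "pos", "haps")

    def __init__(self, name: str, length: int, pos: np.ndarray, haps: np.ndarray):
        self.name = name
        self.length = length
        self.pos = pos          # sorted int positions, 1-based
        self.haps = haps        # (2N, S) uint8


def _sfs_init(rng, n_chrom: int, length: int, theta_per_bp: float) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium-SFS standing variation for one scaffold."""
    i = np.arange(1, n_chrom)
    a_n = np.sum(1.0 / i)
    n_sites = rng.poisson(theta_per_bp * length * a_n)
    n_sites = min(n_sites, length // 2)
    if n_sites == 0:
        return np.empty(0, dtype=np.int64), np.zeros((n_chrom, 0), dtype=np.uint8)
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_sites, replace=False))
    copies = rng.choice(i, size=n_sites, p=(1.0 / i) / a_n)
    haps = np.zeros((n_chrom, n_sites), dtype=np.uint8)
    for col, k in enumerate(copies):
        rows = rng.choice(n_chrom, size=k, replace=False)
        haps[rows, col] = 1
    return pos.astype(np.int64), haps


def _make_gametes(rng, sc: _Scaffold, parents: np.ndarray, recomb: float) -> np.ndarray:
    """One gamete row per entry of ``parents`` (global diploid indices)."""
    n_gam = parents.size
    S = sc.pos.size
    out = np.empty((n_gam, S), dtype=np.uint8)
    k = rng.poisson(recomb * sc.length, size=n_gam)
    phase = rng.integers(0, 2, size=n_gam)
    plain = k == 0
    out[plain] = sc.haps[2 * parents[plain] + phase[plain]]
    for g in np.flatnonzero(~plain):
        bps = np.sort(rng.uniform(0.0, sc.length, size=k[g]))
        which = (phase[g] + np.searchsorted(bps, sc.pos)) % 2
        h = sc.haps[2 * parents[g] : 2 * parents[g] + 2]
        out[g] = np.where(which == 0, h[0], h[1])
    return out


def simulate_population(cfg: SimConfig) -> SimResult:
    """Run the forward simulation and sample the final generation."""
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes_at(0)
    n_total = sum(sizes)
    theta = 4.0 * n_total * cfg.mu

    scaffolds: list[_Scaffold] = []
    sel_by_scaffold: dict[str, list[SelectedLocus]] = {}
    for loc in cfg.selected:
        sel_by_scaffold.setdefault(loc.scaffold, []).append(loc)
    for name, length in cfg.scaffolds:
        if cfg.sfs_init:
            pos, haps = _sfs_init(rng, 2 * n_total, length, theta)
        else:
            pos = np.empty(0, dtype=np.int64)
            haps = np.zeros((2 * n_total, 0), dtype=np.uint8)
        # insert selected loci at the configured initial frequency
        for loc in sel_by_scaffold.get(name, []):
            if loc.pos in pos:
                continue
            col = rng.binomial(1, cfg.init_selected_freq, size=2 * n_total).astype(np.uint8)
            at = np.searchsorted(pos, loc.pos)
            pos = np.insert(pos, at, loc.pos)
            haps = np.insert(haps, at, col, axis=1)
        scaffolds.append(_Scaffold(name, length, pos, haps))

    def deme_slices(szs):
        out, start = [], 0
        for N in szs:
            out.append(np.arange(start, start + N))
            start += N
        return out

    def fitness(szs) -> np.ndarray:
        w = np.ones(sum(szs))
        slices = deme_slices(szs)
        for sc in scaffolds:
            for loc in sel_by_scaffold.get(sc.name, []):
                col = np.searchsorted(sc.pos, loc.pos)
                if col >= sc.pos.size or sc.pos[col] != loc.pos:
                    continue
                alt_copies = sc.haps[0::2, col].astype(int) + sc.haps[1::2, col].astype(int)
                copies = alt_copies if loc.allele == "alt" else 2 - alt_copies
                idx = slices[loc.deme]
                w[idx] *= 1.0 + loc.s * copies[idx] / 2.0
        return w

    freq_rows = []

    def record_freqs(gen, szs):
        slices = deme_slices(szs)
        for sc in scaffolds:
            for loc in sel_by_scaffold.get(sc.name, []):
                col = np.searchsorted(sc.pos, loc.pos)
                if col >= sc.pos.size or sc.pos[col] != loc.pos:
                    continue
                for d, idx in enumerate(slices):
                    rows = np.concatenate([2 * idx, 2 * idx + 1])
                    freq_rows.append(
                        {"generation": gen, "deme": d, "scaffold": sc.name,
                         "pos": loc.pos, "freq": float(sc.haps[rows, col].mean())}
                    )

    n_fixed_pruned = 0
    used_positions = [set(sc.pos.tolist()) for sc in scaffolds]
    sel_positions = [
        {loc.pos for loc in sel_by_scaffold.get(sc.name, [])} for sc in scaffolds
    ]

    record_freqs(0, sizes)
    for gen in range(cfg.n_generations):
        next_sizes = cfg.sizes_at(gen + 1)
        w = fitness(sizes)
        slices = deme_slices(sizes)
        probs = []
        for idx in slices:
            wd = w[idx]
            probs.append(wd / wd.sum())

        mothers, fathers = [], []
        for d, N_next in enumerate(next_sizes):
            src = np.full(N_next, d)
            if cfg.migration > 0 and cfg.n_demes == 2:
                mig = rng.random(N_next) < cfg.migration
                src[mig] = 1 - d
            m_idx = np.empty(N_next, dtype=np.int64)
            f_idx = np.empty(N_next, dtype=np.int64)
            for sd in np.unique(src):
                sel = src == sd
                n_k = int(sel.sum())
                m_idx[sel] = rng.choice(slices[sd], size=n_k, p=probs[sd])
                f_idx[sel] = rng.choice(slices[sd], size=n_k, p=probs[sd])
            mothers.append(m_idx)
            fathers.append(f_idx)
        mother_idx = np.concatenate(mothers)
        father_idx = np.concatenate(fathers)
        n_next = mother_idx.size
        # gamete row order: individual i gets rows 2i (maternal), 2i+1 (paternal)
        parent_of_gamete = np.empty(2 * n_next, dtype=np.int64)
        parent_of_gamete[0::2] = mother_idx
        parent_of_gamete[1::2] = father_idx

        for s_i, sc in enumerate(scaffolds):
            new_haps = _make_gametes(rng, sc, parent_of_gamete, cfg.recomb)
            # mutations: infinite sites at unused positions
            n_mut = rng.poisson(cfg.mu * sc.length * 2 * n_next)
            if n_mut > 0:
                new_pos = []
                while len(new_pos) < n_mut:
                    cand = int(rng.integers(1, sc.length + 1))
                    if cand not in used_positions[s_i]:
                        used_positions[s_i].add(cand)
                        new_pos.append(cand)
                cols = np.zeros((2 * n_next, n_mut), dtype=np.uint8)
                rows = rng.integers(0, 2 * n_next, size=n_mut)
                cols[rows, np.arange(n_mut)] = 1
                pos_all = np.concatenate([sc.pos, np.array(new_pos, dtype=np.int64)])
                haps_all = np.concatenate([new_haps, cols], axis=1)
                order = np.argsort(pos_all, kind="mergesort")
                sc.pos = pos_all[order]
                sc.haps = haps_all[:, order]
            else:
                sc.haps = new_haps
            # prune fixed/lost (selected loci are kept alive as columns)
            freq = sc.haps.mean(axis=0)
            seg = (freq > 0) & (freq < 1)
            keep = seg | np.isin(sc.pos, list(sel_positions[s_i]))
            n_fixed_pruned += int(((freq == 1) & ~keep).sum())
            lost = (freq == 0) & ~keep
            used_positions[s_i] -= set(sc.pos[lost | ((freq == 1) & ~keep)].tolist())
            sc.pos = sc.pos[keep]
            sc.haps = sc.haps[:, keep]
        sizes = next_sizes
        record_freqs(gen + 1, sizes)

    gm = _sample_matrix(rng, cfg, scaffolds, sizes)
    return SimResult(
        gm=gm,
        config=cfg,
        selected_freqs=pd.DataFrame(
            freq_rows, columns=["generation", "deme", "scaffold", "pos", "freq"]
        ),
        n_fixed_pruned=n_fixed_pruned,
    )


def _sample_matrix(rng, cfg: SimConfig, scaffolds, sizes) -> GenotypeMatrix:
    # sample individuals without replacement, per deme
    start = 0
    chosen = []
    deme_of = []
    for d, (N, n) in enumerate(zip(sizes, cfg.sample_sizes)):
        pick = np.sort(rng.choice(np.arange(start, start + N), size=n, replace=False))
        chosen.append(pick)
        deme_of += [d] * n
        start += N
    chosen = np.concatenate(chosen)

    frames, gmats = [], []
    for sc in scaffolds:
        g = (
            sc.haps[2 * chosen][:, :].astype(np.int8)
            + sc.haps[2 * chosen + 1][:, :].astype(np.int8)
        ).T  # sites x samples
        has_alt = g.sum(axis=1) > 0
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": sc.name,
                    "pos": sc.pos[has_alt],
                    "ref": "A",
                    "alt": "C",
                }
            )
        )
        gmats.append(g[has_alt])

    names = []
    locations = []
    groups = []
    loc_counter = 1
    for d, n in enumerate(cfg.sample_sizes):
        group = cfg.group_names[d] if d < len(cfg.group_names) else f"deme{d}"
        loc_names = [f"loc{loc_counter + j}" for j in range(cfg.locations_per_deme)]
        loc_counter += cfg.locations_per_deme
        assignment = rng.integers(0, cfg.locations_per_deme, size=n)
        for j in range(n):
            names.append(f"{group[:2]}_{d}_{j:03d}")
            locations.append(loc_names[assignment[j]])
            groups.append(group)
    samples = pd.DataFrame({"sample": names, "location": locations, "group": groups})

    sites = pd.concat(frames, ignore_index=True)
    G = np.concatenate(gmats, axis=0) if gmats else np.zeros((0, len(names)), dtype=np.int8)
    depth = None
    if cfg.depth_mean is not None:
        depth = np.maximum(rng.poisson(cfg.depth_mean, size=G.shape), 1).astype(np.int32)
    gm = GenotypeMatrix(
        sites=sites, G=G, samples=samples, depth=depth, tag="full",
        scaffold_lengths=dict(cfg.scaffolds),
    )
    return gm.sort_sites()


# ---------------------------------------------------------------------------
# ROH planting and fixture output
# ---------------------------------------------------------------------------

def plant_roh(result: SimResult, sample: str, scaffold: str, start: int, end: int) -> SimResult:
    """Force one sample homozygous (major allele) across an interval.

    Mutates ``result`` in place and records the planted tract as ground
    truth; returns ``result`` for chaining.
    """
    gm = result.gm
    matches = np.flatnonzero((gm.samples["sample"] == sample).to_numpy())
    if matches.size != 1:
        raise ValueError(f"unknown sample {sample!r}")
    si = int(matches[0])
    in_tract = (
        (gm.sites["scaffold"] == scaffold)
        & (gm.sites["pos"] >= start)
        & (gm.sites["pos"] <= end)
    ).to_numpy()
    p = gm.alt_freq()
    major_gt = np.where(p > 0.5, 2, 0).astype(np.int8)
    gm.G[in_tract, si] = major_gt[in_tract]
    result.planted_tracts.append(
        {"sample": sample, "scaffold": scaffold, "start": int(start), "end": int(end)}
    )
    return result


def write_fixture(result: SimResult, out_dir) -> dict[str, Path]:
    """Write VCF + metadata TSV + ground-truth JSON; deterministic bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "sim.vcf",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    vcfio.write_vcf(result.gm, paths["vcf"])
    result.gm.samples.to_csv(paths["metadata"], sep="\t", index=False)
    truth = {
        "seed": result.config.seed,
        "scaffolds": result.config.scaffolds,
        "schedule": [[g, list(s)] for g, s in result.config.schedule],
        "selected_loci": [
            {"scaffold": l.scaffold, "pos": l.pos, "s": l.s, "deme": l.deme,
             "allele": l.allele}
            for l in result.config.selected
        ],
        "planted_tracts": result.planted_tracts,
        "n_fixed_pruned": result.n_fixed_pruned,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


# ---------------------------------------------------------------------------
# Scenario presets (the study conditions the analyses are exercised on)
# ---------------------------------------------------------------------------

def constant_config(
    N: int = 500, n_sample: int = 20, seed: int = 0,
    generations: int = 250, mu: float = 1e-7, recomb: float = 1e-7,
) -> SimConfig:
    """Single constant-size deme; neutral.  Warm-up long enough to build
    the LD that the Ne estimator reads for t in roughly [5, 100]."""
    return SimConfig(
        scaffolds=[(f"scaffold_{i + 1}", 1_500_000) for i in range(4)],
        schedule=[(0, (N,))],
        n_generations=generations,
        mu=mu,
        recomb=recomb,
        sample_sizes=(n_sample,),
        group_names=("all",),
        seed=seed,
    )


def bottleneck_config(
    n_sample: int = 20, seed: int = 0,
    n_ancestral: int = 50, ancestral_duration: int = 40,
    n_ancient: int = 2000, ancient_duration: int = 200,
    n_bottleneck: int = 40, bottleneck_duration: int = 5,
    n_recovered: int = 200, recovery_duration: int = 20,
    mu: float = 6e-8, recomb: float = 1e-7,
) -> SimConfig:
    """Severe recent bottleneck with modest re-expansion (single deme).

    The history has two parts.  A long-term expansion (small ancestral
    size, then a 40-fold larger population for ~200 generations) is what
    produces the genome-wide rare-allele excess — negative Tajima's D and
    a surplus of single-individual variants — exactly as post-glacial
    recolonization does in long-lived marine species.  On top of it sits
    the recent, census-severe crash (2000 -> 40 for 5 generations, then
    partial recovery at 200 for 20 generations before sampling).  That
    crash is coalescently mild — it barely dents the site-frequency
    spectrum — but its drift burst is clearly visible in LD, which is the
    point: the decline is detectable from r2 decay while diversity stays
    high.  A recent bottleneck alone cannot produce negative D; it prunes
    rare alleles and pushes D positive.
    """
    return SimConfig(
        scaffolds=[(f"scaffold_{i + 1}", 1_000_000) for i in range(3)],
        schedule=[
            (0, (n_ancestral,)),
            (ancestral_duration, (n_ancient,)),
            (ancestral_duration + ancient_duration, (n_bottleneck,)),
            (ancestral_duration + ancient_duration + bottleneck_duration, (n_recovered,)),
        ],
        n_generations=ancestral_duration + ancient_duration + bottleneck_duration
        + recovery_duration,
        mu=mu,
        recomb=recomb,
        sample_sizes=(n_sample,),
        group_names=("all",),
        seed=seed,
    )


def two_deme_selection_config(
    N: int = 1000, n_sample: int = 20, seed: int = 0,
    generations: int = 12, migration: float = 0.0,
    s: float = 0.5, n_selected: int = 8, mu: float = 1e-7, recomb: float = 1e-7,
) -> SimConfig:
    """Two demes, low background differentiation, selection on scaffold 1.

    A recent split of a large population: over T generations of isolation
    neutral background FST accumulates only to roughly T/(4N) (~0.006 at
    the defaults), so random SNPs in the tens or hundreds carry no usable
    structure signal, while antagonistic additive selection (alt advantaged
    in deme 0, ref in deme 1) at loci spread along scaffold 1 drives those
    loci most of the way to alternative fixation — differentiation
    concentrated on 1 of 5 scaffolds.
    """
    scaffolds = [(f"scaffold_{i + 1}", 600_000) for i in range(5)]
    step = 600_000 // (n_selected + 1)
    selected = []
    for k in range(n_selected):
        pos = (k + 1) * step
        selected.append(SelectedLocus("scaffold_1", pos, s, 0, "alt"))
        selected.append(SelectedLocus("scaffold_1", pos, s, 1, "ref"))
    return SimConfig(
        scaffolds=scaffolds,
        schedule=[(0, (N, N))],
        n_generations=generations,
        mu=mu,
        recomb=recomb,
        migration=migration,
        selected=selected,
        sample_sizes=(n_sample, n_sample),
        seed=seed,
    )


def roh_config(
    N: int = 500, n_sample: int = 30, seed: int = 0,
    generations: int = 5, mu: float = 2e-7, recomb: float = 1e-6,
) -> SimConfig:
    """Dense-SNP single deme for ROH detection tests.

    High mu supplies the SNP density a 100-SNP minimum ROH gate needs;
    the short run, moderate size and high per-bp recombination keep the
    background free of genuine long autozygous tracts (at small N with
    little recombination, whole-scaffold IBD segments arise naturally and
    would swallow planted tracts)."""
    return SimConfig(
        scaffolds=[("scaffold_1", 1_000_000), ("scaffold_2", 1_000_000)],
        schedule=[(0, (N,))],
        n_generations=generations,
        mu=mu,
        recomb=recomb,
        sample_sizes=(n_sample,),
        group_names=("all",),
        seed=seed,
    )
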
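"""Genomic differentiation between two genetic groups.

Per-SNP FST uses the Weir & Cockerham (1984) two-population diploid
estimator theta-hat = a / (a + b + c), built from the among-population (a),
among-individual-within-population (b) and within-individual (c) variance
components, with unequal sample sizes and observed heterozygosity.
Negative estimates are reported as-is (a display clamp is available but
never feeds computation).  The windowed estimator is the ratio of sums
sum(a) / sum(a+b+c) over the SNPs in a window — not the mean of per-SNP
ratios, which is biased for low-information SNPs.

Also provides outlier-window flagging at an empirical percentile
(nearest-rank), top-N SNP ranking, allele-frequency contrasts (delta AF),
fixed-vs-variable classification per grouping unit, and closest-gene
assignment against a BED/GFF annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, WindowStat, tile_windows

DEFAULT_OUTLIER_PERCENTILE = 99.9
DEFAULT_MIN_SCAFFOLD = 125_000


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def _group_arrays(gm: GenotypeMatrix, groups: tuple[str, str]):
    cols = []
    for g in groups:
        idx = np.flatnonzero((gm.samples["group"] == g).to_numpy())
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        cols.append(idx)
    return cols


def wc_components(gm: GenotypeMatrix, groups: tuple[str, str]):
    """Per-site (a, b, c) Weir-Cockerham components for two populations.

    Sites where either group has fewer than 2 non-missing genotypes get
    NaN components (theta undefined there).  Returns (a, b, c) arrays.
    """
    cols_a, cols_b = _group_arrays(gm, groups)
    r = 2
    n_i, p_i, h_i = [], [], []
    for idx in (cols_a, cols_b):
        sub = gm.G[:, idx]
        called = sub != MISSING
        n = called.sum(axis=1).astype(float)  # diploids with data
        alt = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
            h = np.where(n > 0, (sub == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n1, n2 = n_i
    p1, p2 = p_i
    h1, h2 = h_i

    valid = (n1 >= 2) & (n2 >= 2)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    bad = ~valid
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def fst_per_snp(gm: GenotypeMatrix, groups: tuple[str, str]) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham theta-hat with group frequencies and delta AF.

    Columns: scaffold, pos, p_<A>, p_<B>, delta_af, fst (NaN where
    undefined), plus per-location alt-allele frequencies ``loc_<id>``.
    theta may be negative; theta = a/(a+b+c), undefined when a+b+c = 0.
    """
    a, b, c = wc_components(gm, groups)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
    cols_a, cols_b = _group_arrays(gm, groups)
    out = gm.sites[["scaffold", "pos"]].copy()
    freqs = {}
    for label, idx in zip(groups, (cols_a, cols_b)):
        freqs[label] = gm.take_samples(idx).alt_freq()
        out[f"p_{label}"] = freqs[label]
    out["delta_af"] = np.abs(freqs[groups[0]] - freqs[groups[1]])
    out["fst"] = theta
    for loc in dict.fromkeys(gm.samples["location"]):
        idx = np.flatnonzero((gm.samples["location"] == loc).to_numpy())
        out[f"loc_{loc}"] = gm.take_samples(idx).alt_freq()
    return out


def fst_windowed(
    gm: GenotypeMatrix, groups: tuple[str, str], window: int = 50_000
) -> list[WindowStat]:
    """Ratio-of-sums windowed FST: sum(a)/sum(a+b+c) over SNPs per window."""
    a, b, c = wc_components(gm, groups)
    denom = a + b + c
    pos = gm.sites["pos"].to_numpy()
    scaff = gm.sites["scaffold"].to_numpy()
    out = []
    for name in gm.scaffolds():
        rows = np.flatnonzero(scaff == name)
        p = pos[rows]
        length = gm.scaffold_lengths.get(name, int(p.max()) if p.size else window)
        for start, end in tile_windows(length, window):
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="left")
            sub = rows[lo:hi]
            ok = sub[~np.isnan(denom[sub])]
            if ok.size == 0 or np.nansum(denom[ok]) == 0:
                out.append(WindowStat(name, start, end, "fst", float("nan"), len(sub)))
            else:
                val = float(np.nansum(a[ok]) / np.nansum(denom[ok]))
                out.append(WindowStat(name, start, end, "fst", val, len(sub)))
    return out


# ---------------------------------------------------------------------------
# Outlier windows / ranking
# ---------------------------------------------------------------------------

def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank empirical percentile (deterministic, inclusive)."""
    vals = np.sort(np.asarray(values, dtype=float))
    if vals.size == 0:
        raise ValueError("no defined values")
    rank = int(np.ceil(percentile / 100.0 * vals.size))
    rank = min(max(rank, 1), vals.size)
    return float(vals[rank - 1])


def outlier_windows(
    ws: list[WindowStat],
    percentile: float = DEFAULT_OUTLIER_PERCENTILE,
    min_scaffold_length: int | None = DEFAULT_MIN_SCAFFOLD,
    scaffold_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Flag windows with FST >= the nearest-rank percentile of defined windows.

    Windows on scaffolds shorter than ``min_scaffold_length`` can be
    excluded up-front (outliers on very short scaffolds are likely
    artifacts); pass ``min_scaffold_length=None`` to disable.
    """
    rows = []
    for w in ws:
        if (
            min_scaffold_length
            and scaffold_lengths
            and scaffold_lengths.get(w.scaffold, min_scaffold_length) < min_scaffold_length
        ):
            continue
        rows.append((w.scaffold, w.start, w.end, w.n_sites, w.value))
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_sites", "fst"])
    defined = df["fst"].dropna().to_numpy()
    if defined.size == 0:
        raise ValueError("no defined windows")
    cutoff = nearest_rank_percentile(defined, percentile)
    df["percentile_rank"] = df["fst"].rank(pct=True) * 100
    df["outlier"] = df["fst"] >= cutoff
    df.attrs["cutoff"] = cutoff
    return df


def top_differentiated(snps: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top n SNPs by theta-hat, ties broken by genome order; NaN excluded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    defined = snps.dropna(subset=["fst"])
    if n > len(defined):
        warnings.warn(
            f"requested top {n} but only {len(defined)} SNPs have defined FST",
            stacklevel=2,
        )
        n = len(defined)
    ordered = defined.sort_values(
        ["fst", "scaffold", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.head(n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fixed / variable classification
# ---------------------------------------------------------------------------

def classify_freq(p: float, tol: float = 0.0) -> str:
    if np.isnan(p):
        return "undefined"
    if p <= tol:
        return "fixed_ref"
    if p >= 1.0 - tol:
        return "fixed_alt"
    return "variable"


def fixed_variable_classify(
    snps: pd.DataFrame,
    unit_columns: list[str],
    tol: float = 0.0,
) -> pd.DataFrame:
    """Classify each SNP per grouping unit as fixed_ref/fixed_alt/variable.

    ``unit_columns`` names frequency columns of ``snps`` (e.g. the
    ``p_<group>`` or ``loc_<id>`` columns from :func:`fst_per_snp`).
    Fixation requires exact 0/1 by default; ``tol`` relaxes it.
    """
    out = snps[["scaffold", "pos"]].copy()
    for col in unit_columns:
        out[f"state_{col}"] = [classify_freq(p, tol) for p in snps[col]]
    return out


def shared_fixed_differences(
    snps: pd.DataFrame,
    unit_a_columns: list[str],
    other_group_column: str,
    tol: float = 0.0,
) -> pd.DataFrame:
    """Count, per unit, SNPs fixed in the unit for the allele opposite to a
    group fixed for the other allele ("shared fixed differences").

    For two units both fixed for the same allele at such a SNP, the SNP
    counts once for each unit; the pairwise sharing table counts SNPs where
    both units are fixed for the same allele opposing the other group.
    """
    other_state = np.array([classify_freq(p, tol) for p in snps[other_group_column]])
    unit_states = {
        c: np.array([classify_freq(p, tol) for p in snps[c]]) for c in unit_a_columns
    }

    def opposes(unit_s, other_s):
        return ((unit_s == "fixed_ref") & (other_s == "fixed_alt")) | (
            (unit_s == "fixed_alt") & (other_s == "fixed_ref")
        )

    counts = {c: int(opposes(s, other_state).sum()) for c, s in unit_states.items()}
    pair_rows = []
    cols = list(unit_a_columns)
    for i, ci in enumerate(cols):
        for cj in cols[i + 1 :]:
            both = (
                opposes(unit_states[ci], other_state)
                & opposes(unit_states[cj], other_state)
                & (unit_states[ci] == unit_states[cj])
            )
            pair_rows.append({"unit_a": ci, "unit_b": cj, "shared": int(both.sum())})
    per_unit = pd.DataFrame(
        {"unit": cols, "fixed_differences": [counts[c] for c in cols]}
    )
    pairs = pd.DataFrame(pair_rows, columns=["unit_a", "unit_b", "shared"])
    per_unit.attrs["pairs"] = pairs
    return per_unit


# ---------------------------------------------------------------------------
# Closest-gene assignment
# ---------------------------------------------------------------------------

@dataclass
class GeneInterval:
    """Gene interval in internal half-open 1-based coordinates [start, end)."""

    scaffold: str
    start: int
    end: int
    gene_id: str


def read_bed(path) -> list[GeneInterval]:
    """BED: 0-based half-open -> internal 1-based half-open (shift start +1)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            out.append(GeneInterval(f[0], int(f[1]) + 1, int(f[2]) + 1, name))
    return out


def read_gff3(path, feature: str = "gene") -> list[GeneInterval]:
    """GFF3: 1-based inclusive -> internal half-open (end + 1); strand ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            gene_id = f[8]
            for token in f[8].split(";"):
                if token.startswith(("ID=", "gene_id=")):
                    gene_id = token.split("=", 1)[1]
                    break
            out.append(GeneInterval(f[0], int(f[3]), int(f[4]) + 1, gene_id))
    return out


def write_bed(intervals: list[GeneInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda g: (g.scaffold, g.start)):
            fh.write(f"{iv.scaffold}\t{iv.start - 1}\t{iv.end - 1}\t{iv.gene_id}\n")


def closest_gene(snps: pd.DataFrame, annotation: list[GeneInterval]) -> pd.DataFrame:
    """Assign each SNP to the overlapping gene(s), else the nearest by bp.

    Distance is the unsigned bp gap between the SNP position and the
    nearest interval edge (0 when inside).  Ties and multiple overlaps are
    all reported; scaffolds absent from the annotation yield gene 'none'.
    """
    by_scaff: dict[str, list[GeneInterval]] = {}
    for iv in annotation:
        by_scaff.setdefault(iv.scaffold, []).append(iv)
    for lst in by_scaff.values():
        lst.sort(key=lambda g: (g.start, g.end))

    rows = []
    for _, snp in snps.iterrows():
        pos = int(snp["pos"])
        ivs = by_scaff.get(snp["scaffold"])
        if not ivs:
            rows.append(
                {"scaffold": snp["scaffold"], "pos": pos, "gene": "none",
                 "relation": "none", "distance": -1}
            )
            continue
        dists = []
        for iv in ivs:
            if iv.start <= pos < iv.end:
                d = 0
            elif pos < iv.start:
                d = iv.start - pos
            else:
                d = pos - (iv.end - 1)
            dists.append(d)
        dmin = min(dists)
        for iv, d in zip(ivs, dists):
            if d == dmin:
                rows.append(
                    {
                        "scaffold": snp["scaffold"],
                        "pos": pos,
                        "gene": iv.gene_id,
                        "relation": "within" if d == 0 else "closest",
                        "distance": d,
                    }
                )
    return pd.DataFrame(rows, columns=["scaffold", "pos", "gene", "relation", "distance"])
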
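"""Windowed nucleotide diversity, Tajima's D and individual heterozygosity.

Windows are non-overlapping tiles of a fixed width (default 50 kb);
terminal partial windows are retained and their true length is used as the
per-bp denominator for pi.  Per-bp pi makes monomorphic windows meaningful
(they report 0), matching the convention of windowed-diversity tools that
divide by window span rather than SNP count.

Tajima's D uses the canonical 1989 constants.  With missing data the
non-missing allele count varies across sites, so one window-level n is
needed; we use the median non-missing allele count over the window's SNPs,
a robust and documented choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, WindowStat, tile_windows

DEFAULT_WINDOW = 50_000


@dataclass
class HetSummary:
    """Per-sample heterozygosity (het calls / non-missing calls)."""

    het: pd.Series  # index: sample; NaN where no non-missing calls
    dataset_tag: str

    def flagged_undefined(self) -> list[str]:
        return list(self.het.index[self.het.isna()])


def _per_site_pi(gm: GenotypeMatrix) -> np.ndarray:
    """Unbiased per-site pi: (n/(n-1)) * 2*p*q with n non-missing alleles.

    Equals the mean pairwise difference over all C(n,2) haplotype pairs at
    the site (treating genotypes as unordered allele pairs).
    """
    alt, tot = gm.alt_allele_counts()
    n = tot.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        pi = np.where(n > 1, n / (n - 1) * 2.0 * p * (1.0 - p), np.nan)
    return pi


def _window_site_index(gm: GenotypeMatrix, window: int):
    """Yield (scaffold, start, end, site_row_indices) per tiled window."""
    pos = gm.sites["pos"].to_numpy()
    scaff = gm.sites["scaffold"].to_numpy()
    for name in gm.scaffolds():
        rows = np.flatnonzero(scaff == name)
        p = pos[rows]
        length = gm.scaffold_lengths.get(name, int(p.max()) if p.size else window)
        for start, end in tile_windows(length, window):
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="left")
            yield name, start, end, rows[lo:hi]


def windowed_pi(gm: GenotypeMatrix, window: int = DEFAULT_WINDOW) -> list[WindowStat]:
    """Per-bp nucleotide diversity in non-overlapping windows.

    Window value = sum of per-site pi over SNPs in the window, divided by
    the window's true length (monomorphic invariant positions contribute
    zero).  Windows with no SNPs report value 0 with n_sites 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    pi_site = _per_site_pi(gm)
    out = []
    for name, start, end, rows in _window_site_index(gm, window):
        vals = pi_site[rows]
        vals = vals[~np.isnan(vals)]
        out.append(
            WindowStat(name, start, end, "pi", float(vals.sum()) / (end - start), len(rows))
        )
    return out


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for a sample of n alleles."""
    if n < 2:
        raise ValueError("need at least 2 alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_counts(pi_sum: float, S: int, n: int) -> float:
    """Tajima's D from the window's summed pairwise diversity, S and n."""
    if S == 0 or n < 4:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - S / k["a1"]) / np.sqrt(var)


def windowed_tajimas_d(gm: GenotypeMatrix, window: int = DEFAULT_WINDOW) -> list[WindowStat]:
    """Tajima's D per window; undefined (NaN) when S = 0 or n < 4 alleles.

    n_sites reports the number of segregating sites used (S).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    pi_site = _per_site_pi(gm)
    alt, tot = gm.alt_allele_counts()
    seg = (alt > 0) & (alt < tot)
    out = []
    for name, start, end, rows in _window_site_index(gm, window):
        seg_rows = rows[seg[rows]]
        S = len(seg_rows)
        if S == 0:
            out.append(WindowStat(name, start, end, "tajimas_d", float("nan"), 0))
            continue
        n_med = int(np.median(tot[seg_rows]))
        pi_sum = float(np.nansum(pi_site[seg_rows]))
        d = tajimas_d_from_counts(pi_sum, S, n_med)
        out.append(WindowStat(name, start, end, "tajimas_d", float(d), S))
    return out


def mean_window_value(ws: list[WindowStat], weight_by_sites: bool = False) -> float:
    """Mean of defined window values, optionally site-count weighted.

    Both weightings are reported by the drivers since group-level means can
    be computed either way.
    """
    vals = np.array([w.value for w in ws], dtype=float)
    wts = np.array([w.n_sites for w in ws], dtype=float)
    ok = ~np.isnan(vals)
    if not ok.any():
        return float("nan")
    if weight_by_sites:
        if wts[ok].sum() == 0:
            return float("nan")
        return float(np.average(vals[ok], weights=wts[ok]))
    return float(vals[ok].mean())


def individual_heterozygosity(gm: GenotypeMatrix) -> HetSummary:
    """Fraction of non-missing calls that are heterozygous, per sample."""
    called = gm.G != MISSING
    het = gm.G == 1
    n_called = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_called > 0, het.sum(axis=0) / np.maximum(n_called, 1), np.nan)
    return HetSummary(
        het=pd.Series(frac, index=pd.Index(gm.samples["sample"], name="sample")),
        dataset_tag=gm.tag,
    )
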
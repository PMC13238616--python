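"""Core containers shared by every analysis module.

The central object is :class:`GenotypeMatrix`: a sites x samples matrix of
diploid genotype calls (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing)
with per-site metadata (scaffold, position, alleles) and per-sample metadata
(sampling location and genetic group).  All statistics downstream operate on
this container; missing calls are always excluded from frequency
denominators and never imputed (PCA mean-substitution is the documented
exception and lives in :mod:`abalonepg.structure`).

Coordinate conventions: positions are 1-based inclusive at every I/O
boundary (VCF, GFF, output tables); internal window arithmetic uses
half-open ``[start, end)`` windows in 1-based coordinates, i.e. a 50-kb
window starting at 1 covers positions 1..50000.  The conversion helpers
live here so no other module re-derives them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt"]
SAMPLE_COLUMNS = ["sample", "location", "group"]


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for many biallelic sites over many samples.

    Parameters
    ----------
    sites
        DataFrame with columns ``scaffold, pos, ref, alt`` (one row per
        site), sorted by (scaffold, pos) with no duplicate coordinates.
    G
        ``(n_sites, n_samples)`` int8 array of calls in {0, 1, 2, -1}.
    samples
        DataFrame with columns ``sample, location, group``.
    depth
        Optional ``(n_sites, n_samples)`` integer array of per-genotype
        sequencing depths.
    tag
        Which dataset stratum this matrix represents: ``full``, ``common``
        or ``rare``.
    scaffold_lengths
        Physical length in bp of each scaffold (from the VCF header or the
        simulator); used for window tiling and F_ROH denominators.
    """

    sites: pd.DataFrame
    G: np.ndarray
    samples: pd.DataFrame
    depth: np.ndarray | None = None
    tag: str = "full"
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.G.shape:
                raise ValueError("depth array shape must match genotypes")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def scaffolds(self) -> list[str]:
        return list(dict.fromkeys(self.sites["scaffold"]))

    # -- per-site summaries ---------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.G == MISSING

    def site_missing_fraction(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return self.missing_mask().mean(axis=1)

    def sample_missing_fraction(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return self.missing_mask().mean(axis=0)

    def alt_allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt allele count, total non-missing allele count) per site."""
        called = self.G != MISSING
        g = np.where(called, self.G, 0)
        alt = g.sum(axis=1)
        tot = 2 * called.sum(axis=1)
        return alt.astype(np.int64), tot.astype(np.int64)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency over non-missing calls; NaN if all missing."""
        alt, tot = self.alt_allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency in [0, 0.5] over non-missing calls.

        Ties at 0.5 take the alt allele as minor (affects nothing downstream).
        """
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def minor_is_alt(self) -> np.ndarray:
        """True where the minor allele is the alt allele (ties -> alt)."""
        p = self.alt_freq()
        return ~(p > 0.5)

    # -- subsetting ------------------------------------------------------
    def take_sites(self, idx: np.ndarray, tag: str | None = None) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx],
            G=self.G[idx],
            depth=None if self.depth is None else self.depth[idx],
            tag=self.tag if tag is None else tag,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            samples=self.samples.iloc[idx],
            G=self.G[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def subset_group(self, group: str) -> "GenotypeMatrix":
        idx = np.flatnonzero((self.samples["group"] == group).to_numpy())
        if idx.size == 0:
            raise ValueError(f"no samples in group {group!r}")
        return self.take_samples(idx)

    def drop_samples(self, names: list[str]) -> "GenotypeMatrix":
        keep = np.flatnonzero(~self.samples["sample"].isin(names).to_numpy())
        return self.take_samples(keep)

    def sort_sites(self) -> "GenotypeMatrix":
        order = self.sites.sort_values(["scaffold", "pos"], kind="mergesort").index.to_numpy()
        return self.take_sites(order)

    def genome_length(self) -> int:
        """Sum of known scaffold lengths (F_ROH denominator default)."""
        if self.scaffold_lengths:
            return int(sum(self.scaffold_lengths.values()))
        # fall back to max observed position per scaffold
        return int(self.sites.groupby("scaffold")["pos"].max().sum())


@dataclass
class WindowStat:
    """One statistic evaluated on one genomic window.

    ``start``/``end`` follow the internal half-open convention in 1-based
    coordinates; ``value`` is NaN when the statistic is undefined for the
    window (e.g. Tajima's D with no segregating sites).
    """

    scaffold: str
    start: int
    end: int
    statistic: str
    value: float
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start


def tile_windows(length: int, width: int) -> list[tuple[int, int]]:
    """Non-overlapping half-open tiles [1, 1+w), [1+w, 1+2w), ... over a scaffold.

    The terminal window is truncated to the scaffold end (true length is
    used by per-bp statistics).
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    out = []
    start = 1
    while start <= length:
        out.append((start, min(start + width, length + 1)))
        start += width
    return out


def windows_to_frame(ws: list[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in ws],
            "start": [w.start for w in ws],
            "end": [w.end for w in ws],
            "n_sites": [w.n_sites for w in ws],
            "statistic": [w.statistic for w in ws],
            "value": [w.value for w in ws],
        }
    )


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from a single global seed.

    Uses a CRC of the stage name so every randomized stage is independently
    reproducible from the one seed recorded in the run log.  Result is kept
    below 2**31 for portability.
    """
    import zlib

    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
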
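"""Runs of homozygosity: detection, summaries, collapsing, sharing, dating.

Detection follows the classic scanning-window hit-rate algorithm: a window
of ``window_snp`` consecutive SNPs slides one SNP at a time along each
scaffold of one individual; a window "hits" when it contains at most
``window_het`` heterozygous and ``window_missing`` missing calls; every
SNP's hit-rate is the fraction of windows containing it that hit, and SNPs
at hit-rate >= ``threshold`` are run-eligible.  Maximal eligible stretches
become segments when they satisfy the minimum SNP count, minimum length,
maximum internal gap and minimum SNP density gates.  Defaults are the
scanning tool's v1.9 defaults, with the minimum segment length overridden
to 100 kb, appropriate for a high-diversity marine invertebrate whose ROHs
are short.

A detected ROH of length L Mb coalesces, in expectation, t = 100/(2*L*r)
generations ago (r in cM/Mb): recombination whittles IBD tracts at rate
2*r*L per 100 cM per generation, so short segments are old and long
segments are recent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass
class ROHParams:
    """Scanning-window parameters (tool v1.9 defaults; min_length_bp per study)."""

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    hit_threshold: float = 0.05
    min_snps: int = 100
    min_length_bp: int = 100_000
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int = 50_000


@dataclass
class ROHSegment:
    sample: str
    scaffold: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class UniqueROH:
    uid: int
    scaffold: str
    start: int
    end: int
    members: list[ROHSegment]
    carriers: list[str] = field(default_factory=list)
    carrier_locations: list[str] = field(default_factory=list)


@dataclass
class IndividualROHSummary:
    sample: str
    nroh: int
    sroh_bp: int
    genome_length: int
    froh: float  # fraction of genome in segments >= the F_ROH length cutoff

    @property
    def sroh_fraction(self) -> float:
        return self.sroh_bp / self.genome_length


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _eligible_snps(het: np.ndarray, miss: np.ndarray, p: ROHParams) -> np.ndarray:
    """Hit-rate eligibility for one individual's calls along one scaffold."""
    m = len(het)
    w = p.window_snp
    # windows i..i+w-1 for i in [0, m-w]
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(miss)])
    n_win = m - w + 1
    hit = (
        (ch[w:] - ch[:n_win] <= p.window_het)
        & (cm[w:] - cm[:n_win] <= p.window_missing)
    ).astype(np.int64)
    # SNP j is in windows i in [max(0, j-w+1), min(j, n_win-1)]
    chit = np.concatenate([[0], np.cumsum(hit)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    n_containing = (hi - lo + 1).astype(float)
    n_hits = chit[hi + 1] - chit[lo]
    return (n_hits / n_containing) >= p.hit_threshold


def _segments_from_eligible(
    pos: np.ndarray, eligible: np.ndarray, p: ROHParams
) -> list[tuple[int, int, int]]:
    """(start, end, n_snps) for maximal eligible stretches passing all gates."""
    out = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return out
    # split stretches at non-eligible SNPs, then at physical gaps > max_gap
    breaks = np.flatnonzero(np.diff(idx) > 1)
    stretches = np.split(idx, breaks + 1)
    for run in stretches:
        sub = [run]
        gaps = np.flatnonzero(np.diff(pos[run]) > p.max_gap_bp)
        if gaps.size:
            sub = np.split(run, gaps + 1)
        for seg in sub:
            n = len(seg)
            if n < p.min_snps:
                continue
            start, end = int(pos[seg[0]]), int(pos[seg[-1]])
            length = end - start + 1
            if length < p.min_length_bp:
                continue
            if length / n > p.min_density_bp_per_snp:
                continue
            out.append((start, end, n))
    return out


def detect_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH segments for every sample on every scaffold."""
    p = params or ROHParams()
    segments: list[ROHSegment] = []
    scaff = gm.sites["scaffold"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    for name in gm.scaffolds():
        rows = np.flatnonzero(scaff == name)
        if rows.size < p.window_snp:
            warnings.warn(
                f"scaffold {name} has {rows.size} SNPs < window of {p.window_snp}; skipped"
            )
            continue
        sub = gm.G[rows]
        sub_pos = pos[rows]
        for si, sample in enumerate(gm.samples["sample"]):
            calls = sub[:, si]
            elig = _eligible_snps(calls == 1, calls == MISSING, p)
            for start, end, n in _segments_from_eligible(sub_pos, elig, p):
                segments.append(ROHSegment(sample, name, start, end, n))
    return segments


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_roh(
    segments: list[ROHSegment],
    samples: list[str],
    genome_length: int,
    froh_min_mb: float = 1.5,
) -> list[IndividualROHSummary]:
    """Per-sample NROH, SROH and F_ROH (segments >= froh_min_mb only)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in samples}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    out = []
    for s in samples:
        segs = by_sample[s]
        sroh = sum(x.length_bp for x in segs)
        long_bp = sum(x.length_bp for x in segs if x.length_mb >= froh_min_mb)
        out.append(
            IndividualROHSummary(
                sample=s, nroh=len(segs), sroh_bp=sroh,
                genome_length=genome_length, froh=long_bp / genome_length,
            )
        )
    return out


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [s.sample for s in segments],
            "scaffold": [s.scaffold for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "length_kb": [s.length_bp / 1e3 for s in segments],
        }
    )


# ---------------------------------------------------------------------------
# Collapsing across individuals
# ---------------------------------------------------------------------------

def _overlap_fraction(a: ROHSegment, b: ROHSegment, denominator: str) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    if denominator == "longer":
        return ov / max(a.length_bp, b.length_bp)
    if denominator == "shorter":
        return ov / min(a.length_bp, b.length_bp)
    if denominator == "reciprocal":
        return min(ov / a.length_bp, ov / b.length_bp)
    raise ValueError(f"unknown overlap denominator {denominator!r}")


def collapse_roh(
    segments: list[ROHSegment],
    min_overlap: float = 0.5,
    sample_locations: dict[str, str] | None = None,
    denominator: str = "longer",
) -> list[UniqueROH]:
    """Single-linkage collapse of segments that overlap by more than
    ``min_overlap`` of the longer segment (denominator configurable).

    The output is a partition of the input: every segment belongs to
    exactly one UniqueROH (possibly a singleton).  Consensus interval =
    median member start to median member end; cluster ids follow the
    leftmost member so the result is independent of input order.
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    segs = sorted(segments, key=lambda s: (s.scaffold, s.start, s.end, s.sample))
    parent = list(range(len(segs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # sweep within scaffold: only pairs whose intervals intersect can link
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if segs[j].scaffold != segs[i].scaffold or segs[j].start > segs[i].end:
                break
            if _overlap_fraction(segs[i], segs[j], denominator) > min_overlap:
                union(i, j)

    clusters: dict[int, list[ROHSegment]] = {}
    for i, seg in enumerate(segs):
        clusters.setdefault(find(i), []).append(seg)
    out = []
    for uid, root in enumerate(sorted(clusters)):
        members = clusters[root]
        start = int(np.median([m.start for m in members]))
        end = int(np.median([m.end for m in members]))
        carriers = sorted({m.sample for m in members})
        locs = sorted(
            {sample_locations[c] for c in carriers} if sample_locations else set()
        )
        out.append(
            UniqueROH(
                uid=uid, scaffold=members[0].scaffold, start=start, end=end,
                members=members, carriers=carriers, carrier_locations=locs,
            )
        )
    return out


def sharing_matrix(
    uniques: list[UniqueROH], sample_locations: dict[str, str]
) -> pd.DataFrame:
    """Location x location ROH-sharing counts, M = X^T X.

    X is the (unique ROH) x location incidence of carrier counts; the Gram
    matrix M is symmetric PSD, its diagonal counts within-location sharing.
    """
    locations = sorted(set(sample_locations.values()))
    X = np.zeros((len(uniques), len(locations)))
    loc_index = {l: i for i, l in enumerate(locations)}
    for r, u in enumerate(uniques):
        for carrier in u.carriers:
            X[r, loc_index[sample_locations[carrier]]] += 1
    M = X.T @ X
    return pd.DataFrame(M, index=locations, columns=locations)


# ---------------------------------------------------------------------------
# Coalescent dating
# ---------------------------------------------------------------------------

def date_roh(length_mb: float, r_cm_per_mb: float) -> float:
    """Expected coalescent age in generations: t = 100 / (2 * L * r).

    L in Mb, r in cM/Mb.  Strictly decreasing in both L and r: long
    segments and high recombination mean recent common ancestry.
    """
    if length_mb <= 0 or r_cm_per_mb <= 0:
        raise ValueError("segment length and recombination rate must be positive")
    return 100.0 / (2.0 * length_mb * r_cm_per_mb)
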
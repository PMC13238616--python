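"""PCA-based population structure and the SNP-count detectability scan.

The scan asks: how many SNPs are needed before two genetic groups separate
on PC1?  Random subsets of common SNPs are contrasted with the top-N most
differentiated SNPs (by per-SNP FST).  Because judging separation by eye is
not testable, separation is quantified as a two-group standardized mean
difference on PC1 (|mean_A - mean_B| / pooled within-group SD) with a
configurable detection threshold (default 2.0: clean two-cluster toys
always exceed it, label-free noise essentially never does).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

DEFAULT_DETECTION_THRESHOLD = 2.0


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x PCs (columns PC1..PCk)
    explained: np.ndarray         # per-PC explained-variance fraction
    n_snps: int
    selection_mode: str = "all"


@dataclass
class SeparationReport:
    size: int
    mode: str
    separation: float             # mean over replicates
    detected: bool
    replicate_separations: list[float]


def _normalized_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Samples x sites matrix, EIGENSTRAT-normalized.

    Each site is centered by 2*p and scaled by sqrt(p*(1-p)) where p is the
    alt-allele frequency over non-missing calls; missing calls contribute 0
    after centering (mean substitution).  Monomorphic sites get zero weight,
    so duplicating one never changes the scores.
    """
    p = gm.alt_freq()
    poly = (p > 0) & (p < 1)
    G = gm.G[poly].astype(float)
    p = p[poly]
    called = G != MISSING
    X = np.where(called, G, 2 * p[:, None]) - 2 * p[:, None]
    X /= np.sqrt(p * (1 - p))[:, None]
    return X.T  # samples x sites


def pca(gm: GenotypeMatrix, k: int = 10, seed: int | None = None) -> PCAResult:
    """PCA of the normalized genotype matrix; deterministic up to sign,
    with signs fixed by forcing the largest-magnitude loading positive.

    ``seed`` is accepted for interface uniformity; the decomposition itself
    is deterministic (full SVD, no randomized solver).
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = _normalized_matrix(gm)
    if X.shape[1] == 0:
        raise ValueError("all sites are monomorphic; PCA undefined")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(k, len(s))
    # sign convention: largest-|loading| entry of each PC positive
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * s[:k]
    var = s**2
    explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    frame = pd.DataFrame(
        scores,
        index=pd.Index(gm.samples["sample"], name="sample"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(scores=frame, explained=explained, n_snps=X.shape[1])


def group_separation(pc1: np.ndarray, groups: np.ndarray) -> float:
    """Two-group standardized mean difference of PC1 scores.

    |mean_A - mean_B| / pooled within-group SD.  When both groups have zero
    variance: 0 if the means agree, +inf otherwise (forced separation).
    """
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = np.asarray(pc1)[groups == labels[0]]
    b = np.asarray(pc1)[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    diff = abs(a.mean() - b.mean())
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / np.sqrt(pooled_var))


def subsample_pca_scan(
    gm: GenotypeMatrix,
    sizes: list[int],
    mode: str = "random",
    fst_ranking: pd.DataFrame | None = None,
    replicates: int = 5,
    seed: int = 0,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> list[SeparationReport]:
    """Structure-detectability scan over SNP subset sizes.

    ``random`` mode draws ``replicates`` independent subsets per size;
    ``top_differentiated`` mode takes the deterministic top-N SNPs by FST
    (ties broken by genome order) and runs once per size.  Each subset goes
    through PCA and :func:`group_separation` on PC1.
    """
    if mode not in ("random", "top_differentiated"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "top_differentiated" and fst_ranking is None:
        raise ValueError("top_differentiated mode requires fst_ranking")
    rng = np.random.default_rng(seed)
    groups = gm.samples["group"].to_numpy()

    if mode == "top_differentiated":
        from .differentiation import top_differentiated

        key = gm.sites.set_index(["scaffold", "pos"]).index

    reports = []
    for size in sizes:
        if size > gm.n_sites:
            warnings.warn(f"size {size} > {gm.n_sites} SNPs available; clipping")
            size = gm.n_sites
        seps = []
        if mode == "random":
            for _ in range(replicates):
                idx = rng.choice(gm.n_sites, size=size, replace=False)
                res = pca(gm.take_sites(np.sort(idx)), k=2)
                seps.append(group_separation(res.scores["PC1"].to_numpy(), groups))
        else:
            top = top_differentiated(fst_ranking, size)
            want = pd.MultiIndex.from_frame(top[["scaffold", "pos"]])
            idx = np.flatnonzero(key.isin(want))
            res = pca(gm.take_sites(idx), k=2)
            seps.append(group_separation(res.scores["PC1"].to_numpy(), groups))
        mean_sep = float(np.mean(seps))
        reports.append(
            SeparationReport(
                size=size,
                mode=mode,
                separation=mean_sep,
                detected=mean_sep > threshold,
                replicate_separations=seps,
            )
        )
    return reports


def scan_to_frame(reports: list[SeparationReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for i, s in enumerate(r.replicate_separations):
            rows.append(
                {"size": r.size, "mode": r.mode, "replicate": i,
                 "separation": s, "mean_separation": r.separation,
                 "detected": r.detected}
            )
    return pd.DataFrame(rows)
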
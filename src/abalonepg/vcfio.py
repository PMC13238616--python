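"""Read, filter, stratify and write variant data.

Implements the QC contract applied to the raw variant calls: per-genotype
depth masking (calls outside [min_depth, max_depth] become missing), then
site-level filters (biallelic SNPs only, missingness cap), then the
MAF-based split into the ``common`` (MAF >= threshold) and ``rare``
(MAF < threshold) strata used by the downstream analyses.

Depth filtering is deliberately per-genotype rather than per-site-mean:
a genotype whose depth falls outside the accepted range is set missing
first, and site missingness is evaluated afterwards.  This is the one
unambiguous, testable reading of a "depth < 4 and > 30" variant filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, SAMPLE_COLUMNS, GenotypeMatrix

DEFAULT_MIN_DEPTH = 4
DEFAULT_MAX_DEPTH = 30
DEFAULT_MAX_MISSING = 0.15
DEFAULT_MAF_THRESHOLD = 0.05

_NUCLEOTIDES = {"A", "C", "G", "T"}


class VCFParseError(RuntimeError):
    pass


@dataclass
class SampleQCReport:
    """Per-sample QC summary with explicit exclusion flags.

    Flagging never drops samples by itself: exclusion is an explicit
    downstream subset so that the decision is always visible in the driver.
    """

    missingness: pd.Series
    mean_depth: pd.Series | None
    flagged: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "reason"])
    )

    def flagged_samples(self) -> list[str]:
        return list(self.flagged["sample"])


def read_metadata(path) -> pd.DataFrame:
    """Read the 3-column sample metadata table (sample, location, group)."""
    md = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(SAMPLE_COLUMNS) - set(md.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns: {sorted(missing)}")
    return md[SAMPLE_COLUMNS]


# cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN/missing, 3 HOM_ALT
_GT_MAP = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf(path, metadata: pd.DataFrame) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix`.

    All records are kept, including indels and multiallelic sites — those
    are passed through untouched for :func:`filter_sites` to drop, so that
    the QC step is the single place where filtering rules live.  Every VCF
    sample must appear in ``metadata``; coordinates stay 1-based.
    """
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    known = set(metadata["sample"])
    for s in vcf_samples:
        if s not in known:
            raise VCFParseError(f"VCF sample {s!r} has no metadata entry")
    md = metadata.set_index("sample").loc[vcf_samples].reset_index()

    scaffold_lengths: dict[str, int] = {}
    try:
        for name, length in zip(vcf.seqnames, vcf.seqlens):
            scaffold_lengths[name] = int(length)
    except AttributeError:  # header without contig lengths
        pass

    scaffolds, positions, refs, alts = [], [], [], []
    gts, depths = [], []
    has_depth = False
    for i, rec in enumerate(vcf):
        try:
            scaffolds.append(rec.CHROM)
            positions.append(rec.POS)
            refs.append(rec.REF)
            alts.append(",".join(rec.ALT) if rec.ALT else ".")
            gts.append(_GT_MAP[rec.gt_types])
            d = rec.format("DP")
            if d is None:
                d = np.full(len(vcf_samples), -1, dtype=np.int32)
            else:
                d = d.reshape(-1).astype(np.int64)
                d[d < 0] = -1  # cyvcf2 encodes missing as large negatives
                has_depth = True
            depths.append(d)
        except Exception as exc:  # pragma: no cover - malformed input
            raise VCFParseError(f"malformed VCF record #{i + 1}: {exc}") from exc

    n = len(positions)
    sites = pd.DataFrame(
        {"scaffold": scaffolds, "pos": positions, "ref": refs, "alt": alts}
    )
    G = (
        np.vstack(gts)
        if n
        else np.zeros((0, len(vcf_samples)), dtype=np.int8)
    )
    depth = None
    if has_depth:
        depth = np.vstack([np.asarray(d, dtype=np.int32) for d in depths])
    gm = GenotypeMatrix(
        sites=sites, G=G, samples=md, depth=depth, tag="full",
        scaffold_lengths=scaffold_lengths,
    )
    return gm.sort_sites()


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT (and DP when depths are present)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for name, length in gm.scaffold_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples["sample"])
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT" if gm.depth is None else "GT:DP"
        for i in range(gm.n_sites):
            row = gm.sites.iloc[i]
            if gm.depth is None:
                calls = [gt_strings[int(g)] for g in gm.G[i]]
            else:
                calls = [
                    f"{gt_strings[int(g)]}:{int(d)}"
                    for g, d in zip(gm.G[i], gm.depth[i])
                ]
            fh.write(
                f"{row.scaffold}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(calls)
                + "\n"
            )


def _is_biallelic_snp(sites: pd.DataFrame) -> np.ndarray:
    ref_ok = sites["ref"].str.len().eq(1) & sites["ref"].isin(_NUCLEOTIDES)
    alt = sites["alt"].astype(str)
    alt_ok = alt.str.len().eq(1) & alt.isin(_NUCLEOTIDES)
    return (ref_ok & alt_ok).to_numpy()


def filter_sites(
    gm: GenotypeMatrix,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_depth: int = DEFAULT_MAX_DEPTH,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> GenotypeMatrix:
    """Apply the QC filters: depth masking, biallelic SNPs, missingness.

    Order matters and is part of the contract: (1) genotypes with depth
    outside [min_depth, max_depth] are set missing; (2) indels and
    non-biallelic records are removed; (3) sites with a missing fraction
    above ``max_missing`` (evaluated after depth masking) are removed.
    Idempotent: running the filter twice yields the same matrix.
    """
    if not min_depth < max_depth:
        raise ValueError("min_depth must be < max_depth")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")

    G = gm.G.copy()
    depth = gm.depth
    if depth is not None:
        bad = (depth < min_depth) | (depth > max_depth)
        G[bad] = MISSING
    masked = GenotypeMatrix(
        sites=gm.sites, G=G, samples=gm.samples, depth=depth, tag=gm.tag,
        scaffold_lengths=gm.scaffold_lengths,
    )
    keep = _is_biallelic_snp(gm.sites)
    keep &= masked.site_missing_fraction() <= max_missing
    out = masked.take_sites(np.flatnonzero(keep))
    if out.n_sites == 0:
        warnings.warn("all sites removed by QC filters", stacklevel=2)
    return out


def split_by_maf(
    gm: GenotypeMatrix, threshold: float = DEFAULT_MAF_THRESHOLD
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Partition sites into (common: MAF >= threshold, rare: MAF < threshold).

    MAF is computed across all individuals (non-missing calls).  The
    boundary MAF == threshold goes to the common stratum; monomorphic sites
    (MAF 0) are rare.  The two outputs partition the input exactly.
    """
    if not 0 < threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    maf = gm.maf()
    common_idx = np.flatnonzero(maf >= threshold)
    rare_idx = np.flatnonzero(~(maf >= threshold))  # NaN-mafs fall to rare
    return gm.take_sites(common_idx, tag="common"), gm.take_sites(rare_idx, tag="rare")


def sample_qc(
    gm: GenotypeMatrix,
    max_sample_missing: float = DEFAULT_MAX_MISSING,
    pc_scores: np.ndarray | None = None,
    pc_zscore_cutoff: float | None = None,
) -> SampleQCReport:
    """Flag samples for exclusion; never drops them.

    Samples with missingness strictly above ``max_sample_missing`` are
    flagged ``high_missingness``.  If PC scores and a z-score cutoff are
    supplied (see :mod:`abalonepg.structure`), samples whose PC1/PC2
    z-score magnitude exceeds the cutoff are flagged ``pca_outlier`` —
    there is no automatic numeric criterion for anomalous divergence, so
    the cutoff is always caller-supplied.
    """
    missing = pd.Series(gm.sample_missing_fraction(), index=gm.samples["sample"])
    mean_depth = None
    if gm.depth is not None:
        mean_depth = pd.Series(gm.depth.mean(axis=0), index=gm.samples["sample"])
    rows = [
        {"sample": s, "reason": "high_missingness"}
        for s, frac in missing.items()
        if frac > max_sample_missing
    ]
    if pc_scores is not None and pc_zscore_cutoff is not None:
        scores = np.asarray(pc_scores, dtype=float)
        z = (scores - scores.mean(axis=0)) / np.where(
            scores.std(axis=0) > 0, scores.std(axis=0), 1.0
        )
        outl = np.abs(z).max(axis=1) > pc_zscore_cutoff
        rows += [
            {"sample": s, "reason": "pca_outlier"}
            for s, o in zip(gm.samples["sample"], outl)
            if o
        ]
    flagged = pd.DataFrame(rows, columns=["sample", "reason"])
    return SampleQCReport(missingness=missing, mean_depth=mean_depth, flagged=flagged)


def write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write an output table with header comments recording parameters."""
    with open(path, "w") as fh:
        if params:
            for k, v in params.items():
                fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)
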
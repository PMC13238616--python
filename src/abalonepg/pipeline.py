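"""Config-driven orchestration of the full analysis.

``run`` executes the stages in dependency order — QC/stratification first,
then diversity, structure, differentiation, ROH, rare-allele and LD-Ne
stages on the appropriate stratum — writing one TSV per product, a
machine-readable ``summary.json`` with the headline numbers, and a run log
echoing every parameter and derived seed.  A single global seed fans out
to per-stage seeds via a stage-name hash so each randomized stage is
independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, differentiation, ne_ld, rare, roh, structure, vcfio
from .core import GenotypeMatrix, derive_seed, windows_to_frame

log = logging.getLogger("abalonepg")

ALL_STAGES = ("diversity", "structure", "differentiation", "roh", "rare", "ne")


@dataclass
class RunConfig:
    """Every knob of the pipeline, with the protocol defaults.

    The defaults reproduce the study protocol: depth 4/30, site and sample
    missingness 0.15, MAF split 0.05, 50-kb windows, 99.9th-percentile FST
    outliers, top-1000 differentiated SNPs, ROH minimum length 100 kb with
    >50% collapsing overlap, r = 1 cM/Mb (with 0.5 and 2 as sensitivity
    variants), LD thinning 1 kb / 10 Mb scaffolds / 500k SNP cap, and 40
    trajectory replicates.
    """

    vcf: str = ""
    metadata: str = ""
    out_dir: str = "results/run"
    annotation: str | None = None
    annotation_format: str = "bed"  # or "gff3"
    groups: tuple[str, str] | None = None
    exclude_samples: tuple[str, ...] = ()
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    # vcfio
    min_depth: int = 4
    max_depth: int = 30
    max_missing: float = 0.15
    max_sample_missing: float = 0.15
    maf_threshold: float = 0.05
    # windows
    window: int = 50_000
    # structure
    scan_sizes: tuple[int, ...] = (10, 100, 1_000, 10_000)
    scan_replicates: int = 5
    detection_threshold: float = 2.0
    pca_components: int = 10
    # differentiation
    outlier_percentile: float = 99.9
    min_scaffold_outlier: int = 125_000
    top_n: int = 1_000
    # roh
    roh_params: dict = field(default_factory=dict)
    froh_min_mb: float = 1.5
    collapse_overlap: float = 0.5
    genome_length: int | None = None
    # dating / ne
    rate_cm_per_mb: float = 1.0
    ne_min_spacing: int = 1_000
    ne_min_scaffold: int = 10_000_000
    ne_cap: int = 500_000
    ne_replicates: int = 40
    ne_bin_t_min: float = 5.0
    ne_bin_t_max: float = 140.0
    ne_bins: int = 20
    ne_max_pairs_per_scaffold: int = 50_000
    ne_min_pairs: int = 100
    ne_method: str = "sved"  # or "deconvolve"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for k in ("groups", "exclude_samples", "stages", "scan_sizes"):
            v = getattr(cfg, k)
            if isinstance(v, list):
                setattr(cfg, k, tuple(v))
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _detect_groups(gm: GenotypeMatrix) -> tuple[str, str]:
    groups = list(dict.fromkeys(gm.samples["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in metadata, found {groups}")
    return tuple(groups)


def load_input(cfg: RunConfig) -> GenotypeMatrix:
    """Read + QC: parse VCF, flag/exclude samples, filter sites."""
    md = vcfio.read_metadata(cfg.metadata)
    gm = vcfio.read_vcf(cfg.vcf, md)
    qc = vcfio.sample_qc(gm, cfg.max_sample_missing)
    drop = set(cfg.exclude_samples) | set(qc.flagged_samples())
    if drop:
        log.info("excluding %d samples: %s", len(drop), sorted(drop))
        gm = gm.drop_samples(sorted(drop))
    return vcfio.filter_sites(gm, cfg.min_depth, cfg.max_depth, cfg.max_missing)


def run(cfg: RunConfig) -> Path:
    """Execute all enabled stages; returns the report directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.to_dict()
    summary: dict = {"parameters": params, "seeds": {}}

    def stage_seed(name: str) -> int:
        s = derive_seed(cfg.seed, name)
        summary["seeds"][name] = s
        return s

    try:
        full = load_input(cfg)
    except Exception as exc:
        raise StageError("input", exc)
    common, rare_gm = vcfio.split_by_maf(full, cfg.maf_threshold)
    summary["n_sites_full"] = full.n_sites
    summary["n_sites_common"] = common.n_sites
    summary["n_sites_rare"] = rare_gm.n_sites
    summary["n_samples"] = full.n_samples
    needs_groups = {"structure", "differentiation"} & set(cfg.stages)
    if cfg.groups:
        groups = cfg.groups
    else:
        try:
            groups = _detect_groups(full)
        except ValueError as exc:
            if needs_groups:
                raise StageError("input", exc)
            groups = None
    summary["groups"] = list(groups) if groups else None

    for name in cfg.stages:
        try:
            _STAGES[name](cfg, full, common, rare_gm, groups, out, summary, stage_seed)
        except Exception as exc:  # pragma: no cover - error path
            _write_summary(summary, out)
            raise StageError(name, exc)
        log.info("stage %s done", name)

    _write_summary(summary, out)
    return out


def _write_summary(summary: dict, out: Path) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_jsonable, sort_keys=True)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not jsonable: {type(x)}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_diversity(cfg, full, common, rare_gm, groups, out, summary, stage_seed):
    pws = diversity.windowed_pi(full, cfg.window)
    dws = diversity.windowed_tajimas_d(full, cfg.window)
    vcfio.write_tsv(windows_to_frame(pws), out / "pi_windows.tsv", {"window": cfg.window})
    vcfio.write_tsv(windows_to_frame(dws), out / "tajimas_d_windows.tsv", {"window": cfg.window})
    summary["mean_pi"] = diversity.mean_window_value(pws)
    summary["mean_tajimas_d"] = diversity.mean_window_value(dws)
    summary["mean_tajimas_d_weighted"] = diversity.mean_window_value(dws, weight_by_sites=True)
    for g in groups or ():
        sub = full.subset_group(g)
        summary[f"mean_pi_{g}"] = diversity.mean_window_value(
            diversity.windowed_pi(sub, cfg.window)
        )
        summary[f"mean_tajimas_d_{g}"] = diversity.mean_window_value(
            diversity.windowed_tajimas_d(sub, cfg.window)
        )
    het_rows = []
    for gm in (full, common):
        het = diversity.individual_heterozygosity(gm)
        summary[f"mean_het_{gm.tag}"] = float(het.het.mean())
        het_rows.append(
            pd.DataFrame({"sample": het.het.index, "dataset": gm.tag, "het": het.het.values})
        )
    vcfio.write_tsv(pd.concat(het_rows, ignore_index=True), out / "heterozygosity.tsv")


def _stage_structure(cfg, full, common, rare_gm, groups, out, summary, stage_seed):
    res = structure.pca(common, k=cfg.pca_components)
    frame = res.scores.reset_index().merge(common.samples, on="sample")
    vcfio.write_tsv(frame, out / "pca_scores.tsv", {"n_snps": res.n_snps})
    summary["pca_explained"] = res.explained.tolist()
    snps = differentiation.fst_per_snp(common, groups)
    reports = structure.subsample_pca_scan(
        common,
        sizes=list(cfg.scan_sizes),
        mode="random",
        replicates=cfg.scan_replicates,
        seed=stage_seed("structure.random_scan"),
        threshold=cfg.detection_threshold,
    )
    reports += structure.subsample_pca_scan(
        common,
        sizes=list(cfg.scan_sizes),
        mode="top_differentiated",
        fst_ranking=snps,
        seed=stage_seed("structure.top_scan"),
        threshold=cfg.detection_threshold,
    )
    vcfio.write_tsv(structure.scan_to_frame(reports), out / "structure_scan.tsv")
    summary["scan"] = [
        {"size": r.size, "mode": r.mode, "separation": r.separation, "detected": r.detected}
        for r in reports
    ]


def _stage_differentiation(cfg, full, common, rare_gm, groups, out, summary, stage_seed):
    snps = differentiation.fst_per_snp(common, groups)
    vcfio.write_tsv(snps, out / "fst_per_snp.tsv", {"groups": groups})
    ws = differentiation.fst_windowed(common, groups, cfg.window)
    vcfio.write_tsv(windows_to_frame(ws), out / "fst_windows.tsv", {"window": cfg.window})
    summary["mean_fst_snp"] = float(snps["fst"].mean())
    vals = [w.value for w in ws if not np.isnan(w.value)]
    summary["mean_fst_window"] = float(np.mean(vals)) if vals else float("nan")
    outl = differentiation.outlier_windows(
        ws, cfg.outlier_percentile, cfg.min_scaffold_outlier, common.scaffold_lengths
    )
    vcfio.write_tsv(outl, out / "fst_outlier_windows.tsv",
                    {"percentile": cfg.outlier_percentile, "cutoff": outl.attrs["cutoff"]})
    summary["n_outlier_windows"] = int(outl["outlier"].sum())
    summary["outlier_scaffolds"] = (
        outl[outl["outlier"]].groupby("scaffold").size().to_dict()
    )
    top = differentiation.top_differentiated(snps, cfg.top_n)
    vcfio.write_tsv(top, out / "top_differentiated.tsv", {"n": cfg.top_n})
    summary["top_snp_scaffolds"] = top.groupby("scaffold").size().to_dict()
    if cfg.annotation:
        reader = differentiation.read_gff3 if cfg.annotation_format == "gff3" else differentiation.read_bed
        genes = differentiation.closest_gene(top, reader(cfg.annotation))
        vcfio.write_tsv(genes, out / "closest_genes.tsv")
        summary["n_genes_hit"] = int(genes[genes["gene"] != "none"]["gene"].nunique())


def _stage_roh(cfg, full, common, rare_gm, groups, out, summary, stage_seed):
    params = roh.ROHParams(**cfg.roh_params)
    segments = roh.detect_roh(full, params)
    vcfio.write_tsv(roh.segments_to_frame(segments), out / "roh_segments.tsv",
                    {"min_length_bp": params.min_length_bp})
    genome_length = cfg.genome_length or full.genome_length()
    summaries = roh.summarize_roh(
        segments, list(full.samples["sample"]), genome_length, cfg.froh_min_mb
    )
    sdf = pd.DataFrame(
        {
            "sample": [s.sample for s in summaries],
            "nroh": [s.nroh for s in summaries],
            "sroh_bp": [s.sroh_bp for s in summaries],
            "sroh_fraction": [s.sroh_fraction for s in summaries],
            "froh": [s.froh for s in summaries],
        }
    )
    vcfio.write_tsv(sdf, out / "roh_individual.tsv", {"genome_length": genome_length})
    summary["nroh_mean"] = float(sdf["nroh"].mean())
    summary["sroh_mean_bp"] = float(sdf["sroh_bp"].mean())
    summary["froh_mean"] = float(sdf["froh"].mean())
    loc_of = dict(zip(full.samples["sample"], full.samples["location"]))
    uniques = roh.collapse_roh(segments, cfg.collapse_overlap, loc_of)
    udf = pd.DataFrame(
        {
            "uid": [u.uid for u in uniques],
            "scaffold": [u.scaffold for u in uniques],
            "start": [u.start for u in uniques],
            "end": [u.end for u in uniques],
            "n_carriers": [len(u.carriers) for u in uniques],
            "n_locations": [len(u.carrier_locations) for u in uniques],
        }
    )
    vcfio.write_tsv(udf, out / "roh_unique.tsv", {"min_overlap": cfg.collapse_overlap})
    share = roh.sharing_matrix(uniques, loc_of)
    share.to_csv(out / "roh_sharing.tsv", sep="\t")
    summary["n_roh_segments"] = len(segments)
    summary["n_unique_roh"] = len(uniques)
    if segments:
        lengths = [s.length_mb for s in segments]
        summary["roh_age_youngest_gen"] = roh.date_roh(max(lengths), cfg.rate_cm_per_mb)
        summary["roh_age_oldest_gen"] = roh.date_roh(min(lengths), cfg.rate_cm_per_mb)


def _stage_rare(cfg, full, common, rare_gm, groups, out, summary, stage_seed):
    occ = rare.allele_occupancy(rare_gm)
    vcfio.write_tsv(occ, out / "rare_occupancy.tsv")
    rs = rare.rare_summaries(occ, rare_gm)
    summary["rare_fraction_of_full"] = rare_gm.n_sites / max(full.n_sites, 1)
    summary["single_individual_fraction_of_rare"] = rs.single_fraction
    summary["private_fraction_of_rare"] = rs.private_fraction
    summary["single_het_fraction"] = rs.single_het_fraction
    vcfio.write_tsv(
        rs.per_location_singles.rename("n_singles").rename_axis("location").reset_index(),
        out / "rare_per_location.tsv",
    )
    vcfio.write_tsv(
        rs.location_sharing_histogram.rename("n_variants")
        .rename_axis("n_locations").reset_index(),
        out / "rare_location_sharing.tsv",
    )


def _stage_ne(cfg, full, common, rare_gm, groups, out, summary, stage_seed):
    inp = ne_ld.prepare_ne_input(
        full, cfg.ne_min_spacing, cfg.ne_min_scaffold, cfg.ne_cap,
        seed=stage_seed("ne.thin"),
    )
    bins = ne_ld.default_bin_grid(cfg.ne_bin_t_min, cfg.ne_bin_t_max, cfg.ne_bins)
    ld = ne_ld.ld_r2_binned(
        inp, cfg.rate_cm_per_mb, bins,
        max_pairs_per_scaffold=cfg.ne_max_pairs_per_scaffold,
        seed=stage_seed("ne.pairs"), maf_min=cfg.maf_threshold,
        min_pairs=cfg.ne_min_pairs,
    )
    if cfg.ne_method == "deconvolve":
        traj = ne_ld.ne_trajectory_deconvolved(
            ld, replicates=cfg.ne_replicates, seed=stage_seed("ne.replicates")
        )
    else:
        traj = ne_ld.ne_trajectory(
            ld, replicates=cfg.ne_replicates, seed=stage_seed("ne.replicates")
        )
    vcfio.write_tsv(
        traj, out / "ne_trajectory.tsv",
        {"rate_cm_per_mb": cfg.rate_cm_per_mb, "replicates": cfg.ne_replicates,
         "thinning": inp.log, "method": cfg.ne_method},
    )
    summary["ne_trajectory"] = traj.to_dict(orient="records")


_STAGES = {
    "diversity": _stage_diversity,
    "structure": _stage_structure,
    "differentiation": _stage_differentiation,
    "roh": _stage_roh,
    "rare": _stage_rare,
    "ne": _stage_ne,
}


def recombination_sensitivity(cfg: RunConfig, rates: list[float]) -> pd.DataFrame:
    """Run Ne reconstruction and ROH dating at several recombination rates.

    Ages and time axes scale exactly as 1/r: the physical data are fixed
    and r only enters the bp->Morgan and length->age conversions.
    """
    if len(rates) < 2:
        raise ValueError("need at least 2 rates")
    full = load_input(cfg)
    segments = roh.detect_roh(full, roh.ROHParams(**cfg.roh_params))
    inp = ne_ld.prepare_ne_input(
        full, cfg.ne_min_spacing, cfg.ne_min_scaffold, cfg.ne_cap,
        seed=derive_seed(cfg.seed, "ne.thin"),
    )
    rows = []
    for r in rates:
        bins = ne_ld.default_bin_grid(cfg.ne_bin_t_min, cfg.ne_bin_t_max, cfg.ne_bins)
        ld = ne_ld.ld_r2_binned(
            inp, r, bins, max_pairs_per_scaffold=cfg.ne_max_pairs_per_scaffold,
            seed=derive_seed(cfg.seed, "ne.pairs"), maf_min=cfg.maf_threshold,
            min_pairs=cfg.ne_min_pairs,
        )
        traj = ne_ld.ne_trajectory(
            ld, replicates=cfg.ne_replicates, seed=derive_seed(cfg.seed, "ne.replicates")
        )
        for _, row in traj.iterrows():
            rows.append({"rate_cm_per_mb": r, "kind": "ne", **row.to_dict()})
        for seg in segments:
            rows.append(
                {
                    "rate_cm_per_mb": r,
                    "kind": "roh_age",
                    "sample": seg.sample,
                    "scaffold": seg.scaffold,
                    "start": seg.start,
                    "length_mb": seg.length_mb,
                    "age_gen": roh.date_roh(seg.length_mb, r),
                }
            )
    return pd.DataFrame(rows)
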
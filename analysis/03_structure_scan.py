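"""Population structure and the SNP-count detectability scan.

PCA on the common-allele stratum, then the question the whole exercise
turns on: how many random SNPs does it take to see the two groups, versus
how few top-FST SNPs suffice?  With differentiation concentrated on one
scaffold, ten top SNPs separate the groups cleanly while ten — or a
hundred — random SNPs show nothing.
"""

from pathlib import Path

from abalonepg import differentiation, structure, vcfio

FIX = Path("results/fixtures/two_deme")
OUT = Path("results/structure")
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    md = vcfio.read_metadata(FIX / "metadata.tsv")
    full = vcfio.filter_sites(vcfio.read_vcf(FIX / "sim.vcf", md))
    common, _ = vcfio.split_by_maf(full)
    groups = ("southeast", "northwest")

    res = structure.pca(common, k=4)
    print(f"PCA on {res.n_snps} SNPs; PC1 explains {res.explained[0]:.1%}")
    vcfio.write_tsv(
        res.scores.reset_index().merge(common.samples, on="sample"),
        OUT / "pca_scores.tsv", {"n_snps": res.n_snps},
    )

    snps = differentiation.fst_per_snp(common, groups)
    reports = structure.subsample_pca_scan(
        common, [10, 100, 1000], mode="random", replicates=5, seed=SEED
    )
    reports += structure.subsample_pca_scan(
        common, [10, 100], mode="top_differentiated", fst_ranking=snps, seed=SEED
    )
    vcfio.write_tsv(structure.scan_to_frame(reports), OUT / "scan.tsv")
    print("size  mode               separation  detected")
    for r in reports:
        print(f"{r.size:>5} {r.mode:<18} {r.separation:>9.2f}  {r.detected}")


if __name__ == "__main__":
    main()
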
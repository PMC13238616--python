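"""The landscape of differentiation between the two genetic groups.

Per-SNP and 50-kb windowed Weir-Cockerham FST, outlier windows at the
99.9th percentile, the most-differentiated SNPs with their allele-frequency
contrast, fixed-vs-variable classification per group, and closest-gene
assignment against a toy annotation of the selected scaffold.
"""

from pathlib import Path

import numpy as np

from abalonepg import differentiation as diff
from abalonepg import vcfio
from abalonepg.core import windows_to_frame

FIX = Path("results/fixtures/two_deme")
OUT = Path("results/differentiation")
GROUPS = ("southeast", "northwest")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    md = vcfio.read_metadata(FIX / "metadata.tsv")
    full = vcfio.filter_sites(vcfio.read_vcf(FIX / "sim.vcf", md))
    common, _ = vcfio.split_by_maf(full)

    snps = diff.fst_per_snp(common, GROUPS)
    ws = diff.fst_windowed(common, GROUPS, 50_000)
    print(f"mean per-SNP FST {np.nanmean(snps['fst']):.4f}; "
          f"mean windowed FST {np.nanmean([w.value for w in ws]):.4f}")
    vcfio.write_tsv(snps, OUT / "fst_per_snp.tsv", {"groups": GROUPS})
    vcfio.write_tsv(windows_to_frame(ws), OUT / "fst_windows.tsv")

    outl = diff.outlier_windows(ws, 99.0, None)
    flagged = outl[outl["outlier"]]
    print(f"{len(flagged)} outlier windows, on scaffolds "
          f"{sorted(set(flagged['scaffold']))}")
    vcfio.write_tsv(outl, OUT / "outlier_windows.tsv")

    top = diff.top_differentiated(snps, 100)
    conc = top.groupby("scaffold").size().sort_values(ascending=False)
    print("top-100 SNPs per scaffold:", conc.to_dict())
    vcfio.write_tsv(top, OUT / "top100.tsv")

    classified = diff.fixed_variable_classify(top, [f"p_{g}" for g in GROUPS])
    vcfio.write_tsv(classified, OUT / "fixed_variable.tsv")

    # toy annotation: one gene straddling each selected locus
    genes = [
        diff.GeneInterval("scaffold_1", p - 5_000, p + 5_000, f"gene_{i}")
        for i, p in enumerate(range(46_153, 600_000, 46_153))
    ]
    assign = diff.closest_gene(top, genes)
    print(f"{(assign['relation'] == 'within').sum()} of top-100 SNPs inside genes")
    vcfio.write_tsv(assign, OUT / "closest_genes.tsv")


if __name__ == "__main__":
    main()
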
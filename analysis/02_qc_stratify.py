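"""QC and dataset stratification of the simulated cohort.

Applies the variant filters (per-genotype depth 4-30, site missingness
<= 15%, biallelic SNPs only), flags high-missingness samples, and splits
the surviving variants into the common (MAF >= 0.05) and rare (MAF < 0.05)
strata that the downstream analyses consume.
"""

from pathlib import Path

from abalonepg import vcfio

FIX = Path("results/fixtures/two_deme")
OUT = Path("results/qc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    md = vcfio.read_metadata(FIX / "metadata.tsv")
    raw = vcfio.read_vcf(FIX / "sim.vcf", md)
    qc = vcfio.sample_qc(raw)
    print(f"parsed {raw.n_sites} records, {raw.n_samples} samples; "
          f"{len(qc.flagged)} samples flagged")
    full = vcfio.filter_sites(raw)
    common, rare = vcfio.split_by_maf(full)
    print(f"full: {full.n_sites}  common: {common.n_sites} "
          f"({100 * common.n_sites / full.n_sites:.0f}%)  rare: {rare.n_sites} "
          f"({100 * rare.n_sites / full.n_sites:.0f}%)")
    vcfio.write_tsv(
        qc.missingness.rename("missingness").rename_axis("sample").reset_index(),
        OUT / "sample_missingness.tsv",
    )
    vcfio.write_vcf(full, OUT / "full.vcf")


if __name__ == "__main__":
    main()
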
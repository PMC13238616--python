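"""Rare-allele occupancy: single-individual variants and private variants.

Contrasts the bottleneck cohort with a constant-size control: a recovering
population carries an excess of variants seen in just one individual,
because recent mutations have not had time to spread.
"""

from pathlib import Path

from abalonepg import rare, vcfio

OUT = Path("results/rare")


def load(fixture: str):
    fix = Path("results/fixtures") / fixture
    md = vcfio.read_metadata(fix / "metadata.tsv")
    return vcfio.filter_sites(vcfio.read_vcf(fix / "sim.vcf", md))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bott = load("bottleneck")
    const = load("constant")

    occ = rare.allele_occupancy(bott)
    rs = rare.rare_summaries(occ, bott)
    vcfio.write_tsv(occ, OUT / "occupancy_bottleneck.tsv")
    print(f"bottleneck: {rs.n_sites} polymorphic sites; "
          f"{rs.single_fraction:.1%} in one individual "
          f"({rs.single_het_fraction:.1%} of those heterozygous); "
          f"{rs.private_fraction:.1%} private to one location")

    rc = rare.rare_summaries(rare.allele_occupancy(const), const)
    print(f"constant-N control: {rc.single_fraction:.1%} single-individual")
    print(f"excess: {rs.single_fraction - rc.single_fraction:+.1%}")

    vcfio.write_tsv(
        rs.location_sharing_histogram.rename("n_variants")
        .rename_axis("n_locations").reset_index(),
        OUT / "location_sharing.tsv",
    )


if __name__ == "__main__":
    main()
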
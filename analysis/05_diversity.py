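"""Genomic diversity: windowed pi, Tajima's D, individual heterozygosity.

Run on the bottleneck-scenario cohort, where the long-term expansion
leaves a genome-wide negative Tajima's D despite high diversity — the
signature that separates 'recovering after a crash' from 'stable'.
"""

from pathlib import Path

from abalonepg import diversity, vcfio
from abalonepg.core import windows_to_frame

FIX = Path("results/fixtures/bottleneck")
OUT = Path("results/diversity")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    md = vcfio.read_metadata(FIX / "metadata.tsv")
    full = vcfio.filter_sites(vcfio.read_vcf(FIX / "sim.vcf", md))

    pws = diversity.windowed_pi(full, 50_000)
    dws = diversity.windowed_tajimas_d(full, 50_000)
    print(f"mean pi per bp: {diversity.mean_window_value(pws):.3e}")
    print(f"mean Tajima's D: {diversity.mean_window_value(dws):+.3f} "
          f"(site-weighted {diversity.mean_window_value(dws, True):+.3f})")
    vcfio.write_tsv(windows_to_frame(pws), OUT / "pi_windows.tsv")
    vcfio.write_tsv(windows_to_frame(dws), OUT / "tajimas_d_windows.tsv")

    het = diversity.individual_heterozygosity(full)
    print(f"mean individual heterozygosity: {het.het.mean():.3f}")
    vcfio.write_tsv(
        het.het.rename("het").rename_axis("sample").reset_index(),
        OUT / "heterozygosity.tsv",
    )


if __name__ == "__main__":
    main()
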
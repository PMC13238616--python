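"""LD-based effective-population-size trajectories.

Constant-size cohort: the per-bin Sved inversion should read a flat ~500.
Bottleneck cohort: the per-bin estimate mixes epochs, so the epoch
deconvolution is used to separate the recent crash from the large ancient
size — the decline-and-recovery picture.
"""

from pathlib import Path

from abalonepg import ne_ld, vcfio

OUT = Path("results/ne")
RATE_CM_PER_MB = 10.0  # matches the simulated 1e-7 Morgan/bp


def load(fixture: str):
    fix = Path("results/fixtures") / fixture
    md = vcfio.read_metadata(fix / "metadata.tsv")
    return vcfio.filter_sites(vcfio.read_vcf(fix / "sim.vcf", md))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for fixture, method in (("constant", "sved"), ("bottleneck", "deconvolve")):
        gm = load(fixture)
        inp = ne_ld.prepare_ne_input(gm, min_spacing=100, min_scaffold=900_000,
                                     cap=500_000, seed=1)
        ld = ne_ld.ld_r2_binned(inp, rate_cm_per_mb=RATE_CM_PER_MB, seed=1)
        if method == "sved":
            traj = ne_ld.ne_trajectory(ld, replicates=20, seed=1)
        else:
            traj = ne_ld.ne_trajectory_deconvolved(ld, replicates=20, seed=1)
        vcfio.write_tsv(traj, OUT / f"trajectory_{fixture}.tsv",
                        {"method": method, "rate_cm_per_mb": RATE_CM_PER_MB})
        print(f"--- {fixture} ({method}), {len(ld.c)} SNP pairs ---")
        cols = ["t", "ne", "ne_q05", "ne_q95"]
        print(traj[cols].round(1).to_string(index=False))


if __name__ == "__main__":
    main()
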
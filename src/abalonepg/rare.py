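"""Rare-allele occupancy: single-individual variants, private variants,
and cross-location sharing.

Terminology note: "singleton/doubleton" here follows the occupancy usage —
a variant carried by exactly ONE individual, as one (heterozygous,
"singleton") or both (homozygous, "doubleton") of that individual's
alleles.  This is NOT the classical allele-count definition (a site whose
minor allele count is 1 or 2 across the sample); the two coincide only for
the single-carrier case.  A "private" variant is carried in exactly one
sampling location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass
class RareSummary:
    """Headline occupancy fractions plus the raw tables to recompute them.

    Display rounding (whole percent, het fraction to 0.1%) is applied only
    in :meth:`display`; every stored value is unrounded.
    """

    n_sites: int
    n_single_individual: int
    n_private: int
    single_fraction: float
    private_fraction: float
    single_het_fraction: float
    per_location_singles: pd.Series
    location_sharing_histogram: pd.Series
    n_all_carriers_missing: int = 0

    def display(self) -> dict[str, float]:
        return {
            "single_individual_pct": round(100 * self.single_fraction),
            "private_pct": round(100 * self.private_fraction),
            "single_het_pct": round(100 * self.single_het_fraction, 1),
        }


def allele_occupancy(gm: GenotypeMatrix) -> pd.DataFrame:
    """One occupancy record per site, by exhaustive counting.

    The minor allele is defined per site from overall non-missing
    frequencies (ties at 0.5 -> alt).  Carriers are individuals with at
    least one copy of the minor allele.  Sites whose minor-allele carriers
    are all missing (possible only at monomorphic-after-masking edge
    cases) are excluded and counted in ``attrs['n_all_carriers_missing']``.
    """
    minor_alt = gm.minor_is_alt()
    locations = gm.samples["location"].to_numpy()
    called = gm.G != MISSING
    # per-site per-sample minor allele count
    g = np.where(called, gm.G, 0)
    minor_count = np.where(minor_alt[:, None], g, np.where(called, 2 - g, 0))
    carrier = (minor_count >= 1) & called
    hom_carrier = (minor_count == 2) & called

    n_carriers = carrier.sum(axis=1)
    any_hom = hom_carrier.any(axis=1)
    n_locations = np.array(
        [len(np.unique(locations[c])) if c.any() else 0 for c in carrier]
    )
    maf = gm.maf()
    polymorphic = maf > 0
    dropped = int((polymorphic & (n_carriers == 0)).sum())
    keep = ~(polymorphic & (n_carriers == 0))

    df = pd.DataFrame(
        {
            "scaffold": gm.sites["scaffold"],
            "pos": gm.sites["pos"],
            "maf": maf,
            "n_carrier_individuals": n_carriers,
            "carrier_state": np.where(any_hom, "hom_present", "het_only"),
            "n_locations": n_locations,
        }
    )[keep].reset_index(drop=True)
    df["is_single_individual"] = df["n_carrier_individuals"] == 1
    df["is_private"] = df["n_locations"] == 1
    df.attrs["n_all_carriers_missing"] = dropped
    return df


def rare_summaries(records: pd.DataFrame, gm: GenotypeMatrix | None = None) -> RareSummary:
    """Aggregate occupancy records into the headline fractions.

    ``records`` should already be restricted to the stratum of interest
    (typically the rare dataset); fractions are of the records supplied.
    """
    poly = records[records["n_carrier_individuals"] > 0]
    n = len(poly)
    if n == 0:
        raise ValueError("no polymorphic occupancy records; fractions undefined")
    single = poly[poly["is_single_individual"]]
    private = poly[poly["is_private"]]
    single_het = (single["carrier_state"] == "het_only").sum()

    per_loc = pd.Series(dtype=int)
    if gm is not None and len(single):
        minor_alt = gm.minor_is_alt()
        key = gm.sites.set_index(["scaffold", "pos"]).index
        want = pd.MultiIndex.from_frame(single[["scaffold", "pos"]])
        rows = np.flatnonzero(key.isin(want))
        locations = gm.samples["location"].to_numpy()
        called = gm.G[rows] != MISSING
        g = np.where(called, gm.G[rows], 0)
        mc = np.where(minor_alt[rows][:, None], g, np.where(called, 2 - g, 0))
        carrier = (mc >= 1) & called
        loc_of_carrier = [locations[c][0] for c in carrier if c.any()]
        per_loc = pd.Series(loc_of_carrier).value_counts().sort_index()

    hist = poly["n_locations"].value_counts().sort_index()
    return RareSummary(
        n_sites=n,
        n_single_individual=len(single),
        n_private=len(private),
        single_fraction=len(single) / n,
        private_fraction=len(private) / n,
        single_het_fraction=single_het / len(single) if len(single) else float("nan"),
        per_location_singles=per_loc,
        location_sharing_histogram=hist,
        n_all_carriers_missing=records.attrs.get("n_all_carriers_missing", 0),
    )


def headline_fractions(
    n_full: float,
    n_common: float,
    n_private: float | None = None,
    n_single: float | None = None,
    n_single_het: float | None = None,
) -> dict[str, float]:
    """Dataset-split arithmetic on variant counts (pure bookkeeping).

    Returns percentages on the display scale: the common and rare shares of
    the full dataset and, when given, the private/single-individual shares
    of all and of rare variants and the heterozygous share of
    single-individual variants.
    """
    if not 0 < n_common <= n_full:
        raise ValueError("need 0 < n_common <= n_full")
    n_rare = n_full - n_common
    out = {
        "common_pct_of_all": 100.0 * n_common / n_full,
        "rare_pct_of_all": 100.0 * n_rare / n_full,
    }
    if n_private is not None:
        out["private_pct_of_all"] = 100.0 * n_private / n_full
        out["private_pct_of_rare"] = 100.0 * n_private / n_rare
    if n_single is not None:
        out["single_pct_of_all"] = 100.0 * n_single / n_full
        out["single_pct_of_rare"] = 100.0 * n_single / n_rare
        if n_single_het is not None:
            out["single_het_pct"] = 100.0 * n_single_het / n_single
    return out
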
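"""Nucleocytoplasmic enrichment classification and population summaries.

A transcript observed in fractionated nucleus (N) and cytoplasm (C) RNA-seq
is called nucleus-enriched when N_fpkm/C_fpkm >= 2 with fragments detected
in both compartments, or when it is absent from the cytoplasm (C_count = 0)
but supported by at least 3 nuclear fragments; the mirrored rules define
cytoplasm enrichment; everything else is "middle". Per-time-point summaries
report population sizes, N/C ratios, mean half-lives and KS/ANOVA contrasts
between the populations, and a 5461-feature k-mer/GC contrast compares
nucleus- against cytoplasm-specific sequence populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .screening import anova_oneway, bonferroni_adjust, ks_two_sample
from .seqfeatures import all_kmers, gc_content, kmer_frequencies_K1

__all__ = [
    "Location",
    "CompartmentObservation",
    "classify_location",
    "classify_table",
    "summarize_populations",
    "population_feature_contrast",
]


class Location(Enum):
    NUCLEUS = "nucleus"
    CYTOPLASM = "cytoplasm"
    MIDDLE = "middle"


@dataclass(frozen=True)
class CompartmentObservation:
    """Counts and FPKM for one transcript in both compartments at one time."""

    transcript_id: str
    time_h: float
    n_count: int
    n_fpkm: float
    c_count: int
    c_fpkm: float

    def __post_init__(self) -> None:
        if self.n_count < 0 or self.c_count < 0:
            raise ValueError("counts must be non-negative")
        if self.n_fpkm < 0 or self.c_fpkm < 0:
            raise ValueError("FPKM must be non-negative")

    @property
    def undetected(self) -> bool:
        return self.n_count == 0 and self.c_count == 0


def classify_location(obs: CompartmentObservation) -> Location:
    """Total, deterministic three-way partition by the enrichment rules."""
    # zero count forces the FPKM to count as absent for that compartment
    nf = obs.n_fpkm if obs.n_count > 0 else 0.0
    cf = obs.c_fpkm if obs.c_count > 0 else 0.0
    if obs.n_count > 0 and obs.c_count > 0 and cf > 0 and nf / cf >= 2.0:
        return Location.NUCLEUS
    if obs.c_count == 0 and obs.n_count >= 3:
        return Location.NUCLEUS
    if obs.c_count > 0 and obs.n_count > 0 and nf > 0 and cf / nf >= 2.0:
        return Location.CYTOPLASM
    if obs.n_count == 0 and obs.c_count >= 3:
        return Location.CYTOPLASM
    return Location.MIDDLE


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a compartment TSV-style table.

    Adds ``location`` and an ``undetected`` flag (both counts zero; such
    rows are middle but may deserve exclusion).
    """
    out = table.copy()
    obs = [CompartmentObservation(str(r.transcript_id), float(r.time_h),
                                  int(r.n_count), float(r.n_fpkm),
                                  int(r.c_count), float(r.c_fpkm))
           for r in table.itertuples()]
    out["location"] = [classify_location(o).value for o in obs]
    out["undetected"] = [o.undetected for o in obs]
    return out


def summarize_populations(observations: pd.DataFrame, halflives: pd.DataFrame,
                          biotype: str = "lncRNA") -> pd.DataFrame:
    """Per-time-point population summary joining enrichment with half-lives.

    For each time point: counts per population (total conserved), the
    nucleus/cytoplasm count ratio to 2 decimals, mean half-life per
    population, a two-sample KS p between nucleus and cytoplasm half-life
    sets and the one-way ANOVA p across all three.
    """
    classified = (observations if "location" in observations.columns
                  else classify_table(observations))
    hl = halflives.set_index("transcript_id")["t_half_mean"]
    rows = []
    for time_h, grp in classified.groupby("time_h", sort=True):
        grp = grp[grp.transcript_id.isin(hl.index)]
        sets = {loc: hl.loc[grp.loc[grp.location == loc, "transcript_id"]].to_numpy()
                for loc in ("nucleus", "middle", "cytoplasm")}
        nn, nm, nc = (len(sets[k]) for k in ("nucleus", "middle", "cytoplasm"))
        p_ks = p_anova = np.nan
        if nn and nc:
            _, p_ks = ks_two_sample(sets["nucleus"], sets["cytoplasm"])
        if min(nn, nm, nc) >= 2:
            _, p_anova = anova_oneway([sets["nucleus"], sets["middle"],
                                       sets["cytoplasm"]])
        rows.append({
            "biotype": biotype, "time_h": time_h,
            "num_total": nn + nm + nc, "num_nucleus": nn,
            "num_middle": nm, "num_cytoplasm": nc,
            "ratio_nc": round(nn / nc, 2) if nc else np.nan,
            "mean_thalf_nucleus": sets["nucleus"].mean() if nn else np.nan,
            "mean_thalf_middle": sets["middle"].mean() if nm else np.nan,
            "mean_thalf_cytoplasm": sets["cytoplasm"].mean() if nc else np.nan,
            "p_ks": p_ks, "p_anova": p_anova,
        })
    return pd.DataFrame(rows)


def population_feature_contrast(seqs_pop1, seqs_pop2, kmax: int = 6
                                ) -> pd.DataFrame:
    """Compositional contrast between two sequence populations.

    The feature space is every k-mer for k = 1..kmax (5460 for kmax=6) plus
    GC content, 5461 features in all. Per feature, the per-sequence K1
    frequency distributions of the two populations are compared by a
    two-sample KS test; p values are Bonferroni-adjusted over the whole
    feature space. Empty sequences are skipped with a warning.
    """
    import warnings

    def _freqs(seqs) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(seqs):
            if not s:
                warnings.warn(f"skipping empty sequence at index {i}")
                continue
            row = kmer_frequencies_K1(s, ks=range(1, kmax + 1))
            row["gc"] = gc_content(s)
            rows.append(row)
        return pd.DataFrame(rows)

    f1, f2 = _freqs(seqs_pop1), _freqs(seqs_pop2)
    if f1.empty or f2.empty:
        raise ValueError("both populations must be non-empty")
    features = [km for k in range(1, kmax + 1) for km in all_kmers(k)] + ["gc"]
    d = np.empty(len(features))
    p = np.empty(len(features))
    for i, feat in enumerate(features):
        d[i], p[i] = ks_two_sample(f1[feat].to_numpy(), f2[feat].to_numpy())
    return pd.DataFrame({
        "feature": features, "ks_d": d, "p": p,
        "fdr": bonferroni_adjust(p),
        "direction": np.where(f1.mean(axis=0)[features] >= f2.mean(axis=0)[features],
                              "pop1_higher", "pop2_higher"),
    })
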
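"""Genotype / sample filtering cascade, kinship and sex-linkage screens.

Implements the standard RADseq SNP quality cascade — per-locus call rate
(overall and within demes), per-sample missingness, minor allele count,
mean-depth window, distance thinning — plus two cohort screens:

* a kinship screen using the robust within-pair moment estimator of the
  kinship coefficient K (heterozygote concordance minus twice the
  opposite-homozygote count, normalized by the summed heterozygote counts)
  together with a frequency-normalized estimate of K0, the probability of
  sharing zero alleles identical by descent.  K0 near 0 marks
  parent-offspring pairs; K0 of 0.25 or more marks sibling pairs.
* a sex-linkage screen comparing heterozygote proportions and call rates
  between sexes at each locus with exact tests, flagging X-linked patterns
  (males never heterozygous) and Y/W-like patterns (one sex uncalled).

Every locus-level filter returns a new GenotypeTable plus a FilterReport
stage entry, so a pipeline run documents counts in and out at each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gtable import GenotypeTable

__all__ = [
    "FilterReport",
    "KinshipDyad",
    "locus_call_rate_filter",
    "sample_missingness_filter",
    "mac_filter",
    "depth_window_filter",
    "site_quality_filter",
    "li_max_depth",
    "thin_loci",
    "kinship_screen",
    "sex_linkage_screen",
    "run_filter_cascade",
]


@dataclass
class FilterReport:
    """Accumulates per-stage in/out counts and thresholds."""

    stages: list[dict] = field(default_factory=list)

    def record(
        self,
        stage: str,
        sites_in: int,
        sites_out: int,
        samples_in: int,
        samples_out: int,
        **thresholds,
    ) -> None:
        self.stages.append(
            {
                "stage": stage,
                "sites_in": sites_in,
                "sites_out": sites_out,
                "samples_in": samples_in,
                "samples_out": samples_out,
                "thresholds": dict(thresholds),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            row = {k: v for k, v in s.items() if k != "thresholds"}
            row["thresholds"] = ";".join(
                f"{k}={v}" for k, v in s["thresholds"].items()
            )
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class KinshipDyad:
    sample_i: str
    sample_j: str
    k: float
    k0: float
    inferred_class: str


def _deme_indices(
    table: GenotypeTable, deme_assignments: pd.Series | dict
) -> dict[str, np.ndarray]:
    if isinstance(deme_assignments, pd.Series):
        mapping = deme_assignments.to_dict()
    else:
        mapping = dict(deme_assignments)
    unknown = [s for s in table.samples if s not in mapping]
    if unknown:
        raise ValueError(f"samples without a deme assignment: {unknown[:5]}")
    demes: dict[str, list[int]] = {}
    for i, s in enumerate(table.samples):
        demes.setdefault(mapping[s], []).append(i)
    return {d: np.array(ix) for d, ix in demes.items()}


# ----------------------------------------------------------------------
# locus- and sample-level filters
# ----------------------------------------------------------------------

def locus_call_rate_filter(
    table: GenotypeTable,
    deme_assignments: pd.Series | dict,
    overall_rate: float = 0.85,
    per_deme_rate: float = 0.5,
    min_demes: int | None = None,
    report: FilterReport | None = None,
) -> tuple[GenotypeTable, FilterReport]:
    """Keep loci called in > ``overall_rate`` of samples overall AND in
    > ``per_deme_rate`` of samples within at least ``min_demes`` demes
    (default: every deme)."""
    if not (0 <= overall_rate <= 1 and 0 <= per_deme_rate <= 1):
        raise ValueError("call rates must lie in [0, 1]")
    demes = _deme_indices(table, deme_assignments)
    if min_demes is None:
        min_demes = len(demes)
    called = table.called_mask()
    keep = called.mean(axis=0) > overall_rate
    per_deme_ok = np.zeros(table.n_sites, dtype=int)
    for ix in demes.values():
        per_deme_ok += called[ix].mean(axis=0) > per_deme_rate
    keep &= per_deme_ok >= min_demes
    out = table.take_sites(keep)
    report = report or FilterReport()
    report.record(
        "locus_call_rate",
        table.n_sites,
        out.n_sites,
        table.n_samples,
        out.n_samples,
        overall_rate=overall_rate,
        per_deme_rate=per_deme_rate,
        min_demes=min_demes,
    )
    return out, report


def sample_missingness_filter(
    table: GenotypeTable,
    max_missing: float = 0.10,
    report: FilterReport | None = None,
) -> tuple[GenotypeTable, FilterReport]:
    """Retain samples with missing-call fraction strictly below the cut."""
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must lie in [0, 1]")
    missing_frac = 1.0 - table.called_mask().mean(axis=1)
    keep = missing_frac < max_missing
    out = table.take_samples(keep)
    report = report or FilterReport()
    report.record(
        "sample_missingness",
        table.n_sites,
        out.n_sites,
        table.n_samples,
        out.n_samples,
        max_missing=max_missing,
    )
    return out, report


def mac_filter(
    table: GenotypeTable,
    min_mac: int = 3,
    report: FilterReport | None = None,
) -> tuple[GenotypeTable, FilterReport]:
    """Keep loci whose minor allele count (over called genotypes) >= min_mac.

    Invariant sites have MAC 0 and are removed whenever min_mac >= 1.  At
    multi-allelic sites the minor count is the total count of all non-major
    alleles' rarest allele (computed over every distinct allele observed).
    """
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")
    n_alts = table.n_alts()
    max_allele = int(n_alts.max()) if table.n_sites else 0
    called = table.called_mask()
    counts = np.zeros((max_allele + 1, table.n_sites), dtype=np.int64)
    for a in range(max_allele + 1):
        counts[a] = ((table.alleles == a) & called[:, :, None]).sum(axis=(0, 2))
    total = counts.sum(axis=0)
    macs = np.zeros(table.n_sites, dtype=np.int64)
    for j in range(table.n_sites):
        present = counts[: n_alts[j] + 1, j]
        present = present[present > 0]
        if len(present) >= 2 and total[j] > 0:
            macs[j] = np.sort(present)[:-1].sum() if len(present) > 2 else present.min()
    keep = macs >= min_mac if min_mac > 0 else np.ones(table.n_sites, bool)
    out = table.take_sites(keep)
    report = report or FilterReport()
    report.record(
        "mac", table.n_sites, out.n_sites, table.n_samples, out.n_samples,
        min_mac=min_mac,
    )
    return out, report


def depth_window_filter(
    table: GenotypeTable,
    min_mean_dp: float = 5.0,
    max_mean_dp: float = 95.0,
    report: FilterReport | None = None,
) -> tuple[GenotypeTable, FilterReport]:
    """Keep loci whose mean depth over called genotypes lies in the window.

    A locus with no called genotypes fails.
    """
    if not 0 <= min_mean_dp < max_mean_dp:
        raise ValueError("need 0 <= min_mean_dp < max_mean_dp")
    called = table.called_mask()
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dp = np.where(called, table.depth, 0).sum(axis=0) / n_called
    keep = (n_called > 0) & (mean_dp >= min_mean_dp) & (mean_dp <= max_mean_dp)
    out = table.take_sites(keep)
    report = report or FilterReport()
    report.record(
        "depth_window", table.n_sites, out.n_sites, table.n_samples,
        out.n_samples, min_mean_dp=min_mean_dp, max_mean_dp=max_mean_dp,
    )
    return out, report


def site_quality_filter(
    table: GenotypeTable,
    min_qual: float = 30.0,
    report: FilterReport | None = None,
) -> tuple[GenotypeTable, FilterReport]:
    """Drop loci with site quality below ``min_qual`` (hard filter)."""
    keep = table.sites["qual"].to_numpy() >= min_qual
    out = table.take_sites(keep)
    report = report or FilterReport()
    report.record(
        "site_quality", table.n_sites, out.n_sites, table.n_samples,
        out.n_samples, min_qual=min_qual,
    )
    return out, report


def li_max_depth(mean_depth: float, coefficient: float = 4.0) -> float:
    """Maximum-depth rule of thumb: mean + c * sqrt(mean).

    With the default coefficient 4, a locus mean depth beyond roughly four
    Poisson standard deviations above the genome-wide mean flags likely
    collapsed repeats / paralogs.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    return mean_depth + coefficient * math.sqrt(mean_depth)


def thin_loci(
    table: GenotypeTable,
    min_distance_bp: int = 10_000,
    report: FilterReport | None = None,
) -> tuple[GenotypeTable, FilterReport]:
    """Greedy left-to-right thinning: per contig keep the first site, then
    each site at least ``min_distance_bp`` from the last kept site."""
    contig = table.sites["contig"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    keep = np.zeros(table.n_sites, dtype=bool)
    last_contig = None
    last_pos = None
    for j in range(table.n_sites):
        if contig[j] != last_contig:
            last_contig, last_pos = contig[j], pos[j]
            keep[j] = True
        else:
            if pos[j] <= last_pos:
                raise ValueError(
                    f"positions not sorted on contig {contig[j]} at {pos[j]}"
                )
            if pos[j] - last_pos >= min_distance_bp:
                keep[j] = True
                last_pos = pos[j]
    out = table.take_sites(keep)
    report = report or FilterReport()
    report.record(
        "thin", table.n_sites, out.n_sites, table.n_samples, out.n_samples,
        min_distance_bp=min_distance_bp,
    )
    return out, report


# ----------------------------------------------------------------------
# kinship screen
# ----------------------------------------------------------------------

# moment-estimator classification bands (powers of 2^-k/2 midpoints)
_K_PO_SIB = (0.177, 0.354)
_K_HALFSIB = (0.088, 0.177)


def _classify(k: float, k0: float) -> str:
    if k >= _K_PO_SIB[1]:
        return "duplicate-or-self"
    if _K_PO_SIB[0] <= k < _K_PO_SIB[1]:
        return "parent-offspring" if k0 < 0.1 else "full-sib"
    if _K_HALFSIB[0] <= k < _K_HALFSIB[1]:
        return "half-sib"
    return "unrelated"


def kinship_screen(table: GenotypeTable) -> list[KinshipDyad]:
    """Moment-estimator kinship screen over every unordered sample pair.

    K is the robust within-pair estimator
    (N_het,het - 2 N_opp-hom) / (N_het,i + N_het,j), with counts taken over
    loci called in both samples.  K0 is the opposite-homozygote count
    normalized by its unrelated-pair expectation sum_l 2 p_l^2 (1-p_l)^2 and
    clamped to [0, 1].  Only biallelic polymorphic loci contribute.
    """
    bial = table.biallelic_snp_mask()
    g = table.dosage(bial)  # n x L with NaN for missing
    freq = np.nanmean(g, axis=0) / 2.0
    poly = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    g = g[:, poly]
    freq = freq[poly]
    if g.shape[1] == 0:
        raise ValueError("kinship screen needs polymorphic loci")

    called = ~np.isnan(g)
    het = (g == 1) & called
    aa = (g == 0) & called
    bb = (g == 2) & called
    hetf = het.astype(np.float64)
    n_hethet = hetf @ hetf.T
    n_ibs0 = aa.astype(np.float64) @ bb.T.astype(np.float64)
    n_ibs0 = n_ibs0 + n_ibs0.T
    calledf = called.astype(np.float64)
    n_het_shared = hetf @ calledf.T  # het in i over loci called in both
    denom = n_het_shared + n_het_shared.T
    w = 2.0 * freq**2 * (1.0 - freq) ** 2
    e_ibs0 = (calledf * w) @ calledf.T

    n = table.n_samples
    out: list[KinshipDyad] = []
    for i in range(n):
        for j in range(i + 1, n):
            if denom[i, j] <= 0:
                k = 0.0
            else:
                k = (n_hethet[i, j] - 2.0 * n_ibs0[i, j]) / denom[i, j]
            k = float(np.clip(k, -0.5, 0.5))
            k0 = (
                float(np.clip(n_ibs0[i, j] / e_ibs0[i, j], 0.0, 1.0))
                if e_ibs0[i, j] > 0
                else 1.0
            )
            out.append(
                KinshipDyad(table.samples[i], table.samples[j], k, k0, _classify(k, k0))
            )
    return out


def kinship_frame(dyads: list[KinshipDyad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_i": d.sample_i,
                "sample_j": d.sample_j,
                "K": d.k,
                "K0": d.k0,
                "class": d.inferred_class,
            }
            for d in dyads
        ]
    )


# ----------------------------------------------------------------------
# sex-linkage screen
# ----------------------------------------------------------------------

def sex_linkage_screen(
    table: GenotypeTable,
    sexes: pd.Series | dict,
    alpha: float = 0.05,
    min_per_sex: int = 5,
) -> pd.DataFrame:
    """Flag loci with sex-biased heterozygosity or call-rate patterns.

    Per testable locus (>= ``min_per_sex`` called individuals of each sex):

    * X-linked pattern — Fisher exact test on the 2x2 het/non-het by sex
      table, flagged when significant after Bonferroni correction *and*
      males show the lower heterozygote proportion;
    * Y/W-like pattern — Fisher exact test on called/missing by sex.

    Samples without a sex label are ignored.  Returns a DataFrame of flagged
    loci (site index, pattern, raw p).
    """
    if isinstance(sexes, pd.Series):
        mapping = sexes.to_dict()
    else:
        mapping = dict(sexes)
    sex_arr = np.array([str(mapping.get(s, "")) for s in table.samples])
    male = sex_arr == "M"
    female = sex_arr == "F"
    called = table.called_mask()
    het = table.het_mask()

    n_called_m = called[male].sum(axis=0)
    n_called_f = called[female].sum(axis=0)
    n_het_m = het[male].sum(axis=0)
    n_het_f = het[female].sum(axis=0)
    variant = table.n_alts() > 0
    testable = (n_called_m >= min_per_sex) & (n_called_f >= min_per_sex) & variant
    n_tests = int(testable.sum())
    if n_tests == 0:
        return pd.DataFrame(columns=["site", "contig", "pos", "pattern", "p"])
    cutoff = alpha / n_tests

    rows = []
    n_m, n_f = int(male.sum()), int(female.sum())
    for j in np.flatnonzero(testable):
        # heterozygosity contrast
        tbl = [
            [int(n_het_m[j]), int(n_called_m[j] - n_het_m[j])],
            [int(n_het_f[j]), int(n_called_f[j] - n_het_f[j])],
        ]
        p_het = stats.fisher_exact(tbl)[1]
        if p_het < cutoff and (
            n_het_m[j] / n_called_m[j] < n_het_f[j] / n_called_f[j]
        ):
            rows.append((j, "X-linked", p_het))
            continue
        # call-rate contrast (one sex largely uncalled)
        tbl = [
            [int(n_called_m[j]), n_m - int(n_called_m[j])],
            [int(n_called_f[j]), n_f - int(n_called_f[j])],
        ]
        p_call = stats.fisher_exact(tbl)[1]
        if p_call < cutoff:
            rows.append((j, "YW-like", p_call))
    sites = table.sites
    return pd.DataFrame(
        [
            {
                "site": j,
                "contig": sites["contig"].iat[j],
                "pos": int(sites["pos"].iat[j]),
                "pattern": pat,
                "p": p,
            }
            for j, pat, p in rows
        ],
        columns=["site", "contig", "pos", "pattern", "p"],
    )


# ----------------------------------------------------------------------
# cascade
# ----------------------------------------------------------------------

def run_filter_cascade(
    table: GenotypeTable,
    deme_assignments: pd.Series | dict,
    first_pass_rate: float = 0.70,
    overall_rate: float = 0.85,
    per_deme_rate: float = 0.50,
    max_missing: float = 0.10,
    min_mac: int = 3,
    min_mean_dp: float = 5.0,
    max_mean_dp: float = 95.0,
    min_qual: float = 30.0,
    thin_bp: int | None = None,
) -> tuple[GenotypeTable, FilterReport]:
    """Apply the documented stage order.

    First-pass call rate -> sample missingness -> re-filtered call rate
    (overall + per-deme) -> MAC -> site quality -> depth window -> optional
    thinning.  Returns the filtered table and the cumulative report.
    """
    report = FilterReport()
    t, report = locus_call_rate_filter(
        table, deme_assignments, overall_rate=first_pass_rate,
        per_deme_rate=0.0, min_demes=0, report=report,
    )
    t, report = sample_missingness_filter(t, max_missing, report=report)
    t, report = locus_call_rate_filter(
        t, deme_assignments, overall_rate=overall_rate,
        per_deme_rate=per_deme_rate, report=report,
    )
    t, report = mac_filter(t, min_mac, report=report)
    t, report = site_quality_filter(t, min_qual, report=report)
    t, report = depth_window_filter(t, min_mean_dp, max_mean_dp, report=report)
    if thin_bp:
        t, report = thin_loci(t, thin_bp, report=report)
    return t, report
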
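"""Per-individual autosomal heterozygosity, per-deme F_IS, window profiles.

Observed autosomal heterozygosity H_O for an individual is the fraction of
that individual's *retained* genotype records that are heterozygous, where
retention applies per-individual filters (depth window, missingness,
spanning-deletion sites) and the denominator keeps every retained record
irrespective of polymorphism — invariant sites included.  Multi-allelic
records are atomized into one biallelic record per alternate allele before
counting, so a genotype composed of two different alternate alleles counts as
heterozygous in two derived records.

Because each individual is filtered separately against a jointly genotyped
site set, H_O is comparable across individuals with different amounts of
missing data and is not biased by cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gtable import GenotypeTable, STAR_ALLELE

__all__ = [
    "IndividualHetResult",
    "DemeFisResult",
    "WindowHetProfile",
    "per_individual_site_filter",
    "atomize_multiallelic",
    "autosomal_het",
    "autosomal_het_all",
    "deme_fis",
    "window_profile",
    "het_covariate_check",
]


@dataclass
class IndividualHetResult:
    sample: str
    n_retained: int
    n_het: int

    @property
    def h_o(self) -> float:
        return self.n_het / self.n_retained


@dataclass
class DemeFisResult:
    deme: str
    fis: float
    n_loci: int
    reliable: bool = True


@dataclass
class WindowHetProfile:
    """Tiled windows over the size-concatenated pseudogenome.

    ``windows``: DataFrame with ``start``/``end`` (pseudogenome bp);
    ``h_o``: (n_windows, n_samples) H_O, NaN where the per-window record
    count falls below the denominator floor;
    ``n_records``: matching per-window record counts.
    """

    windows: pd.DataFrame
    h_o: np.ndarray
    n_records: np.ndarray
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = self.windows.copy()
        for i, s in enumerate(self.samples):
            df[s] = self.h_o[:, i]
        return df


# ----------------------------------------------------------------------
# per-individual retention
# ----------------------------------------------------------------------

def _star_site_mask(table: GenotypeTable) -> np.ndarray:
    return table.sites["alts"].map(lambda a: STAR_ALLELE in a).to_numpy()


def per_individual_site_filter(
    table: GenotypeTable,
    sample: str,
    min_dp: int = 15,
    max_dp: int = 95,
) -> np.ndarray:
    """Boolean site mask of records retained for one individual.

    Drops, for this individual only: missing calls; sites whose alternate
    alleles include the spanning-deletion symbol (or whose genotype
    references it); calls with depth below ``min_dp`` or above ``max_dp``
    (depth exactly at either bound is retained).
    """
    i = table.sample_index(sample)
    called = table.alleles[i, :, 0] >= 0
    dp = table.depth[i]
    keep = called & (dp >= min_dp) & (dp <= max_dp) & ~_star_site_mask(table)
    return keep


def atomize_multiallelic(
    alts: tuple[str, ...], genotypes: np.ndarray
) -> list[tuple[str, np.ndarray]]:
    """Decompose one site into one biallelic record per alternate allele.

    ``genotypes`` is (n_samples, 2) allele indices.  In derived record j a
    genotype is heterozygous iff exactly one of its two alleles equals alt j;
    missing stays missing.  Returns [(alt, derived (n,2) alleles), ...].
    """
    out = []
    for j, alt in enumerate(alts, start=1):
        hits = (genotypes == j).sum(axis=1)
        derived = np.zeros_like(genotypes)
        derived[hits == 1, 1] = 1
        derived[hits == 2] = 1
        derived[genotypes[:, 0] < 0] = -1
        out.append((alt, derived))
    return out


def _record_counts(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per (sample, site): atomized record count and heterozygous-record count.

    A site with k alternate alleles contributes max(k, 1) records; a
    heterozygous genotype (a0 != a1) is heterozygous in one derived record
    per distinct non-reference allele it carries.
    """
    n_alts = table.n_alts()
    records = np.maximum(n_alts, 1)[None, :]  # per-site record count
    a = table.alleles
    het = (a[:, :, 0] != a[:, :, 1]) & (a[:, :, 0] >= 0)
    het_records = np.where(het, (a[:, :, 0] > 0).astype(int) + (a[:, :, 1] > 0), 0)
    return np.broadcast_to(records, het_records.shape), het_records


def autosomal_het(
    table: GenotypeTable,
    sample: str,
    min_dp: int = 15,
    max_dp: int = 95,
    excluded_sites: np.ndarray | None = None,
) -> IndividualHetResult:
    """H_O for one individual: heterozygous retained records / all retained
    records, invariant records included in the denominator.

    ``excluded_sites`` is an optional boolean mask of sites to drop for every
    individual (conventionally the sex-linkage screen's flagged loci, keeping
    the estimate autosomal).
    """
    keep = per_individual_site_filter(table, sample, min_dp, max_dp)
    if excluded_sites is not None:
        keep = keep & ~np.asarray(excluded_sites, dtype=bool)
    i = table.sample_index(sample)
    records, het_records = _record_counts(table)
    n_ret = int(records[i, keep].sum())
    if n_ret == 0:
        raise ValueError(f"no retained records for sample {sample!r}")
    n_het = int(het_records[i, keep].sum())
    return IndividualHetResult(sample, n_ret, n_het)


def autosomal_het_all(
    table: GenotypeTable,
    min_dp: int = 15,
    max_dp: int = 95,
    excluded_sites: np.ndarray | None = None,
) -> pd.DataFrame:
    """H_O for every sample; returns sample, n_retained, n_het, H_O."""
    rows = []
    for s in table.samples:
        r = autosomal_het(table, s, min_dp, max_dp, excluded_sites)
        rows.append(
            {"sample": s, "n_retained": r.n_retained, "n_het": r.n_het, "H_O": r.h_o}
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# per-deme F_IS
# ----------------------------------------------------------------------

def deme_fis(
    table: GenotypeTable,
    deme_assignments: pd.Series | dict,
    min_called: int = 2,
    sample_size_correction: bool = False,
) -> list[DemeFisResult]:
    """Per-deme inbreeding coefficient F_IS.

    For each biallelic locus polymorphic within the deme (>= ``min_called``
    called individuals), F_locus = 1 - H_obs / H_exp with
    H_exp = 2 p (1 - p); the deme's F_IS is the unweighted mean over
    contributing loci.  ``sample_size_correction`` multiplies H_exp by
    2n/(2n-1).  A deme with fewer than two samples is flagged unreliable but
    still reported.
    """
    if isinstance(deme_assignments, pd.Series):
        mapping = deme_assignments.to_dict()
    else:
        mapping = dict(deme_assignments)
    bial = table.biallelic_snp_mask()
    g = table.dosage(bial)
    out = []
    demes = sorted(set(mapping[s] for s in table.samples))
    sample_idx = {s: i for i, s in enumerate(table.samples)}
    for d in demes:
        ix = [sample_idx[s] for s in table.samples if mapping[s] == d]
        gd = g[ix]
        called = ~np.isnan(gd)
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(gd, axis=0) / (2.0 * n_called)
            h_obs = np.nansum(gd == 1, axis=0) / n_called
        h_exp = 2.0 * p * (1.0 - p)
        if sample_size_correction:
            h_exp = h_exp * (2.0 * n_called) / (2.0 * n_called - 1.0)
        ok = (n_called >= min_called) & (h_exp > 0)
        fis_per_locus = 1.0 - h_obs[ok] / h_exp[ok]
        out.append(
            DemeFisResult(
                deme=d,
                fis=float(fis_per_locus.mean()) if ok.any() else np.nan,
                n_loci=int(ok.sum()),
                reliable=len(ix) >= 2,
            )
        )
    return out


# ----------------------------------------------------------------------
# pseudogenome window profile
# ----------------------------------------------------------------------

def window_profile(
    table: GenotypeTable,
    window_bp: int,
    min_dp: int = 15,
    max_dp: int = 95,
    denominator_floor: int = 50,
    contig_lengths: dict[str, int] | None = None,
    excluded_sites: np.ndarray | None = None,
) -> WindowHetProfile:
    """Per-sample H_O in windows tiling the size-concatenated pseudogenome.

    Contigs are ordered by descending length and concatenated; each site gets
    a pseudogenome coordinate and windows of ``window_bp`` tile the result.
    Windows whose retained-record count for a sample falls below
    ``denominator_floor`` are reported as NaN (absent), not zero.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    contigs = list(dict.fromkeys(table.sites["contig"]))
    if contig_lengths is None:
        contig_lengths = {
            c: int(table.sites.loc[table.sites["contig"] == c, "pos"].max())
            for c in contigs
        }
    order = sorted(contigs, key=lambda c: -contig_lengths[c])
    offset = {}
    acc = 0
    for c in order:
        offset[c] = acc
        acc += contig_lengths[c]
    pseudo = (
        table.sites["contig"].map(offset).to_numpy()
        + table.sites["pos"].to_numpy()
        - 1
    )
    n_windows = int(np.ceil(acc / window_bp))
    win_of_site = (pseudo // window_bp).astype(int)

    records, het_records = _record_counts(table)
    n = table.n_samples
    rec_mat = np.zeros((n_windows, n))
    het_mat = np.zeros((n_windows, n))
    for i, s in enumerate(table.samples):
        keep = per_individual_site_filter(table, s, min_dp, max_dp)
        if excluded_sites is not None:
            keep = keep & ~np.asarray(excluded_sites, dtype=bool)
        rec_mat[:, i] = np.bincount(
            win_of_site[keep], weights=records[i, keep], minlength=n_windows
        )
        het_mat[:, i] = np.bincount(
            win_of_site[keep], weights=het_records[i, keep], minlength=n_windows
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        h_o = np.where(rec_mat >= denominator_floor, het_mat / rec_mat, np.nan)
    windows = pd.DataFrame(
        {
            "start": np.arange(n_windows) * window_bp,
            "end": np.minimum((np.arange(n_windows) + 1) * window_bp, acc),
        }
    )
    return WindowHetProfile(
        windows=windows, h_o=h_o, n_records=rec_mat, samples=list(table.samples)
    )


# ----------------------------------------------------------------------
# covariate regression
# ----------------------------------------------------------------------

def het_covariate_check(
    het: pd.DataFrame | np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """OLS of H_O on a covariate; returns (slope, R^2).

    Used to confirm that H_O does not track nuisance covariates such as the
    number of retained sites or the sampling year.
    """
    y = het["H_O"].to_numpy() if isinstance(het, pd.DataFrame) else np.asarray(het)
    x = np.asarray(covariate, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 individuals")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance covariate")
    if np.ptp(y) == 0:
        return 0.0, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)
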
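"""Differentiation and isolation-by-distance statistics.

Weir-Cockerham F_ST (theta) with locus bootstrap, private allele tallies,
Rousset's a-hat individual genetic distance, Mantel permutation tests and a
genotype PCA.

Multilocus theta uses the ratio-of-sums convention: per-locus variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are summed over loci before the ratio
theta = sum(a) / sum(a + b + c).  This is not the mean of per-locus ratios;
low-information loci are thereby down-weighted automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gtable import GenotypeTable

__all__ = [
    "FstResult",
    "MantelResult",
    "RoussetA",
    "wc_theta",
    "wc_components",
    "fst_bootstrap",
    "fst_matrix",
    "private_alleles",
    "rousset_a",
    "rousset_a_matrix",
    "mantel",
    "geo_distances",
    "haversine_km",
    "pca_scores",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class FstResult:
    deme_a: str
    deme_b: str
    theta: float
    n_loci: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    significant: bool | None = None


@dataclass
class MantelResult:
    scope: str
    r: float
    p: float
    n_perm: int
    n: int


@dataclass
class RoussetA:
    sample_i: str
    sample_j: str
    a_hat: float
    n_loci: int
    degenerate: bool = False


# ----------------------------------------------------------------------
# Weir-Cockerham theta
# ----------------------------------------------------------------------

def _pop_summaries(
    table: GenotypeTable, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population, per-locus (n called, alt freq, het proportion)."""
    bial = table.biallelic_snp_mask()
    g = table.dosage(bial)
    n = np.zeros((len(groups), g.shape[1]))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, ix in enumerate(groups):
        gk = g[ix]
        called = ~np.isnan(gk)
        n[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p[k] = np.nansum(gk, axis=0) / (2.0 * n[k])
            h[k] = np.nansum(gk == 1, axis=0) / n[k]
    return n, p, h


def wc_components(
    table: GenotypeTable,
    deme_assignments: pd.Series | dict,
    demes: list[str],
    min_called: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus variance components (a, a+b+c) for the given demes.

    Loci need >= ``min_called`` called individuals in every deme and a
    non-zero total variance; others are dropped.
    """
    mapping = (
        deme_assignments.to_dict()
        if isinstance(deme_assignments, pd.Series)
        else dict(deme_assignments)
    )
    groups = []
    for d in demes:
        ix = np.array([i for i, s in enumerate(table.samples) if mapping.get(s) == d])
        if len(ix) == 0:
            raise ValueError(f"deme {d!r} has no samples in the table")
        groups.append(ix)
    r = len(groups)
    n, p, h = _pop_summaries(table, groups)

    ok = (n >= min_called).all(axis=0)
    n, p, h = n[:, ok], p[:, ok], h[:, ok]
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
    c = hbar / 2.0
    abc = a + b + c
    keep = np.isfinite(abc) & (abc != 0)
    return a[keep], abc[keep]


def wc_theta(
    table: GenotypeTable,
    deme_assignments: pd.Series | dict,
    deme_a: str,
    deme_b: str,
) -> FstResult:
    """Two-population multilocus Weir-Cockerham theta (ratio of sums)."""
    a, abc = wc_components(table, deme_assignments, [deme_a, deme_b])
    if len(a) == 0:
        raise ValueError("no informative loci for this deme pair")
    return FstResult(
        deme_a=deme_a,
        deme_b=deme_b,
        theta=float(a.sum() / abc.sum()),
        n_loci=len(a),
    )


def fst_bootstrap(
    table: GenotypeTable,
    deme_assignments: pd.Series | dict,
    pairs: list[tuple[str, str]] | None = None,
    n_boot: int = 10_000,
    alpha_tablewide: float = 0.01,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise theta with locus bootstrap and Bonferroni significance.

    Loci are resampled with replacement ``n_boot`` times per pair; the CI is
    the 2.5/97.5 bootstrap percentile and the one-sided p-value is the
    fraction of bootstrap thetas <= 0.  A pair is flagged significant when
    p < alpha_tablewide / n_pairs.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap quantiles")
    mapping = (
        deme_assignments.to_dict()
        if isinstance(deme_assignments, pd.Series)
        else dict(deme_assignments)
    )
    if pairs is None:
        demes = sorted(set(mapping[s] for s in table.samples))
        pairs = [
            (demes[i], demes[j])
            for i in range(len(demes))
            for j in range(i + 1, len(demes))
        ]
    per_test_alpha = alpha_tablewide / len(pairs)
    rng = np.random.default_rng(seed)
    rows = []
    for da, db in pairs:
        a, abc = wc_components(table, deme_assignments, [da, db])
        L = len(a)
        theta = float(a.sum() / abc.sum())
        boot = np.empty(n_boot)
        chunk = max(1, int(2e7 // max(L, 1)))
        done = 0
        while done < n_boot:
            m = min(chunk, n_boot - done)
            idx = rng.integers(0, L, size=(m, L))
            boot[done : done + m] = a[idx].sum(axis=1) / abc[idx].sum(axis=1)
            done += m
        lo, hi = np.percentile(boot, [2.5, 97.5])
        p = float((boot <= 0).mean())
        rows.append(
            {
                "deme_a": da,
                "deme_b": db,
                "theta": theta,
                "n_loci": L,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p": p,
                "significant": p < per_test_alpha,
            }
        )
    return pd.DataFrame(rows)


def fst_matrix(results: pd.DataFrame, demes: list[str] | None = None) -> pd.DataFrame:
    """Square lower-triangle theta matrix with per-deme means appended."""
    if demes is None:
        demes = sorted(set(results["deme_a"]) | set(results["deme_b"]))
    mat = pd.DataFrame(np.nan, index=demes, columns=demes)
    for _, row in results.iterrows():
        i, j = demes.index(row["deme_a"]), demes.index(row["deme_b"])
        lo, hi = (i, j) if i > j else (j, i)
        mat.iloc[lo, hi] = row["theta"]
    means = []
    for d in demes:
        vals = results.loc[
            (results["deme_a"] == d) | (results["deme_b"] == d), "theta"
        ]
        means.append(vals.mean())
    mat["deme_mean"] = means
    return mat


# ----------------------------------------------------------------------
# private alleles
# ----------------------------------------------------------------------

def private_alleles(
    table: GenotypeTable, deme_assignments: pd.Series | dict
) -> pd.DataFrame:
    """Count alleles observed in exactly one deme (over called genotypes)."""
    mapping = (
        deme_assignments.to_dict()
        if isinstance(deme_assignments, pd.Series)
        else dict(deme_assignments)
    )
    demes = sorted(set(mapping[s] for s in table.samples))
    groups = [
        np.array([i for i, s in enumerate(table.samples) if mapping[s] == d])
        for d in demes
    ]
    called = table.called_mask()
    max_allele = int(table.n_alts().max()) if table.n_sites else 0
    counts = np.zeros((len(demes), max_allele + 1, table.n_sites), dtype=np.int64)
    for k, ix in enumerate(groups):
        for al in range(max_allele + 1):
            counts[k, al] = (
                (table.alleles[ix] == al) & called[ix][:, :, None]
            ).sum(axis=(0, 2))
    present = counts > 0
    n_demes_with = present.sum(axis=0)
    private = present & (n_demes_with == 1)[None, :, :]
    return pd.DataFrame(
        {"deme": demes, "private_alleles": private.sum(axis=(1, 2))}
    )


# ----------------------------------------------------------------------
# Rousset's a-hat
# ----------------------------------------------------------------------

def _identity_inputs(
    table: GenotypeTable, scope: list[str] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dosage matrix, called mask and per-locus within-individual identity
    averaged over the scope sample (NaN where no scope individual called)."""
    bial = table.biallelic_snp_mask()
    g = table.dosage(bial)
    if scope is not None:
        six = [table.sample_index(s) for s in scope]
    else:
        six = list(range(table.n_samples))
    gs = g[six]
    within = np.where(~np.isnan(gs), (gs != 1).astype(float), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        qw = np.nanmean(within, axis=0)  # per-locus mean within-individual identity
    return g, ~np.isnan(g), qw


def rousset_a(
    table: GenotypeTable,
    sample_i: str,
    sample_j: str,
    scope: list[str] | None = None,
) -> RoussetA:
    """Rousset's a-hat between two individuals.

    a_hat = sum_l (Qw_l - Qij_l) / sum_l (1 - Qw_l) over loci called in both
    individuals, where Qw_l is the sample-average probability of identity of
    the two genes within an individual and Qij_l the identity probability of
    one gene from each individual.  ``scope`` restricts the Qw average (deme
    for within-deme analyses, the whole cohort otherwise).  A zero
    denominator (no within-individual diversity in scope) is degenerate.
    """
    g, called, qw = _identity_inputs(table, scope)
    i, j = table.sample_index(sample_i), table.sample_index(sample_j)
    shared = called[i] & called[j] & ~np.isnan(qw)
    if not shared.any():
        raise ValueError("no shared called loci")
    if i == j:
        # self-pair: the two genes are the individual's own pair, sampled
        # without replacement, so Qij is the within-individual identity
        qij = (g[i, shared] != 1).astype(float)
    else:
        xi, xj = g[i, shared] / 2.0, g[j, shared] / 2.0
        qij = xi * xj + (1.0 - xi) * (1.0 - xj)
    num = (qw[shared] - qij).sum()
    den = (1.0 - qw[shared]).sum()
    if den <= 0:
        return RoussetA(sample_i, sample_j, np.nan, int(shared.sum()), degenerate=True)
    return RoussetA(sample_i, sample_j, float(num / den), int(shared.sum()))


def rousset_a_matrix(
    table: GenotypeTable, scope: list[str] | None = None
) -> pd.DataFrame:
    """a-hat for every pair in ``scope`` (default: all samples).

    Returns a square DataFrame indexed by sample (NaN diagonal); vectorized
    over loci via identity-probability sums.
    """
    g, called, qw = _identity_inputs(table, scope)
    names = scope if scope is not None else list(table.samples)
    ix = [table.sample_index(s) for s in names]
    g, called = g[ix], called[ix] & ~np.isnan(qw)[None, :]
    x = np.where(called, g / 2.0, 0.0)
    y = np.where(called, 1.0 - g / 2.0, 0.0)
    qij = x @ x.T + y @ y.T
    c = called.astype(float)
    qw0 = np.nan_to_num(qw)
    qw_sum = (c * qw0) @ c.T
    shared = c @ c.T
    den = shared - qw_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(den > 0, (qw_sum - qij) / den, np.nan)
    np.fill_diagonal(a, np.nan)
    return pd.DataFrame(a, index=names, columns=names)


# ----------------------------------------------------------------------
# Mantel test
# ----------------------------------------------------------------------

def mantel(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    scope: str = "global",
) -> MantelResult:
    """One-sided Mantel test for positive matrix association.

    r is the Pearson correlation of the upper-triangle entries; the null
    distribution comes from simultaneous row/column permutations of the
    second matrix; p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(a, a.T, equal_nan=True) and np.allclose(b, b.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = a.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    va, vb = a[iu, ju], b[iu, ju]
    ok = np.isfinite(va) & np.isfinite(vb)
    va, vb = va[ok], vb[ok]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    vb_perm = b[perms[:, iu], perms[:, ju]][:, ok]
    vb_c = vb_perm - vb_perm.mean(axis=1, keepdims=True)
    va_c = va - va.mean()
    denom = np.sqrt((vb_c**2).sum(axis=1)) * np.sqrt((va_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (vb_c @ va_c) / denom
    # ties (e.g. symmetric relabelings reproducing r_obs) count toward the
    # tail; the tolerance absorbs float noise between the two code paths
    p = float((1 + np.sum(r_perm >= r_obs - 1e-12)) / (n_perm + 1))
    return MantelResult(scope=scope, r=r_obs, p=p, n_perm=n_perm, n=n)


# ----------------------------------------------------------------------
# geography
# ----------------------------------------------------------------------

def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km (mean Earth radius 6371.0088 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def geo_distances(
    lon: np.ndarray, lat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Pairwise great-circle distance matrix (km) and its natural log.

    Coincident pairs (distance 0) get NaN in the log matrix and are returned
    as an exclusion list so Mantel inputs can drop them.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates outside valid degree ranges")
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, 0.0)
    iu, ju = np.triu_indices(len(lon), k=1)
    zero_pairs = [(int(i), int(j)) for i, j in zip(iu, ju) if d[i, j] == 0]
    with np.errstate(divide="ignore"):
        logd = np.log(d)
    np.fill_diagonal(logd, np.nan)
    logd[np.isinf(logd)] = np.nan
    return d, logd, zero_pairs


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def pca_scores(
    table: GenotypeTable, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centered alt-dosage matrix (mean-imputed missing calls).

    Returns per-sample scores for the leading components and the explained
    variance fractions (eigenvalue shares, non-increasing).
    """
    bial = table.biallelic_snp_mask()
    g = table.dosage(bial)
    freq = np.nanmean(g, axis=0)
    poly = (freq > 0) & (freq < 2) & ~np.isnan(freq)
    g = g[:, poly]
    if g.shape[1] < n_components:
        raise ValueError(
            f"only {g.shape[1]} polymorphic loci for {n_components} components"
        )
    col_mean = np.nanmean(g, axis=0)
    gi = np.where(np.isnan(g), col_mean, g) - col_mean
    u, s, _ = np.linalg.svd(gi, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=table.samples,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return scores, explained[:k]
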
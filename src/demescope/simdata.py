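"""Synthetic RAD-like genotype data with known truth.

Generates diploid genotypes for demes grouped into two regions under a
hierarchical Balding-Nichols allele-frequency model, with per-individual
inbreeding coefficients, within-deme isolation by distance, planted sibling /
parent-offspring dyads, optional X-linked loci, overdispersed per-genotype
sequencing depth and missingness.  Output is a standard VCF (variant plus
invariant records) and CSV metadata / truth tables, so every downstream stage
consumes exactly the file formats a real study would produce.

The generative model, per variable site with ancestral frequency p:

* region frequency  ~ Beta(p(1-t_r)/t_r, (1-p)(1-t_r)/t_r)
* deme frequency    ~ Beta(q(1-t_d)/t_d, (1-q)(1-t_d)/t_d) around region q

so t_r / t_d play the role of region- and deme-level F_ST.  Individual
genotypes are drawn with inbreeding coefficient F_i:
P(het) = 2p(1-p)(1-F_i), and the homozygote classes receive p^2 + F_i p(1-p)
and (1-p)^2 + F_i p(1-p).  Invariant sites (ancestral p = 0) propagate
unchanged and are emitted with no alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .gtable import GenotypeTable, write_vcf, write_metadata

__all__ = [
    "Frequencies",
    "TruthTable",
    "SimResult",
    "draw_hierarchical_frequencies",
    "place_coordinates",
    "sample_individuals",
    "add_noise_and_depth",
    "write_outputs",
    "simulate",
]

_BASES = np.array(list("ACGT"))
# km per degree of latitude (mean Earth radius 6371.0088 km)
_KM_PER_DEG = 111.19492664455873


def _rng_for(config: SimConfig, stage: int) -> np.random.Generator:
    """Stage-scoped RNG: one master seed, independent stream per stage."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stage,))
    )


@dataclass
class Frequencies:
    """Hierarchical allele frequencies plus the site scaffold."""

    sites: pd.DataFrame  # contig, pos, ref, alts, qual (placeholder qual)
    ancestral: np.ndarray  # (n_sites,)
    region: np.ndarray  # (2, n_sites)
    deme: np.ndarray  # (n_demes, n_sites)
    variable: np.ndarray  # bool (n_sites,)
    contig_lengths: dict[str, int]


@dataclass
class TruthTable:
    """Ground truth emitted alongside the genotypes.

    ``individuals``: sample, deme, region, lon, lat, sex, year, f_true.
    ``pairs``: planted dyads with relationship class; all other pairs are
    unrelated by construction.
    ``deme_freqs``: per-deme allele frequency per site.
    ``loci``: per-site variable / sex-linkage flags.
    """

    individuals: pd.DataFrame
    pairs: pd.DataFrame
    deme_freqs: pd.DataFrame
    loci: pd.DataFrame


@dataclass
class SimResult:
    table: GenotypeTable
    meta: pd.DataFrame
    truth: TruthTable
    contig_lengths: dict[str, int]


# ----------------------------------------------------------------------
# frequencies
# ----------------------------------------------------------------------

def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, theta: float
) -> np.ndarray:
    """One Balding-Nichols draw around each frequency in ``p``.

    Frequencies of exactly 0 or 1 (invariant sites) propagate unchanged.
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    out = p.copy().astype(float)
    seg = (p > 0) & (p < 1)
    scale = (1.0 - theta) / theta
    out[seg] = rng.beta(p[seg] * scale, (1.0 - p[seg]) * scale)
    return out


def _site_scaffold(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Place n_sites on n_contigs of decreasing length (RAD-like scatter)."""
    lengths = np.linspace(
        config.contig_length, max(config.contig_length // 5, 1000), config.n_contigs
    ).astype(int)
    names = [f"ctg{k + 1:04d}" for k in range(config.n_contigs)]
    # distribute sites proportionally to contig length
    weights = lengths / lengths.sum()
    counts = np.floor(weights * config.n_sites).astype(int)
    short = config.n_sites - counts.sum()
    order = np.argsort(-(weights * config.n_sites - counts))
    counts[order[:short]] += 1
    contig_col, pos_col = [], []
    for name, length, k in zip(names, lengths, counts):
        k = min(k, length)
        pos = np.sort(rng.choice(length, size=k, replace=False)) + 1
        contig_col.extend([name] * k)
        pos_col.extend(pos.tolist())
    sites = pd.DataFrame({"contig": contig_col, "pos": pos_col})
    return sites, dict(zip(names, lengths.tolist()))


def draw_hierarchical_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> Frequencies:
    """Draw ancestral, region and deme allele frequencies for every site.

    Variable sites get ancestral frequencies uniform on [0.05, 0.95];
    invariant sites are fixed for the reference allele (frequency 0) and
    propagate unchanged through the hierarchy.
    """
    rng = rng if rng is not None else _rng_for(config, 0)
    sites, contig_lengths = _site_scaffold(config, rng)
    n = len(sites)
    variable = np.zeros(n, dtype=bool)
    variable[rng.choice(n, size=config.n_variable, replace=False)] = True

    ancestral = np.zeros(n)
    ancestral[variable] = rng.uniform(0.05, 0.95, size=variable.sum())

    region = np.stack(
        [_balding_nichols(rng, ancestral, config.theta_region) for _ in range(2)]
    )
    deme = np.zeros((config.n_demes, n))
    for d, name in enumerate(config.deme_names):
        deme[d] = _balding_nichols(
            rng, region[config.region_of(name)], config.theta_deme
        )

    ref = rng.choice(4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    sites["ref"] = _BASES[ref]
    sites["alts"] = [
        (str(_BASES[a]),) if v else () for a, v in zip(alt, variable)
    ]
    sites["qual"] = 60.0
    return Frequencies(
        sites=sites,
        ancestral=ancestral,
        region=region,
        deme=deme,
        variable=variable,
        contig_lengths=contig_lengths,
    )


# ----------------------------------------------------------------------
# individuals
# ----------------------------------------------------------------------

def place_coordinates(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Scatter individuals around deme centroids; assign sex and year.

    Scatter is isotropic Gaussian with s.d. ``scatter_sd`` km, converted to
    degrees at the centroid latitude.  Returns the sample metadata table.
    """
    rng = rng if rng is not None else _rng_for(config, 1)
    if len(config.deme_centroids) != config.n_demes:
        raise ValueError("centroid count must equal n_demes")
    rows = []
    idx = 0
    for d, (name, size) in enumerate(zip(config.deme_names, config.deme_sizes)):
        lon0, lat0 = config.deme_centroids[d]
        dlat = rng.normal(0.0, config.scatter_sd, size) / _KM_PER_DEG
        dlon = rng.normal(0.0, config.scatter_sd, size) / (
            _KM_PER_DEG * np.cos(np.radians(lat0))
        )
        sexes = rng.choice(["F", "M"], size=size)
        years = rng.choice([2008, 2009, 2010, 2011], size=size)
        for i in range(size):
            rows.append(
                {
                    "sample": f"{name}_{i + 1:03d}",
                    "deme": name,
                    "lon": lon0 + dlon[i],
                    "lat": lat0 + dlat[i],
                    "sex": sexes[i],
                    "year": int(years[i]),
                }
            )
            idx += 1
    meta = pd.DataFrame(rows)
    if (meta["lat"].abs() > 90).any() or (meta["lon"].abs() > 180).any():
        raise ValueError("coordinates left valid degree ranges")
    return meta


def _draw_genotypes(
    rng: np.random.Generator, p: np.ndarray, f: np.ndarray
) -> np.ndarray:
    """Draw (n_ind, n_sites, 2) allele pairs with inbreeding.

    ``p``: (n_ind, n_sites) individual-specific alt frequencies;
    ``f``: (n_ind,) inbreeding coefficients.
    """
    f = f[:, None]
    p_het = 2.0 * p * (1.0 - p) * (1.0 - f)
    p_homref = (1.0 - p) ** 2 + f * p * (1.0 - p)
    u = rng.random(p.shape)
    het = (u >= p_homref) & (u < p_homref + p_het)
    homalt = u >= p_homref + p_het
    alleles = np.zeros(p.shape + (2,), dtype=np.int8)
    alleles[het, 1] = 1
    alleles[homalt, :] = 1
    return alleles


def _mendelian_child(
    rng: np.random.Generator, father: np.ndarray, mother: np.ndarray
) -> np.ndarray:
    """One offspring by random transmission: (n_sites, 2) from two parents."""
    n = father.shape[0]
    a = father[np.arange(n), rng.integers(0, 2, n)]
    b = mother[np.arange(n), rng.integers(0, 2, n)]
    return np.stack([a, b], axis=1)


def sample_individuals(
    freqs: Frequencies,
    config: SimConfig,
    meta: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeTable, TruthTable, pd.DataFrame]:
    """Draw genotypes for all individuals; plant dyads and X-linked loci.

    With ``ibd_slope > 0`` each deme's frequencies are tilted along the
    within-deme east-west axis: individual-specific frequency at site l is
    clip(p_dl + slope * s_dl * u_i, 0, 1), with u_i the standardized
    longitude of individual i inside the deme (range about [-1/2, 1/2]) and
    s_dl a random-sign site effect of magnitude sqrt(p(1-p)).  Spatially
    close individuals then share similar frequencies, producing positive
    isolation by distance within demes.
    """
    rng = rng if rng is not None else _rng_for(config, 2)
    if meta is None:
        meta = place_coordinates(config, rng=rng)
    for lo, hi in config.f_range_per_deme:
        if not (0 <= lo <= hi <= 1):
            raise ValueError("f range outside [0, 1]")

    n_sites = len(freqs.sites)
    n_ind = config.n_individuals
    alleles = np.zeros((n_ind, n_sites, 2), dtype=np.int8)
    f_true = np.zeros(n_ind)

    deme_of = meta["deme"].to_numpy()
    for d, name in enumerate(config.deme_names):
        rows = np.flatnonzero(deme_of == name)
        lon = meta.loc[rows, "lon"].to_numpy()
        sd = lon.std()
        u = np.clip((lon - lon.mean()) / (2 * sd), -0.5, 0.5) if sd > 0 else np.zeros(len(rows))
        p_d = freqs.deme[d]
        if config.ibd_slope > 0:
            sign = rng.choice([-1.0, 1.0], size=n_sites)
            s = sign * np.sqrt(p_d * (1.0 - p_d))
            p_ind = np.clip(p_d + config.ibd_slope * u[:, None] * s, 0.0, 1.0)
        else:
            p_ind = np.broadcast_to(p_d, (len(rows), n_sites)).copy()
        lo, hi = config.f_range_per_deme[d]
        f = rng.uniform(lo, hi, size=len(rows))
        alleles[rows] = _draw_genotypes(rng, p_ind, f)
        f_true[rows] = f

    # plant related dyads by explicit Mendelian transmission
    pair_rows = []
    used: set[int] = set()
    order = np.argsort(-np.asarray(config.deme_sizes))
    dyad_specs = ["full-sib"] * config.n_sib_pairs + [
        "parent-offspring"
    ] * config.n_po_pairs
    for k, rel in enumerate(dyad_specs):
        d = int(order[k % config.n_demes])
        name = config.deme_names[d]
        rows = [r for r in np.flatnonzero(deme_of == name) if r not in used]
        if len(rows) < 2:
            raise ValueError(f"deme {name} too small to plant a {rel} dyad")
        i, j = rows[0], rows[1]
        used.update((i, j))
        p_d = freqs.deme[d]
        pp = np.broadcast_to(p_d, (2, n_sites))
        father, mother = _draw_genotypes(rng, pp, np.zeros(2))
        if rel == "full-sib":
            alleles[i] = _mendelian_child(rng, father, mother)
            alleles[j] = _mendelian_child(rng, father, mother)
            f_true[i] = f_true[j] = 0.0
        else:  # parent-offspring
            alleles[i] = father
            alleles[j] = _mendelian_child(rng, father, mother)
            f_true[i] = f_true[j] = 0.0
        pair_rows.append(
            {
                "sample_i": meta.loc[i, "sample"],
                "sample_j": meta.loc[j, "sample"],
                "relationship": rel,
            }
        )

    # X-linked loci: males carry a single allele, reported as homozygous
    sexlinked = np.zeros(n_sites, dtype=bool)
    if config.n_sexlinked > 0:
        candidates = np.flatnonzero(freqs.variable)
        chosen = rng.choice(
            candidates, size=min(config.n_sexlinked, len(candidates)), replace=False
        )
        sexlinked[chosen] = True
        males = np.flatnonzero(meta["sex"].to_numpy() == "M")
        for l in chosen:
            hemi = (
                rng.random(len(males))
                < np.clip(freqs.deme[:, l].mean(), 0, 1)
            ).astype(np.int8)
            alleles[males, l, 0] = hemi
            alleles[males, l, 1] = hemi

    alleles = np.sort(alleles, axis=2)  # unphased: canonical low/high order
    depth = np.full((n_ind, n_sites), int(round(config.mean_depth)), np.int32)
    table = GenotypeTable(
        samples=meta["sample"].tolist(),
        sites=freqs.sites.copy(),
        alleles=alleles,
        depth=depth,
    )
    individuals = meta.copy()
    individuals["region"] = [config.region_of(d) for d in individuals["deme"]]
    individuals["f_true"] = f_true
    deme_freqs = freqs.sites[["contig", "pos"]].copy()
    for d, name in enumerate(config.deme_names):
        deme_freqs[name] = freqs.deme[d]
    loci = freqs.sites[["contig", "pos"]].copy()
    loci["variable"] = freqs.variable
    loci["sexlinked"] = sexlinked
    truth = TruthTable(
        individuals=individuals,
        pairs=pd.DataFrame(
            pair_rows, columns=["sample_i", "sample_j", "relationship"]
        ),
        deme_freqs=deme_freqs,
        loci=loci,
    )
    return table, truth, meta


# ----------------------------------------------------------------------
# noise
# ----------------------------------------------------------------------

def add_noise_and_depth(
    table: GenotypeTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeTable:
    """Overlay depth, genotype error, missingness and site quality.

    Depth is negative binomial with mean ``mean_depth`` and size
    ``depth_dispersion`` (Poisson when dispersion is None).  Genotypes with
    zero depth, plus an independent ``missing_rate`` fraction, are set to
    missing.  With probability ``error_rate`` a called genotype at a variant
    site is replaced by one of the other two genotype classes.
    """
    rng = rng if rng is not None else _rng_for(config, 3)
    shape = table.depth.shape
    if config.depth_dispersion is None:
        depth = rng.poisson(config.mean_depth, size=shape)
    else:
        k = config.depth_dispersion
        depth = rng.negative_binomial(k, k / (k + config.mean_depth), size=shape)
    depth = depth.astype(np.int32)

    alleles = table.alleles.copy()
    if config.error_rate > 0:
        variant = table.n_alts() > 0
        err = (rng.random(shape) < config.error_rate) & variant[None, :] & (
            alleles[:, :, 0] >= 0
        )
        cur = alleles[err].sum(axis=1)  # 0, 1, or 2 alt copies
        shift = rng.integers(1, 3, size=err.sum())
        new = (cur + shift) % 3
        repl = np.zeros((err.sum(), 2), dtype=np.int8)
        repl[new >= 1, 1] = 1
        repl[new == 2, 0] = 1
        alleles[err] = repl

    miss = (rng.random(shape) < config.missing_rate) | (depth == 0)
    alleles[miss] = -1

    sites = table.sites.copy()
    sites["qual"] = np.round(np.clip(rng.normal(60.0, 10.0, len(sites)), 10, 99), 1)
    return GenotypeTable(
        samples=list(table.samples), sites=sites, alleles=alleles, depth=depth
    )


# ----------------------------------------------------------------------
# output
# ----------------------------------------------------------------------

def write_outputs(
    table: GenotypeTable,
    truth: TruthTable,
    meta: pd.DataFrame,
    outdir: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> dict[str, Path]:
    """Write VCF + metadata + truth CSVs; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "sim.vcf",
        "meta": outdir / "meta.csv",
        "truth_individuals": outdir / "truth_individuals.csv",
        "truth_pairs": outdir / "truth_pairs.csv",
        "truth_deme_freqs": outdir / "truth_deme_freqs.csv",
        "truth_loci": outdir / "truth_loci.csv",
    }
    write_vcf(table, paths["vcf"], contig_lengths=contig_lengths)
    write_metadata(meta, paths["meta"])
    truth.individuals.to_csv(paths["truth_individuals"], index=False)
    truth.pairs.to_csv(paths["truth_pairs"], index=False)
    truth.deme_freqs.to_csv(paths["truth_deme_freqs"], index=False)
    truth.loci.to_csv(paths["truth_loci"], index=False)
    return paths


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: frequencies -> individuals -> noise."""
    freqs = draw_hierarchical_frequencies(config)
    meta = place_coordinates(config)
    clean, truth, meta = sample_individuals(freqs, config, meta=meta)
    noisy = add_noise_and_depth(clean, config)
    return SimResult(
        table=noisy, meta=meta, truth=truth, contig_lengths=freqs.contig_lengths
    )
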
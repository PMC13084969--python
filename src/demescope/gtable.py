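"""Genotype containers and VCF / metadata I/O.

The central object is :class:`GenotypeTable`: an in-memory matrix of diploid
genotype calls (allele-index pairs) with per-genotype sequencing depth, over
an ordered list of sites that may be variant *or* invariant.  Invariant sites
(no alternate allele) are first-class citizens because the individual
heterozygosity estimator uses them in its denominator, which is what makes
per-individual estimates comparable across samples with different amounts of
retained data.

Sites live in a pandas DataFrame with columns ``contig``, ``pos`` (1-based),
``ref``, ``alts`` (tuple of alternate alleles, empty for invariant sites,
possibly containing the spanning-deletion symbol ``*``) and ``qual``.
Genotypes are stored as an ``(n_samples, n_sites, 2)`` int8 array of allele
indices (0 = REF, 1.. = ALT index, -1 = missing); depth is an
``(n_samples, n_sites)`` int32 array.

VCF parsing goes through :mod:`cyvcf2`.  Writing is done by this module's own
serializer because invariant records (``ALT=.``) cannot be constructed through
the available writer APIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "write_metadata",
    "STAR_ALLELE",
]

STAR_ALLELE = "*"

META_COLUMNS = ["sample", "deme", "lon", "lat", "sex", "year"]


class VcfWriteError(IOError):
    """Raised when a record cannot be serialized, with file/record context."""


@dataclass
class GenotypeTable:
    """Samples x sites genotype calls with per-genotype depth.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers.
    sites
        DataFrame with columns ``contig, pos, ref, alts, qual``; positions
        strictly increasing within each contig.
    alleles
        ``(n_samples, n_sites, 2)`` int8 allele indices; -1 marks a missing
        call (both entries -1).
    depth
        ``(n_samples, n_sites)`` int32 read depth per genotype.
    """

    samples: list[str]
    sites: pd.DataFrame
    alleles: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        n, m = len(self.samples), len(self.sites)
        if self.alleles.shape != (n, m, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {m}, 2)"
            )
        if self.depth.shape != (n, m):
            raise ValueError(f"depth shape {self.depth.shape} != ({n}, {m})")
        for contig, grp in self.sites.groupby("contig", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"site positions not strictly increasing on contig {contig}"
                )

    # ------------------------------------------------------------------
    # basic properties
    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    # ------------------------------------------------------------------
    # masks
    # ------------------------------------------------------------------
    def called_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_sites): genotype has both alleles called."""
        return self.alleles[:, :, 0] >= 0

    def het_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_sites): called and heterozygous."""
        return self.called_mask() & (self.alleles[:, :, 0] != self.alleles[:, :, 1])

    def n_alts(self) -> np.ndarray:
        """Number of alternate alleles per site (0 for invariant)."""
        return self.sites["alts"].map(len).to_numpy()

    def biallelic_snp_mask(self) -> np.ndarray:
        """Sites with exactly one alternate allele, not a spanning deletion."""
        return self.sites["alts"].map(
            lambda a: len(a) == 1 and a[0] != STAR_ALLELE
        ).to_numpy()

    def dosage(self, site_mask: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele dosage (0/1/2, NaN when missing) for biallelic sites.

        ``site_mask`` selects sites (defaults to all); at multi-allelic sites
        dosage counts copies of the first alternate allele.
        """
        a = self.alleles if site_mask is None else self.alleles[:, site_mask, :]
        d = (a == 1).sum(axis=2).astype(float)
        d[a[:, :, 0] < 0] = np.nan
        return d

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the first alternate allele from called genotypes.

        Returns NaN for sites with no called genotypes.
        """
        called = self.called_mask()
        alt = (self.alleles == 1).sum(axis=2)
        with np.errstate(invalid="ignore"):
            return np.where(called, alt, 0).sum(axis=0) / (2.0 * called.sum(axis=0))

    # ------------------------------------------------------------------
    # subsetting
    # ------------------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeTable":
        """New table with the given site selection (bool mask or int index)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeTable(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            alleles=self.alleles[:, index, :].copy(),
            depth=self.depth[:, index].copy(),
        )

    def take_samples(self, keep: Sequence[str] | np.ndarray) -> "GenotypeTable":
        """New table restricted to the given samples (names or indices)."""
        if isinstance(keep, np.ndarray) and keep.dtype != object:
            if keep.dtype == bool:
                idx = np.flatnonzero(keep)
            else:
                idx = keep
        else:
            idx = np.array([self.sample_index(s) for s in keep])
        return GenotypeTable(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.copy(),
            alleles=self.alleles[idx].copy(),
            depth=self.depth[idx].copy(),
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.samples == other.samples
            and self.sites[["contig", "pos", "ref", "alts"]].equals(
                other.sites[["contig", "pos", "ref", "alts"]]
            )
            and np.allclose(self.sites["qual"], other.sites["qual"], atol=0.05)
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.depth, other.depth)
        )


# ----------------------------------------------------------------------
# VCF I/O
# ----------------------------------------------------------------------

def write_vcf(
    table: GenotypeTable,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Serialize a GenotypeTable to a VCF 4.2 text file.

    Invariant sites are written with ``ALT=.`` per the VCF standard; genotypes
    carry GT and DP per sample.  Alleles within a genotype are written in
    sorted order (unphased).
    """
    path = Path(path)
    sites = table.sites
    lines: list[str] = ["##fileformat=VCFv4.2"]
    contigs = list(dict.fromkeys(sites["contig"]))
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
    )

    alleles = table.alleles
    depth = table.depth
    contig_arr = sites["contig"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    ref_arr = sites["ref"].to_numpy()
    alts_arr = sites["alts"].to_numpy()
    qual_arr = sites["qual"].to_numpy()

    try:
        with path.open("w") as fh:
            fh.write("\n".join(lines) + "\n")
            for j in range(table.n_sites):
                alts = alts_arr[j]
                alt_field = ",".join(alts) if len(alts) else "."
                cols = [
                    str(contig_arr[j]),
                    str(int(pos_arr[j])),
                    ".",
                    str(ref_arr[j]),
                    alt_field,
                    f"{qual_arr[j]:.1f}",
                    "PASS",
                    ".",
                    "GT:DP",
                ]
                for i in range(table.n_samples):
                    a0, a1 = alleles[i, j]
                    if a0 < 0:
                        gt = "./."
                    else:
                        lo, hi = (a0, a1) if a0 <= a1 else (a1, a0)
                        gt = f"{lo}/{hi}"
                    cols.append(f"{gt}:{int(depth[i, j])}")
                fh.write("\t".join(cols) + "\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise VcfWriteError(f"failed writing {path}: {exc}") from exc


def read_vcf(path: str | Path) -> GenotypeTable:
    """Parse a VCF (with invariant sites) into a GenotypeTable via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    contigs: list[str] = []
    pos: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    quals: list[float] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    for rec in vcf:
        contigs.append(rec.CHROM)
        pos.append(rec.POS)
        refs.append(rec.REF)
        alts.append(tuple(rec.ALT))
        quals.append(rec.QUAL if rec.QUAL is not None else np.nan)
        g = np.array([gt[:2] for gt in rec.genotypes], dtype=np.int8)
        gts.append(g)
        dp = rec.format("DP")
        dps.append(
            dp.flatten().astype(np.int32)
            if dp is not None
            else np.zeros(len(samples), np.int32)
        )
    sites = pd.DataFrame(
        {"contig": contigs, "pos": pos, "ref": refs, "alts": alts, "qual": quals}
    )
    alleles = (
        np.stack(gts, axis=1)
        if gts
        else np.empty((len(samples), 0, 2), np.int8)
    )
    # normalize partially-missing calls to fully missing; canonical allele order
    miss = (alleles[:, :, 0] < 0) | (alleles[:, :, 1] < 0)
    alleles[miss] = -1
    alleles = np.sort(alleles, axis=2)
    depth = (
        np.stack(dps, axis=1) if dps else np.empty((len(samples), 0), np.int32)
    )
    depth = np.maximum(depth, 0)
    return GenotypeTable(samples=samples, sites=sites, alleles=alleles, depth=depth)


# ----------------------------------------------------------------------
# sample metadata
# ----------------------------------------------------------------------

def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    """Write the sample metadata table (sample, deme, lon, lat, sex, year)."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta[META_COLUMNS].to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample": str, "deme": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    return meta
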
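"""Simulation and run configuration objects (YAML-serializable)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["SimConfig", "load_sim_config", "dump_sim_config"]

# Default deme layout: seven demes in two regions, sized like a realistic
# state-wide marsupial survey (four northern, three southern demes).
DEFAULT_DEME_NAMES = ["NW", "TW", "TE", "NE", "DW", "DE", "TP"]
DEFAULT_DEME_SIZES = [18, 9, 7, 6, 22, 13, 10]
DEFAULT_REGION_SPLIT = [["NW", "TW", "TE", "NE"], ["DW", "DE", "TP"]]
# Approximate centroids (lon, lat) spanning ~250 km north-south.
DEFAULT_CENTROIDS = [
    (145.30, -41.10),
    (146.85, -41.45),
    (147.25, -41.35),
    (148.00, -41.30),
    (146.90, -43.00),
    (147.50, -42.80),
    (147.85, -43.05),
]


@dataclass
class SimConfig:
    """Parameters of the synthetic RAD-like genotype generator.

    The generator produces diploid genotypes for ``sum(deme_sizes)``
    individuals in ``n_demes`` demes grouped into two regions, under a
    hierarchical Balding-Nichols allele-frequency model: region frequencies
    diverge from an ancestral pool with parameter ``theta_region``, deme
    frequencies from their region with ``theta_deme``.  Individual inbreeding
    coefficients F_i are drawn uniformly from a per-deme interval and shrink
    expected heterozygosity by (1 - F_i).  Sites are scattered across many
    short contigs; only a fraction ``prop_variable`` is polymorphic, the rest
    are invariant (fixed reference) but still genotyped with depth.
    """

    seed: int = 0
    n_demes: int = 7
    deme_names: list[str] = field(default_factory=lambda: list(DEFAULT_DEME_NAMES))
    deme_sizes: list[int] = field(default_factory=lambda: list(DEFAULT_DEME_SIZES))
    region_split: list[list[str]] = field(
        default_factory=lambda: [list(r) for r in DEFAULT_REGION_SPLIT]
    )
    theta_region: float = 0.08
    theta_deme: float = 0.05
    n_contigs: int = 200
    contig_length: int = 100_000
    n_sites: int = 50_000
    prop_variable: float = 0.10
    # per-deme [f_lo, f_hi] for individual inbreeding coefficients; a range of
    # [0, 0.5] makes expected heterozygosity vary two-fold within a deme
    f_range_per_deme: list[list[float]] = field(
        default_factory=lambda: [[0.0, 0.5]] * 7
    )
    deme_centroids: list[tuple[float, float]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_CENTROIDS]
    )
    scatter_sd: float = 8.0  # km
    ibd_slope: float = 0.3
    n_sib_pairs: int = 3
    n_po_pairs: int = 0
    n_sexlinked: int = 0
    mean_depth: float = 40.0
    depth_dispersion: float | None = 8.0  # NB size parameter; None = Poisson
    missing_rate: float = 0.05
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.theta_region < 1) or not (0 < self.theta_deme < 1):
            raise ValueError("theta_region and theta_deme must lie in (0, 1)")
        for name, p in [
            ("prop_variable", self.prop_variable),
            ("missing_rate", self.missing_rate),
            ("error_rate", self.error_rate),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if len(self.deme_sizes) != self.n_demes:
            raise ValueError("deme_sizes length must equal n_demes")
        if len(self.deme_names) != self.n_demes:
            raise ValueError("deme_names length must equal n_demes")
        if len(self.deme_centroids) != self.n_demes:
            raise ValueError("deme_centroids length must equal n_demes")
        if sum(self.deme_sizes) < 2:
            raise ValueError("need at least 2 individuals in total")
        if len(self.f_range_per_deme) != self.n_demes:
            raise ValueError("f_range_per_deme length must equal n_demes")
        for lo, hi in self.f_range_per_deme:
            if not (0 <= lo <= hi <= 1):
                raise ValueError("f ranges must satisfy 0 <= lo <= hi <= 1")
        split = [d for region in self.region_split for d in region]
        if sorted(split) != sorted(self.deme_names):
            raise ValueError("region_split must partition deme_names")
        if len(self.region_split) != 2:
            raise ValueError("exactly two regions are modelled")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")

    @property
    def n_individuals(self) -> int:
        return sum(self.deme_sizes)

    @property
    def n_variable(self) -> int:
        return int(round(self.n_sites * self.prop_variable))

    def region_of(self, deme: str) -> int:
        for k, region in enumerate(self.region_split):
            if deme in region:
                return k
        raise KeyError(deme)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["deme_centroids"] = [list(c) for c in self.deme_centroids]
        return d


def load_sim_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "deme_centroids" in raw:
        raw["deme_centroids"] = [tuple(c) for c in raw["deme_centroids"]]
    return SimConfig(**raw)


def dump_sim_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
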
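"""End-to-end run orchestration: simulate -> filter -> het -> structure -> krige.

A :class:`RunConfig` (YAML-serializable) holds every stage's parameters with
the conventional defaults of a RADseq conservation-genomics study: call-rate
0.85 overall / 0.5 per deme, per-sample missingness < 0.10, MAC 3, mean-depth
window [5, 95], thinning 10 kb, per-individual depth window [15, 95],
10,000-replicate F_ST bootstrap at table-wide alpha 0.01, exponential kriging
with 36 neighbours.  One global seed expands into independent per-stage
streams via ``numpy.random.SeedSequence(seed, spawn_key=(stage,))``, so a
stage rerun in isolation reproduces its in-pipeline output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import genofilter, hetpipe, simdata, spatialhet, structstats
from .config import SimConfig
from .gtable import GenotypeTable, read_metadata, read_vcf

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "summary_report", "load_run_config"]

ALL_STAGES = ["simulate", "filter", "het", "structure", "krige", "report"]

# per-stage spawn keys for the global seed
_STAGE_KEY = {name: k for k, name in enumerate(ALL_STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic sub-2^31 seed for a named stage."""
    ss = np.random.SeedSequence(global_seed, spawn_key=(100 + _STAGE_KEY[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # inputs: either a simulation config or an existing VCF + metadata
    sim: SimConfig | None = None
    vcf: str | None = None
    meta: str | None = None
    # filter stage
    first_pass_rate: float = 0.70
    overall_rate: float = 0.85
    per_deme_rate: float = 0.50
    max_missing: float = 0.10
    min_mac: int = 3
    min_mean_dp: float = 5.0
    max_mean_dp: float = 95.0
    min_qual: float = 30.0
    thin_bp: int = 10_000
    # het stage
    het_min_dp: int = 15
    het_max_dp: int = 95
    window_bp: int = 200_000
    window_floor: int = 50
    # structure stage
    n_boot: int = 10_000
    alpha_tablewide: float = 0.01
    n_perm: int = 999
    # krige stage
    k_neighbors: int = 36
    grid_nx: int = 100
    grid_ny: int = 100

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if self.sim is None and "simulate" in self.stages:
            self.sim = SimConfig(seed=stage_seed(self.seed, "simulate"))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if raw.get("sim"):
        sim = raw["sim"]
        if "deme_centroids" in sim:
            sim["deme_centroids"] = [tuple(c) for c in sim["deme_centroids"]]
        raw["sim"] = SimConfig(**sim)
    return RunConfig(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)
    log.info("wrote %s (%d rows)", path, len(df))


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Run the configured stages, writing all artefacts under ``outdir``.

    The serialized config is written into the output directory; a failing
    stage raises :class:`StageError` naming the stage, with all earlier
    artefacts left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    table: GenotypeTable | None = None
    meta: pd.DataFrame | None = None
    contig_lengths = None

    stage = "simulate"
    try:
        if "simulate" in config.stages:
            res = simdata.simulate(config.sim)
            simdata.write_outputs(
                res.table, res.truth, res.meta, outdir, res.contig_lengths
            )
            table, meta, contig_lengths = res.table, res.meta, res.contig_lengths
        else:
            if not config.vcf or not config.meta:
                raise ValueError("need vcf and meta paths when not simulating")
            table = read_vcf(config.vcf)
            meta = read_metadata(config.meta)
    except Exception as exc:  # noqa: BLE001 - report failing stage
        raise StageError(stage, exc) from exc

    if set(config.stages) == {"simulate"}:
        return outdir

    demes = meta.set_index("sample")["deme"]
    sexes = meta.set_index("sample")["sex"]

    filtered = None
    flagged_sites = np.zeros(table.n_sites, dtype=bool)
    stage = "filter"
    if "filter" in config.stages:
        try:
            filtered, report = genofilter.run_filter_cascade(
                table,
                demes,
                first_pass_rate=config.first_pass_rate,
                overall_rate=config.overall_rate,
                per_deme_rate=config.per_deme_rate,
                max_missing=config.max_missing,
                min_mac=config.min_mac,
                min_mean_dp=config.min_mean_dp,
                max_mean_dp=config.max_mean_dp,
                min_qual=config.min_qual,
            )
            _write(report.to_frame(), outdir / "filter_report.csv")
            thinned, _ = genofilter.thin_loci(filtered, config.thin_bp)
            log.info("thinned SNP panel: %d loci", thinned.n_sites)
            dyads = genofilter.kinship_screen(filtered)
            _write(genofilter.kinship_frame(dyads), outdir / "kinship.csv")
            flagged = genofilter.sex_linkage_screen(table, sexes)
            _write(flagged, outdir / "sexlinked_loci.csv")
            if len(flagged):
                flagged_sites[flagged["site"].to_numpy()] = True
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    het_df = None
    stage = "het"
    if "het" in config.stages:
        try:
            het_table, _ = genofilter.site_quality_filter(table, config.min_qual)
            qual_keep = table.sites["qual"].to_numpy() >= config.min_qual
            excl = flagged_sites[qual_keep]
            het_df = hetpipe.autosomal_het_all(
                het_table, config.het_min_dp, config.het_max_dp, excluded_sites=excl
            )
            _write(het_df, outdir / "het_individual.csv")
            fis = hetpipe.deme_fis(het_table, demes)
            _write(
                pd.DataFrame(
                    [
                        {"deme": r.deme, "FIS": r.fis, "n_loci": r.n_loci,
                         "reliable": r.reliable}
                        for r in fis
                    ]
                ),
                outdir / "deme_fis.csv",
            )
            profile = hetpipe.window_profile(
                het_table, config.window_bp, config.het_min_dp,
                config.het_max_dp, config.window_floor,
                contig_lengths=contig_lengths, excluded_sites=excl,
            )
            _write(profile.to_frame(), outdir / "window_profile.csv")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    mantel_rows = []
    stage = "structure"
    if "structure" in config.stages:
        try:
            if filtered is None:
                filtered, _ = genofilter.run_filter_cascade(table, demes)
            seed = stage_seed(config.seed, "structure")
            fst = structstats.fst_bootstrap(
                filtered, demes, n_boot=config.n_boot,
                alpha_tablewide=config.alpha_tablewide, seed=seed,
            )
            _write(fst, outdir / "fst_pairs.csv")
            structstats.fst_matrix(fst).to_csv(outdir / "fst_matrix.csv")
            _write(
                structstats.private_alleles(filtered, demes),
                outdir / "private_alleles.csv",
            )
            scores, explained = structstats.pca_scores(
                filtered, n_components=min(10, filtered.n_samples - 1)
            )
            scores.insert(0, "sample", scores.index)
            _write(scores.reset_index(drop=True), outdir / "pca_scores.csv")

            order = meta["sample"].tolist()
            lon = meta["lon"].to_numpy()
            lat = meta["lat"].to_numpy()
            d_km, logd, _ = structstats.geo_distances(lon, lat)
            scopes: list[tuple[str, list[int]]] = [
                ("global", list(range(len(order))))
            ]
            for deme_name, grp in meta.groupby("deme"):
                if len(grp) >= 5:
                    scopes.append((f"deme:{deme_name}", list(grp.index)))
            for scope_name, ix in scopes:
                sub = [order[i] for i in ix]
                ahat = structstats.rousset_a_matrix(filtered, scope=sub).to_numpy()
                sub_log = logd[np.ix_(ix, ix)]
                try:
                    res = structstats.mantel(
                        sub_log, ahat, n_perm=config.n_perm,
                        seed=seed, scope=scope_name,
                    )
                    mantel_rows.append(
                        {"scope": res.scope, "r": res.r, "p": res.p,
                         "n_perm": res.n_perm, "n": res.n}
                    )
                except ValueError as e:
                    log.warning("Mantel skipped for %s: %s", scope_name, e)
            _write(pd.DataFrame(mantel_rows), outdir / "mantel.csv")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    stage = "krige"
    if "krige" in config.stages and het_df is not None:
        try:
            merged = het_df.merge(meta, on="sample")
            surf, model, _ = spatialhet.krige_heterozygosity(
                merged["lon"].to_numpy(),
                merged["lat"].to_numpy(),
                merged["H_O"].to_numpy(),
                k_neighbors=config.k_neighbors,
                n_x=config.grid_nx,
                n_y=config.grid_ny,
            )
            surf.to_frame().to_csv(outdir / "kriged_surface.csv", index=False)
            with open(outdir / "variogram_model.yaml", "w") as fh:
                yaml.safe_dump(
                    {"nugget": model.nugget, "psill": model.psill,
                     "range_km": model.range_km}, fh,
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    stage = "report"
    if "report" in config.stages and het_df is not None:
        try:
            text, numbers = summary_report(het_df, meta)
            (outdir / "summary.txt").write_text(text)
            pd.DataFrame([numbers]).to_csv(outdir / "summary.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    return outdir


# ----------------------------------------------------------------------
# summary report
# ----------------------------------------------------------------------

def summary_report(
    het: pd.DataFrame, meta: pd.DataFrame
) -> tuple[str, dict]:
    """Cohort summary: H_O extremes, per-deme ranges, ANOVA, covariate R^2.

    Returns the formatted text plus a flat dict of the computed numbers.
    """
    df = het.merge(meta, on="sample")
    lines = ["# Individual autosomal heterozygosity summary", ""]
    numbers: dict = {}

    imin = df.loc[df["H_O"].idxmin()]
    imax = df.loc[df["H_O"].idxmax()]
    numbers["h_o_min"] = float(imin["H_O"])
    numbers["h_o_min_sample"] = imin["sample"]
    numbers["h_o_min_deme"] = imin["deme"]
    numbers["h_o_max"] = float(imax["H_O"])
    numbers["h_o_max_sample"] = imax["sample"]
    numbers["h_o_max_deme"] = imax["deme"]
    lines.append(
        f"Lowest H_O : {imin['H_O']:.3e} ({imin['sample']}, deme {imin['deme']})"
    )
    lines.append(
        f"Highest H_O: {imax['H_O']:.3e} ({imax['sample']}, deme {imax['deme']})"
    )
    lines.append("")

    per = df.groupby("deme")["H_O"].agg(["count", "mean", "min", "max"])
    per["max_min_ratio"] = per["max"] / per["min"]
    lines.append(per.to_string(float_format=lambda v: f"{v:.4g}"))
    lines.append("")
    numbers["max_within_deme_ratio"] = float(per["max_min_ratio"].max())
    numbers["lowest_mean_deme"] = per["mean"].idxmin()

    demes = sorted(df["deme"].unique())
    df1, df2 = len(demes) - 1, len(df) - len(demes)
    if len(demes) >= 2 and df2 > 0:
        groups = [df.loc[df["deme"] == d, "H_O"].to_numpy() for d in demes]
        if df["H_O"].nunique() == 1:
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*groups)
        numbers.update(anova_f=float(F), anova_p=float(p), anova_df1=df1,
                       anova_df2=df2)
        lines.append(f"One-way ANOVA across demes: F_{df1},{df2} = {F:.3f}, "
                     f"p = {p:.3g}")
    elif len(demes) < 2:
        lines.append("One-way ANOVA skipped: single deme")
    else:
        lines.append("One-way ANOVA skipped: no within-deme replication")

    if df["n_retained"].nunique() > 1:
        slope, r2 = hetpipe.het_covariate_check(df, df["n_retained"].to_numpy())
        numbers["r2_retained_sites"] = r2
        lines.append(f"H_O ~ retained sites: R^2 = {r2:.3f} (slope {slope:.3g})")
    if df["year"].nunique() > 1:
        slope, r2 = hetpipe.het_covariate_check(df, df["year"].to_numpy())
        numbers["r2_year"] = r2
        lines.append(f"H_O ~ sampling year: R^2 = {r2:.3f} (slope {slope:.3g})")
    return "\n".join(lines) + "\n", numbers
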
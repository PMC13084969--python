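import numpy as np
import pandas as pd
import pytest

from demescope.gtable import GenotypeTable


def make_table(
    codes,
    depth=30,
    contig="ctg1",
    positions=None,
    alts=None,
    qual=60.0,
    samples=None,
):
    """Build a GenotypeTable from simple genotype codes.

    ``codes``: (n_samples, n_sites) ints with 0 hom-ref, 1 het, 2 hom-alt,
    -1 missing.  ``alts`` may be a per-site list of alt tuples (empty tuple =
    invariant site).
    """
    codes = np.asarray(codes)
    n, m = codes.shape
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    alleles[codes == 1, 1] = 1
    alleles[codes == 2] = 1
    alleles[codes == -1] = -1
    if np.isscalar(depth):
        depth = np.full((n, m), depth)
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if alts is None:
        alts = [("T",)] * m
    if isinstance(contig, str):
        contig = [contig] * m
    sites = pd.DataFrame(
        {
            "contig": contig,
            "pos": positions,
            "ref": ["A"] * m,
            "alts": [tuple(a) for a in alts],
            "qual": [float(qual)] * m,
        }
    )
    if samples is None:
        samples = [f"S{i:03d}" for i in range(n)]
    return GenotypeTable(
        samples=list(samples),
        sites=sites,
        alleles=alleles,
        depth=np.asarray(depth, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-region cohort used by several integration tests."""
    from demescope import SimConfig, simulate

    cfg = SimConfig(
        seed=7,
        n_sites=3000,
        prop_variable=0.3,
        n_contigs=20,
        contig_length=20_000,
        missing_rate=0.03,
    )
    return simulate(cfg)
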
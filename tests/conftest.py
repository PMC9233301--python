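import numpy as np
import pytest

from hapshare import ibd, simdata
from hapshare.panel import HaplotypePanel


def make_panel(alleles, cm=None, chrom=None, bp=None, ids=None) -> HaplotypePanel:
    """Small-panel constructor with sensible coordinate defaults."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    H, S = alleles.shape
    if cm is None:
        cm = np.arange(S, dtype=float)
    cm = np.asarray(cm, dtype=float)
    if bp is None:
        bp = (cm * 1e6).astype(np.int64) + 1
    if chrom is None:
        chrom = np.full(S, "chr1")
    if ids is None:
        ids = [f"I{i}" for i in range(H // 2)]
    return HaplotypePanel(alleles, np.asarray(chrom), bp, cm, ids)


@pytest.fixture(scope="session")
def deep_sim():
    """Single population, diploid size 500 held for 50 generations, 200
    sampled individuals on 2 x 100 cM chromosomes — the main error-free
    validation panel for IBD detection and Ne recovery."""
    cfg = simdata.SimConfig(
        n_subpops=1,
        size_per_generation=500,
        n_generations=50,
        chromosomes=((100.0, 3000, 100_000_000),) * 2,
        sample_size=200,
        seed=1,
    )
    return simdata.simulate(cfg)


@pytest.fixture(scope="session")
def deep_sim_segments(deep_sim):
    seg = ibd.detect_ibd(deep_sim.panel, min_cM=1.0)
    return ibd.merge_ibd(seg, deep_sim.panel)


@pytest.fixture(scope="session")
def deep_sim_truth(deep_sim):
    return deep_sim.truth_ibd(min_cM=0.0)
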
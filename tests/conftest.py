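import numpy as np
import pandas as pd
import pytest

from anchorforge import PipelineConfig, SimConfig, run_pipeline
from anchorforge.config import DistortionLocus
from anchorforge.evaluation import group_purity
from anchorforge.simulate import marker_truth


def small_sim_config(seed: int = 11, **kw) -> SimConfig:
    """3-chromosome configuration for fast unit tests."""
    defaults = dict(
        n_chrom=3,
        n_markers=150,
        chimera_count=1,
        seed=seed,
        distortion_loci=[DistortionLocus(0, 0.3, 0.5, 1.0, 1.0)],
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_world():
    """Simulated 3-chromosome world: genome, scaffolds, truth, variants,
    panel and genotypes (no sequences realized)."""
    from anchorforge import simulate as sim
    from anchorforge.snp_selection import select_panel

    cfg = small_sim_config()
    genome = sim.simulate_genome(cfg)
    scaffolds, truth = sim.fragment_into_scaffolds(genome, cfg)
    variants = sim.generate_variants(scaffolds, cfg)
    panel = select_panel(scaffolds, variants, panel_size=cfg.n_markers)
    mt = marker_truth(panel, truth, genome)
    data = sim.simulate_f2(genome, mt, cfg)
    return {"config": cfg, "genome": genome, "scaffolds": scaffolds,
            "truth": truth, "variants": variants, "panel": panel,
            "marker_truth": mt, "genotypes": data}


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full-pipeline run at the default study conditions (12
    chromosomes, 580-SNP panel, 139 F2 individuals), shared by the
    end-to-end tests."""
    outdir = tmp_path_factory.mktemp("default_run")
    res = run_pipeline(PipelineConfig(), outdir, seed=1)
    res["outdir"] = outdir
    res["marker_truth"] = marker_truth(res["panel"], res["truth"],
                                       res["genome"])
    _, res["group_to_chrom"] = group_purity(res["map"], res["marker_truth"])
    return res


def simulate_f2_pair(r: float, n: int, rng: np.random.Generator) -> tuple:
    """Direct two-locus F2 simulation at true recombination fraction r:
    each individual is the sum of two gametes, each gamete recombinant
    with probability r. Independent of the pipeline's meiosis code."""
    a1 = rng.integers(0, 2, size=n)
    rec1 = rng.random(n) < r
    b1 = np.where(rec1, 1 - a1, a1)
    a2 = rng.integers(0, 2, size=n)
    rec2 = rng.random(n) < r
    b2 = np.where(rec2, 1 - a2, a2)
    return (a1 + a2).astype(np.int8), (b1 + b2).astype(np.int8)
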
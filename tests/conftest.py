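import numpy as np
import pytest

from lumoscall import caller, panel as panel_mod
from lumoscall.formats_io import Config
from lumoscall.simulate import SegmentSpec, synthesize_cohort


@pytest.fixture(scope="session")
def cohort_k1():
    """Single-clone tumor (f=0.7) with a diploid and a one-copy-loss segment."""
    return synthesize_cohort([0.7], [SegmentSpec(120), SegmentSpec(80, 0, 1, 0)],
                             n_hets=150, n_somatics=40, mean_coverage=600,
                             seed=3)


@pytest.fixture(scope="session")
def cohort_k2():
    """Two-clone tumor (f=0.6/0.3) with loss and gain segments."""
    return synthesize_cohort(
        [0.6, 0.3],
        [SegmentSpec(150), SegmentSpec(80, 0, 1, 0), SegmentSpec(80, 1, 3, 1)],
        n_hets=250, n_somatics=60, mean_coverage=600, seed=5)


@pytest.fixture(scope="session")
def cohort_e2e():
    """Cohort for end-to-end calling: hets (incl. private), somatics in two
    clones, and artifact sites."""
    return synthesize_cohort([0.6, 0.3], [SegmentSpec(120), SegmentSpec(80, 0, 1, 0)],
                             n_hets=150, n_somatics=40, n_artifacts=30,
                             mean_coverage=600, seed=7)


@pytest.fixture(scope="session")
def e2e_panel(cohort_e2e):
    cfg = Config()
    cols = ["chrom", "start", "end", "control_0", "control_1"]
    return panel_mod.build_panel(cohort_e2e.control_sites,
                                 cohort_e2e.exon_depths[cols],
                                 cohort_e2e.priors, pi_u=cfg.pi_U)


@pytest.fixture(scope="session")
def e2e_run(cohort_e2e, e2e_panel):
    """One full caller pass over the end-to-end cohort (records, model,
    segments, report)."""
    cfg = Config(K=2)
    return caller.run_caller(cohort_e2e.tumor_sites, cohort_e2e.exon_depths,
                             cohort_e2e.priors, e2e_panel, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
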
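"""Shared fixtures: simulated families reused across the suite.

All randomness is seeded; session scope keeps the expensive simulations
(19-chromosome family, clustering pipelines) to a single run each.
"""

import warnings

import numpy as np
import pytest

from gbslink import identify_pt_markers, run_synteny_pipeline
from gbslink.denovo import build_denovo_lgs, sweep_and_select
from gbslink.simulate import SimConfig, simulate_gbs_family


@pytest.fixture(scope="session")
def family6():
    """Default study conditions: 19 chromosomes, 200 progeny, depth 6."""
    cfg = SimConfig(seed=11)
    calls, truth_mat, truth = simulate_gbs_family(cfg)
    return {"config": cfg, "calls": calls, "truth_mat": truth_mat, "truth": truth}


@pytest.fixture(scope="session")
def pt6(family6):
    retained, binary, audit, progenitors = identify_pt_markers(family6["calls"])
    return {"retained": retained, "binary": binary, "audit": audit,
            "progenitors": progenitors}


@pytest.fixture(scope="session")
def synteny6(pt6):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_synteny_pipeline(pt6["binary"])


@pytest.fixture(scope="session")
def denovo6(pt6):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sweep = sweep_and_select(pt6["binary"])
        result = build_denovo_lgs(pt6["binary"], sweep)
    return {"sweep": sweep, "result": result}


@pytest.fixture(scope="session")
def small_family8():
    """Ordering/curation conditions: 3 chromosomes, depth 8, 200 progeny."""
    cfg = SimConfig(seed=21, n_chrom=3, n_pt_female=50, n_pt_male=50,
                    n_nonpt=5, mean_depth=8.0)
    calls, truth_mat, truth = simulate_gbs_family(cfg)
    retained, binary, audit, progenitors = identify_pt_markers(calls)
    return {"config": cfg, "calls": calls, "truth": truth, "binary": binary,
            "retained": retained, "progenitors": progenitors}


def true_phase_rows(truth, site_ids):
    return truth.true_phase_rows(site_ids)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
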
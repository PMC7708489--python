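import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import specklemix as sm


def match_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Best-matching cosine similarities between columns of A and B (Hungarian)."""
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / (np.linalg.norm(B, axis=0, keepdims=True) + 1e-15)
    C = An.T @ Bn
    ri, ci = linear_sum_assignment(-C)
    return C[ri, ci]


@pytest.fixture(scope="session")
def small_sim():
    """Noiseless 5-emitter acquisition with ground truth, shared across tests."""
    cfg = sm.SimulationConfig(
        n_targets=5,
        n_slm=64,
        grid_shape=(48, 48),
        n_patterns=768,
        me_range=6.0,
        seed=11,
    )
    emitters = sm.random_emitters(
        cfg.grid_shape, cfg.n_targets, min_sep=12, rng=np.random.default_rng(2)
    )
    patterns = sm.generate_random_patterns(cfg.n_slm, cfg.n_patterns, cfg.seed)
    field_tm = sm.make_field_tm(cfg, emitters)
    intensity_tm = sm.make_intensity_tm(cfg, emitters)
    stack = sm.simulate_acquisition(field_tm, intensity_tm, patterns, cfg)
    return {
        "config": cfg,
        "emitters": emitters,
        "patterns": patterns,
        "field_tm": field_tm,
        "intensity_tm": intensity_tm,
        "stack": stack,
    }


@pytest.fixture(scope="session")
def small_factorization(small_sim):
    """Rank-5 NMF of the noiseless 5-emitter stack."""
    result = sm.nmf_factorize(
        small_sim["stack"],
        sm.FactorizationConfig(rank=5, n_iter_max=500, tol=1e-9, n_restarts=3, init_seed=1),
    )
    return result
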
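import numpy as np
import pandas as pd
import pytest

import sqindex as sq
from sqindex.reference import (
    DEFAULT_SITES,
    EXAMPLE_EIGENVALUES,
    EXAMPLE_LOADINGS,
    example_redundancy_correlations,
)
from sqindex.synthetic_trial import TrialDesign, default_design, default_effects, generate_trial


def charpoly_eigenvalues(A: np.ndarray) -> np.ndarray:
    """Eigenvalues via the Faddeev–LeVerrier characteristic polynomial and
    polynomial root finding — independent of the symmetric eigensolver path."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    coeffs = [1.0]
    M = np.zeros_like(A)
    c = 1.0
    for k in range(1, n + 1):
        M = A @ M + c * np.eye(n)
        c = -np.trace(A @ M) / k
        coeffs.append(c)
    roots = np.roots(coeffs)
    return np.sort(roots.real)[::-1]


def random_correlation_matrix(rng: np.random.Generator, p: int, n: int = 60) -> pd.DataFrame:
    """Full-rank sample correlation matrix of random normal data."""
    X = rng.standard_normal((n, p))
    names = [f"x{j}" for j in range(p)]
    return pd.DataFrame(np.corrcoef(X.T), index=names, columns=names)


@pytest.fixture(scope="session")
def trial_df() -> pd.DataFrame:
    """One seeded default trial: 6 sites x 4 treatments x 3 reps x 3 yr x 2 seasons."""
    samples = generate_trial(default_design(), default_effects())
    return sq.samples_to_frame(samples)


@pytest.fixture(scope="session")
def study_selection():
    """MDS selection resolved from the worked-example loading matrix."""
    retained = sq.retain_components(EXAMPLE_EIGENVALUES)
    cands = sq.candidate_indicators(EXAMPLE_LOADINGS, retained)
    weights = sq.indicator_weights(EXAMPLE_LOADINGS, EXAMPLE_EIGENVALUES, retained)
    return sq.prune_redundant(cands, example_redundancy_correlations(),
                              weights, EXAMPLE_LOADINGS)


@pytest.fixture(scope="session")
def noise_free_samples():
    """Deterministic-limit trial: cv=0, latent factors off, point deltas."""
    effects = sq.EffectConfig(
        deltas={
            "control": {},
            "NPK": {"som": (0.08, 0.08), "an": (0.10, 0.10)},
            "30%M": {"bd": (-0.10, -0.10), "som": (0.20, 0.20), "an": (0.30, 0.30),
                     "yield": (1.00, 1.00)},
        },
        cv=0.0,
        yield_cv={},
    )
    design = TrialDesign(sites=DEFAULT_SITES, treatments=("control", "NPK", "30%M"),
                         n_replicates=2, years=(2021,), seed=7)
    return generate_trial(design, effects), effects
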
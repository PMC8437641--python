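import numpy as np
import pytest

from cscrseg import (PhantomSpec, RunConfig, generate_phantom, phantom_batch,
                     roi_covering_blobs)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec phantom shared across tests."""
    return generate_phantom(PhantomSpec(rng_seed=0))


@pytest.fixture(scope="session")
def default_box(default_phantom):
    pair, truth = default_phantom
    return roi_covering_blobs(truth, pair.shape)


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced phantom whose ROI stays cheap to decompose."""
    spec = PhantomSpec(height=288, width=288, n_vessels=3,
                       macular_radius_px=40, rng_seed=5)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def acceptance_batch():
    """The seeded phantom batch used by the end-to-end performance tests."""
    return phantom_batch(20, PhantomSpec(rng_seed=2024))


@pytest.fixture(scope="session")
def ablation_table(acceptance_batch):
    """Ablation of all four variants over the five-threshold grid."""
    from cscrseg import ablation_study

    return ablation_study(acceptance_batch,
                          T_grid=(0.10, 0.12, 0.14, 0.16, 0.18),
                          config=RunConfig())


def ista_reference(M, lam, mu, tol=1e-12, max_iter=60000):
    """Unaccelerated proximal gradient on the same relaxed objective,
    run to stagnation. Independent of the accelerated solver it checks."""
    from cscrseg import singular_value_threshold, soft_threshold

    M = np.asarray(M, float)
    L = np.zeros_like(M)
    S = np.zeros_like(M)
    scale = max(1.0, np.linalg.norm(M))
    for _ in range(max_iter):
        R = 0.5 * (L + S - M)
        L_new = singular_value_threshold(L - R, mu / 2.0)
        S_new = soft_threshold(S - R, lam * mu / 2.0)
        step = max(np.linalg.norm(L_new - L), np.linalg.norm(S_new - S))
        L, S = L_new, S_new
        if step < tol * scale:
            break
    return L, S


def flood_fill_oracle(I, seed_pos, seed_value, T):
    """Exhaustive region-growing oracle: label the admissible set with
    8-connectivity and keep the component containing the seed."""
    from scipy import ndimage

    admissible = np.abs(I - seed_value) <= T
    labeled, _ = ndimage.label(admissible, structure=np.ones((3, 3), bool))
    lab = labeled[seed_pos]
    if lab == 0:
        out = np.zeros(I.shape, dtype=bool)
        out[seed_pos] = True
        return out
    return labeled == lab
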
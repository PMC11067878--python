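import numpy as np
import pytest

import sagarep as sr


@pytest.fixture(scope="session")
def toy_genome():
    """10 bins of 200 bp on one chromosome."""
    return sr.bin_genome({"chr1": 2000}, 200)


@pytest.fixture(scope="session")
def toy_pair(toy_genome):
    """Hand-checkable two-annotation pair (3 state ids; state 0 unused).

    base  = [1,1,1,1,1,2,2,2,2,2]
    verif = [1,1,1,2,2,2,2,2,2,2]
    joint = [[0,0,0],[0,.3,.2],[0,0,.5]]
    """
    base = sr.Annotation(toy_genome, np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]), K=3)
    verif = sr.Annotation(toy_genome, np.array([1, 1, 1, 2, 2, 2, 2, 2, 2, 2]), K=3)
    return base, verif


@pytest.fixture(scope="session")
def small_synthetic():
    """Deterministic synthetic replicate pair used across modules."""
    cfg = sr.GeneratorConfig(G=5000, K=6, flip_prob=0.2, mean_segment_len=12, seed=42)
    return sr.generate_pair(cfg, w=0)


def random_annotation(genome, K, seed, with_posterior=False, missing_frac=0.0):
    """Uniform-random annotation, optionally with random normalized posteriors."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(K, size=genome.G)
    if missing_frac:
        labels[rng.random(genome.G) < missing_frac] = -1
    post = None
    if with_posterior:
        post = rng.dirichlet(np.ones(K), size=genome.G)
        post[labels < 0] = 0.0
        return sr.Annotation(genome, labels, post, K=K)
    return sr.Annotation(genome, labels, K=K)
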
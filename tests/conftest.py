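import numpy as np
import pytest

from fadspath import sem, synthetic


@pytest.fixture(scope="session")
def ara_cohort_small():
    """Seeded n=2000 cohort from the ARA-model generating values."""
    config = synthetic.default_config(model="2a", n_subjects=2000, seed=1234)
    cohort, ledger = synthetic.generate_cohort(config)
    return cohort, ledger


@pytest.fixture(scope="session")
def chain_fit():
    """A fitted well-specified three-edge chain model at n=10000."""
    paths = {("SNP", "ARA"): -0.24, ("ARA", "BMI"): 0.2, ("BMI", "SBP"): 0.28}
    config = synthetic.SyntheticConfig(
        n_subjects=10_000, maf=0.29, std_paths=paths, seed=77
    )
    cohort, _ = synthetic.generate_cohort(config)
    spec = sem.PathModelSpec(
        variables=("SNP", "ARA", "BMI", "SBP"),
        edges=(("SNP", "ARA"), ("ARA", "BMI"), ("BMI", "SBP")),
    )
    return sem.fit(spec, cohort), cohort


def random_recursive_model(rng, n_vars=None):
    """Random recursive path model + generating config, for oracle tests."""
    n_vars = n_vars or rng.integers(3, 7)
    names = [f"x{i}" for i in range(n_vars)]
    edges = []
    paths = {}
    for j in range(1, n_vars):
        parents = [i for i in range(j) if rng.random() < 0.5]
        for i in parents:
            edges.append((names[i], names[j]))
    if not edges:  # ensure at least one edge
        edges.append((names[0], names[1]))
    # coefficients scaled to keep each equation's R^2 < 1
    for _, t in edges:
        pass
    by_target = {}
    for s, t in edges:
        by_target.setdefault(t, []).append(s)
    for t, parents in by_target.items():
        coefs = rng.uniform(-0.9, 0.9, size=len(parents)) / max(len(parents), 1)
        for s, c in zip(parents, coefs):
            paths[(s, t)] = float(c)
    spec = sem.PathModelSpec(variables=tuple(names), edges=tuple(paths.keys()))
    # unit marginals so isolated variables are still drawn into the cohort
    marginals = {v: (0.0, 1.0) for v in names}
    return spec, paths, marginals
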
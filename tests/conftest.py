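import numpy as np
import pytest

from tcassign import lda, synthetic


@pytest.fixture(scope="session")
def protein():
    """A well-separated 239-residue synthetic protein (default config)."""
    return synthetic.sample_protein(synthetic.GeneratorConfig(length=239), seed=11)


@pytest.fixture(scope="session")
def benchmark(protein):
    return synthetic.make_benchmark(protein, train_fraction=0.65, seed=11)


@pytest.fixture(scope="session")
def cache(benchmark):
    with np.errstate(all="ignore"):
        return lda.fit_subset_family(benchmark.train, "v")


def random_training_systems(rng, features, n_classes, n_per_class, spread=3.0):
    """Random labeled spin systems over the given feature ids."""
    from tcassign.spinsys import SpinSystem

    classes = list("ACDEFHIKLMNQRSTVWY")[:n_classes]
    systems = []
    for c in classes:
        mu = rng.normal(0.0, spread, size=len(features))
        for i in range(n_per_class):
            vec = mu + rng.normal(0.0, 1.0, size=len(features))
            shifts = {f: v for f, v in zip(features, vec) if not f.startswith("TC")}
            tcs = {f: v for f, v in zip(features, vec) if f.startswith("TC")}
            systems.append(
                SpinSystem(id=f"{c}{i}", res_type=c, res_num=None, shifts=shifts, tcs=tcs)
            )
    return systems, classes
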
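import numpy as np
import pytest

from geneage import Timeline, default_timeline


@pytest.fixture(scope="session")
def tl16() -> Timeline:
    """The default 16-taxon human-lineage timeline."""
    return default_timeline()


@pytest.fixture()
def tl3() -> Timeline:
    return Timeline(taxa=("A", "B", "C"), ages=(100.0, 50.0, 0.0))


@pytest.fixture()
def tl4_adjacent() -> Timeline:
    """Small timeline with the 910/797 Ma breakpoints adjacent."""
    return Timeline(taxa=("W", "X", "Y", "Z"), ages=(1500.0, 910.0, 797.0, 0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_distribution(rng, k: int, n: int, name: str = "cls"):
    """Random age distribution over k taxa with all-positive dirichlet weights."""
    from geneage.distributions import from_counts
    from geneage import Timeline

    ages = tuple(float(a) for a in np.sort(rng.uniform(1, 4000, size=k))[::-1])
    tl = Timeline(taxa=tuple(f"t{i}" for i in range(k)), ages=ages, root_age=4200.0)
    counts = rng.multinomial(n, rng.dirichlet(np.ones(k)))
    while counts.sum() == 0:  # pragma: no cover
        counts = rng.multinomial(n, rng.dirichlet(np.ones(k)))
    return from_counts(name, counts, tl), tl
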
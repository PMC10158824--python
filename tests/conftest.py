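import numpy as np
import pytest

from domfact import synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """One planted event of every class across 3 species."""
    cfg = synthetic.FixtureConfig(seed=101, n_species=3, n_pairs_per_species=5)
    return synthetic.generate(cfg)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Ten planted events per class, enough for precision/recall estimates."""
    cfg = synthetic.FixtureConfig(
        seed=2023,
        n_species=5,
        n_pairs_per_species=22,
        events_per_class={c: 10 for c in synthetic.PLANT_CLASSES},
    )
    return synthetic.generate(cfg)


def ultrametric_caterpillar(labels, depth, rng):
    """Ultrametric ladder tree; the last label is the most nested tip.

    Split times sit on a 0.01 grid so printed branch lengths are exact and
    every tip is at the same height; patristic distances to the last tip
    still vary, which keeps a distance covariate informative.
    """
    n = len(labels)
    grid = np.arange(0.05, 0.86, 0.01)
    u = np.sort(rng.choice(grid, size=n - 2, replace=False))
    u = np.concatenate([[0.0], u])

    def clade(i):
        if i == n - 1:
            return (
                f"({labels[n - 2]}:{depth - u[n - 2]:.6f},"
                f"{labels[n - 1]}:{depth - u[n - 2]:.6f})"
            )
        return (
            f"({labels[i - 1]}:{depth - u[i - 1]:.6f},"
            f"{clade(i + 1)}:{u[i] - u[i - 1]:.6f})"
        )

    return clade(1) + ";"


@pytest.fixture(scope="session")
def pgls_setup():
    """16 study tips plus a nested reference on an ultrametric ladder."""
    from domfact import stats

    rng = np.random.default_rng(2024)
    labels = [f"T{i:02d}" for i in range(16)] + ["REF"]
    tree = stats.load_tree(ultrametric_caterpillar(labels, 1.0, rng))
    dist = stats.patristic_distances(tree, "REF")
    species = dist.species
    x = np.array([dist.distance_to_ref[s] for s in species])
    V = stats.phylo_vcv(tree, species)
    return dist, species, x, V
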
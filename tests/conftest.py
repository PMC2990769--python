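import numpy as np
import pytest

from circapal.data_io import (
    ExpressionMatrix,
    PathwayGeneSet,
    PathwayExpressionMatrix,
    TimeDesign,
    rat_liver_design,
)


@pytest.fixture(scope="session")
def design54() -> TimeDesign:
    """The 18-time-point x 3-replicate (54-sample) study design."""
    return rat_liver_design()


@pytest.fixture
def small_design() -> TimeDesign:
    """A compact 6-time-point x 2-replicate design for cheap tests."""
    return TimeDesign((0.0, 4.0, 8.0, 12.0, 16.0, 20.0), replicates_per_time=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231115)


def make_pathway_matrix(values, design, name="P", gene_ids=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    pw = PathwayGeneSet(name, "test", frozenset(gene_ids))
    return PathwayExpressionMatrix(pw, list(gene_ids), values, design)


@pytest.fixture
def gaussian_expr(design54, rng) -> ExpressionMatrix:
    """An i.i.d. Gaussian background matrix (no structure)."""
    values = rng.normal(size=(400, design54.n_samples))
    return ExpressionMatrix(
        [f"g{i}" for i in range(400)], values, design54
    )


def planted_study(design, seed=2024):
    """A 300-gene matrix with 5 planted circadian pathways and 5 noise
    pathways (15 genes each), plus unassigned background genes.

    Planted pathways carry a coherent cosine (amplitude 300, phases in two
    well-separated groups) under uniform noise; noise pathways and the
    background are pure uniform noise of the same scale.  Returns
    ``(ExpressionMatrix, PathwayCollection, planted_names, noise_names)``.
    """
    from circapal.data_io import PathwayCollection

    rng = np.random.default_rng(seed)
    t = design.sample_times()
    omega = 2 * np.pi / 24
    phases = [0.0, 0.15, 0.3, 2.2, 2.35]   # two phase groups: 3 + 2
    n_per = 15
    rows, gene_ids = [], []
    pathways, planted, noisy = [], [], []
    for p, phase in enumerate(phases):
        ids = [f"circ{p}_{g}" for g in range(n_per)]
        for gid in ids:
            rows.append(300.0 * np.cos(omega * t + phase)
                        + rng.uniform(0, 250, size=t.size))
        gene_ids += ids
        name = f"PLANTED_{p}"
        planted.append(name)
        pathways.append(PathwayGeneSet(name, "planted circadian",
                                       frozenset(ids)))
    for p in range(5):
        ids = [f"noise{p}_{g}" for g in range(n_per)]
        for gid in ids:
            rows.append(rng.uniform(0, 250, size=t.size))
        gene_ids += ids
        name = f"NOISE_{p}"
        noisy.append(name)
        pathways.append(PathwayGeneSet(name, "pure noise", frozenset(ids)))
    for g in range(150):
        gene_ids.append(f"bg{g}")
        rows.append(rng.uniform(0, 250, size=t.size))
    expr = ExpressionMatrix(gene_ids, np.array(rows), design)
    return expr, PathwayCollection(pathways), planted, noisy
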
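import numpy as np
import pytest

from gpcnet.hierarchy import EdgeList, HierarchyMap, build_hierarchy
from gpcnet.network import init_params
from gpcnet.synthetic import GeneratorSpec, generate_cohort, generate_hierarchy


def random_hierarchy(rng: np.random.Generator, g: int, p: int, c: int) -> HierarchyMap:
    """Small random hierarchy where every pathway/compound has a parent."""
    mask_gp = rng.random((g, p)) < 0.5
    for j in range(p):
        if not mask_gp[:, j].any():
            mask_gp[rng.integers(g), j] = True
    mask_pc = rng.random((p, c)) < 0.5
    for k in range(c):
        if not mask_pc[:, k].any():
            mask_pc[rng.integers(p), k] = True
    genes = [f"G{i:03d}" for i in range(g)]
    pathways = [f"P{i:03d}" for i in range(p)]
    gp = EdgeList()
    for j, pw in enumerate(pathways):
        gp.groups[pw] = [genes[i] for i in np.flatnonzero(mask_gp[:, j])]
    pc = EdgeList()
    for j, pw in enumerate(pathways):
        pc.groups[pw] = [f"C{k:03d}" for k in np.flatnonzero(mask_pc[j, :])]
    return build_hierarchy(gp, pc, genes)


@pytest.fixture
def tiny_hierarchy() -> HierarchyMap:
    """3 genes, 2 pathways, 2 compounds, hand-wired."""
    gp = EdgeList()
    gp.groups = {"P1": ["A", "B"], "P2": ["B", "X"]}
    pc = EdgeList()
    pc.groups = {"P1": ["C1"], "P2": ["C1", "C2"]}
    return build_hierarchy(gp, pc, ["A", "B", "X"])


@pytest.fixture
def toy_params(tiny_hierarchy):
    return init_params(tiny_hierarchy, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-signal cohort small enough for fast training in unit tests."""
    spec = GeneratorSpec(G=40, P=6, C=10, n=400, n_drivers=3,
                         effect_size=3.0, seed=11)
    h = generate_hierarchy(spec)
    x, y, truth = generate_cohort(h, spec)
    return h, x, y, truth, spec
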
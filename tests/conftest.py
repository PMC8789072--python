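import numpy as np
import pytest

from hieranno.config import RunConfig
from hieranno.engine import run_multires
from hieranno.reference import ReferenceTree, propagate_markers
from hieranno.simulate import SimulationSpec, simulate, toy_hematopoietic_tree


def build_tree(structure: dict, markers: dict) -> ReferenceTree:
    """Tree from {name: subtree} nesting with explicit marker sets."""
    tree = ReferenceTree()

    def visit(sub, prefix):
        for name, children in sub.items():
            path = prefix + [name]
            tree.add_path(path, markers.get(name, set()))
            if children:
                visit(children, path)

    visit(structure, [])
    return propagate_markers(tree)


def random_tree(rng: np.random.Generator, max_children: int = 3, max_depth: int = 3):
    """A random rooted marker tree over a small shared gene pool."""
    pool = [f"G{i:03d}" for i in range(40)]
    counter = [0]
    tree = ReferenceTree()

    def grow(prefix, depth):
        for _ in range(rng.integers(1, max_children + 1)):
            counter[0] += 1
            name = f"type{counter[0]:03d}"
            path = prefix + [name]
            genes = set(rng.choice(pool, size=rng.integers(1, 6), replace=False))
            tree.add_path(path, genes)
            if depth < max_depth and rng.random() < 0.5:
                grow(path, depth + 1)

    grow([], 1)
    return propagate_markers(tree)


@pytest.fixture(scope="session")
def toy_tree():
    return toy_hematopoietic_tree()


@pytest.fixture(scope="session")
def small_sim(toy_tree):
    spec = SimulationSpec(tree=toy_tree, cells_per_leaf=60, seed=11)
    return simulate(spec)


@pytest.fixture(scope="session")
def small_run(toy_tree, small_sim):
    counts, truth = small_sim
    table = run_multires(counts, toy_tree, RunConfig())
    return table, truth
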
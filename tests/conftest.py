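"""Shared fixtures: small hand-built trees and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

import phylogeo_gec as pg


@pytest.fixture
def simple_tree() -> pg.TimedTree:
    """((A:1,B:1):2,C:3); — ultrametric, root age 3."""
    return pg.TimedTree.from_newick("((A:1,B:1):2,C:3);")


@pytest.fixture
def regions_ab_wlc() -> pg.TipRegionMap:
    return pg.TipRegionMap({"A": "WLC", "B": "WLC", "C": "PAP"})


@pytest.fixture
def small_dataset() -> pg.SyntheticDataset:
    """20-tip coalescent dataset with a 30-tree emulated posterior."""
    cfg = pg.SimulationConfig(n_tips=20, n_posterior=30, seed=11)
    return pg.make_dataset(cfg)


def random_timed_tree(rng: np.random.Generator, n_tips: int) -> pg.TimedTree:
    """A random coalescent-shaped tree for oracle comparisons."""
    cfg = pg.SimulationConfig(n_tips=n_tips, seed=int(rng.integers(2**31 - 1)),
                              n_posterior=1)
    return pg.simulate_tree(cfg)


def random_regions(rng: np.random.Generator, tree: pg.TimedTree,
                   states=pg.DEFAULT_STATES) -> pg.TipRegionMap:
    labels = sorted(tree.tip_labels)
    mapping = {t: states[rng.integers(len(states))] for t in labels}
    return pg.TipRegionMap(mapping, tuple(states))


def random_generator_matrix(rng: np.random.Generator, k: int = 3,
                            scale: float = 1.0) -> np.ndarray:
    """A random valid CTMC generator with off-diagonal rates ~ U(0, scale)."""
    q = rng.uniform(0.0, scale, size=(k, k))
    np.fill_diagonal(q, 0.0)
    q[np.diag_indices(k)] = -q.sum(axis=1)
    return q
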
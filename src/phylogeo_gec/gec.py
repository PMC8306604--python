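"""Geographically exclusive clade (GEC) extraction from posterior tree sets.

A GEC is a monophyletic group of >= 2 samples whose tips all come from one
geographic region.  For every posterior tree we find, for each sample, the
largest region-pure clade containing it; candidates are pooled across trees,
filtered to those monophyletic in more than a threshold fraction of the
posterior (majority support by default), and their MRCA ages collected as
TMRCA samples.  The retained clades are pairwise tip-disjoint, making their
TMRCAs independent with respect to the samples they contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treeio import PosteriorTreeSet, TimedTree, TipRegionMap

#: A clade's identity across trees: the frozen set of its tip labels.
CladeKey = frozenset


@dataclass
class GEClade:
    """A retained geographically exclusive clade with its TMRCA samples."""

    key: CladeKey
    region: str
    support: float
    tmrca_samples: list[float] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.key)

    @property
    def median_tmrca(self) -> float:
        return float(np.median(self.tmrca_samples))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GEClade({self.region}, n={self.size}, support={self.support:.3f}, "
            f"median_tmrca={self.median_tmrca:.4g})"
        )


def exclusive_clades(tree: TimedTree, regions: TipRegionMap) -> set[tuple[CladeKey, str]]:
    """All monophyletic >= 2-tip clades whose tips share one region.

    Nested exclusive clades are all returned; maximality is applied later by
    :func:`largest_gec_per_sample`.
    """
    regions.check_total(tree.tip_labels)
    out: set[tuple[CladeKey, str]] = set()
    for node, tipset in enumerate(tree.clade_tip_sets):
        if len(tipset) >= 2 and tree.children[node]:
            region = regions.region_of(tipset)
            if region is not None:
                out.add((tipset, region))
    return out


def largest_gec_per_sample(tree: TimedTree, regions: TipRegionMap) -> set[tuple[CladeKey, str]]:
    """For each sample, the largest region-pure clade containing it.

    The result is the set of *maximal* exclusive clades: region-pure nodes
    with >= 2 tips whose parent subtree is no longer pure.  Maximal clades
    are pairwise disjoint; samples in no exclusive clade are dropped.
    """
    regions.check_total(tree.tip_labels)
    sets = tree.clade_tip_sets
    pure = [
        regions.region_of(sets[i]) if tree.children[i] or len(sets[i]) == 1 else None
        for i in range(tree.n_nodes)
    ]
    out: set[tuple[CladeKey, str]] = set()
    for i in range(tree.n_nodes):
        if not tree.children[i] or len(sets[i]) < 2 or pure[i] is None:
            continue
        p = int(tree.parent[i])
        if p < 0 or pure[p] is None:
            out.add((sets[i], pure[i]))
    return out


def clade_support(key: CladeKey, tree_set: PosteriorTreeSet) -> float:
    """Fraction of posterior trees in which ``key`` is monophyletic."""
    if not key <= tree_set.tip_universe:
        raise KeyError(f"clade tips outside tree universe: {sorted(key - tree_set.tip_universe)}")
    hits = sum(1 for t in tree_set if t.is_monophyletic(key))
    return hits / len(tree_set)


def extract_gecs(
    tree_set: PosteriorTreeSet,
    regions: TipRegionMap,
    support_threshold: float = 0.5,
) -> list[GEClade]:
    """Extract majority-supported, tip-disjoint GECs with TMRCA samples.

    Candidates are the union over posterior trees of each tree's maximal
    region-pure clades.  A candidate is retained when monophyletic in more
    than ``support_threshold`` of the trees; its TMRCA samples are the MRCA
    ages in exactly those trees.  Overlapping survivors (possible only at
    generalised thresholds) are resolved deterministically: higher support,
    then larger size, then older median TMRCA, then lexicographic key.

    Returned clades are sorted by region then descending median TMRCA.
    """
    if not 0.5 <= support_threshold < 1:
        raise ValueError("support_threshold must lie in [0.5, 1)")
    regions.check_total(tree_set.tip_universe)
    n = len(tree_set)

    candidates: dict[CladeKey, str] = {}
    for tree in tree_set:
        for key, region in largest_gec_per_sample(tree, regions):
            candidates[key] = region

    kept: list[GEClade] = []
    for key, region in candidates.items():
        samples = []
        for tree in tree_set:
            node = tree.mrca(key)
            if tree.clade_tip_sets[node] == key:
                samples.append(float(tree.node_ages()[node]))
        support = len(samples) / n
        if support > support_threshold:
            kept.append(GEClade(key=key, region=region, support=support, tmrca_samples=samples))

    # resolve any tip overlaps deterministically
    kept.sort(
        key=lambda c: (-c.support, -c.size, -c.median_tmrca, tuple(sorted(c.key)))
    )
    claimed: set[str] = set()
    final: list[GEClade] = []
    for clade in kept:
        if clade.key.isdisjoint(claimed):
            final.append(clade)
            claimed |= clade.key
    final.sort(key=lambda c: (c.region, -c.median_tmrca, tuple(sorted(c.key))))
    return final
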
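"""Tree and table I/O, the time axis, and consensus-tree construction.

This module owns the package's tree containers and everything needed to get
posterior samples of time-calibrated trees in and out of them: NEXUS/Newick
parsing (BEAST dialect, translate blocks, bracketed metadata comments),
node-age computation in years before present (yBP), the maximum clade
credibility (MCC) consensus with common-ancestor heights, tip-to-region
tables, and simple frequency tabulations.

Age convention
--------------
Ages are measured in years before present, increasing rootward.  The
youngest tip sits at age 0; dated (ancient) tips are offset by their own
age; internal-node ages follow ``age(parent) = age(child) + branch_length``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger("phylogeo_gec")

#: Default region state space: Australia, New Guinea, Wallacea.
DEFAULT_STATES: tuple[str, ...] = ("AUS", "PAP", "WLC")

#: Relative tolerance (fraction of root age) for clock-consistency checks.
ULTRAMETRIC_RTOL = 1e-6


class TreeFormatError(ValueError):
    """Raised for unreadable, unrooted, or otherwise invalid tree input."""


# ---------------------------------------------------------------------------
# TimedTree
# ---------------------------------------------------------------------------

class TimedTree:
    """A rooted tree with branch lengths in years and node ages in yBP.

    Nodes are integer-indexed; ``parent[i]`` is the parent index of node
    ``i`` (``-1`` for the root) and ``lengths[i]`` the length of the branch
    above ``i`` in years (0 for the root).  Tips carry unique string labels.

    Parameters
    ----------
    parent
        Parent index per node, -1 for the single root.
    lengths
        Branch length in years above each node; must be >= 0.
    labels
        Per-node label, ``None`` for unlabelled internal nodes.
    tip_ages
        Optional mapping label -> age in yBP for dated (ancient) tips.
        Tips not listed are taken to sit at age 0.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
        tip_ages: Mapping[str, float] | None = None,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels: tuple[str | None, ...] = tuple(labels)
        self.tip_ages: dict[str, float] = dict(tip_ages or {})
        self._validate()
        self._children: list[list[int]] | None = None
        self._postorder: np.ndarray | None = None
        self._ages: np.ndarray | None = None
        self._tip_sets: list[frozenset[str]] | None = None

    # -- construction checks -------------------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        if n == 0 or len(self.lengths) != n or len(self.labels) != n:
            raise TreeFormatError("parent/lengths/labels sizes disagree")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeFormatError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.lengths < 0):
            raise TreeFormatError("negative branch length")
        if not np.all(np.isfinite(self.lengths)):
            raise TreeFormatError("non-numeric branch length")
        tips = [self.labels[i] for i in range(n) if self._is_tip_index(i)]
        if any(t is None for t in tips):
            raise TreeFormatError("unlabelled tip")
        if len(set(tips)) != len(tips):
            raise TreeFormatError("duplicate tip label")

    def _is_tip_index(self, i: int) -> bool:
        return not np.any(self.parent == i)

    # -- basic topology ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    @property
    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            seen = []
            while stack:
                node = stack.pop()
                seen.append(node)
                stack.extend(self.children[node])
            self._postorder = np.asarray(seen[::-1], dtype=np.int64)
        return self._postorder

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(self.labels[i] for i in self.tip_indices)  # type: ignore[misc]

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths, in years."""
        return float(self.lengths.sum())

    # -- ages ----------------------------------------------------------------

    def node_ages(self, require_clock: bool = False) -> np.ndarray:
        """Node ages in yBP under the tips-at-their-dates convention.

        Internal ages are the mean of ``age(child) + length(child)`` over
        children.  If root-to-tip paths disagree by more than
        ``ULTRAMETRIC_RTOL`` x root age the tree is not clock-like: a
        warning is logged, or an error raised when ``require_clock``.
        """
        if self._ages is not None and not require_clock:
            return self._ages
        ages = np.zeros(self.n_nodes)
        worst = 0.0
        for node in self.postorder:
            kids = self.children[node]
            if not kids:
                label = self.labels[node]
                ages[node] = self.tip_ages.get(label, 0.0)  # type: ignore[arg-type]
            else:
                cand = np.array([ages[k] + self.lengths[k] for k in kids])
                ages[node] = cand.mean()
                worst = max(worst, float(cand.max() - cand.min()))
        root_age = ages[self.root]
        tol = ULTRAMETRIC_RTOL * max(root_age, 1.0)
        if worst > tol:
            msg = (
                f"root-to-tip paths disagree by {worst:.6g} years "
                f"(> {tol:.3g}); tree is not clock-like"
            )
            if require_clock:
                raise TreeFormatError(msg)
            logger.warning(msg)
        self._ages = ages
        return ages

    @property
    def root_age(self) -> float:
        return float(self.node_ages()[self.root])

    # -- clades --------------------------------------------------------------

    @property
    def clade_tip_sets(self) -> list[frozenset[str]]:
        """Per-node frozenset of descendant tip labels."""
        if self._tip_sets is None:
            sets: list[frozenset[str]] = [frozenset()] * self.n_nodes
            for node in self.postorder:
                kids = self.children[node]
                if not kids:
                    sets[node] = frozenset([self.labels[node]])  # type: ignore[list-item]
                else:
                    acc: set[str] = set()
                    for k in kids:
                        acc |= sets[k]
                    sets[node] = frozenset(acc)
            self._tip_sets = sets
        return self._tip_sets

    def mrca(self, labels: Iterable[str]) -> int:
        """Index of the most recent common ancestor of ``labels``."""
        want = frozenset(labels)
        if not want <= self.tip_labels:
            missing = sorted(want - self.tip_labels)
            raise KeyError(f"labels not in tree: {missing}")
        sets = self.clade_tip_sets
        start = next(i for i in self.tip_indices if self.labels[i] in want)
        node = start
        while not want <= sets[node]:
            node = int(self.parent[node])
        return node

    def is_monophyletic(self, labels: Iterable[str]) -> bool:
        want = frozenset(labels)
        return self.clade_tip_sets[self.mrca(want)] == want

    # -- conversion ----------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, tip_ages: Mapping[str, float] | None = None) -> "TimedTree":
        if tree.is_rooted is False:
            raise TreeFormatError("tree is explicitly unrooted")
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        for nd in nodes:
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            edge = nd.edge.length
            if nd.parent_node is None:
                lengths.append(0.0)
            elif edge is None:
                raise TreeFormatError("missing branch length")
            else:
                lengths.append(float(edge))
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeFormatError("unlabelled tip")
                labels.append(str(nd.taxon.label))
            else:
                labels.append(None)
        return cls(parent, lengths, labels, tip_ages)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.is_rooted = True
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                dnodes[p].add_child(dnodes[i])
                dnodes[i].edge.length = float(self.lengths[i])
            if self.labels[i] is not None and not self.children[i]:
                dnodes[i].taxon = tns.require_taxon(label=self.labels[i])
        tree.seed_node = dnodes[self.root]
        return tree

    @classmethod
    def from_newick(cls, newick: str, tip_ages: Mapping[str, float] | None = None) -> "TimedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(tree, tip_ages)

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True,
            real_value_format_specifier=".17g",
        ).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimedTree(n_tips={len(self.tip_indices)}, root_age={self.root_age:.4g})"


# ---------------------------------------------------------------------------
# PosteriorTreeSet
# ---------------------------------------------------------------------------

@dataclass
class PosteriorTreeSet:
    """An ordered collection of :class:`TimedTree` sharing one tip universe."""

    trees: list[TimedTree]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeFormatError("posterior tree set is empty")
        universe = self.trees[0].tip_labels
        for k, t in enumerate(self.trees):
            if t.tip_labels != universe:
                raise TreeFormatError(f"tree {k} has a different tip label set")

    @property
    def tip_universe(self) -> frozenset[str]:
        return self.trees[0].tip_labels

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, k: int) -> TimedTree:
        return self.trees[k]


def _infer_schema(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".nex", ".nexus", ".trees", ".t"}:
        return "nexus"
    if suffix in {".nwk", ".newick", ".tre", ".txt"}:
        return "newick"
    with open(path) as fh:
        head = fh.read(512).lstrip()
    return "nexus" if head.upper().startswith("#NEXUS") else "newick"


def read_tree_set(
    path: str | Path,
    format: str | None = None,
    burnin: float | int = 0,
    tip_ages: Mapping[str, float] | None = None,
) -> PosteriorTreeSet:
    """Read a posterior tree set from NEXUS (BEAST dialect) or Newick.

    Translate blocks are resolved to tip labels and bracketed ``[&...]``
    metadata comments are ignored.  ``burnin`` discards leading trees:
    a fraction in [0, 1) or an absolute count; the default 0 assumes the
    input is already post burn-in.
    """
    path = Path(path)
    if not path.exists():
        raise TreeFormatError(f"no such file: {path}")
    schema = format or _infer_schema(path)
    if schema not in {"nexus", "newick"}:
        raise TreeFormatError(f"unsupported format: {schema}")
    try:
        tree_list = dendropy.TreeList.get(
            path=str(path), schema=schema, rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises many parse error types
        raise TreeFormatError(f"could not parse {path}: {exc}") from exc
    trees = [TimedTree.from_dendropy(t, tip_ages) for t in tree_list]
    if not trees:
        raise TreeFormatError(f"no trees found in {path}")
    n_skip = int(round(burnin * len(trees))) if 0 < burnin < 1 else int(burnin)
    if n_skip >= len(trees):
        raise TreeFormatError(f"burn-in {burnin} discards all {len(trees)} trees")
    trees = trees[n_skip:]
    meta = {"path": str(path), "format": schema, "count": len(trees), "burnin": n_skip}
    return PosteriorTreeSet(trees, metadata=meta)


def write_tree_set(tree_set: PosteriorTreeSet | Iterable[TimedTree], path: str | Path, format: str = "nexus") -> None:
    """Write trees to NEXUS or Newick, preserving branch lengths to full precision."""
    trees = list(tree_set)
    tns = dendropy.TaxonNamespace()
    dlist = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        dlist.append(t.to_dendropy(taxon_namespace=tns))
    dlist.write(path=str(path), schema=format, real_value_format_specifier=".17g")


# ---------------------------------------------------------------------------
# MCC consensus with common-ancestor heights
# ---------------------------------------------------------------------------

def mcc_consensus(tree_set: PosteriorTreeSet) -> TimedTree:
    """Maximum clade credibility tree with common-ancestor node heights.

    The returned topology is the posterior sample maximising the product of
    its clades' posterior frequencies (computed as a log-sum; ties broken by
    file order, earliest first).  Each internal node's age is then replaced
    by the mean, over *all* posterior trees, of the age of the MRCA of that
    node's tip set, and branch lengths are rederived from the ages.
    """
    trees = tree_set.trees
    n = len(trees)
    counts: dict[frozenset[str], int] = {}
    per_tree_clades: list[list[frozenset[str]]] = []
    for t in trees:
        clades = [s for i, s in enumerate(t.clade_tip_sets) if t.children[i]]
        per_tree_clades.append(clades)
        for s in clades:
            counts[s] = counts.get(s, 0) + 1

    best_k, best_score = 0, -math.inf
    for k, clades in enumerate(per_tree_clades):
        score = sum(math.log(counts[s] / n) for s in clades)
        if score > best_score + 1e-12:
            best_k, best_score = k, score
        elif abs(score - best_score) <= 1e-12 and k != best_k:
            logger.info("MCC tie between trees %d and %d; keeping %d", best_k, k, best_k)
    best = trees[best_k]

    # common-ancestor heights: mean MRCA age of each clade's tip set
    mean_age: dict[frozenset[str], float] = {}
    for s in per_tree_clades[best_k]:
        total = 0.0
        for t in trees:
            ages = t.node_ages()
            total += ages[t.mrca(s)]
        mean_age[s] = total / n

    new_ages = np.array(best.node_ages(), copy=True)
    sets = best.clade_tip_sets
    for i in range(best.n_nodes):
        if best.children[i]:
            new_ages[i] = mean_age[sets[i]]
    # rederive lengths; clamp tiny negative lengths that mean heights can create
    lengths = np.zeros(best.n_nodes)
    n_clamped = 0
    for i in range(best.n_nodes):
        p = best.parent[i]
        if p >= 0:
            bl = new_ages[p] - new_ages[i]
            if bl < 0:
                n_clamped += 1
                bl = 0.0
            lengths[i] = bl
    if n_clamped:
        logger.warning("common-ancestor heights produced %d negative branch lengths; clamped to 0", n_clamped)
    out = TimedTree(best.parent, lengths, best.labels, best.tip_ages)
    return out


# ---------------------------------------------------------------------------
# Tip -> region tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TipRegionMap:
    """Total mapping tip label -> region code over a declared state space."""

    mapping: Mapping[str, str]
    states: tuple[str, ...] = DEFAULT_STATES

    def __post_init__(self) -> None:
        bad = {r for r in self.mapping.values() if r not in self.states}
        if bad:
            raise ValueError(f"unknown region code(s) {sorted(bad)}; declared states are {self.states}")
        if len(self.states) < 2 or len(set(self.states)) != len(self.states):
            raise ValueError("state space must hold >= 2 unique codes")

    def __getitem__(self, tip: str) -> str:
        return self.mapping[tip]

    def __len__(self) -> int:
        return len(self.mapping)

    def state_index(self, tip: str) -> int:
        return self.states.index(self.mapping[tip])

    def check_total(self, tips: Iterable[str]) -> None:
        missing = sorted(set(tips) - set(self.mapping))
        if missing:
            raise ValueError(f"tips without a region assignment: {missing}")

    def region_of(self, tips: Iterable[str]) -> str | None:
        """The common region of ``tips``, or None if they span regions."""
        regions = {self.mapping[t] for t in tips}
        return next(iter(regions)) if len(regions) == 1 else None


_HEADER_HINTS = {"tip", "tip_label", "label", "sample", "region", "state", "location"}


def read_region_map(path: str | Path, states: Sequence[str] | None = None) -> TipRegionMap:
    """Read a two-column TSV (tip_label, region); '#' lines are comments.

    A first row whose fields look like column names is treated as a header.
    Region codes must come from ``states`` (default AUS/PAP/WLC); duplicate
    rows are accepted when consistent and rejected when conflicting.
    """
    states = tuple(states) if states is not None else DEFAULT_STATES
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            rows.append((parts[0].strip(), parts[1].strip()))
    if rows and all(f.lower() in _HEADER_HINTS for f in rows[0]):
        rows = rows[1:]
    mapping: dict[str, str] = {}
    for tip, region in rows:
        if region not in states:
            raise ValueError(f"unknown region code {region!r} for tip {tip!r}; declared states are {states}")
        if tip in mapping and mapping[tip] != region:
            raise ValueError(f"conflicting regions for tip {tip!r}: {mapping[tip]} vs {region}")
        mapping[tip] = region
    return TipRegionMap(mapping, states)


def write_region_map(regions: TipRegionMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tip_label\tregion\n")
        for tip in sorted(regions.mapping):
            fh.write(f"{tip}\t{regions.mapping[tip]}\n")


# ---------------------------------------------------------------------------
# Frequency tabulation
# ---------------------------------------------------------------------------

@dataclass
class RegionSummary:
    """Category counts and percentages within a stratum of tips."""

    counts: dict[str, int]
    percent: dict[str, float]
    n: int


def tabulate_frequencies(labels: Mapping[str, str], stratum: Iterable[str] | None = None) -> RegionSummary:
    """Count categories among ``stratum`` tips; percent = 100 * count / n to 0.1.

    ``labels`` maps tip -> category (region, haplogroup, ...).  ``stratum``
    defaults to the whole label domain and must be a subset of it.
    """
    tips = list(labels) if stratum is None else list(stratum)
    if not tips:
        raise ValueError("empty stratum")
    missing = [t for t in tips if t not in labels]
    if missing:
        raise ValueError(f"stratum tips without a label: {sorted(missing)}")
    counts: dict[str, int] = {}
    for t in tips:
        counts[labels[t]] = counts.get(labels[t], 0) + 1
    n = len(tips)
    percent = {c: round(100.0 * k / n, 1) for c, k in counts.items()}
    return RegionSummary(counts=counts, percent=percent, n=n)
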
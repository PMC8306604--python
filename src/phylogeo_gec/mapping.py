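"""Stochastic mapping of migration events and the branch-length correction.

Given a dated tree, tip regions, and a fitted generator Q, stochastic
character mapping draws full transition histories conditional on the tips:
internal node states are sampled from their joint conditional distribution
(upward pruning pass, downward sampling pass), then each branch's path is
sampled conditioned on its endpoint states by uniformization.  Each state
transition is a migration event with a time on the tree.

Because a constant-rate process accrues more events where the tree has more
branch length, raw event counts per time interval are corrected: the
expected count in an interval is the total transition count multiplied by
the fraction of total tree length falling in that interval, and the
corrected value is observed minus expected.  The corrected values sum to
zero over intervals for every ordered state pair, by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import (PruningEngine, RootPrior, _root_prior_weights,
                     ordered_pairs, transition_matrices)
from .treeio import TimedTree, TipRegionMap


@dataclass(frozen=True)
class TransitionEvent:
    """One migration event: a state change at a time point on a branch."""

    time: float       # age, yBP
    branch: int       # child-node index of the branch carrying the event
    from_state: str
    to_state: str


@dataclass
class MappingRealisation:
    """One simulated transition history on the tree."""

    node_states: np.ndarray            # state index per node
    events: list[TransitionEvent]
    states: tuple[str, ...]

    def event_count(self, pair: tuple[str, str] | None = None) -> int:
        if pair is None:
            return len(self.events)
        return sum(1 for e in self.events if (e.from_state, e.to_state) == pair)


@dataclass
class BranchLengthProfile:
    """Total branch length per successive time interval, tips to root."""

    interval: float                    # years
    totals: np.ndarray                 # years per interval, index 0 youngest

    @property
    def n_intervals(self) -> int:
        return len(self.totals)

    @property
    def total_length(self) -> float:
        return float(self.totals.sum())


@dataclass
class TransitionHistogram:
    """Mean event counts per ordered pair in fine reporting bins."""

    bin_width: float
    pairs: list[tuple[str, str]]
    counts: np.ndarray                 # (n_pairs, n_bins), means over realisations


@dataclass
class CorrectedRates:
    """Observed, expected, and corrected event counts per pair and interval."""

    interval: float
    pairs: list[tuple[str, str]]
    observed: np.ndarray               # (n_pairs, n_intervals) means
    expected: np.ndarray
    corrected: np.ndarray
    observed_se: np.ndarray            # Monte-Carlo SE of the observed means


# ---------------------------------------------------------------------------
# Endpoint-conditioned path sampling by uniformization
# ---------------------------------------------------------------------------

_MAX_JUMPS = 10_000


def sample_conditioned_path(a: int, b: int, t: float, Q: np.ndarray,
                            rng: np.random.Generator,
                            P_t: np.ndarray | None = None) -> list[tuple[float, int, int]]:
    """Sample a CTMC path on [0, t] conditioned on X(0)=a, X(t)=b.

    Uniformization with dominating rate Omega = max |Q_ii|: the jump count
    is drawn from its exact conditional distribution, the uniformized jump
    chain is sampled bridge-style, virtual (self) transitions dropped, and
    jump times placed as uniform order statistics.  Returns a list of
    (time-from-branch-start, from_state, to_state).
    """
    k = Q.shape[0]
    omega = float(np.max(-np.diag(Q)))
    if omega <= 0.0:
        if a != b:
            raise ValueError("zero-rate generator cannot connect differing endpoints")
        return []
    if P_t is None:
        P_t = transition_matrices(Q, np.array([t]))[0]
    p_ab = P_t[a, b]
    if p_ab <= 0.0:
        raise ValueError("endpoint pair has zero transition probability")
    R = np.eye(k) + Q / omega
    # conditional number of uniformized jumps
    u = rng.random() * p_ab
    log_pois = -omega * t
    Rpow = [np.eye(k)]
    acc = math.exp(log_pois) * Rpow[0][a, b]
    n = 0
    while acc < u and n < _MAX_JUMPS:
        n += 1
        log_pois += math.log(omega * t) - math.log(n)
        Rpow.append(Rpow[-1] @ R)
        acc += math.exp(log_pois) * Rpow[n][a, b]
    if n == 0:
        return []
    # bridge sampling of the jump chain s_0 = a, ..., s_n = b
    states = [a]
    for m in range(1, n):
        w = R[states[-1], :] * Rpow[n - m][:, b]
        total = w.sum()
        states.append(int(rng.choice(k, p=w / total)))
    states.append(b)
    times = np.sort(rng.random(n)) * t
    events = []
    for tm, s0, s1 in zip(times, states[:-1], states[1:]):
        if s0 != s1:
            events.append((float(tm), s0, s1))
    return events


def simulate_mappings(tree: TimedTree, regions: TipRegionMap, Q: np.ndarray,
                      root_prior: RootPrior = RootPrior("equal"),
                      n: int = 1000, seed: int = 0,
                      states: Sequence[str] | None = None) -> list[MappingRealisation]:
    """Draw ``n`` stochastic-mapping realisations conditional on tip regions.

    Node states come from their joint conditional distribution given tips,
    Q, and the root prior; branch paths are endpoint-conditioned by
    uniformization.  Reproducible under ``seed``.  A tip configuration that
    is impossible under Q (e.g. a zero-constrained rate the data require)
    raises a :class:`ValueError` naming the first impossible branch.
    """
    engine = PruningEngine(tree, regions, states)
    st = engine.states
    Q = np.asarray(Q, dtype=float)
    rng = np.random.default_rng(seed)
    P = transition_matrices(Q, engine.lengths)
    ages = tree.node_ages()
    k = engine.k

    # upward pass once: scaled conditional likelihoods below every node
    down = np.zeros((tree.n_nodes, k))
    for node in engine.postorder:
        kids = engine.children[node]
        if not kids:
            down[node, engine.tip_state[node]] = 1.0
        else:
            acc = np.ones(k)
            for c in kids:
                acc *= P[c] @ down[c]
            top = acc.max()
            if top <= 0.0:
                bad = min(kids)
                raise ValueError(
                    f"tip configuration impossible under Q at branch {bad} "
                    f"(above node {node})"
                )
            down[node] = acc / top
    root = tree.root
    root_w = _root_prior_weights(root_prior, down[root], st) * down[root]
    if root_w.sum() <= 0:
        raise ValueError("tip configuration impossible under Q at the root")
    root_w = root_w / root_w.sum()

    preorder = engine.postorder[::-1]
    out: list[MappingRealisation] = []
    for _ in range(n):
        node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
        node_states[root] = int(rng.choice(k, p=root_w))
        events: list[TransitionEvent] = []
        for node in preorder:
            for c in engine.children[node]:
                i = node_states[node]
                w = P[c][i, :] * down[c]
                total = w.sum()
                if total <= 0:
                    raise ValueError(f"tip configuration impossible under Q at branch {c}")
                j = int(rng.choice(k, p=w / total))
                node_states[c] = j
                t = float(engine.lengths[c])
                if t > 0:
                    path = sample_conditioned_path(i, j, t, Q, rng, P_t=P[c])
                elif i != j:
                    raise ValueError(f"zero-length branch {c} with differing endpoint states")
                else:
                    path = []
                age_parent = float(ages[node])
                for tm, s0, s1 in path:
                    events.append(TransitionEvent(
                        time=age_parent - tm, branch=int(c),
                        from_state=st[s0], to_state=st[s1],
                    ))
        events.sort(key=lambda e: -e.time)
        out.append(MappingRealisation(node_states=node_states, events=events, states=st))
    return out


def three_parameterisations(tree: TimedTree, regions: TipRegionMap,
                            model, fitted_rates: np.ndarray,
                            fixed_state: str = "WLC") -> list[tuple[str, np.ndarray, RootPrior]]:
    """The three mapping parameterisations used per migration model.

    (i) the fitted Q with the empirical (marginal) root state, (ii) an
    internally re-estimated maximum-likelihood Q with an equal root prior,
    and (iii) the fitted Q with the root fixed to ``fixed_state``.
    """
    from .models import ml_rates

    q_fit = model.q_matrix(fitted_rates)
    q_ml = model.q_matrix(ml_rates(tree, regions, model))
    return [
        ("fitted-empirical", q_fit, RootPrior("empirical")),
        ("ml-equal", q_ml, RootPrior("equal")),
        (f"fitted-fixed-{fixed_state}", q_fit, RootPrior("fixed", fixed_state)),
    ]


# ---------------------------------------------------------------------------
# Branch-length profile and the correction
# ---------------------------------------------------------------------------

def branch_length_profile(tree: TimedTree, interval: float = 1000.0) -> BranchLengthProfile:
    """Total branch length per successive time interval from tips to root.

    Intervals are half-open in age, ``[k*w, (k+1)*w)``, anchored at age 0;
    a branch contributes its overlapping length to every interval it spans.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    ages = tree.node_ages()
    n_int = max(int(math.ceil(float(ages.max()) / interval)), 1)
    totals = np.zeros(n_int)
    for c in range(tree.n_nodes):
        p = tree.parent[c]
        if p < 0:
            continue
        lo, hi = float(ages[c]), float(ages[p])
        k0 = int(lo // interval)
        k1 = min(int(math.ceil(hi / interval)), n_int)
        for k in range(k0, k1):
            a, b = k * interval, (k + 1) * interval
            totals[k] += max(0.0, min(hi, b) - max(lo, a))
    return BranchLengthProfile(interval=interval, totals=totals)


def expected_counts(total_transitions: float, profile: BranchLengthProfile) -> np.ndarray:
    """Expected per-interval counts: total x interval share of tree length."""
    if total_transitions < 0:
        raise ValueError("total transition count must be >= 0")
    if profile.n_intervals == 0 or profile.total_length <= 0:
        raise ValueError("empty branch-length profile")
    return total_transitions * profile.totals / profile.total_length


def _bin_events(realisations: Sequence[MappingRealisation],
                pairs: list[tuple[str, str]], width: float,
                n_bins: int) -> np.ndarray:
    """Per-realisation binned event counts, shape (n_real, n_pairs, n_bins)."""
    pair_index = {p: i for i, p in enumerate(pairs)}
    out = np.zeros((len(realisations), len(pairs), n_bins))
    for r, real in enumerate(realisations):
        for e in real.events:
            b = min(int(e.time // width), n_bins - 1)
            out[r, pair_index[(e.from_state, e.to_state)], b] += 1
    return out


def corrected_rates(realisations: Sequence[MappingRealisation],
                    profile: BranchLengthProfile,
                    reporting_bin: float = 500.0) -> tuple[CorrectedRates, TransitionHistogram]:
    """Observed-minus-expected event counts per pair and time interval.

    Observed counts are means over realisations in the profile's intervals;
    the expectation spreads each pair's own total over intervals in
    proportion to branch length, so corrected values sum to zero exactly
    per pair.  A finer histogram at ``reporting_bin`` is returned alongside.
    """
    if not realisations:
        raise ValueError("need at least one realisation")
    states = realisations[0].states
    pairs = ordered_pairs(states)
    n_int = profile.n_intervals
    per_real = _bin_events(realisations, pairs, profile.interval, n_int)
    observed = per_real.mean(axis=0)
    n = per_real.shape[0]
    observed_se = per_real.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(observed)
    share = profile.totals / profile.total_length
    totals = observed.sum(axis=1, keepdims=True)
    expected = totals * share[None, :]
    corrected = observed - expected
    # absorb float rounding into the oldest interval so each pair's
    # corrected values sum to zero exactly
    for _ in range(5):
        resid = corrected.sum(axis=1)
        if not resid.any():
            break
        corrected[:, -1] -= resid

    span = n_int * profile.interval
    n_bins = max(int(math.ceil(span / reporting_bin)), 1)
    hist_counts = _bin_events(realisations, pairs, reporting_bin, n_bins).mean(axis=0)
    hist = TransitionHistogram(bin_width=reporting_bin, pairs=pairs, counts=hist_counts)
    return (
        CorrectedRates(interval=profile.interval, pairs=pairs, observed=observed,
                       expected=expected, corrected=corrected, observed_se=observed_se),
        hist,
    )
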
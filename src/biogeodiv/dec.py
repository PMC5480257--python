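"""Dispersal-Extinction-Cladogenesis (DEC) ancestral-range model.

Geographic ranges are sets of areas from a small alphabet, constrained by
pairwise adjacency and a maximum range size (two areas in the study design
this package follows). Anagenetic evolution along branches is a
continuous-time Markov chain: a range gains an adjacent area by dispersal
(rate ``d`` per occupied area) and loses an occupied area by local
extinction (rate ``e``); the empty range is absorbing. At speciation the
ancestral range is partitioned between the daughters under the canonical
DEC cladogenetic scenario set (sympatry, subset sympatry, vicariance), each
allowed scenario weighted equally.

The model is exposed statsmodels-style: :class:`DECModel` is built from a
tree plus tip ranges and an :class:`AreaSystem`; ``fit()`` returns a
:class:`DECResults` carrying the ML rates, log-likelihood, convergence
diagnostics, and per-node split-scenario probabilities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .treeio import CladeDefinition, TimeTree, locate_clade

__all__ = [
    "AreaSystem",
    "DECParams",
    "SplitScenario",
    "DECModel",
    "DECResults",
    "enumerate_states",
    "split_scenarios",
    "build_q_matrix",
    "tree_log_likelihood",
    "fit_ml",
    "node_split_probs",
    "range_label",
]

EMPTY: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# state space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaSystem:
    """Ordered area alphabet with a symmetric adjacency relation and a
    maximum range size."""

    areas: tuple[str, ...]
    adjacency: frozenset[frozenset[str]]
    max_range_size: int = 2

    def __post_init__(self):
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("duplicate area codes")
        if not 1 <= self.max_range_size <= len(self.areas):
            raise ValueError("max_range_size out of bounds")
        for pair in self.adjacency:
            if len(pair) != 2:
                raise ValueError(f"adjacency entries must be unordered pairs "
                                 f"of distinct areas, got {set(pair)}")
            if not pair <= set(self.areas):
                raise ValueError(f"adjacency pair {set(pair)} outside alphabet")

    @classmethod
    def from_pairs(cls, areas: Iterable[str],
                   pairs: Iterable[tuple[str, str]],
                   max_range_size: int = 2) -> "AreaSystem":
        return cls(tuple(areas),
                   frozenset(frozenset(p) for p in pairs),
                   max_range_size)

    @classmethod
    def complete(cls, areas: Iterable[str], max_range_size: int = 2
                 ) -> "AreaSystem":
        areas = tuple(areas)
        return cls.from_pairs(areas, itertools.combinations(areas, 2),
                              max_range_size)

    @classmethod
    def from_adjacency_tsv(cls, path: str | Path, max_range_size: int = 2
                           ) -> "AreaSystem":
        """Read a symmetric 0/1 adjacency matrix with area-letter headers."""
        m = pd.read_csv(path, sep="\t", index_col=0)
        m.index = m.index.astype(str)
        areas = tuple(str(c) for c in m.columns)
        if tuple(m.index) != areas:
            raise ValueError("adjacency matrix rows and columns differ")
        vals = m.to_numpy()
        if not np.array_equal(vals, vals.T):
            raise ValueError("adjacency matrix is not symmetric")
        if np.any(np.diag(vals) != 0):
            raise ValueError("adjacency matrix must be irreflexive "
                             "(zero diagonal)")
        pairs = [(areas[i], areas[j])
                 for i in range(len(areas)) for j in range(i + 1, len(areas))
                 if vals[i, j]]
        return cls.from_pairs(areas, pairs, max_range_size)

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.adjacency

    def is_connected(self, members: frozenset[str]) -> bool:
        if len(members) <= 1:
            return True
        seen = {next(iter(sorted(members)))}
        frontier = list(seen)
        while frontier:
            a = frontier.pop()
            for b in members - seen:
                if self.adjacent(a, b):
                    seen.add(b)
                    frontier.append(b)
        return seen == members

    def is_allowed(self, members: frozenset[str]) -> bool:
        return (members <= set(self.areas)
                and len(members) <= self.max_range_size
                and self.is_connected(members))


def range_label(members: frozenset[str], system: AreaSystem) -> str:
    """Spell a range as concatenated letters in alphabet order; ∅ -> '-'."""
    order = {a: i for i, a in enumerate(system.areas)}
    return "".join(sorted(members, key=order.get)) or "-"


def enumerate_states(system: AreaSystem) -> list[frozenset[str]]:
    """All allowed range states, ordered by size then lexicographically
    (in alphabet order). Includes the empty (globally extinct) range."""
    order = {a: i for i, a in enumerate(system.areas)}
    states: list[frozenset[str]] = [EMPTY]
    for size in range(1, system.max_range_size + 1):
        for combo in itertools.combinations(system.areas, size):
            s = frozenset(combo)
            if system.is_connected(s):
                states.append(s)
    states.sort(key=lambda s: (len(s), sorted(order[a] for a in s)))
    return states


@dataclass(frozen=True)
class DECParams:
    """Dispersal (range expansion) and extinction (area loss) rates,
    per Myr."""

    d: float
    e: float

    def __post_init__(self):
        if not (np.isfinite(self.d) and np.isfinite(self.e)):
            raise ValueError("rates must be finite")
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")


def build_q_matrix(system: AreaSystem, params: DECParams,
                   states: Optional[Sequence[frozenset[str]]] = None
                   ) -> np.ndarray:
    """Anagenetic rate matrix over the allowed states.

    Off-diagonals: ``R -> R ∪ {a}`` at rate ``d·|R|`` when the target is an
    allowed state, and ``R -> R ∖ {a}`` at rate ``e`` for each occupied
    area (again only to allowed states). Rows sum to zero; ∅ is absorbing.
    """
    if states is None:
        states = enumerate_states(system)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    q = np.zeros((n, n))
    for s, i in index.items():
        if not s:
            continue
        for a in system.areas:
            if a in s:
                continue
            tgt = s | {a}
            j = index.get(tgt)
            if j is not None:
                q[i, j] += params.d * len(s)
        for a in sorted(s):
            tgt = s - {a}
            j = index.get(tgt)
            if j is not None:
                q[i, j] += params.e
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


def split_scenarios(members: frozenset[str], allowed: set[frozenset[str]]
                    ) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Cladogenetic scenarios for an ancestral range.

    Singleton ancestor: sympatry ``R|R`` only. Larger ancestor: subset
    sympatry (``{a}|R`` and ``R|{a}`` for each occupied area) and
    vicariance (``{a}|R∖{a}`` and its mirror, when the complement is an
    allowed state). Scenarios are deduplicated and deterministically
    ordered.
    """
    if not members:
        raise ValueError("no scenarios for the empty range")
    if len(members) == 1:
        return [(members, members)]
    out: dict[tuple[frozenset[str], frozenset[str]], None] = {}
    for a in sorted(members):
        one = frozenset((a,))
        rest = members - one
        out[(one, members)] = None
        out[(members, one)] = None
        if rest in allowed:
            out[(one, rest)] = None
            out[(rest, one)] = None
    return sorted(out, key=lambda lr: (sorted(lr[0]), sorted(lr[1])))


@dataclass(frozen=True)
class SplitScenario:
    """One cladogenetic assignment (left | right) with its relative
    probability; the ancestor range is the union of the two sides."""

    left_range: frozenset[str]
    right_range: frozenset[str]
    rel_prob: float

    @property
    def ancestor_range(self) -> frozenset[str]:
        return self.left_range | self.right_range

    def label(self, system: AreaSystem) -> str:
        return (f"{range_label(self.left_range, system)}|"
                f"{range_label(self.right_range, system)}")


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class DECModel:
    """DEC likelihood model for one binary ultrametric tree.

    Parameters
    ----------
    tree
        Binary rooted time tree.
    tip_ranges
        Mapping from tip label to a non-empty allowed range
        (``frozenset`` of area letters).
    system
        The constrained area system.
    """

    def __init__(self, tree: TimeTree, tip_ranges: Mapping[str, frozenset],
                 system: AreaSystem):
        if not tree.is_binary():
            raise ValueError(
                "DEC requires a binary tree; use "
                "treeio.resolve_polytomies for an explicit seeded resolution")
        self.tree = tree
        self.system = system
        self.states = enumerate_states(system)
        self.state_index = {s: i for i, s in enumerate(self.states)}
        self.n_states = len(self.states)
        self._nonempty = np.array([bool(s) for s in self.states])

        allowed = set(self.states)
        # flat scenario arrays shared by every internal node; the empty
        # (extinct) ancestor can only pass emptiness to both daughters,
        # which lets extinct tips enter the data as ∅ observations
        anc, left, right, wt = [], [], [], []
        self._scenarios_by_state: dict[frozenset, list] = {}
        for s in self.states:
            scn = ([(EMPTY, EMPTY)] if not s
                   else split_scenarios(s, allowed))
            self._scenarios_by_state[s] = scn
            w = 1.0 / len(scn)
            for l, r in scn:
                anc.append(self.state_index[s])
                left.append(self.state_index[l])
                right.append(self.state_index[r])
                wt.append(w)
        self._scn_anc = np.array(anc, dtype=np.intp)
        self._scn_left = np.array(left, dtype=np.intp)
        self._scn_right = np.array(right, dtype=np.intp)
        self._scn_wt = np.array(wt)

        self.tip_ranges = {}
        for label in tree.tip_labels:
            if label not in tip_ranges:
                raise ValueError(f"no range given for tip {label!r}")
            r = frozenset(tip_ranges[label])
            if r not in self.state_index:
                raise ValueError(
                    f"tip {label!r} has a disallowed range "
                    f"{set(r) or '∅'} under the configured area system")
            self.tip_ranges[label] = r

        # deterministic child ordering: by smallest tip label underneath
        self._children: dict[dendropy.Node, list[dendropy.Node]] = {}
        self._min_label: dict[dendropy.Node, str] = {}
        for nd in self.tree.tree.postorder_node_iter():
            if nd.is_leaf():
                self._min_label[nd] = nd.taxon.label
            else:
                ch = sorted(nd.child_nodes(),
                            key=lambda c: self._min_label[c])
                self._children[nd] = ch
                self._min_label[nd] = self._min_label[ch[0]]
        self._postorder = list(self.tree.tree.postorder_node_iter())
        self.nobs = tree.n_tips

    # -- likelihood ---------------------------------------------------
    def _branch_matrices(self, params: DECParams
                         ) -> dict[dendropy.Node, np.ndarray]:
        q = build_q_matrix(self.system, params, self.states)
        mats = {}
        cache: dict[float, np.ndarray] = {}
        for nd in self._postorder:
            if nd.parent_node is None:
                continue
            t = nd.edge.length or 0.0
            if t not in cache:
                cache[t] = expm(q * t)
            mats[nd] = cache[t]
        return mats

    def _pass_up(self, params: DECParams):
        """Postorder conditional likelihoods.

        Returns (L, D, logscale, mats): per-node conditional vectors at the
        node (L) and propagated to the top of the node's branch (D), the
        accumulated log of rescaling constants for the full tree, and the
        per-branch transition matrices.
        """
        mats = self._branch_matrices(params)
        L: dict[dendropy.Node, np.ndarray] = {}
        D: dict[dendropy.Node, np.ndarray] = {}
        logscale = 0.0
        for nd in self._postorder:
            if nd.is_leaf():
                v = np.zeros(self.n_states)
                v[self.state_index[self.tip_ranges[nd.taxon.label]]] = 1.0
            else:
                c1, c2 = self._children[nd]
                contrib = (D[c1][self._scn_left] * D[c2][self._scn_right]
                           * self._scn_wt)
                v = np.zeros(self.n_states)
                np.add.at(v, self._scn_anc, contrib)
            m = v.max()
            if m <= 0.0:
                return None, None, -np.inf, mats
            v = v / m
            logscale += np.log(m)
            L[nd] = v
            if nd.parent_node is not None:
                D[nd] = mats[nd] @ v
        return L, D, logscale, mats

    def loglike(self, params: DECParams) -> float:
        """Log-probability of the tip ranges given the tree and rates.

        Root states: uniform weight over allowed non-empty ranges.
        """
        L, _D, logscale, _ = self._pass_up(params)
        if L is None:
            return -np.inf
        root = self._postorder[-1]
        w = self._nonempty / self._nonempty.sum()
        val = float(w @ L[root])
        if val <= 0.0:
            return -np.inf
        return np.log(val) + logscale

    # -- per-node scenario probabilities -------------------------------
    def _pass_down(self, params: DECParams):
        """Preorder outside vectors O (probability of all data outside a
        node's subtree, given the node's state), rescaled per node."""
        L, D, logscale, mats = self._pass_up(params)
        if L is None:
            raise ValueError("likelihood is zero under these parameters")
        O: dict[dendropy.Node, np.ndarray] = {}
        root = self._postorder[-1]
        O[root] = self._nonempty / self._nonempty.sum()
        for nd in self.tree.tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            c1, c2 = self._children[nd]
            base = O[nd][self._scn_anc] * self._scn_wt
            top1 = np.zeros(self.n_states)
            np.add.at(top1, self._scn_left, base * D[c2][self._scn_right])
            top2 = np.zeros(self.n_states)
            np.add.at(top2, self._scn_right, base * D[c1][self._scn_left])
            for child, top in ((c1, top1), (c2, top2)):
                o = top @ mats[child]
                m = o.max()
                O[child] = o / m if m > 0 else o
        return L, D, O

    def node_split_probs(self, params: DECParams, node: dendropy.Node
                         ) -> list[SplitScenario]:
        """Relative probabilities of every cladogenetic scenario at an
        internal node (global-likelihood clamping, normalized to 1)."""
        if node.is_leaf():
            raise ValueError("split scenarios are defined for internal "
                             "nodes only")
        L, D, O = self._pass_down(params)
        c1, c2 = self._children[node]
        raw = (O[node][self._scn_anc] * self._scn_wt
               * D[c1][self._scn_left] * D[c2][self._scn_right])
        total = raw.sum()
        if total <= 0:
            raise ValueError("zero likelihood at node")
        probs = raw / total
        order = {a: i for i, a in enumerate(self.system.areas)}
        out = [SplitScenario(self.states[l], self.states[r], float(p))
               for l, r, p in zip(self._scn_left, self._scn_right, probs)
               if p > 0.0]
        out.sort(key=lambda s: (-s.rel_prob,
                                sorted(order[a] for a in s.left_range),
                                sorted(order[a] for a in s.right_range)))
        return out

    # -- fitting -------------------------------------------------------
    def fit(self, start: Optional[tuple[float, float]] = None,
            bounds: tuple[float, float] = (1e-9, 10.0),
            n_restarts: int = 3, seed: int = 0) -> "DECResults":
        """Bounded quasi-Newton ML estimation of (d, e) on the log scale,
        with seeded restarts. Non-convergence is flagged, not raised."""
        lo, hi = np.log(bounds[0]), np.log(bounds[1])

        def nll(x):
            ll = self.loglike(DECParams(*np.exp(x)))
            return -ll if np.isfinite(ll) else 1e300

        rng = np.random.default_rng(seed)
        starts = []
        if start is not None:
            starts.append(np.log(np.asarray(start, dtype=float)))
        else:
            starts.append(np.log([0.01, 0.01]))
        while len(starts) < max(1, n_restarts):
            starts.append(np.log(np.exp(rng.uniform(np.log(1e-3), 0.0,
                                                    size=2))))
        best = None
        converged = False
        for x0 in starts:
            res = minimize(nll, x0, method="L-BFGS-B",
                           bounds=[(lo, hi), (lo, hi)])
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        x = best.x
        hits = []
        for name, xi in zip("de", x):
            if xi - lo < 1e-6:
                hits.append(f"{name}:lower")
            elif hi - xi < 1e-6:
                hits.append(f"{name}:upper")
        params = DECParams(*np.exp(x))
        return DECResults(model=self, params=params, llf=-best.fun,
                          converged=converged, bounds_hit=tuple(hits),
                          n_restarts=len(starts))


@dataclass
class DECResults:
    """ML fit of a :class:`DECModel`: rates, log-likelihood and
    diagnostics, plus per-node scenario probabilities."""

    model: DECModel
    params: DECParams
    llf: float
    converged: bool
    bounds_hit: tuple[str, ...]
    n_restarts: int

    root_weighting: str = "uniform over allowed non-empty states"

    def node_split_probs(self, node: Optional[dendropy.Node] = None,
                         clade: Optional[CladeDefinition] = None
                         ) -> list[SplitScenario]:
        if node is None:
            if clade is None:
                raise ValueError("give a node or a clade definition")
            node = locate_clade(self.model.tree, clade)
            if node is None:
                raise ValueError(f"clade {clade.name!r} not found "
                                 f"(or non-monophyletic)")
        return self.model.node_split_probs(self.params, node)

    def summary(self) -> str:
        sys_ = self.model.system
        lines = [
            "DEC maximum-likelihood fit",
            "==========================",
            f"areas: {''.join(sys_.areas)}  "
            f"(max range size {sys_.max_range_size})",
            f"states: {self.model.n_states} (incl. empty)",
            f"tips: {self.model.nobs}",
            f"d (dispersal/Myr):  {self.params.d:.6g}",
            f"e (extinction/Myr): {self.params.e:.6g}",
            f"logL: {self.llf:.6f}",
            f"converged: {self.converged}   restarts: {self.n_restarts}",
            f"bounds hit: {', '.join(self.bounds_hit) or 'none'}",
            f"root weighting: {self.root_weighting}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def tree_log_likelihood(tree: TimeTree, tip_ranges: Mapping[str, frozenset],
                        system: AreaSystem, params: DECParams) -> float:
    return DECModel(tree, tip_ranges, system).loglike(params)


def fit_ml(tree: TimeTree, tip_ranges: Mapping[str, frozenset],
           system: AreaSystem, **kwargs) -> DECResults:
    return DECModel(tree, tip_ranges, system).fit(**kwargs)


def node_split_probs(tree: TimeTree, tip_ranges: Mapping[str, frozenset],
                     system: AreaSystem, params: DECParams,
                     node: dendropy.Node) -> list[SplitScenario]:
    return DECModel(tree, tip_ranges, system).node_split_probs(params, node)
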
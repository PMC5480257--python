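"""Seeded generators for every input the pipeline consumes.

The defaults mirror the study conditions the pipeline targets: posterior
samples of 18-tip ultrametric trees with a crown age around 14 Myr and a
late diversification-rate increase (0.04 -> 0.29 per lineage per Myr at
7.82 Mya), tip ranges over five areas evolved under DEC with known rates,
and low-divergence multi-locus alignments (three loci, ~800-1100 sites
each) whose collapse yields 10-25 haplotypes organized in star-like groups
plus a relict chain.

Every generator is a pure function of its configuration (seed included):
the same config yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .dec import AreaSystem, DECParams, enumerate_states, split_scenarios
from .hapnet import HaplotypeAlignment
from .treeio import TimeTree

__all__ = ["SimConfig", "simulate_trees", "simulate_ranges",
           "simulate_haplotypes", "DEFAULT_STRUCTURE"]

DEFAULT_STRUCTURE = (("star", 9, "E"), ("star", 7, "D"), ("chain", 5, "A"))


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of the synthetic study system."""

    seed: int = 0
    # trees
    n_tips: int = 18
    crown_age: Optional[float] = 14.0
    rates: tuple[float, ...] = (0.04, 0.29)
    shift_ages: tuple[float, ...] = (7.82,)
    stem_length: Optional[float] = 4.0
    n_posterior_trees: int = 1000
    jitter_sd: float = 0.05
    max_rejects: int = 200_000
    # ranges
    areas: tuple[str, ...] = ("A", "B", "C", "D", "E")
    adjacency: tuple[tuple[str, str], ...] = (
        ("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"))
    max_range_size: int = 2
    d: float = 0.2
    e: float = 0.05
    root_range: tuple[str, ...] = ("C",)
    # haplotypes
    n_loci: int = 3
    locus_lengths: tuple[int, ...] = (800, 950, 1100)
    gap_fraction: float = 0.02
    structure: tuple = DEFAULT_STRUCTURE
    inter_group_steps: int = 4
    center_frequency: int = 12
    mutation_scale: float = 1.0
    outgroup_steps: int = 17

    def __post_init__(self):
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be non-negative")
        if len(self.rates) != len(self.shift_ages) + 1:
            raise ValueError("need one more rate than shift ages")
        if self.crown_age is not None:
            for s in self.shift_ages:
                if not 0 < s < self.crown_age:
                    raise ValueError("shift ages must lie inside "
                                     "(0, crown_age)")
        elif self.shift_ages:
            raise ValueError("rate shifts need a fixed crown age")

    def area_system(self) -> AreaSystem:
        return AreaSystem.from_pairs(self.areas, self.adjacency,
                                     self.max_range_size)

    def dec_params(self) -> DECParams:
        return DECParams(self.d, self.e)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _rate_at_age(cfg: SimConfig, age: float) -> float:
    for r, s in zip(cfg.rates, cfg.shift_ages):
        if age > s:
            return r
    return cfg.rates[-1]


def _simulate_fixed_age(cfg: SimConfig, rng: np.random.Generator):
    """One forward pure-birth realization over [crown_age, 0]; returns the
    event times (forward time from the crown) or None if tip count missed."""
    T = cfg.crown_age
    taus = sorted(T - s for s in cfg.shift_ages) + [T]
    n = 2
    tau = 0.0
    bp_i = 0
    events = []
    while tau < T:
        lam = _rate_at_age(cfg, T - tau - 1e-12)
        next_bp = taus[bp_i]
        wait = rng.exponential(1.0 / (n * lam)) if lam > 0 else math.inf
        if tau + wait < next_bp:
            tau += wait
            events.append((tau, int(rng.integers(n))))
            n += 1
            if n > cfg.n_tips:
                return None
        else:
            tau = next_bp
            bp_i += 1
    return events if n == cfg.n_tips else None


def _simulate_free_age(cfg: SimConfig, rng: np.random.Generator):
    """Constant-rate growth from two lineages until n_tips is reached;
    the present is one further (unexecuted) waiting time later, so the
    youngest branching age stays positive."""
    lam = cfg.rates[0]
    tau = 0.0
    events = []
    for n in range(2, cfg.n_tips):
        tau += rng.exponential(1.0 / (n * lam))
        events.append((tau, int(rng.integers(n))))
    T = tau + rng.exponential(1.0 / (cfg.n_tips * lam))
    return events, T


def _events_to_tree(events, T: float, stem_length: Optional[float]
                    ) -> TimeTree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    c1, c2 = root.new_child(), root.new_child()
    active = [[c1, 0.0], [c2, 0.0]]
    for tau, idx in events:
        node, birth = active[idx]
        node.edge.length = tau - birth
        k1, k2 = node.new_child(), node.new_child()
        active[idx] = [k1, tau]
        active.append([k2, tau])
    for i, (node, birth) in enumerate(active, start=1):
        node.edge.length = T - birth
        node.taxon = tns.new_taxon(label=f"t{i}")
    if stem_length is not None:
        root.edge.length = stem_length
    return TimeTree(tree, check=False)


def _jitter_tree(tree: TimeTree, sd: float, rng: np.random.Generator
                 ) -> TimeTree:
    """Posterior-like replicate: multiplicative lognormal noise on
    internal-node ages, clamped so parent > child and ultrametricity is
    preserved (tips stay at the present)."""
    if sd == 0:
        return tree.clone()
    t = tree.clone()
    ages = t.node_ages()
    new_age: dict = {}
    for nd in t.tree.preorder_node_iter():
        if nd.is_leaf():
            new_age[nd] = 0.0
            continue
        a = ages[nd] * (rng.lognormal(0.0, sd) if sd > 0 else 1.0)
        if nd.parent_node is not None:
            a = min(a, new_age[nd.parent_node] * (1 - 1e-9))
        new_age[nd] = max(a, 1e-9)
    for nd in t.tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = new_age[nd.parent_node] - new_age[nd]
    return TimeTree(t.tree, check=False)


def simulate_trees(cfg: SimConfig) -> tuple[TimeTree, list[TimeTree]]:
    """Simulate a summary tree plus a posterior-like sample.

    With a fixed ``crown_age`` the piecewise pure-birth process is run
    forward and rejected until exactly ``n_tips`` survive to the present
    (shift ages are absolute, so the time span must be fixed). With
    ``crown_age=None`` (constant rate only) the process stops when
    ``n_tips`` is reached and the crown age is random. The posterior
    sample consists of ``n_posterior_trees`` node-age-jittered replicates
    of the summary tree.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.crown_age is not None:
        events = None
        for _ in range(cfg.max_rejects):
            events = _simulate_fixed_age(cfg, rng)
            if events is not None:
                break
        if events is None:
            raise RuntimeError(
                f"could not reach exactly {cfg.n_tips} tips in "
                f"{cfg.max_rejects} attempts (rates {cfg.rates}, crown age "
                f"{cfg.crown_age}); adjust rates, age or tip count")
        summary = _events_to_tree(events, cfg.crown_age, cfg.stem_length)
    else:
        events, T = _simulate_free_age(cfg, rng)
        summary = _events_to_tree(events, T, cfg.stem_length)
    posterior = [_jitter_tree(summary, cfg.jitter_sd, rng)
                 for _ in range(cfg.n_posterior_trees)]
    return summary, posterior


# ---------------------------------------------------------------------------
# ranges
# ---------------------------------------------------------------------------

def simulate_ranges(tree: TimeTree, system: AreaSystem, params: DECParams,
                    root_range: frozenset[str], seed: int = 0
                    ) -> dict[str, frozenset[str]]:
    """Forward (Gillespie) simulation of the DEC process along the tree.

    Anagenesis along each branch follows the dispersal/extinction rates;
    at every internal node a cladogenetic scenario is drawn uniformly
    from the allowed set. Lineages reaching the empty range are globally
    extinct: their tips are reported with an empty range and the caller
    decides whether to prune them.
    """
    root_range = frozenset(root_range)
    states = set(enumerate_states(system))
    if root_range not in states or not root_range:
        raise ValueError("root range is not an allowed non-empty state")
    rng = np.random.default_rng(seed)

    def evolve(state: frozenset, t: float) -> frozenset:
        remaining = t
        while state and remaining > 0:
            targets, rates = [], []
            for a in system.areas:
                if a in state:
                    continue
                tgt = state | {a}
                if tgt in states:
                    targets.append(tgt)
                    rates.append(params.d * len(state))
            for a in sorted(state):
                tgt = state - {a}
                if tgt in states:
                    targets.append(tgt)
                    rates.append(params.e)
            total = sum(rates)
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if wait > remaining:
                break
            remaining -= wait
            state = targets[rng.choice(len(targets),
                                       p=np.asarray(rates) / total)]
        return state

    out: dict[str, frozenset] = {}
    node_state = {tree.tree.seed_node: root_range}
    for nd in tree.tree.preorder_node_iter():
        state = node_state[nd]
        if nd.is_leaf():
            out[nd.taxon.label] = state
            continue
        children = nd.child_nodes()
        if not state:
            parts = [frozenset()] * len(children)
        else:
            scns = split_scenarios(state, states)
            left, right = scns[rng.integers(len(scns))]
            parts = [left, right] + [frozenset()] * (len(children) - 2)
        for child, part in zip(children, parts):
            node_state[child] = evolve(part, child.edge.length or 0.0)
    return out


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_haplotypes(cfg: SimConfig,
                        structure: Optional[Sequence[tuple]] = None
                        ) -> tuple[HaplotypeAlignment, dict]:
    """Constructed haplotype genealogy with known truth.

    ``structure`` is a sequence of groups ``(kind, size, area)`` with kind
    ``'star'`` (one center plus ``size`` one-step descendants — the
    star-like pattern of recent expansion) or ``'chain'`` (a path of
    ``size`` haplotypes one step apart — a relict gradient). Successive
    groups attach to the previous group's anchor ``inter_group_steps``
    steps away. Every mutational step consumes a fresh alignment site
    (no homoplasy in the truth), scaled by ``mutation_scale`` (0 makes
    every sample identical). Gaps are inserted per site at
    ``gap_fraction`` and are treated as missing downstream.

    Returns the alignment plus a truth dict: prototype sequences, the
    genealogy edge list with step counts, sample-to-haplotype map, and
    the star centers.
    """
    rng = np.random.default_rng(cfg.seed + 104729)
    structure = tuple(structure if structure is not None else cfg.structure)
    m = int(sum(cfg.locus_lengths[:cfg.n_loci]))
    ancestral = rng.choice(_BASES, size=m)
    free_sites = list(rng.permutation(m))

    def mutate(seq: np.ndarray, steps: int) -> np.ndarray:
        steps = int(round(steps * cfg.mutation_scale))
        s = seq.copy()
        for _ in range(steps):
            if not free_sites:
                raise RuntimeError("alignment too short for the requested "
                                   "number of mutational steps")
            site = free_sites.pop()
            choices = [b for b in "ACGT" if b != s[site]]
            s[site] = choices[rng.integers(3)]
        return s

    protos: list[np.ndarray] = []
    areas: list[str] = []
    kinds: list[str] = []
    edges: list[tuple[int, int, int]] = []   # (parent_idx, child_idx, steps)
    centers: list[int] = []
    prev_anchor = None
    for kind, size, area in structure:
        if kind == "star":
            if prev_anchor is None:
                center_seq = ancestral.copy()
            else:
                center_seq = mutate(protos[prev_anchor],
                                    cfg.inter_group_steps)
            protos.append(center_seq)
            areas.append(area)
            kinds.append("center")
            center = len(protos) - 1
            if prev_anchor is not None:
                edges.append((prev_anchor, center, cfg.inter_group_steps))
            centers.append(center)
            for _ in range(size):
                protos.append(mutate(center_seq, 1))
                areas.append(area)
                kinds.append("leaf")
                edges.append((center, len(protos) - 1, 1))
            prev_anchor = center
        elif kind == "chain":
            prev = prev_anchor
            first = True
            for _ in range(size):
                if prev is None:
                    protos.append(ancestral.copy())
                    steps = 0
                else:
                    steps = cfg.inter_group_steps if first and \
                        prev_anchor is not None else 1
                    protos.append(mutate(protos[prev], steps))
                areas.append(area)
                kinds.append("chain")
                if prev is not None:
                    edges.append((prev, len(protos) - 1, steps))
                prev = len(protos) - 1
                first = False
            prev_anchor = prev
        else:
            raise ValueError(f"unknown group kind {kind!r}")

    sample_ids, seqs, metarows = [], [], []
    sample_to_hap = {}
    k = 0
    for idx, (proto, area, kind) in enumerate(zip(protos, areas, kinds)):
        if kind == "center":
            freq = cfg.center_frequency
        else:
            freq = 1 + int(rng.random() < 0.35)
        for _ in range(freq):
            k += 1
            sid = f"s{k}"
            seq = proto.copy()
            if cfg.gap_fraction > 0:
                gaps = rng.random(m) < cfg.gap_fraction
                seq = seq.copy()
                seq[gaps] = "-"
            sample_ids.append(sid)
            seqs.append("".join(seq))
            sample_to_hap[sid] = idx
            metarows.append((sid, "sim", area, f"loc_{area}"))
    meta = pd.DataFrame(metarows,
                        columns=["sample_id", "taxon", "area", "locality"])
    aln = HaplotypeAlignment(sample_ids, seqs, meta)
    truth = {
        "outgroup": "".join(mutate(protos[0], cfg.outgroup_steps)),
        "prototypes": ["".join(p) for p in protos],
        "areas": list(areas),
        "edges": edges,
        "sample_to_hap": sample_to_hap,
        "centers": centers,
        "locus_lengths": tuple(cfg.locus_lengths[:cfg.n_loci]),
    }
    return aln, truth
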
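"""Statistical-parsimony haplotype networks from aligned sequences.

Samples are collapsed into haplotypes treating gaps and Ns as missing
data; haplotypes are linked by single-substitution steps up to a 95%
parsimony connection limit, inserting unsampled ("extinct or not
detected") intermediate nodes where more than one step separates them.
Reticulations (loops) left by homoplasy are resolved with coalescent
predictions — interior, high-frequency and geographically co-occurring
haplotypes retain their connections — and haplotypes are classified as
interior (degree >= 2) or tip (degree <= 1), with the class statistics
used in the accompanying frequency tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .diversification import ChiSquareResult, chisq_gof

__all__ = [
    "HaplotypeAlignment",
    "Haplotype",
    "HaplotypeNetwork",
    "NetworkStats",
    "OutgroupConnection",
    "collapse_haplotypes",
    "step_distance",
    "parsimony_limit",
    "build_network",
    "resolve_ambiguities",
    "network_stats",
    "outgroup_connection",
    "concat_loci",
]

MISSING = frozenset("-N?")


# ---------------------------------------------------------------------------
# alignment container
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAlignment:
    """Equal-length aligned sequences with per-sample metadata."""

    sample_ids: list[str]
    sequences: list[str]
    metadata: Optional[pd.DataFrame] = None   # sample_id, taxon, area, ...

    def __post_init__(self):
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @classmethod
    def from_fasta(cls, path: str | Path,
                   metadata: Optional[pd.DataFrame | str | Path] = None
                   ) -> "HaplotypeAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no sequences")
        meta = metadata
        if isinstance(metadata, (str, Path)):
            meta = pd.read_csv(metadata, sep="\t", dtype=str)
        return cls([r.id for r in records], [str(r.seq) for r in records],
                   meta)

    def area_of(self, sample_id: str) -> Optional[str]:
        if self.metadata is None or "area" not in self.metadata.columns:
            return None
        row = self.metadata.loc[self.metadata["sample_id"] == sample_id]
        return None if row.empty else row["area"].iloc[0]


def concat_loci(alignments: Sequence[HaplotypeAlignment],
                require_all: bool = True) -> HaplotypeAlignment:
    """Concatenate loci sample-wise; by default only samples sequenced at
    every locus are kept."""
    if not alignments:
        raise ValueError("nothing to concatenate")
    sets = [set(a.sample_ids) for a in alignments]
    common = set.intersection(*sets) if require_all else set.union(*sets)
    order = [s for s in alignments[0].sample_ids if s in common]
    for a in alignments[1:]:
        order += [s for s in a.sample_ids if s in common and s not in order]
    seqs = []
    for s in order:
        parts = []
        for a in alignments:
            if s in a.sample_ids:
                parts.append(a.sequences[a.sample_ids.index(s)])
            else:
                parts.append("N" * a.n_sites)
        seqs.append("".join(parts))
    meta = alignments[0].metadata
    return HaplotypeAlignment(order, seqs, meta)


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    """A collapsed sequence class; the representative sequence keeps 'N'
    at positions never resolved by any member."""

    id: int
    sequence: str
    member_samples: list[str]
    areas: Counter = field(default_factory=Counter)

    @property
    def frequency(self) -> int:
        return len(self.member_samples)


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1").copy()


_MISS_BYTES = np.array([c.encode() for c in MISSING])


def _missing_mask(arr: np.ndarray) -> np.ndarray:
    return np.isin(arr, _MISS_BYTES)


def collapse_haplotypes(aln: HaplotypeAlignment,
                        return_conflicts: bool = False):
    """Collapse samples into haplotypes under the missing-data rule.

    Two samples share a haplotype iff they agree at every site where both
    are resolved. Because that relation is not transitive, samples are
    assigned in input order to the earliest class whose accumulated
    consensus they are compatible with; samples compatible with more than
    one class are counted as conflicts (logged, earliest class wins).
    """
    if not aln.sample_ids:
        raise ValueError("empty alignment")
    classes: list[dict] = []
    n_conflicts = 0
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        arr = _seq_array(seq)
        miss = _missing_mask(arr)
        hits = []
        for cl in classes:
            both = ~(miss | cl["miss"])
            if np.all(arr[both] == cl["consensus"][both]):
                hits.append(cl)
        if hits:
            if len(hits) > 1:
                n_conflicts += 1
            cl = hits[0]
            fill = cl["miss"] & ~miss
            cl["consensus"][fill] = arr[fill]
            cl["miss"] &= miss
            cl["members"].append(sid)
        else:
            classes.append({"consensus": arr.copy(), "miss": miss.copy(),
                            "members": [sid]})
    haps = []
    for i, cl in enumerate(classes, start=1):
        cons = cl["consensus"].copy()
        cons[cl["miss"]] = b"N"
        areas = Counter()
        for sid in cl["members"]:
            a = aln.area_of(sid)
            if a is not None:
                areas[a] += 1
        haps.append(Haplotype(id=i, sequence=cons.tobytes().decode("ascii"),
                              member_samples=list(cl["members"]),
                              areas=areas))
    if return_conflicts:
        return haps, n_conflicts
    return haps


def step_distance(seq_a: str, seq_b: str) -> int:
    """Mutational steps: sites where both sequences are resolved and
    differ. Symmetric; zero iff the sequences are compatible."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = _seq_array(seq_a), _seq_array(seq_b)
    both = ~(_missing_mask(a) | _missing_mask(b))
    return int(np.sum(a[both] != b[both]))


# ---------------------------------------------------------------------------
# parsimony connection limit
# ---------------------------------------------------------------------------

def parsimony_limit(aln_length: int, prob: float = 0.95,
                    fixed: Optional[int] = None) -> int:
    """Largest number of steps for which a connection is parsimonious
    with probability above ``prob``.

    The no-homoplasy probability of a j-step connection over ``m`` sites
    is estimated as P_j = prod_{i=1..j} (1 - 3(i-1)/(4m)): the i-th change
    collides with a previously hit site with probability (i-1)/m, and
    under equal-rate substitution 3/4 of collisions break parsimony. P_1
    is 1, so the limit is always at least 1, and it is non-decreasing in
    the alignment length. ``fixed`` overrides the computation.
    """
    if fixed is not None:
        return int(fixed)
    if aln_length < 1:
        raise ValueError("alignment length must be >= 1")
    m = float(aln_length)
    p = 1.0
    j = 0
    while True:
        q = 1.0 - 0.75 * j / m          # collision factor for change j+1
        if q <= 0 or p * q <= prob:
            return max(j, 1)
        p *= q
        j += 1


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """Graph of sampled haplotypes (``H<i>``) and inferred intermediates
    (``I<k>``, frequency 0), with single-step edges."""

    graph: nx.Graph
    haplotypes: dict[int, Haplotype]
    limit: int
    resolved: bool = False
    resolution_log: list = field(default_factory=list)

    @property
    def loops(self) -> list[list[str]]:
        return nx.cycle_basis(self.graph)

    def node_frequency(self, node: str) -> int:
        return self.graph.nodes[node].get("frequency", 0)

    def node_areas(self, node: str) -> frozenset[str]:
        return frozenset(self.graph.nodes[node].get("areas", ()))

    def sampled_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if n.startswith("H")]

    def to_edge_tsv(self, path: str | Path) -> None:
        lines = ["source\ttarget\tdashed"]
        for u, v, d in sorted(self.graph.edges(data=True)):
            lines.append(f"{u}\t{v}\t{int(d.get('dashed', False))}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_node_tsv(self, path: str | Path) -> None:
        lines = ["node\tfrequency\tareas\tdegree"]
        for n in sorted(self.graph.nodes):
            areas = "".join(sorted(self.node_areas(n)))
            lines.append(f"{n}\t{self.node_frequency(n)}\t{areas}\t"
                         f"{self.graph.degree[n]}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, frequency=d.get("frequency", 0),
                       areas="".join(sorted(d.get("areas", ()))))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, dashed=int(d.get("dashed", False)))
        nx.write_graphml(g, str(path))


def build_network(haps: Sequence[Haplotype], limit: int) -> HaplotypeNetwork:
    """Connect haplotypes in ascending step-distance order up to the
    parsimony limit.

    A pair is linked only when no path of as few hops already connects
    it; links longer than one step pass through inferred intermediate
    nodes. Equal-distance alternatives can close cycles, which are kept
    and reported as loops for :func:`resolve_ambiguities`.
    """
    if not haps:
        raise ValueError("need at least one haplotype")
    g = nx.Graph()
    for h in haps:
        g.add_node(f"H{h.id}", frequency=h.frequency,
                   areas=frozenset(h.areas))
    pairs = []
    for i, a in enumerate(haps):
        for b in haps[i + 1:]:
            d = step_distance(a.sequence, b.sequence)
            pairs.append((d, a.id, b.id))
    pairs.sort()
    n_inter = 0
    for d, ia, ib in pairs:
        if d == 0 or d > limit:
            continue
        na, nb = f"H{ia}", f"H{ib}"
        try:
            if nx.shortest_path_length(g, na, nb) <= d:
                continue
        except nx.NetworkXNoPath:
            pass
        prev = na
        for _ in range(d - 1):
            n_inter += 1
            mid = f"I{n_inter}"
            g.add_node(mid, frequency=0, areas=frozenset())
            g.add_edge(prev, mid, dashed=False)
            prev = mid
        g.add_edge(prev, nb, dashed=False)
    return HaplotypeNetwork(graph=g, haplotypes={h.id: h for h in haps},
                            limit=limit)


# ---------------------------------------------------------------------------
# loop resolution (coalescent predictions)
# ---------------------------------------------------------------------------

def _edge_key(u: str, v: str) -> tuple[str, str]:
    return tuple(sorted((u, v)))


def _removal_rank(g: nx.Graph, u: str, v: str):
    """Lower rank = removed first. Keeps edges touching high-frequency
    haplotypes, then interior (sampled, degree >= 2) haplotypes, then
    same-region pairs — the coalescent predictions, in that order."""
    freq = max(g.nodes[u].get("frequency", 0), g.nodes[v].get("frequency", 0))
    interior = sum(1 for n in (u, v)
                   if n.startswith("H") and g.degree[n] >= 2)
    same_region = int(bool(g.nodes[u].get("areas", frozenset())
                           & g.nodes[v].get("areas", frozenset())))
    return (freq, interior, same_region)


def resolve_ambiguities(net: HaplotypeNetwork) -> HaplotypeNetwork:
    """Break every loop by removing one edge per cycle.

    Removal candidates are ranked by the coalescent criteria (frequency,
    topology, geography); remaining ties remove the edge latest in
    id-sorted order and are flagged. Edges that survived a cycle are
    marked dashed. Removing a cycle edge never disconnects a component.
    """
    g = net.graph.copy()
    log = []
    while True:
        cycles = nx.cycle_basis(g)
        if not cycles:
            break
        cycle = min((sorted(c) for c in cycles), key=tuple)
        # recover the actual cycle node order for its edge list
        cyc = next(c for c in cycles if sorted(c) == cycle)
        edges = [_edge_key(cyc[i], cyc[(i + 1) % len(cyc)])
                 for i in range(len(cyc))]
        ranked = sorted(edges,
                        key=lambda e: (_removal_rank(g, *e), e))
        best_rank = _removal_rank(g, *ranked[0])
        tied = [e for e in ranked if _removal_rank(g, *e) == best_rank]
        target = max(tied)              # latest in id-sorted order
        g.remove_edge(*target)
        for e in edges:
            if e != target and g.has_edge(*e):
                g.edges[e]["dashed"] = True
        log.append({"cycle_edges": tuple(sorted(edges)),
                    "removed": target,
                    "tie": len(tied) > 1})
    out = HaplotypeNetwork(graph=g, haplotypes=dict(net.haplotypes),
                           limit=net.limit, resolved=True,
                           resolution_log=net.resolution_log + log)
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class NetworkStats:
    """Interior/tip bookkeeping of a resolved network."""

    interior_unambiguous: list[int]
    interior_ambiguous: list[int]
    tips: list[int]
    samples_per_class: dict[str, int]
    mean_samples: dict[str, float]
    singleton_fraction: dict[str, float]
    singleton_ratio: dict[str, float]
    interior_vs_tip_test: Optional[ChiSquareResult]
    region_haplotype_counts: dict[str, int]
    region_exclusive_counts: dict[str, int]

    def summary(self) -> str:
        n_int = len(self.interior_unambiguous) + len(self.interior_ambiguous)
        lines = [
            f"interior haplotypes: {n_int} "
            f"({len(self.interior_unambiguous)} unambiguous, "
            f"{self.samples_per_class['interior_unambiguous']} samples; "
            f"{len(self.interior_ambiguous)} ambiguous, "
            f"{self.samples_per_class['interior_ambiguous']} samples)",
            f"tip haplotypes: {len(self.tips)} "
            f"({self.samples_per_class['tip']} samples)",
            f"mean samples/haplotype: "
            f"{self.mean_samples['interior_unambiguous']:.2f} "
            f"(unambiguous interior), {self.mean_samples['tip']:.2f} (tip)",
        ]
        if self.interior_vs_tip_test:
            t = self.interior_vs_tip_test
            lines.append(f"interior vs tip samples: chi2 = "
                         f"{t.statistic:.4f}, df = {t.df}, "
                         f"p = {t.pvalue:.3g}")
        return "\n".join(lines)


def _classify(g: nx.Graph) -> dict[str, str]:
    """'interior' (degree >= 2) or 'tip' per sampled haplotype node."""
    return {n: ("interior" if g.degree[n] >= 2 else "tip")
            for n in g.nodes if n.startswith("H")}


def network_stats(net: HaplotypeNetwork) -> NetworkStats:
    """Interior/tip classification, per-class sample statistics, the
    interior-vs-tip chi-square frequency test, and per-region counts.

    A haplotype is 'ambiguous interior' when its degree class depends on
    which edge was removed from some loop (checked against every
    alternative single-edge resolution recorded during
    :func:`resolve_ambiguities`).
    """
    if net.loops:
        raise ValueError("network still has unresolved loops; run "
                         "resolve_ambiguities first")
    g = net.graph
    base = _classify(g)

    ambiguous: set[str] = set()
    for entry in net.resolution_log:
        removed = entry["removed"]
        for alt in entry["cycle_edges"]:
            if alt == removed or not g.has_edge(*alt):
                continue
            g_alt = g.copy()
            g_alt.add_edge(*removed)
            g_alt.remove_edge(*alt)
            for n, cls in _classify(g_alt).items():
                if cls != base[n]:
                    ambiguous.add(n)

    def hap_id(node: str) -> int:
        return int(node[1:])

    interiors = sorted(n for n, c in base.items() if c == "interior")
    tips = sorted(n for n, c in base.items() if c == "tip")
    int_unamb = [hap_id(n) for n in interiors if n not in ambiguous]
    int_amb = sorted({hap_id(n) for n in interiors if n in ambiguous}
                     | {hap_id(n) for n in tips if n in ambiguous})
    tip_ids = [hap_id(n) for n in tips if n not in ambiguous]

    def freq(i: int) -> int:
        return net.haplotypes[i].frequency

    classes = {"interior_unambiguous": int_unamb,
               "interior_ambiguous": int_amb,
               "tip": tip_ids}
    samples = {k: sum(freq(i) for i in v) for k, v in classes.items()}
    mean = {k: (samples[k] / len(v) if v else 0.0)
            for k, v in classes.items()}
    singles = {k: sum(1 for i in v if freq(i) == 1)
               for k, v in classes.items()}
    frac = {k: (singles[k] / len(v) if v else 0.0)
            for k, v in classes.items()}
    ratio = {k: (singles[k] / (len(v) - singles[k])
                 if len(v) > singles[k] else float("inf") if v else 0.0)
             for k, v in classes.items()}

    n_int_samples = samples["interior_unambiguous"] + \
        samples["interior_ambiguous"]
    test = None
    if n_int_samples + samples["tip"] > 0:
        test = chisq_gof([n_int_samples, samples["tip"]])

    region_counts: dict[str, int] = {}
    region_exclusive: dict[str, int] = {}
    for h in net.haplotypes.values():
        regions = sorted(set(h.areas))
        for r in regions:
            region_counts[r] = region_counts.get(r, 0) + 1
            if len(regions) == 1:
                region_exclusive[r] = region_exclusive.get(r, 0) + 1
    return NetworkStats(
        interior_unambiguous=sorted(int_unamb),
        interior_ambiguous=sorted(int_amb),
        tips=sorted(tip_ids),
        samples_per_class=samples,
        mean_samples=mean,
        singleton_fraction=frac,
        singleton_ratio=ratio,
        interior_vs_tip_test=test,
        region_haplotype_counts=region_counts,
        region_exclusive_counts=region_exclusive,
    )


@dataclass
class OutgroupConnection:
    """Nearest ingroup haplotype(s) to the outgroup and the number of
    unsampled intermediates that connection needs."""

    haplotype_ids: list[int]
    steps: int
    intermediates: int


def outgroup_connection(haps: Sequence[Haplotype], outgroup_seq: str
                        ) -> OutgroupConnection:
    if not haps:
        raise ValueError("no ingroup haplotypes")
    if len(outgroup_seq) != len(haps[0].sequence):
        raise ValueError("outgroup sequence length does not match the "
                         "ingroup alignment")
    dists = {h.id: step_distance(h.sequence, outgroup_seq) for h in haps}
    dmin = min(dists.values())
    ids = sorted(i for i, d in dists.items() if d == dmin)
    return OutgroupConnection(haplotype_ids=ids, steps=dmin,
                              intermediates=max(dmin - 1, 0))
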
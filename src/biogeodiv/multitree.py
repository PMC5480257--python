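"""Multi-tree DEC summarization with the incongruence-grouping rule.

Ancestral-range probabilities estimated on a single tree are fragile when
the clade's phylogenetic placement is uncertain, so the DEC analysis is run
across a posterior sample of trees and scenario probabilities are averaged
per clade over the trees where the clade exists. When the same descendant
assignment is the per-tree top pattern in (nearly) every tree the split is
reported as congruent; otherwise split patterns are grouped by their
ancestral range (the union of the two descendant ranges) and the grouped
mean probabilities are reported for the node alone. Example: top patterns
E|D (0.39), D|E (0.16) and ED|D (0.14) all imply ancestor ED, which is
reported with mean probability 0.69.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .dec import AreaSystem, DECModel, DECParams, range_label
from .treeio import CladeDefinition, TimeTree, locate_clade

__all__ = [
    "TreeScenarioRecord",
    "NodeRangeSummary",
    "run_multitree",
    "summarize_node",
    "write_summary_report",
]

Pattern = tuple[frozenset, frozenset]


@dataclass
class TreeScenarioRecord:
    """Per-tree outcome for one clade: either absent, or the scenario
    probability table keyed by (left_range, right_range)."""

    present: bool
    patterns: dict[Pattern, float] = field(default_factory=dict)
    params: Optional[DECParams] = None
    llf: Optional[float] = None


@dataclass
class NodeRangeSummary:
    """Posterior-averaged biogeographic summary for one clade."""

    clade_name: str
    n_trees_present: int
    n_trees_total: int
    pattern_mode: str                      # 'congruent-split' | 'grouped-range'
    split_table: dict[Pattern, float]      # mean prob per split pattern
    range_table: dict[frozenset, float]    # grouped by ancestor range
    top_range: Optional[frozenset]
    top_prob: float
    top_pattern: Optional[Pattern] = None
    congruence_fraction: float = 0.0
    tie_flag: bool = False

    def as_dict(self, system: AreaSystem) -> dict:
        return {
            "clade": self.clade_name,
            "n_trees_present": self.n_trees_present,
            "n_trees_total": self.n_trees_total,
            "pattern_mode": self.pattern_mode,
            "split_table": {
                f"{range_label(l, system)}|{range_label(r, system)}": p
                for (l, r), p in sorted(
                    self.split_table.items(),
                    key=lambda kv: (-kv[1], str(kv[0])))},
            "range_table": {
                range_label(r, system): p
                for r, p in sorted(self.range_table.items(),
                                   key=lambda kv: (-kv[1], str(kv[0])))},
            "top_range": (range_label(self.top_range, system)
                          if self.top_range is not None else None),
            "top_prob": self.top_prob,
            "top_pattern": (
                f"{range_label(self.top_pattern[0], system)}|"
                f"{range_label(self.top_pattern[1], system)}"
                if self.top_pattern else None),
            "congruence_fraction": self.congruence_fraction,
            "tie_flag": self.tie_flag,
        }


def run_multitree(trees: Sequence[TimeTree],
                  tip_ranges: Mapping[str, frozenset],
                  system: AreaSystem,
                  clades: Sequence[CladeDefinition],
                  params_mode: str = "per-tree-ml",
                  fixed_params: Optional[DECParams] = None,
                  seed: int = 0,
                  fit_kwargs: Optional[dict] = None,
                  ) -> dict[str, list[TreeScenarioRecord]]:
    """Run DEC over a posterior tree sample and collect per-clade
    scenario tables.

    ``params_mode='per-tree-ml'`` refits (d, e) on every tree;
    ``'fixed'`` reuses ``fixed_params`` throughout (fitting them once on a
    summary tree is the caller's choice). Trees where a clade is absent
    (or non-monophyletic, when required) are recorded as such and excluded
    from that clade's averages.
    """
    if not trees:
        raise ValueError("need at least one tree")
    if params_mode not in ("per-tree-ml", "fixed"):
        raise ValueError("params_mode must be 'per-tree-ml' or 'fixed'")
    if params_mode == "fixed" and fixed_params is None:
        raise ValueError("fixed params_mode needs fixed_params")
    fit_kwargs = dict(fit_kwargs or {})
    out: dict[str, list[TreeScenarioRecord]] = {c.name: [] for c in clades}
    for i, tree in enumerate(trees):
        ranges_here = {t: tip_ranges[t] for t in tree.tip_labels}
        model = DECModel(tree, ranges_here, system)
        if params_mode == "per-tree-ml":
            res = model.fit(seed=seed + i, **fit_kwargs)
            params, llf = res.params, res.llf
        else:
            params, llf = fixed_params, None
        for clade in clades:
            node = locate_clade(tree, clade)
            if node is None:
                out[clade.name].append(TreeScenarioRecord(present=False))
                continue
            scns = model.node_split_probs(params, node)
            patterns = {(s.left_range, s.right_range): s.rel_prob
                        for s in scns}
            out[clade.name].append(TreeScenarioRecord(
                present=True, patterns=patterns, params=params, llf=llf))
    return out


def summarize_node(records: Sequence[TreeScenarioRecord],
                   clade_name: str = "node",
                   congruence_threshold: float = 0.95,
                   ) -> NodeRangeSummary:
    """Average per-tree scenario tables and apply the grouping rule.

    Means are taken over trees where the clade is present (absent trees
    contribute nothing, not zeros). The grouped range table is always
    computed — each split pattern's mean probability is credited to its
    ancestral range (union of the descendant ranges) — and ``top_range``
    is its argmax; ``pattern_mode`` records whether the same top split
    pattern recurred in at least ``congruence_threshold`` of the trees.
    """
    if not records:
        raise ValueError("no records to summarize")
    present = [r for r in records if r.present]
    n_present = len(present)
    if n_present == 0:
        return NodeRangeSummary(
            clade_name=clade_name, n_trees_present=0,
            n_trees_total=len(records), pattern_mode="grouped-range",
            split_table={}, range_table={}, top_range=None, top_prob=0.0)

    split_table: dict[Pattern, float] = {}
    for rec in present:
        for pat, p in rec.patterns.items():
            split_table[pat] = split_table.get(pat, 0.0) + p
    split_table = {pat: s / n_present for pat, s in split_table.items()}

    # per-tree top pattern consistency
    tops = []
    for rec in present:
        if rec.patterns:
            tops.append(max(rec.patterns.items(),
                            key=lambda kv: (kv[1], str(sorted(kv[0][0])),
                                            str(sorted(kv[0][1]))))[0])
    top_counts: dict[Pattern, int] = {}
    for t in tops:
        top_counts[t] = top_counts.get(t, 0) + 1
    best_top, best_n = max(top_counts.items(),
                           key=lambda kv: (kv[1], str(kv[0])))
    frac = best_n / n_present
    congruent = frac >= congruence_threshold

    range_table: dict[frozenset, float] = {}
    for (l, r), p in split_table.items():
        anc = l | r
        range_table[anc] = range_table.get(anc, 0.0) + p

    top_prob = max(range_table.values())
    ties = sorted((r for r, p in range_table.items()
                   if abs(p - top_prob) <= 1e-12),
                  key=lambda r: sorted(r))
    top_range = ties[0]
    return NodeRangeSummary(
        clade_name=clade_name,
        n_trees_present=n_present,
        n_trees_total=len(records),
        pattern_mode="congruent-split" if congruent else "grouped-range",
        split_table=split_table,
        range_table=range_table,
        top_range=top_range,
        top_prob=float(top_prob),
        top_pattern=best_top if congruent else None,
        congruence_fraction=frac,
        tie_flag=len(ties) > 1,
    )


def summarize_all(raw: Mapping[str, Sequence[TreeScenarioRecord]],
                  congruence_threshold: float = 0.95
                  ) -> list[NodeRangeSummary]:
    return [summarize_node(records, clade_name=name,
                           congruence_threshold=congruence_threshold)
            for name, records in raw.items()]


def write_summary_report(summaries: Sequence[NodeRangeSummary],
                         system: AreaSystem,
                         json_path: Optional[str | Path] = None,
                         text_path: Optional[str | Path] = None) -> str:
    """JSON (full precision) plus a human-readable node table.

    Text probabilities use round-half-even to two decimals.
    """
    payload = [s.as_dict(system) for s in summaries]
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    lines = ["clade\trange\tmean_prob\tmode\tn_trees_present/total"]
    for s in summaries:
        if s.n_trees_present == 0:
            lines.append(f"{s.clade_name}\tabsent in all trees\t-\t-\t"
                         f"0/{s.n_trees_total}")
            continue
        if s.pattern_mode == "congruent-split" and s.top_pattern:
            l, r = s.top_pattern
            rng = (f"{range_label(l | r, system)} "
                   f"[{range_label(l, system)}|{range_label(r, system)}]")
            prob = s.split_table[s.top_pattern]
        else:
            rng = range_label(s.top_range, system)
            prob = s.top_prob
        lines.append(
            f"{s.clade_name}\t{rng}\t{round(prob, 2)}\t"
            f"{s.pattern_mode}\t{s.n_trees_present}/{s.n_trees_total}")
    text = "\n".join(lines) + "\n"
    if text_path is not None:
        Path(text_path).write_text(text)
    return text
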
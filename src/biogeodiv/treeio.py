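"""Tree and table input/output, pruning and clade location.

All trees are rooted ultrametric chronograms with branch lengths in Myr.
Parsing is delegated to dendropy; this module adds the validation,
pruning-to-representatives and taxon-set clade tracking the downstream
biogeographic and diversification stages rely on.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "TipTable",
    "CladeDefinition",
    "TreeFormatError",
    "TreeValidationError",
    "read_trees",
    "write_trees",
    "read_tip_table",
    "prune_to_representatives",
    "prune_to_tips",
    "locate_clade",
    "subsample_trees",
    "resolve_polytomies",
]

ULTRAMETRIC_TOL_FACTOR = 1e-6


class TreeFormatError(ValueError):
    """Raised when a tree file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


class UltrametricityWarning(UserWarning):
    """Emitted when root-to-tip path lengths differ beyond tolerance."""


class TimeTree:
    """A rooted time-calibrated tree (branch lengths in Myr).

    Thin wrapper around a :class:`dendropy.Tree` that enforces unique tip
    labels and non-negative branch lengths, and checks ultrametricity to a
    tolerance of ``1e-6 x root age`` (warning, not error, beyond it).
    """

    def __init__(self, tree: dendropy.Tree, check: bool = True):
        self.tree = tree
        self.tree.is_rooted = True
        if check:
            self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, check: bool = True) -> "TimeTree":
        try:
            t = dendropy.Tree.get(data=newick, schema="newick",
                                  rooting="default-rooted",
                                  suppress_internal_node_taxa=True)
        except Exception as exc:
            if "multiple" in str(exc).lower():
                raise TreeValidationError(
                    f"duplicate tip labels: {exc}") from exc
            raise TreeFormatError(f"cannot parse newick: {exc}") from exc
        return cls(t, check=check)

    def clone(self) -> "TimeTree":
        return TimeTree(self.tree.clone(depth=1), check=False)

    # -- basic views --------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def root_age(self) -> float:
        return max(self._tip_depths().values(), default=0.0)

    @property
    def stem_length(self) -> Optional[float]:
        e = self.tree.seed_node.edge
        return e.length if e is not None and e.length else None

    def is_binary(self) -> bool:
        for nd in self.tree.preorder_node_iter():
            if nd.is_internal() and len(nd.child_nodes()) != 2:
                return False
        return True

    def _tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        for lf in self.tree.leaf_node_iter():
            depths[lf.taxon.label] = lf.root_distance
        return depths

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Age (Myr before present) of every node; tips are ~0."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        root_age = max(lf.root_distance for lf in self.tree.leaf_node_iter())
        return {nd: root_age - nd.root_distance
                for nd in self.tree.preorder_node_iter()}

    # -- validation ---------------------------------------------------
    def validate(self) -> list[str]:
        labels = self.tip_labels
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(
                f"duplicate tip labels: {sorted(dupes)}")
        for nd in self.tree.preorder_node_iter():
            if nd.edge.length is not None and nd.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length at edge above "
                    f"{nd.taxon.label if nd.taxon else 'internal node'}")
        msgs: list[str] = []
        depths = list(self._tip_depths().values())
        if depths:
            root_age = max(depths)
            tol = ULTRAMETRIC_TOL_FACTOR * max(root_age, 1e-300)
            if max(depths) - min(depths) > tol:
                msg = (f"tree is not ultrametric: root-to-tip depths span "
                       f"[{min(depths):g}, {max(depths):g}]")
                msgs.append(msg)
                warnings.warn(msg, UltrametricityWarning, stacklevel=2)
        return msgs

    def is_ultrametric(self) -> bool:
        depths = list(self._tip_depths().values())
        if not depths:
            return True
        return max(depths) - min(depths) <= ULTRAMETRIC_TOL_FACTOR * max(depths)

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True,
            real_value_format_specifier=".17g").strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree n_tips={self.n_tips} root_age={self.root_age:.4g}>"


# ---------------------------------------------------------------------------
# tabular metadata
# ---------------------------------------------------------------------------

@dataclass
class TipTable:
    """Tip metadata: taxon assignment, area codes and optional ploidy.

    Backed by a DataFrame with columns ``tip_label``, ``taxon``, ``areas``
    (concatenated single-letter codes, e.g. ``"DE"``) and optionally
    ``lineage`` and ``ploidy``.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"tip_label", "taxon"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"tip table missing columns: {sorted(missing)}")
        if self.frame["tip_label"].duplicated().any():
            dup = self.frame.loc[self.frame["tip_label"].duplicated(),
                                 "tip_label"].tolist()
            raise ValueError(f"duplicate tip labels in table: {dup}")

    @property
    def tip_labels(self) -> list[str]:
        return self.frame["tip_label"].tolist()

    def areas_for(self, tip_label: str) -> frozenset[str]:
        row = self.frame.loc[self.frame["tip_label"] == tip_label]
        if row.empty:
            raise KeyError(f"tip {tip_label!r} not in table")
        areas = row["areas"].iloc[0]
        if pd.isna(areas) or not str(areas):
            return frozenset()
        return frozenset(str(areas))

    def tip_ranges(self) -> dict[str, frozenset[str]]:
        return {t: self.areas_for(t) for t in self.tip_labels}

    def validate_against(self, tree: TimeTree,
                         area_alphabet: Optional[Iterable[str]] = None
                         ) -> list[str]:
        """Return a list of fatal inconsistency messages (empty = OK)."""
        problems = []
        tree_tips = set(tree.tip_labels)
        table_tips = set(self.tip_labels)
        for t in sorted(tree_tips - table_tips):
            problems.append(f"tip {t!r} present in tree but absent from table")
        if area_alphabet is not None:
            alpha = set(area_alphabet)
            for t in sorted(table_tips & tree_tips):
                bad = self.areas_for(t) - alpha
                if bad:
                    problems.append(
                        f"tip {t!r} has area codes outside alphabet: "
                        f"{sorted(bad)}")
        return problems


def read_tip_table(path: str | Path) -> TipTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return TipTable(frame)


@dataclass(frozen=True)
class CladeDefinition:
    """A clade tracked across trees by its member taxon set."""

    name: str
    member_taxa: frozenset[str]
    require_monophyly: bool = True

    def __post_init__(self):
        if len(self.member_taxa) < 2:
            raise ValueError("a clade needs at least two member taxa")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s:
                return "nexus" if s.upper().startswith("#NEXUS") else "newick"
    raise TreeFormatError(f"{path}: empty file")


def read_trees(path: str | Path, format: Optional[str] = None,
               check: bool = True) -> list[TimeTree]:
    """Read all trees from a newick or NEXUS file, preserving order.

    Ultrametricity is checked but violations only warn; duplicate tip
    labels or parse failures raise.
    """
    path = Path(path)
    schema = format or _detect_format(path)
    try:
        tl = dendropy.TreeList.get(path=str(path), schema=schema,
                                   rooting="default-rooted",
                                   suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises many error types
        raise TreeFormatError(f"{path}: cannot parse as {schema}: {exc}")
    if not tl:
        raise TreeFormatError(f"{path}: no trees found")
    return [TimeTree(t, check=check) for t in tl]


def write_trees(trees: Sequence[TimeTree], path: str | Path,
                format: str = "newick") -> None:
    path = Path(path)
    tl = dendropy.TreeList()
    for t in trees:
        tl.append(t.tree.clone(depth=1), taxon_import_strategy="add")
    kwargs = dict(real_value_format_specifier=".17g")
    if format == "newick":
        kwargs["suppress_rooting"] = True
    tl.write(path=str(path), schema=format, **kwargs)


# ---------------------------------------------------------------------------
# pruning and clade tracking
# ---------------------------------------------------------------------------

def prune_to_tips(tree: TimeTree, keep: Iterable[str]) -> TimeTree:
    """Prune to the given tips, merging branch lengths through removed
    degree-2 nodes (root-to-tip depths of retained tips are conserved)."""
    keep = list(keep)
    missing = sorted(set(keep) - set(tree.tip_labels))
    if missing:
        raise TreeValidationError(f"tips not in tree: {missing}")
    t = tree.tree.clone(depth=1)
    t.retain_taxa_with_labels(keep)
    # dendropy can leave an unifurcation at the seed node; merge it into
    # the root edge so depths below stay intact and record stem length.
    t.suppress_unifurcations()
    return TimeTree(t, check=False)


def prune_to_representatives(tree: TimeTree, table: TipTable,
                             one_per: str = "taxon") -> TimeTree:
    """Keep exactly one tip per taxon (or per declared species-lineage).

    ``one_per='lineage'`` groups by ``(taxon, lineage)`` using the table's
    ``lineage`` column, which is how non-monophyletic species keep one tip
    per lineage. The representative is the alphabetically first tip label
    of each group (deterministic).
    """
    if one_per not in ("taxon", "lineage"):
        raise ValueError("one_per must be 'taxon' or 'lineage'")
    frame = table.frame
    in_tree = frame[frame["tip_label"].isin(set(tree.tip_labels))]
    if one_per == "lineage":
        if "lineage" not in frame.columns:
            raise ValueError("tip table has no 'lineage' column")
        key = [in_tree["taxon"], in_tree["lineage"].fillna("")]
    else:
        key = [in_tree["taxon"]]
    groups = in_tree.groupby(key, dropna=False)["tip_label"]
    all_key = frame.groupby(
        [frame["taxon"], frame["lineage"].fillna("")] if one_per == "lineage"
        and "lineage" in frame.columns else [frame["taxon"]],
        dropna=False).groups.keys()
    empty = sorted(set(all_key) - set(groups.groups.keys()))
    if empty:
        raise TreeValidationError(
            f"taxa/lineages with zero tips in tree: {empty}")
    keep = sorted(groups.min())
    return prune_to_tips(tree, keep)


def locate_clade(tree: TimeTree, clade: CladeDefinition
                 ) -> Optional[dendropy.Node]:
    """MRCA of the clade's member taxa; ``None`` when monophyly is required
    and the MRCA subtends extra tips (a recorded, countable outcome)."""
    members = set(clade.member_taxa)
    missing = sorted(members - set(tree.tip_labels))
    if missing:
        raise TreeValidationError(
            f"clade {clade.name!r}: member taxa missing from tree: {missing}")
    node = tree.tree.mrca(taxon_labels=sorted(members))
    if node is None:
        return None
    if clade.require_monophyly:
        under = {lf.taxon.label for lf in node.leaf_iter()}
        if under != members:
            return None
    return node


def subsample_trees(trees: Sequence[TimeTree], n: int, seed: int
                    ) -> list[TimeTree]:
    """Uniform subsample without replacement (seeded, order-preserving)."""
    if n > len(trees):
        raise ValueError(f"cannot subsample {n} from {len(trees)} trees")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(trees), size=n, replace=False))
    return [trees[i] for i in idx]


def resolve_polytomies(tree: TimeTree, seed: int) -> TimeTree:
    """Opt-in random resolution of polytomies with zero-length branches.

    DEC and diversification stages require binary trees; the default
    elsewhere is to reject non-binary input with a clear error.
    """
    t = tree.tree.clone(depth=1)
    t.resolve_polytomies(rng=random.Random(seed))
    for nd in t.preorder_node_iter():
        if nd.edge.length is None and nd.parent_node is not None:
            nd.edge.length = 0.0
    return TimeTree(t, check=False)
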
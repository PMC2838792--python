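"""Nested clades from the consensus network, and clade-derived affection.

Each internal node of the rooted consensus defines a clade (its descendant
leaves). Clades are labeled ``level_index``: levels count nesting depth with
the largest number at the most inclusive split (the root's children) and
decrease toward the leaves; the index enumerates clades within a level in
preorder. A family-count filter is applied a priori before linkage, and each
retained clade induces an affection coding: members affected, their scored
family members unaffected, unscored relatives unknown, families without any
member excluded from that clade's analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import CladelinkError, Pedigree, TraitMatrix
from .parsimony import PhenoTree

__all__ = ["Clade", "AffectionCoding", "nest_tree", "filter_clades",
           "affection_coding", "ASYMPTOMATIC"]

#: label of the artificial all-zero outgroup used to root the network
ASYMPTOMATIC = "ROOT:asymptomatic"


def _family_of(u: str) -> str:
    return u.split(":", 1)[0]


@dataclass(frozen=True)
class Clade:
    """A nested group of individuals (one internal node of the network)."""

    label: str
    level: int
    index: int
    members: frozenset[str]

    @property
    def n_families(self) -> int:
        return len({_family_of(u) for u in self.members})

    @property
    def family_ids(self) -> frozenset[str]:
        return frozenset(_family_of(u) for u in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AffectionCoding:
    """Per-individual affection derived from clade membership.

    ``status`` maps uid to "affected" / "unaffected" / "unknown" for members
    of analyzed families only; ``families`` lists the analyzed family ids
    (those contributing at least one clade member).
    """

    clade: Clade
    status: dict[str, str]
    families: list[str] = field(default_factory=list)

    def of(self, u: str) -> str:
        return self.status.get(u, "unknown")


def nest_tree(consensus: PhenoTree, outgroup: str = ASYMPTOMATIC) -> list[Clade]:
    """Extract the nested clades of a consensus network.

    The tree is rooted at ``outgroup`` (an artificial asymptomatic leaf by
    default, removed after rooting, or any real leaf uid); every internal
    node with >=2 descendant leaves becomes a clade. Level numbers decrease
    with depth so the most inclusive split carries the maximum level.
    """
    if consensus.n_leaves < 2:
        raise CladelinkError("consensus must have at least 2 leaves")
    if outgroup not in consensus.leaf_labels:
        raise CladelinkError(f"outgroup {outgroup!r} is not a leaf of the consensus")
    root, children = consensus.rooted_children(outgroup)
    labels = consensus.labels

    # descendant leaf sets and depths, iteratively
    leafset: dict[int, frozenset[str]] = {}
    order: list[int] = []
    stack = [root]
    depth = {root: 0}
    while stack:
        u = stack.pop()
        order.append(u)
        for w in children[u]:
            depth[w] = depth[u] + 1
            stack.append(w)
    for u in reversed(order):
        if not children[u]:
            leafset[u] = frozenset([labels[u]]) if u in labels else frozenset()
        else:
            s: set[str] = set()
            for w in children[u]:
                s |= leafset[w]
            if u in labels:
                s.add(labels[u])
            leafset[u] = frozenset(s)

    clade_nodes = [u for u in order
                   if u != root and children[u] and len(leafset[u]) >= 2]
    if not clade_nodes:
        return []
    depths = sorted({depth[u] for u in clade_nodes})
    rank = {d: i for i, d in enumerate(depths)}
    top = len(depths)
    # preorder enumeration per level, deterministic by construction order
    preorder: list[int] = []
    stack = [root]
    while stack:
        u = stack.pop()
        preorder.append(u)
        for w in reversed(children[u]):
            stack.append(w)
    counters: dict[int, int] = {}
    out: list[Clade] = []
    clade_set = set(clade_nodes)
    for u in preorder:
        if u not in clade_set:
            continue
        level = top - rank[depth[u]]
        idx = counters.get(level, 0)
        counters[level] = idx + 1
        out.append(Clade(f"{level}_{idx}", level, idx, leafset[u]))
    return out


def filter_clades(clades: Sequence[Clade], min_families: int = 40) -> list[Clade]:
    """Keep clades drawing members from at least ``min_families`` distinct
    families; applied before any linkage test."""
    return [c for c in clades if c.n_families >= min_families]


def affection_coding(clade: Clade, pedigree: Pedigree,
                     traits: TraitMatrix | None = None) -> AffectionCoding:
    """Affection status induced by a clade.

    Clade members are affected; their family members are unaffected when they
    carry symptom scores and unknown otherwise; families with no clade member
    are excluded from this clade's linkage run entirely.
    """
    if not clade.members:
        raise CladelinkError("empty clade")
    fams = sorted(f for f in clade.family_ids if f in pedigree.families)
    status: dict[str, str] = {}
    for fam in fams:
        for ind in pedigree.families[fam]:
            if ind.uid in clade.members:
                status[ind.uid] = "affected"
            elif traits is None or traits.is_scored(ind.uid):
                status[ind.uid] = "unaffected"
            else:
                status[ind.uid] = "unknown"
    return AffectionCoding(clade, status, fams)
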
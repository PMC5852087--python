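"""Rooted taxonomy trees with rank-aware ancestor queries.

A :class:`TaxonomyTree` is the container shared by the simulator, the
filtered-LCA classifier and the taxon-profile report.  It stores the parent
pointer, rank label and scientific name of every taxon id and answers
lineage / lowest-common-ancestor queries.  Trees round-trip through the NCBI
``nodes.dmp`` / ``names.dmp`` dump dialect (fields separated by ``\\t|\\t``,
lines terminated by ``\\t|``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

#: Canonical rank order from shallowest to deepest.  Ranks along any
#: root-to-leaf path must appear in this order (with "no rank" allowed for
#: the root itself).
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


class UnknownTaxonError(KeyError):
    """Raised when a taxon id is not present in the tree."""


@dataclass
class TaxonomyTree:
    """Rooted tree of taxa with ranks and names.

    Parameters
    ----------
    parent
        Maps each taxon id to its parent id.  The root maps to itself
        (NCBI convention: node 1 is its own parent).
    rank
        Maps each taxon id to a rank label ("family", "species", ... or
        "no rank" for the root).
    name
        Maps each taxon id to its scientific name.
    """

    parent: dict[int, int] = field(default_factory=dict)
    rank: dict[int, str] = field(default_factory=dict)
    name: dict[int, str] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    def add_node(self, taxid: int, parent: int, rank: str, name: str) -> None:
        self.parent[taxid] = parent
        self.rank[taxid] = rank
        self.name[taxid] = name

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        for taxid, par in self.parent.items():
            if taxid == par:
                return taxid
        raise ValueError("tree has no root (no self-parented node)")

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        roots = [t for t, p in self.parent.items() if t == p]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        for taxid, par in self.parent.items():
            if par not in self.parent:
                raise ValueError(f"parent {par} of {taxid} not in tree")
        for taxid in self.parent:
            depths = [
                _RANK_DEPTH[self.rank[t]]
                for t in self.lineage(taxid)
                if self.rank[t] in _RANK_DEPTH
            ]
            if depths != sorted(depths) or len(depths) != len(set(depths)):
                raise ValueError(
                    f"ranks along lineage of {taxid} are not strictly ordered"
                )

    # -- queries ----------------------------------------------------------

    def lineage(self, taxid: int) -> list[int]:
        """Root-to-node path of taxon ids (inclusive of both ends)."""
        if taxid not in self.parent:
            raise UnknownTaxonError(taxid)
        path = [taxid]
        seen = {taxid}
        while self.parent[path[-1]] != path[-1]:
            nxt = self.parent[path[-1]]
            if nxt in seen:  # cycle guard
                raise ValueError(f"cycle detected at taxon {nxt}")
            path.append(nxt)
            seen.add(nxt)
        path.reverse()
        return path

    def lineage_names(self, taxid: int) -> str:
        """Human-readable semicolon-joined lineage (root excluded)."""
        return ";".join(self.name[t] for t in self.lineage(taxid)[1:])

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Ancestor-or-self of ``taxid`` at ``rank``, or None if the
        lineage never reaches that rank (assignment above the rank)."""
        for t in self.lineage(taxid):
            if self.rank[t] == rank:
                return t
        return None

    def depth(self, taxid: int) -> int:
        return len(self.lineage(taxid)) - 1

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor: the deepest node that is an
        ancestor-or-self of every input taxon.

        Computed as the longest shared prefix of the root-to-node paths.
        ``lca({t})`` is ``t``; mixing taxa from different domains falls back
        to the root.
        """
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of empty taxon set is undefined")
        paths = [self.lineage(t) for t in taxa]
        anc = paths[0][0]
        for level in range(min(len(p) for p in paths)):
            node = paths[0][level]
            if all(p[level] == node for p in paths):
                anc = node
            else:
                break
        return anc

    def species(self) -> list[int]:
        return [t for t, r in self.rank.items() if r == "species"]

    # -- NCBI dump dialect ------------------------------------------------

    def to_ncbi_dumps(self, directory: str | os.PathLike) -> None:
        """Write ``nodes.dmp`` and ``names.dmp`` into *directory*."""
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "nodes.dmp"), "w") as fh:
            for taxid in sorted(self.parent):
                fh.write(
                    f"{taxid}\t|\t{self.parent[taxid]}\t|\t{self.rank[taxid]}\t|\n"
                )
        with open(os.path.join(directory, "names.dmp"), "w") as fh:
            for taxid in sorted(self.name):
                fh.write(
                    f"{taxid}\t|\t{self.name[taxid]}\t|\t\t|\tscientific name\t|\n"
                )

    @classmethod
    def from_ncbi_dumps(
        cls, nodes_path: str | os.PathLike, names_path: str | os.PathLike
    ) -> "TaxonomyTree":
        """Parse the ``nodes.dmp`` / ``names.dmp`` dump dialect."""
        tree = cls()
        with open(nodes_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\n").rstrip("\t|").split("\t|\t")]
                taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
                tree.parent[taxid] = parent
                tree.rank[taxid] = rank
        with open(names_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\n").rstrip("\t|").split("\t|\t")]
                taxid, name = int(fields[0]), fields[1]
                name_class = fields[3] if len(fields) > 3 else "scientific name"
                if name_class == "scientific name" or taxid not in tree.name:
                    tree.name[taxid] = name
        return tree
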
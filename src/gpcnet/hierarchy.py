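"""Knowledge hierarchy: parsing gene-set / edge files and building mask matrices.

The network's sparse connectivity is fixed *a priori* by curated biology:
genes belong to pathways, pathways involve compounds. This module turns the
two carrier files (a GMT gene-set file for gene->pathway membership and a
two-column TSV for pathway->compound edges) into a :class:`HierarchyMap` --
deterministic, lexicographically ordered index maps plus two binary mask
matrices that are Hadamard-multiplied with weight matrices downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("gpcnet.hierarchy")

__all__ = [
    "EdgeList",
    "HierarchyMap",
    "ParamCount",
    "load_gene_sets",
    "load_edges",
    "build_hierarchy",
    "count_parameters",
    "write_gene_sets",
    "write_edges",
]


class ParseError(ValueError):
    """Malformed knowledge file; message carries the 1-based line number."""


@dataclass
class EdgeList:
    """Parent -> children adjacency with insertion order and per-parent dedup."""

    groups: dict[str, list[str]] = field(default_factory=dict)

    def add(self, parent: str, child: str) -> None:
        parent = parent.strip()
        child = child.strip()
        if not parent or not child:
            raise ValueError("identifiers must be non-empty")
        members = self.groups.setdefault(parent, [])
        if child not in members:
            members.append(child)

    @property
    def parents(self) -> list[str]:
        return list(self.groups)

    def children_of(self, parent: str) -> list[str]:
        return list(self.groups.get(parent, []))

    def __len__(self) -> int:
        return len(self.groups)


def load_gene_sets(path: str | Path) -> EdgeList:
    """Parse a GMT file (set name, description, members...) into an EdgeList.

    Duplicate members within a line are dropped, keeping first occurrence.
    Lines with fewer than 3 tab-separated fields raise :class:`ParseError`.
    """
    edges = EdgeList()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, members...), got {len(fields)}"
                )
            name = fields[0]
            for member in fields[2:]:
                if member.strip():
                    edges.add(name, member)
            edges.groups.setdefault(name.strip(), [])
    return edges


def load_edges(path: str | Path) -> EdgeList:
    """Parse a 2-column TSV (parent, child); '#' lines are comments."""
    edges = EdgeList()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected exactly 2 tab-separated "
                    f"fields, got {len(fields)}"
                )
            edges.add(fields[0], fields[1])
    return edges


def write_gene_sets(edges: EdgeList, path: str | Path, description: str = "na") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for parent in sorted(edges.groups):
            members = "\t".join(edges.groups[parent])
            fh.write(f"{parent}\t{description}\t{members}\n")


def write_edges(edges: EdgeList, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for parent in sorted(edges.groups):
            for child in edges.groups[parent]:
                fh.write(f"{parent}\t{child}\n")


@dataclass
class HierarchyMap:
    """Index maps and binary masks defining the gene/pathway/compound wiring.

    ``mask_gp[g, p] == 1`` iff gene g belongs to pathway p; ``mask_pc[p, c] == 1``
    iff pathway p involves compound c. Index order is lexicographic over
    identifiers, so the layout is reproducible regardless of input file order.
    """

    gene_index: dict[str, int]
    pathway_index: dict[str, int]
    compound_index: dict[str, int]
    mask_gp: np.ndarray
    mask_pc: np.ndarray
    dropped_pathways: list[str] = field(default_factory=list)
    dropped_compounds: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_index)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_index)

    @property
    def genes(self) -> list[str]:
        return list(self.gene_index)

    @property
    def pathways(self) -> list[str]:
        return list(self.pathway_index)

    @property
    def compounds(self) -> list[str]:
        return list(self.compound_index)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update("|".join(self.gene_index).encode())
        h.update("|".join(self.pathway_index).encode())
        h.update("|".join(self.compound_index).encode())
        h.update(np.ascontiguousarray(self.mask_gp, dtype=np.uint8).tobytes())
        h.update(np.ascontiguousarray(self.mask_pc, dtype=np.uint8).tobytes())
        return h.hexdigest()

    def summary(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_pathways": self.n_pathways,
            "n_compounds": self.n_compounds,
            "nnz_gene_pathway": int(self.mask_gp.sum()),
            "nnz_pathway_compound": int(self.mask_pc.sum()),
            "dropped_pathways": list(self.dropped_pathways),
            "dropped_compounds": list(self.dropped_compounds),
            "hash": self.content_hash(),
        }

    def to_edge_lists(self) -> tuple[EdgeList, EdgeList]:
        """Inverse of :func:`build_hierarchy` for round-tripping to files."""
        gp = EdgeList()
        genes = self.genes
        for pw, j in self.pathway_index.items():
            gp.groups.setdefault(pw, [])
            for i in np.flatnonzero(self.mask_gp[:, j]):
                gp.add(pw, genes[i])
        pc = EdgeList()
        pathways = self.pathways
        compounds = self.compounds
        for pw, j in self.pathway_index.items():
            for k in np.flatnonzero(self.mask_pc[j, :]):
                pc.add(pathways[j], compounds[k])
        return gp, pc

    def write(self, gmt_path: str | Path, edges_path: str | Path) -> None:
        gp, pc = self.to_edge_lists()
        write_gene_sets(gp, gmt_path)
        write_edges(pc, edges_path)

    def write_summary(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


def build_hierarchy(
    gp: EdgeList,
    pc: EdgeList,
    gene_universe: Sequence[str],
    *,
    allow_empty_compound_layer: bool = False,
) -> HierarchyMap:
    """Assemble a HierarchyMap from edge lists restricted to ``gene_universe``.

    Pathways that map no gene in the universe are dropped (warning logged);
    compounds whose parent pathways were all dropped are dropped in turn, so
    every retained column of each mask has at least one nonzero entry.
    """
    if not gene_universe:
        raise ValueError("gene_universe must be non-empty")
    universe = [g.strip() for g in gene_universe]
    if len(set(universe)) != len(universe):
        raise ValueError("gene_universe contains duplicates")
    genes = sorted(universe)
    gene_index = {g: i for i, g in enumerate(genes)}

    kept_pathways: list[str] = []
    dropped_pathways: list[str] = []
    pathway_members: dict[str, list[str]] = {}
    for pw in gp.groups:
        members = [g for g in gp.groups[pw] if g in gene_index]
        if members:
            kept_pathways.append(pw)
            pathway_members[pw] = members
        else:
            dropped_pathways.append(pw)
    if not kept_pathways:
        raise ValueError("no pathway maps any gene in the gene universe")
    if dropped_pathways:
        logger.warning(
            "dropping %d pathway(s) with no genes in the universe: %s",
            len(dropped_pathways), ", ".join(sorted(dropped_pathways)),
        )
    kept_pathways.sort()
    pathway_index = {p: j for j, p in enumerate(kept_pathways)}

    kept_compounds: set[str] = set()
    dropped_compounds: set[str] = set()
    for pw in pc.groups:
        targets = pc.groups[pw]
        if pw in pathway_index:
            kept_compounds.update(targets)
        else:
            dropped_compounds.update(targets)
    dropped_compounds -= kept_compounds
    if dropped_compounds:
        logger.warning(
            "dropping %d compound(s) with no surviving parent pathway: %s",
            len(dropped_compounds), ", ".join(sorted(dropped_compounds)),
        )
    if not kept_compounds and not allow_empty_compound_layer:
        raise ValueError(
            "no compound is reachable from a retained pathway "
            "(set allow_empty_compound_layer=True to permit this)"
        )
    compounds = sorted(kept_compounds)
    compound_index = {c: k for k, c in enumerate(compounds)}

    mask_gp = np.zeros((len(genes), len(kept_pathways)), dtype=np.float64)
    for pw, members in pathway_members.items():
        j = pathway_index[pw]
        for g in members:
            mask_gp[gene_index[g], j] = 1.0
    mask_pc = np.zeros((len(kept_pathways), len(compounds)), dtype=np.float64)
    for pw in pc.groups:
        if pw not in pathway_index:
            continue
        j = pathway_index[pw]
        for c in pc.groups[pw]:
            mask_pc[j, compound_index[c]] = 1.0

    return HierarchyMap(
        gene_index=gene_index,
        pathway_index=pathway_index,
        compound_index=compound_index,
        mask_gp=mask_gp,
        mask_pc=mask_pc,
        dropped_pathways=sorted(dropped_pathways),
        dropped_compounds=sorted(dropped_compounds),
    )


@dataclass
class ParamCount:
    sparse: int
    dense: int
    detail: dict[str, int]


def count_parameters(h: HierarchyMap, per_gene_channels: int = 4) -> ParamCount:
    """Trainable-parameter counts of the masked network and its dense twin.

    Sparse count = nonzero mask entries + per-gene combiner weights + biases
    for every node + the three predictive heads (one weight per node in the
    layer plus a bias each). The dense count replaces both masks by all-ones.
    """
    g, p, c = h.n_genes, h.n_pathways, h.n_compounds
    detail = {
        "gene_combiner": g * per_gene_channels,
        "gene_pathway_weights": int(h.mask_gp.sum()),
        "pathway_compound_weights": int(h.mask_pc.sum()),
        "biases": g + p + c,
        "heads": (g + 1) + (p + 1) + (c + 1),
    }
    sparse = sum(detail.values())
    dense = sparse - detail["gene_pathway_weights"] - detail["pathway_compound_weights"] + g * p + p * c
    return ParamCount(sparse=sparse, dense=dense, detail=detail)
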
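"""Binary presence/absence matrices, per-genome ANF profiles, and the
core/dispensable/singleton pan-genome partition.

Two matrix modes mirror the two readings of a "gene count":

* ``enzyme`` mode — features are catalog enzymes; a genome's cell is 1 when
  it carries at least one hit for that enzyme (paralogs collapse).
* ``cluster`` mode — features are ortholog clusters containing at least one
  hit; paralogs appear as separate features only when BBH separates them.

The pan-genome partition counts each ortholog cluster by the number of
*distinct* genomes it spans: all genomes → core, exactly one → singleton,
anything in between → dispensable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .homology import GeneHit

__all__ = [
    "PresenceMatrix",
    "ANFProfile",
    "PanGenomePartition",
    "build_matrix",
    "profiles",
    "profiles_frame",
    "tally_category",
    "partition",
    "hits_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PresenceMatrix:
    """Genomes × features binary matrix with a feature→category map."""

    genome_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    cells: np.ndarray  # int array, shape (n_genomes, n_features), values 0/1
    feature_category: dict[str, str]
    mode: str  # "enzyme" | "cluster"

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        object.__setattr__(self, "cells", cells)
        if cells.shape != (len(self.genome_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {cells.shape} inconsistent with "
                f"{len(self.genome_ids)} genomes x {len(self.feature_ids)} features"
            )
        if cells.size and not np.isin(cells, (0, 1)).all():
            raise ValueError("matrix cells must be 0/1")
        missing = set(self.feature_ids) - set(self.feature_category)
        if missing:
            raise ValueError(f"features without category: {sorted(missing)}")

    def row(self, genome_id: str) -> np.ndarray:
        return self.cells[self.genome_ids.index(genome_id)]

    def category_columns(self, category_id: str) -> list[int]:
        return [
            j
            for j, f in enumerate(self.feature_ids)
            if self.feature_category[f] == category_id
        ]


@dataclass(frozen=True)
class ANFProfile:
    """Per-genome gene counts per ANF category."""

    genome_id: str
    genes_per_category: dict[str, int]
    total_genes: int
    categories_covered: int


@dataclass(frozen=True)
class PanGenomePartition:
    """Core / dispensable / singleton tallies over ortholog clusters."""

    n_genomes: int
    core_count: int
    singleton_count: int
    dispensable_count: int
    total_clusters: int

    def __post_init__(self) -> None:
        if self.core_count + self.singleton_count + self.dispensable_count != (
            self.total_clusters
        ):
            raise ValueError("partition counts do not sum to total_clusters")


def build_matrix(
    hits: list[GeneHit],
    genome_ids,
    mode: str = "enzyme",
    clusters=None,
) -> PresenceMatrix:
    """Build the binary matrix from screening hits.

    In ``cluster`` mode *clusters* (from
    :func:`~anfscreen.homology.cluster_orthologs`) must cover every hit
    protein; cluster features are named ``OC####`` in cluster order and
    inherit the category of their member hits — on conflict, the category of
    the highest-scoring member hit wins and a warning is logged.
    """
    genome_ids = tuple(genome_ids)
    known = set(genome_ids)
    for hit in hits:
        if hit.genome_id not in known:
            raise ValueError(f"hit references unknown genome id {hit.genome_id!r}")

    if mode == "enzyme":
        feature_ids = tuple(
            sorted({h.enzyme_id for h in hits})
        )
        # an enzyme belongs to exactly one category, so any hit's mapping works
        feature_category = {h.enzyme_id: h.category_id for h in hits}
        col = {f: j for j, f in enumerate(feature_ids)}
        cells = np.zeros((len(genome_ids), len(feature_ids)), dtype=int)
        row = {g: i for i, g in enumerate(genome_ids)}
        for h in hits:
            cells[row[h.genome_id], col[h.enzyme_id]] = 1
        return PresenceMatrix(genome_ids, feature_ids, cells, feature_category, mode)

    if mode != "cluster":
        raise ValueError(f"unknown matrix mode {mode!r}")
    if clusters is None:
        raise ValueError("cluster mode requires ortholog clusters")

    member_of: dict[tuple[str, str], int] = {}
    for idx, cluster in enumerate(clusters):
        for member in cluster:
            member_of[member] = idx
    # clusters containing >=1 hit, in cluster order
    hit_by_cluster: dict[int, list[GeneHit]] = {}
    for h in hits:
        key = (h.genome_id, h.protein_id)
        if key not in member_of:
            raise ValueError(
                f"hit protein {key} not covered by any ortholog cluster"
            )
        hit_by_cluster.setdefault(member_of[key], []).append(h)

    used = sorted(hit_by_cluster)
    width = max(4, len(str(len(clusters))))
    feature_ids = tuple(f"OC{idx:0{width}d}" for idx in used)
    feature_category = {}
    for fid, idx in zip(feature_ids, used):
        members = hit_by_cluster[idx]
        cats = {m.category_id for m in members}
        best = max(
            members,
            key=lambda m: (-np.inf if m.score is None else m.score, m.category_id),
        )
        if len(cats) > 1:
            logger.warning(
                "cluster %s spans categories %s; keeping %s (highest-scoring hit)",
                fid, sorted(cats), best.category_id,
            )
        feature_category[fid] = best.category_id
    row = {g: i for i, g in enumerate(genome_ids)}
    cells = np.zeros((len(genome_ids), len(feature_ids)), dtype=int)
    for j, idx in enumerate(used):
        for member in hit_by_cluster[idx]:
            cells[row[member.genome_id], j] = 1
    return PresenceMatrix(genome_ids, feature_ids, cells, feature_category, mode)


def profiles(matrix: PresenceMatrix) -> list[ANFProfile]:
    """Per-genome ANF profiles: distinct features per category, totals, and
    the number of categories covered."""
    categories = sorted(set(matrix.feature_category.values()))
    cols = {c: matrix.category_columns(c) for c in categories}
    out = []
    for i, gid in enumerate(matrix.genome_ids):
        per_cat = {
            c: int(matrix.cells[i, cols[c]].sum()) for c in categories
        }
        total = int(matrix.cells[i].sum())
        out.append(
            ANFProfile(
                genome_id=gid,
                genes_per_category=per_cat,
                total_genes=total,
                categories_covered=sum(1 for v in per_cat.values() if v),
            )
        )
    return out


def profiles_frame(matrix: PresenceMatrix) -> pd.DataFrame:
    """Profiles as a DataFrame (one row per genome, one column per
    category, plus ``total_genes`` and ``categories_covered``)."""
    profs = profiles(matrix)
    categories = sorted(set(matrix.feature_category.values()))
    rows = []
    for p in profs:
        row = {"genome_id": p.genome_id}
        row.update({c: p.genes_per_category.get(c, 0) for c in categories})
        row["total_genes"] = p.total_genes
        row["categories_covered"] = p.categories_covered
        rows.append(row)
    return pd.DataFrame(rows)


def tally_category(
    matrix: PresenceMatrix, category_id: str, min_features: int = 1
) -> int:
    """Number of genomes carrying ≥ *min_features* features of a category."""
    if category_id not in set(matrix.feature_category.values()):
        raise KeyError(f"unknown category {category_id!r}")
    if min_features < 1:
        raise ValueError("min_features must be >= 1")
    cols = matrix.category_columns(category_id)
    return int((matrix.cells[:, cols].sum(axis=1) >= min_features).sum())


def tally_by_group(
    matrix: PresenceMatrix,
    groups: dict[str, str],
    category_id: str,
    min_features: int = 1,
) -> dict[str, tuple[int, int]]:
    """Per-taxon-group ``(carriers, group size)`` for one category.

    *groups* maps genome_id → taxon group; genomes absent from the mapping
    are ignored.
    """
    if category_id not in set(matrix.feature_category.values()):
        raise KeyError(f"unknown category {category_id!r}")
    cols = matrix.category_columns(category_id)
    counts: dict[str, list[int]] = {}
    for i, gid in enumerate(matrix.genome_ids):
        group = groups.get(gid)
        if group is None:
            continue
        carrier = int(matrix.cells[i, cols].sum()) >= min_features
        entry = counts.setdefault(group, [0, 0])
        entry[0] += int(carrier)
        entry[1] += 1
    return {g: (c, n) for g, (c, n) in counts.items()}


def partition(clusters, n_genomes: int) -> PanGenomePartition:
    """Classify ortholog clusters as core / singleton / dispensable.

    A cluster is counted by the number of distinct genomes it spans; two
    paralogs from one genome still span one genome.
    """
    core = singleton = dispensable = 0
    for cluster in clusters:
        if not cluster:
            raise ValueError("empty ortholog cluster")
        span = len({genome_id for genome_id, _ in cluster})
        if span > n_genomes:
            raise ValueError(
                f"cluster spans {span} genomes but only {n_genomes} declared"
            )
        if span == n_genomes:
            core += 1
        elif span == 1:
            singleton += 1
        else:
            dispensable += 1
    return PanGenomePartition(
        n_genomes=n_genomes,
        core_count=core,
        singleton_count=singleton,
        dispensable_count=dispensable,
        total_clusters=core + singleton + dispensable,
    )


def hits_frame(hits: list[GeneHit]) -> pd.DataFrame:
    """Hits as a TSV-ready DataFrame."""
    return pd.DataFrame(
        [
            {
                "genome_id": h.genome_id,
                "protein_id": h.protein_id,
                "enzyme_id": h.enzyme_id,
                "category_id": h.category_id,
                "evidence": h.evidence,
                "identity": h.identity,
                "coverage": h.query_coverage,
                "score": h.score,
            }
            for h in hits
        ],
        columns=[
            "genome_id", "protein_id", "enzyme_id", "category_id",
            "evidence", "identity", "coverage", "score",
        ],
    )
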
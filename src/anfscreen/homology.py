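"""Detection of catalog enzymes in proteomes and BBH ortholog clustering.

Two evidence routes produce a :class:`GeneHit`:

* **keyword** — a catalog keyword occurs (case-insensitively, after
  whitespace normalisation) in the protein's product annotation;
* **homology** — global alignment against one of the enzyme's reference
  proteins reaches the identity and coverage thresholds (best-scoring
  reference kept).

By default alignment is only attempted for proteins that pass a keyword
prefilter (or have an empty product); ``full_scan=True`` aligns every
protein against every reference, which is the mode used to validate the
screen against planted synthetic genes.

Orthology across genomes is established by bidirectional best hits (BBH):
x in genome A and y in genome B are paired when each is the other's unique
highest-scoring partner among partners that pass the thresholds.  Ties are
broken by higher identity, then lexicographic protein id.  Multi-genome
ortholog clusters are the connected components of the union of all pairwise
BBH graphs; proteins without any BBH edge form singleton clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .align import (
    AlignmentParams,
    align_global,
    alignment_score,
    may_pass_thresholds,
)
from .catalog import ANFCatalog
from .io import GenomeRecord

__all__ = [
    "Thresholds",
    "GeneHit",
    "keyword_match",
    "screen_genome",
    "screen_collection",
    "bbh_pairs",
    "cluster_orthologs",
]


@dataclass(frozen=True)
class Thresholds:
    """Identity/coverage cut-offs for homology evidence (both sequences)."""

    min_identity: float = 0.40
    min_coverage: float = 0.70


@dataclass(frozen=True)
class GeneHit:
    """One detected enzyme gene in one genome.

    Alignment fields are ``None`` for keyword-only evidence.
    """

    genome_id: str
    protein_id: str
    enzyme_id: str
    category_id: str
    evidence: str  # "keyword" | "homology" | "both"
    identity: float | None = None
    query_coverage: float | None = None
    score: float | None = None


def keyword_match(product: str, keywords) -> bool:
    """True iff any keyword is a case-insensitive substring of *product*.

    Whitespace in the product is normalised to single spaces before
    matching, so line-wrapped annotations still match multi-word keywords.
    """
    normalized = " ".join(product.lower().split())
    return any(kw.lower() in normalized for kw in keywords)


def screen_genome(
    genome: GenomeRecord,
    catalog: ANFCatalog,
    thresholds: Thresholds = Thresholds(),
    full_scan: bool = False,
    params: AlignmentParams = AlignmentParams(),
) -> list[GeneHit]:
    """Screen one genome against the catalog; at most one hit per
    (protein, enzyme).

    Keyword evidence is tested first.  Alignment evidence is tested against
    each of the enzyme's reference proteins (the best-scoring passing
    reference is kept) for proteins that matched a keyword of *any* catalog
    enzyme or have an empty product — or for every protein when
    ``full_scan`` is set.
    """
    all_keywords = [kw for _, enz in catalog.iter_enzymes() for kw in enz.product_keywords]
    hits: list[GeneHit] = []
    for protein in genome.proteins:
        alignable = (
            full_scan
            or not protein.product
            or keyword_match(protein.product, all_keywords)
        )
        for cat in catalog.categories:
            for enz in cat.enzymes:
                kw_hit = keyword_match(protein.product, enz.product_keywords)
                best = None
                if alignable:
                    for _, ref_seq in enz.reference_proteins:
                        if not may_pass_thresholds(
                            protein.sequence, ref_seq,
                            thresholds.min_identity, thresholds.min_coverage,
                        ):
                            continue
                        res = align_global(protein.sequence, ref_seq, params)
                        if (
                            res.identity >= thresholds.min_identity
                            and res.query_coverage >= thresholds.min_coverage
                            and res.subject_coverage >= thresholds.min_coverage
                        ):
                            if best is None or res.score > best.score:
                                best = res
                if kw_hit and best is not None:
                    evidence = "both"
                elif kw_hit:
                    evidence = "keyword"
                elif best is not None:
                    evidence = "homology"
                else:
                    continue
                hits.append(
                    GeneHit(
                        genome_id=genome.genome_id,
                        protein_id=protein.protein_id,
                        enzyme_id=enz.enzyme_id,
                        category_id=cat.category_id,
                        evidence=evidence,
                        identity=None if best is None else best.identity,
                        query_coverage=None if best is None else best.query_coverage,
                        score=None if best is None else best.score,
                    )
                )
    return hits


def screen_collection(
    genomes,
    catalog: ANFCatalog,
    thresholds: Thresholds = Thresholds(),
    full_scan: bool = False,
    params: AlignmentParams = AlignmentParams(),
) -> list[GeneHit]:
    """Screen a list of genomes; concatenated hits in input genome order."""
    hits: list[GeneHit] = []
    for genome in genomes:
        hits.extend(screen_genome(genome, catalog, thresholds, full_scan, params))
    return hits


# ---------------------------------------------------------------------------
# BBH orthology


def _best_partner(
    query, candidates, thresholds: Thresholds, params: AlignmentParams
) -> str | None:
    """Best passing partner of *query* among *candidates*, or None.

    Ranking is score desc, then identity desc, then protein id asc — fully
    deterministic, so the best partner is always unique.
    """
    scored = []
    for cand in candidates:
        if cand.protein_id == query.protein_id and cand.genome_id == query.genome_id:
            continue
        if not may_pass_thresholds(
            query.sequence, cand.sequence,
            thresholds.min_identity, thresholds.min_coverage,
        ):
            continue
        scored.append((alignment_score(query.sequence, cand.sequence, params), cand))
    # walk candidates from highest score; traceback only until the winner is
    # settled (a strictly lower score can no longer tie the best passing hit)
    scored.sort(key=lambda t: (-t[0], t[1].protein_id))
    passing = []  # (score, identity, protein_id)
    for score, cand in scored:
        if passing and score < passing[0][0]:
            break
        res = align_global(query.sequence, cand.sequence, params)
        if (
            res.identity >= thresholds.min_identity
            and res.query_coverage >= thresholds.min_coverage
            and res.subject_coverage >= thresholds.min_coverage
        ):
            passing.append((score, res.identity, cand.protein_id))
    if not passing:
        return None
    passing.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return passing[0][2]


def bbh_pairs(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    thresholds: Thresholds = Thresholds(),
    params: AlignmentParams = AlignmentParams(),
) -> list[tuple[str, str]]:
    """Bidirectional best hits between two genomes.

    ``(x, y)`` is reported iff y is x's best passing partner in B and x is
    y's best passing partner in A (ties resolved by identity, then protein
    id).  Pairs are returned sorted by the A-side protein id.
    """
    if not genome_a.proteins or not genome_b.proteins:
        raise ValueError("bbh_pairs requires two non-empty genomes")
    best_ab: dict[str, str] = {}
    for x in genome_a.proteins:
        partner = _best_partner(x, genome_b.proteins, thresholds, params)
        if partner is not None:
            best_ab[x.protein_id] = partner
    pairs = []
    wanted_b = set(best_ab.values())
    for y in genome_b.proteins:
        if y.protein_id not in wanted_b:
            continue
        partner = _best_partner(y, genome_a.proteins, thresholds, params)
        if partner is None:
            continue
        if best_ab.get(partner) == y.protein_id:
            pairs.append((partner, y.protein_id))
    pairs.sort()
    return pairs


def cluster_orthologs(
    genomes,
    thresholds: Thresholds = Thresholds(),
    params: AlignmentParams = AlignmentParams(),
) -> list[frozenset[tuple[str, str]]]:
    """Ortholog clusters over ≥1 genomes.

    Clusters are connected components of the union of all pairwise BBH
    graphs; every protein of every genome lands in exactly one cluster
    (singletons included).  Output is deterministically ordered: clusters
    sorted by their smallest (genome_id, protein_id) member.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("cluster_orthologs requires at least one genome")
    graph: nx.Graph = nx.Graph()
    for genome in genomes:
        for protein in genome.proteins:
            graph.add_node((genome.genome_id, protein.protein_id))
    for ga, gb in itertools.combinations(genomes, 2):
        for pa, pb in bbh_pairs(ga, gb, thresholds, params):
            graph.add_edge((ga.genome_id, pa), (gb.genome_id, pb))
    components = [frozenset(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: min(c))
    return components
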
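import itertools
import random

import pytest

from anfscreen.align import AlignmentParams, align_global
from anfscreen.catalog import loads_catalog
from anfscreen.homology import (
    Thresholds,
    bbh_pairs,
    cluster_orthologs,
    keyword_match,
    screen_genome,
)
from anfscreen.io import GenomeRecord, ProteinRecord
from anfscreen.simulate import SyntheticConfig, generate_collection

from _oracles import UnionFind

AA = "ACDEFGHIKLMNPQRSTVWY"


def protein(pid, seq, gid="g", product=""):
    return ProteinRecord(protein_id=pid, genome_id=gid, product=product,
                         sequence=seq)


def genome(gid, proteins, group="grp"):
    return GenomeRecord(genome_id=gid, label=gid, taxon_group=group,
                        proteins=tuple(proteins))


def random_seq(rng, lo=60, hi=150):
    return "".join(rng.choice(AA) for _ in range(rng.randint(lo, hi)))


def mutate(seq, rate, rng):
    return "".join(
        rng.choice([c2 for c2 in AA if c2 != c]) if rng.random() < rate else c
        for c in seq
    )


# ---------------------------------------------------------------------------
# keyword matching


@pytest.mark.parametrize(
    "product,keywords,expected",
    [
        ("3-phytase precursor", ["phytase"], True),
        ("hypothetical protein", ["phytase"], False),
        ("Phenolic acid DECARBOXYLASE subunit B",
         ["phenolic acid decarboxylase"], True),
        ("", ["phytase"], False),
        ("phenolic\tacid   decarboxylase", ["phenolic acid decarboxylase"],
         True),  # whitespace normalisation
    ],
)
def test_keyword_match(product, keywords, expected):
    assert keyword_match(product, keywords) is expected


# ---------------------------------------------------------------------------
# screen_genome

KEYWORD_ONLY_CATALOG = loads_catalog("""
categories:
  - id: phytate
    name: Phytate
    enzymes:
      - id: phy
        name: phytase
        keywords: [phytase]
""")


def test_keyword_only_hit():
    g = genome("g1", [protein("p1", "MKT", product="putative phytase")])
    hits = screen_genome(g, KEYWORD_ONLY_CATALOG)
    assert len(hits) == 1
    assert hits[0].evidence == "keyword"
    assert hits[0].identity is None


def test_decoy_genome_yields_no_hits():
    g = genome("g1", [protein("p1", "MKTW", product="hypothetical protein")])
    assert screen_genome(g, KEYWORD_ONLY_CATALOG) == []


def test_planted_genes_recovered_full_scan(catalog):
    """Three planted genes mutated at 5% per residue are recovered in
    full-scan mode against the generator's truth table."""
    config = SyntheticConfig(
        n_genomes={"grp": 1},
        presence_prob={
            ("grp", "phytate_degradation"): 1.0,
            ("grp", "tannin_degradation"): 1.0,
            ("grp", "alpha_gos"): 1.0,
        },
        mutation_rate=0.05,
        n_decoys=10,
        annotated=False,
        seed=42,
    )
    genomes, truth = generate_collection(config, catalog)
    hits = screen_genome(genomes[0], catalog, full_scan=True)
    hit_keys = {(h.protein_id, h.enzyme_id) for h in hits}
    for row in truth:
        assert (row.protein_id, row.enzyme_id) in hit_keys
    assert all(h.evidence == "homology" for h in hits)
    truth_proteins = {r.protein_id for r in truth}
    assert {h.protein_id for h in hits} <= truth_proteins  # no decoy hits


def test_annotated_planted_gene_evidence_is_both(catalog):
    config = SyntheticConfig(
        n_genomes={"grp": 1},
        presence_prob={("grp", "tannin_degradation"): 1.0},
        mutation_rate=0.0,
        n_decoys=0,
        annotated=True,
        seed=1,
    )
    genomes, truth = generate_collection(config, catalog)
    hits = screen_genome(genomes[0], catalog, full_scan=True)
    by_key = {(h.protein_id, h.enzyme_id): h for h in hits}
    for row in truth:
        assert by_key[(row.protein_id, row.enzyme_id)].evidence == "both"


def test_raising_min_identity_is_monotone(catalog):
    config = SyntheticConfig(
        n_genomes={"grp": 3},
        presence_prob={(
            "grp", c): 1.0 for c in (
                "phytate_degradation", "myo_inositol", "alpha_gos")},
        mutation_rate=0.10,
        n_decoys=5,
        annotated=False,
        seed=3,
    )
    genomes, _ = generate_collection(config, catalog)
    counts = []
    for min_id in (0.3, 0.5, 0.7, 0.9, 0.99):
        n = sum(
            len(screen_genome(g, catalog, Thresholds(min_identity=min_id),
                              full_scan=True))
            for g in genomes
        )
        counts.append(n)
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# BBH


def _bbh_bruteforce(ga, gb, thresholds=Thresholds()):
    """All-vs-all reciprocal maxima with (score, identity, id) tie-break."""
    def best(query, others):
        ranked = []
        for o in others:
            res = align_global(query.sequence, o.sequence)
            if (
                res.identity >= thresholds.min_identity
                and res.query_coverage >= thresholds.min_coverage
                and res.subject_coverage >= thresholds.min_coverage
            ):
                ranked.append((-res.score, -res.identity, o.protein_id))
        if not ranked:
            return None
        return min(ranked)[2]

    pairs = []
    for x in ga.proteins:
        y = best(x, gb.proteins)
        if y is not None and best(
            next(p for p in gb.proteins if p.protein_id == y), ga.proteins
        ) == x.protein_id:
            pairs.append((x.protein_id, y))
    return sorted(pairs)


def test_bbh_identical_proteomes_pair_by_copy():
    rng = random.Random(5)
    seqs = [random_seq(rng) for _ in range(3)]
    ga = genome("A", [protein(f"a{i}", s, "A") for i, s in enumerate(seqs)])
    gb = genome("B", [protein(f"b{i}", s, "B") for i, s in enumerate(seqs)])
    assert bbh_pairs(ga, gb) == [("a0", "b0"), ("a1", "b1"), ("a2", "b2")]


def test_bbh_unrelated_protein_unpaired():
    rng = random.Random(6)
    shared = random_seq(rng)
    ga = genome("A", [protein("a0", shared, "A"),
                      protein("a1", random_seq(rng), "A")])
    gb = genome("B", [protein("b0", shared, "B")])
    assert bbh_pairs(ga, gb) == [("a0", "b0")]


def test_bbh_matches_bruteforce_oracle():
    rng = random.Random(11)
    family = random_seq(rng, 80, 120)
    ga = genome("A", [protein("a0", mutate(family, 0.1, rng), "A"),
                      protein("a1", random_seq(rng), "A")])
    gb = genome("B", [protein("b0", mutate(family, 0.1, rng), "B"),
                      protein("b1", random_seq(rng), "B")])
    result = bbh_pairs(ga, gb)
    assert result == _bbh_bruteforce(ga, gb)
    assert result == [("a0", "b0")]


def test_bbh_symmetric():
    rng = random.Random(17)
    fam1, fam2 = random_seq(rng), random_seq(rng)
    ga = genome("A", [protein("a0", mutate(fam1, 0.08, rng), "A"),
                      protein("a1", mutate(fam2, 0.08, rng), "A")])
    gb = genome("B", [protein("b0", mutate(fam1, 0.08, rng), "B"),
                      protein("b1", mutate(fam2, 0.08, rng), "B")])
    ab = bbh_pairs(ga, gb)
    ba = bbh_pairs(gb, ga)
    assert sorted((y, x) for x, y in ab) == sorted(ba)


def test_bbh_empty_genome_rejected():
    rng = random.Random(1)
    ga = genome("A", [protein("a0", random_seq(rng), "A")])
    with pytest.raises(ValueError):
        bbh_pairs(ga, genome("B", []))


# ---------------------------------------------------------------------------
# ortholog clustering


def test_single_family_across_three_genomes_is_one_cluster():
    rng = random.Random(23)
    family = random_seq(rng, 80, 120)
    genomes = [
        genome(gid, [protein(f"{gid}_p", mutate(family, 0.05, rng), gid)])
        for gid in ("A", "B", "C")
    ]
    clusters = cluster_orthologs(genomes)
    assert len(clusters) == 1
    assert len(clusters[0]) == 3


def test_unrelated_proteomes_all_singletons():
    rng = random.Random(29)
    genomes = [
        genome(gid, [protein(f"{gid}_{i}", random_seq(rng), gid)
                     for i in range(3)])
        for gid in ("A", "B")
    ]
    clusters = cluster_orthologs(genomes)
    assert len(clusters) == 6
    assert all(len(c) == 1 for c in clusters)


def test_clusters_match_unionfind_over_bbh_edges():
    rng = random.Random(31)
    fam1, fam2 = random_seq(rng), random_seq(rng)
    genomes = []
    for gid in ("A", "B", "C", "D"):
        prots = [protein(f"{gid}_f1", mutate(fam1, 0.07, rng), gid),
                 protein(f"{gid}_f2", mutate(fam2, 0.07, rng), gid),
                 protein(f"{gid}_dec", random_seq(rng), gid)]
        genomes.append(genome(gid, prots))
    clusters = cluster_orthologs(genomes)

    nodes = [(g.genome_id, p.protein_id) for g in genomes for p in g.proteins]
    uf = UnionFind(nodes)
    for ga, gb in itertools.combinations(genomes, 2):
        for pa, pb in bbh_pairs(ga, gb):
            uf.union((ga.genome_id, pa), (gb.genome_id, pb))
    assert sorted(clusters, key=min) == sorted(uf.components(), key=min)


def test_cluster_sizes_conserve_protein_count():
    rng = random.Random(37)
    fam = random_seq(rng)
    genomes = [
        genome(gid, [protein(f"{gid}_0", mutate(fam, 0.05, rng), gid),
                     protein(f"{gid}_1", random_seq(rng), gid)])
        for gid in ("A", "B", "C")
    ]
    clusters = cluster_orthologs(genomes)
    assert sum(len(c) for c in clusters) == sum(len(g) for g in genomes)
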
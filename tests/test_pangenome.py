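import numpy as np
import pytest

from anfscreen.homology import GeneHit
from anfscreen.pangenome import (
    PanGenomePartition,
    PresenceMatrix,
    build_matrix,
    partition,
    profiles,
    profiles_frame,
    tally_by_group,
    tally_category,
)

from conftest import random_matrix


def hit(g, e, cat=None, pid=None, score=None):
    return GeneHit(
        genome_id=g,
        protein_id=pid or f"{g}_{e}",
        enzyme_id=e,
        category_id=cat or f"cat_{e}",
        evidence="keyword",
        score=score,
    )


# ---------------------------------------------------------------------------
# build_matrix


def test_enzyme_mode_rows():
    hits = [hit("g1", "phy"), hit("g1", "tan"), hit("g2", "phy")]
    m = build_matrix(hits, ["g1", "g2"])
    assert m.feature_ids == ("phy", "tan")
    assert m.cells.tolist() == [[1, 1], [1, 0]]


def test_empty_hits_gives_zero_width_matrix():
    m = build_matrix([], ["g1", "g2", "g3"])
    assert m.cells.shape == (3, 0)


def test_unknown_genome_rejected():
    with pytest.raises(ValueError, match="unknown genome"):
        build_matrix([hit("gX", "phy")], ["g1"])


def test_genome_without_hits_is_all_zero_row():
    m = build_matrix([hit("g1", "phy")], ["g1", "g2"])
    assert m.cells[1].sum() == 0


def test_cluster_mode_single_shared_cluster():
    hits = [hit("g1", "phy", pid="p1"), hit("g2", "phy", pid="p2")]
    clusters = [frozenset({("g1", "p1"), ("g2", "p2")})]
    m = build_matrix(hits, ["g1", "g2"], mode="cluster", clusters=clusters)
    assert len(m.feature_ids) == 1
    assert m.cells.tolist() == [[1], [1]]
    assert m.feature_category[m.feature_ids[0]] == "cat_phy"


def test_cluster_mode_requires_cluster_membership():
    hits = [hit("g1", "phy", pid="p1")]
    with pytest.raises(ValueError, match="not covered"):
        build_matrix(hits, ["g1"], mode="cluster", clusters=[])


def test_cluster_mode_category_conflict_resolved_by_score(caplog):
    hits = [
        hit("g1", "phy", cat="phytate", pid="p1", score=50.0),
        hit("g2", "tan", cat="tannin", pid="p2", score=90.0),
    ]
    clusters = [frozenset({("g1", "p1"), ("g2", "p2")})]
    with caplog.at_level("WARNING"):
        m = build_matrix(hits, ["g1", "g2"], mode="cluster", clusters=clusters)
    assert m.feature_category[m.feature_ids[0]] == "tannin"
    assert any("spans categories" in msg for msg in caplog.messages)


# ---------------------------------------------------------------------------
# profiles


def test_profile_counts_and_coverage():
    hits = [
        hit("g1", "phy", cat="phytate"),
        hit("g1", "tan", cat="tannin"),
    ]
    m = build_matrix(hits, ["g1", "g2"])
    prof = {p.genome_id: p for p in profiles(m)}
    assert prof["g1"].total_genes == 2
    assert prof["g1"].categories_covered == 2
    assert prof["g2"].total_genes == 0
    assert prof["g2"].categories_covered == 0


def test_profile_paralog_family_counts_features_once_per_enzyme():
    # three distinct phytase-family enzymes in one genome: 3 genes, 1 category
    hits = [
        hit("g1", "phy3", cat="phytate"),
        hit("g1", "phy4", cat="phytate"),
        hit("g1", "bpp", cat="phytate"),
    ]
    m = build_matrix(hits, ["g1"])
    p = profiles(m)[0]
    assert p.genes_per_category == {"phytate": 3}
    assert p.total_genes == 3
    assert p.categories_covered == 1


def test_profiles_total_equals_category_sum(rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    m = random_matrix(rng, 6, 12)
    for p in profiles(m):
        assert p.total_genes == sum(p.genes_per_category.values())
    frame = profiles_frame(m)
    assert (frame["total_genes"] == m.cells.sum(axis=1)).all()


# ---------------------------------------------------------------------------
# tallies


def test_tally_min_features():
    hits = [
        hit("g1", "phy3", cat="phytate"),
        hit("g1", "phy4", cat="phytate"),
        hit("g2", "phy3", cat="phytate"),
    ]
    m = build_matrix(hits, ["g1", "g2"])
    assert tally_category(m, "phytate", 1) == 2
    assert tally_category(m, "phytate", 2) == 1
    with pytest.raises(KeyError):
        tally_category(m, "nonexistent")


def test_tally_matches_bruteforce_row_scan():
    rng = np.random.default_rng(5)
    m = random_matrix(rng, 5, 9, n_categories=3)
    for cat in ("cat0", "cat1", "cat2"):
        cols = [j for j, f in enumerate(m.feature_ids)
                if m.feature_category[f] == cat]
        for min_features in (1, 2):
            expected = sum(
                1 for i in range(len(m.genome_ids))
                if int(m.cells[i, cols].sum()) >= min_features
            )
            assert tally_category(m, cat, min_features) == expected


def test_tally_by_group():
    hits = [hit("b1", "phy", cat="phytate"), hit("l1", "tan", cat="tannin")]
    m = build_matrix(hits, ["b1", "b2", "l1"])
    groups = {"b1": "Bacillus", "b2": "Bacillus", "l1": "Lacto"}
    assert tally_by_group(m, groups, "phytate") == {
        "Bacillus": (1, 2), "Lacto": (0, 1)
    }


# ---------------------------------------------------------------------------
# partition


def test_partition_core_singleton_dispensable():
    clusters = [
        frozenset({("g1", "a"), ("g2", "b"), ("g3", "c")}),  # spans 3 = core
        frozenset({("g1", "d")}),                            # singleton
        frozenset({("g1", "e"), ("g2", "f")}),               # dispensable
    ]
    p = partition(clusters, n_genomes=3)
    assert (p.core_count, p.singleton_count, p.dispensable_count) == (1, 1, 1)
    assert p.total_clusters == 3


def test_partition_no_edges_all_singletons():
    clusters = [frozenset({(f"g{i}", f"p{j}")}) for i in range(3)
                for j in range(4)]
    p = partition(clusters, n_genomes=3)
    assert p.singleton_count == 12
    assert p.core_count == 0 and p.dispensable_count == 0


def test_partition_paralogs_span_one_genome():
    clusters = [frozenset({("g1", "a"), ("g1", "b")})]
    p = partition(clusters, n_genomes=2)
    assert p.singleton_count == 1


def test_partition_overspanning_cluster_rejected():
    clusters = [frozenset({("g1", "a"), ("g2", "b")})]
    with pytest.raises(ValueError, match="spans"):
        partition(clusters, n_genomes=1)


def test_partition_matches_independent_span_tally():
    rng = np.random.default_rng(11)
    genome_ids = [f"g{i}" for i in range(6)]
    clusters = []
    pid = 0
    for _ in range(40):
        span = rng.integers(1, 7)
        members = set()
        for g in rng.choice(genome_ids, size=span, replace=False):
            members.add((g, f"p{pid}"))
            pid += 1
        clusters.append(frozenset(members))
    p = partition(clusters, n_genomes=6)
    spans = [len({g for g, _ in c}) for c in clusters]
    assert p.core_count == sum(1 for s in spans if s == 6)
    assert p.singleton_count == sum(1 for s in spans if s == 1)
    assert p.dispensable_count == sum(1 for s in spans if 1 < s < 6)
    assert p.core_count + p.singleton_count + p.dispensable_count == (
        p.total_clusters
    )


def test_partition_counts_must_sum():
    with pytest.raises(ValueError):
        PanGenomePartition(
            n_genomes=2, core_count=1, singleton_count=1,
            dispensable_count=1, total_clusters=2,
        )
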
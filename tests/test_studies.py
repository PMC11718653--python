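import networkx as nx
import numpy as np
import pytest

from ppibias.correction import RoleAnnotatedStudy
from ppibias.graphs import generate_er
from ppibias.powerlaw import EstimationError, fit_discrete_pl
from ppibias.studies import (
    StudyCatalog,
    aggregate,
    merge_random_subsets,
    read_catalog_tsv,
    read_mitab_lite,
    synthetic_catalog,
    write_catalog_tsv,
)


class TestMitab:
    def test_roles_and_orientation(self, mitab_file):
        catalog = read_mitab_lite(mitab_file)
        by_id = {s.study_id: s for s in catalog.studies}
        assert set(by_id) == {"pubmed:111", "pubmed:222"}
        # role columns orient bait -> prey regardless of column order
        assert set(by_id["pubmed:111"].interactions) == {("P1", "P2"), ("P1", "P3")}
        assert by_id["pubmed:222"].interactions == [("P2", "P4")]

    def test_missing_roles_kept_unoriented(self, mitab_file):
        catalog = read_mitab_lite(mitab_file)
        by_id = {s.study_id: s for s in catalog.studies}
        assert ("P5", "P6") in by_id["pubmed:222"].unoriented

    def test_self_interaction_dropped(self, mitab_file):
        catalog = read_mitab_lite(mitab_file)
        all_proteins = set().union(*(s.proteins for s in catalog.studies))
        assert "P7" not in all_proteins

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(OSError):
            read_mitab_lite(tmp_path / "missing.mitab")

    def test_roundtrip_via_tsv(self, mitab_file, tmp_path):
        catalog = read_mitab_lite(mitab_file)
        path = tmp_path / "catalog.tsv"
        write_catalog_tsv(catalog, path)
        back = read_catalog_tsv(path)
        orig = {s.study_id: (sorted(s.interactions), sorted(s.unoriented)) for s in catalog.studies}
        rt = {s.study_id: (sorted(s.interactions), sorted(s.unoriented)) for s in back.studies}
        assert orig == rt


class TestAggregate:
    def test_shared_edge_provenance(self, tiny_catalog):
        agg = aggregate(tiny_catalog)
        assert agg.provenance[frozenset({"A", "B"})] == {"s1", "s2"}
        assert agg.graph.number_of_edges() == 3

    def test_bait_usage_counts_studies(self, tiny_catalog):
        agg = aggregate(tiny_catalog)
        assert agg.bait_usage["A"] == 1
        assert agg.bait_usage["B"] == 1
        assert agg.bait_usage["D"] == 0

    def test_idempotent(self, tiny_catalog):
        agg = aggregate(tiny_catalog)
        merged = StudyCatalog(
            studies=[RoleAnnotatedStudy("merged", [tuple(e) for e in agg.graph.edges()])]
        )
        agg2 = aggregate(merged)
        assert {frozenset(e) for e in agg2.graph.edges()} == {
            frozenset(e) for e in agg.graph.edges()
        }

    def test_union_of_per_study_edges(self, tiny_catalog):
        agg = aggregate(tiny_catalog)
        union = set().union(*(s.edges for s in tiny_catalog.studies))
        assert {frozenset(e) for e in agg.graph.edges()} == union

    def test_whitelist_restriction(self):
        catalog = StudyCatalog(
            studies=[RoleAnnotatedStudy("s", [("A", "B"), ("A", "Z")])],
            protein_universe={"A", "B"},
        )
        agg = aggregate(catalog)
        assert set(agg.graph.nodes()) <= {"A", "B"}


class TestMergeRandomSubsets:
    def test_same_seed_reproducible(self, tiny_catalog):
        r1 = merge_random_subsets(tiny_catalog, subset_size=2, reps=3, seed=0, n_boot=10)
        r2 = merge_random_subsets(tiny_catalog, subset_size=2, reps=3, seed=0, n_boot=10)
        assert len(r1) == 3
        assert r1 == r2

    def test_zero_reps_rejected(self, tiny_catalog):
        with pytest.raises(ValueError):
            merge_random_subsets(tiny_catalog, 1, 0, seed=0)

    def test_oversized_subset_rejected(self, tiny_catalog):
        with pytest.raises(ValueError):
            merge_random_subsets(tiny_catalog, 3, 1, seed=0)

    def test_plausibility_grows_with_aggregation(self):
        """Aggregating more small, bait-biased studies makes the merged degree
        distribution more often power-law plausible: tiny merges cannot even
        express the usage tail, large merges inherit it."""
        gt = generate_er(800, 1600, seed=0)
        catalog = synthetic_catalog(
            800, 200, fpr=0.1, fnr=0.2, ground_truth=gt, seed=1,
            method="Y2H", min_balance=0.3,
        )
        fracs = []
        for size in (3, 20, 60):
            res = merge_random_subsets(catalog, size, reps=12, seed=2, n_boot=50)
            fracs.append(np.mean([r.plausible for r in res]))
        assert fracs[2] > fracs[0]
        assert fracs[1] >= fracs[0] - 0.1  # monotone within noise


class TestSyntheticCatalog:
    def test_error_free_empty_truth_gives_empty_studies(self):
        gt = nx.empty_graph(100)
        catalog = synthetic_catalog(100, 20, fpr=0.0, fnr=0.0, ground_truth=gt, seed=0)
        assert all(not s.interactions for s in catalog.studies)

    def test_realized_bait_usage_is_powerlaw_like(self):
        gt = generate_er(800, 1600, seed=3)
        hits = 0
        for seed in range(5):
            catalog = synthetic_catalog(
                800, 1600, fpr=0.02, fnr=0.1, ground_truth=gt, seed=seed
            )
            agg = aggregate(catalog)
            usage = agg.bait_usage.as_array(sorted(agg.bait_usage.counts))
            try:
                fit = fit_discrete_pl(usage)
            except EstimationError:
                continue
            hits += 2.3 <= fit.alpha <= 4.3
        assert hits >= 3

    def test_never_tested_fraction_lower_bounded_by_zero_frac(self):
        gt = nx.empty_graph(2000)
        catalog = synthetic_catalog(
            2000, 4000, fpr=0.05, fnr=0.0, ground_truth=gt, seed=4, zero_frac=0.24
        )
        baited = set()
        for s in catalog.studies:
            baited |= s.baits
        zero_frac = 1 - len(baited) / 2000
        # proteins with zero interest are never baited; sampling noise only
        # adds never-selected proteins on top of the structural 24%
        assert zero_frac >= 0.24 - 0.03

    def test_study_ids_unique(self):
        gt = nx.empty_graph(50)
        catalog = synthetic_catalog(50, 30, fpr=0.1, fnr=0.0, ground_truth=gt, seed=5)
        ids = [s.study_id for s in catalog.studies]
        assert len(ids) == len(set(ids)) == 30
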
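import numpy as np
import pytest

from acutoxmap.clustering import cluster_chemicals
from acutoxmap.data_io import AssayDataset, ChemicalRecord, derive_toxicity_labels
from acutoxmap.hitcalls import apply_burst_filter
from acutoxmap.selection import (
    candidate_pool,
    greedy_min_cover,
    per_cluster_selection,
    select_global,
)

from _oracles import brute_min_cover_size


class TestGreedyCover:
    def test_single_covering_assay(self):
        sel = greedy_min_cover(
            ["a1"], {"a1": {"t1", "t2"}}, {"a1": set()}
        )
        assert sel.selected_assays == ["a1"]
        assert sel.covered_toxics == {"t1", "t2"}
        assert not sel.uncovered_toxics
        assert sel.selection_fdr == 0.0

    def test_net_score_orders_b_before_a(self):
        # A covers 3 toxics with 2 nontoxic hits (net 1); B covers 2 clean (net 2)
        toxics = {"A": {"t1", "t2", "t3"}, "B": {"t1", "t2"}}
        nontox = {"A": {"n1", "n2"}, "B": set()}
        sel = greedy_min_cover(["A", "B"], toxics, nontox)
        assert sel.selected_assays == ["B", "A"]
        assert sel.steps[1].newly_covered == 1  # A adds only t3

    def test_tie_broken_by_total_toxic_actives_then_fdr_then_id(self):
        toxics = {"A": {"t1"}, "B": {"t1", "t2"}}
        nontox = {"A": set(), "B": {"n1"}}  # both net 1 on first step
        sel = greedy_min_cover(["A", "B"], toxics, nontox)
        assert sel.selected_assays[0] == "B"  # larger static toxic total
        toxics = {"A": {"t1"}, "B": {"t1"}}
        nontox = {"A": set(), "B": set()}
        sel = greedy_min_cover(["A", "B"], toxics, nontox, {"A": 0.5, "B": 0.1})
        assert sel.selected_assays == ["B"]  # lower toxic-contrast FDR
        sel = greedy_min_cover(["A", "B"], toxics, nontox)
        assert sel.selected_assays == ["A"]  # lexicographic last resort

    def test_zero_gain_assays_never_selected(self):
        toxics = {"A": {"t1"}, "B": {"t1"}}
        sel = greedy_min_cover(["A", "B"], toxics, {"A": set(), "B": set()})
        assert sel.selected_assays == ["A"]

    def test_empty_pool_with_uncovered_toxics_warns(self):
        with pytest.warns(UserWarning, match="not coverable"):
            sel = greedy_min_cover([], {}, {}, toxics_to_cover={"t1"})
        assert sel.selected_assays == []
        assert sel.uncovered_toxics == {"t1"}

    def test_selection_fdr_definition(self):
        sel = greedy_min_cover(
            ["A"], {"A": {"t1", "t2", "t3"}}, {"A": {"n1"}}
        )
        assert sel.selection_fdr == pytest.approx(1 / 4)

    def test_deterministic_on_repeated_runs(self, rng):
        assays = [f"a{k}" for k in range(10)]
        toxics = {a: set(map(str, rng.choice(30, rng.integers(0, 6)))) for a in assays}
        nontox = {a: set() for a in assays}
        first = greedy_min_cover(assays, toxics, nontox).selected_assays
        again = greedy_min_cover(assays, toxics, nontox).selected_assays
        assert first == again

    def test_removing_nontoxic_never_demotes_selected_assay(self, rng):
        for trial in range(20):
            r = np.random.default_rng(trial)
            assays = [f"a{k}" for k in range(6)]
            toxics = {
                a: set(f"t{i}" for i in r.choice(12, r.integers(1, 5), replace=False))
                for a in assays
            }
            nontox = {
                a: set(f"n{i}" for i in r.choice(6, r.integers(0, 3), replace=False))
                for a in assays
            }
            sel = greedy_min_cover(assays, toxics, nontox)
            if not sel.steps:
                continue
            first = sel.selected_assays[0]
            if not nontox[first]:
                continue
            relaxed = dict(nontox)
            relaxed[first] = set(list(nontox[first])[1:])
            sel2 = greedy_min_cover(assays, toxics, relaxed)
            assert sel2.selected_assays[0] == first

    def test_covers_everything_and_bounds_brute_force(self):
        # random instances small enough for the exhaustive oracle
        for trial in range(25):
            r = np.random.default_rng(100 + trial)
            n_assays, n_tox = 8, 16
            toxics = {
                f"a{k}": set(
                    f"t{i}" for i in r.choice(n_tox, r.integers(0, 6), replace=False)
                )
                for k in range(n_assays)
            }
            nontox = {
                f"a{k}": set(
                    f"n{i}" for i in r.choice(5, r.integers(0, 3), replace=False)
                )
                for k in range(n_assays)
            }
            sel = greedy_min_cover(list(toxics), toxics, nontox)
            coverable = set().union(*toxics.values())
            assert sel.covered_toxics == coverable
            assert not sel.uncovered_toxics
            assert len(sel.selected_assays) >= brute_min_cover_size(toxics, coverable)


def _toy_study():
    chemicals = derive_toxicity_labels(
        [
            ChemicalRecord("t1", ld50=10.0, cytotox_point=300.0, cytotox_lower_bound=100.0),
            ChemicalRecord("t2", ld50=20.0, cytotox_point=300.0, cytotox_lower_bound=100.0),
            ChemicalRecord("n1", ld50=4000.0, cytotox_point=300.0, cytotox_lower_bound=100.0),
        ]
    )
    tested = np.ones((3, 2), bool)
    raw_hit = np.array([[1, 0], [0, 1], [0, 0]], bool)
    ac50 = np.where(raw_hit, 5.0, np.nan)
    assays = AssayDataset(["t1", "t2", "n1"], ["a1", "a2"], tested, raw_hit, ac50)
    return chemicals, apply_burst_filter(assays, chemicals)


class TestPools:
    def test_global_pool_contains_single_hit_assay(self):
        chemicals, assays = _toy_study()
        pool, fallback = candidate_pool("global", assays, chemicals)
        assert set(pool) == {"a1", "a2"}
        assert not fallback

    def test_cluster_without_enrichment_falls_back(self, small_study_burst):
        chemicals, fps, assays, _ = small_study_burst
        clusters = cluster_chemicals(fps)
        toxic = {c.chem_id for c in chemicals if c.toxic is True}
        burst_any = dict(zip(assays.chem_ids, (assays.burst_hit == 1).any(axis=1)))
        # find a cluster with an active toxic member; no enrichment passed at all
        for cid in range(1, clusters.n_clusters + 1):
            members = clusters.members(cid)
            if any(c in toxic and burst_any[c] for c in members):
                pool, fallback = candidate_pool(
                    "cluster", assays, chemicals, clusters, cid, cluster_enrichment=[]
                )
                assert fallback and pool
                return
        pytest.fail("no cluster with an active toxic member in fixture")

    def test_unknown_cluster_rejected(self, small_study_burst):
        chemicals, fps, assays, _ = small_study_burst
        clusters = cluster_chemicals(fps)
        with pytest.raises(ValueError, match="unknown cluster_id"):
            candidate_pool("cluster", assays, chemicals, clusters, 10**6, [])

    def test_excluded_cytotoxicity_assays_removed(self):
        chemicals, assays = _toy_study()
        pool, _ = candidate_pool(
            "global", assays, chemicals, exclude_assays=["a1"]
        )
        assert pool == ["a2"]


class TestPerCluster:
    def test_disjoint_activity_needs_two_assays(self):
        chemicals, assays = _toy_study()
        fake_clusters = cluster_chemicals(
            __import__("acutoxmap.data_io", fromlist=["FingerprintMatrix"]).FingerprintMatrix(
                ["t1", "t2", "n1"], np.array([[1, 1, 0], [1, 1, 0], [1, 1, 0]])
            ),
            cut_height=0.7,
        )
        selections, summary = per_cluster_selection(
            chemicals, fake_clusters, assays, cluster_enrichment=[]
        )
        assert len(selections) == 1
        assert sorted(selections[0].selected_assays) == ["a1", "a2"]

    def test_planted_fixture_pools_contain_mechanism_assay(self, small_study_burst):
        from acutoxmap.enrichment import run_enrichment

        chemicals, fps, assays, truth = small_study_burst
        clusters = cluster_chemicals(fps)
        enr = run_enrichment("cluster_toxics_vs_all_toxics", chemicals, assays, clusters)
        recovered = clusters.as_dict()
        toxic = {c.chem_id for c in chemicals if c.toxic is True}
        burst_any = dict(zip(assays.chem_ids, (assays.burst_hit == 1).any(axis=1)))
        for true_cid, mech in truth.mechanism_assays.items():
            members = [c for c, t in truth.true_cluster.items() if t == true_cid]
            if sum(1 for c in members if c in toxic and burst_any[c]) < 3:
                continue
            pool, _ = candidate_pool(
                "cluster", assays, chemicals, clusters, recovered[members[0]], enr
            )
            assert set(mech) & set(pool)

    def test_full_coverage_and_summary(self, small_study_burst):
        from acutoxmap.enrichment import run_enrichment

        chemicals, fps, assays, _ = small_study_burst
        clusters = cluster_chemicals(fps)
        enr = run_enrichment("cluster_toxics_vs_all_toxics", chemicals, assays, clusters)
        selections, summary = per_cluster_selection(
            chemicals, clusters, assays, enr
        )
        for s in selections:
            assert not s.uncovered_toxics
        assert summary["union_assay_count"] == len(summary["union_assays"])
        assert sum(summary["assay_count_histogram"].values()) == len(selections)

    def test_global_coverage_complete(self, small_study_burst):
        chemicals, _, assays, _ = small_study_burst
        sel = select_global(chemicals, assays)
        assert not sel.uncovered_toxics
        toxic = {c.chem_id for c in chemicals if c.toxic is True}
        burst_any = dict(zip(assays.chem_ids, (assays.burst_hit == 1).any(axis=1)))
        assert sel.covered_toxics == {c for c in toxic if burst_any[c]}
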
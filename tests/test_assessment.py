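import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from acutoxmap.assessment import (
    binary_association,
    cluster_ghs_span,
    composite_ac50,
    compute_composite_activity,
    ghs_association,
    montecarlo_fisher_rxc,
)
from acutoxmap.clustering import cluster_chemicals
from acutoxmap.data_io import AssayDataset, ChemicalRecord, FingerprintMatrix, derive_toxicity_labels


def _dataset(chem_ids, assay_ids, tested, raw_hit, ac50):
    return AssayDataset(chem_ids, assay_ids, np.array(tested, bool),
                        np.array(raw_hit, bool), np.array(ac50, float))


class TestCompositeAC50:
    def test_minimum_of_cluster_and_cytotoxicity(self):
        chem = ChemicalRecord("x", cytotox_point=100.0, cytotox_lower_bound=30.0)
        ds = _dataset(["x"], ["a1", "a2"], [[1, 1]], [[1, 1]], [[50.0, 20.0]])
        res = composite_ac50(chem, ["a1", "a2"], ds)
        assert res.cluster_ac50 == 20.0
        assert res.composite_ac50 == 20.0
        assert res.status == "active"

    def test_no_cluster_activity_falls_back_to_cytotoxicity(self):
        chem = ChemicalRecord("x", cytotox_point=1500.0, cytotox_lower_bound=500.0)
        ds = _dataset(["x"], ["a1"], [[1]], [[0]], [[np.nan]])
        res = composite_ac50(chem, ["a1"], ds)
        assert res.composite_ac50 == 1500.0
        assert res.status == "inactive"  # 1,500 µM >= 1 mM threshold

    def test_untested_without_cytotoxicity_is_unevaluable(self):
        chem = ChemicalRecord("x")
        ds = _dataset(["x"], ["a1"], [[0]], [[0]], [[np.nan]])
        assert composite_ac50(chem, ["a1"], ds).status == "unevaluable"

    def test_tested_inactive_without_cytotoxicity_is_inactive(self):
        chem = ChemicalRecord("x")
        ds = _dataset(["x"], ["a1"], [[1]], [[0]], [[np.nan]])
        assert composite_ac50(chem, ["a1"], ds).status == "inactive"

    def test_composite_never_exceeds_inputs(self, small_study_burst):
        chemicals, fps, assays, _ = small_study_burst
        clusters = cluster_chemicals(fps)
        amap = {cid: list(assays.assay_ids[:3]) for cid in range(1, clusters.n_clusters + 1)}
        for res in compute_composite_activity(chemicals, clusters, amap, assays):
            if res.composite_ac50 is None:
                continue
            for v in (res.cluster_ac50, res.cytotox_ac50):
                if v is not None:
                    assert res.composite_ac50 <= v


class TestBinaryAssociation:
    def test_reported_counts_reproduce_odds_ratio(self):
        chems, acts = [], []
        counts = {(True, True): 1406, (True, False): 621, (False, True): 649, (False, False): 1279}
        i = 0
        from acutoxmap.assessment import CompositeActivity

        for (active, toxic), k in counts.items():
            for _ in range(k):
                cid = f"c{i}"
                i += 1
                chems.append(ChemicalRecord(cid, ld50=100.0 if toxic else 3000.0))
                acts.append(
                    CompositeActivity(cid, None, None, 10.0 if active else 2000.0,
                                      "active" if active else "inactive")
                )
        chems = derive_toxicity_labels(chems)
        table, p, odds = binary_association(acts, chems)
        assert table.tolist() == [[1406, 621], [649, 1279]]
        assert odds == pytest.approx(4.46, abs=0.01)
        assert p <= 2.2e-16

    def test_empty_evaluable_set_rejected(self):
        from acutoxmap.assessment import CompositeActivity

        chems = derive_toxicity_labels([ChemicalRecord("x", ld50=10.0)])
        acts = [CompositeActivity("x", None, None, None, "unevaluable")]
        with pytest.raises(ValueError, match="no evaluable"):
            binary_association(acts, chems)

    def test_balanced_counts_give_p_one(self):
        from acutoxmap.assessment import CompositeActivity

        chems, acts = [], []
        i = 0
        for active in (True, False):
            for toxic in (True, False):
                for _ in range(10):
                    cid = f"c{i}"
                    i += 1
                    chems.append(ChemicalRecord(cid, ld50=100.0 if toxic else 3000.0))
                    acts.append(CompositeActivity(cid, None, None, 10.0, "active" if active else "inactive"))
        table, p, odds = binary_association(acts, derive_toxicity_labels(chems))
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)


class TestMonteCarloFisher:
    def test_strong_association_hits_estimator_floor(self):
        p = montecarlo_fisher_rxc(np.array([[1406, 621], [649, 1279]]), 20000, seed=0)
        assert p == pytest.approx(1 / 20001, abs=1e-9)

    def test_identical_rows_give_p_near_one(self):
        p = montecarlo_fisher_rxc(np.array([[5, 5], [5, 5]]), 5000, seed=0)
        assert p > 0.9

    def test_matches_exact_two_by_two_within_three_se(self):
        rng = np.random.default_rng(21)
        reps = 4000
        for _ in range(10):
            t = rng.integers(0, 8, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            exact = fisher_exact(t)[1]
            est = montecarlo_fisher_rxc(t, reps, seed=int(rng.integers(2**31)))
            se = math.sqrt(max(exact * (1 - exact), 1e-12) / reps)
            assert abs(est - exact) <= 3 * se + 2 / reps

    def test_degenerate_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropping zero"):
            p = montecarlo_fisher_rxc(np.array([[3, 4], [0, 0]]), 1000, seed=1)
        assert p == 1.0

    def test_reproducible_for_fixed_seed(self):
        t = np.array([[8, 2, 1], [3, 6, 4]])
        a = montecarlo_fisher_rxc(t, 2000, seed=5)
        b = montecarlo_fisher_rxc(t, 2000, seed=5)
        assert a == b

    def test_rxc_p_small_under_planted_dependence(self):
        t = np.array([[40, 2, 1], [2, 35, 3], [1, 4, 30]])
        assert montecarlo_fisher_rxc(t, 5000, seed=2) < 0.01


class TestGHSAssociation:
    def test_activity_category_table_excludes_unclassified(self, small_study_burst):
        chemicals, fps, assays, _ = small_study_burst
        clusters = cluster_chemicals(fps)
        acts = compute_composite_activity(chemicals, clusters, {}, assays)
        table, p = ghs_association(acts, chemicals, n_reps=500, seed=3)
        assert set(table.columns) <= {1, 2, 3, 4, 5}
        assert 0 < p <= 1


class TestGHSSpan:
    def _clusters(self, mapping):
        ids = list(mapping)
        # one fingerprint bit per cluster id keeps them apart at any cut < 1
        classes = sorted(set(mapping.values()))
        bits = np.zeros((len(ids), len(classes)), dtype=int)
        for i, c in enumerate(ids):
            bits[i, classes.index(mapping[c])] = 1
        return cluster_chemicals(FingerprintMatrix(ids, bits), cut_height=0.5)

    def test_span_fractions(self):
        chems = derive_toxicity_labels(
            [
                ChemicalRecord("a", ld50=20.0),   # cat 2, cluster 1
                ChemicalRecord("b", ld50=30.0),   # cat 2, cluster 1
                ChemicalRecord("c", ld50=20.0),   # cat 2, cluster 2
                ChemicalRecord("d", ld50=200.0),  # cat 3, cluster 2
                ChemicalRecord("e", ld50=2.0),    # cat 1, cluster 3
                ChemicalRecord("f", ld50=1000.0), # cat 4, cluster 3
            ]
        )
        clusters = self._clusters({"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3})
        spans, summary = cluster_ghs_span(clusters, chems)
        assert summary["n_clusters_with_toxic"] == 3
        assert summary["frac_single_category"] == pytest.approx(1 / 3)
        # {2} and {2,3} count; {1,4} is non-neighboring
        assert summary["frac_le2_neighboring"] == pytest.approx(2 / 3)
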
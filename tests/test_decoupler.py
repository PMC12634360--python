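"""Edit distance, hierarchical decoupling, assignment, GMM baseline, t-test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

import ddss
from ddss import synthetic as syn
from ddss.decoupler import (
    DistanceMatrix,
    Partition,
    assign_sample,
    assign_surgeon,
    cluster_surgeons,
    gmm_partition,
    group_duration_test,
    levenshtein,
    pairwise_distances,
)
from ddss.exceptions import ValidationError
from ddss.trajectory import PreferenceSequence, surgeon_sequences
from _oracles import levenshtein_recursive
from conftest import make_dataset, random_codes

tokens = st.lists(st.sampled_from("abc"), max_size=6)


class TestLevenshtein:
    def test_identity(self):
        assert levenshtein(("A", "B", "C"), ("A", "B", "C")) == 0

    def test_pure_insertions(self):
        assert levenshtein((), ("A", "B")) == 2

    def test_mixed_edits(self):
        pair = (("A", "B", "C", "D"), ("B", "C", "D", "E"))
        assert levenshtein(*pair) == levenshtein_recursive(*pair) == 2

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(tokens, tokens)
    def test_agrees_with_recursion_oracle(self, a, b):
        assert levenshtein(a, b) == levenshtein_recursive(a, b)

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(tokens, tokens, tokens)
    def test_metric_axioms(self, a, b, c):
        dab, dba = levenshtein(a, b), levenshtein(b, a)
        assert dab == dba
        assert (dab == 0) == (list(a) == list(b))
        assert dab <= levenshtein(a, c) + levenshtein(c, b)

    def test_accepts_preference_sequences(self):
        p = PreferenceSequence("s", ("Angle", "Depth"))
        q = PreferenceSequence("t", ("Angle",))
        assert levenshtein(p, q) == 1


class TestPairwiseDistances:
    def test_identical_sequences_have_zero_distance(self):
        seqs = [
            PreferenceSequence("a", ("X", "Y")),
            PreferenceSequence("b", ("X", "Y")),
        ]
        D = pairwise_distances(seqs)
        assert D.values[0, 1] == 0

    def test_matrix_equals_elementwise_calls(self):
        rng = np.random.default_rng(0)
        alphabet = ["T1", "T2", "T3", "T4", "T5"]
        seqs = []
        for i in range(4):
            k = rng.integers(0, 5)
            seqs.append(
                PreferenceSequence(f"s{i}", tuple(rng.permutation(alphabet)[:k]))
            )
        D = pairwise_distances(seqs)
        for i in range(4):
            for j in range(4):
                assert D.values[i, j] == levenshtein(seqs[i], seqs[j])

    def test_duplicate_ids_rejected(self):
        seqs = [PreferenceSequence("a", ()), PreferenceSequence("a", ("X",))]
        with pytest.raises(ValidationError, match="duplicate"):
            pairwise_distances(seqs)


def _dm(ids, values):
    return DistanceMatrix(ids=tuple(ids), values=np.asarray(values, dtype=float))


class TestClusterSurgeons:
    def test_block_structure_recovered(self):
        # within-block distance 1, between-block 10: brute-force optimum {12}{34}
        D = np.full((4, 4), 10.0)
        D[0, 1] = D[1, 0] = D[2, 3] = D[3, 2] = 1.0
        np.fill_diagonal(D, 0.0)
        part = cluster_surgeons(_dm("ABCD", D))
        assert set(map(frozenset, (part.members(1), part.members(2)))) == {
            frozenset("AB"),
            frozenset("CD"),
        }

    def test_two_surgeons_split_into_singletons(self):
        part = cluster_surgeons(_dm("AB", [[0, 3], [3, 0]]))
        assert part.members(1) == ("A",) and part.members(2) == ("B",)

    def test_all_equal_distances_use_lowest_index_tie_rule(self):
        D = np.full((4, 4), 5.0)
        np.fill_diagonal(D, 0.0)
        part = cluster_surgeons(_dm("ABCD", D))
        # merges: (A,B) then (AB,C); cut at 2 leaves {A,B,C} vs {D}
        assert part.members(1) == ("A", "B", "C")
        assert part.members(2) == ("D",)

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValidationError):
            cluster_surgeons(_dm("AB", [[0, 1], [1, 0]]), k=3)

    def test_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(1)
        seqs = []
        alphabet = [f"T{i}" for i in range(6)]
        for i in range(6):
            k = int(rng.integers(1, 6))
            seqs.append(
                PreferenceSequence(f"s{i}", tuple(rng.permutation(alphabet)[:k]))
            )
        part1 = cluster_surgeons(pairwise_distances(seqs))
        perm = list(rng.permutation(len(seqs)))
        part2 = cluster_surgeons(pairwise_distances([seqs[i] for i in perm]))
        groups1 = {frozenset(part1.members(c)) for c in part1.clusters}
        groups2 = {frozenset(part2.members(c)) for c in part2.clusters}
        assert groups1 == groups2

    def test_matches_scipy_average_linkage_on_tie_free_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = 8
            pts = rng.normal(size=(n, 3))
            D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            ids = [f"s{i}" for i in range(n)]
            for k in (2, 3):
                mine = cluster_surgeons(_dm(ids, D), k=k)
                ref = fcluster(linkage(squareform(D), "average"), k, "maxclust")
                groups_mine = {frozenset(mine.members(c)) for c in mine.clusters}
                groups_ref = {
                    frozenset(np.array(ids)[ref == c]) for c in np.unique(ref)
                }
                assert groups_mine == groups_ref


class TestAssignment:
    def _toy_partition(self):
        members = [
            PreferenceSequence("a1", ("X", "Y", "Z")),
            PreferenceSequence("a2", ("X", "Y")),
            PreferenceSequence("b1", ("P", "Q", "R")),
            PreferenceSequence("b2", ("P", "Q")),
        ]
        part = Partition(assignment={"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        return part, members

    def test_identical_member_wins(self):
        part, members = self._toy_partition()
        assert assign_surgeon(PreferenceSequence("new", ("X", "Y", "Z")), part, members) == 1
        assert assign_surgeon(PreferenceSequence("new", ("P", "Q")), part, members) == 2

    def test_equidistant_tie_goes_to_cluster_one(self):
        part = Partition(assignment={"a": 1, "b": 2})
        members = [
            PreferenceSequence("a", ("X", "Y")),
            PreferenceSequence("b", ("P", "Q")),
        ]
        assert assign_surgeon(PreferenceSequence("n", ("U", "V")), part, members) == 1

    def test_held_out_novice_joins_planted_novice_cluster(self):
        hits = 0
        for seed in range(50):
            cfg = ddss.default_config(seed=seed)
            ds = ddss.generate_dataset(cfg)
            seqs = surgeon_sequences(ds)
            train = [s for s in seqs if s.surgeon_id != "S9"]
            part = cluster_surgeons(pairwise_distances(train))
            held = next(s for s in seqs if s.surgeon_id == "S9")
            novice_cluster = part.assignment["S6"]
            hits += (
                assign_surgeon(held, part, train) == novice_cluster
                and part.assignment["S5"] == novice_cluster
                and part.assignment["S8"] == novice_cluster
            )
        assert hits >= 45

    def _feature_separated(self, schema):
        # cluster A surgeons draw low codes, cluster B high codes
        rng = np.random.default_rng(3)
        rows, surgeons = [], []
        for s, hi in (("A1", 0), ("A2", 0), ("B1", 1), ("B2", 1)):
            for _ in range(20):
                caps = [ind.n_levels - 1 for ind in schema.indicators]
                rows.append([c if hi else 0 for c in caps])
                surgeons.append(s)
        ds = make_dataset(
            schema,
            rng.uniform(400, 2000, len(rows)),
            surgeons=surgeons,
            codes=rows,
        )
        part = Partition(assignment={"A1": 1, "A2": 1, "B1": 2, "B2": 2})
        return ds, part

    def test_sample_routing_by_surgeon_lookup(self, schema):
        ds, part = self._feature_separated(schema)
        rec = ds.records[-1]  # a B2 record
        assert assign_sample(rec, part, ds) == 2

    def test_unknown_surgeon_routed_to_nearest_centroid(self, schema):
        ds, part = self._feature_separated(schema)
        base = ds.records[0]
        low = type(base)(
            record_id="x",
            surgeon_id="UNSEEN",
            month_index=1,
            levels=(0,) * 14,
            duration_s=500.0,
        )
        caps = tuple(ind.n_levels - 1 for ind in schema.indicators)
        high = type(base)(
            record_id="y",
            surgeon_id="UNSEEN",
            month_index=1,
            levels=caps,
            duration_s=500.0,
        )
        assert assign_sample(low, part, ds) == 1
        assert assign_sample(high, part, ds) == 2
        # per-sample mode overrides the surgeon lookup
        rec = ds.records[0]  # an A1 record at the low centroid
        assert assign_sample(rec, part, ds, mode="feature") == 1


class TestGMM:
    def _separated_cfg(self, seed):
        base = ddss.default_config(seed=seed)
        surgeons = tuple(
            syn.SurgeonSpec(
                surgeon_id=s.surgeon_id,
                group=s.group,
                tenure_months=s.tenure_months,
                baseline_log_duration=float(
                    np.log(700.0 if s.group == "experienced" else 2000.0)
                ),
                records_per_month=s.records_per_month,
            )
            for s in base.surgeons
        )
        return ddss.default_config(seed=seed, surgeons=surgeons)

    def test_recovers_well_separated_groups(self):
        for seed in range(5):
            cfg = self._separated_cfg(seed)
            ds = ddss.generate_dataset(cfg)
            part = gmm_partition(ds, k=2, seed=seed)
            planted = syn.planted_groups(cfg)
            ids = ds.surgeon_ids
            ari = adjusted_rand_score(
                [planted[s] for s in ids], [part.assignment[s] for s in ids]
            )
            assert ari == 1.0

    def test_k1_puts_everyone_together(self):
        ds = ddss.generate_dataset(ddss.default_config(seed=0))
        part = gmm_partition(ds, k=1, seed=0)
        assert set(part.assignment.values()) == {1}

    def test_seeded_reproducibility(self):
        ds = ddss.generate_dataset(ddss.default_config(seed=1))
        assert gmm_partition(ds, seed=7).assignment == gmm_partition(ds, seed=7).assignment


class TestGroupDurationTest:
    def _two_groups(self, schema, d1, d2):
        ds = make_dataset(
            schema,
            list(d1) + list(d2),
            surgeons=["A"] * len(d1) + ["B"] * len(d2),
        )
        part = Partition(assignment={"A": 1, "B": 2})
        return ds, part

    def test_identical_groups_give_t0_p1(self, schema):
        ds, part = self._two_groups(schema, [600, 900, 1200], [600, 900, 1200])
        res = group_duration_test(ds, part)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_pooled_variance_closed_form(self, schema):
        ds, part = self._two_groups(schema, [1, 2], [3, 4])
        res = group_duration_test(ds, part)
        assert res.t == pytest.approx(-2.0 / np.sqrt(0.5), abs=1e-3)  # -2.828
        assert res.group_means == {1: 1.5, 2: 3.5}

    def test_zero_variance_errors(self, schema):
        ds, part = self._two_groups(schema, [900, 900], [900, 900])
        with pytest.raises(ValidationError, match="variance"):
            group_duration_test(ds, part)

    def test_power_under_planted_shift(self, schema):
        rng = np.random.default_rng(11)
        a = rng.normal(900, 100, 100)
        b = rng.normal(1200, 100, 100)
        ds, part = self._two_groups(schema, a, b)
        assert group_duration_test(ds, part).p <= 0.05

    def test_default_generator_groups_differ_significantly(self):
        cfg = ddss.default_config(seed=0)
        ds = ddss.generate_dataset(cfg)
        planted = syn.planted_groups(cfg)
        part = Partition(assignment=planted)
        res = group_duration_test(ds, part)
        assert res.p <= 0.05
        assert res.group_means[2] > res.group_means[1]  # novices take longer
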
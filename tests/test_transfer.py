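"""Out-of-sample group assignment and median-split behavioural prediction."""

import numpy as np
import pandas as pd
import pytest

import tractclust as tc
from tractclust import transfer

MARKERS = ["cingulum_L", "cingulum_R"]


def truth_partition(profiles, truth):
    return tc.CommunityPartition(
        ids=list(profiles["participant_id"]), labels=truth, q=0.0
    )


@pytest.fixture(scope="module")
def discovery():
    spec = tc.CohortSpec(seed=21, n_participants=80, group_effect=1.2)
    profiles, _, truth = tc.generate_cohort(spec)
    res = tc.residualize(profiles)
    return res, truth_partition(profiles, truth), truth


class TestRangeAssign:
    def test_group_mean_point_gets_group_label(self, discovery):
        res, part, truth = discovery
        table = res.data
        new = table.iloc[[0]].copy()
        for t in MARKERS:
            new[t] = table.loc[np.asarray(truth) == 1, t].mean()
        ga = tc.range_assign(res, part, new, MARKERS)
        assert ga.labels[0] == "C1"

    def test_extreme_point_unassigned(self, discovery):
        res, part, _ = discovery
        new = res.data.iloc[[0]].copy()
        for t in MARKERS:
            new[t] = 10.0  # +10 SD on the z scale
        ga = tc.range_assign(res, part, new, MARKERS)
        assert ga.labels[0] == "C0"

    def test_synthetic_transfer_recovery(self):
        """Label recovery on an independent cohort sits at the accuracy a
        known-model oracle classifier attains at this separation (~0.80;
        Monte-Carlo mean 0.786 over seeds), well above chance."""
        accs = []
        for seed in range(6):
            spec_d = tc.CohortSpec(seed=seed, n_participants=80, group_effect=1.2)
            spec_a = tc.CohortSpec(seed=seed + 500, n_participants=150,
                                   group_effect=1.2)
            pd_, _, td = tc.generate_cohort(spec_d)
            pa, _, ta = tc.generate_cohort(spec_a)
            ga = tc.range_assign(tc.residualize(pd_), truth_partition(pd_, td),
                                 tc.residualize(pa), MARKERS)
            lab = ga.labels
            m = lab != "C0"
            truth_lab = np.where(ta == 1, "C1", "C2")
            accs.append(float(np.mean(lab[m] == truth_lab[m])))
        assert 0.72 <= np.mean(accs) <= 0.88
        assert min(accs) > 0.6

    def test_missing_marker_rejected(self, discovery):
        res, part, _ = discovery
        with pytest.raises(KeyError, match="no_such_tract"):
            tc.range_assign(res, part, res.data, ["no_such_tract"])


class TestCorrelationAssign:
    def test_centroid_profile_gets_label(self, discovery):
        res, part, truth = discovery
        table = res.data
        tracts = tc.tract_columns(table)
        new = table.iloc[[0]].copy()
        centroid = table.loc[np.asarray(truth) == 1, tracts].mean()
        new[tracts] = centroid.to_numpy()
        ga = tc.correlation_assign(res, part, new, cutoff=0.3)
        assert ga.labels[0] == "C1"

    def test_orthogonal_profile_unassigned(self, discovery):
        res, part, truth = discovery
        table = res.data
        tracts = tc.tract_columns(table)
        rng = np.random.default_rng(0)
        c1 = table.loc[np.asarray(truth) == 1, tracts].mean().to_numpy()
        c2 = table.loc[np.asarray(truth) == 2, tracts].mean().to_numpy()
        # build a profile orthogonal to both centroids (after centering)
        basis = np.vstack([np.ones_like(c1), c1, c2])
        v = rng.normal(size=len(c1))
        v -= basis.T @ np.linalg.lstsq(basis.T, v, rcond=None)[0]
        new = table.iloc[[0]].copy()
        new[tracts] = v
        ga = tc.correlation_assign(res, part, new, cutoff=0.2)
        assert ga.labels[0] == "C0"

    def test_labelled_count_monotone_in_cutoff(self, discovery):
        res, part, _ = discovery
        spec = tc.CohortSpec(seed=77, n_participants=100, group_effect=1.2)
        pa, _, _ = tc.generate_cohort(spec)
        ra = tc.residualize(pa)
        counts = []
        for cutoff in (0.0, 0.1, 0.3, 0.5, 0.7, 0.9):
            ga = tc.correlation_assign(res, part, ra, cutoff=cutoff)
            counts.append(int(np.sum(ga.labels != "C0")))
        assert counts == sorted(counts, reverse=True)


class TestTuneAndValidate:
    def make_cohort(self, n=180, seed=0, effect=8.0, shift=None):
        spec = tc.CohortSpec(seed=seed, n_participants=n, group_effect=effect)
        if shift is not None:
            spec.behaviour = tc.BehaviourSpec(group_shift=shift)
        profiles, behaviour, truth = tc.generate_cohort(spec)
        return tc.residualize(profiles), behaviour, truth

    def test_perfect_implication_scores_one(self):
        """When labels perfectly imply the median side, accuracy is 1."""
        behaviour = np.array([2.0, 3.0, -1.0, -2.0])
        labels = np.array(["C1", "C1", "C2", "C2"])
        acc = transfer.median_split_accuracy(labels, behaviour, 0.0, "C1")
        assert acc == 1.0

    def test_perfectly_separated_behaviour(self):
        """Behaviour determined by the (widely separated) true groups:
        the tuned rule predicts nearly every validation participant."""
        res, behaviour, truth = self.make_cohort(seed=3)
        behaviour = behaviour.copy()
        behaviour["matrix_reasoning"] = np.where(truth == 1, 1.0, -1.0)
        result = tc.tune_and_validate(res, behaviour, None, "matrix_reasoning",
                                      marker_tracts=MARKERS, seed=0, n_perm=200)
        assert result.validation_accuracy >= 0.9
        assert result.permutation_p < 0.05

    def test_null_behaviour_near_chance(self):
        res, behaviour, _ = self.make_cohort(seed=4)
        rng = np.random.default_rng(0)
        behaviour = behaviour.copy()
        behaviour["matrix_reasoning"] = rng.normal(size=len(behaviour))
        result = tc.tune_and_validate(res, behaviour, None, "matrix_reasoning",
                                      marker_tracts=MARKERS, seed=1, n_perm=200)
        n_val = len(behaviour) // 3
        ci = 2.6 * np.sqrt(0.25 / n_val)
        assert abs(result.validation_accuracy - 0.5) < ci

    def test_planted_shift_predicts(self):
        """0.8 SD behaviour shift with near-perfect group separability:
        validation accuracy lands near the Phi(0.4)~0.655 oracle ceiling."""
        accs = []
        for seed in range(8):
            res, behaviour, _ = self.make_cohort(seed=seed, shift=0.8)
            r = tc.tune_and_validate(res, behaviour, None, "matrix_reasoning",
                                     marker_tracts=MARKERS, seed=seed, n_perm=200)
            accs.append(r.validation_accuracy)
        assert np.mean(accs) > 0.55
        assert sum(a >= 0.55 for a in accs) >= 6

    def test_tuning_ignores_validation_split(self):
        res, behaviour, _ = self.make_cohort(seed=6, shift=0.8)
        r1 = tc.tune_and_validate(res, behaviour, None, "matrix_reasoning",
                                  marker_tracts=MARKERS, seed=2, n_perm=200)
        # permute behaviour values WITHIN the validation third
        rng = np.random.default_rng(99)
        table = res.data.reset_index(drop=True)
        order = np.random.default_rng(2).permutation(len(table))
        third = len(table) // 3
        idx_val = order[2 * third: 3 * third]
        beh2 = behaviour.copy().set_index("participant_id")
        ids_val = table.loc[idx_val, "participant_id"]
        vals = beh2.loc[ids_val, "matrix_reasoning"].to_numpy()
        beh2.loc[ids_val, "matrix_reasoning"] = rng.permutation(vals)
        r2 = tc.tune_and_validate(res, beh2.reset_index(), None,
                                  "matrix_reasoning", marker_tracts=MARKERS,
                                  seed=2, n_perm=200)
        assert r2.tuned_value == r1.tuned_value
        assert r2.train_accuracy == r1.train_accuracy
        assert r2.test_accuracy == r1.test_accuracy

    def test_accuracy_invariant_to_monotone_transform(self):
        res, behaviour, _ = self.make_cohort(seed=7, shift=0.8)
        r1 = tc.tune_and_validate(res, behaviour, None, "matrix_reasoning",
                                  marker_tracts=MARKERS, seed=3, n_perm=200)
        beh2 = behaviour.copy()
        beh2["matrix_reasoning"] = np.exp(beh2["matrix_reasoning"])
        r2 = tc.tune_and_validate(res, beh2, None, "matrix_reasoning",
                                  marker_tracts=MARKERS, seed=3, n_perm=200)
        assert r2.validation_accuracy == r1.validation_accuracy
        assert r2.tuned_value == r1.tuned_value


class TestPermutationP:
    def test_perfect_accuracy_small_p(self):
        rng = np.random.default_rng(0)
        labels = np.array(["C1"] * 20 + ["C2"] * 20)
        behaviour = np.concatenate([rng.uniform(1, 2, 20), rng.uniform(-2, -1, 20)])
        p = transfer.permutation_p(1.0, labels, behaviour, n_perm=1000, seed=1)
        assert p <= 0.01

    def test_chance_accuracy_p_near_half(self):
        rng = np.random.default_rng(1)
        labels = np.array(["C1", "C2"] * 30)
        behaviour = rng.normal(size=60)
        obs = transfer.median_split_accuracy(labels, behaviour,
                                             float(np.median(behaviour)), "C1")
        p = transfer.permutation_p(obs, labels, behaviour, n_perm=1000, seed=2)
        assert 0.1 < p <= 1.0

    def test_add_one_estimator_bounds(self):
        rng = np.random.default_rng(3)
        labels = np.array(["C1", "C2"] * 10)
        behaviour = rng.normal(size=20)
        for obs in (0.0, 0.5, 1.0):
            p = transfer.permutation_p(obs, labels, behaviour, n_perm=100, seed=0)
            assert 0 < p <= 1

    def test_degenerate_behaviour_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            transfer.permutation_p(0.5, np.array(["C1", "C2"] * 60),
                                   np.ones(120), n_perm=100)


class TestClusterFit:
    def test_two_cliques_exact_strengths(self, two_clique_net):
        table = pd.DataFrame({
            "participant_id": two_clique_net.ids,
            "label": ["C1"] * 5 + ["C2"] * 5,
        })
        ga = tc.GroupAssignment(table=table, rule="percentile-range")
        fit = tc.cluster_fit(two_clique_net, ga, n_perm=200, seed=0)
        w = two_clique_net.weights
        pos_total = w[w > 0].sum() / 2
        neg_total = w[w < 0].sum() / 2
        assert fit["intra_strength"] == pytest.approx(pos_total)
        assert fit["inter_strength"] == pytest.approx(neg_total)
        assert fit["p_intra"] < 0.05
        assert fit["p_inter"] < 0.05

    def test_c0_excluded(self, two_clique_net):
        table = pd.DataFrame({
            "participant_id": two_clique_net.ids,
            "label": ["C1"] * 5 + ["C2"] * 4 + ["C0"],
        })
        ga = tc.GroupAssignment(table=table, rule="percentile-range")
        fit = tc.cluster_fit(two_clique_net, ga, n_perm=100, seed=0)
        w = two_clique_net.weights[:9, :9]
        assert fit["intra_strength"] == pytest.approx(
            w[:5, :5].sum() / 2 + w[5:9, 5:9].sum() / 2
        )

    def test_all_unassigned_rejected(self, two_clique_net):
        table = pd.DataFrame({"participant_id": two_clique_net.ids,
                              "label": ["C0"] * 10})
        ga = tc.GroupAssignment(table=table, rule="percentile-range")
        with pytest.raises(ValueError, match="unassigned"):
            tc.cluster_fit(two_clique_net, ga)
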
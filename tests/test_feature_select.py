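import itertools
import math

import numpy as np
import pytest

from beadbench.feature_select import (
    DiscretizedMatrix,
    FeatureSetParams,
    InfeasibleError,
    build_coverage,
    discretize_matrix,
    fayyad_irani_discretize,
    max_alpha_beta,
    maxcover_de,
    solve_feature_set,
)
from beadbench.normalize import normalize_none
from beadbench.synthetic import SimulationConfig, simulate_experiment

from conftest import make_labels, make_matrix


# ---------------------------------------------------------------------------
# independent oracles


def entropy_oracle(labels):
    n = len(labels)
    out = 0.0
    for c in set(labels):
        p = labels.count(c) / n
        out -= p * math.log2(p)
    return out


def brute_force_cut(values, labels):
    """Exhaustive search over all midpoints between distinct sorted values,
    plus a hand-coded MDL accept/reject evaluation."""
    pairs = sorted(zip(values, labels))
    v = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    n = len(v)
    distinct = sorted(set(v))
    best = None
    for a, b in zip(distinct, distinct[1:]):
        cut = (a + b) / 2
        s1 = [y[i] for i in range(n) if v[i] <= cut]
        s2 = [y[i] for i in range(n) if v[i] > cut]
        e = len(s1) / n * entropy_oracle(s1) + len(s2) / n * entropy_oracle(s2)
        if best is None or e < best[0] - 1e-12:
            best = (e, cut, s1, s2)
    if best is None:
        return None, False, 0.0
    e, cut, s1, s2 = best
    ent_s = entropy_oracle(y)
    gain = ent_s - e
    c = len(set(y))
    c1, c2 = len(set(s1)), len(set(s2))
    delta = math.log2(3**c - 2) - (
        c * ent_s - c1 * entropy_oracle(s1) - c2 * entropy_oracle(s2))
    accepted = gain > math.log2(n - 1) / n + delta / n
    return cut, accepted, gain


def coverage_oracle(binary, classes):
    """Brute-force pair x feature coverage table."""
    n = len(classes)
    covers = {}
    for f in range(binary.shape[0]):
        cov = set()
        for i, j in itertools.combinations(range(n), 2):
            differs = binary[f, i] != binary[f, j]
            if (classes[i] != classes[j]) == differs:
                cov.add((i, j))
        covers[f] = cov
    return covers


def exhaustive_min_k(cov, alpha, beta):
    """Exhaustive minimal feasible subset size (oracle)."""
    feats = cov.feature_ids

    def feasible(subset):
        for p in cov.inter_pairs:
            if sum(p in cov.covers[f] for f in subset) < alpha:
                return False
        for p in cov.intra_pairs:
            if sum(p in cov.covers[f] for f in subset) < beta:
                return False
        return True

    for k in range(len(feats) + 1):
        for subset in itertools.combinations(feats, k):
            if feasible(subset):
                return k, subset
    return None, None


def random_instance(rng, max_features=12, max_samples=8):
    n_f = rng.integers(2, max_features + 1)
    n_s = rng.integers(4, max_samples + 1)
    n_ctrl = n_s // 2
    binary = rng.integers(0, 2, size=(n_f, n_s)).astype(np.int8)
    sample_ids = [f"S{j}" for j in range(n_s)]
    d = DiscretizedMatrix(
        feature_ids=[f"F{i:02d}" for i in range(n_f)],
        sample_ids=sample_ids,
        binary=binary,
        thresholds={f"F{i:02d}": 0.5 for i in range(n_f)},
        gains={f"F{i:02d}": 1.0 for i in range(n_f)},
    )
    return d, make_labels(sample_ids, n_ctrl)


# ---------------------------------------------------------------------------


class TestFayyadIrani:
    def test_worked_example(self):
        # values 1,2,3,10,11,12 / AAABBB: cut 6.5, Gain 1 bit, MDL bound
        # log2(5)/6 + (log2(7) - 2)/6 ~ 0.522 < 1 -> accepted
        res = fayyad_irani_discretize([1, 2, 3, 10, 11, 12],
                                      ["A", "A", "A", "B", "B", "B"])
        assert res.threshold == 6.5
        assert res.gain == pytest.approx(1.0)
        bound = math.log2(5) / 6 + (math.log2(7) - 2) / 6
        assert bound == pytest.approx(0.5215, abs=1e-3)
        assert res.accepted

    def test_interleaved_rejected(self):
        res = fayyad_irani_discretize([1, 2, 3, 4], ["A", "B", "A", "B"])
        assert not res.accepted

    def test_constant_feature_rejected_no_exception(self):
        res = fayyad_irani_discretize([5, 5, 5, 5], ["A", "A", "B", "B"])
        assert res.threshold is None
        assert not res.accepted

    def test_matches_brute_force_on_random_features(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 21))
            values = rng.choice([0, 1], p=[0.8, 0.2]) * rng.integers(1, 5, n) \
                + rng.uniform(0, 10, n)  # occasional ties
            labels = list(rng.choice(["A", "B"], n))
            if len(set(labels)) < 2:
                labels[0] = "A"
                labels[1] = "B"
            res = fayyad_irani_discretize(values, labels)
            cut_ref, acc_ref, gain_ref = brute_force_cut(list(values), labels)
            if cut_ref is None:
                assert not res.accepted
                continue
            assert res.accepted == acc_ref
            assert res.gain == pytest.approx(gain_ref, abs=1e-10)
            if res.accepted:
                assert res.threshold == pytest.approx(cut_ref, abs=1e-12)

    def test_cut_is_boundary_midpoint(self, rng):
        # Fayyad-Irani boundary-point theorem: the chosen cut is always a
        # midpoint between consecutive distinct values
        for _ in range(50):
            n = int(rng.integers(4, 15))
            values = rng.uniform(0, 10, n)
            labels = list(rng.choice(["A", "B"], n))
            if len(set(labels)) < 2:
                labels[:2] = ["A", "B"]
            res = fayyad_irani_discretize(values, labels)
            if res.threshold is None:
                continue
            sv = np.unique(values)
            midpoints = (sv[:-1] + sv[1:]) / 2
            assert np.min(np.abs(midpoints - res.threshold)) < 1e-12


class TestDiscretizeMatrix:
    def test_constant_features_all_dropped(self):
        m = make_matrix(np.ones((5, 6)))
        labels = make_labels(m.sample_ids, 3)
        d = discretize_matrix(normalize_none(m), labels)
        assert d.feature_ids == []
        assert d.dropped == set(m.probe_ids)

    def test_one_separating_feature_retained(self):
        sig = np.ones((4, 6))
        sig[2] = [1, 2, 3, 10, 11, 12]
        m = make_matrix(sig)
        labels = make_labels(m.sample_ids, 3)
        d = discretize_matrix(normalize_none(m), labels)
        assert d.feature_ids == ["P2"]
        assert d.thresholds["P2"] == 6.5
        assert np.array_equal(d.binary[0], [0, 0, 0, 1, 1, 1])

    def test_sample_order_invariance(self, rng):
        sig = rng.normal(100, 20, (20, 8))
        sig[:5, 4:] += 80
        m1 = make_matrix(sig)
        labels1 = make_labels(m1.sample_ids, 4)
        perm = np.concatenate([rng.permutation(4), 4 + rng.permutation(4)])
        m2 = make_matrix(sig[:, perm], sample_ids=[m1.sample_ids[j] for j in perm])
        labels2 = labels1
        d1 = discretize_matrix(normalize_none(m1), labels1)
        d2 = discretize_matrix(normalize_none(m2), labels2)
        assert d1.retained == d2.retained
        assert d1.thresholds == d2.thresholds


class TestCoverage:
    def test_two_samples_inter_covered(self):
        d = DiscretizedMatrix(["F0"], ["S0", "S1"], np.array([[0, 1]]),
                              {"F0": 0.5}, {"F0": 1.0})
        # only 1/1 split: bypass class-size validation via direct construction
        from beadbench.io_bead import ClassLabels
        labels = ClassLabels.__new__(ClassLabels)
        labels.assignment = {"S0": "control", "S1": "test"}
        labels.control_class = "control"
        cov = build_coverage(d, labels)
        assert cov.inter_pairs == [(0, 1)]
        assert cov.covers["F0"] == {(0, 1)}

    def test_same_class_disagreeing_not_covered(self):
        from beadbench.io_bead import ClassLabels
        labels = ClassLabels.__new__(ClassLabels)
        labels.assignment = {"S0": "control", "S1": "control"}
        labels.control_class = "control"
        d = DiscretizedMatrix(["F0"], ["S0", "S1"], np.array([[0, 1]]),
                              {"F0": 0.5}, {"F0": 1.0})
        cov = build_coverage(d, labels)
        assert cov.intra_pairs == [(0, 1)]
        assert cov.covers["F0"] == set()

    def test_matches_exhaustive_enumeration(self, rng):
        binary = np.array([[0, 0, 1, 1], [0, 1, 0, 1], [1, 1, 1, 1]], dtype=np.int8)
        d = DiscretizedMatrix([f"F{i}" for i in range(3)],
                              [f"S{j}" for j in range(4)], binary,
                              {f"F{i}": 0.5 for i in range(3)},
                              {f"F{i}": 1.0 for i in range(3)})
        labels = make_labels(d.sample_ids, 2)
        cov = build_coverage(d, labels)
        oracle = coverage_oracle(binary, labels.label_vector(d.sample_ids))
        for i, f in enumerate(d.feature_ids):
            assert cov.covers[f] == oracle[i]
        # every pair in exactly one of inter/intra
        allp = set(cov.inter_pairs) | set(cov.intra_pairs)
        assert len(allp) == 6
        assert not set(cov.inter_pairs) & set(cov.intra_pairs)


class TestMaxAlphaBeta:
    def test_single_all_covering_feature(self):
        binary = np.array([[0, 0, 1, 1]], dtype=np.int8)
        d = DiscretizedMatrix(["F0"], [f"S{j}" for j in range(4)], binary,
                              {"F0": 0.5}, {"F0": 1.0})
        labels = make_labels(d.sample_ids, 2)
        params = max_alpha_beta(build_coverage(d, labels))
        assert (params.alpha, params.beta) == (1, 1)

    def test_duplicating_features_doubles_ceiling(self, rng):
        d, labels = random_instance(rng)
        cov = build_coverage(d, labels)
        base = max_alpha_beta(cov)
        dd = DiscretizedMatrix(
            d.feature_ids + [f + "_copy" for f in d.feature_ids],
            d.sample_ids, np.vstack([d.binary, d.binary]),
            {**d.thresholds, **{f + "_copy": t for f, t in d.thresholds.items()}},
            {**d.gains, **{f + "_copy": g for f, g in d.gains.items()}},
        )
        doubled = max_alpha_beta(build_coverage(dd, labels))
        assert doubled.alpha == 2 * base.alpha
        assert doubled.beta == 2 * base.beta

    def test_uncovered_inter_pair_alpha_zero(self):
        binary = np.array([[1, 1, 1, 1]], dtype=np.int8)  # never discriminates
        d = DiscretizedMatrix(["F0"], [f"S{j}" for j in range(4)], binary,
                              {"F0": 0.5}, {"F0": 1.0})
        labels = make_labels(d.sample_ids, 2)
        params = max_alpha_beta(build_coverage(d, labels))
        assert params.alpha == 0
        assert params.beta == 1


class TestSolver:
    def test_singleton_solution(self):
        binary = np.array([[0, 0, 1, 1], [0, 1, 1, 1]], dtype=np.int8)
        d = DiscretizedMatrix(["F0", "F1"], [f"S{j}" for j in range(4)], binary,
                              {"F0": 0.5, "F1": 0.5}, {"F0": 1.0, "F1": 0.5})
        labels = make_labels(d.sample_ids, 2)
        cov = build_coverage(d, labels)
        for solver in ("greedy", "exact"):
            sol = solve_feature_set(cov, FeatureSetParams(1, 1, 1), solver=solver)
            assert sol.features == ["F0"]
            assert sol.feasible

    def test_infeasible_alpha_error(self):
        binary = np.array([[0, 0, 1, 1]], dtype=np.int8)
        d = DiscretizedMatrix(["F0"], [f"S{j}" for j in range(4)], binary,
                              {"F0": 0.5}, {"F0": 1.0})
        labels = make_labels(d.sample_ids, 2)
        cov = build_coverage(d, labels)
        with pytest.raises(InfeasibleError):
            solve_feature_set(cov, FeatureSetParams(2, 0, 1))

    def test_greedy_vs_exact_on_random_instances(self, rng):
        # exact k <= greedy k; both feasible by brute-force recount
        for _ in range(120):
            d, labels = random_instance(rng)
            cov = build_coverage(d, labels)
            ceiling = max_alpha_beta(cov)
            alpha = int(rng.integers(0, ceiling.alpha + 1))
            beta = int(rng.integers(0, ceiling.beta + 1))
            if alpha == 0 and beta == 0:
                continue
            params = FeatureSetParams(alpha, beta, 0)
            greedy = solve_feature_set(cov, params, solver="greedy")
            k_exact, subset = exhaustive_min_k(cov, alpha, beta)
            assert greedy.feasible
            assert k_exact is not None
            assert k_exact <= len(greedy.features)
            exact = solve_feature_set(cov, params, solver="exact")
            assert len(exact.features) == k_exact
            # brute-force recount of both solutions
            for sol in (greedy, exact):
                for p in cov.inter_pairs:
                    assert sum(p in cov.covers[f] for f in sol.features) >= alpha
                for p in cov.intra_pairs:
                    assert sum(p in cov.covers[f] for f in sol.features) >= beta

    def test_max_cover_mode_extends_to_k(self, rng):
        d, labels = random_instance(rng)
        cov = build_coverage(d, labels)
        ceiling = max_alpha_beta(cov)
        a = min(1, ceiling.alpha)
        b = min(1, ceiling.beta)
        base = solve_feature_set(cov, FeatureSetParams(a, b, 0), mode="min_k")
        k = min(len(cov.feature_ids), len(base.features) + 1)
        ext = solve_feature_set(cov, FeatureSetParams(a, b, k), mode="max_cover")
        assert len(ext.features) == k
        assert ext.total_coverage >= base.total_coverage

    def test_max_cover_k_below_minimum_error(self):
        binary = np.array([[0, 0, 1, 1], [1, 0, 1, 1], [0, 1, 1, 1]], dtype=np.int8)
        d = DiscretizedMatrix([f"F{i}" for i in range(3)],
                              [f"S{j}" for j in range(4)], binary,
                              {f"F{i}": 0.5 for i in range(3)},
                              {f"F{i}": 1.0 for i in range(3)})
        labels = make_labels(d.sample_ids, 2)
        cov = build_coverage(d, labels)
        ceiling = max_alpha_beta(cov)
        base = solve_feature_set(cov, FeatureSetParams(ceiling.alpha, ceiling.beta, 0))
        if len(base.features) > 1:
            with pytest.raises(InfeasibleError):
                solve_feature_set(
                    cov, FeatureSetParams(ceiling.alpha, ceiling.beta,
                                          len(base.features) - 1),
                    mode="max_cover")

    def test_exact_guard(self, rng):
        d, labels = random_instance(rng)
        big = DiscretizedMatrix(
            [f"F{i:03d}" for i in range(25)], d.sample_ids,
            rng.integers(0, 2, (25, len(d.sample_ids))).astype(np.int8),
            {f"F{i:03d}": 0.5 for i in range(25)},
            {f"F{i:03d}": 1.0 for i in range(25)},
        )
        cov = build_coverage(big, labels)
        with pytest.raises(ValueError, match="guard"):
            solve_feature_set(cov, FeatureSetParams(0, 0, 1), solver="exact")

    def test_permutation_invariance_minimal_k(self, rng):
        d, labels = random_instance(rng)
        cov = build_coverage(d, labels)
        ceiling = max_alpha_beta(cov)
        if ceiling.alpha == 0 and ceiling.beta == 0:
            return
        params = FeatureSetParams(ceiling.alpha, ceiling.beta, 0)
        k1 = len(solve_feature_set(cov, params).features)
        perm = rng.permutation(len(d.sample_ids))
        d2 = DiscretizedMatrix(
            d.feature_ids, [d.sample_ids[j] for j in perm],
            d.binary[:, perm], d.thresholds, d.gains)
        cov2 = build_coverage(d2, labels)
        k2 = len(solve_feature_set(cov2, params).features)
        assert k1 == k2


class TestMaxCoverDE:
    def test_single_perfect_separator(self):
        sig = np.ones((4, 6))
        sig[1] = [1, 2, 3, 10, 11, 12]
        m = make_matrix(sig)
        labels = make_labels(m.sample_ids, 3)
        ps = maxcover_de(normalize_none(m), labels)
        assert ps.probe_ids == ["P1"]
        assert ps.scores["P1"].p_value is None
        assert ps.scores["P1"].direction == "up"

    def test_empty_retained_set_empty_probe_set(self):
        m = make_matrix(np.ones((4, 6)))
        labels = make_labels(m.sample_ids, 3)
        with pytest.warns(UserWarning, match="no features"):
            ps = maxcover_de(normalize_none(m), labels)
        assert len(ps) == 0

    def test_strong_planted_folds_all_retained(self):
        # fold >= 2 with tiny noise at n=5/group separates perfectly
        cfg = SimulationConfig(n_probes=200, frac_unexpressed=0.0, frac_de=0.1,
                               fold_range=(2.0, 2.5), bio_cv=0.05,
                               array_scale_cv=0.0, bead_cv=0.0,
                               n_per_group=(5, 5), seed=21)
        m, labels, truth = simulate_experiment(cfg)
        d = discretize_matrix(normalize_none(m), labels)
        assert set(truth.de_probes) <= d.retained

    def test_provenance_records_params(self, rng):
        sig = rng.normal(100, 10, (30, 8))
        sig[:6, 4:] += 100
        m = make_matrix(sig)
        labels = make_labels(m.sample_ids, 4)
        ps = maxcover_de(normalize_none(m), labels)
        for key in ("alpha", "beta", "k", "solver", "n_retained"):
            assert key in ps.provenance
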
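import itertools
import math

import numpy as np
import pytest

from adaptsel import SyntheticSpec, generate, normalize_minmax
from adaptsel.chemspace import distance_matrix, pca_project
from adaptsel.selectors_adaptive import (
    DescriptorScores,
    compute_exponent,
    descrep_run,
    initial_seed,
    pls_optimal_extend,
    pls_optimal_run,
    priority_scores,
    score_descriptors,
    select_batch,
    select_descriptors,
)

from .conftest import make_space


class TestScoreDescriptors:
    def test_self_correlated_descriptor_scores_one(self, rng):
        y = rng.normal(size=10)
        X = np.column_stack([y, rng.normal(size=10)])
        s = score_descriptors(X, y, X)
        assert s.S[0] == pytest.approx(1.0)

    def test_constant_descriptor_scores_zero(self, rng):
        X = np.column_stack([np.full(8, 3.0), rng.normal(size=8)])
        s = score_descriptors(X, rng.normal(size=8), X)
        assert s.S[0] == 0.0
        assert s.M[0, 0] == 1.0 and s.M[0, 1] == 0.0

    def test_linear_column_ranks_first(self, rng):
        x = np.arange(5.0)
        y = 2.0 * x
        X = np.column_stack([x, rng.normal(size=5)])
        s = score_descriptors(X, y, X)
        # hand Pearson: r(x, 2x) = 1
        assert s.S[0] == pytest.approx(1.0)
        assert np.argmax(s.S) == 0

    def test_m_is_absolute_symmetric_unit_diagonal(self, rng):
        X = rng.normal(size=(30, 6))
        s = score_descriptors(X[:5], rng.normal(size=5), X)
        assert np.allclose(s.M, s.M.T)
        assert np.all((s.M >= 0) & (s.M <= 1))
        assert np.allclose(np.diag(s.M), 1.0)

    def test_too_few_measured_rejected(self, rng):
        X = rng.normal(size=(2, 3))
        with pytest.raises(ValueError, match="3 measured"):
            score_descriptors(X, np.array([1.0, 2.0]), X)


class TestSelectDescriptors:
    def test_perfectly_correlated_runner_up_annihilated(self):
        S = np.array([0.9, 0.8, 0.5])
        M = np.eye(3)
        M[0, 1] = M[1, 0] = 1.0  # descriptor 1 duplicates descriptor 0
        picked = select_descriptors(DescriptorScores(S=S, M=M), 2)
        assert picked == [0, 2]

    def test_orthogonal_descriptor_untouched(self):
        S = np.array([0.9, 0.8])
        picked = select_descriptors(DescriptorScores(S=S, M=np.eye(2)), 2)
        assert picked == [0, 1]

    def test_cubic_downweight_value(self):
        # printed update: 0.6 * (1 - 0.5)^3 = 0.075
        S = np.array([0.9, 0.6])
        M = np.eye(2)
        M[0, 1] = M[1, 0] = 0.5
        scores = DescriptorScores(S=S.copy(), M=M)
        select_descriptors(scores, 1)
        updated = S[1] * (1 - M[0, 1]) ** 3
        assert updated == pytest.approx(0.075)

    def test_exhausted_scores_fill_by_lowest_index(self):
        S = np.array([0.5, 0.0, 0.0])
        M = np.eye(3)
        with pytest.warns(UserWarning, match="exhausted"):
            picked = select_descriptors(DescriptorScores(S=S, M=M), 3)
        assert picked == [0, 1, 2]


class TestInitialSeed:
    def test_two_separated_clusters_one_each(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.05, (2, 2)), rng.normal(10, 0.05, (2, 2))]
        )
        seed = initial_seed(make_space(pts), 2, rng=rng)
        assert len({0, 1} & set(seed)) == 1
        assert len({2, 3} & set(seed)) == 1

    def test_k1_returns_central(self, cloud_space, rng):
        from adaptsel.chemspace import central_index

        assert initial_seed(cloud_space, 1, rng=rng) == [central_index(cloud_space.DM)]

    def test_three_tight_triads_recover_brute_force_medoids(self, rng):
        centers = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        pts = np.vstack([c + rng.normal(0, 0.1, (3, 2)) for c in centers])
        space = make_space(pts)
        seed = initial_seed(space, 3, rng=rng)
        # brute-force: best partition into 3 groups by within-group distances
        best, best_obj = None, np.inf
        from scipy.spatial.distance import pdist, squareform

        full = squareform(pdist(pts))
        for labels in itertools.product(range(3), repeat=9):
            if len(set(labels)) < 3:
                continue
            obj = sum(
                full[i, j]
                for i in range(9)
                for j in range(i + 1, 9)
                if labels[i] == labels[j]
            )
            if obj < best_obj:
                best_obj, best = obj, labels
        medoids = []
        for c in set(best):
            members = [i for i in range(9) if best[i] == c]
            sums = [sum(space.DM[i, j] for j in members) for i in members]
            medoids.append(members[int(np.argmin(sums))])
        assert sorted(seed) == sorted(medoids)


class TestComputeExponent:
    def test_fixed_point(self):
        # if 1 - d_k = lambda the defining equation gives exp = 1
        DM = distance_matrix(np.array([[0.0], [0.25], [1.0]]))
        exp = compute_exponent(DM, central=1, n_cover=1, lamda=1 - DM[1, 0])
        assert exp == pytest.approx(1.0)

    def test_near_duplicate_needs_sharp_kernel(self):
        pts = np.array([[0.0], [1e-12], [1.0]])
        DM = distance_matrix(pts)
        exp = compute_exponent(DM, central=0, n_cover=1)
        assert exp > 1e6

    def test_printed_value(self):
        # lambda = 0.75, d_k = 0.5 -> exp = ln .75 / ln .5 ~ 0.415
        DM = np.array([[0.0, 0.5, 1.0], [0.5, 0.0, 0.5], [1.0, 0.5, 0.0]])
        exp = compute_exponent(DM, central=1, n_cover=1, lamda=0.75)
        assert exp == pytest.approx(math.log(0.75) / math.log(0.5), rel=1e-12)
        assert exp == pytest.approx(0.415, abs=5e-4)
        assert (1 - 0.5) ** exp == pytest.approx(0.75)


class TestPriorityScores:
    def test_covered_and_uncovered_extremes(self):
        DM = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        ps = priority_scores(DM, [0], exp=2.0)
        assert ps[0] == 0.0  # selected itself
        assert ps[1] == 0.0  # coincident with a selected compound
        assert ps[2] == 1.0  # maximally distant

    def test_printed_cf_value(self):
        # CF(DM=0.5, exp=2) = 1 - 0.25 = 0.75
        DM = np.array([[0.0, 0.5], [0.5, 0.0]])
        ps = priority_scores(DM, [0], exp=2.0)
        assert ps[1] == pytest.approx(0.75)

    def test_monotone_under_set_growth(self, cloud_space):
        exp = 1.3
        ps1 = priority_scores(cloud_space.DM, [0], exp)
        ps2 = priority_scores(cloud_space.DM, [0, 5], exp)
        ps3 = priority_scores(cloud_space.DM, [0, 5, 11], exp)
        assert np.all(ps2 <= ps1 + 1e-15)
        assert np.all(ps3 <= ps2 + 1e-15)


class TestSelectBatch:
    def test_uncovered_cluster_preferred(self, rng):
        near = rng.normal(0, 0.05, (5, 2))
        far = rng.normal(8, 0.05, (4, 2))
        space = make_space(np.vstack([near, far]))
        batch = select_batch(space.DM, [0], 1, exp=1.0)
        assert batch[0] >= 5

    def test_exhaustive_matches_enumeration(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(10, 3))
            DM = distance_matrix(pts)
            exp = 1.1
            selected = [0, 1]
            got = select_batch(DM, selected, 2, exp)
            base = priority_scores(DM, selected, exp)
            CF = 1 - (1 - DM) ** exp
            best, best_total = None, np.inf
            for combo in itertools.combinations(range(2, 10), 2):
                total = float((base * CF[:, combo[0]] * CF[:, combo[1]]).sum())
                if total < best_total - 1e-15:
                    best_total, best = total, combo
            assert tuple(got) == best

    def test_greedy_never_increases_total_ps(self, cloud_space):
        exp = 1.2
        before = priority_scores(cloud_space.DM, [0, 3], exp).sum()
        batch = select_batch(
            cloud_space.DM, [0, 3], 4, exp, max_exhaustive=1
        )  # force greedy
        after = priority_scores(cloud_space.DM, [0, 3] + batch, exp).sum()
        assert after <= before + 1e-12


class TestDescrepRun:
    def oracle(self, y):
        return lambda idx: y[np.asarray(idx, dtype=int)]

    def test_schedule_of_one_equals_seed(self, small_table):
        table, y, _ = small_table
        run = descrep_run(table, self.oracle(y), [5], rng=np.random.default_rng(1))
        assert run.selected == run.cycles[0].new_indices
        assert len(run.cycles) == 1

    def test_seeded_determinism(self, small_table):
        table, y, _ = small_table
        a = descrep_run(table, self.oracle(y), [5, 7, 10], rng=np.random.default_rng(4))
        b = descrep_run(table, self.oracle(y), [5, 7, 10], rng=np.random.default_rng(4))
        assert a.selected == b.selected

    def test_selections_nested_across_schedule(self, small_table):
        table, y, _ = small_table
        run = descrep_run(
            table, self.oracle(y), [5, 7, 10, 15], rng=np.random.default_rng(2)
        )
        for s, s2 in zip(run.schedule, run.schedule[1:]):
            assert run.selection_at(s) == run.selection_at(s2)[:s]
        assert len(run.selected) == 15
        assert len(set(run.selected)) == 15

    def test_driver_descriptors_recovered(self):
        # two mutually uncorrelated drivers among 50 descriptors; the
        # refinement schedule measures 10/20/30 compounds so the Pearson
        # ranking has stabilized by the second adaptive cycle
        hits = 0
        for seed in range(25):
            spec = SyntheticSpec(
                n_compounds=150, n_dense=2, n_sparse=48, dense_corr=0.0,
                drivers=(0, 1), weights=(1.0, 0.8), noise_sd=0.1, seed=seed,
            )
            table, y, truth = generate(spec)
            table = normalize_minmax(table)
            run = descrep_run(
                table, self.oracle(y), [10, 20, 30],
                rng=np.random.default_rng(seed + 1000),
            )
            picked = set(run.cycles[2].descriptor_indices)
            if set(truth["drivers"]) <= picked:
                hits += 1
        assert hits >= 20  # >= 80% of 25 replicates

    def test_correlated_driver_pair_yields_one_representative(self):
        # strongly anticorrelated dense drivers: the cubic decorrelation is
        # expected to keep only one of them, by design
        spec = SyntheticSpec(
            n_compounds=150, n_dense=2, n_sparse=48,
            drivers=(0, 1), weights=(1.0, -0.8), dense_corr=-0.9,
            noise_sd=0.1, seed=0,
        )
        table, y, truth = generate(spec)
        table = normalize_minmax(table)
        run = descrep_run(
            table, self.oracle(y), [10, 20, 30], rng=np.random.default_rng(7)
        )
        picked = set(run.cycles[2].descriptor_indices)
        assert len(picked & {0, 1}) == 1

    def test_permutation_equivariance(self, small_table):
        # the adaptive cycles are deterministic given the seed compounds, so
        # reordering the table must select the same compound identities
        table, y, _ = small_table
        seed = [2, 10, 25, 40, 55]
        run = descrep_run(
            table, self.oracle(y), [5, 7, 10], rng=np.random.default_rng(9),
            seed_indices=seed,
        )
        perm = np.random.default_rng(3).permutation(table.n_compounds)
        inv = np.argsort(perm)
        pt = table.subset(perm)
        py = y[perm]
        pseed = [int(inv[i]) for i in seed]
        prun = descrep_run(
            pt, self.oracle(py), [5, 7, 10], rng=np.random.default_rng(1234),
            seed_indices=pseed,
        )
        ids = [table.ids[i] for i in run.selected]
        pids = [pt.ids[i] for i in prun.selected]
        assert sorted(ids[5:7]) == sorted(pids[5:7])
        assert sorted(ids) == sorted(pids)


class TestPlsOptimal:
    def oracle(self, y):
        return lambda idx: y[np.asarray(idx, dtype=int)]

    def test_single_factor_limit(self, rng):
        # y perfectly linear in descriptor 0: LV1 concentrates there
        X = rng.random((40, 5))
        y = 3.0 * X[:, 0]
        from adaptsel.selectors_adaptive import _fit_pls_scores

        pls = _fit_pls_scores(X, y, 1)
        w = np.abs(pls.x_weights_[:, 0])
        assert np.argmax(w) == 0
        scores = pls.transform(X)[:, 0]
        r = abs(np.corrcoef(scores, X[:, 0])[0, 1])
        assert r > 0.95

    def test_batch_zero_returns_selected(self, small_table):
        table, y, _ = small_table
        sel = [0, 3, 5, 9, 11, 20, 33]
        out = pls_optimal_extend(table, y[sel], sel, batch=0)
        assert out == sel

    def test_extension_beats_random_extensions(self, small_table, rng):
        table, y, _ = small_table
        sel = list(range(0, 20, 2))
        out = pls_optimal_extend(table, y[sel], sel, batch=5, rng=rng)
        new = [i for i in out if i not in sel]
        assert len(new) == 5

        from adaptsel.selectors_adaptive import _fit_pls_scores

        pls = _fit_pls_scores(table.X[sel], y[sel], 5)
        scores = pls.transform(table.X)

        def det_of(idx):
            Xs = np.hstack([np.ones((len(idx), 1)), scores[list(idx)]])
            return np.linalg.det(Xs.T @ Xs)

        d_star = det_of(out)
        pool = [i for i in range(table.n_compounds) if i not in sel]
        for _ in range(50):
            cand = sel + [int(i) for i in rng.choice(pool, 5, replace=False)]
            assert d_star >= det_of(cand) * (1 - 1e-9)

    def test_run_nested_and_deterministic(self, small_table):
        table, y, _ = small_table
        a = pls_optimal_run(table, self.oracle(y), [5, 7, 10], rng=np.random.default_rng(6))
        b = pls_optimal_run(table, self.oracle(y), [5, 7, 10], rng=np.random.default_rng(6))
        assert a.selected == b.selected
        assert a.selection_at(5) == a.selection_at(10)[:5]
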
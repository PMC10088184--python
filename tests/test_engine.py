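import numpy as np
import pytest

from evoqtl.data import split_data
from evoqtl.engine import (
    SENTINEL_FITNESS,
    FitnessPair,
    GPConfig,
    ParetoArchive,
    crossover,
    difference_score,
    evaluate_pipeline,
    evolve,
    fast_nondominated_sort,
    holdout_scores,
    mutate,
    nsga2_select,
    random_pipeline,
    summarize_front,
)
from evoqtl.operators import EncodingMap, RegressorSpec, SelectorSpec
from evoqtl.pipeline import EmptyPipelineError, PipelineTree, execute_pipeline
from oracles import brute_force_select

LR = RegressorSpec("LR")


def plain(root=LR, *phases):
    return PipelineTree(tuple(phases), root)


class TestDifferenceScore:
    @pytest.mark.parametrize(
        "train,test,expected",
        [(0.50, 0.25, 2**0.5), (1.0, 0.0, 1.0), (0.3, 0.3, 100.0), (0.0, 1.0, 1.0)],
    )
    def test_closed_form(self, train, test, expected):
        assert difference_score(train, test) == pytest.approx(expected)

    def test_range(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.uniform(-1, 1, 2)
            assert 0 < difference_score(a, b) <= 100.0


class TestRandomPipeline:
    def test_structure_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            t = random_pipeline(rng, max_phases=6)
            assert isinstance(t.root, RegressorSpec)  # exactly one root
            assert t.n_phases <= 6

    def test_deterministic_sequence(self):
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        s1 = [random_pipeline(rng1, 6).key() for _ in range(20)]
        s2 = [random_pipeline(rng2, 6).key() for _ in range(20)]
        assert s1 == s2


class TestExecutePipeline:
    def test_empty_phase_list_identity(self, additive_small):
        X, y, split = additive_small
        Xtr, Xte, mask = execute_pipeline(plain(), X.codes[split.train_idx], X.codes[split.test_idx])
        assert np.array_equal(Xtr, X.codes[split.train_idx])
        assert mask.all()

    def test_encoding_then_threshold_drops_collapsed_column(self):
        # second locus holds only {0,1}: recessive encoding collapses it to 0
        Xtr = np.array([[0, 0], [1, 1], [2, 0], [1, 1]])
        tree = plain(LR, EncodingMap.named("recessive"), SelectorSpec("VT", 0.05))
        _, _, mask = execute_pipeline(tree, Xtr)
        assert mask.tolist() == [True, False]

    def test_phase_order_matters(self):
        Xtr = np.array([[0, 0], [1, 1], [2, 0], [1, 1]])
        a = plain(LR, SelectorSpec("VT", 0.05), EncodingMap.named("recessive"))
        b = plain(LR, EncodingMap.named("recessive"), SelectorSpec("VT", 0.05))
        _, _, mask_a = execute_pipeline(a, Xtr)
        _, _, mask_b = execute_pipeline(b, Xtr)
        assert mask_a.tolist() != mask_b.tolist()

    def test_selector_fit_on_train_only(self):
        # column 1 is constant on train but varies on the apply matrix:
        # the mask must come from train alone and still drop it there
        Xtr = np.array([[0, 1], [1, 1], [2, 1], [0, 1]])
        Xap = np.array([[0, 0], [1, 2]])
        tree = plain(LR, SelectorSpec("VT", 0.0))
        _, Xap_t, mask = execute_pipeline(tree, Xtr, Xap)
        assert mask.tolist() == [True, False]
        assert Xap_t.shape == (2, 1)

    def test_all_removed_raises(self):
        tree = plain(LR, SelectorSpec("VT", 0.35))
        with pytest.raises(EmptyPipelineError):
            execute_pipeline(tree, np.ones((6, 2), dtype=np.int64))


class TestEvaluate:
    def test_noiseless_lr(self, noiseless_linear):
        X, y, split = noiseless_linear
        fit = evaluate_pipeline(plain(), X, y, split, seed=0)
        assert fit.test_r2 == pytest.approx(1.0)
        assert fit.ds == pytest.approx(100.0)

    def test_empty_pipeline_gets_sentinel(self, additive_small):
        X, y, split = additive_small
        # recessive then heterosis collapses every column to 0; VT(0) removes all
        fit = evaluate_pipeline(
            plain(LR, EncodingMap.named("recessive"), EncodingMap.named("heterosis"),
                  SelectorSpec("VT", 0.0)),
            X, y, split, seed=0,
        )
        assert fit == SENTINEL_FITNESS
        assert not fit.valid

    def test_deterministic(self, additive_small):
        X, y, split = additive_small
        tree = plain(RegressorSpec("DT", (("max_depth", 3), ("min_samples_leaf", 2),
                                          ("min_samples_split", 4))),
                     EncodingMap.named("dominant"))
        a = evaluate_pipeline(tree, X, y, split, seed=4)
        b = evaluate_pipeline(tree, X, y, split, seed=4)
        assert a == b


class TestMutation:
    def test_shrink_removes_single_phase(self):
        tree = plain(LR, EncodingMap.named("recessive"))
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(100):
            child = mutate(tree, rng)
            seen.add(child.n_phases)
            assert isinstance(child.root, RegressorSpec)
        assert 0 in seen  # shrink reached the phase-free pipeline

    def test_insert_on_empty_adds_one(self):
        rng = np.random.default_rng(1)
        inserted = [mutate(plain(), rng) for _ in range(200)]
        counts = {t.n_phases for t in inserted}
        assert counts <= {0, 1}  # uniform keeps 0 phases, insert adds exactly 1
        assert 1 in counts

    def test_insert_refused_at_cap(self):
        rng = np.random.default_rng(2)
        full = plain(LR, *[EncodingMap.named("dominant")] * 6)
        for _ in range(200):
            assert mutate(full, rng, max_phases=6).n_phases <= 6

    def test_uniform_hyperparameter_changes_value(self):
        tree = plain(LR, SelectorSpec("VT", 0.05))
        rng = np.random.default_rng(3)
        for _ in range(300):
            child = mutate(tree, rng)
            if child.n_phases == 1 and isinstance(child.phases[0], SelectorSpec) \
                    and child.phases[0].kind == "VT":
                assert child.key() != tree.key()  # resampled until different

    def test_root_never_deleted(self):
        rng = np.random.default_rng(4)
        tree = random_pipeline(rng)
        for _ in range(500):
            tree = mutate(tree, rng)
            assert isinstance(tree.root, RegressorSpec)


class TestCrossover:
    def test_shared_encoder_class(self):
        a = plain(LR, EncodingMap.named("recessive"))
        b = PipelineTree(
            (EncodingMap.named("heterosis"), SelectorSpec("GF", 0.1)),
            RegressorSpec("RF", (("bootstrap", True), ("max_features", 0.25),
                                 ("min_samples_leaf", 3), ("min_samples_split", 11))),
        )
        child = crossover(a, b, np.random.default_rng(0))
        assert child is not None
        assert child.root == a.root  # first offspring keeps parent A's root
        assert child.n_phases <= 6

    def test_phase_free_parents_ineligible(self):
        assert crossover(plain(), plain(RegressorSpec("LR")), np.random.default_rng(0)) is None

    def test_disjoint_classes_ineligible(self):
        a = plain(LR, EncodingMap.named("dominant"))
        b = plain(LR, SelectorSpec("VT", 0.1))
        assert crossover(a, b, np.random.default_rng(1)) is None


class TestNSGA2:
    def _cands(self, fit_values):
        return [(f"p{i}", FitnessPair(a, b)) for i, (a, b) in enumerate(fit_values)]

    def test_strict_domination(self):
        cands = self._cands([(1, 1), (0, 0)])
        assert nsga2_select(cands, 1) == ["p0"]

    def test_mutually_nondominated_all_survive(self):
        cands = self._cands([(1, 0), (0, 1), (0.5, 0.5)])
        assert sorted(nsga2_select(cands, 3)) == ["p0", "p1", "p2"]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(3, 50))
            cands = self._cands(rng.uniform(-1, 1, size=(n, 2)))
            k = int(rng.integers(1, n + 1))
            assert nsga2_select(cands, k) == brute_force_select(cands, k)

    def test_front_partition_is_by_domination(self):
        rng = np.random.default_rng(12)
        fits = [FitnessPair(a, b) for a, b in rng.uniform(0, 1, size=(25, 2))]
        fronts = fast_nondominated_sort(fits)
        assert sorted(i for f in fronts for i in f) == list(range(25))
        # no member of a front is dominated by a member of the same front
        for front in fronts:
            for i in front:
                for j in front:
                    if i != j:
                        assert not (fits[j].test_r2 > fits[i].test_r2
                                    and fits[j].ds > fits[i].ds)


class TestArchive:
    def _member(self, name, a, b):
        return (plain(LR, *[EncodingMap.named(name)]), FitnessPair(a, b))

    def test_dominated_addition_ignored(self):
        arch = ParetoArchive()
        arch.update([self._member("dominant", 1.0, 1.0)])
        arch.update([self._member("recessive", 0.5, 0.5)])
        assert len(arch) == 1

    def test_dominating_addition_collapses(self):
        arch = ParetoArchive()
        arch.update([self._member("dominant", 0.2, 0.2), self._member("recessive", 0.1, 0.9)])
        arch.update([self._member("heterosis", 1.0, 1.0)])
        assert len(arch) == 1
        assert arch.members[0][0].phases[0].name == "heterosis"

    def test_structural_duplicate_ignored(self):
        arch = ParetoArchive()
        arch.update([self._member("dominant", 0.5, 0.5)])
        arch.update([self._member("dominant", 0.5, 0.5)])
        assert len(arch) == 1

    def test_sentinel_never_enters(self):
        arch = ParetoArchive()
        arch.update([(plain(), SENTINEL_FITNESS)])
        assert len(arch) == 0

    def test_invariant_under_random_update_batches(self):
        rng = np.random.default_rng(13)
        arch = ParetoArchive()
        for _ in range(20):
            batch = [(random_pipeline(rng), FitnessPair(*rng.uniform(-1, 1, 2)))
                     for _ in range(15)]
            arch.update(batch)
            fits = [f for _, f in arch]
            keys = [t.key() for t, _ in arch]
            assert len(set(keys)) == len(keys)
            for i, fi in enumerate(fits):
                assert not any(
                    fj.test_r2 >= fi.test_r2 and fj.ds >= fi.ds
                    and (fj.test_r2 > fi.test_r2 or fj.ds > fi.ds)
                    for j, fj in enumerate(fits) if j != i
                )


def archive_hypervolume(archive, ref=(-1.0, 0.0)):
    """Area dominated by the front (both objectives maximized) above ``ref``."""
    pts = sorted(
        {(max(f.test_r2, ref[0]), max(f.ds, ref[1])) for _, f in archive}, reverse=True
    )
    hv, best_y = 0.0, ref[1]
    for i, (x, y) in enumerate(pts):
        x_next = pts[i + 1][0] if i + 1 < len(pts) else ref[0]
        best_y = max(best_y, y)
        hv += (x - x_next) * (best_y - ref[1])
    return hv


@pytest.fixture(scope="module")
def small_run(additive_small):
    X, y, split = additive_small
    config = GPConfig(population_size=12, offspring_size=12, generations=4, seed=21)
    return X, y, split, config, evolve(X, y, split, config)


class TestEvolve:
    def test_deterministic_reruns(self, small_run):
        X, y, split, config, (archive, log) = small_run
        archive2, log2 = evolve(X, y, split, config)
        assert [(t.key(), f) for t, f in archive] == [(t.key(), f) for t, f in archive2]
        assert log.to_frame().equals(log2.to_frame())

    def test_zero_generations_is_initial_front(self, additive_small):
        X, y, split = additive_small
        config = GPConfig(population_size=12, offspring_size=12, generations=0, seed=21)
        archive, log = evolve(X, y, split, config)
        assert len(log.records) == 1
        assert len(archive) >= 1

    def test_best_archive_r2_monotone(self, small_run):
        *_, (archive, log) = small_run
        best = [r.best_archive_test_r2 for r in log.records]
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_hypervolume_monotone(self, additive_small):
        X, y, split = additive_small
        hv = []
        for gens in range(4):
            archive, _ = evolve(X, y, split,
                                GPConfig(population_size=12, offspring_size=12,
                                         generations=gens, seed=21))
            hv.append(archive_hypervolume(archive))
        assert all(b >= a - 1e-12 for a, b in zip(hv, hv[1:]))


class TestReporting:
    def test_holdout_scores(self, noiseless_linear):
        X, y, split = noiseless_linear
        arch = ParetoArchive()
        arch.update([(plain(), evaluate_pipeline(plain(), X, y, split, 0))])
        scores = holdout_scores(arch, X, y, split, seed=0)
        assert scores[0] == pytest.approx(1.0)
        assert holdout_scores(arch, X, y, split, seed=0) == scores

    def test_summary_census(self):
        arch = ParetoArchive()
        trees = [plain(LR, EncodingMap.named("heterosis")), plain(), plain(LR, EncodingMap.named("overdominance")),
                 plain(LR, SelectorSpec("VT", 0.1)),
                 PipelineTree((), RegressorSpec("RF", (("bootstrap", True), ("max_features", 0.5),
                                                       ("min_samples_leaf", 1), ("min_samples_split", 2))))]
        fits = [FitnessPair(0.1, 5.0), FitnessPair(0.5, 1.0), FitnessPair(0.2, 4.0),
                FitnessPair(0.3, 3.0), FitnessPair(0.4, 2.0)]
        arch.update(list(zip(trees, fits)))
        s = summarize_front(arch)
        assert s.n_pipelines == 5
        assert s.root_percent["LR"] == pytest.approx(80.0)
        assert s.root_percent["RF"] == pytest.approx(20.0)
        classes = dict(zip(s.members["pipeline"], s.members["encoding_class"]))
        assert classes["Heterosis | LR"] == "2-level"
        assert classes["Overdominance | LR"] == "3-level"
        assert classes["LR"] == "additive"
        assert classes["VT (0.1) | LR"] == "additive"
        assert s.members["pareto_efficient"].all()  # strictly sorted front

    def test_empty_archive_rejected(self):
        with pytest.raises(ValueError):
            summarize_front(ParetoArchive())
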
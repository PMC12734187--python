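import numpy as np
import pytest

from mdignn.core_io import RunConfig
from mdignn.magnetic_spectral import magnetic_laplacian
from mdignn.mdignn_model import forward
from mdignn.pipeline import featurize
from mdignn.synthetic_data import SimSpec, simulate_benchmark
from mdignn.train_eval import (compute_metrics, cross_validate,
                               rank_candidates, train, train_full)


# --- independent metric oracles -------------------------------------------

def auroc_by_concordance(y, p):
    """All-pairs concordance with half-credit ties."""
    pos, neg = p[y == 1], p[y == 0]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


def mcc_by_formula(y, p, thr=0.5):
    pred = (p >= thr).astype(int)
    tp = np.sum((pred == 1) & (y == 1))
    tn = np.sum((pred == 0) & (y == 0))
    fp = np.sum((pred == 1) & (y == 0))
    fn = np.sum((pred == 0) & (y == 1))
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return (tp * tn - fp * fn) / np.sqrt(d) if d > 0 else 0.0


class TestComputeMetrics:
    def test_perfect_ranking(self):
        m = compute_metrics(np.array([1, 1, 0, 0]), np.array([.9, .8, .4, .2]))
        assert m["auroc"] == 1.0
        assert m["aupr"] == 1.0
        assert m["mcc"] == 1.0

    def test_known_confusion_matrix(self):
        # TP=2, TN=3, FP=1, FN=0 -> MCC = 6/sqrt(72)
        y = np.array([1, 1, 0, 0, 0, 0])
        p = np.array([.9, .8, .7, .2, .2, .1])
        m = compute_metrics(y, p)
        assert m["mcc"] == pytest.approx(6 / np.sqrt(72))
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == pytest.approx(3 / 4)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(5 / 6)

    def test_constant_scores_give_chance_auroc(self):
        m = compute_metrics(np.array([1, 0, 1, 0]), np.full(4, 0.7))
        assert m["auroc"] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(4), np.linspace(0, 1, 4))

    def test_matches_brute_force_oracles(self, rng):
        for _ in range(200):
            n = rng.integers(8, 40)
            y = (rng.random(n) < 0.4).astype(float)
            if y.sum() in (0, n):
                continue
            p = np.round(rng.random(n), 2)  # ties likely
            m = compute_metrics(y, p)
            assert m["auroc"] == pytest.approx(auroc_by_concordance(y, p), abs=1e-10)
            assert m["mcc"] == pytest.approx(mcc_by_formula(y, p), abs=1e-10)


@pytest.fixture(scope="module")
def trained_setup():
    """Small benchmark + short training shared across training tests."""
    spec = SimSpec(n_genes=80, n_drivers=12, n_nondrivers=30,
                   n_cancer_types=2, samples_per_type=10, seed=11)
    graph, cohort, sys_t, labels = simulate_benchmark(spec)
    cfg = RunConfig(max_epochs=80, patience=25, seed=3, use_enhancement=False)
    feats = featurize(graph, cohort, sys_t, cfg)
    return graph, feats, labels, cfg


class TestTrain:
    def _masks(self, graph, labels, seed=0):
        from sklearn.model_selection import train_test_split

        y, labeled = labels.masks(graph)
        idx = np.flatnonzero(labeled)
        rest, te = train_test_split(idx, test_size=0.2, stratify=y[idx],
                                    random_state=seed)
        tr, va = train_test_split(rest, test_size=0.15, stratify=y[rest],
                                  random_state=seed)
        return y, np.sort(tr), np.sort(va), np.sort(te)

    def test_early_stopping_within_patience_of_best(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        y, tr, va, _ = self._masks(graph, labels)
        _, hist = train(graph, feats, y, tr, va, cfg.replace(patience=10))
        assert hist["stopped_epoch"] - hist["best_epoch"] <= 10
        assert hist["stopped_epoch"] < cfg.max_epochs

    def test_same_seed_identical_history(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        y, tr, va, _ = self._masks(graph, labels)
        short = cfg.replace(max_epochs=15, patience=15)
        _, h1 = train(graph, feats, y, tr, va, short)
        _, h2 = train(graph, feats, y, tr, va, short)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_loss_decreases_on_planted_signal(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        y, tr, va, _ = self._masks(graph, labels)
        _, hist = train(graph, feats, y, tr, va,
                        cfg.replace(max_epochs=50, patience=50))
        losses = hist["train_loss"]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_no_positives_rejected(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        y, tr, va, _ = self._masks(graph, labels)
        with pytest.raises(ValueError, match="positive"):
            train(graph, feats, np.zeros_like(y), tr, va, cfg)

    def test_overlapping_masks_rejected(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        y, tr, va, _ = self._masks(graph, labels)
        with pytest.raises(ValueError, match="overlap"):
            train(graph, feats, y, tr, np.concatenate([va, tr[:1]]), cfg)

    def test_edge_dropout_zero_reuses_full_operator(self, trained_setup):
        """Without edge dropout the per-epoch operator equals the full one,
        so two runs differing only in the dropout RNG draw are identical."""
        graph, feats, labels, cfg = trained_setup
        y, tr, va, _ = self._masks(graph, labels)
        short = cfg.replace(max_epochs=10, patience=10, edge_dropout=0.0)
        _, h1 = train(graph, feats, y, tr, va, short)
        _, h2 = train(graph, feats, y, tr, va, short)
        assert h1["train_loss"] == h2["train_loss"]

    def test_held_out_genes_recovered(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        y, tr, va, te = self._masks(graph, labels)
        params, _ = train(graph, feats, y, tr, va,
                          cfg.replace(max_epochs=150, patience=40))
        op = magnetic_laplacian(graph, cfg.q)
        probs = forward(feats.values, op.L_shifted, params, cfg)
        m = compute_metrics(y[te], probs[te])
        assert m["auroc"] >= 0.8  # strong planted signal, small holdout


class TestCrossValidate:
    def test_each_gene_tested_once_per_repeat_and_row_count(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        fast = cfg.replace(max_epochs=5, patience=5)
        report = cross_validate(graph, feats, labels, fast,
                                n_folds=5, n_repeats=2)
        assert len(report.rows) == 10
        assert set(report.rows["repeat"]) == {0, 1}
        # stratified 5-fold: each labeled gene appears in exactly one test fold
        from sklearn.model_selection import StratifiedKFold
        y, labeled = labels.masks(graph)
        idx = np.flatnonzero(labeled)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.concatenate([te for _, te in skf.split(idx, y[idx])])
        assert sorted(seen) == list(range(len(idx)))

    def test_too_few_class_members_rejected(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        from mdignn.core_io import LabelSet
        tiny = LabelSet(positives=frozenset(list(labels.positives)[:3]),
                        negatives=labels.negatives,
                        unknown=labels.unknown | frozenset(list(labels.positives)[3:]))
        with pytest.raises(ValueError, match="class"):
            cross_validate(graph, feats, tiny, cfg, n_folds=5, n_repeats=1)

    def test_perfectly_separable_scores_auroc_one(self, two_node_graph):
        """Degenerate oracle: if probabilities already separate the classes,
        metrics computed on them are exact."""
        m = compute_metrics(np.array([1, 1, 0, 0, 0]),
                            np.array([.99, .98, .01, .02, .03]))
        assert m["auroc"] == m["aupr"] == 1.0


class TestRankCandidates:
    def test_threshold_and_novelty_semantics(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        params, _ = train_full(graph, feats, labels,
                               cfg.replace(max_epochs=60, patience=20))
        table = rank_candidates(params, graph, feats, labels, cfg,
                                threshold=0.9)
        assert len(table) == graph.n_nodes
        assert sorted(table["rank"]) == list(range(1, graph.n_nodes + 1))
        assert (table.loc[table["candidate"], "probability"] > 0.9).all()
        assert not (table["novel"] & (table["label_status"] == "positive")).any()
        # known positives above threshold are candidates but not novel
        known = table[(table["label_status"] == "positive") & table["candidate"]]
        assert (~known["novel"]).all()

    def test_threshold_one_empty_candidates(self, trained_setup):
        graph, feats, labels, cfg = trained_setup
        params, _ = train_full(graph, feats, labels,
                               cfg.replace(max_epochs=5, patience=5))
        table = rank_candidates(params, graph, feats, labels, cfg,
                                threshold=1.0)
        assert int(table["candidate"].sum()) == 0

    def test_simple_filter_count(self):
        """Threshold semantics on a hand-made table: strict > keeps 2 of 3."""
        probs = np.array([.95, .91, .5])
        assert int((probs > 0.9).sum()) == 2
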
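"""Sampling, folds, curve construction, CV, grid search and ablation."""

import numpy as np
import pytest

from catres.encoding import CHANNEL_NAMES, WindowLayout, build_dataset, build_table_from_tracks
from catres.errors import ValidationError
from catres.evaluation import (
    LAMBDA_GRID,
    WINDOW_GRID,
    ablate_channel,
    auc,
    auc_scores,
    aupr,
    best_operating_point,
    cross_validate,
    evaluate_scores,
    grid_search,
    make_folds,
    make_training_selection,
    pr_roc_points,
    subsample_negatives,
    sweep_table,
)
from catres.synthetic import SyntheticSpec, generate_dataset
from catres.types import SequenceRecord


def auc_pair_oracle(scores, labels):
    """Brute-force pair counting with half ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSubsampling:
    def _record(self, length, catalytic):
        return SequenceRecord(chain_id="c", sequence="A" * length,
                              catalytic_positions=set(catalytic))

    def test_count_contract(self):
        rec = self._record(50, {3, 17})
        sel = subsample_negatives(rec, ratio=6, rng_seed=0)
        assert len(sel) == 12
        assert all(p + 1 not in rec.catalytic_positions for p in sel)
        assert len(set(sel)) == 12

    def test_exhaustion(self):
        rec = self._record(5, {2})
        assert len(subsample_negatives(rec, ratio=6, rng_seed=0)) == 4

    def test_no_catalytic_no_rows(self):
        rec = self._record(30, set())
        assert subsample_negatives(rec, ratio=6, rng_seed=0) == []

    def test_seed_determinism_and_sensitivity(self):
        rec = self._record(200, {10})
        a = subsample_negatives(rec, 6, rng_seed=42)
        b = subsample_negatives(rec, 6, rng_seed=42)
        c = subsample_negatives(rec, 6, rng_seed=43)
        assert a == b
        assert a != c

    def test_ratio_validation(self):
        with pytest.raises(ValidationError):
            subsample_negatives(self._record(30, {1}), ratio=0)

    def test_training_selection_ratio(self, planted_dataset):
        records, _, _ = planted_dataset
        sel = make_training_selection(records, ratio=6, seed=0)
        y = [lbl for _, _, lbl in sel]
        assert y.count(-1) == 6 * y.count(1)


class TestFolds:
    def test_balanced(self):
        chains = [f"c{i}" for i in range(20)]
        folds = make_folds(chains, k=10, seed=0)
        sizes = [len(folds.chains_in(f)) for f in range(10)]
        assert sizes == [2] * 10

    def test_remainder(self):
        chains = [f"c{i}" for i in range(23)]
        folds = make_folds(chains, k=10, seed=0)
        sizes = sorted(len(folds.chains_in(f)) for f in range(10))
        assert set(sizes) <= {2, 3} and sum(sizes) == 23

    def test_partition(self):
        chains = [f"c{i}" for i in range(17)]
        folds = make_folds(chains, k=5, seed=3)
        seen = [c for f in range(5) for c in folds.chains_in(f)]
        assert sorted(seen) == sorted(chains)

    def test_too_many_folds(self):
        with pytest.raises(ValidationError):
            make_folds(["a", "b"], k=3, seed=0)


class TestSweep:
    SCORES = np.array([0.9, 0.8, 0.7, 0.6])
    LABELS = np.array([1, -1, 1, -1])

    def test_hand_computed_pr_points(self):
        pr, roc = pr_roc_points(self.SCORES, self.LABELS)
        assert pr == [(0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3), (1.0, 0.5)]
        assert roc == [(0.0, 0.5), (0.5, 0.5), (0.5, 1.0), (1.0, 1.0)]

    def test_perfect_ranking_hits_full_precision_recall(self):
        pr, _ = pr_roc_points(np.array([0.9, 0.8, 0.2, 0.1]),
                              np.array([1, 1, -1, -1]))
        assert (1.0, 1.0) in pr

    def test_reversed_ranking_traces_fpr_first(self):
        _, roc = pr_roc_points(np.array([0.9, 0.8, 0.2, 0.1]),
                               np.array([-1, -1, 1, 1]))
        assert roc[0] == (0.5, 0.0) and roc[1] == (1.0, 0.0)

    def test_counts_consistent_with_rates(self, rng):
        scores = rng.random(60)
        labels = np.where(rng.random(60) < 0.3, 1, -1)
        labels[0], labels[1] = 1, -1
        t = sweep_table(scores, labels)
        assert np.allclose(t["precision"], t["tp"] / (t["tp"] + t["fp"]))
        assert np.allclose(t["recall"], t["tp"] / (t["tp"] + t["fn"]))
        assert np.allclose(t["fpr"], t["fp"] / (t["fp"] + t["tn"]))
        assert np.all(t["tp"] + t["fp"] + t["tn"] + t["fn"] == 60)
        assert np.all(np.diff(t["recall"]) >= 0)
        assert np.all(np.diff(t["fpr"]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            pr_roc_points(np.array([0.1, 0.2]), np.array([1, 1]))


class TestAreas:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, -1, -1])
        pr, roc = pr_roc_points(scores, labels)
        assert aupr(pr) == pytest.approx(1.0)
        assert auc(roc) == pytest.approx(1.0)
        assert auc_scores(scores, labels) == pytest.approx(1.0)

    def test_auc_equals_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 2)  # induce some ties
            labels = np.where(rng.random(n) < 0.4, 1, -1)
            labels[0], labels[1] = 1, -1
            assert auc_scores(scores, labels) == pytest.approx(
                auc_pair_oracle(scores.tolist(), labels.tolist()), abs=1e-12)

    def test_null_scores_concentrate_at_half(self, rng):
        vals = []
        for _ in range(1000):
            scores = rng.random(30)
            labels = np.where(rng.random(30) < 0.5, 1, -1)
            labels[0], labels[1] = 1, -1
            vals.append(auc_scores(scores, labels))
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_trapezoid_aupr_option(self):
        pr, _ = pr_roc_points(np.array([0.9, 0.8, 0.2, 0.1]),
                              np.array([1, 1, -1, -1]))
        assert aupr(pr, method="trapezoid") <= 1.0


class TestOperatingPoint:
    def test_harmonic_mean_selection(self):
        # among these sweeps, (0.5, 0.5) beats (0.9, 0.1) on F
        f = lambda p, r: 2 * p * r / (p + r)
        assert f(0.5, 0.5) > f(0.9, 0.1)
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, -1, 1, -1])
        op = best_operating_point(scores, labels)
        assert op.f_measure == pytest.approx(0.8, abs=1e-12)
        assert (op.precision, op.recall) == (2 / 3, 1.0)
        assert op.tp == 2 and op.fp == 1 and op.fn == 0 and op.tn == 1

    def test_f_equals_common_value_when_p_equals_r(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, -1, 1, -1])
        t = sweep_table(scores, labels)
        row = t.iloc[1]  # P = R = 0.5 there
        assert row["precision"] == row["recall"] == 0.5
        assert row["f_measure"] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def small_cv_setup(request):
    spec = SyntheticSpec(seed=21, n_chains=12, length_range=(50, 80),
                         catalytic_per_chain=2, signal_strength=0.8)
    records, tracks = generate_dataset(spec)
    tables = {c: build_table_from_tracks(t) for c, t in tracks.items()}
    sel = make_training_selection(records, 6, seed=5)
    return records, tables, sel


class TestCrossValidation:
    def test_signal_recovery_and_count_conservation(self, small_cv_setup):
        _, tables, sel = small_cv_setup
        ds = build_dataset(tables, sel, WindowLayout(2))
        folds = make_folds(sorted(tables), k=6, seed=5)
        scores, report = cross_validate(ds, folds, 0.005)
        assert report.auc >= 0.85
        op = report.operating_point
        assert op.tp + op.fp + op.tn + op.fn == len(ds)
        assert len(scores) == len(ds)

    def test_permuted_labels_are_null(self, small_cv_setup):
        _, tables, sel = small_cv_setup
        rng = np.random.default_rng(9)
        labels = np.array([lbl for _, _, lbl in sel])
        shuffled = rng.permutation(labels)
        sel_null = [(c, p, int(l)) for (c, p, _), l in zip(sel, shuffled)]
        ds = build_dataset(tables, sel_null, WindowLayout(2))
        folds = make_folds(sorted(tables), k=6, seed=5)
        _, report = cross_validate(ds, folds, 0.005)
        assert 0.35 <= report.auc <= 0.65

    def test_leave_one_chain_out_also_recovers(self, small_cv_setup):
        _, tables, sel = small_cv_setup
        ds = build_dataset(tables, sel, WindowLayout(2))
        folds = make_folds(sorted(tables), k=len(tables), seed=5)
        _, report = cross_validate(ds, folds, 0.005)
        assert report.auc >= 0.85

    def test_missing_fold_assignment_rejected(self, small_cv_setup):
        _, tables, sel = small_cv_setup
        ds = build_dataset(tables, sel, WindowLayout(0))
        folds = make_folds(sorted(tables)[:-1], k=4, seed=0)
        with pytest.raises(ValidationError):
            cross_validate(ds, folds, 0.01)


class TestGridSearch:
    def test_default_grid_shape(self):
        assert len(LAMBDA_GRID) == 20
        assert len(WINDOW_GRID) == 11
        assert LAMBDA_GRID[0] == 0.001 and LAMBDA_GRID[-1] == 0.020
        assert WINDOW_GRID == tuple(range(11))

    def test_single_cell_reduces_to_cross_validate(self, small_cv_setup):
        _, tables, sel = small_cv_setup
        result = grid_search(tables, sel, lambdas=[0.005], windows=[2],
                             k=6, seed=5)
        ds = build_dataset(tables, sel, WindowLayout(2))
        folds = make_folds(sorted(tables), k=6, seed=5)
        _, report = cross_validate(ds, folds, 0.005)
        assert result.best() == (2, 0.005)
        assert result.table.iloc[0]["aupr"] == pytest.approx(report.aupr)
        assert result.table.iloc[0]["auc"] == pytest.approx(report.auc)

    def test_deterministic(self, small_cv_setup):
        _, tables, sel = small_cv_setup
        a = grid_search(tables, sel, lambdas=[0.005, 0.01], windows=[0, 1],
                        k=6, seed=5)
        b = grid_search(tables, sel, lambdas=[0.005, 0.01], windows=[0, 1],
                        k=6, seed=5)
        assert a.table.equals(b.table) and a.best() == b.best()

    def test_flanking_signal_needs_wide_window(self):
        # signal lives only in the conservation track at offsets +-2, so a
        # window of at least 2 is required to see it
        spec = SyntheticSpec(seed=33, n_chains=14, length_range=(50, 80),
                             catalytic_per_chain=2, signal_strength=1.0,
                             signal_channels=("consurf",),
                             signal_offsets=(-2, 2))
        records, tracks = generate_dataset(spec)
        tables = {c: build_table_from_tracks(t) for c, t in tracks.items()}
        sel = make_training_selection(records, 6, seed=7)
        result = grid_search(tables, sel, lambdas=[0.003], windows=[0, 1, 2, 3],
                             k=7, seed=7)
        assert result.best_window >= 2

    def test_empty_grid_rejected(self, small_cv_setup):
        _, tables, sel = small_cv_setup
        with pytest.raises(ValidationError):
            grid_search(tables, sel, lambdas=[], windows=[1])


class TestAblation:
    def test_dimension_bookkeeping(self):
        w = 3
        full = WindowLayout(w).dim
        drops = {"RT": 20, "OP": 10, "ACH": 10, "SS": 3 * (2 * w + 1),
                 "ASA": 2 * w + 1, "JSD": 2 * w + 1, "VJSD": 2 * w + 1,
                 "Consurf": 2 * w + 1}
        for channel, d in drops.items():
            kept = tuple(c for c in CHANNEL_NAMES if c != channel)
            assert WindowLayout(w, kept).dim == full - d

    def test_removing_sole_signal_channel_kills_auc(self):
        spec = SyntheticSpec(seed=44, n_chains=14, length_range=(50, 80),
                             catalytic_per_chain=2, signal_strength=1.0,
                             signal_channels=("consurf",))
        records, tracks = generate_dataset(spec)
        tables = {c: build_table_from_tracks(t) for c, t in tracks.items()}
        sel = make_training_selection(records, 6, seed=2)
        with_sig = ablate_channel(tables, sel, "RT", window=1, lam=0.005,
                                  k=7, seed=2)
        without = ablate_channel(tables, sel, "Consurf", window=1, lam=0.005,
                                 k=7, seed=2)
        assert with_sig.auc >= 0.85
        assert 0.3 <= without.auc <= 0.7

    def test_unknown_channel_rejected(self, small_cv_setup):
        _, tables, sel = small_cv_setup
        with pytest.raises(ValidationError):
            ablate_channel(tables, sel, "Entropy", window=1, lam=0.01,
                           k=6, seed=0)


def test_report_serialization_round_trip(tmp_path, rng):
    from catres.evaluation import write_curves_tsv, write_report_json

    scores = rng.random(40)
    labels = np.where(rng.random(40) < 0.3, 1, -1)
    labels[0], labels[1] = 1, -1
    report = evaluate_scores(scores, labels)
    write_report_json(report, tmp_path / "report.json")
    write_curves_tsv(report, tmp_path / "pr.tsv", tmp_path / "roc.tsv")
    import json

    payload = json.loads((tmp_path / "report.json").read_text())
    assert payload["aupr"] == report.aupr and payload["auc"] == report.auc
    assert len(payload["pr_points"]) == 40
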
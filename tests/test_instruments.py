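import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as stn

import clpnet as cn
from clpnet.instruments import (
    composite_scores,
    cronbach_alpha,
    get_instrument,
    impute_missing,
    screen_participants,
)


def _tiny_dataset(screen_rows, control_ok, wave1=None, nodes=("s1", "s2")):
    n = len(screen_rows)
    w1 = pd.DataFrame(
        wave1 if wave1 is not None else np.zeros((n, len(nodes))), columns=list(nodes)
    )
    return cn.PanelDataset(
        ids=np.arange(n),
        covariates=pd.DataFrame({"gender": np.zeros(n), "age": np.full(n, 15.0)}),
        screening=pd.DataFrame(
            np.asarray(screen_rows), columns=[f"screen_v{i+1}" for i in range(len(screen_rows[0]))]
        ).assign(control_ok=control_ok),
        wave1=w1,
        wave2=w1.copy(),
    )


class TestScreening:
    def test_all_never_responses_dropped(self):
        ds = _tiny_dataset([[0, 0, 0]], [True])
        res = screen_participants(ds)
        assert res.n_victimized == 0 and res.n_final == 0

    def test_single_event_with_valid_control_kept(self):
        ds = _tiny_dataset([[1, 0, 0]], [True])
        res = screen_participants(ds)
        assert res.n_final == 1 and list(res.kept_ids) == [0]

    def test_control_failure_excluded_after_victimization(self):
        ds = _tiny_dataset([[2, 0, 0], [3, 1, 0], [0, 0, 0]], [True, False, True])
        res = screen_participants(ds)
        assert (res.n_input, res.n_victimized, res.n_excluded_invalid, res.n_final) == (3, 2, 1, 1)

    def test_never_anchor_above_zero(self):
        # a scale whose "never" response is coded 1 (Delaware-style)
        ds = _tiny_dataset([[1, 1], [2, 1]], [True, True])
        res = screen_participants(ds, never_anchor=1)
        assert res.n_final == 1

    def test_counts_match_brute_force_refilter_of_csv(self, canonical_small, tmp_path):
        path = tmp_path / "panel.csv"
        canonical_small.to_csv(path)
        frame = pd.read_csv(path)
        screen_cols = [c for c in frame.columns if c.startswith("screen_v")]
        brute = ((frame[screen_cols] > 0).any(axis=1) & (frame["control_ok"] == 1)).sum()
        res = screen_participants(canonical_small)
        assert res.n_final == brute
        assert res.n_final == res.n_victimized - res.n_excluded_invalid


class TestImputation:
    def test_column_mean_fills_missing_cell(self):
        w1 = np.array([[1.0, 0], [3.0, 0], [np.nan, 0]])
        ds = _tiny_dataset([[1, 0]] * 3, [True] * 3, wave1=w1)
        out = impute_missing(ds)
        assert out.wave1.iloc[2, 0] == pytest.approx(2.0)
        assert out.wave1.iloc[0, 0] == 1.0  # observed cells untouched

    def test_no_missing_is_identity(self, canonical_small):
        complete = canonical_small.subset(
            ~canonical_small.wave1.isna().any(axis=1).to_numpy()
        )
        out = impute_missing(complete)
        pd.testing.assert_frame_equal(out.wave1, complete.wave1)
        pd.testing.assert_frame_equal(out.wave2, complete.wave2)

    def test_entirely_missing_column_rejected(self):
        w1 = np.full((3, 2), np.nan)
        w1[:, 1] = 1.0
        ds = _tiny_dataset([[1, 0]] * 3, [True] * 3, wave1=w1)
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(ds)

    def test_imputation_preserves_observed_item_means(self, canonical_small):
        before = canonical_small.wave1.mean()  # pandas mean skips NaN
        after = impute_missing(canonical_small).wave1.mean()
        assert np.allclose(before.to_numpy(), after.to_numpy(), atol=1e-12)


class TestCompositeScores:
    @pytest.mark.parametrize(
        "instrument, fill, expected",
        [("PHQ-9", 3, 27), ("ITQ", 0, 0), ("ITQ", 4, 48)],
    )
    def test_constant_responses(self, instrument, fill, expected):
        spec = get_instrument(instrument)
        n = 4
        w = pd.DataFrame(
            np.full((n, len(spec.node_labels)), fill, dtype=float),
            columns=list(spec.node_labels),
        )
        ds = _tiny_dataset([[1]] * n, [True] * n)
        ds = cn.PanelDataset(ds.ids, ds.covariates, ds.screening, w, w.copy())
        out = composite_scores(ds, instrument)
        assert (out["t1_total"] == expected).all()

    def test_gad7_arithmetic_and_subscale_totals(self):
        spec = get_instrument("GAD-7")
        responses = [3, 2, 3, 1, 0, 2, 2]
        w = pd.DataFrame([responses], columns=list(spec.node_labels), dtype=float)
        ds = _tiny_dataset([[1]], [True])
        ds = cn.PanelDataset(ds.ids, ds.covariates, ds.screening, w, w.copy())
        out = composite_scores(ds, "GAD-7")
        assert out.loc[0, "t1_total"] == 13
        # ITQ subscales: each dimension total is the sum of its two items
        itq = get_instrument("ITQ")
        vals = [0, 1, 2, 3, 4, 0, 1, 2, 3, 4, 1, 2]
        w2 = pd.DataFrame([np.asarray(vals, dtype=float)], columns=list(itq.node_labels))
        ds2 = cn.PanelDataset(ds.ids, ds.covariates, ds.screening, w2, w2.copy())
        out2 = composite_scores(ds2, "ITQ")
        assert out2.loc[0, "t1_re_experiencing"] == 0 + 1
        assert out2.loc[0, "t1_disturbed_relationships"] == 1 + 2
        assert out2.loc[0, "t1_total"] == sum(vals)

    def test_out_of_range_response_rejected(self):
        spec = get_instrument("GAD-7")
        w = pd.DataFrame([[5, 0, 0, 0, 0, 0, 0]], columns=list(spec.node_labels), dtype=float)
        ds = _tiny_dataset([[1]], [True])
        ds = cn.PanelDataset(ds.ids, ds.covariates, ds.screening, w, w.copy())
        with pytest.raises(ValueError, match="outside"):
            composite_scores(ds, "GAD-7")

    def test_unknown_instrument_rejected(self, canonical_small):
        with pytest.raises(KeyError, match="unknown instrument"):
            composite_scores(canonical_small, "SCL-90")


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.array([1.0, 2, 3, 4])
        assert cronbach_alpha(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_perfectly_covarying_items_give_one(self):
        X = np.array([[1.0, 1], [2, 2], [3, 3]])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_independent_items_give_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10_000, 2))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_zero_total_variance_rejected(self):
        X = np.array([[1.0, -1], [2, -2], [3, -3]])
        with pytest.raises(ValueError, match="zero variance"):
            cronbach_alpha(X)


class TestPipelineProperties:
    def test_screen_impute_score_commutes_with_row_subsetting(self, canonical_small):
        screened, _ = cn.apply_screening(canonical_small)
        clean = impute_missing(screened)
        full_scores = composite_scores(clean, "PHQ-9")
        # scoring then subsetting == subsetting then scoring (kept rows)
        half = clean.subset(np.arange(clean.n // 2))
        sub_scores = composite_scores(half, "PHQ-9")
        assert np.allclose(
            full_scores.iloc[: clean.n // 2]["t1_total"].to_numpy(),
            sub_scores["t1_total"].to_numpy(),
        )

    @given(perm_seed=stn.integers(0, 2**16))
    def test_composite_scoring_is_permutation_invariant(self, canonical_small, perm_seed):
        clean = impute_missing(cn.apply_screening(canonical_small)[0])
        rng = np.random.default_rng(perm_seed)
        perm = rng.permutation(clean.n)
        scores = composite_scores(clean, "GAD-7")["t1_total"].to_numpy()
        permuted = composite_scores(clean.subset(perm), "GAD-7")["t1_total"].to_numpy()
        assert np.array_equal(scores[perm], permuted)
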
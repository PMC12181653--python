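import numpy as np
import pytest
from hypothesis import given, strategies as stn

import clpnet as cn
from clpnet.stability import (
    CaseDropResult,
    bootstrap_edges,
    case_drop_bootstrap,
    cs_coefficient,
    cs_label,
)


@pytest.fixture(scope="module")
def strong_edge_data():
    """One dominant cross-lagged edge (s0 -> s1 at 0.5), n=2000."""
    labels = tuple(f"s{i}" for i in range(10))
    B = np.zeros((10, 10))
    B[0, 1] = 0.5
    truth = cn.TruthNetwork(labels, B, np.full(10, 0.3), 0.3, np.full((2, 10), 0.1))
    data = cn.simulate_panel(truth, cn.GeneratorConfig(n=2000, seed=0))
    return cn.impute_missing(cn.apply_screening(data)[0])


class TestEdgeBootstrap:
    def test_two_replicates_give_min_max_bounds(self, demo10):
        res = bootstrap_edges(demo10, n_boot=2, seed=1)
        assert res.samples.shape[0] == 2
        summ = res.summary()
        lo = np.minimum(res.samples[0], res.samples[1])
        hi = np.maximum(res.samples[0], res.samples[1])
        for _, row in summ.head(20).iterrows():
            i = list(demo10.node_labels).index(row["from"])
            j = list(demo10.node_labels).index(row["to"])
            assert row["ci_low"] == pytest.approx(lo[i, j])
            assert row["ci_high"] == pytest.approx(hi[i, j])

    def test_bounds_bracket_bootstrap_mean(self, demo10):
        summ = bootstrap_edges(demo10, n_boot=20, seed=2).summary()
        assert (summ["ci_low"] <= summ["boot_mean"] + 1e-12).all()
        assert (summ["boot_mean"] <= summ["ci_high"] + 1e-12).all()

    def test_strong_edge_ci_excludes_zero(self, strong_edge_data):
        res = bootstrap_edges(strong_edge_data, n_boot=100, seed=0)
        row = res.summary().set_index(["from", "to"]).loc[("s0", "s1")]
        assert row["ci_low"] > 0

    def test_bootstrap_mean_approaches_point_estimate(self, strong_edge_data):
        """More replicates bring the bootstrap mean of the largest edge
        closer to the point estimate (fixed seed pair)."""
        res50 = bootstrap_edges(strong_edge_data, n_boot=50, seed=1)
        res200 = bootstrap_edges(strong_edge_data, n_boot=200, seed=1)
        i, j = np.unravel_index(np.argmax(np.abs(res50.point)), res50.point.shape)
        d50 = abs(res50.samples[:, i, j].mean() - res50.point[i, j])
        d200 = abs(res200.samples[:, i, j].mean() - res200.point[i, j])
        assert d200 <= d50

    def test_null_edges_cover_zero(self):
        """Frozen bound: under a null truth network, >= 90% of edge CIs
        contain 0 (5-seed average at 8 nodes, n=600, 50 replicates)."""
        fracs = []
        for s in range(5):
            truth = cn.make_truth(
                node_labels=tuple(f"s{i}" for i in range(8)), edge_density=0.0, seed=s
            )
            data = cn.simulate_panel(truth, cn.GeneratorConfig(n=600, seed=50 + s))
            clean = cn.impute_missing(cn.apply_screening(data)[0])
            summ = bootstrap_edges(clean, n_boot=50, seed=s).summary()
            fracs.append(np.mean((summ["ci_low"] <= 0) & (summ["ci_high"] >= 0)))
        assert np.mean(fracs) >= 0.90

    def test_too_few_replicates_rejected(self, demo10):
        with pytest.raises(ValueError):
            bootstrap_edges(demo10, n_boot=1)


class TestCaseDrop:
    def test_deterministic_given_seed(self, demo10):
        kwargs = dict(index="in_ei", proportions=(0.1, 0.3), n_boot=5, seed=4)
        a = case_drop_bootstrap(demo10, **kwargs)
        b = case_drop_bootstrap(demo10, **kwargs)
        for p in a.drop_proportions:
            assert np.array_equal(a.correlations[p], b.correlations[p])

    def test_small_drop_keeps_centralities_stable(self, strong10):
        res = case_drop_bootstrap(
            strong10, index="out_ei", proportions=(0.05,), n_boot=20, seed=0
        )
        assert np.median(res.correlations[0.05]) >= 0.99

    def test_empty_proportion_grid_rejected(self, demo10):
        with pytest.raises(ValueError, match="empty"):
            case_drop_bootstrap(demo10, proportions=())

    def test_undersized_subsamples_skipped_with_warning(self, demo10):
        small = demo10.subset(np.arange(140))  # 0.75 drop leaves < 10 x 10 rows
        with pytest.warns(UserWarning, match="skipping"):
            res = case_drop_bootstrap(
                small, proportions=(0.05, 0.75), n_boot=3, seed=1
            )
        assert res.drop_proportions == (0.05,)

    def test_curve_frame_layout(self, demo10):
        res = case_drop_bootstrap(
            demo10, index="in_ei", proportions=(0.2,), n_boot=4, seed=2
        )
        frame = res.curve_frame()
        assert list(frame.columns) == ["proportion", "replicate", "correlation"]
        assert len(frame) == 4


def _result(props_to_corrs):
    return CaseDropResult(
        index="in_ei",
        drop_proportions=tuple(sorted(props_to_corrs)),
        correlations={p: np.asarray(v, dtype=float) for p, v in props_to_corrs.items()},
        n_total=1000,
    )


class TestCSCoefficient:
    def test_perfect_stability_reaches_grid_maximum(self):
        grid = np.round(np.arange(0.05, 0.751, 0.05), 2)
        res = _result({float(p): np.ones(40) for p in grid})
        assert cs_coefficient(res) == 0.75

    def test_no_stability_gives_zero(self):
        res = _result({0.05: np.zeros(40), 0.1: np.zeros(40)})
        assert cs_coefficient(res) == 0.0

    def test_threshold_met_exactly_up_to_quarter(self):
        # >= 0.7 with probability exactly 0.95 at p <= 0.25, failing above
        good = np.array([0.9] * 19 + [0.1])          # 95% above threshold
        bad = np.array([0.9] * 18 + [0.1, 0.1])      # 90% above threshold
        res = _result({0.05: good, 0.15: good, 0.25: good, 0.28: bad, 0.4: good})
        assert cs_coefficient(res) == 0.25

    def test_gap_in_retention_blocks_higher_proportions(self):
        good, bad = np.ones(20), np.zeros(20)
        res = _result({0.05: good, 0.1: bad, 0.3: good})
        assert cs_coefficient(res) == 0.05

    @given(
        thr=stn.floats(0.5, 0.95),
        prob=stn.floats(0.8, 1.0),
        seed=stn.integers(0, 1000),
    )
    def test_raising_requirements_never_raises_cs(self, thr, prob, seed):
        rng = np.random.default_rng(seed)
        res = _result({
            float(p): rng.uniform(0.3, 1.0, 25)
            for p in np.round(np.arange(0.05, 0.41, 0.05), 2)
        })
        base = cs_coefficient(res, cor_threshold=0.7, retain_prob=0.95)
        assert cs_coefficient(res, cor_threshold=max(thr, 0.7), retain_prob=0.95) <= base
        assert cs_coefficient(res, cor_threshold=0.7, retain_prob=max(prob, 0.95)) <= base

    def test_interpretive_labels(self):
        assert cs_label(0.75) == "very stable"
        assert cs_label(0.51) == "very stable"
        assert cs_label(0.5) == "moderately stable"
        assert cs_label(0.283) == "moderately stable"
        assert cs_label(0.25) == "unstable"
        assert cs_label(0.0) == "unstable"
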
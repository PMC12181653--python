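"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two procedures, following the bootnet conventions for network psychometrics:

* **edge-weight bootstrap** — resample participants with replacement,
  re-estimate the network, and summarize each cross-lagged edge's sampling
  distribution with percentile confidence intervals (wide, heavily
  overlapping intervals mean poorly separated edge estimates);
* **case-dropping bootstrap** — repeatedly drop a fraction of participants,
  re-estimate, and correlate the subsample centralities with the
  full-sample ones; the CS-coefficient is the largest drop fraction at
  which that correlation stays >= 0.7 in at least 95% of subsamples
  (CS > 0.25: moderately stable; CS > 0.5: very stable).

Per-replicate seeds are derived from the top-level seed and the replicate
index, so results are reproducible and independent of any parallel
execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import INDICES, expected_influence
from .clpn import EstimatorSettings, estimate_network
from .datasets import PanelDataset

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


@dataclass
class EdgeBootstrapResult:
    """Edge-weight bootstrap distributions and percentile CIs."""

    node_labels: tuple[str, ...]
    point: np.ndarray            # p x p point-estimate B
    samples: np.ndarray          # n_boot x p x p bootstrap Bs
    n_boot: int
    n_failed: int = 0
    alpha: float = 0.05

    def summary(self, only_nonzero: bool = False) -> pd.DataFrame:
        """Per-edge table: point estimate, bootstrap mean, percentile CI."""
        labels = self.node_labels
        p = len(labels)
        lo_q, hi_q = 100 * self.alpha / 2, 100 * (1 - self.alpha / 2)
        rows = []
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                if only_nonzero and self.point[i, j] == 0.0:
                    continue
                draw = self.samples[:, i, j]
                lo, hi = np.percentile(draw, [lo_q, hi_q])
                rows.append(
                    (labels[i], labels[j], float(self.point[i, j]),
                     float(draw.mean()), float(lo), float(hi))
                )
        return pd.DataFrame(
            rows, columns=["from", "to", "estimate", "boot_mean", "ci_low", "ci_high"]
        )

    def ci_overlap_matrix(self, only_nonzero: bool = True) -> pd.DataFrame:
        """For each pair of edges, whether their CIs overlap (the paper's
        reading of bootstrap accuracy: more overlap = less separable)."""
        summ = self.summary(only_nonzero=only_nonzero)
        names = [f"{r['from']}->{r['to']}" for _, r in summ.iterrows()]
        lo = summ["ci_low"].to_numpy()
        hi = summ["ci_high"].to_numpy()
        overlap = (lo[:, None] <= hi[None, :]) & (lo[None, :] <= hi[:, None])
        return pd.DataFrame(overlap, index=names, columns=names)


def bootstrap_edges(
    dataset: PanelDataset,
    settings: EstimatorSettings | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> EdgeBootstrapResult:
    """Nonparametric edge-weight bootstrap (resample rows with replacement).

    Estimator failures inside a replicate (e.g. a zero-variance column
    after resampling) are skipped and counted; more than 5% failures
    aborts.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    settings = settings or EstimatorSettings()
    point = estimate_network(dataset, settings)
    p = point.p
    samples = np.empty((n_boot, p, p))
    n_failed = 0
    b = 0
    for rep in range(n_boot * 2):  # allow retries for failed replicates
        if b >= n_boot:
            break
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        rows = rng.integers(0, dataset.n, size=dataset.n)
        try:
            net = estimate_network(dataset.subset(rows), settings)
        except ValueError as exc:
            n_failed += 1
            if n_failed > 0.05 * n_boot:
                raise RuntimeError(
                    f"more than 5% of bootstrap replicates failed ({exc})"
                ) from exc
            continue
        samples[b] = net.B
        b += 1
    if b < n_boot:
        raise RuntimeError("could not complete the requested number of replicates")
    return EdgeBootstrapResult(
        node_labels=point.node_labels,
        point=point.B.copy(),
        samples=samples,
        n_boot=n_boot,
        n_failed=n_failed,
        alpha=alpha,
    )


@dataclass
class CaseDropResult:
    """Case-dropping bootstrap output for one centrality index."""

    index: str
    drop_proportions: tuple[float, ...]
    correlations: dict[float, np.ndarray]  # proportion -> n_boot correlations
    n_total: int
    correlation_method: str = "pearson"

    def curve_frame(self) -> pd.DataFrame:
        rows = [
            (p, r, float(c))
            for p in self.drop_proportions
            for r, c in enumerate(self.correlations[p])
        ]
        return pd.DataFrame(rows, columns=["proportion", "replicate", "correlation"])


def case_drop_bootstrap(
    dataset: PanelDataset,
    settings: EstimatorSettings | None = None,
    index: str = "in_ei",
    proportions=DEFAULT_PROPORTIONS,
    n_boot: int = 100,
    seed: int = 0,
    correlation: str = "pearson",
) -> CaseDropResult:
    """Case-dropping bootstrap of a centrality index.

    For each drop proportion p, draws ``n_boot`` subsamples without
    replacement of size (1-p)*N, re-estimates the network, and records the
    correlation (Pearson by default, Spearman by flag) between subsample
    and full-sample centralities across nodes.  Proportions whose retained
    subsample would fall below 10 rows per node are skipped with a warning.
    """
    if index not in INDICES:
        raise ValueError(f"index must be one of {INDICES}")
    if len(tuple(proportions)) == 0:
        raise ValueError("empty proportion grid")
    if correlation not in ("pearson", "spearman"):
        raise ValueError("correlation must be 'pearson' or 'spearman'")
    settings = settings or EstimatorSettings()
    full = expected_influence(estimate_network(dataset, settings))[index].to_numpy()
    p_nodes = len(dataset.node_labels)
    corr_fn = stats.pearsonr if correlation == "pearson" else stats.spearmanr

    kept: list[float] = []
    corrs: dict[float, np.ndarray] = {}
    for prop in proportions:
        if not 0.0 < prop <= 0.75:
            raise ValueError("drop proportions must lie in (0, 0.75]")
        m = int(round((1.0 - prop) * dataset.n))
        if m < 10 * p_nodes:
            warnings.warn(
                f"skipping drop proportion {prop}: retained subsample {m} < "
                f"10 x {p_nodes} nodes",
                stacklevel=2,
            )
            continue
        vals = np.empty(n_boot)
        for b in range(n_boot):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, int(round(prop * 100)), b])
            )
            rows = rng.choice(dataset.n, size=m, replace=False)
            net = estimate_network(dataset.subset(rows), settings)
            sub = expected_influence(net)[index].to_numpy()
            if np.std(sub) == 0 or np.std(full) == 0:
                vals[b] = 0.0
            else:
                vals[b] = corr_fn(full, sub)[0]
        kept.append(float(prop))
        corrs[float(prop)] = vals
    if not kept:
        raise ValueError("all drop proportions were skipped; dataset too small")
    return CaseDropResult(index, tuple(kept), corrs, dataset.n, correlation)


def cs_coefficient(
    result: CaseDropResult, cor_threshold: float = 0.7, retain_prob: float = 0.95
) -> float:
    """Correlation-stability coefficient.

    The largest drop proportion p such that, at every recorded proportion
    q <= p, at least ``retain_prob`` of the subsample correlations are
    >= ``cor_threshold``; 0.0 if no proportion qualifies.
    """
    if not result.correlations:
        raise ValueError("malformed CaseDropResult: no correlations recorded")
    cs = 0.0
    for prop in sorted(result.drop_proportions):
        vals = np.asarray(result.correlations[prop], dtype=float)
        ok = np.mean(np.nan_to_num(vals, nan=-1.0) >= cor_threshold)
        if ok >= retain_prob:
            cs = prop
        else:
            break
    return float(cs)


def cs_label(cs: float) -> str:
    """Interpretive label for a CS-coefficient (>0.5 very stable,
    >0.25 moderately stable, otherwise unstable)."""
    if cs > 0.5:
        return "very stable"
    if cs > 0.25:
        return "moderately stable"
    return "unstable"


def stability_summary(results: dict[str, CaseDropResult]) -> str:
    """Human-readable CS summary block for the written reports."""
    lines = []
    for index, res in results.items():
        cs = cs_coefficient(res)
        lines.append(f"CS-coefficient ({index}): {cs:.2f} [{cs_label(cs)}]")
    return "\n".join(lines)
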
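"""Expected-influence centrality for directed cross-lagged networks.

Out-EI of a node is the signed sum of its outgoing cross-lagged edge
weights (how much the symptom predicts others six months later); In-EI the
signed sum of incoming weights (how much it is predicted by others).
Autoregressive paths are set to zero before summation, and covariate
coefficients are excluded, so the indices reflect between-symptom
prospective influence only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clpn import CLPNetwork, EstimatorSettings, estimate_network
from .datasets import PanelDataset

INDICES = ("in_ei", "out_ei")


def expected_influence(network: CLPNetwork, standardized: bool = False) -> pd.DataFrame:
    """Per-node In-EI and Out-EI (signed sums over B's off-diagonal).

    With ``standardized=True``, z-scored versions (across nodes) are added
    for plotting.  The identity sum(in_ei) == sum(out_ei) == sum(B) holds
    by construction.
    """
    B = network.B
    if B.shape != (network.p, network.p):
        raise ValueError("coefficient matrix dimension mismatch")
    table = pd.DataFrame(
        {
            "node": list(network.node_labels),
            "in_ei": B.sum(axis=0),   # column sums: incoming
            "out_ei": B.sum(axis=1),  # row sums: outgoing
        }
    )
    if standardized:
        for col in INDICES:
            v = table[col].to_numpy()
            sd = v.std(ddof=1)
            table[f"{col}_z"] = (v - v.mean()) / sd if sd > 0 else 0.0
    return table


def rank_report(table: pd.DataFrame, k: int = 3) -> dict[str, list[str]]:
    """Top-k nodes by Out-EI and by In-EI (descending signed value).

    Ties break lexicographically by node label, with a warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(table):
        raise ValueError(f"k={k} exceeds node count {len(table)}")
    report: dict[str, list[str]] = {}
    for col in ("out_ei", "in_ei"):
        ordered = table.sort_values([col, "node"], ascending=[False, True])
        top = ordered.head(k)
        if k and len(table) > k:
            boundary = top[col].iloc[-1]
            n_at_boundary = (table[col] == boundary).sum()
            if n_at_boundary > (top[col] == boundary).sum():
                warnings.warn(
                    f"tie at the top-{k} boundary of {col}; lexicographic order used",
                    stacklevel=2,
                )
        elif k and top[col].nunique() < len(top):
            warnings.warn(f"tied {col} values in top-{k}; lexicographic order used", stacklevel=2)
        report[col] = top["node"].tolist()
    return report


def bootstrap_centralities(
    dataset: PanelDataset,
    settings: EstimatorSettings | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Nonparametric bootstrap of both centrality indices.

    Resamples participants with replacement, re-estimates the network and
    recomputes In-EI/Out-EI each time.  Per-replicate seeds are derived
    from ``seed`` by replicate index, so results do not depend on any
    execution order or worker count.  Returns arrays of shape
    (n_boot, p) per index.
    """
    settings = settings or EstimatorSettings()
    out = {idx: np.empty((n_boot, len(dataset.node_labels))) for idx in INDICES}
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        rows = rng.integers(0, dataset.n, size=dataset.n)
        net = estimate_network(dataset.subset(rows), settings)
        table = expected_influence(net)
        out["in_ei"][b] = table["in_ei"].to_numpy()
        out["out_ei"][b] = table["out_ei"].to_numpy()
    return out


@dataclass(frozen=True)
class DifferenceTestResult:
    node_a: str
    node_b: str
    index: str
    difference: float
    ci_low: float
    ci_high: float
    significant: bool
    n_boot: int


def centrality_difference_test(
    dataset: PanelDataset,
    settings: EstimatorSettings | None = None,
    node_a: str = "",
    node_b: str = "",
    index: str = "in_ei",
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    boot: dict[str, np.ndarray] | None = None,
) -> DifferenceTestResult:
    """Bootstrap difference test between two nodes' centralities.

    Significant when the (1 - alpha) percentile interval of
    c(node_a) - c(node_b) excludes zero.  A precomputed
    :func:`bootstrap_centralities` result may be passed to test several
    pairs from one set of resamples.
    """
    if index not in INDICES:
        raise ValueError(f"index must be one of {INDICES}")
    labels = list(dataset.node_labels)
    for node in (node_a, node_b):
        if node not in labels:
            raise KeyError(f"unknown node label {node!r}")
    settings = settings or EstimatorSettings()
    point_net = estimate_network(dataset, settings)
    table = expected_influence(point_net).set_index("node")
    point_diff = float(table.loc[node_a, index] - table.loc[node_b, index])
    if node_a == node_b:
        return DifferenceTestResult(node_a, node_b, index, 0.0, 0.0, 0.0, False, n_boot)
    if boot is None:
        boot = bootstrap_centralities(dataset, settings, n_boot=n_boot, seed=seed)
    ia, ib = labels.index(node_a), labels.index(node_b)
    diffs = boot[index][:, ia] - boot[index][:, ib]
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    significant = bool(lo > 0 or hi < 0)
    return DifferenceTestResult(
        node_a, node_b, index, point_diff, float(lo), float(hi), significant, len(diffs)
    )


def centrality_difference_matrix(
    dataset: PanelDataset,
    settings: EstimatorSettings | None = None,
    index: str = "in_ei",
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Node-by-node significance indicator matrix from one bootstrap run."""
    boot = bootstrap_centralities(dataset, settings, n_boot=n_boot, seed=seed)
    labels = list(dataset.node_labels)
    sig = np.zeros((len(labels), len(labels)), dtype=int)
    for i, na in enumerate(labels):
        for j in range(i + 1, len(labels)):
            res = centrality_difference_test(
                dataset, settings, na, labels[j], index,
                n_boot=n_boot, seed=seed, alpha=alpha, boot=boot,
            )
            sig[i, j] = sig[j, i] = int(res.significant)
    return pd.DataFrame(sig, index=labels, columns=labels)
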
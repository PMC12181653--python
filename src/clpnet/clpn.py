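"""Cross-lagged panel network estimation by node-wise regularized regression.

Each of the p wave-2 symptoms is regressed on all p wave-1 symptoms plus
gender and age, with an L1 penalty on the symptom predictors (covariates are
unpenalized) and the penalty chosen per outcome by 10-fold cross-validation.
All columns — predictors and outcomes — are z-scored first, so every edge
weight is a standardized regression coefficient and expected-influence sums
are comparable across instruments with different response ranges.  One
seeded fold permutation is shared across the p node regressions, making the
whole network a deterministic function of (data, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._lasso import CVResult, _fold_assignment, cv_select_lambda, lasso_path
from .datasets import PanelDataset

COVARIATES = ("gender", "age")


@dataclass(frozen=True)
class EstimatorSettings:
    """Tuning knobs of the node-wise LASSO estimator.

    ``lambda_rule`` is ``"1se"`` (one-standard-error rule, the default —
    the penalty is raised to the largest value whose CV error sits within
    one standard error of the minimum, which keeps false-positive edges
    rare) or ``"min"`` (minimum mean CV error, denser networks).  ``seed``
    fixes the fold assignment.
    """

    n_folds: int = 10
    lambda_rule: str = "1se"
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    tol: float = 1e-8
    max_iter: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")

    def with_seed(self, seed: int) -> "EstimatorSettings":
        return replace(self, seed=seed)


@dataclass
class Standardized:
    """Z-scored item matrices per wave plus the transform parameters."""

    wave1: pd.DataFrame
    wave2: pd.DataFrame
    covariates: pd.DataFrame
    means: pd.DataFrame  # rows: wave1/wave2/cov parameter locations
    sds: pd.DataFrame


def _zscore_frame(frame: pd.DataFrame, context: str) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    means = frame.mean()
    sds = frame.std(ddof=1)
    bad = sds[~(sds > 0)].index.tolist()
    if bad:
        raise ValueError(f"zero-variance column(s) in {context}: {bad}")
    return (frame - means) / sds, means, sds


def standardize(dataset: PanelDataset) -> Standardized:
    """Z-score both waves' item columns and the covariates (ddof=1).

    Idempotent on already-standardized data; errors name any
    zero-variance column.  Requires imputation to have removed all
    missing responses.
    """
    for wave_name, wave in (("wave1", dataset.wave1), ("wave2", dataset.wave2)):
        if wave.isna().any().any():
            raise ValueError(f"{wave_name} contains missing values; impute first")
    z1, m1, s1 = _zscore_frame(dataset.wave1, "wave1")
    z2, m2, s2 = _zscore_frame(dataset.wave2, "wave2")
    cov = dataset.covariates[list(COVARIATES)].astype(float)
    zc, mc, sc = _zscore_frame(cov, "covariates")
    means = pd.DataFrame({"wave1": m1, "wave2": m2}).T
    sds = pd.DataFrame({"wave1": s1, "wave2": s2}).T
    means = pd.concat([means, mc.to_frame("cov").T])
    sds = pd.concat([sds, sc.to_frame("cov").T])
    return Standardized(z1, z2, zc, means, sds)


@dataclass
class CLPNetwork:
    """Estimated directed cross-lagged network.

    ``B[i, j]`` is the standardized cross-lagged effect of node i at wave 1
    on node j at wave 2 (zero diagonal); ``a`` holds the autoregressive
    coefficients; ``lambda_per_node`` the CV-selected penalty of each
    outcome regression; ``covariate_coefs`` the unpenalized gender/age
    coefficients per outcome.
    """

    node_labels: tuple[str, ...]
    B: np.ndarray
    a: np.ndarray
    lambda_per_node: np.ndarray
    covariate_coefs: pd.DataFrame
    cv_curves: list[CVResult] | None = None

    def __post_init__(self) -> None:
        p = len(self.node_labels)
        if self.B.shape != (p, p):
            raise ValueError("B must be square with one row per node")
        if np.any(np.diag(self.B) != 0.0):
            raise ValueError("B must have a zero diagonal")
        if self.a.shape != (p,) or self.lambda_per_node.shape != (p,):
            raise ValueError("a and lambda_per_node must have one entry per node")

    @property
    def p(self) -> int:
        return len(self.node_labels)


def estimate_network(dataset: PanelDataset, settings: EstimatorSettings | None = None) -> CLPNetwork:
    """Fit the cross-lagged panel network on a screened, imputed dataset.

    For each wave-2 outcome: select the penalty by K-fold CV (folds shared
    across outcomes), then refit on the full sample at that penalty.  The
    self-lag coefficient goes to ``a``; all other symptom coefficients form
    B's off-diagonal; gender/age enter unpenalized.
    """
    settings = settings or EstimatorSettings()
    if list(dataset.wave1.columns) != list(dataset.wave2.columns):
        raise ValueError("node-set mismatch between waves")
    std = standardize(dataset)
    labels = dataset.node_labels
    p = len(labels)
    X = np.column_stack([std.wave1.to_numpy(), std.covariates.to_numpy()])
    unpenalized = (p, p + 1)
    n = X.shape[0]
    folds = _fold_assignment(n, settings.n_folds, settings.seed)

    B = np.zeros((p, p))
    a = np.zeros(p)
    lam = np.zeros(p)
    cov_coefs = np.zeros((p, 2))
    curves: list[CVResult] = []
    for j in range(p):
        y = std.wave2.iloc[:, j].to_numpy()
        cv = cv_select_lambda(
            y,
            X,
            unpenalized_cols=unpenalized,
            n_folds=settings.n_folds,
            lambda_rule=settings.lambda_rule,
            n_lambda=settings.n_lambda,
            lambda_min_ratio=settings.lambda_min_ratio,
            tol=settings.tol,
            max_iter=settings.max_iter,
            folds=folds,
        )
        _, beta = lasso_path(
            y, X, cv.selected, unpenalized_cols=unpenalized,
            tol=settings.tol, max_iter=settings.max_iter,
        )
        B[:, j] = beta[:p]
        a[j] = beta[j]
        B[j, j] = 0.0
        lam[j] = cv.selected
        cov_coefs[j] = beta[p:]
        curves.append(cv)

    return CLPNetwork(
        node_labels=labels,
        B=B,
        a=a,
        lambda_per_node=lam,
        covariate_coefs=pd.DataFrame(cov_coefs, index=list(labels), columns=list(COVARIATES)),
        cv_curves=curves,
    )


def threshold_for_display(network: CLPNetwork, threshold: float = 0.05) -> pd.DataFrame:
    """Cross-lagged edges with |weight| >= threshold, strongest first.

    Display-only: the stored B is never altered.  Ties in |weight| break by
    (source, target) lexicographic order.  The head of this list is the
    "strongest cross-lagged associations" report.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rows = []
    for i, src in enumerate(network.node_labels):
        for j, dst in enumerate(network.node_labels):
            w = network.B[i, j]
            if i != j and w != 0.0 and abs(w) >= threshold:
                rows.append((src, dst, float(w)))
    rows.sort(key=lambda r: (-abs(r[2]), r[0], r[1]))
    return pd.DataFrame(rows, columns=["from", "to", "weight"])


def strongest_edges(network: CLPNetwork, k: int = 5) -> pd.DataFrame:
    """Top-k cross-lagged associations by absolute weight."""
    return threshold_for_display(network, threshold=0.0).head(k).reset_index(drop=True)


def network_to_edge_frame(network: CLPNetwork, threshold: float = 0.0) -> pd.DataFrame:
    """Full export table: cross-lagged + autoregressive + covariate rows."""
    rows = [
        (r["from"], r["to"], r["weight"], "cross_lagged")
        for _, r in threshold_for_display(network, threshold).iterrows()
    ]
    for label, w in zip(network.node_labels, network.a):
        if w != 0.0:
            rows.append((label, label, float(w), "autoregressive"))
    for label in network.node_labels:
        for cov in COVARIATES:
            w = float(network.covariate_coefs.loc[label, cov])
            if w != 0.0:
                rows.append((cov, label, w, "covariate"))
    return pd.DataFrame(rows, columns=["from", "to", "weight", "kind"])


def write_edge_csv(network: CLPNetwork, path, threshold: float = 0.0) -> None:
    network_to_edge_frame(network, threshold).to_csv(path, index=False)


def to_graphml(network: CLPNetwork, path, threshold: float = 0.0) -> None:
    """Export the directed network (including autoregressive self-loops)
    for external network viewers."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(network.node_labels)
    for _, row in threshold_for_display(network, threshold).iterrows():
        g.add_edge(row["from"], row["to"], weight=float(row["weight"]), kind="cross_lagged")
    for label, w in zip(network.node_labels, network.a):
        if w != 0.0:
            g.add_edge(label, label, weight=float(w), kind="autoregressive")
    nx.write_graphml(g, path)
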
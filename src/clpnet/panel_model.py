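"""Construct-level cross-lagged panel path model on composite scores.

The three constructs (CPTSD = ITQ total, depression = PHQ-9 total, anxiety
= GAD-7 total) are z-scored and modelled as a recursive path system: every
wave-2 construct is regressed on all wave-1 constructs (cross-lagged +
autoregressive paths) and on gender/age; wave-1 covariances and wave-2
residual covariances are free (concurrent covariance at both waves).

Constructs are deliberately *manifest* composites rather than latent
variables: the path-level logic — asymmetric cross-lagged prediction — is
fully exercised at the composite level, and no measurement (factor-loading)
model is estimated.  Estimation is maximum likelihood on the sample
covariance matrix via iterated-FGLS seemingly-unrelated regressions (for a
recursive system with free residual covariances the two coincide; with
identical regressors in every equation both reduce to equation-by-equation
least squares).  Fit indices follow the conventional ML definitions:
chi-square = (n-1) * F_ML against the saturated model, CFI/TLI against the
independence baseline, RMSEA from the noncentrality estimate, SRMR as the
root mean square standardized covariance residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CONSTRUCTS = ("cptsd", "dep", "anx")
DEFAULT_COVARIATES = ("gender", "age")


@dataclass(frozen=True)
class PathModelSpec:
    """Which regression paths enter the wave-2 construct equations.

    ``paths`` are (wave-1 construct, wave-2 construct) pairs — the default
    full set contains all 9, i.e. three autoregressive and six cross-lagged
    paths; ``covariate_paths`` are (covariate, wave-2 construct) pairs.
    Wave-1 covariances and wave-2 residual covariances are always free.
    """

    constructs: tuple[str, ...] = DEFAULT_CONSTRUCTS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    paths: tuple[tuple[str, str], ...] | None = None
    covariate_paths: tuple[tuple[str, str], ...] | None = None

    def resolved_paths(self):
        if self.paths is not None:
            return tuple(self.paths)
        return tuple((a, b) for b in self.constructs for a in self.constructs)

    def resolved_covariate_paths(self):
        if self.covariate_paths is not None:
            return tuple(self.covariate_paths)
        return tuple((c, b) for b in self.constructs for c in self.covariates)


@dataclass
class PathModelResult:
    """Fitted path model: standardized estimates, fit indices, and the
    joint coefficient covariance used by Wald tests."""

    spec: PathModelSpec
    paths: pd.DataFrame              # from, to, kind, estimate, se, z, p
    wave1_corr: pd.DataFrame
    wave2_residual_corr: pd.DataFrame
    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    n: int
    coef_cov: np.ndarray = field(repr=False)
    _coef_index: dict = field(repr=False, default_factory=dict)

    def path_estimate(self, source: str, target: str) -> float:
        return float(self.paths.set_index(["from", "to"]).loc[(source, target), "estimate"])


def _zscore(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(ddof=1)
    bad = sd[~(sd > 0)].index.tolist()
    if bad:
        raise ValueError(f"zero-variance column(s): {bad}")
    return (frame - frame.mean()) / sd


def _fml(S: np.ndarray, Sigma: np.ndarray) -> float:
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("implied covariance not positive definite")
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise np.linalg.LinAlgError("singular sample covariance")
    p = S.shape[0]
    return float(logdet_sigma - logdet_s + np.trace(np.linalg.solve(Sigma, S)) - p)


def fit_path_model(
    scores: pd.DataFrame,
    spec: PathModelSpec | None = None,
    max_gls_iter: int = 100,
    gls_tol: float = 1e-12,
) -> PathModelResult:
    """Fit the cross-lagged path system on composite scores.

    ``scores`` must contain ``<construct>_t1`` and ``<construct>_t2``
    columns for every construct plus the covariate columns.  All columns
    are z-scored before fitting, so estimates are standardized path
    coefficients with delta-method (GLS) standard errors.
    """
    spec = spec or PathModelSpec()
    constructs = spec.constructs
    covariates = spec.covariates
    exog_cols = [f"{c}_t1" for c in constructs] + list(covariates)
    endog_cols = [f"{c}_t2" for c in constructs]
    needed = exog_cols + endog_cols
    missing = [c for c in needed if c not in scores.columns]
    if missing:
        raise KeyError(f"scores frame missing columns: {missing}")
    n = len(scores)
    if n <= len(needed):
        raise ValueError("need more participants than observed variables")

    Z = _zscore(scores[needed].astype(float))
    X = Z[exog_cols].to_numpy()
    Y = Z[endog_cols].to_numpy()
    n_eq = len(constructs)

    # per-equation regressor index lists from the path spec
    exog_names = [f"{c}_t1" for c in constructs] + list(covariates)
    path_set = spec.resolved_paths()
    cov_set = spec.resolved_covariate_paths()
    eq_cols: list[list[int]] = []
    eq_names: list[list[tuple[str, str, str]]] = []
    for target in constructs:
        cols, names = [], []
        for k, src in enumerate(constructs):
            if (src, target) in path_set:
                cols.append(k)
                kind = "autoregressive" if src == target else "cross_lagged"
                names.append((src, target, kind))
        for k, cov in enumerate(covariates):
            if (cov, target) in cov_set:
                cols.append(n_eq + k)
                names.append((cov, target, "covariate"))
        eq_cols.append(cols)
        eq_names.append(names)

    # iterated FGLS (== ML for this recursive system with free Psi)
    beta = [
        np.linalg.lstsq(X[:, cols], Y[:, i], rcond=None)[0] if cols else np.zeros(0)
        for i, cols in enumerate(eq_cols)
    ]
    identical = all(cols == eq_cols[0] for cols in eq_cols)
    n_coef = sum(len(c) for c in eq_cols)
    for _ in range(1 if identical else max_gls_iter):
        resid = np.column_stack(
            [Y[:, i] - (X[:, eq_cols[i]] @ beta[i] if eq_cols[i] else 0.0) for i in range(n_eq)]
        )
        psi = resid.T @ resid / n
        psi_inv = np.linalg.inv(psi)
        A = np.zeros((n_coef, n_coef))
        r = np.zeros(n_coef)
        offs = np.cumsum([0] + [len(c) for c in eq_cols])
        for i in range(n_eq):
            Zi = X[:, eq_cols[i]]
            for j in range(n_eq):
                Zj = X[:, eq_cols[j]]
                A[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = psi_inv[i, j] * (Zi.T @ Zj)
                r[offs[i]:offs[i + 1]] += psi_inv[i, j] * (Zi.T @ Y[:, j])
        b_new = np.linalg.solve(A, r)
        change = max(
            (np.abs(b_new[offs[i]:offs[i + 1]] - beta[i]).max() if eq_cols[i] else 0.0)
            for i in range(n_eq)
        )
        beta = [b_new[offs[i]:offs[i + 1]] for i in range(n_eq)]
        if change < gls_tol:
            break

    resid = np.column_stack(
        [Y[:, i] - (X[:, eq_cols[i]] @ beta[i] if eq_cols[i] else 0.0) for i in range(n_eq)]
    )
    psi = resid.T @ resid / n
    psi_inv = np.linalg.inv(psi)
    offs = np.cumsum([0] + [len(c) for c in eq_cols])
    A = np.zeros((n_coef, n_coef))
    for i in range(n_eq):
        Zi = X[:, eq_cols[i]]
        for j in range(n_eq):
            Zj = X[:, eq_cols[j]]
            A[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = psi_inv[i, j] * (Zi.T @ Zj)
    coef_cov = np.linalg.inv(A)

    # implied covariance over [exog, endog]
    n_x = X.shape[1]
    S = np.cov(np.column_stack([X, Y]), rowvar=False, ddof=0)
    S_xx = S[:n_x, :n_x]
    Gamma = np.zeros((n_eq, n_x))
    for i, cols in enumerate(eq_cols):
        Gamma[i, cols] = beta[i]
    Sigma = np.empty_like(S)
    Sigma[:n_x, :n_x] = S_xx
    Sigma[n_x:, :n_x] = Gamma @ S_xx
    Sigma[:n_x, n_x:] = Sigma[n_x:, :n_x].T
    Sigma[n_x:, n_x:] = Gamma @ S_xx @ Gamma.T + psi

    p_var = S.shape[0]
    n_free = n_x * (n_x + 1) // 2 + n_coef + n_eq * (n_eq + 1) // 2
    df = p_var * (p_var + 1) // 2 - n_free
    fml = _fml(S, Sigma)
    chi2 = max((n - 1) * fml, 0.0)
    if df == 0:
        chi2 = 0.0 if chi2 < 1e-8 * n else chi2

    # independence baseline
    Sigma_base = np.diag(np.diag(S))
    chi2_base = (n - 1) * _fml(S, Sigma_base)
    df_base = p_var * (p_var - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df == 0:
        tli = 1.0
    else:
        base_ratio = chi2_base / df_base
        tli = (base_ratio - chi2 / df) / (base_ratio - 1.0)
    rmsea = 0.0 if df == 0 else float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    d = np.sqrt(np.diag(S))
    resid_std = (S - Sigma) / np.outer(d, d)
    tri = np.tril_indices(p_var)
    srmr = float(np.sqrt(np.mean(resid_std[tri] ** 2)))

    # assemble the path table
    rows = []
    index_map: dict[tuple[str, str], int] = {}
    flat = np.concatenate([b for b in beta]) if n_coef else np.zeros(0)
    ses = np.sqrt(np.diag(coef_cov))
    k = 0
    for i in range(n_eq):
        for (src, target, kind) in eq_names[i]:
            z = flat[k] / ses[k] if ses[k] > 0 else np.inf
            rows.append(
                (src, target, kind, float(flat[k]), float(ses[k]),
                 float(z), float(2 * stats.norm.sf(abs(z))))
            )
            index_map[(src, target)] = k
            k += 1
    paths = pd.DataFrame(rows, columns=["from", "to", "kind", "estimate", "se", "z", "p"])

    corr1 = pd.DataFrame(
        np.corrcoef(X[:, :n_eq], rowvar=False), index=constructs, columns=constructs
    )
    dpsi = np.sqrt(np.diag(psi))
    corr2 = pd.DataFrame(
        psi / np.outer(dpsi, dpsi), index=constructs, columns=constructs
    )

    return PathModelResult(
        spec=spec,
        paths=paths,
        wave1_corr=corr1,
        wave2_residual_corr=corr2,
        chi2=float(chi2),
        df=int(df),
        cfi=float(min(cfi, 1.0)),
        tli=float(tli),
        rmsea=rmsea,
        srmr=srmr,
        n=n,
        coef_cov=coef_cov,
        _coef_index=index_map,
    )


def _parse_path(path) -> tuple[str, str]:
    if isinstance(path, str):
        if "->" not in path:
            raise KeyError(f"path {path!r} must look like 'cptsd->anx'")
        a, b = path.split("->", 1)
        return a.strip(), b.strip()
    return tuple(path)


@dataclass(frozen=True)
class PathDifferenceResult:
    """Wald test of b(path_ba) - b(path_ab).

    Sign convention: the *reverse-minus-forward* difference, so a stronger
    forward path yields a negative difference.
    """

    path_ab: tuple[str, str]
    path_ba: tuple[str, str]
    difference: float
    se: float
    z: float
    p: float


def wald_path_difference(result: PathModelResult, path_ab, path_ba) -> PathDifferenceResult:
    """Wald test of equality of two fitted paths via their joint covariance."""
    pa = _parse_path(path_ab)
    pb = _parse_path(path_ba)
    for path in (pa, pb):
        if path not in result._coef_index:
            raise KeyError(f"path {path[0]}->{path[1]} not in the fitted model")
    if pa == pb:
        return PathDifferenceResult(pa, pb, 0.0, 0.0, 0.0, 1.0)
    ia, ib = result._coef_index[pa], result._coef_index[pb]
    est = result.paths.set_index(["from", "to"])["estimate"]
    diff = float(est.loc[pb] - est.loc[pa])
    var = (
        result.coef_cov[ia, ia] + result.coef_cov[ib, ib] - 2 * result.coef_cov[ia, ib]
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = diff / se if se > 0 else np.inf * np.sign(diff)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return PathDifferenceResult(pa, pb, diff, se, float(z), p)


#: Hu & Bentler-style cutoffs: CFI/TLI >= 0.95 good, >= 0.90 acceptable;
#: RMSEA/SRMR <= 0.08 acceptable (boundary inclusive).
DEFAULT_CUTOFFS = {
    "cfi": {"good": 0.95, "acceptable": 0.90},
    "tli": {"good": 0.95, "acceptable": 0.90},
    "rmsea": {"acceptable": 0.08},
    "srmr": {"acceptable": 0.08},
}


def evaluate_fit(result, cutoffs: dict | None = None) -> dict[str, str]:
    """Label each fit index good/acceptable/poor by conventional cutoffs.

    ``result`` may be a :class:`PathModelResult` or a plain mapping of
    index name to value.
    """
    cutoffs = cutoffs or DEFAULT_CUTOFFS
    values = (
        {"cfi": result.cfi, "tli": result.tli, "rmsea": result.rmsea, "srmr": result.srmr}
        if isinstance(result, PathModelResult)
        else dict(result)
    )
    labels: dict[str, str] = {}
    for name, value in values.items():
        rule = cutoffs.get(name)
        if rule is None:
            continue
        if name in ("cfi", "tli"):
            if value > rule["good"]:
                labels[name] = "good"
            elif value > rule["acceptable"]:
                labels[name] = "acceptable"
            else:
                labels[name] = "poor"
        else:  # rmsea / srmr: lower is better, boundary inclusive
            labels[name] = "acceptable" if value <= rule["acceptable"] else "poor"
    return labels
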
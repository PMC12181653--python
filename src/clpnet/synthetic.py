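"""Two-wave ordinal panel data simulation from a known directed network.

The generator draws wave-1 latent symptom scores from a correlated Gaussian,
propagates them to wave 2 through a first-order cross-lagged system

    W2 = W1 (diag(a) + B) + covariate effects + correlated Gaussian noise,

and discretizes each latent column to the instrument's ordinal range with
equiprobable quantile thresholds.  ``B`` (zero diagonal) holds the directed
cross-lagged effects — entry (i, j) is the standardized effect of symptom i
at wave 1 on symptom j at wave 2 — and ``a`` the autoregressive effects.
Item-level missingness is injected completely at random at wave 1 only
(emulating paper-based wave-1 questionnaires), and victimization-screening
fields are populated so the screening stage is exercised end to end.

Everything is deterministic given the seed: a single ``numpy`` Generator is
consumed in a fixed order per call; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CANONICAL_NODES, PanelDataset


@dataclass(frozen=True)
class TruthNetwork:
    """Ground-truth directed network driving the simulation.

    ``B_true[i, j]`` is the cross-lagged effect of node i (wave 1) on node j
    (wave 2); autoregressive effects live in ``a_true`` (conceptually B's
    diagonal).  ``covariate_effects`` has one row per covariate (gender,
    age) of per-node loadings on the wave-2 latents.
    """

    node_labels: tuple[str, ...]
    B_true: np.ndarray
    a_true: np.ndarray
    within_wave_corr: float = 0.3
    covariate_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = len(self.node_labels)
        if len(set(self.node_labels)) != p:
            raise ValueError("node_labels must be unique")
        B = np.asarray(self.B_true, dtype=float)
        a = np.asarray(self.a_true, dtype=float)
        if B.shape != (p, p):
            raise ValueError(f"B_true must be {p}x{p}")
        if a.shape != (p,):
            raise ValueError(f"a_true must have length {p}")
        if np.any(np.diag(B) != 0.0):
            raise ValueError("B_true must have a zero diagonal")
        if not 0.0 <= self.within_wave_corr < 1.0:
            raise ValueError("within_wave_corr must lie in [0, 1)")
        if self.spectral_radius >= 1.0:
            raise ValueError(
                f"unstable system: spectral radius {self.spectral_radius:.3f} >= 1"
            )
        cov = self.covariate_effects
        if cov is not None and np.asarray(cov).shape != (2, p):
            raise ValueError("covariate_effects must be a (2, p) array (gender, age)")
        object.__setattr__(self, "B_true", B)
        object.__setattr__(self, "a_true", a)
        if cov is not None:
            object.__setattr__(self, "covariate_effects", np.asarray(cov, dtype=float))

    @property
    def p(self) -> int:
        return len(self.node_labels)

    @property
    def transition_matrix(self) -> np.ndarray:
        return self.B_true + np.diag(self.a_true)

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.B_true + np.diag(self.a_true))).max())

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i, src in enumerate(self.node_labels):
            for j, dst in enumerate(self.node_labels):
                if i != j and self.B_true[i, j] != 0.0:
                    out.append((src, dst, float(self.B_true[i, j])))
        return out

    # ------------------------------ I/O ------------------------------- #

    def to_edge_csv(self, path) -> None:
        """Edge list ``from,to,weight`` preceded by a comment header that
        carries the autoregressions and generator-level scalars."""
        with open(path, "w") as fh:
            fh.write(f"# within_wave_corr {self.within_wave_corr}\n")
            for label, val in zip(self.node_labels, self.a_true):
                fh.write(f"# auto {label} {val}\n")
            if self.covariate_effects is not None:
                for name, row in zip(("gender", "age"), self.covariate_effects):
                    fh.write(f"# covariate {name} " + " ".join(map(str, row)) + "\n")
            fh.write("# nodes " + " ".join(self.node_labels) + "\n")
            fh.write("from,to,weight\n")
            for src, dst, w in self.edges:
                fh.write(f"{src},{dst},{w}\n")

    @classmethod
    def from_edge_csv(cls, path) -> "TruthNetwork":
        within = 0.3
        autos: dict[str, float] = {}
        covs: dict[str, list[float]] = {}
        nodes: list[str] = []
        rows: list[tuple[str, str, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line == "from,to,weight":
                    continue
                if line.startswith("#"):
                    parts = line[1:].split()
                    if parts[0] == "within_wave_corr":
                        within = float(parts[1])
                    elif parts[0] == "auto":
                        autos[parts[1]] = float(parts[2])
                    elif parts[0] == "covariate":
                        covs[parts[1]] = [float(x) for x in parts[2:]]
                    elif parts[0] == "nodes":
                        nodes = parts[1:]
                    continue
                src, dst, w = line.split(",")
                rows.append((src, dst, float(w)))
        if not nodes:
            raise ValueError("edge CSV lacks the '# nodes' header line")
        idx = {n: i for i, n in enumerate(nodes)}
        p = len(nodes)
        B = np.zeros((p, p))
        for src, dst, w in rows:
            B[idx[src], idx[dst]] = w
        a = np.array([autos.get(n, 0.0) for n in nodes])
        cov = None
        if covs:
            cov = np.vstack([covs.get("gender", np.zeros(p)), covs.get("age", np.zeros(p))])
        return cls(tuple(nodes), B, a, within, cov)


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling configuration for :func:`simulate_panel`.

    Defaults emulate a school-based victimization cohort: roughly a quarter
    of respondents screen negative (no victimization), a few percent fail
    the control questions, and wave-1 paper questionnaires carry sparse
    item-level missingness.  ``likert_levels`` maps instrument keys to
    response maxima (ITQ items 0-4; PHQ-9/GAD-7 items 0-3); node labels not
    matching a canonical instrument fall back to ``default_max``.  Set
    ``discretize=False`` to emit the continuous latent scores directly
    (useful for construct-level recovery experiments where composites are
    quasi-continuous).
    """

    n: int
    seed: int = 0
    likert_levels: dict = field(
        default_factory=lambda: {"ITQ": 4, "PHQ-9": 3, "GAD-7": 3}
    )
    default_max: int = 3
    missing_rate: float = 0.02
    screen_negative_rate: float = 0.25
    control_fail_rate: float = 0.07
    discretize: bool = True
    age_mean: float = 13.22
    age_sd: float = 1.96

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("missing_rate", "screen_negative_rate", "control_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


_ITQ_PREFIXES = ("RE", "AV", "TH", "NSC", "AD", "DR")


def _levels_for(label: str, config: GeneratorConfig) -> int:
    """Number of ordinal levels for a node label."""
    if label.startswith(_ITQ_PREFIXES):
        return config.likert_levels.get("ITQ", 4) + 1
    if label.startswith("dep"):
        return config.likert_levels.get("PHQ-9", 3) + 1
    if label.startswith("anx"):
        return config.likert_levels.get("GAD-7", 3) + 1
    return config.default_max + 1


def make_truth(
    node_labels=CANONICAL_NODES,
    edge_density: float = 0.05,
    effect_size: float = 0.3,
    autoregression: float = 0.3,
    seed: int = 0,
    within_wave_corr: float = 0.3,
    covariate_effect: float = 0.1,
    max_attempts: int = 100,
) -> TruthNetwork:
    """Draw a random sparse truth network of the requested edge density.

    Exactly ``round(edge_density * p * (p-1))`` off-diagonal cells are given
    weight ``±effect_size`` (signs drawn 50/50); the diagonal is the constant
    ``autoregression``.  If the implied transition matrix has spectral
    radius >= 1, the support and signs are redrawn (same magnitudes) up to
    ``max_attempts`` times before the configuration is rejected — the
    magnitudes themselves are never silently shrunk.
    """
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must lie in [0, 1]")
    node_labels = tuple(node_labels)
    p = len(node_labels)
    k = int(round(edge_density * p * (p - 1)))
    rng = np.random.default_rng(seed)
    off = [(i, j) for i in range(p) for j in range(p) if i != j]
    a = np.full(p, float(autoregression))
    cov = np.full((2, p), float(covariate_effect))
    for _ in range(max_attempts):
        B = np.zeros((p, p))
        if k:
            chosen = rng.choice(len(off), size=k, replace=False)
            signs = np.where(rng.random(k) < 0.5, -1.0, 1.0)
            for cell, s in zip(chosen, signs):
                i, j = off[cell]
                B[i, j] = s * effect_size
        radius = float(np.abs(np.linalg.eigvals(B + np.diag(a))).max())
        if radius < 1.0:
            return TruthNetwork(node_labels, B, a, within_wave_corr, cov)
    raise ValueError(
        f"could not draw a stable network (spectral radius >= 1) in "
        f"{max_attempts} attempts: density={edge_density}, "
        f"effect_size={effect_size}, autoregression={autoregression}"
    )


def _discretize(latent: np.ndarray, sd: np.ndarray, labels, config: GeneratorConfig) -> np.ndarray:
    """Map standardized-latent columns to ordinal levels by equiprobable
    normal quantile thresholds."""
    out = np.empty_like(latent)
    for j, label in enumerate(labels):
        L = _levels_for(label, config)
        cuts = stats.norm.ppf(np.arange(1, L) / L)
        out[:, j] = np.searchsorted(cuts, latent[:, j] / sd[j])
    return out


def simulate_panel(truth: TruthNetwork, config: GeneratorConfig) -> PanelDataset:
    """Simulate a two-wave ordinal panel dataset from ``truth``.

    Deterministic given ``config.seed``.  Wave-1 latents are standard
    normal with exchangeable correlation ``within_wave_corr``; wave-2
    latents follow the cross-lagged system plus covariate effects and
    correlated residuals; both waves are discretized by fixed quantile
    thresholds (unless ``config.discretize`` is off).
    """
    p = truth.p
    n = config.n
    rng = np.random.default_rng(config.seed)

    rho = truth.within_wave_corr
    sigma = np.full((p, p), rho) + (1.0 - rho) * np.eye(p)
    L = np.linalg.cholesky(sigma)

    gender = rng.integers(0, 2, size=n).astype(float)
    age = rng.normal(config.age_mean, config.age_sd, size=n)

    W1 = rng.standard_normal((n, p)) @ L.T
    E2 = rng.standard_normal((n, p)) @ L.T
    M = truth.transition_matrix
    W2 = W1 @ M + E2

    gender_c = gender - 0.5
    age_z = (age - config.age_mean) / config.age_sd
    cov_var = np.zeros(p)
    if truth.covariate_effects is not None:
        cg, ca = truth.covariate_effects
        W2 = W2 + np.outer(gender_c, cg) + np.outer(age_z, ca)
        cov_var = 0.25 * cg**2 + ca**2

    # theoretical marginal SDs so thresholds hit their target frequencies
    sd1 = np.ones(p)
    sd2 = np.sqrt(np.einsum("ij,jk,ki->i", M.T, sigma, M) + cov_var + 1.0)

    if config.discretize:
        X1 = _discretize(W1, sd1, truth.node_labels, config)
        X2 = _discretize(W2, sd2, truth.node_labels, config)
    else:
        X1, X2 = W1.copy(), W2.copy()

    # MCAR missingness at wave 1 only
    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        X1 = X1.astype(float)
        X1[mask] = np.nan

    # screening block: 10 victimization-frequency items (0-4) + control flag
    never = rng.random(n) < config.screen_negative_rate
    freq_probs = np.array([0.50, 0.25, 0.12, 0.08, 0.05])
    screen = rng.choice(5, size=(n, 10), p=freq_probs)
    first_item = rng.integers(0, 10, size=n)
    all_zero = screen.sum(axis=1) == 0
    force = ~never & all_zero
    screen[force, first_item[force]] = 1
    screen[never] = 0
    control_ok = rng.random(n) >= config.control_fail_rate

    screening = pd.DataFrame(screen, columns=[f"screen_v{i+1}" for i in range(10)])
    screening["control_ok"] = control_ok
    return PanelDataset(
        ids=np.arange(1, n + 1),
        covariates=pd.DataFrame({"gender": gender, "age": age}),
        screening=screening,
        wave1=pd.DataFrame(X1, columns=list(truth.node_labels)),
        wave2=pd.DataFrame(X2, columns=list(truth.node_labels)),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Edge-recovery diagnostics of an estimated network against truth.

    ``sensitivity`` counts true edges recovered with any sign;
    ``sensitivity_signed`` requires the sign to match; ``specificity`` is
    the fraction of truly-absent off-diagonal cells estimated as zero, and
    ``false_edge_rate`` its complement.  ``sensitivity`` is None when the
    truth has no edges.
    """

    n_true_edges: int
    n_estimated_edges: int
    sensitivity: float | None
    sensitivity_signed: float | None
    sign_agreement: float | None
    specificity: float
    false_edge_rate: float
    n_participants: int


def recovery_experiment(truth: TruthNetwork, config: GeneratorConfig, settings=None) -> RecoveryReport:
    """Simulate, run the full screening + estimation pipeline, and compare
    the estimated cross-lagged support and signs against ``truth``."""
    from .clpn import EstimatorSettings, estimate_network
    from .instruments import apply_screening, impute_missing

    settings = settings or EstimatorSettings()
    data = simulate_panel(truth, config)
    screened, _ = apply_screening(data)
    clean = impute_missing(screened)
    net = estimate_network(clean, settings)

    Bt, Be = truth.B_true, net.B
    true_edge = Bt != 0.0
    est_edge = Be != 0.0
    off = ~np.eye(truth.p, dtype=bool)

    n_true = int(true_edge.sum())
    n_est = int((est_edge & off).sum())
    neg_cells = off & ~true_edge
    fp = int((est_edge & neg_cells).sum())
    specificity = 1.0 - fp / neg_cells.sum()

    if n_true == 0:
        sens = sens_signed = sign_agree = None
    else:
        hit = true_edge & est_edge
        sens = hit.sum() / n_true
        signed = hit & (np.sign(Bt) == np.sign(Be))
        sens_signed = signed.sum() / n_true
        sign_agree = float(signed.sum() / hit.sum()) if hit.any() else None
    return RecoveryReport(
        n_true_edges=n_true,
        n_estimated_edges=n_est,
        sensitivity=None if sens is None else float(sens),
        sensitivity_signed=None if sens_signed is None else float(sens_signed),
        sign_agreement=sign_agree,
        specificity=float(specificity),
        false_edge_rate=float(1.0 - specificity),
        n_participants=clean.n,
    )
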
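"""End-to-end analysis pipeline driven by one YAML configuration.

Stages: simulate (or load a CSV) -> screen -> impute -> composite scoring +
path model (when the canonical instruments are present) and standardize ->
CLPN -> centralities -> stability diagnostics.  One global seed is declared
in the config; each stage derives its own seed deterministically from the
stage name, so stages can be run independently yet reproducibly.  Data
files never contain timestamps; the log does.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import centrality as centrality_mod
from . import stability as stability_mod
from .clpn import (
    EstimatorSettings,
    estimate_network,
    strongest_edges,
    threshold_for_display,
    to_graphml,
    write_edge_csv,
)
from .datasets import CANONICAL_NODES, PanelDataset
from .instruments import apply_screening, construct_scores, impute_missing
from .panel_model import evaluate_fit, fit_path_model, wald_path_difference
from .synthetic import GeneratorConfig, TruthNetwork, make_truth, simulate_panel


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one of ``input_path`` or
    ``simulation`` must be present, never both)."""

    seed: int = 0
    output_dir: str = "clpnet_out"
    input_path: str | None = None
    simulation: dict | None = None
    estimator: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    display_threshold: float = 0.05
    never_anchor: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError(
                "config must declare exactly one of 'input' (a CSV path) or "
                "'simulation' (a generator block)"
            )
        if self.display_threshold < 0:
            raise ValueError("display_threshold must be >= 0")

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "clpnet_out")),
            input_path=raw.get("input"),
            simulation=raw.get("simulation"),
            estimator=raw.get("estimator", {}) or {},
            bootstrap=raw.get("bootstrap", {}) or {},
            display_threshold=float(raw.get("display_threshold", 0.05)),
            never_anchor=int(raw.get("never_anchor", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} did not parse to a mapping")
        return cls.from_mapping(raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "input": self.input_path,
                "simulation": self.simulation,
                "estimator": self.estimator,
                "bootstrap": self.bootstrap,
                "display_threshold": self.display_threshold,
                "never_anchor": self.never_anchor,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_truth(sim: dict, seed: int) -> TruthNetwork:
    """Construct the ground-truth network described by a simulation block."""
    nodes = sim.get("nodes", "canonical")
    if nodes == "canonical":
        labels = CANONICAL_NODES
    elif isinstance(nodes, int):
        labels = tuple(f"s{i+1}" for i in range(nodes))
    else:
        labels = tuple(nodes)
    return make_truth(
        node_labels=labels,
        edge_density=float(sim.get("edge_density", 0.05)),
        effect_size=float(sim.get("effect_size", 0.3)),
        autoregression=float(sim.get("autoregression", 0.3)),
        within_wave_corr=float(sim.get("within_wave_corr", 0.3)),
        covariate_effect=float(sim.get("covariate_effect", 0.1)),
        seed=sim.get("truth_seed", seed),
    )


def build_generator_config(sim: dict, seed: int) -> GeneratorConfig:
    return GeneratorConfig(
        n=int(sim.get("n", 2000)),
        seed=seed,
        missing_rate=float(sim.get("missing_rate", 0.02)),
        screen_negative_rate=float(sim.get("screen_negative_rate", 0.25)),
        control_fail_rate=float(sim.get("control_fail_rate", 0.07)),
        discretize=bool(sim.get("discretize", True)),
    )


def estimator_from_config(config: PipelineConfig) -> EstimatorSettings:
    est = dict(config.estimator)
    est.setdefault("seed", derive_seed(config.seed, "estimator"))
    return EstimatorSettings(**est)


def _has_canonical_nodes(dataset: PanelDataset) -> bool:
    return set(CANONICAL_NODES) <= set(dataset.node_labels)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts to the output dir.

    Returns a dict of in-memory results (dataset, network, tables, reports).
    Identical config + seed produce byte-identical data outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.time()

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {stage}: {msg}")

    results: dict = {}
    stage = "load"
    try:
        # ---------------- simulate / load ---------------- #
        if config.simulation is not None:
            stage = "simulate"
            truth = build_truth(config.simulation, derive_seed(config.seed, "truth"))
            gen = build_generator_config(
                config.simulation, derive_seed(config.seed, "simulate")
            )
            dataset = simulate_panel(truth, gen)
            truth.to_edge_csv(out / "truth_edges.csv")
            results["truth"] = truth
            log(stage, f"simulated n={dataset.n}, p={len(dataset.node_labels)} nodes")
        else:
            dataset = PanelDataset.from_csv(config.input_path)
            log(stage, f"loaded {config.input_path}: n={dataset.n}")

        # ---------------- screen + impute ---------------- #
        stage = "screen"
        screened, screen_result = apply_screening(dataset, config.never_anchor)
        log(
            stage,
            f"{screen_result.n_input} -> victimized {screen_result.n_victimized} "
            f"-> excluded {screen_result.n_excluded_invalid} -> final {screen_result.n_final}",
        )
        stage = "impute"
        clean = impute_missing(screened)
        clean.to_csv(out / "analysis_dataset.csv")
        results["dataset"] = clean
        results["screening"] = screen_result
        with open(out / "screening_summary.txt", "w") as fh:
            fh.write(
                f"n_input {screen_result.n_input}\n"
                f"n_victimized {screen_result.n_victimized}\n"
                f"n_excluded_invalid {screen_result.n_excluded_invalid}\n"
                f"n_final {screen_result.n_final}\n"
            )

        # ---------------- path model (canonical data only) ---------------- #
        if _has_canonical_nodes(clean):
            stage = "panel_model"
            scores = construct_scores(clean)
            path_result = fit_path_model(scores)
            path_result.paths.to_csv(out / "path_model.csv", index=False)
            diff = wald_path_difference(path_result, ("cptsd", "anx"), ("anx", "cptsd"))
            fit_labels = evaluate_fit(path_result)
            with open(out / "path_model_summary.txt", "w") as fh:
                fh.write(
                    f"chi2 {path_result.chi2:.6f}\ndf {path_result.df}\n"
                    f"cfi {path_result.cfi:.4f}\ntli {path_result.tli:.4f}\n"
                    f"rmsea {path_result.rmsea:.4f}\nsrmr {path_result.srmr:.6f}\n"
                )
                for k, v in fit_labels.items():
                    fh.write(f"label_{k} {v}\n")
                fh.write(
                    "wald_cptsd_anx_vs_anx_cptsd "
                    f"diff={diff.difference:.4f} z={diff.z:.3f} p={diff.p:.3g}\n"
                )
            results["path_model"] = path_result
            results["path_difference"] = diff
            log(stage, f"df={path_result.df} chi2={path_result.chi2:.3f}")
        else:
            log("panel_model", "skipped (dataset lacks canonical instrument nodes)")

        # ---------------- CLPN ---------------- #
        stage = "clpn"
        settings = estimator_from_config(config)
        network = estimate_network(clean, settings)
        write_edge_csv(network, out / "network_edges.csv", threshold=0.0)
        display = threshold_for_display(network, config.display_threshold)
        display.to_csv(out / "network_edges_display.csv", index=False)
        to_graphml(network, out / "network.graphml", threshold=config.display_threshold)
        results["network"] = network
        results["strongest_edges"] = strongest_edges(network, k=5)
        log(stage, f"{int((network.B != 0).sum())} nonzero edges; "
                   f"{len(display)} above display threshold {config.display_threshold}")

        # ---------------- centrality ---------------- #
        stage = "centrality"
        table = centrality_mod.expected_influence(network, standardized=True)
        table.to_csv(out / "centrality.csv", index=False)
        results["centrality"] = table
        results["rank_report"] = centrality_mod.rank_report(table, k=3)
        log(stage, f"top out_ei: {results['rank_report']['out_ei']}")

        # ---------------- stability ---------------- #
        stage = "stability"
        n_boot = int(config.bootstrap.get("n_boot", 200))
        case_n_boot = int(config.bootstrap.get("case_n_boot", 50))
        proportions = tuple(
            config.bootstrap.get("proportions", stability_mod.DEFAULT_PROPORTIONS)
        )
        edge_boot = stability_mod.bootstrap_edges(
            clean, settings, n_boot=n_boot, seed=derive_seed(config.seed, "edge_boot")
        )
        edge_boot.summary().to_csv(out / "edge_bootstrap.csv", index=False)
        case_results = {}
        for index in ("in_ei", "out_ei"):
            res = stability_mod.case_drop_bootstrap(
                clean,
                settings,
                index=index,
                proportions=proportions,
                n_boot=case_n_boot,
                seed=derive_seed(config.seed, f"case_drop_{index}"),
            )
            res.curve_frame().to_csv(out / f"stability_curve_{index}.csv", index=False)
            case_results[index] = res
        with open(out / "stability_summary.txt", "w") as fh:
            fh.write(stability_mod.stability_summary(case_results) + "\n")
        results["edge_bootstrap"] = edge_boot
        results["case_drop"] = case_results
        results["cs"] = {
            idx: stability_mod.cs_coefficient(res) for idx, res in case_results.items()
        }
        log(stage, f"CS: {results['cs']}")

        # ---------------- manifest + log ---------------- #
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_final": screen_result.n_final,
            "nodes": list(clean.node_labels),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(out / "log.txt", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
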
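"""Scale definitions, screening rules, imputation, scoring and reliability.

The analysis sample is constructed in two steps mirroring common practice in
school-based victimization surveys: keep participants who report having been
victimized *at least once* (any screening item strictly above the scale's
"never" anchor), then drop those who failed the embedded control questions.
Missing item responses are replaced by the item's observed mean across the
screened participants (series-mean imputation); composite scores are simple
item sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .datasets import PanelDataset


@dataclass(frozen=True)
class InstrumentSpec:
    """Declarative description of a questionnaire scale.

    ``node_labels`` are the short per-item labels used as node names in the
    symptom network (e.g. ``dep9`` for the ninth PHQ-9 item); ``subscales``
    map a subscale name to the item identifiers it contains.
    """

    name: str
    items: tuple[str, ...]
    response_min: int
    response_max: int
    node_labels: tuple[str, ...]
    subscales: dict[str, tuple[str, ...]] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise ValueError("response_min must be < response_max")
        if len(self.items) != len(self.node_labels):
            raise ValueError("items and node_labels must have equal length")
        if len(set(self.items)) != len(self.items):
            raise ValueError("item identifiers must be unique")
        seen: set[str] = set()
        for sub, members in self.subscales.items():
            for item in members:
                if item not in self.items:
                    raise ValueError(f"subscale {sub!r} references unknown item {item!r}")
                if item in seen:
                    raise ValueError(f"item {item!r} appears in more than one subscale")
                seen.add(item)

    @property
    def n_items(self) -> int:
        return len(self.items)


def _spec_from_mapping(name: str, entry: dict) -> InstrumentSpec:
    return InstrumentSpec(
        name=name,
        items=tuple(entry["items"]),
        response_min=int(entry["response_min"]),
        response_max=int(entry["response_max"]),
        node_labels=tuple(entry.get("node_labels", entry["items"])),
        subscales={k: tuple(v) for k, v in (entry.get("subscales") or {}).items()},
        description=str(entry.get("description", "")),
    )


def load_instruments(path) -> dict[str, InstrumentSpec]:
    """Load instrument specs from a YAML file of the bundled shape."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: _spec_from_mapping(name, entry) for name, entry in raw.items()}


def _load_builtin() -> dict[str, InstrumentSpec]:
    text = resources.files("clpnet").joinpath("data/instruments.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: _spec_from_mapping(name, entry) for name, entry in raw.items()}


_REGISTRY: dict[str, InstrumentSpec] = _load_builtin()


def get_instrument(name: str) -> InstrumentSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown instrument {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def register_instrument(spec: InstrumentSpec, overwrite: bool = False) -> None:
    if spec.name in _REGISTRY and not overwrite:
        raise ValueError(f"instrument {spec.name!r} already registered")
    _REGISTRY[spec.name] = spec


#: Instruments whose node labels make up the canonical 28-node network.
NETWORK_INSTRUMENTS = ("ITQ", "PHQ-9", "GAD-7")

#: Construct names used at the composite (scale-total) level.
CONSTRUCTS = {"cptsd": "ITQ", "dep": "PHQ-9", "anx": "GAD-7"}


# --------------------------------------------------------------------- #
# screening
# --------------------------------------------------------------------- #

@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the victimization screen and control-question exclusion."""

    n_input: int
    n_victimized: int
    n_excluded_invalid: int
    n_final: int
    kept_ids: tuple

    def __post_init__(self) -> None:
        if self.n_final != self.n_victimized - self.n_excluded_invalid:
            raise ValueError("inconsistent screening counts")
        if self.n_final != len(self.kept_ids):
            raise ValueError("n_final must equal len(kept_ids)")


def screen_participants(dataset: PanelDataset, never_anchor: int = 0) -> ScreeningResult:
    """Apply the victimization screen and control-question exclusion.

    A participant is *victimized* when any screening item response is
    strictly above ``never_anchor`` (the scale's "never" response: 0 for the
    BPBQ victim subscale, 1 for the Delaware scale).  Victimized
    participants who failed the control questions are excluded.  Order of
    retained participants is preserved.
    """
    items = dataset.screen_items
    if not items:
        raise ValueError("dataset has no screening columns (screen_v*)")
    freq = dataset.screening[items].to_numpy(dtype=float)
    victimized = np.nansum(freq > never_anchor, axis=1) > 0
    control_ok = dataset.screening["control_ok"].to_numpy(dtype=bool)
    kept = victimized & control_ok
    return ScreeningResult(
        n_input=dataset.n,
        n_victimized=int(victimized.sum()),
        n_excluded_invalid=int((victimized & ~control_ok).sum()),
        n_final=int(kept.sum()),
        kept_ids=tuple(dataset.ids[kept]),
    )


def apply_screening(
    dataset: PanelDataset, never_anchor: int = 0
) -> tuple[PanelDataset, ScreeningResult]:
    """Screen and return the retained subset together with the counts."""
    result = screen_participants(dataset, never_anchor=never_anchor)
    keep = set(result.kept_ids)
    mask = np.array([i in keep for i in dataset.ids])
    return dataset.subset(mask), result


# --------------------------------------------------------------------- #
# imputation and scoring
# --------------------------------------------------------------------- #

def impute_missing(dataset: PanelDataset) -> PanelDataset:
    """Replace each missing item response by its item's observed mean.

    Means are taken per item column across participants (series-mean
    imputation), separately per wave.  Imputed values are left on the
    continuous scale — responses are treated as numeric downstream, and not
    rounding preserves each item's observed mean exactly.
    """
    out = dataset.copy()
    for wave in (out.wave1, out.wave2):
        for col in wave.columns:
            values = wave[col].to_numpy(dtype=float)
            missing = np.isnan(values)
            if not missing.any():
                continue
            if missing.all():
                raise ValueError(f"item column {col!r} is entirely missing")
            values[missing] = values[~missing].mean()
            wave[col] = values
    return out


def composite_scores(dataset: PanelDataset, instrument) -> pd.DataFrame:
    """Per-participant scale totals (and subscale totals) for both waves.

    ``instrument`` is an :class:`InstrumentSpec` or a registered name.
    Requires imputation to have been applied (no missing responses) and all
    responses inside the instrument's declared range.
    """
    spec = instrument if isinstance(instrument, InstrumentSpec) else get_instrument(instrument)
    missing_nodes = [n for n in spec.node_labels if n not in dataset.wave1.columns]
    if missing_nodes:
        raise KeyError(
            f"instrument {spec.name!r} nodes absent from dataset: {missing_nodes}"
        )
    label_of = dict(zip(spec.items, spec.node_labels))
    out = pd.DataFrame(index=pd.RangeIndex(dataset.n))
    for wave_name, wave in (("t1", dataset.wave1), ("t2", dataset.wave2)):
        block = wave[list(spec.node_labels)].to_numpy(dtype=float)
        if np.isnan(block).any():
            raise ValueError("missing responses present; run impute_missing first")
        if (block < spec.response_min).any() or (block > spec.response_max).any():
            raise ValueError(
                f"responses outside [{spec.response_min}, {spec.response_max}] "
                f"for instrument {spec.name!r} at {wave_name}"
            )
        out[f"{wave_name}_total"] = block.sum(axis=1)
        for sub, members in spec.subscales.items():
            cols = [label_of[m] for m in members]
            out[f"{wave_name}_{sub}"] = wave[cols].to_numpy(dtype=float).sum(axis=1)
    return out


def construct_scores(dataset: PanelDataset) -> pd.DataFrame:
    """Composite totals for the three constructs (CPTSD, depression,
    anxiety) at both waves, plus covariates — the input of the
    construct-level cross-lagged path model."""
    out = pd.DataFrame(index=pd.RangeIndex(dataset.n))
    for construct, instrument in CONSTRUCTS.items():
        totals = composite_scores(dataset, instrument)
        out[f"{construct}_t1"] = totals["t1_total"]
        out[f"{construct}_t2"] = totals["t2_total"]
    out["gender"] = dataset.covariates["gender"].to_numpy(dtype=float)
    out["age"] = dataset.covariates["age"].to_numpy(dtype=float)
    return out


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance).

    Sample variances use denominator n-1.  Requires >= 2 items, >= 2
    participants and a nonzero variance of the total score.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 items")
    if np.isnan(X).any():
        raise ValueError("item matrix contains missing values")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
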
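"""Two-wave panel dataset container and its CSV dialect.

A :class:`PanelDataset` holds item-level responses for two assessment waves
plus covariates (gender, age) and victimization-screening fields for N
participants.  The on-disk form is a single CSV with columns::

    id, gender, age, screen_v1..screen_vK, control_ok, t1_<node>..., t2_<node>...

where ``<node>`` are the symptom node labels (for the canonical 28-node
network: RE1, RE2, AV1, AV2, TH1, TH2, NSC1, NSC2, AD1, AD2, DR1, DR2,
dep1..dep9, anx1..anx7).  Missing item responses are empty cells on disk and
NaN in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

SCREEN_PREFIX = "screen_v"

#: Canonical node ordering of the 28-symptom CPTSD + depression + anxiety
#: network: 12 ITQ nodes (six two-item dimensions), 9 PHQ-9 nodes, 7 GAD-7
#: nodes.
CANONICAL_NODES: tuple[str, ...] = (
    "RE1", "RE2", "AV1", "AV2", "TH1", "TH2",
    "NSC1", "NSC2", "AD1", "AD2", "DR1", "DR2",
    "dep1", "dep2", "dep3", "dep4", "dep5", "dep6", "dep7", "dep8", "dep9",
    "anx1", "anx2", "anx3", "anx4", "anx5", "anx6", "anx7",
)


@dataclass
class PanelDataset:
    """Item-level two-wave panel data for N participants.

    Parameters
    ----------
    ids : array of participant identifiers.
    covariates : DataFrame with columns ``gender`` (0/1) and ``age`` (years).
    screening : DataFrame with victimization frequency items
        (``screen_v1..screen_vK``) and a boolean ``control_ok`` column
        (control questions answered correctly).
    wave1, wave2 : DataFrames of ordinal item responses, one column per
        symptom node; identical column sets across waves.  NaN marks a
        missing response.
    """

    ids: np.ndarray
    covariates: pd.DataFrame
    screening: pd.DataFrame
    wave1: pd.DataFrame
    wave2: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.wave1.columns) != list(self.wave2.columns):
            raise ValueError(
                "node-set mismatch: wave1 and wave2 must carry identical item "
                f"columns (wave1 has {len(self.wave1.columns)}, wave2 has "
                f"{len(self.wave2.columns)})"
            )
        n = len(self.ids)
        for name, frame in (
            ("covariates", self.covariates),
            ("screening", self.screening),
            ("wave1", self.wave1),
            ("wave2", self.wave2),
        ):
            if len(frame) != n:
                raise ValueError(f"{name} has {len(frame)} rows, expected {n}")
        if len(set(self.wave1.columns)) != len(self.wave1.columns):
            raise ValueError("node labels must be unique")
        for col in ("gender", "age"):
            if col not in self.covariates.columns:
                raise ValueError(f"covariates missing required column {col!r}")
        if "control_ok" not in self.screening.columns:
            raise ValueError("screening missing required column 'control_ok'")

    # ------------------------------------------------------------------ #

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def node_labels(self) -> tuple[str, ...]:
        return tuple(self.wave1.columns)

    @property
    def screen_items(self) -> list[str]:
        return [c for c in self.screening.columns if c.startswith(SCREEN_PREFIX)]

    def subset(self, mask_or_indices) -> "PanelDataset":
        """Row-subset the dataset (boolean mask or positional indices)."""
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return PanelDataset(
            ids=self.ids[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            screening=self.screening.iloc[idx].reset_index(drop=True),
            wave1=self.wave1.iloc[idx].reset_index(drop=True),
            wave2=self.wave2.iloc[idx].reset_index(drop=True),
        )

    def subset_ids(self, keep_ids) -> "PanelDataset":
        keep = set(keep_ids)
        mask = np.array([i in keep for i in self.ids])
        return self.subset(mask)

    def copy(self) -> "PanelDataset":
        return replace(
            self,
            ids=self.ids.copy(),
            covariates=self.covariates.copy(),
            screening=self.screening.copy(),
            wave1=self.wave1.copy(),
            wave2=self.wave2.copy(),
        )

    # ------------------------------ I/O ------------------------------- #

    def to_frame(self) -> pd.DataFrame:
        """Assemble the single-table CSV dialect."""
        out = pd.DataFrame({"id": self.ids})
        out["gender"] = self.covariates["gender"].to_numpy()
        out["age"] = self.covariates["age"].to_numpy()
        for c in self.screen_items:
            out[c] = self.screening[c].to_numpy()
        out["control_ok"] = self.screening["control_ok"].astype(int).to_numpy()
        for node in self.node_labels:
            out[f"t1_{node}"] = self.wave1[node].to_numpy()
        for node in self.node_labels:
            out[f"t2_{node}"] = self.wave2[node].to_numpy()
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PanelDataset":
        screen_cols = [c for c in frame.columns if c.startswith(SCREEN_PREFIX)]
        t1 = [c for c in frame.columns if c.startswith("t1_")]
        t2 = [c for c in frame.columns if c.startswith("t2_")]
        nodes1 = [c[3:] for c in t1]
        nodes2 = [c[3:] for c in t2]
        if nodes1 != nodes2:
            raise ValueError("node-set mismatch between t1_* and t2_* columns")
        screening = frame[screen_cols].copy()
        screening["control_ok"] = frame["control_ok"].astype(bool).to_numpy()
        return cls(
            ids=frame["id"].to_numpy(),
            covariates=frame[["gender", "age"]].reset_index(drop=True),
            screening=screening.reset_index(drop=True),
            wave1=frame[t1].rename(columns=dict(zip(t1, nodes1))).reset_index(drop=True),
            wave2=frame[t2].rename(columns=dict(zip(t2, nodes2))).reset_index(drop=True),
        )

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        return cls.from_frame(pd.read_csv(path))
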
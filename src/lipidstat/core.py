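"""Shared containers for the analysis pipeline.

The central object is :class:`AbundanceMatrix`, a features x samples table
that carries an explicit processing *stage* tag.  Stages form a fixed
pipeline order (raw peak area -> concentration -> normalized ->
class_fraction -> logit -> zscore) and out-of-order transitions are
rejected, so a matrix can never silently skip a preprocessing step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Processing stages in their mandatory order.
STAGES = ("raw", "concentration", "normalized", "class_fraction", "logit", "zscore")

GROUPS = ("CTL", "CKD")
TISSUES = ("plasma", "PMphi", "liver")


class ContractError(ValueError):
    """A precondition of an operation was violated."""


class StageError(ContractError):
    """An operation was applied to a matrix in the wrong stage."""


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one biological sample.

    ``protein_mass`` (ug) is required for cell-pellet tissues (PMphi,
    liver); ``volume`` (ul) is required for plasma.  Exactly the
    denominator demanded by the tissue must be present.
    """

    sample_id: str
    group: str
    tissue: str
    protein_mass: Optional[float] = None
    volume: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ContractError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.tissue not in TISSUES:
            raise ContractError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.protein_mass is not None and self.protein_mass <= 0:
            raise ContractError(f"sample {self.sample_id}: protein_mass must be positive")
        if self.volume is not None and self.volume <= 0:
            raise ContractError(f"sample {self.sample_id}: volume must be positive")

    @property
    def denominator(self) -> float:
        """Normalisation denominator demanded by the tissue."""
        if self.tissue == "plasma":
            if self.volume is None:
                raise ContractError(f"sample {self.sample_id}: plasma sample lacks volume")
            return self.volume
        if self.protein_mass is None:
            raise ContractError(
                f"sample {self.sample_id}: {self.tissue} sample lacks protein_mass"
            )
        return self.protein_mass


def samples_to_frame(samples: list[SampleInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "tissue": [s.tissue for s in samples],
            "protein_mass": [s.protein_mass for s in samples],
            "volume": [s.volume for s in samples],
        }
    ).set_index("sample_id")


def samples_from_frame(frame: pd.DataFrame) -> list[SampleInfo]:
    out = []
    for sid, row in frame.iterrows():
        pm = row.get("protein_mass")
        vol = row.get("volume")
        out.append(
            SampleInfo(
                sample_id=str(sid),
                group=str(row["group"]),
                tissue=str(row["tissue"]),
                protein_mass=None if pd.isna(pm) else float(pm),
                volume=None if pd.isna(vol) else float(vol),
            )
        )
    return out


@dataclass
class AbundanceMatrix:
    """Features x samples abundance table with a processing-stage tag.

    ``data`` rows are lipid features (indexed by feature name), columns are
    sample ids; missing measurements are NaN.  ``samples`` is a metadata
    frame indexed by sample id (columns group, tissue, protein_mass,
    volume), aligned with ``data.columns``.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    stage: str = "raw"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if list(self.data.columns) != list(self.samples.index):
            raise ContractError("data columns and sample metadata index do not align")
        self.data = self.data.astype(float)

    # -- stage machinery ---------------------------------------------------
    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, matrix is at {self.stage!r}"
            )

    def advance(self, new_stage: str, data: pd.DataFrame, note: str = "") -> "AbundanceMatrix":
        """Return a copy at ``new_stage``; the transition must move forward."""
        if STAGES.index(new_stage) <= STAGES.index(self.stage) and new_stage != self.stage:
            raise StageError(f"cannot move from {self.stage!r} back to {new_stage!r}")
        log = self.log + ([note] if note else [])
        return AbundanceMatrix(data=data, samples=self.samples.copy(), stage=new_stage, log=log)

    # -- conveniences ------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.index)

    def group_columns(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(
            data=self.data.loc[:, sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
            stage=self.stage,
            log=list(self.log),
        )

    def split_by_tissue(self) -> dict[str, "AbundanceMatrix"]:
        out = {}
        for tissue in self.samples["tissue"].unique():
            cols = list(self.samples.index[self.samples["tissue"] == tissue])
            out[str(tissue)] = self.subset_samples(cols)
        return out

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            data=self.data.copy(),
            samples=self.samples.copy(),
            stage=self.stage,
            log=list(self.log),
        )
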
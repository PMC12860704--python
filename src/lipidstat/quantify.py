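"""Internal-standard quantification and per-sample normalisation.

Each lipid class is quantified against one spiked internal standard (IS):
concentration = (peak area / IS peak area) x IS concentration.  Quantified
lipids are then normalised to total protein content for cell pellets
(macrophages, liver) or to sample volume for plasma.  Which IS serves
which class is a platform detail supplied as a configuration mapping and
validated for completeness at load time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, ContractError, SampleInfo


@dataclass(frozen=True)
class InternalStandard:
    """One class internal standard: per-sample peak areas + spiked concentration."""

    is_id: str
    concentration: float  # spiked amount, units carried opaquely
    peak_areas: pd.Series  # per sample, strictly positive

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ContractError(f"IS {self.is_id}: concentration must be positive")
        if (self.peak_areas <= 0).any() or self.peak_areas.isna().any():
            bad = self.peak_areas.index[(self.peak_areas <= 0) | self.peak_areas.isna()]
            raise ContractError(
                f"IS {self.is_id}: nonpositive/missing peak area for sample(s) "
                f"{list(bad)} — internal standard failure"
            )


def quantify(peak_area: float, is_peak_area: float, is_concentration: float) -> float:
    """Concentration from a single peak-area / internal-standard pair.

    Linear in peak area; zero area gives zero concentration; missing (NaN)
    area propagates as missing.
    """
    if not np.isfinite(is_peak_area) or is_peak_area <= 0:
        raise ContractError("internal-standard peak area must be positive")
    if is_concentration <= 0:
        raise ContractError("internal-standard concentration must be positive")
    if peak_area is None or (isinstance(peak_area, float) and np.isnan(peak_area)):
        return float("nan")
    if peak_area < 0:
        raise ContractError("peak area must be nonnegative")
    return peak_area / is_peak_area * is_concentration


def quantify_matrix(
    peaks: AbundanceMatrix,
    standards: dict[str, InternalStandard],
    class_of_feature: pd.Series | dict[str, str],
) -> AbundanceMatrix:
    """Quantify a raw peak-area matrix feature-by-feature via class standards.

    ``standards`` maps class code -> :class:`InternalStandard`;
    ``class_of_feature`` maps feature name -> class code.  The mapping must
    cover every feature (completeness is validated up front).
    """
    peaks.require_stage("raw")
    cls = pd.Series(class_of_feature)
    missing = [f for f in peaks.feature_names if f not in cls.index]
    if missing:
        raise ContractError(f"no class assignment for feature(s) {missing[:5]}")
    needed = set(cls.loc[peaks.feature_names])
    absent = sorted(needed - set(standards))
    if absent:
        raise ContractError(f"no internal standard configured for class(es) {absent}")

    out = pd.DataFrame(index=peaks.data.index, columns=peaks.data.columns, dtype=float)
    for class_code in needed:
        feats = [f for f in peaks.feature_names if cls[f] == class_code]
        std = standards[class_code]
        areas = std.peak_areas.reindex(peaks.data.columns)
        if areas.isna().any():
            raise ContractError(
                f"IS for class {class_code}: missing peak areas for some samples"
            )
        out.loc[feats] = (
            peaks.data.loc[feats].div(areas, axis=1) * std.concentration
        )
    return peaks.advance("concentration", out, note="quantify: IS ratio x IS concentration")


def normalize_sample(concentrations: np.ndarray | pd.Series, sample: SampleInfo):
    """Divide one sample's concentrations by its protein mass or plasma volume."""
    denom = sample.denominator  # raises ContractError naming the sample if absent
    return concentrations / denom


def normalize_matrix(conc: AbundanceMatrix) -> AbundanceMatrix:
    """Normalise every sample column by its tissue-appropriate denominator."""
    conc.require_stage("concentration")
    denoms = []
    for sid in conc.data.columns:
        row = conc.samples.loc[sid]
        if row["tissue"] == "plasma":
            d = row["volume"]
            if pd.isna(d):
                raise ContractError(f"sample {sid}: plasma sample lacks volume")
        else:
            d = row["protein_mass"]
            if pd.isna(d):
                raise ContractError(f"sample {sid}: {row['tissue']} sample lacks protein_mass")
        if d <= 0:
            raise ContractError(f"sample {sid}: nonpositive normalisation denominator")
        denoms.append(float(d))
    out = conc.data.div(pd.Series(denoms, index=conc.data.columns), axis=1)
    return conc.advance("normalized", out, note="normalize: protein mass / plasma volume")


# -- CSV interfaces --------------------------------------------------------

def read_peak_table(path, samples: pd.DataFrame) -> AbundanceMatrix:
    """Read a features x samples peak-area CSV (first column = feature name)."""
    data = pd.read_csv(path, index_col=0)
    data = data.loc[:, list(samples.index)]
    return AbundanceMatrix(data=data, samples=samples, stage="raw")


def read_internal_standards(path) -> dict[str, InternalStandard]:
    """Read internal standards from a tidy CSV.

    Columns: class, is_id, concentration, sample_id, peak_area (one row per
    class x sample).
    """
    tidy = pd.read_csv(path)
    out: dict[str, InternalStandard] = {}
    for class_code, grp in tidy.groupby("class"):
        conc = grp["concentration"].unique()
        if len(conc) != 1:
            raise ContractError(f"IS for class {class_code}: inconsistent concentration")
        out[str(class_code)] = InternalStandard(
            is_id=str(grp["is_id"].iloc[0]),
            concentration=float(conc[0]),
            peak_areas=pd.Series(
                grp["peak_area"].values, index=grp["sample_id"].astype(str).values
            ),
        )
    return out


def read_sample_info(path) -> pd.DataFrame:
    frame = pd.read_csv(path).set_index("sample_id")
    frame.index = frame.index.astype(str)
    return frame
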
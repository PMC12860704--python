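"""Fatty-acid metabolism metrics.

* Acylcarnitine long/intermediate ratio — summed C16-C20 over summed
  C5-C14 acylcarnitine abundance; a lower ratio proxies impaired
  mitochondrial beta-oxidation.
* Palmitate deuterium enrichment — after heavy-water labelling, newly
  synthesized palmitate carries 2H; total enrichment is the
  isotopomer-weighted sum E1 + 2*E2 + 3*E3 + 4*E4 of the M+1..M+4
  mass-shift fractions, averaged over technical triplicates.  No
  natural-abundance isotope correction is applied (limitation flag in the
  tidy output).
* ddCt fold changes — qPCR relative expression 2^-(dCt_sample -
  mean dCt_reference) with a fixed housekeeping gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import ContractError

AC_INTERMEDIATE = (5, 14)  # carbon window, inclusive
AC_LONG = (16, 20)


@dataclass(frozen=True)
class AcylcarnitineProfile:
    """Per-sample acylcarnitine abundances keyed by (carbons, double bonds)."""

    sample_id: str
    species: tuple[tuple[int, int, float], ...]  # (carbons, double_bonds, abundance)

    def __post_init__(self) -> None:
        keys = [(c, d) for c, d, _ in self.species]
        if len(set(keys)) != len(keys):
            raise ContractError(f"sample {self.sample_id}: duplicate acylcarnitine species")
        if any(a < 0 for _, _, a in self.species):
            raise ContractError(f"sample {self.sample_id}: negative abundance")


def acylcarnitine_ratio(p: AcylcarnitineProfile) -> float:
    """Sum(C16-C20) / Sum(C5-C14); species outside both windows are excluded.

    Unsaturated species count toward their carbon window regardless of
    double-bond number (the windows are defined by chain length only).
    """
    long_sum = sum(a for c, _, a in p.species if AC_LONG[0] <= c <= AC_LONG[1])
    inter_sum = sum(a for c, _, a in p.species if AC_INTERMEDIATE[0] <= c <= AC_INTERMEDIATE[1])
    if inter_sum <= 0:
        raise ContractError(
            f"sample {p.sample_id}: zero intermediate-chain sum, ratio undefined"
        )
    return long_sum / inter_sum


def read_acylcarnitine_table(path) -> list[AcylcarnitineProfile]:
    """Tidy CSV with columns sample_id, carbons, double_bonds, abundance."""
    tidy = pd.read_csv(path)
    out = []
    for sid, grp in tidy.groupby("sample_id", sort=False):
        out.append(
            AcylcarnitineProfile(
                sample_id=str(sid),
                species=tuple(
                    (int(r.carbons), int(r.double_bonds), float(r.abundance))
                    for r in grp.itertuples()
                ),
            )
        )
    return out


# -- de novo lipogenesis ---------------------------------------------------

@dataclass(frozen=True)
class IsotopomerDistribution:
    """Fractional palmitate mass-isotopomer abundances M+0..M+4."""

    sample_id: str
    tissue: str
    fractions: tuple[float, float, float, float, float]  # E0..E4
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ContractError(f"sample {self.sample_id}: negative isotopomer fraction")
        if abs(sum(self.fractions) - 1.0) > 1e-6:
            raise ContractError(
                f"sample {self.sample_id}: isotopomer fractions sum to "
                f"{sum(self.fractions):.8f}, expected 1"
            )


def palmitate_enrichment(d: IsotopomerDistribution) -> float:
    """Total 2H enrichment = E1 + 2*E2 + 3*E3 + 4*E4."""
    _, e1, e2, e3, e4 = d.fractions
    return e1 + 2 * e2 + 3 * e3 + 4 * e4


def dnl_rate(replicates: list[IsotopomerDistribution]) -> float:
    """Mean enrichment over a sample's technical replicates (triplicate expected)."""
    if not replicates:
        raise ContractError("no replicates supplied")
    ids = {(r.sample_id, r.tissue) for r in replicates}
    if len(ids) != 1:
        raise ContractError(f"mixed sample/tissue ids in replicate set: {sorted(ids)}")
    if len(replicates) == 1:
        warnings.warn(
            f"sample {replicates[0].sample_id}: single replicate (triplicate expected)",
            stacklevel=2,
        )
    return float(np.mean([palmitate_enrichment(r) for r in replicates]))


def read_isotopomer_table(path) -> list[IsotopomerDistribution]:
    """CSV with columns sample_id, tissue, replicate_id, E0..E4."""
    tidy = pd.read_csv(path)
    return [
        IsotopomerDistribution(
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
            replicate_id=int(r.replicate_id),
            fractions=(float(r.E0), float(r.E1), float(r.E2), float(r.E3), float(r.E4)),
        )
        for r in tidy.itertuples()
    ]


def dnl_table(distributions: list[IsotopomerDistribution]) -> pd.DataFrame:
    """Per (sample, tissue) mean enrichment across replicates, tidy frame."""
    rows = {}
    for d in distributions:
        rows.setdefault((d.sample_id, d.tissue), []).append(d)
    out = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "tissue": tissue,
                "n_replicates": len(reps),
                "enrichment": dnl_rate(reps),
                "isotope_correction": "none",  # natural-abundance correction not applied
            }
            for (sid, tissue), reps in rows.items()
        ]
    )
    return out


# -- qPCR ddCt -------------------------------------------------------------

@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and housekeeping Ct for one sample."""

    sample_id: str
    group: str
    target_gene: str
    ct_target: float
    ct_housekeeping: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct_target) and np.isfinite(self.ct_housekeeping)):
            raise ContractError(f"sample {self.sample_id}: non-finite Ct value")


def ddct_fold_change(records: list[CtRecord], reference_group: str) -> pd.DataFrame:
    """Per-sample expression fold changes by the ddCt method.

    dCt = Ct_target - Ct_housekeeping; ddCt = dCt - mean(dCt | reference
    group); fold = 2^-ddCt.  By construction the reference group's
    geometric-mean fold change is 1 per gene.  Returns a tidy frame
    (sample_id, group, target_gene, dct, ddct, fold_change).
    """
    if not records:
        raise ContractError("no Ct records supplied")
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "target_gene": [r.target_gene for r in records],
            "dct": [r.ct_target - r.ct_housekeeping for r in records],
        }
    )
    out = []
    for gene, grp in frame.groupby("target_gene", sort=False):
        ref = grp.loc[grp["group"] == reference_group, "dct"]
        if ref.empty:
            raise ContractError(
                f"gene {gene}: reference group {reference_group!r} has no records"
            )
        g = grp.copy()
        g["ddct"] = g["dct"] - ref.mean()
        g["fold_change"] = 2.0 ** (-g["ddct"])
        out.append(g)
    return pd.concat(out, ignore_index=True)


def read_ct_table(path) -> list[CtRecord]:
    """CSV with columns sample_id, group, target_gene, ct_target, ct_housekeeping."""
    tidy = pd.read_csv(path)
    return [
        CtRecord(
            sample_id=str(r.sample_id),
            group=str(r.group),
            target_gene=str(r.target_gene),
            ct_target=float(r.ct_target),
            ct_housekeeping=float(r.ct_housekeeping),
        )
        for r in tidy.itertuples()
    ]
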
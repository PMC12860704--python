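"""Group-effect models for processed lipid abundances.

Feature-level two-sample tests, class/subclass-level linear mixed models
(fixed group effect, random intercept per lipid species), pooled-variance
t-tests from printed summary statistics, Benjamini-Hochberg adjustment,
and cross-tissue significance accounting.

The class-level model treats each feature x sample z-score as one
observation: y_ij = beta0 + beta1 * group_j + u_i + e_ij with u_i a random
intercept for lipid species i.  This respects the within-class correlation
of features while estimating one group effect per class or stratum, which
is the natural dimensionality reduction when features far outnumber
samples.  Single-feature strata degenerate to a plain two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .core import AbundanceMatrix, ContractError


def benjamini_hochberg(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ContractError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GroupSummaryStats:
    """Printed-table summary: n, mean, SD per group."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ContractError("each group needs n >= 2")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ContractError("group SDs must be positive")


def summary_stat_ttest(
    s: GroupSummaryStats, variance: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns (t, df, p).

    ``pooled`` uses the classical pooled-variance statistic with
    df = n1 + n2 - 2; ``welch`` uses Satterthwaite df.
    """
    if variance not in ("pooled", "welch"):
        raise ContractError("variance must be 'pooled' or 'welch'")
    t, p = stats.ttest_ind_from_stats(
        s.mean1, s.sd1, s.n1, s.mean2, s.sd2, s.n2, equal_var=(variance == "pooled")
    )
    if variance == "pooled":
        df = float(s.n1 + s.n2 - 2)
    else:
        v1, v2 = s.sd1**2 / s.n1, s.sd2**2 / s.n2
        df = (v1 + v2) ** 2 / (v1**2 / (s.n1 - 1) + v2**2 / (s.n2 - 1))
    return float(t), df, float(p)


def feature_ttests(
    m: AbundanceMatrix, alpha: float = 0.01, variance: str = "pooled"
) -> pd.DataFrame:
    """Per-feature two-sample group comparison on a z-scored matrix.

    Returns a frame indexed by feature with columns effect (CKD - CTL),
    t, p_raw, p_adjusted (BH), significant (p_raw < alpha, the feature
    counting rule; the stricter BH column is reported alongside).
    """
    m.require_stage("zscore")
    ctl = m.group_columns("CTL")
    ckd = m.group_columns("CKD")
    if len(ctl) < 2 or len(ckd) < 2:
        raise ContractError("each group needs n >= 2 samples")
    a = m.data[ckd].to_numpy()
    b = m.data[ctl].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=(variance == "pooled"))
    effect = a.mean(axis=1) - b.mean(axis=1)
    out = pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p_raw": p,
            "p_adjusted": benjamini_hochberg(np.clip(p, np.nextafter(0, 1), 1.0)),
        },
        index=m.data.index,
    )
    out["significant"] = out["p_raw"] < alpha
    return out


@dataclass(frozen=True)
class ClassEffectResult:
    """Group effect for one lipid class or class stratum."""

    class_code: str
    subclass: Optional[str]
    effect: float  # CKD - CTL on the z-score scale
    se: float
    p_raw: float
    p_adjusted: float
    n_features: int
    model: str  # mixed | fixed

    @property
    def label(self) -> str:
        return f"{self.subclass} {self.class_code}" if self.subclass else self.class_code


def _strata(annotation: pd.DataFrame, stratify_by: str) -> pd.Series:
    """Stratum label per feature: class optionally split by saturation bin.

    Saturation split uses the two-level saturated/unsaturated convention
    (unsaturated = at least one double bond).
    """
    cls = annotation["class"]
    if stratify_by == "none":
        return cls.astype(str) + "||"
    sat = np.where(annotation["double_bonds"] == 0, "saturated", "unsaturated")
    if stratify_by == "saturation":
        return cls.astype(str) + "||" + pd.Series(sat, index=annotation.index)
    raise ContractError(f"unsupported stratification {stratify_by!r}")


def class_level_model(
    m: AbundanceMatrix,
    annotation: pd.DataFrame,
    stratify_by: str = "saturation",
    model: str = "mixed",
) -> list[ClassEffectResult]:
    """Fit the group-effect model per lipid class / stratum.

    ``model='mixed'``: random intercept per lipid species (the default —
    the per-class observations are correlated across features within a
    sample and within a feature).  ``model='fixed'``: ordinary two-sample
    t-test on the pooled observations.  Strata of a single feature always
    fall back to the plain t-test.  BH adjustment is applied across all
    strata tested.
    """
    m.require_stage("zscore")
    annotation = annotation.reindex(m.feature_names)
    strata = _strata(annotation, stratify_by)
    group = (m.samples["group"] == "CKD").astype(float)

    partial: list[dict] = []
    for label, feats in m.data.groupby(strata, sort=False).groups.items():
        class_code, subclass = str(label).split("||")
        sub = m.data.loc[feats]
        if set(m.samples["group"]) != {"CTL", "CKD"}:
            raise ContractError("both groups must be present")
        long = sub.stack().rename("y").reset_index()
        long.columns = ["feature", "sample_id", "y"]
        long["g"] = group.reindex(long["sample_id"]).to_numpy()

        if len(feats) == 1 or model == "fixed":
            y1 = long.loc[long["g"] == 1, "y"].to_numpy()
            y0 = long.loc[long["g"] == 0, "y"].to_numpy()
            t, p = stats.ttest_ind(y1, y0, equal_var=True)
            eff = float(y1.mean() - y0.mean())
            n1, n0 = len(y1), len(y0)
            sp = np.sqrt(
                ((n1 - 1) * y1.var(ddof=1) + (n0 - 1) * y0.var(ddof=1)) / (n1 + n0 - 2)
            )
            se = float(sp * np.sqrt(1 / n1 + 1 / n0))
            used = "fixed"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = MixedLM(
                    long["y"].to_numpy(),
                    np.column_stack([np.ones(len(long)), long["g"].to_numpy()]),
                    groups=long["feature"].to_numpy(),
                )
                try:
                    fit = mod.fit(reml=True, method="lbfgs")
                    eff = float(fit.params[1])
                    se = float(fit.bse[1])
                    p = float(fit.pvalues[1])
                    used = "mixed"
                except (np.linalg.LinAlgError, ValueError):
                    # Zero random-intercept variance (z-scored features all
                    # have mean 0, so species intercepts are degenerate):
                    # the mixed model collapses to the fixed-effects fit.
                    y1 = long.loc[long["g"] == 1, "y"].to_numpy()
                    y0 = long.loc[long["g"] == 0, "y"].to_numpy()
                    t, p = stats.ttest_ind(y1, y0, equal_var=True)
                    eff = float(y1.mean() - y0.mean())
                    n1, n0 = len(y1), len(y0)
                    sp = np.sqrt(
                        ((n1 - 1) * y1.var(ddof=1) + (n0 - 1) * y0.var(ddof=1))
                        / (n1 + n0 - 2)
                    )
                    se = float(sp * np.sqrt(1 / n1 + 1 / n0))
                    used = "fixed"
        if not np.isfinite(p) or p <= 0:
            p = np.nextafter(0, 1) if p <= 0 else 1.0
        partial.append(
            dict(
                class_code=class_code,
                subclass=subclass or None,
                effect=eff,
                se=se,
                p_raw=min(float(p), 1.0),
                n_features=len(feats),
                model=used,
            )
        )

    q = benjamini_hochberg([r["p_raw"] for r in partial])
    return [
        ClassEffectResult(p_adjusted=float(qi), **r) for r, qi in zip(partial, q)
    ]


def class_results_frame(results: list[ClassEffectResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": r.class_code,
                "subclass": r.subclass,
                "effect": r.effect,
                "se": r.se,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "n_features": r.n_features,
                "model": r.model,
            }
            for r in results
        ]
    )


def summarize_significance(
    results_plasma: pd.DataFrame, results_pm: pd.DataFrame, alpha: float = 0.01
) -> dict:
    """Cross-tissue accounting of detected and significant features.

    Percent significant = 100 * n_significant / n_detected, rounded to one
    decimal (the convention of printed summaries).  Shared counts use the
    feature-name intersection of the two tissues.
    """
    out: dict = {}
    shared = results_plasma.index.intersection(results_pm.index)
    for name, res in (("plasma", results_plasma), ("PMphi", results_pm)):
        sig = res["p_raw"] < alpha
        out[f"n_detected_{name}"] = int(len(res))
        out[f"n_significant_{name}"] = int(sig.sum())
        out[f"percent_significant_{name}"] = (
            round(100.0 * sig.sum() / len(res), 1) if len(res) else 0.0
        )
    out["n_shared_features"] = int(len(shared))
    out["n_shared_significant"] = int(
        (
            (results_plasma.loc[shared, "p_raw"] < alpha)
            & (results_pm.loc[shared, "p_raw"] < alpha)
        ).sum()
    )
    return out


def percent_significant(n_significant: int, n_detected: int) -> float:
    """100 * n_significant / n_detected, one-decimal rounding."""
    if n_detected <= 0:
        return 0.0
    return round(100.0 * n_significant / n_detected, 1)
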
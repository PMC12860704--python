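"""Preprocessing chain for quantified lipid abundances.

Order of operations: missingness filter -> K-nearest-neighbour imputation
-> TAG isotopomer collapse -> class-wise sum normalisation (class
fractions) -> logit transform -> per-feature z-scoring.  The chain is
deterministic: no step draws random numbers.

KNN imputation operates in feature space: a missing cell is replaced by
the mean of that sample's values on the k features nearest to the target
feature, where nearness is Euclidean distance between per-feature
standardized profiles over pairwise-complete samples.  This is the
convention of metabolomics preprocessing suites (impute features from
co-regulated features, not samples from samples).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import collapse_tag_isotopomers, parse_lipid_name
from .core import AbundanceMatrix, ContractError


def filter_by_missingness(
    m: AbundanceMatrix, max_missing_fraction: float = 0.5
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Drop features whose within-tissue missing fraction is >= the threshold.

    "Retained below 50% missing" is read strictly: a feature missing in
    exactly half the samples is dropped.  Missingness is computed within
    tissue, since different tissues detect different panels; a feature is
    dropped if it exceeds the threshold in any tissue present.

    Returns the filtered matrix and a report frame of dropped features.
    """
    m.require_stage("concentration", "normalized")
    if not (0 < max_missing_fraction <= 1):
        raise ContractError("max_missing_fraction must be in (0, 1]")
    frac = pd.DataFrame(index=m.data.index)
    for tissue in m.samples["tissue"].unique():
        cols = m.samples.index[m.samples["tissue"] == tissue]
        frac[tissue] = m.data[cols].isna().mean(axis=1)
    worst = frac.max(axis=1)
    drop = worst >= max_missing_fraction
    report = pd.DataFrame(
        {"missing_fraction": worst[drop]}, index=m.data.index[drop]
    )
    kept = AbundanceMatrix(
        data=m.data.loc[~drop].copy(),
        samples=m.samples.copy(),
        stage=m.stage,
        log=m.log + [f"filter_by_missingness: dropped {int(drop.sum())} of {m.n_features}"],
    )
    return kept, report


def _standardized_profiles(data: np.ndarray) -> np.ndarray:
    """Per-feature standardization over observed cells (for distances only)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(data, axis=1, keepdims=True)
        sd = np.nanstd(data, axis=1, ddof=1, keepdims=True)
    sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
    return (data - mu) / sd


def _feature_distances(z: np.ndarray) -> np.ndarray:
    """Pairwise-complete Euclidean distances between feature profiles.

    Distance = sqrt(mean of squared differences over co-observed samples),
    so features with different missingness patterns are comparable.  Pairs
    with no co-observed sample get +inf.
    """
    obs = ~np.isnan(z)
    zf = np.where(obs, z, 0.0)
    counts = obs.astype(float) @ obs.T.astype(float)
    sq = (zf**2 @ obs.T.astype(float)) + (obs.astype(float) @ (zf**2).T) - 2 * zf @ zf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(sq, 0.0) / counts)
    d[counts == 0] = np.inf
    return d


def knn_impute(m: AbundanceMatrix, k: int = 10) -> AbundanceMatrix:
    """Feature-space K-nearest-neighbour imputation.

    Each missing cell becomes the mean of the k nearest features'
    standardized values in that sample, back-transformed to the target
    feature's own location and scale.  Donor averaging happens on the
    standardized scale because neighbours are found by profile shape, not
    magnitude — features spanning orders of magnitude would otherwise
    inject wildly off-scale values.  A feature with no co-observed partner
    falls back to its own median (logged).  Observed cells are never
    altered.
    """
    m.require_stage("concentration", "normalized")
    if k < 1:
        raise ContractError("k must be >= 1")
    if k >= m.n_features:
        raise ContractError(f"k={k} must be < number of features ({m.n_features})")
    worst = m.data.isna().mean(axis=1).max()
    if worst >= 0.5:
        raise ContractError(
            "features with >= 50% missing present; run filter_by_missingness first"
        )

    values = m.data.to_numpy(dtype=float)
    if not np.isnan(values).any():
        return AbundanceMatrix(
            data=m.data.copy(), samples=m.samples.copy(), stage=m.stage,
            log=m.log + ["knn_impute: no missing cells"],
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
    sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
    z = (values - mu[:, None]) / sd[:, None]
    dist = _feature_distances(z)
    np.fill_diagonal(dist, np.inf)
    out = values.copy()
    log_notes: list[str] = []
    n_fallback = 0
    for i, j in zip(*np.nonzero(np.isnan(values))):
        # donors: features observed in sample j, ranked by profile distance
        candidates = np.nonzero(~np.isnan(values[:, j]) & np.isfinite(dist[i]))[0]
        if candidates.size == 0:
            med = np.nanmedian(values[i])
            out[i, j] = med
            n_fallback += 1
            continue
        ranked = candidates[np.argsort(dist[i, candidates], kind="stable")]
        donors = ranked[:k]
        out[i, j] = mu[i] + sd[i] * z[donors, j].mean()
    if n_fallback:
        log_notes.append(f"knn_impute: {n_fallback} cell(s) fell back to feature median")
        warnings.warn(log_notes[-1], stacklevel=2)
    return AbundanceMatrix(
        data=pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        samples=m.samples.copy(),
        stage=m.stage,
        log=m.log + [f"knn_impute: k={k}"] + log_notes,
    )


def class_sum_normalize(
    m: AbundanceMatrix, annotation: pd.DataFrame
) -> AbundanceMatrix:
    """Convert abundances to within-sample class fractions.

    Every value is divided by the summed abundance of its lipid class in
    the same sample, so each class's fractions sum to one per sample.
    """
    m.require_stage("normalized")
    if m.data.isna().any().any():
        raise ContractError("class_sum_normalize requires a complete matrix (impute first)")
    cls = annotation["class"].reindex(m.data.index)
    if cls.isna().any():
        missing = list(m.data.index[cls.isna()])[:5]
        raise ContractError(f"no annotation for feature(s) {missing}")
    out = m.data.copy()
    for class_code, idx in m.data.groupby(cls, sort=False).groups.items():
        block = m.data.loc[idx]
        sums = block.sum(axis=0)
        bad = sums.index[sums <= 0]
        if len(bad):
            raise ContractError(
                f"class {class_code}: nonpositive class sum in sample(s) {list(bad)}"
            )
        out.loc[idx] = block.div(sums, axis=1)
    return m.advance("class_fraction", out, note="class_sum_normalize")


@dataclass(frozen=True)
class EpsPolicy:
    """Clamp policy for the logit transform.

    Epsilon is half the smallest nonzero class fraction observed in the
    matrix, floored at ``floor`` — data-adaptive, keeps singleton-class
    fractions (exactly 1) finite and preserves monotonicity.
    """

    floor: float = 1e-6
    fixed: float | None = None  # override: use this epsilon verbatim

    def epsilon(self, data: pd.DataFrame) -> float:
        if self.fixed is not None:
            return self.fixed
        vals = data.to_numpy()
        nz = vals[(vals > 0) & np.isfinite(vals)]
        if nz.size == 0:
            return self.floor
        return max(float(nz.min()) / 2.0, self.floor)


def logit_transform(m: AbundanceMatrix, eps_policy: EpsPolicy | None = None) -> AbundanceMatrix:
    """Elementwise ln(p / (1-p)) after clamping p into [eps, 1-eps]."""
    m.require_stage("class_fraction")
    policy = eps_policy or EpsPolicy()
    eps = policy.epsilon(m.data)
    p = m.data.clip(lower=eps, upper=1 - eps)
    out = np.log(p / (1 - p))
    return m.advance("logit", out, note=f"logit_transform: eps={eps:.3g}")


def zscore(m: AbundanceMatrix) -> AbundanceMatrix:
    """Standardize each feature across samples to mean 0, SD 1 (n-1 SD).

    Features constant across samples (zero SD, e.g. a singleton class
    clamped at both ends) are dropped with a warning.
    """
    m.require_stage("logit", "class_fraction")
    mu = m.data.mean(axis=1)
    sd = m.data.std(axis=1, ddof=1)
    constant = (sd == 0) | sd.isna()
    if constant.any():
        warnings.warn(
            f"zscore: dropping {int(constant.sum())} constant feature(s)", stacklevel=2
        )
    kept = m.data.loc[~constant]
    out = kept.sub(mu[~constant], axis=0).div(sd[~constant], axis=0)
    note = f"zscore: {int(constant.sum())} constant feature(s) dropped"
    result = AbundanceMatrix(
        data=out, samples=m.samples.copy(), stage=m.stage, log=list(m.log)
    )
    return result.advance("zscore", out, note=note)


@dataclass
class PreprocessConfig:
    max_missing_fraction: float = 0.5
    knn_k: int = 10
    eps_floor: float = 1e-6
    eps_fixed: float | None = None
    collapse_tags: bool = True


def run_preprocessing(
    m: AbundanceMatrix,
    config: PreprocessConfig | None = None,
    annotation: pd.DataFrame | None = None,
) -> AbundanceMatrix:
    """Full chain: filter -> impute -> TAG collapse -> class fractions -> logit -> z.

    If ``annotation`` is None, feature names are parsed on the fly.
    Per-stage feature counts accumulate in the matrix log.
    """
    cfg = config or PreprocessConfig()
    m.require_stage("normalized")
    m, _report = filter_by_missingness(m, cfg.max_missing_fraction)
    if m.data.isna().any().any():
        m = knn_impute(m, k=min(cfg.knn_k, max(1, m.n_features - 1)))
    if cfg.collapse_tags:
        species = [parse_lipid_name(name) for name in m.feature_names]
        _, m, _mapping = collapse_tag_isotopomers(species, m)
    if annotation is None:
        from .annotation import annotate_panel

        annotation = annotate_panel(m.feature_names)
    else:
        annotation = annotation.reindex(m.feature_names)
        if annotation["class"].isna().any():
            from .annotation import annotate_panel

            annotation = annotate_panel(m.feature_names)
    m = class_sum_normalize(m, annotation)
    m = logit_transform(m, EpsPolicy(floor=cfg.eps_floor, fixed=cfg.eps_fixed))
    m = zscore(m)
    return m
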
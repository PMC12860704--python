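"""Synthetic two-group lipidomics studies with known ground truth.

The generator emulates the design the analysis assumes: two groups (sham
control CTL vs CKD) of ~12 mice, a targeted panel of ~900 lipid features
across 21 classes (445 TAG isotopomer features collapsing to 95 species),
log-normal abundances spanning ~3 orders of magnitude with class-level
baselines, programmed class/stratum group shifts on the standardized
scale, latent-factor correlation blocks (optionally restricted to one
group, to create differential network structure), abundance-dependent
missingness mimicking limit-of-detection censoring, acylcarnitine
profiles with a programmed long/intermediate ratio shift, palmitate
isotopomer distributions at a programmed deuterium enrichment, and qPCR
Ct tables encoding programmed fold changes (Acsl1 5-fold up in CKD).

Peak areas are back-computed through the internal-standard relation, so
quantification inverts the generator exactly; with zero noise and zero
missingness the programmed concentrations are recovered to machine
precision.  Identical configs (including seed) produce byte-identical
output bundles.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import parse_lipid_name
from .core import AbundanceMatrix, ContractError
from .quantify import InternalStandard

# (cmin, cmax, step) carbon ranges used to spell out feature names per class
_CLASS_CARBONS = {
    "CE": (14, 20, 1), "MAG": (18, 18, 1), "DAG": (30, 40, 2), "FFA": (14, 21, 1),
    "PC": (30, 44, 2), "PE": (34, 44, 2), "PE-O": (34, 40, 2), "PE-P": (34, 42, 2),
    "PI": (32, 40, 2), "PG": (32, 40, 2), "LPC": (16, 21, 1), "PS": (34, 40, 2),
    "LPS": (18, 18, 1), "LPE": (16, 20, 1), "SM": (32, 42, 2), "HCER": (34, 42, 2),
    "LCER": (34, 40, 2), "DCER": (34, 40, 2), "CER": (34, 42, 2),
}

#: Panel sizes of the targeted platform (per class; TAG counted as
#: isotopomer features that collapse to 95 composition-level species).
DEFAULT_PANEL = {
    "CE": 19, "MAG": 1, "DAG": 39, "TAG": 445, "FFA": 16, "PC": 65, "PE": 47,
    "PE-O": 19, "PE-P": 41, "PI": 22, "PG": 24, "LPC": 11, "PS": 26, "LPS": 1,
    "LPE": 10, "SM": 27, "HCER": 9, "LCER": 6, "DCER": 6, "CER": 10, "AC": 29,
}

#: Default programmed stratum shifts (standardized units, CKD - CTL),
#: mirroring the direction of the reported class-level changes: saturated
#: FFA / PG / PE / saturated ether-PE up and unsaturated FFA / TAG / DAG /
#: PC / SM down in macrophages; PG / PE / PC up in plasma.
DEFAULT_EFFECTS = {
    "PMphi": {
        "saturated FFA": 0.8, "PG": 0.8, "PE": 0.8,
        "saturated PE-O": 0.8, "saturated PE-P": 0.8,
        "unsaturated FFA": -0.8, "TAG": -0.8, "DAG": -0.8, "PC": -0.8, "SM": -0.8,
    },
    "plasma": {"PG": 0.8, "PE": 0.8, "PC": 0.8},
}

_SN_TAGS = ["FA14:0", "FA16:0", "FA16:1", "FA18:0", "FA18:1", "FA18:2", "FA20:4"]


@dataclass(frozen=True)
class CorrelationBlock:
    """Latent-factor block inducing programmed correlations.

    ``members`` maps a stratum label (e.g. "unsaturated FFA", "TAG") to a
    signed loading; all features of the stratum load on one latent factor
    per sample.  ``groups`` restricts the block to one group to create
    group-specific network structure.
    """

    members: dict[str, float]
    tissue: str = "PMphi"
    groups: tuple[str, ...] = ("CTL", "CKD")


#: One default block: unsaturated FFA co-vary with unsaturated TAG and DAG
#: in CKD macrophages only (differential glycerolipid coupling between
#: groups).  Blocks load saturation-resolved strata, not whole classes:
#: class-sum normalisation cancels any factor common to every member of a
#: class, so a whole-class loading would be invisible downstream.
DEFAULT_BLOCKS = (
    CorrelationBlock(
        members={"unsaturated FFA": 0.9, "unsaturated TAG": 0.9,
                 "unsaturated DAG": 0.9},
        tissue="PMphi",
        groups=("CKD",),
    ),
)

DEFAULT_CT_FOLDS = {
    "Acsl1": 5.0, "Acsl3": 1.0, "Acsl4": 1.0, "Acsl5": 1.0, "Acsl6": 1.0,
    "Il1b": 3.0, "Il6": 2.0, "Tnfa": 2.0,
}


@dataclass
class StudyConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_per_group: int = 12
    tissues: tuple[str, ...] = ("PMphi", "plasma")
    panel: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PANEL))
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_EFFECTS.items()}
    )
    correlation_blocks: tuple[CorrelationBlock, ...] = DEFAULT_BLOCKS
    missing_rate: float = 0.10
    missing_mechanism: str = "abundance_dependent"  # or MCAR
    noise_sd: float = 0.5  # per-feature log-scale SD
    ac_ratio_shift: float = 0.75  # multiplicative on long-chain AC in CKD
    dnl_enrichment: dict[str, float] = field(
        default_factory=lambda: {"PMphi": 0.25, "plasma": 0.25, "liver": 0.25}
    )
    dnl_n_per_group: int = 5
    dnl_concentration: float = 2000.0  # Dirichlet concentration (replicate noise)
    ct_folds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CT_FOLDS))
    ct_n_per_group: int = 6
    ct_noise_sd: float = 0.1
    is_concentration: float = 10.0
    plasma_volume: float = 50.0  # ul

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.panel.values()):
            raise ContractError("panel feature counts must be positive")
        if self.missing_mechanism not in ("MCAR", "abundance_dependent"):
            raise ContractError(f"unknown missing mechanism {self.missing_mechanism!r}")


# -- panel construction ----------------------------------------------------

def _cc_db_pairs(cmin: int, cmax: int, step: int, n: int) -> list[tuple[int, int]]:
    carbons = list(range(cmin, cmax + 1, step))
    # at least two double-bond levels so saturated and unsaturated members
    # both exist whenever the class has more than one feature
    dmax = max(2, math.ceil(n / len(carbons)))
    pairs = [(c, d) for c in carbons for d in range(dmax)]
    return sorted(pairs)[:n]


def _tag_features(n_isotopomers: int) -> list[str]:
    """445 isotopomer names over 95 (carbons, double-bond) compositions."""
    combos = [(c, d) for c in range(40, 59, 2) for d in range(10)][:95]
    n_groups = min(95, n_isotopomers)
    base, extra = divmod(n_isotopomers, n_groups)
    names = []
    for gi, (c, d) in enumerate(combos[:n_groups]):
        k = base + (1 if gi < extra else 0)
        tags = _SN_TAGS * math.ceil(k / len(_SN_TAGS))
        for t in tags[:k]:
            names.append(f"TAG{c}:{d}-{t}")
    # duplicate (composition, sn-tag) pairs cannot occur for k <= 7 tags
    if len(set(names)) != len(names):
        raise ContractError("TAG isotopomer construction produced duplicate names")
    return names


def panel_features(panel: dict[str, int]) -> list[str]:
    """Deterministic feature-name list for a class -> count panel map."""
    names: list[str] = []
    for cls, n in panel.items():
        if cls == "TAG":
            names.extend(_tag_features(n))
        elif cls == "AC":
            pairs = [(c, 0) for c in range(2, 21)] + [(c, 1) for c in range(12, 22)]
            for c, d in pairs[:n]:
                names.append(f"AC({c}:{d})")
        elif cls in ("PE-O", "PE-P"):
            ether = cls[-1]
            for c, d in _cc_db_pairs(*_CLASS_CARBONS[cls], n):
                names.append(f"PE({ether}-{c}:{d})")
        else:
            for c, d in _cc_db_pairs(*_CLASS_CARBONS[cls], n):
                names.append(f"{cls}({c}:{d})")
    if len(set(names)) != len(names):
        raise ContractError("panel construction produced duplicate feature names")
    return names


def _stratum_members(names: list[str], stratum: str) -> list[str]:
    """Features matched by a stratum label '[saturation ]CLASS'."""
    parts = stratum.split()
    if len(parts) == 2:
        qualifier, cls = parts
    elif len(parts) == 1:
        qualifier, cls = None, parts[0]
    else:
        raise ContractError(f"malformed stratum label {stratum!r}")
    out = []
    for name in names:
        sp = parse_lipid_name(name)
        if sp.class_code != cls:
            continue
        db = sp.total_double_bonds
        if qualifier == "saturated" and db != 0:
            continue
        if qualifier == "unsaturated" and db < 1:
            continue
        if qualifier == "monounsaturated" and db != 1:
            continue
        if qualifier == "polyunsaturated" and db < 2:
            continue
        out.append(name)
    return out


# -- study bundle ----------------------------------------------------------

@dataclass
class TissueData:
    peaks: AbundanceMatrix  # raw peak areas, NaN = missing
    standards: dict[str, InternalStandard]
    true_normalized: pd.DataFrame  # programmed per-denominator concentrations


@dataclass
class StudyBundle:
    config: StudyConfig
    tissues: dict[str, TissueData]
    samples: pd.DataFrame  # all tissue-samples
    ac_profiles: pd.DataFrame  # tidy: sample_id, group, carbons, double_bonds, abundance
    isotopomers: pd.DataFrame  # tidy: sample_id, tissue, group, replicate_id, E0..E4
    ct_table: pd.DataFrame  # tidy: sample_id, group, target_gene, ct_target, ct_housekeeping
    truth: dict

    def write(self, outdir) -> None:
        """Write the full CSV bundle plus a manifest JSON of programmed truths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.12g"
        self.samples.to_csv(outdir / "samples.csv", float_format=fmt)
        for tissue, td in self.tissues.items():
            td.peaks.data.to_csv(outdir / f"peaks_{tissue}.csv", float_format=fmt)
            rows = []
            for cls, std in td.standards.items():
                for sid, area in std.peak_areas.items():
                    rows.append(
                        {
                            "class": cls,
                            "is_id": std.is_id,
                            "concentration": std.concentration,
                            "sample_id": sid,
                            "peak_area": area,
                        }
                    )
            pd.DataFrame(rows).to_csv(
                outdir / f"internal_standards_{tissue}.csv", index=False, float_format=fmt
            )
        self.ac_profiles.to_csv(outdir / "ac_profiles.csv", index=False, float_format=fmt)
        self.isotopomers.to_csv(outdir / "isotopomers.csv", index=False, float_format=fmt)
        self.ct_table.to_csv(outdir / "ct_table.csv", index=False, float_format=fmt)
        manifest = {
            "config": _config_dict(self.config),
            "truth": self.truth,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _config_dict(cfg: StudyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["correlation_blocks"] = [dataclasses.asdict(b) for b in cfg.correlation_blocks]
    return d


# -- generation ------------------------------------------------------------

def generate_study(config: StudyConfig | None = None) -> StudyBundle:
    """Draw one complete synthetic study from a :class:`StudyConfig`."""
    cfg = config or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    names = panel_features(cfg.panel)
    species = {n: parse_lipid_name(n) for n in names}
    classes = sorted({sp.class_code for sp in species.values()})

    mice = [f"CTL{i + 1:02d}" for i in range(cfg.n_per_group)] + [
        f"CKD{i + 1:02d}" for i in range(cfg.n_per_group)
    ]
    groups = ["CTL"] * cfg.n_per_group + ["CKD"] * cfg.n_per_group

    # class baselines: geometric means spanning ~3 orders of magnitude
    class_mu = {
        c: math.log(10.0 ** rng.uniform(0.0, 3.0)) for c in sorted(cfg.panel)
    }
    feat_mu = np.array(
        [class_mu[species[n].class_code] + rng.uniform(-0.5, 0.5) for n in names]
    )
    sigma = cfg.noise_sd

    # resolve blocks / effects to member index arrays per tissue
    sample_frames = []
    tissue_data: dict[str, TissueData] = {}
    for tissue in cfg.tissues:
        sids = [f"{m}_{tissue}" for m in mice]
        n_s = len(sids)
        denom = (
            np.full(n_s, cfg.plasma_volume)
            if tissue == "plasma"
            else np.round(rng.uniform(60.0, 140.0, size=n_s), 3)  # ug protein
        )
        sample_frames.append(
            pd.DataFrame(
                {
                    "sample_id": sids,
                    "group": groups,
                    "tissue": tissue,
                    "protein_mass": denom if tissue != "plasma" else np.nan,
                    "volume": denom if tissue == "plasma" else np.nan,
                }
            )
        )

        shift = np.zeros((len(names), n_s))
        for stratum, delta in cfg.effects.get(tissue, {}).items():
            members = _stratum_members(names, stratum)
            if not members:
                continue
            idx = [names.index(f) for f in members]
            for j, g in enumerate(groups):
                if g == "CKD":
                    shift[np.ix_(idx, [j])] += delta * sigma

        # latent blocks: value adds loading*z, residual scaled to keep unit var
        loading = np.zeros((len(names), n_s))
        loading_sq = np.zeros(len(names))
        for block in cfg.correlation_blocks:
            if block.tissue != tissue:
                continue
            z = rng.standard_normal(n_s)
            active = np.array([g in block.groups for g in groups])
            for stratum, lam in block.members.items():
                members = _stratum_members(names, stratum)
                if not members:
                    raise ContractError(
                        f"correlation block stratum {stratum!r} matches no panel feature"
                    )
                idx = np.array([names.index(f) for f in members])
                loading[np.ix_(idx, np.nonzero(active)[0])] += (
                    lam * z[active][None, :]
                )
                loading_sq[idx] += lam**2
        if (loading_sq > 1.0 + 1e-9).any():
            raise ContractError("block loadings exceed unit variance for some feature")
        resid_scale = np.sqrt(np.clip(1.0 - loading_sq, 0.0, 1.0))

        eps = rng.standard_normal((len(names), n_s))
        ln_conc = (
            feat_mu[:, None]
            + shift
            + sigma * (loading + resid_scale[:, None] * eps)
        )
        true_norm = pd.DataFrame(np.exp(ln_conc), index=names, columns=sids)

        # invert the quantification chain: peak areas from concentrations
        pre_conc = true_norm * denom  # undo protein/volume normalisation
        standards: dict[str, InternalStandard] = {}
        peak = pd.DataFrame(index=names, columns=sids, dtype=float)
        for cls in classes:
            areas = pd.Series(
                np.exp(rng.normal(math.log(1e5), 0.2, size=n_s)), index=sids
            )
            standards[cls] = InternalStandard(
                is_id=f"IS-{cls}", concentration=cfg.is_concentration, peak_areas=areas
            )
            feats = [n for n in names if species[n].class_code == cls]
            peak.loc[feats] = (
                pre_conc.loc[feats].div(cfg.is_concentration).mul(areas, axis=1)
            )

        # missingness
        if cfg.missing_rate > 0:
            if cfg.missing_mechanism == "MCAR":
                mask = rng.uniform(size=peak.shape) < cfg.missing_rate
            else:
                # LOD-like: low log-abundance cells censored preferentially
                u = rng.logistic(scale=1.0, size=peak.shape)
                score = ln_conc + 1.5 * u
                thr = np.quantile(score, cfg.missing_rate)
                mask = score < thr
            peak = peak.mask(pd.DataFrame(mask, index=names, columns=sids))

        sample_frame = sample_frames[-1].set_index("sample_id")
        tissue_data[tissue] = TissueData(
            peaks=AbundanceMatrix(data=peak, samples=sample_frame, stage="raw"),
            standards=standards,
            true_normalized=true_norm,
        )

    samples = pd.concat(sample_frames, ignore_index=True).set_index("sample_id")

    ac_profiles = _generate_ac_profiles(cfg, rng, mice, groups)
    isotopomers = _generate_isotopomers(cfg, rng)
    ct_table = _generate_ct(cfg, rng)

    truth = {
        "effects": {t: dict(v) for t, v in cfg.effects.items()},
        "blocks": [dataclasses.asdict(b) for b in cfg.correlation_blocks],
        "ac_ratio_shift": cfg.ac_ratio_shift,
        "dnl_enrichment": dict(cfg.dnl_enrichment),
        "ct_folds": dict(cfg.ct_folds),
        "n_tag_species": len(
            {
                (sp.total_carbons, sp.total_double_bonds)
                for sp in species.values()
                if sp.class_code == "TAG"
            }
        ),
    }
    return StudyBundle(
        config=cfg,
        tissues=tissue_data,
        samples=samples,
        ac_profiles=ac_profiles,
        isotopomers=isotopomers,
        ct_table=ct_table,
        truth=truth,
    )


def _generate_ac_profiles(cfg, rng, mice, groups) -> pd.DataFrame:
    # the acylcarnitine assay is a separate targeted method with its own
    # fixed 29-species panel, independent of the complex-lipid panel map
    pairs = ([(c, 0) for c in range(2, 21)] + [(c, 1) for c in range(12, 22)])[:29]
    base = {p: math.exp(rng.normal(math.log(50.0), 0.3)) for p in pairs}
    rows = []
    for m, g in zip(mice, groups):
        for (c, d) in pairs:
            mult = cfg.ac_ratio_shift if (g == "CKD" and 16 <= c <= 20) else 1.0
            ab = base[(c, d)] * mult * math.exp(rng.normal(0.0, 0.2))
            rows.append(
                {
                    "sample_id": m,
                    "group": g,
                    "carbons": c,
                    "double_bonds": d,
                    "abundance": ab,
                }
            )
    return pd.DataFrame(rows)


def _isotopomer_base(enrichment: float) -> np.ndarray:
    """Base M0..M4 fractions whose weighted enrichment equals the target."""
    w = np.array([0.5, 0.25, 0.15, 0.10])  # labelled-pool isotopomer shape
    labelled = enrichment / float(np.dot(w, [1, 2, 3, 4]))
    if not (0 <= labelled < 1):
        raise ContractError(f"infeasible enrichment target {enrichment}")
    return np.concatenate([[1.0 - labelled], labelled * w])


def _generate_isotopomers(cfg, rng) -> pd.DataFrame:
    rows = []
    for tissue, enrich in cfg.dnl_enrichment.items():
        base = _isotopomer_base(enrich)
        for g in ("CTL", "CKD"):
            for i in range(cfg.dnl_n_per_group):
                sid = f"{g}{i + 1:02d}"
                for rep in (1, 2, 3):
                    if cfg.dnl_concentration == math.inf:
                        frac = base
                    else:
                        frac = rng.dirichlet(base * cfg.dnl_concentration)
                    rows.append(
                        {
                            "sample_id": sid,
                            "tissue": tissue,
                            "group": g,
                            "replicate_id": rep,
                            **{f"E{k}": frac[k] for k in range(5)},
                        }
                    )
    return pd.DataFrame(rows)


def _generate_ct(cfg, rng) -> pd.DataFrame:
    rows = []
    for gene, fold in cfg.ct_folds.items():
        base_dct = rng.uniform(4.0, 8.0)
        for g in ("CTL", "CKD"):
            for i in range(cfg.ct_n_per_group):
                sid = f"{g}{i + 1:02d}"
                dct = base_dct - (math.log2(fold) if g == "CKD" else 0.0)
                dct += rng.normal(0.0, cfg.ct_noise_sd)
                ct_hk = 18.0 + rng.normal(0.0, cfg.ct_noise_sd)
                rows.append(
                    {
                        "sample_id": sid,
                        "group": g,
                        "target_gene": gene,
                        "ct_target": ct_hk + dct,
                        "ct_housekeeping": ct_hk,
                    }
                )
    return pd.DataFrame(rows)


# -- Gaussian graphical model harness --------------------------------------

def generate_ggm(
    n: int, precision: np.ndarray, seed: int = 0, feature_names: list[str] | None = None
) -> tuple[AbundanceMatrix, set[frozenset]]:
    """Multivariate-normal sample with a specified inverse covariance.

    Returns an analysis-ready matrix (rows standardized to mean 0, SD 1,
    which leaves partial correlations unchanged) and the true edge set
    {frozenset({u, v}) : precision[u, v] != 0, u != v}.
    """
    if n <= 0:
        raise ContractError("n must be positive")
    precision = np.asarray(precision, dtype=float)
    p = precision.shape[0]
    if precision.shape != (p, p) or not np.allclose(precision, precision.T):
        raise ContractError("precision matrix must be square symmetric")
    try:
        cov = np.linalg.inv(precision)
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ContractError("precision matrix must be positive definite") from err
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    names = feature_names or [f"V{i + 1}" for i in range(p)]
    data = pd.DataFrame(x.T, index=names, columns=[f"s{i + 1}" for i in range(n)])
    data = data.sub(data.mean(axis=1), axis=0).div(data.std(axis=1, ddof=1), axis=0)
    samples = pd.DataFrame(
        {
            "group": ["CTL"] * n,
            "tissue": ["PMphi"] * n,
            "protein_mass": [100.0] * n,
            "volume": [np.nan] * n,
        },
        index=data.columns,
    )
    samples.index.name = "sample_id"
    m = AbundanceMatrix(data=data, samples=samples, stage="zscore")
    edges = {
        frozenset({names[i], names[j]})
        for i in range(p)
        for j in range(i + 1, p)
        if precision[i, j] != 0
    }
    return m, edges


def reduced_panel(scale: float = 0.25) -> dict[str, int]:
    """A proportionally shrunken panel for fast exercises (>=1 per class)."""
    out = {}
    for cls, n in DEFAULT_PANEL.items():
        out[cls] = max(1, int(round(n * scale)))
    return out
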
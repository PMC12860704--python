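"""Config-driven orchestration of the full analysis.

``run_all`` executes quantification -> preprocessing -> differential ->
networks -> fatty-acid metabolism on either a synthetic study (a ``synth``
config block) or CSV inputs, writing tidy CSVs, network exports and a run
manifest (config echo, package version, per-stage counts, output digests,
warnings).  Every stage can equally be run in isolation from its
predecessor's CSV output; matrices travel with a JSON sidecar holding the
stage tag so out-of-order application is still rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_panel
from .core import AbundanceMatrix, ContractError
from .differential import (
    class_level_model,
    class_results_frame,
    feature_ttests,
    summarize_significance,
)
from .fa_metabolism import (
    AcylcarnitineProfile,
    acylcarnitine_ratio,
    ddct_fold_change,
    dnl_table,
    read_acylcarnitine_table,
    read_ct_table,
    read_isotopomer_table,
)
from .networks import (
    dspc_network,
    edge_contingency_compare,
    export_network,
    ffa_correlation_profile,
    pearson_network,
    stratum_means,
)
from .preprocess import PreprocessConfig, run_preprocessing
from .quantify import (
    normalize_matrix,
    quantify_matrix,
    read_internal_standards,
    read_peak_table,
    read_sample_info,
)
from .synth import StudyBundle, StudyConfig, generate_study, reduced_panel


# -- matrix round-trip with stage sidecar ----------------------------------

def save_matrix(m: AbundanceMatrix, path) -> None:
    path = Path(path)
    m.data.to_csv(path, float_format="%.12g")
    sidecar = {"stage": m.stage, "log": m.log}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_matrix(path, samples: pd.DataFrame) -> AbundanceMatrix:
    path = Path(path)
    data = pd.read_csv(path, index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    stage, log = "raw", []
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        stage, log = meta.get("stage", "raw"), meta.get("log", [])
    samples = samples.loc[list(data.columns)]
    return AbundanceMatrix(data=data, samples=samples, stage=stage, log=log)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# -- configuration ----------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _study_config_from(cfg: dict, seed: int | None) -> StudyConfig:
    synth = dict(cfg.get("synth") or {})
    scale = synth.pop("panel_scale", None)
    if scale is not None:
        synth["panel"] = reduced_panel(scale)
    if seed is not None:
        synth["seed"] = seed
    if "tissues" in synth:
        synth["tissues"] = tuple(synth["tissues"])
    return StudyConfig(**synth)


# -- orchestration ----------------------------------------------------------

def run_all(config: dict | str | Path, seed: int | None = None, outdir=None) -> dict:
    """Execute the full pipeline; returns the run manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir or config.get("outdir", "lipidstat_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": _jsonable(config),
        "stages": {},
        "warnings": [],
        "outputs": {},
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        bundle = _load_inputs(config, seed, out)
        results = _analyse(bundle, config, out, manifest)
        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest["outputs"] = {
        p.name: _digest(p) for p in sorted(out.glob("*")) if p.is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["results"] = results
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _load_inputs(config: dict, seed: int | None, out: Path) -> StudyBundle:
    if "synth" in config or "inputs" not in config:
        bundle = generate_study(_study_config_from(config, seed))
        return bundle
    inp = config["inputs"]
    samples = read_sample_info(inp["samples"])
    from .quantify import InternalStandard  # noqa: F401  (type for readers)
    from .synth import TissueData

    tissues = {}
    for tissue, peaks_path in inp["peaks"].items():
        sub = samples[samples["tissue"] == tissue]
        peaks = read_peak_table(peaks_path, sub)
        standards = read_internal_standards(inp["internal_standards"][tissue])
        tissues[tissue] = TissueData(
            peaks=peaks, standards=standards, true_normalized=None
        )
    ac = (
        pd.read_csv(inp["ac_profiles"]) if inp.get("ac_profiles") else pd.DataFrame()
    )
    iso = (
        pd.read_csv(inp["isotopomers"]) if inp.get("isotopomers") else pd.DataFrame()
    )
    ct = pd.read_csv(inp["ct_table"]) if inp.get("ct_table") else pd.DataFrame()
    return StudyBundle(
        config=None,
        tissues=tissues,
        samples=samples,
        ac_profiles=ac,
        isotopomers=iso,
        ct_table=ct,
        truth={},
    )


def _analyse(bundle: StudyBundle, config: dict, out: Path, manifest: dict) -> dict:
    pre_cfg = PreprocessConfig(**(config.get("preprocessing") or {}))
    diff_cfg = dict(config.get("differential") or {})
    net_cfg = dict(config.get("networks") or {})
    alpha = diff_cfg.get("alpha", 0.01)
    results: dict = {}

    feature_results: dict[str, pd.DataFrame] = {}
    processed: dict[str, AbundanceMatrix] = {}
    for tissue, td in bundle.tissues.items():
        conc = quantify_matrix(
            td.peaks,
            td.standards,
            {n: _class_of(n) for n in td.peaks.feature_names},
        )
        norm = normalize_matrix(conc)
        save_matrix(norm, out / f"normalized_{tissue}.csv")
        z = run_preprocessing(norm, pre_cfg)
        save_matrix(z, out / f"zscore_{tissue}.csv")
        processed[tissue] = z
        manifest["stages"][tissue] = {
            "n_raw_features": td.peaks.n_features,
            "n_final_features": z.n_features,
            "n_samples": z.n_samples,
            "log": z.log,
        }

        ft = feature_ttests(z, alpha=alpha)
        ft.to_csv(out / f"feature_tests_{tissue}.csv")
        feature_results[tissue] = ft

        ann = annotate_panel(z.feature_names)
        cls_res = class_level_model(
            z,
            ann,
            stratify_by=diff_cfg.get("stratify_by", "saturation"),
            model=diff_cfg.get("model", "mixed"),
        )
        class_results_frame(cls_res).to_csv(
            out / f"class_effects_{tissue}.csv", index=False
        )
        results[f"class_effects_{tissue}"] = class_results_frame(cls_res)

    if {"plasma", "PMphi"} <= set(feature_results):
        acc = summarize_significance(
            feature_results["plasma"], feature_results["PMphi"], alpha=alpha
        )
        (out / "significance_summary.json").write_text(json.dumps(acc, indent=2))
        results["significance_summary"] = acc

    # networks on macrophage stratum means, one per group and kind
    net_tissue = net_cfg.get("tissue", "PMphi")
    if net_tissue in processed:
        z = processed[net_tissue]
        ann = annotate_panel(z.feature_names)
        means = stratum_means(z, ann)
        mm = AbundanceMatrix(
            data=means, samples=z.samples.copy(), stage="zscore", log=[]
        )
        # re-standardize stratum means so downstream stages see unit scale
        mu, sd = mm.data.mean(axis=1), mm.data.std(axis=1, ddof=1)
        mm.data = mm.data.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).dropna()
        nets = {}
        for group in ("CTL", "CKD"):
            pn = pearson_network(mm, group, r_min=net_cfg.get("r_min", 0.7))
            export_network(pn, out / f"pearson_{group}.csv", "edge-CSV")
            dn = dspc_network(
                mm, group, alpha=net_cfg.get("alpha", 0.1),
                seed=net_cfg.get("seed", 0),
            )
            export_network(dn, out / f"dspc_{group}.csv", "edge-CSV")
            export_network(dn, out / f"dspc_{group}.graphml", "GraphML")
            nets[group] = {"pearson": pn, "dspc": dn}
            prof = ffa_correlation_profile(z, ann, group, "unsaturated")
            prof.to_csv(out / f"ffa_profile_unsaturated_{group}.csv")
        contingency = {}
        for sat in ("unsaturated", "saturated"):
            stratum = [n for n in mm.feature_names if n.startswith(f"{sat} FFA")]
            if not stratum:
                continue
            table, orr, p = edge_contingency_compare(
                nets["CTL"]["dspc"], nets["CKD"]["dspc"], stratum
            )
            contingency[sat] = {
                "table": table.table.tolist(),
                "odds_ratio": orr,
                "p": p,
            }
        (out / "edge_contingency.json").write_text(json.dumps(contingency, indent=2))
        results["edge_contingency"] = contingency

    # fatty-acid metabolism
    if len(bundle.ac_profiles):
        ratios = _ac_ratio_frame(bundle.ac_profiles)
        ratios.to_csv(out / "ac_ratios.csv", index=False)
        results["ac_ratios"] = ratios
    if len(bundle.isotopomers):
        from .fa_metabolism import IsotopomerDistribution

        dists = [
            IsotopomerDistribution(
                sample_id=str(r.sample_id),
                tissue=str(r.tissue),
                replicate_id=int(r.replicate_id),
                fractions=(r.E0, r.E1, r.E2, r.E3, r.E4),
            )
            for r in bundle.isotopomers.itertuples()
        ]
        dnl = dnl_table(dists)
        if "group" in bundle.isotopomers.columns:
            grp = bundle.isotopomers.drop_duplicates("sample_id").set_index("sample_id")[
                "group"
            ]
            dnl["group"] = dnl["sample_id"].map(grp)
        dnl.to_csv(out / "dnl_rates.csv", index=False)
        results["dnl_rates"] = dnl
    if len(bundle.ct_table):
        from .fa_metabolism import CtRecord

        records = [
            CtRecord(
                sample_id=str(r.sample_id),
                group=str(r.group),
                target_gene=str(r.target_gene),
                ct_target=float(r.ct_target),
                ct_housekeeping=float(r.ct_housekeeping),
            )
            for r in bundle.ct_table.itertuples()
        ]
        folds = ddct_fold_change(records, reference_group="CTL")
        folds.to_csv(out / "ct_fold_changes.csv", index=False)
        results["ct_fold_changes"] = folds
    return results


def _class_of(name: str) -> str:
    from .annotation import parse_lipid_name

    return parse_lipid_name(name).class_code


def _ac_ratio_frame(ac_profiles: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sid, grp in ac_profiles.groupby("sample_id", sort=False):
        profile = AcylcarnitineProfile(
            sample_id=str(sid),
            species=tuple(
                (int(r.carbons), int(r.double_bonds), float(r.abundance))
                for r in grp.itertuples()
            ),
        )
        rows.append(
            {
                "sample_id": sid,
                "group": grp["group"].iloc[0] if "group" in grp else None,
                "ac_ratio": acylcarnitine_ratio(profile),
            }
        )
    return pd.DataFrame(rows)
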
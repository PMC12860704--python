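"""Group-specific lipid correlation networks and their comparison.

The default study couples unsaturated FFA with unsaturated TAG/DAG in CKD
macrophages only.  Marginal (Pearson + Fisher-Z + BH) and debiased sparse
partial correlation (DSPC) networks are built per group, and a Fisher
exact test compares the count of significant FFA-incident edges.
"""

import warnings

import numpy as np

from lipidstat import (
    annotate_panel,
    dspc_network,
    edge_contingency_compare,
    ffa_correlation_profile,
    normalize_matrix,
    parse_lipid_name,
    quantify_matrix,
    run_preprocessing,
)
from lipidstat.core import AbundanceMatrix
from lipidstat.networks import stratum_means
from lipidstat.synth import StudyConfig, generate_study

cfg = StudyConfig(seed=5, n_per_group=12,
                  panel={"FFA": 16, "PC": 20, "TAG": 40, "DAG": 10, "PE": 12})
bundle = generate_study(cfg)
td = bundle.tissues["PMphi"]
cls = {n: parse_lipid_name(n).class_code for n in td.peaks.feature_names}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    z = run_preprocessing(normalize_matrix(quantify_matrix(td.peaks, td.standards, cls)))
ann = annotate_panel(z.feature_names)

for group in ("CTL", "CKD"):
    prof = ffa_correlation_profile(z, ann, group, "unsaturated")
    tag = prof.loc["unsaturated TAG"]
    print(f"{group}: r(unsaturated FFA, unsaturated TAG) = {tag['r']:+.2f} "
          f"(q = {tag['q']:.3f})")

# DSPC networks on class-stratum means, compared around unsaturated FFA
means = stratum_means(z, ann)
means = means.sub(means.mean(axis=1), axis=0).div(means.std(axis=1, ddof=1), axis=0)
mm = AbundanceMatrix(data=means, samples=z.samples.copy(), stage="zscore")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    nets = {g: dspc_network(mm, g, alpha=0.1) for g in ("CTL", "CKD")}
stratum = [n for n in mm.feature_names if n == "unsaturated FFA"]
table, orr, p = edge_contingency_compare(nets["CTL"], nets["CKD"], stratum)
print(f"\nDSPC FFA-incident edges (significant/total): "
      f"CTL {table.a}/{table.a + table.b}, CKD {table.c}/{table.c + table.d}")
print(f"Fisher exact: odds ratio = {orr:.2f}, p = {p:.3f}")
print("\nThe correlation appears in CKD only — the programmed group-specific")
print("coupling of unsaturated FFA with glycerolipids is recovered.")
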
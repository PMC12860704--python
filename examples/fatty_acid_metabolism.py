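"""Beta-oxidation, de novo lipogenesis and gene-expression metrics.

The long/intermediate acylcarnitine ratio proxies mitochondrial fatty-acid
oxidation; palmitate deuterium enrichment after heavy-water labelling
measures de novo lipogenesis; ddCt fold changes quantify qPCR expression.
"""

import numpy as np

from lipidstat import (
    AcylcarnitineProfile,
    CtRecord,
    IsotopomerDistribution,
    acylcarnitine_ratio,
    ddct_fold_change,
    dnl_rate,
)
from lipidstat.synth import StudyConfig, generate_study

bundle = generate_study(StudyConfig(seed=3, n_per_group=11, panel={"FFA": 16}, correlation_blocks=()))

ratios = {"CTL": [], "CKD": []}
for (sid, grp), sub in bundle.ac_profiles.groupby(["sample_id", "group"]):
    prof = AcylcarnitineProfile(
        sample_id=str(sid),
        species=tuple((int(r.carbons), int(r.double_bonds), float(r.abundance))
                      for r in sub.itertuples()),
    )
    ratios[str(grp)].append(acylcarnitine_ratio(prof))
for grp, vals in ratios.items():
    print(f"AC long/intermediate ratio, {grp}: {np.mean(vals):.2f} "
          f"+/- {np.std(vals, ddof=1):.2f} (n={len(vals)})")
print("A lower CKD ratio indicates impaired beta-oxidation.\n")

liver = bundle.isotopomers.query("tissue == 'liver'")
for sid, sub in list(liver.groupby("sample_id"))[:2]:
    reps = [IsotopomerDistribution(str(sid), "liver",
                                   (r.E0, r.E1, r.E2, r.E3, r.E4), int(r.replicate_id))
            for r in sub.itertuples()]
    print(f"liver sample {sid}: palmitate 2H enrichment = {dnl_rate(reps):.3f} "
          f"(mean of {len(reps)} replicates)")
print("Enrichment = E1 + 2*E2 + 3*E3 + 4*E4 over the M+1..M+4 fractions.\n")

recs = [CtRecord(str(r.sample_id), str(r.group), str(r.target_gene),
                 float(r.ct_target), float(r.ct_housekeeping))
        for r in bundle.ct_table.itertuples()]
folds = ddct_fold_change(recs, "CTL")
acsl1 = folds[(folds["target_gene"] == "Acsl1") & (folds["group"] == "CKD")]
print(f"Acsl1 fold change in CKD (ddCt): {acsl1['fold_change'].mean():.2f}x")
print("The generator programs a 5-fold induction; ddCt recovers it.")
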
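"""Score single-sample FSHD biomarkers on a small synthetic cohort.

Builds a seeded cohort with a planted 64-up / 79-down biomarker whose
expression is repressed in FSHD muscle, then computes the single-sample
t-statistic score for every biopsy.  Lower scores mean stronger repression
of the up-regulated target genes, the hallmark of FSHD muscle.
"""

import fshdmbb as f

spec = f.CohortSpec(genes_total=600)
clinical = f.generate_clinical(spec, seed=17)
matrices = f.generate_expression(spec, clinical, seed=18)
muscle = matrices["muscle_tirm_neg"]

scores = f.score_battery(muscle, [spec.signature(), spec.dux4_signature()])
wide = scores.pivot(index="sample_id", columns="signature", values="score")
groups = muscle.samples["group"]

print("per-group mean biomarker score (t-statistic, non-inflamed muscle):")
for group in ("control", "fshd"):
    ids = groups[groups == group].index
    print(f"  {group:8s} n={len(ids):2d}  planted biomarker {wide.loc[ids, 'planted'].mean():+.2f}")
print()
print("A negative gap (FSHD below control) reproduces the repression the")
print("score is designed to detect; the DUX4-like set is scored as a mean")
print("and is not depressed here:",
      f"{wide['dux4_like'].loc[groups[groups=='fshd'].index].mean():.2f} vs",
      f"{wide['dux4_like'].loc[groups[groups=='control'].index].mean():.2f}")
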
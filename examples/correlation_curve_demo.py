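"""The core statistic: expression-ranked correlation curves with AUC
permutation inference.

Simulates a genotyped patient cohort and a ketamine/midazolam/placebo
crossover sample with a shared connectivity perturbation in the 20
highest-expressing regions, fits the per-edge allele-dose GLM and the three
paired drug contrasts, and compares each drug effect matrix with the genetic
effect matrix over nested expression-ranked submatrices.  Significance of
the area under each curve comes from re-assigning genotype labels and
re-running the whole second level per permutation.
"""

import numpy as np
import pandas as pd

from connsig import correlation_curve, fit_edge_glm, permutation_test
from connsig.expression import profile_from_scores
from connsig.validation import simulate_effects
from connsig.simulate import SimulationConfig
from connsig.atlas import default_labels

labels = tuple(default_labels()["name"])
rng = np.random.default_rng(5)
scores = np.linspace(2.0, -2.0, len(labels))[rng.permutation(len(labels))]
ranking = profile_from_scores(pd.Series(scores, index=list(labels)))

cfg = SimulationConfig(
    seed=5,
    n_timepoints=200,
    region_labels=labels,
    signal_regions=tuple(ranking.ranking()[:20]),
    background_allele_sd=0.03,
    background_drug_sd=0.03,
)
conn_stack, design, pharm, lab, _, _ = simulate_effects(
    cfg, contrasts=("ket_gt_pla", "mdz_gt_pla", "ket_gt_mdz")
)
snp = fit_edge_glm(conn_stack, design, lab, contrast_name="snp")

results = permutation_test(conn_stack, design, pharm, ranking, lab,
                           n_perm=500, seed=5)
for name in ("ket_gt_pla", "mdz_gt_pla", "ket_gt_mdz"):
    curve = correlation_curve(snp, pharm[name], ranking)
    res = results[name]
    print(
        f"{name:11s} r(full 106) = {curve.r_values[0]:+.3f}  "
        f"r(top 20) = {curve.r_values[list(curve.sizes).index(20)]:+.3f}  "
        f"AUC = {curve.auc:+7.2f}  p_raw = {res.p_raw:.4f}  p_fdr = {res.p_fdr:.4f}"
    )

print(
    "\nKetamine-like contrasts correlate positively with the allele-dose\n"
    "effect and midazolam negatively; the correlation strengthens as low-\n"
    "expression regions are removed, and the AUC is far outside the\n"
    "genotype-permutation null."
)
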
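"""Bipolar-scale symptom association: MANOVA per domain and partial
correlations.

Couples qualitative-language symptom sums negatively to the allele count and
positively to the connectivity of a hypo-connected temporal-occipital edge,
then recovers both associations with the Wilks-lambda domain test and
covariate-adjusted partial correlations.
"""

import numpy as np

from connsig import domain_tests, partial_corr
from connsig.atlas import default_labels, region_sets
from connsig.simulate import SetEffect, SimulationConfig, simulate_symptoms
from connsig.validation import simulate_effects

sets = region_sets()
labels = tuple(default_labels()["name"])
cfg = SimulationConfig(
    seed=13,
    n_timepoints=300,
    region_labels=labels,
    allele_set_effects=(SetEffect(sets["STG"], sets["TO"], -0.15),),
)
conn_stack, design, _, lab, patients, conns = simulate_effects(cfg, contrasts=())

edge = ("pSTG l", "TOFusC r")
ei, ej = lab.index(edge[0]), lab.index(edge[1])
edge_vals = np.array([conns[(sid, "rest")].z[ei, ej] for sid in patients["subject_id"]])
scores = simulate_symptoms(patients, edge_vals, cfg)

for res in domain_tests(scores, design):
    print(
        f"{res.domain:9s} Wilks lambda = {res.wilks_lambda:.3f}  "
        f"F({res.df[0]},{res.df[1]}) = {res.f_stat:.2f}  p_fdr = {res.p_fdr:.4f}"
    )

covs = design.matrix[:, [design.columns.index("gender"), design.columns.index("dose")]]
lang = scores["language_qualitative"].to_numpy()
r_geno, df1, p1 = partial_corr(patients["allele_count"].to_numpy(), lang, covs)
r_edge, df2, p2 = partial_corr(edge_vals, lang, covs)
print(f"\ngenotype ~ language  partial r = {r_geno:+.3f} (df={df1}, p={p1:.4f})")
print(f"edge     ~ language  partial r = {r_edge:+.3f} (df={df2}, p={p2:.4f})")
print(
    "\nOnly the language domain carries the planted effect; allele carriers\n"
    "sit toward the negative (hypoactive) symptom pole while stronger\n"
    "edge connectivity predicts milder language symptoms."
)
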
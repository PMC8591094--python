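"""Cox risk model on subnetwork scores, median-split survival stratification.

Builds a survival cohort whose hazard follows the mean marker activity, fits
the multivariate Cox model of the subnetwork scores, computes the risk score
sum_i SS_i * beta_i, splits at the median, and compares high vs low risk
groups with Kaplan-Meier / log-rank — then validates the frozen betas on an
external cohort.
"""

import warnings
from dataclasses import replace

from subnetmark import SyntheticSpec, gen_expression, gen_ppi, gen_survival
from subnetmark.diffexpr import differential_expression, intersect_seeds, select_degs
from subnetmark.mcl import filter_subnetworks, mcl_cluster
from subnetmark.network import expand_network
from subnetmark.scoring import activity_scores, assign_directions, zscore
from subnetmark.survival import build_risk_model, external_validation, km_logrank, risk_score, stratify_median

warnings.simplefilter("ignore")

spec = SyntheticSpec(rng_seed=3)
train, truth = gen_expression(spec, sample_prefix="tr_")
edges, _, cna = gen_ppi(spec, truth)
de = differential_expression(train)
seeds = intersect_seeds(select_degs(de), cna)
subnets = [
    assign_directions(sn, de, train)
    for sn in filter_subnetworks(mcl_cluster(expand_network(seeds, edges)).clusters, seeds)
]


def cohort(seed, n, prefix):
    expr, _ = gen_expression(
        replace(spec, rng_seed=seed, n_case=n, n_control=0), prefix, truth=truth
    )
    scores = activity_scores(subnets, zscore(expr))
    clinical = gen_survival(
        scores.scores.mean(axis=0), replace(spec, rng_seed=seed)
    )
    return scores, clinical


scores, clinical = cohort(301, 300, "sv_")
model, fits = build_risk_model(scores, clinical)
risk = risk_score(scores, model)
groups, threshold = stratify_median(risk)
km = km_logrank(clinical, groups)

print("multivariate Cox coefficients per subnetwork:")
for f in fits:
    print(f"  {f.covariate}: beta={f.beta:+.2f}  HR={f.hr:.2f} "
          f"({f.ci95[0]:.2f}-{f.ci95[1]:.2f})  p={f.p_value:.3g}")
print(f"median risk threshold: {threshold:.3f}")
print(f"log-rank high vs low: chi2={km.chi_square:.1f}, p={km.p_value:.2e}")

scores_ext, clinical_ext = cohort(302, 150, "ex_")
km_ext = external_validation(scores_ext, model, clinical_ext)
print(f"external cohort (frozen betas): log-rank p={km_ext.p_value:.2e}")
print()
print("A small log-rank p means the marker-based risk score separates")
print("patients with genuinely different survival, also out of cohort.")
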
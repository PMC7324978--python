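"""Validate the design: simulate progeny at n_opt and test SNP effects.

Breeds half-sib progeny at the designed sample size, attaches a phenotype
with two QTL at h2 = 0.1, fits the ridge (SNP-BLUP) model and the
single-SNP scan, and scores detections inside +/- 0.01 cM map windows.
"""

import numpy as np

from hspower import (
    DesignSpec,
    breed_halfsibs,
    founder_haplotypes,
    maternal_ld_from_haplotypes,
    optimal_sample_size,
    region_correlation,
    ridge_fit,
    ridge_test,
    roc_curve,
    score_detections,
    select_sires,
    shrinkage_lambda,
    simulate_phenotype,
    single_snp_scan,
)
from hspower.simulate import make_gametes

rng = np.random.default_rng(8)
kappa, h2 = 2, 0.1
pop = founder_haplotypes(p=100, n_founders=1000, rng=rng, method="coalescent")
sires = select_sires(pop, 5, h2_trait=h2, rng=rng)
f1, f2 = pop.diplotypes(pop.females)
dams = maternal_ld_from_haplotypes(make_gametes(f1, f2, pop.gmap, rng))
rc = region_correlation(sires, pop.gmap, dams)

spec = DesignSpec(kappa=kappa, h2=h2, n_draws=50, seed=1)
n_opt = optimal_sample_size(rc.R, spec).n_opt_star
print(f"designed sample size n_opt* = {n_opt}")

fam = [n_opt // 5] * 4 + [n_opt - 4 * (n_opt // 5)]
prog = breed_halfsibs(sires, pop, fam, rng=rng)
X, kept = prog.model_matrix()
qtl_model = sorted(rng.choice(X.shape[1], kappa, replace=False))
simulate_phenotype(prog, kept[qtl_model], h2=h2, rng=rng)
y = prog.model_phenotype()

lam = shrinkage_lambda(X.shape[1], h2)
beta = ridge_fit(X, y, lam)
multi = ridge_test(X, y, beta, lam)
single = single_snp_scan(X, y)

gmap_kept = pop.gmap.subset(kept)
for tag, res, alpha in (("multi ", multi, 0.01), ("single", single, 0.05)):
    tpr, fpr = score_detections(res, qtl_model, gmap_kept, alpha=alpha)
    roc = roc_curve(res, qtl_model, gmap_kept)
    auc = np.trapezoid(roc.tpr, roc.fpr)
    print(f"{tag}: TPR = {tpr:.2f}, FPR = {fpr:.3f}, ROC AUC = {auc:.2f}")
# TPR counts a QTL as found when a significant SNP lies within 0.01 cM;
# significant SNPs outside every window count as false positives.
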
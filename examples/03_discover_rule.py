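"""Evolve, select and finalize a prognostic rule on a synthetic cohort.

Runs the full discovery pipeline once: a 300-patient cohort with a
planted BMI1/ETV6 ratio rule is split into stratified training and test
halves; a scaled-down genetic-programming campaign (two sets capped at
2 and 3 genes, six runs each, 4-fold cross-validated AUC fitness)
evolves candidates on the training half; the best candidate by test
AUC is finalized by refining its slice point on the combined halves;
and the finalized rule is evaluated on a freshly generated cohort.
"""

from oncorule.experiments import gp_recovery_experiment

result = gp_recovery_experiment(seed=1)

print(f"best candidate, test-half AUC : {result.test_auc:.3f}")
print(f"finalized rule genes          : {result.genes}")
print(f"fresh-cohort validation AUC   : {result.validation_auc:.3f}")
print(f"planted genes recovered       : {result.recovered_genes}")

# The planted signal is the relative expression of two genes; discovery
# succeeds when the finalized rule keeps held-out discrimination at or
# above 0.9 AUC and its terminals include both planted genes.
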
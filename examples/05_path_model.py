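"""Piecewise SEM: decompose effects on fresh weight over the default DAG.

Builds the node table (light-intensity indicator, genotype tolerance
score, their interaction, and five trait nodes) from a simulated
cohort, fits one standardised regression per endogenous node, checks
the causal structure with Fisher's C over the d-separation basis set,
and splits each node's influence on aboveground fresh weight into
direct and indirect parts.
"""

import heliotol as ht

cohort = ht.generate_cohort(seed=42)
means = ht.aggregate_replicates(cohort.table)
dag = ht.default_dag()

data = ht.sem_table(means, cohort.latent_tolerance)
fit = ht.fit_path_model(dag, data)

claims = ht.basis_set(dag)
print(f"basis set: {len(claims)} independence claims ->")
for x, y, cond in claims:
    print(f"  {x} _||_ {y} | {', '.join(cond)}")
print(f"\nFisher's C = {fit.fisher_c:.3f}, df = {fit.df}, "
      f"model p = {fit.p_value:.3f}")
print("(a large p means the data are consistent with the declared DAG; "
      "a small p flags dependencies the DAG omits — here the simulated "
      "cohort's shared latent vigor factor, which the DAG does not encode)")

eff = ht.effects(fit, dag)
print("\nstandardised effects on aboveground fresh weight:")
print(eff.round(3).sort_values("total").to_string())
print("\n(total = direct + sum over directed paths of edge-coefficient "
      "products; LI is the stress indicator, G the genotype score)")
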
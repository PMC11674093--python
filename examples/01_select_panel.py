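"""Simulate a microarray-like cohort and select a consensus gene panel.

Builds a 500-gene, 3-class dataset with 10 planted discriminative genes,
runs recursive feature elimination under the three boosted learners, and
combines the three 30-gene subsets by 2-of-3 voting into a 10-gene panel.
"""

from panelboost import SimulationConfig, select_panel, simulate

ds = simulate(
    SimulationConfig(
        p=500, n_per_class=20, n_informative=10, effect=3.0, block_rho=0.3, seed=1
    )
)
panel, subsets = select_panel(ds.matrix, ds.labels, target_size=30, final_size=10, seed=1)

print("selected panel :", ", ".join(panel.gene_ids))
print("votes          :", [panel.votes[g] for g in panel.gene_ids])
print("planted truth  :", ", ".join(ds.truth))
recovered = len(set(panel.gene_ids) & set(ds.truth))
print(f"recovered {recovered}/10 planted genes")
# A gene's vote is the number of learners (of 3) whose 30-gene RFE subset
# contains it; the panel keeps the best-voted, best-ranked 10.
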
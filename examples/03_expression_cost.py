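"""Protein expression cost and its comparison between rhythm classes.

The cost of expressing a protein is C_p = N_p * L_p * c_bar_AA: abundance
times length times the mean biosynthetic cost of its residues (high-energy
phosphate bonds). The simulation plants a higher baseline for rhythmic
proteins (cost_coupling = 1 log unit), and the Welch comparison on log C_p
recovers it.
"""

from rhythmecon import (
    SimulationConfig,
    build_cost_table,
    compare_costs,
    read_aacost,
    simulate_proteins,
    simulate_timeseries,
)

cfg = SimulationConfig(n_genes=400, cost_coupling=1.0, seed=2)
ts, truth = simulate_timeseries(cfg, level="protein")
records = simulate_proteins(cfg, truth)
table = build_cost_table(records, ts, read_aacost("wagner"))

classes = truth["is_rhythmic_protein"].map({True: "rhythmic", False: "non_rhythmic"})
results = compare_costs(table, classes)

print(table.head(3).round(2).to_string())
for comp, res in results.items():
    print(f"{comp:>9}: rhythmic {'>' if res.direction == 'group1_higher' else '<'} "
          f"non-rhythmic, Welch t = {res.statistic:6.2f}, p = {res.pvalue:.2e}")
# C_p and the abundance components separate the classes (planted coupling);
# per-residue cost and length do not, since the simulation ties cost to
# expression level only
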
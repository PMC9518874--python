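"""dN/dS versus rhythm class, with and without expression control.

Rhythmic genes are enriched in highly expressed genes, and highly expressed
genes evolve slowly, so a raw dN/dS comparison between rhythm classes is
confounded. Regressing log(dN/dS) on log(expression) and comparing the
residuals isolates the rhythmicity effect. The simulation plants gamma =
-0.3 (rhythmic transcripts more conserved) on top of the expression slope
beta = -0.2.
"""

from rhythmecon import SimulationConfig, compare_dnds, simulate_dnds, simulate_timeseries

cfg = SimulationConfig(n_genes=2000, dnds_beta=-0.2, dnds_gamma=-0.3,
                       cost_coupling=1.0, seed=5)
ts, truth = simulate_timeseries(cfg)
expr = ts.values.mean(axis=1)
dnds = simulate_dnds(cfg, truth, expr)
classes = truth["is_rhythmic_rna"].map({True: "rhythmic", False: "non_rhythmic"})

raw = compare_dnds(dnds, classes, None, "a", controlled=False)
ctl = compare_dnds(dnds, classes, None, "a", expression=expr, controlled=True)

for label, res in (("raw", raw), ("expression-controlled", ctl)):
    print(f"{label:>22}: Welch t = {res.statistic:7.2f}, df = {res.df:7.1f}, "
          f"p = {res.pvalue:.2e}, rhythmic dN/dS "
          f"{'lower' if res.direction == 'group1_lower' else 'higher'}")
# both tests find rhythmic genes more conserved here, but the raw test mixes
# the expression effect (beta) with the rhythmicity effect (gamma); the
# controlled test isolates gamma. Rerun with dnds_gamma=0 to see the raw test
# still reject (pure confounding) while the controlled test stays null.
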
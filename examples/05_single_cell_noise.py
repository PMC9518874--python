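"""Single-cell expression noise with the mean-decorrelated F* statistic.

Variance grows with mean expression, so raw variance cannot compare noise
across genes. F* divides each gene's cross-cell variance by the value a
polynomial log-log trend predicts for its mean; the lowest degree whose
residuals are uncorrelated with the mean is chosen automatically. The
simulation plants reduced dispersion for rhythmic-transcript genes
(noise_coupling = 0.5), mirroring the idea that rhythmic mRNAs buy
expression precision at their peak.
"""

import numpy as np
from scipy import stats

from rhythmecon import (
    SimulationConfig,
    compare_noise,
    filter_expressed,
    noise_table,
    simulate_single_cell,
    simulate_timeseries,
)

cfg = SimulationConfig(n_genes=500, n_cells=300, noise_coupling=0.5, seed=4)
_, truth = simulate_timeseries(cfg)
sc = simulate_single_cell(cfg, truth)
sc = filter_expressed(sc, threshold=1.5)   # log10(FPKM+1) > 1.5 in >= 1 cell
nt = noise_table(sc, degree="auto")

raw_tau = stats.kendalltau(nt["mu"], nt["sigma2"]).statistic
f_tau = stats.kendalltau(np.log(nt["mu"]), np.log(nt["fstar"])).statistic
print(f"{len(nt)} genes pass the expression filter")
print(f"Kendall tau, mean vs variance (raw): {raw_tau:.3f}")
print(f"Kendall tau, mean vs F* (degree {int(nt['degree_selected'].iloc[0])}): {f_tau:.3f}")

rna = truth["is_rhythmic_rna"].map({True: "rhythmic", False: "non_rhythmic"})
prot = truth["is_rhythmic_protein"].map({True: "rhythmic", False: "non_rhythmic"})
for cat in "abcde":
    res = compare_noise(nt, rna, prot, cat)
    print(f"category {cat}: n = ({res.n1}, {res.n2}), "
          f"rhythmic F* {'lower' if res.direction == 'group1_lower' else 'higher'}, "
          f"p = {res.pvalue:.2e}")
# the strong raw mean-variance correlation disappears in F*; categories a, c,
# d (transcript comparisons) show the planted lower noise for rhythmic mRNAs.
# Category b inherits a diluted signal because rhythmic proteins overlap
# rhythmic transcripts, while e — proteins compared among genes with constant
# transcripts — is null, confirming the noise effect lives at the mRNA level
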
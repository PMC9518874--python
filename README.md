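# rhythmecon

**The economics of 24-hour rhythmic gene expression.**

Many genes show nycthemeral (24-h) rhythms of mRNA or protein abundance, and
most of these rhythms are tissue-specific. `rhythmecon` implements, as a
tested and reusable pipeline, the comparative analyses that link rhythmicity
to four gene-level properties:

* **Expression cost** — the energetic cost of expressing a protein,
  `C_p = N_p · L_p · c̄_AA` (abundance x length x mean per-residue
  biosynthesis cost in high-energy phosphate bonds), under both a
  mean-abundance and a max-abundance convention. Are rhythmic proteins the
  costly ones?
* **Tissue specificity** — the per-gene difference δ in normalized expression
  between tissues where the gene is rhythmic and tissues where it is flat,
  and Yanai's specificity index τ ∈ [0, 1]. Are genes rhythmic exactly where
  they are highly expressed?
* **Single-cell expression noise** — the mean-decorrelated noise statistic
  F\*: each gene's cross-cell variance divided by the value predicted by the
  lowest-degree polynomial trend of log σ² on log μ that decorrelates the
  residual from the mean. Are rhythmic transcripts quieter?
* **Purifying selection** — Welch comparisons of dN/dS between rhythm
  classes, raw and after regressing log(dN/dS) on log(expression) to remove
  the expression confound. Are rhythmic genes more conserved?

Upstream of these sit a 24-h rhythm detector (cosinor harmonic regression
with an F-test, plus a robust Tukey-bisquare permutation variant), the
empirical Brown's method for combining dependent probe-level p-values, a
p-value-distribution diagnostic, and threshold / top-fraction classifiers.

Because the real datasets these questions are usually asked of are large
external downloads, the package ships first-class **synthetic-data
generators** that plant every effect the pipeline is meant to detect
(cosine rhythms with uniform phases, cost coupling, tissue-coupled
rhythmicity, negative-binomial single-cell counts with a low-noise subset,
expression- and rhythm-coupled dN/dS). Every stage therefore has
parameter-recovery and null-calibration tests that run in seconds.

## Worked example

```python
from rhythmecon import RunConfig, SimulationConfig, run_all

cfg = RunConfig(outdir="demo_run",
                simulation=SimulationConfig(n_genes=400, n_cells=150, seed=7))
bundle = run_all(cfg)
print(bundle["report"][["category", "n1", "n2", "pvalue", "direction"]])
```

prints (abridged; group 1 is always the rhythmic set):

```
category  n1  n2       pvalue     direction
C_p_mean  93 177 9.164871e-07 group1_higher
       a  73 143 4.198217e-46  group1_lower   # noise: rhythmic mRNAs quieter
       a  89 165 7.777283e-11  group1_lower   # dN/dS controlled: more conserved
```

`C_p_mean` higher for rhythmic proteins recovers the planted cost coupling;
noise category *a* lower recovers the planted dispersion reduction for
rhythmic transcripts; the expression-controlled dN/dS comparison recovers
the planted extra conservation of rhythmic genes. The `examples/` directory
has one short narrative script per capability (detection, Brown's
combination, cost, tissue δ/τ, noise, selection, full pipeline), each
printing the numbers it computes and what they mean.

A thin CLI mirrors the stages:

```bash
rhythmecon simulate --outdir sim --seed 4
rhythmecon rhythm --in sim/rna.tsv --meta sim/rna_meta.tsv --out rhythm.tsv
rhythmecon cost --fasta sim/proteins.fasta --expr sim/protein.tsv \
    --meta sim/protein_meta.tsv --out cost.tsv
rhythmecon noise --sc sim/sc.mtx --genes sim/sc_genes.tsv --cells sim/sc_cells.tsv --out noise.tsv
rhythmecon run --config run.yaml
```

## Layout

```
src/rhythmecon/   simulate, io, rhythm, cost, tissue, noise, selection,
                  pipeline, cli, datatypes, stats
tests/            unit + property tests per module, plus end-to-end checks
examples/         one narrative script per capability
docs/methods.md   models, assumptions, parameter choices, limitations
```
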
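# cavityepp

Extra-pair paternity (EPP) inference from SNP relatedness in cavity-nesting
birds, and the statistics that relate it to local breeding density and
synchrony.

Most of what is known about promiscuity in hole-nesting passerines comes
from nestbox studies, yet nestboxes can create artificial breeding
densities.  Comparing birds breeding in natural tree cavities against a
nestbox plot in the same forest requires a chain of inferences:
genotype QC → genomic relatedness → comparison with the social pedigree →
classification of extra-pair offspring, extra-pair fathers, half-sibling
broods and brood parasitism → molecular sexing of nestlings → per-nest
density/synchrony metrics → binomial GLM/GLMM models.  `cavityepp`
implements that chain as a tested, reusable library with a CLI, plus a
synthetic-data generator with ground truth so every stage is verifiable
without any field data.

## The core method

Pairwise relatedness is estimated from allele dosages x ∈ {0,1,2} with the
GCTA single-SNP estimator,

    G_jk = (1/m_jk) Σ_i (x_ji − 2p_i)(x_ki − 2p_i) / (2 p_i (1 − p_i)),

over the m_jk loci called in both individuals.  Realized relatedness is
then compared with the social expectation (0.5 for a father and the
nestlings in his nest): a social father–offspring pair with G > 0.35 is
within-pair, G < 0.15 is an extra-pair offspring (EPO); an adult male with
G > 0.35 to another pair's offspring is its extra-pair father (EPF);
within-brood pairs with G in (0.15, 0.35) are half-siblings (evidence of
multiple sires when the father is unsampled); a nestling below 0.1 to all
parents and siblings is a brood parasite.  Sex is assigned from Z-linked
SNPs (females are ZW, hence never heterozygous on the Z) with a
cross-validated naive-Bayes classifier.  Density and synchrony use
data-derived radii (median EPF-to-sired-nest distance and its ×2/×3
multiples) and species-specific fertile windows.  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

Simulate a season with a known 12% per-offspring extra-pair rate and run
the whole chain:

```python
from cavityepp import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    simulation=SimulationConfig(
        n_pairs_per_plot=12, n_autosomal_loci=1500, n_sexlinked_loci=15,
        epp_rate=0.12, seed=7),
    seed=7,
)
report = run_pipeline(cfg)
print(report.epp_summary)
```

prints

```
 species    plot  n_broods  n_broods_epp  pct_broods_epp  n_offspring  n_epo  pct_epo
blue_tit natural        12            12             100          117     21       18
blue_tit nestbox        12             9              75          116     13       11
```

so 21 of 117 natural-plot nestlings with a father call (18%) were
classified extra-pair at this small simulated size, every one of them a
true EPO by the generator's truth tables.  `report.radii` holds the
data-derived radius ladder, `report.sex_cv_accuracy` the cross-validated
sexing accuracy, and `report.model_report` the occurrence/proportion/
individual-level model fits with drop-one likelihood-ratio p-values.

The same pipeline is scriptable from the shell:

```bash
cavityepp simulate --seed 1 --n-pairs-per-plot 30 --out data/
cavityepp run-all --seed 1 --epp-rate 0.1 --out results/
cavityepp make-fixture --out fixture/
```

`make-fixture` writes a small label-encoded reference dataset; its summary

```
  species    plot  n_broods  n_broods_epp  pct_broods_epp  n_offspring  n_epo  pct_epo
 blue_tit natural        30            11              37          197     16        8
 blue_tit nestbox        37            17              46          237     28       12
great_tit natural        32            12              38          179     20       11
great_tit nestbox        26            16              62          189     30       16
```

yields Yates-corrected chi-squares of 0.267 and 2.427 (brood level) and
1.230 and 1.352 (nestling level) for the cavity-type comparison — no
statistical support for a difference in promiscuity between natural
cavities and nestboxes in either species.

## Layout

| module | contents |
|---|---|
| `cavityepp.synthetic_data` | two-plot season simulator with truth tables; Mendelian-check oracle |
| `cavityepp.genotypes` | dosage matrix, call-rate QC, GCTA GRM, CSV/VCF I/O |
| `cavityepp.pedigree` | social pedigree, tabular additive relatedness |
| `cavityepp.parentage` | threshold-band classification, EPF links, parasitism, EPP summaries |
| `cavityepp.sexing` | Z-linked marker discovery, naive-Bayes sexing with MC cross-validation |
| `cavityepp.spatiotemporal` | distances, fertile windows, densities, radius derivation |
| `cavityepp.stats` | chi-square, Mann–Whitney, binomial GLM/GLMM (adaptive Gauss–Hermite), VIF, scaled mass index, model battery |
| `cavityepp.pipeline` | end-to-end orchestration, reference fixture |
| `cavityepp.cli` | `cavityepp` command-line interface |
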
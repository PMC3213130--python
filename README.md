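# pmrwls

Measurement-error modeling and empirically weighted regression for
MethyLight **PMR** (Percent Methylated Reference) data.

## The problem

Population studies of tumor DNA methylation often rely on archival
specimens that yield highly variable — and frequently tiny — amounts of
amplifiable DNA. MethyLight quantifies locus-specific methylation as

```
PMR = 100 · (B/G) / (Bʳ/Gʳ)
```

the methylated-allele fraction of the tumor aliquot (B methylated out of G
fragments) relative to a fully methylated M.SssI-treated reference
(Bʳ out of Gʳ). Because the assay samples *fragments* of the genome, a
specimen with h genome equivalents and true methylation proportion p yields

```
B ~ Binomial(G, p/f),   G = h·f,   f = 10⁴ fragments/genome
Bʳ ~ Binomial(Gʳ, c/f),  Gʳ = 5,500·f,  c = conversion efficiency (1 if complete)
```

PMR is unbiased for 100·p at any DNA quantity, but its variance explodes as
h falls: low-input specimens produce spurious zeros
(Pr(B=0) = (1−p/f)^G ≈ (1−p)^h) and ratios far above 100. Treating all
specimens as equally informative wastes power when comparing patient
groups.

`pmrwls` implements this generative model and a family of two-group tests
that confront the resulting heteroscedasticity:

| method | outcome | weights |
|---|---|---|
| `ols_pmr` | PMR | uniform |
| `ols_log` | ln(PMR+1) | uniform |
| `ols_thresh(t)` | PMR | 1 if DNA quantity > t genomes, else 0 |
| `wls_q(k)` | PMR | 1/Var(PMR) estimated per quantile group (k=5 → quintiles) |
| `wls_w(w)` | PMR | 1/Var(PMR) estimated in sliding windows of w ranked neighbours |

The WLS weights are *empirical*: observations are ranked by a declared
DNA-quantity surrogate (genome equivalents, or an inverted C(t) value) and
the PMR variance is estimated within quantile bins or sliding windows, then
inverted. Any method can also be run on the ln(PMR+1) scale. The group
contrast is tested with a two-sided t-test on the group coefficient
(n_effective − 2 degrees of freedom), so 0/1 threshold weights are exactly
OLS on the retained subset.

A simulation-study engine estimates false-positive rates and power for all
methods over a registry of two-group population scenarios
(Beta and Beta–Bernoulli methylation distributions; capped-lognormal DNA
quantities with ~23% of specimens under 10 genomes).

## Worked example

Simulate 200 tumors (100 per group) under scenario `a.i` — both groups pure
Beta with variance 0.01, means 0.2 vs 0.27 — then run all six analyses:

```sh
$ pmrwls simulate --scenario a.i --n 200 --seed 7 --out example.tsv
$ pmrwls analyze --input example.tsv --method all --orientation quantity --out results.tsv
INFO pmrwls: PMR: estimate=7.207 p=0.000275 n_eff=200
INFO pmrwls: ln(PMR+1): estimate=0.2813 p=0.0839 n_eff=200
INFO pmrwls: PMR[h>1]: estimate=7.941 p=4.71e-05 n_eff=187
INFO pmrwls: PMR[h>10]: estimate=6.367 p=0.00104 n_eff=152
INFO pmrwls: WLS-Q(k=5): estimate=5.98 p=0.00049 n_eff=200
INFO pmrwls: WLS-W(w=41): estimate=6.418 p=0.000189 n_eff=200
```

The estimate is the group-2-minus-group-1 mean difference on the analysis
scale: the true difference here is 100·(0.27 − 0.2) = 7 PMR units, and every
raw-scale method recovers it to within sampling error. On this dataset the
log-transform analysis is the only one that misses significance at the 5%
level, while the weighted analyses achieve small p-values *without
discarding* the 48 low-quantity specimens that the h>10 threshold drops —
they are simply down-weighted in proportion to their estimated variance.

The same machinery is available as a library:

```python
import numpy as np
from pmrwls import (SimConstants, QuantityModel, get_scenario,
                    simulate_dataset, run_method_suite)

rng = np.random.default_rng(7)
data = simulate_dataset(get_scenario("a.i"), SimConstants(), QuantityModel(), rng)
for out in run_method_suite(data):
    print(out.method.label(), out.estimate, out.p_value)
```

Power and false-positive-rate grids over the full scenario registry:

```sh
pmrwls study --grid power --reps 1000 --seed 1 --out power.tsv   # 9 scenarios x 6 methods
pmrwls study --grid fpr --reps 10000 --seed 1 --out fpr.tsv      # 6 nulls x 6 methods
```

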
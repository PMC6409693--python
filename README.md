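# ieaco

Entropy-guided ant colony search for epistatic SNP interactions in
case-control genotype data.

Complex-disease susceptibility often depends on the *joint* effect of
several loci (epistasis) whose single-locus marginal effects are weak.
Testing every K-SNP combination is infeasible at genome scale, so this
package searches the combination space with an ant colony: each of M ants
picks a K-locus set with probability

```
p_k(i) = tau_k(i)^alpha * eta_k^beta / sum_j tau_j(i)^alpha * eta_j^beta
```

scores it with Pearson's chi-square on the 2 x 3^K status-by-genotype
contingency table, and deposits the statistic as pheromone,
`tau_k(i+1) = (1 - rho) tau_k(i) + sum of visiting ants' chi2`. Pure
positive feedback converges fast but can lock onto local optima, so the
colony also tracks the Shannon entropy `H(i) = -sum_k p_k log2 p_k` of the
pheromone distribution. While `|H(i) - H(i-1)|` exceeds a switch threshold
theta the standard rule runs; once the entropy change stalls, selection
gains a negative-feedback factor `w_k = mu - tau_k` raised to gamma,

```
p_k(i) ~ tau_k^alpha * eta_k^beta * (mu - tau_k)^gamma
```

which boosts neglected loci and restores exploration. After N iterations
the distinct per-iteration best sets whose p-values clear the
Bonferroni-corrected threshold `alpha / C(L, K)` are reported, ranked by
chi-square.

The package is aimed at methods work on epistasis detection: it bundles a
two-locus penetrance-model simulator (eight classic models ship as
fixtures), the ACO/IEACO search engines, and an evaluation harness
(detection power, recall/precision, top-N breakdown) for simulation
studies.

## Worked example

```python
import ieaco
from ieaco.io import load_builtin_model

model = load_builtin_model("model8")            # XOR model, MAF 0.5/0.5
data = ieaco.simulate_dataset(model, n_snps=100, n_cases=800, n_controls=800,
                              pair_positions=(12, 47), seed=7)
result = ieaco.run_search(data, ieaco.SearchConfig(mode="ieaco", seed=42))
for snp_set, fit in result.reported[:3]:
    print(snp_set, f"chi2={fit.chi2:.1f} dof={fit.dof} p={fit.p_value:.3g}")
```

prints

```
(12, 47) chi2=550.0 dof=8 p=1.3e-113
```

The XOR pair carries no single-locus marginal effect, yet its joint
genotype table separates cases from controls decisively: chi-square 550 on
8 degrees of freedom, far below the Bonferroni-corrected threshold
0.05 / C(100, 2) ~ 1e-5, and it is the only interaction reported. On this
run the pheromone entropy fell from 6.644 to 6.024 bits over 20 iterations
while the colony concentrated on the embedded pair.

The same pipeline from the shell:

```sh
ieaco simulate --model model8 --snps 100 --cases 800 --controls 800 --seed 7 --out ds
ieaco search ds.tsv --mode ieaco --seed 42 --out run
ieaco evaluate -r run.results.tsv -t ds.truth.txt --out metrics.tsv
```

`search` writes a results table, a per-iteration log (best set, chi2,
entropy, active strategy) and a JSON manifest that suffices to reproduce
the run bit-identically.

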
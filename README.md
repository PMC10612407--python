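# tdsgwas

Federated case-control GWAS by **two-step dynamic sampling**: a simulator and
library for collaborative association studies in which several parties
(hospitals, biobanks) jointly identify SNP–phenotype associations without ever
pooling their full genotype data.

## The problem and the method

A case-control GWAS tests each SNP for association with a binary trait via a
per-SNP logistic regression, P(y=1 | x) = σ(α + βx), where x ∈ {0,1,2} is the
minor-allele count, and rejects H₀: β = 0 with the Wald statistic (β̂/se(β̂))²
against χ²(1).  Pooling cohorts across institutions raises power but is often
legally or ethically impossible; meta-analysis of summary statistics is the
usual fallback, yet its power degrades badly when the cohorts are
heterogeneous (for instance opposed case:control imbalances).

The two-step protocol implemented here sits between those extremes:

1. **Local screening (phase 1).**  Each party scans its own data and
   nominates SNPs with local Wald p > μ (a deliberately lenient threshold,
   default μ = 0.3).  SNPs nominated by *every* party are pruned and carry a
   final label of 0.  This typically removes a large share of the panel at
   negligible risk to true signals.
2. **Dynamic sampling (phase 2).**  Iteratively, the parties partition the
   surviving SNPs into batches of at most m (default 300), agree on a common
   column-shuffle seed per batch, each sample K individuals uniformly at
   random (ignoring case/control balance), shuffle rows privately, strip all
   identifiers, and send the blocks to a compute server.  The server pools
   the blocks and returns per-column Wald p-values; the parties invert the
   column shuffle and label SNP i significant at iteration T iff p ≤ μ.
   Labels are aggregated across iterations by majority vote (ties →
   insignificant) until they stabilise or an iteration cap (default 9) is
   reached.

The server is honest-but-curious: it computes correctly but sees only
de-identified, doubly-shuffled integer blocks.  The package quantifies the
residual privacy surface: cumulative exposure of each party's individuals
(expected fraction 1 − (1 − K/N)ᵀ after T iterations) and the accuracy of a
MAF-rank unshuffling adversary who tries to re-identify shuffled columns from
reference allele frequencies.

Also included: a synthetic cohort generator (Hardy–Weinberg genotypes with
MAF ~ U[0.1, 0.5]; liability-threshold phenotypes with sparse additive
effects), a DerSimonian–Laird random-effects meta-analysis baseline
(logistic or Cochran–Armitage trend effects), five canonical two-party
heterogeneity scenarios, and an evaluation harness scoring everything against
the pooled-analysis ground truth.

## Worked example

```python
from tdsgwas import (
    SimulationParams, SCENARIO_PRESETS, ProtocolConfig,
    simulate_genotypes, simulate_liability_phenotypes, assemble_scenario,
    run_protocol,
)
from tdsgwas.evaluation import (
    expected_exposure, exposure_fraction, ground_truth_labels,
    score_protocol_iterations,
)

sim = SimulationParams(n_snps=2000, n_individuals=2400,
                       n_causal=20, heritability=0.5, seed=7)
genotypes = simulate_genotypes(sim)
phenotypes, effects = simulate_liability_phenotypes(genotypes, sim, n_cases=1200)
parties = assemble_scenario(genotypes, phenotypes, SCENARIO_PRESETS[1], seed=7)

config = ProtocolConfig(K=500, mu_phase1=0.3, mu_phase2=0.3,
                        m=300, max_iterations=9, master_seed=7)
result = run_protocol(parties, config)
truth = ground_truth_labels(parties, threshold=0.005)

print(f"phase 1 pruned {len(result.insignificant_phase1)} of {sim.n_snps} SNPs")
print(f"phase 2 ran {result.iterations_run} iterations ({result.stop_reason})")
print(f"final significant SNPs: {sum(result.final_labels.values())}")
best = max(score_protocol_iterations(result, truth),
           key=lambda r: r.sensitivity + r.specificity)
print(f"best iteration {best.iteration}: sensitivity {best.sensitivity:.3f}, "
      f"specificity {best.specificity:.3f}")
print(f"exposure A: observed {exposure_fraction(result.exposure, 'A'):.3f}, "
      f"expected {expected_exposure(500, 1200, result.iterations_run):.3f}")
```

Output:

```
phase 1 pruned 942 of 2000 SNPs
phase 2 ran 9 iterations (max-iterations)
final significant SNPs: 289
best iteration 8: sensitivity 1.000, specificity 0.899
exposure A: observed 0.991, expected 0.992
```

Reading this: local screening discarded 47% of the panel before any data left
the parties, and lost none of the 20-odd truly significant SNPs (sensitivity
1.000 against the pooled scan at 0.005).  The lenient per-iteration label
threshold (μ = 0.3) recovers every true signal but also lets a fraction of
surviving null SNPs through, which is what the specificity of 0.899 measures
on this LD-free synthetic panel.  After nine iterations of sampling 500 of
1200 individuals, ~99% of each party's cohort has been exposed to the server
in de-identified form — the privacy cost the exposure audit tracks.

## Command line

```sh
tdsgwas simulate --scenario 1 --seed 7 --out results/      # party fixtures
tdsgwas run      --config experiment.yaml --out results/   # protocol labels
tdsgwas meta     --config experiment.yaml --out results/   # DL baseline
tdsgwas evaluate --config experiment.yaml --out results/   # sens/spec summary
tdsgwas audit    --config experiment.yaml --out results/   # privacy audit
tdsgwas reproduce-scenario-table --seed 1 --out results/   # scenario grid
```

Each command writes a `manifest.json` (config hash, seed, version) making the
outputs reproducible bit-for-bit.

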
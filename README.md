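# dsmlink

Discriminative sequence models for assessing expression-to-genotype
re-identification risk.

Gene expression correlates with genotype through eQTLs, so a shared
expression profile can leak its owner's genetic identity: an attacker who
holds an expression profile **e** can score candidate phased genotype
profiles **x** from another data set and link the two records (a *linking
attack*).  `dsmlink` is for privacy researchers and data custodians who
want to measure that risk with the strongest match score an attacker could
realistically learn, rather than with deliberately weakened models.

## The model

The core scorer is a conditional random field over the genotype sequence
restricted to eQTL sites.  Per haplotype it combines

- a **Li–Stephens copying chain**: h is an error-prone mosaic of a reference
  panel of K haplotypes, with switch probability 1 − exp(−ρ Δg/K) per
  interval of the genetic map and symmetric copy error ε — this carries the
  LD structure; and
- one **QTL factor per eQTL s**, a logistic link between the allele and the
  expression of the eQTL's eGene set Q(s):
  φ_s(h_s, e) = h_s σ(α_s + β_sᵀ e_Q(s)) + (1 − h_s)(1 − σ(·)).

The two haplotypes decouple (inference is linear, not quadratic, in K), and
candidates are ranked by the prior-normalized match score

    log M(x, e) = log p̃(x | e) − log p_HMM(x) ,

which for observed alleles reduces to the summed log factors.  All factors
(α_s, β_s) are trained **jointly** by maximizing the normalized conditional
likelihood with analytic gradients (per-site gradient: observed dosage minus
twice the model's posterior allele probability); the chain partition
function is what calibrates redundant and LD-linked eQTL signals, which is
exactly what the independence-assuming baselines (Gaussian naive Bayes and
extremity-based linking, both included) cannot do.

A per-query Gaussian null over mismatching-pair scores turns best-match
scores into upper-tail P-values, and a threshold sweep evaluates
unknown-membership attacks with linking-adapted ROC/PR curves.  A seeded
synthetic-data module generates LD-structured panels, mosaic individuals,
and eQTL-coupled expression so the whole pipeline runs with no external
data.

## Worked example

```python
from dsmlink import (
    SimConfig, make_linking_fixture, TrainConfig, train_dsm,
    score_all, link_forward, fit_null, linking_accuracy,
)

cfg = SimConfig(seed=1)
fx = make_linking_fixture(cfg)   # 300 train pairs, 50 queries, 250 decoys
model = train_dsm(
    fx.train_pairs, fx.panel, fx.eqtl_map,
    TrainConfig(recomb_scale=cfg.recomb_scale, emission_error=cfg.copy_error),
)
print(f"training loss: {model.train_loss[0]:.1f} -> {model.train_loss[-1]:.1f}")

candidates = fx.test_genotypes + fx.decoys
scores = score_all(fx.test_expressions, candidates, model)
nulls = fit_null(scores, true_pairing=fx.truth, subsample=500)
links = link_forward(scores, nulls)
acc = linking_accuracy(scores, fx.truth)
print(f"linked {int(acc * len(links))}/{len(links)} queries correctly "
      f"({100 * acc:.0f}%)")
r = links[0]
print(f"{r.query_id} -> {r.best_candidate}  log M = {r.log_score:.1f}  "
      f"P = {r.pvalue:.2e}")
```

Output:

```
training loss: 79.2 -> 58.9
linked 50/50 queries correctly (100%)
test0000 -> test0000  log M = -155.5  P = 1.16e-09
```

The training loss is the negative mean conditional log-likelihood of the
matched pairs.  Every one of the 50 query expression profiles is linked to
its true genotype among 300 candidates, and the first query's best match
sits about six null standard deviations above the impostor distribution
(P ≈ 1e−9) — the kind of separation that keeps the link stable as the
candidate pool grows.

The same pipeline is scriptable from the shell:

```sh
dsmlink simulate --seed 1 --outdir fixture/
dsmlink train dsm --panel fixture/panel.tsv --genotypes fixture/train.vcf \
    --expression fixture/expression_train.tsv --eqtl-map fixture/eqtl_map.tsv \
    --genetic-map fixture/genetic_map.tsv --out model.json
dsmlink link forward --model model.json --panel fixture/panel.tsv \
    --genotypes fixture/candidates.vcf --expression fixture/expression_test.tsv \
    --outdir links/
```

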
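# clonalholes

Analysis of TCRα repertoires across experimental conditions: which T-cell
clones are selected in one condition but missing from another ("clonal
holes"), and which appear only in the perturbed condition ("newcomers").
The package is aimed at immunologists analysing bulk TCR-seq replicate
designs (e.g. control vs. mutant thymic selection backgrounds, or sorted
CD5^lo^ vs. CD5^hi^ subsets) and paired-chain single-cell clonotype tables.

## What it computes

A **clonotype** is the triple (TRAV gene, TRAJ gene, CDR3 amino-acid
sequence); its abundance is the number of unique cDNA molecules (UMIs).
On clonotype × sample abundance tables the package provides:

- **Hill diversity** of order *q*: `D_q = (Σ p_i^q)^{1/(1−q)}`, with
  `D_1 = exp(−Σ p_i ln p_i)` (the effective number of equally abundant
  clonotypes), plus Monte-Carlo **rarefaction** (subsampling without
  replacement) and Good–Turing **sample coverage**
  `Ĉ = 1 − (f₁/n)·[(n−1)f₁ / ((n−1)f₁ + 2f₂)]`.
- **Morisita–Horn overlap** `C = 2 Σ p_i q_i / (Σ p_i² + Σ q_i²)` for all
  sample pairs, grouped into within- and between-condition comparisons.
- **Set-theoretic classification**: *recurrent* clonotypes (detected in
  ≥ 3 of all samples), split into *dependent* (exclusive to condition A),
  *newcomer* (exclusive to B) and *shared*; *natural CD5lo/CD5hi*
  clonotypes (≥ 3 of 4 samples of one CD5 extreme, absent from all of the
  other); cross-assignment of external clone sets; top-k expanded clones;
  public paired-chain clonotypes shared between genotypes.
- **V–J junction statistics**: the junction edit count (germline V + J
  deletions plus P + N additions), positional (distality) V/J gene usage,
  and permutation tests for group differences.
- A **synthetic repertoire generator** that plants dependent/newcomer
  labels, latent CD5 classes, junction and positional shifts, and emits
  AIRR rearrangement TSVs with per-clonotype ground truth, so the whole
  pipeline is testable end to end.

## Worked example

Simulate a 3+3 study with 500 condition-A-exclusive clones, 400 shared
clones and 100 newcomers at 50,000 molecules per sample, then run the full
pipeline:

```python
import clonalholes as ch

config = {
    "simulation": {"s_shared": 400, "s_dependent": 500, "s_newcomer": 100,
                   "reads_per_sample": 50000, "cd5_design": True},
    "seed": 1, "reps": 50,
}
bundle = ch.run_pipeline(config)
cls = bundle.summary["classification"]
print(cls["recurrent"], cls["shared"], cls["dependent"], cls["newcomer"])
# 997 400 497 100
print(bundle.summary["overlap"]["category_means"])
# {'between': 0.599..., 'within_control': 0.9927..., 'within_mutant': 0.9964...}
```

Of the 1,000 planted clonotypes, 997 are recovered as recurrent at this
depth; 497 of the 500 planted condition-A-exclusive clones are classified
dependent and all 100 newcomers are recovered, satisfying the partition
identity `|dependent| + |shared| + |newcomer| = |recurrent|`. Replicates of
the same condition are nearly identical (Morisita–Horn ≈ 0.99) while the
two conditions overlap far less (≈ 0.60), reflecting the planted exclusive
clones. Per-sample coverage is ≈ 0.99998, i.e. sequencing is saturating.

The same stages are available from the shell:

```sh
clonalholes simulate --seed 1 --out study/
clonalholes diversity study/genotype_abundance.tsv --q 1 --grid auto:8 --out div/
clonalholes overlap study/genotype_abundance.tsv --out ov/
clonalholes classify study/genotype_abundance.tsv --groups control,mutant --out cls/
clonalholes run --config config.yaml --out out/
```

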
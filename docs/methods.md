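# Methods

## Clonotype definition and molecule counting

A bulk TCRα clonotype is the exact triple (TRAV gene, TRAJ gene, CDR3
amino-acid sequence); paired single-cell clonotypes add the β chain at the
same V/CDR3/J amino-acid resolution and are retained only when both chains
are in frame. Abundance is counted in unique cDNA molecules: reads sharing
a (sample, UMI) pair collapse to one molecule by exact string match — no
error-tolerant UMI clustering is attempted, since sequencing-error models
for the barcodes are upstream of this package. When a UMI group contains
reads of different clonotypes, the majority clonotype wins and exact ties
go to the lexicographically smallest (v, j, cdr3) key; the conflict rate is
recorded on the table. Gene names are normalized to IMGT-style uppercase
with allele suffixes stripped (`Trav14-1*01` → `TRAV14-1`).

Reads whose V call lists several paralogs (a real feature of the duplicated
mouse *Tcra* locus) are kept in abundance tables, keyed by the sorted
comma-joined paralog string so they never merge with unambiguous calls.
They are excluded only from positional-usage and junction-editing analyses,
where gene identity matters, and optionally from abundance tables via
`drop_paralog_ambiguous`, which also reports the excluded molecule fraction
per sample.

## Diversity

Diversity uses Hill numbers with molecules as individuals and clonotypes
as species: `D_q = (Σ p_i^q)^{1/(1−q)}`, with the entropy limit
`D_1 = exp(−Σ p_i ln p_i)` at q = 1 (0·ln 0 := 0; orders within 1e-9 of 1
use the limit). Rarefaction is Monte-Carlo subsampling without replacement
(multivariate hypergeometric draws), reporting mean and MC standard error
per grid point with 100 replicates by default; the point at full depth is
returned exactly. Extrapolation beyond the observed depth is deliberately
not offered: the intended use-case is saturated repertoires (coverage ≈ 1),
where observed diversities are the estimand. Coverage is the bias-corrected
Good–Turing estimator `Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁ + 2f₂)]`, equal to
1 when there are no singletons and degrading to `1 − f₁/n` when the
correction denominator vanishes. Confidence bands around rarefaction
curves are not drawn; the per-point MC standard error is reported instead.
"Relative diversity" divides each sample's observed diversity by the mean
over a declared reference sample set.

The test suite checks the Monte-Carlo rarefaction against an independent
exhaustive-enumeration oracle (all subsample compositions weighted by
hypergeometric probabilities, feasible for n ≤ 12) at a 3-standard-error
tolerance.

## Overlap

Pairwise similarity is the abundance-weighted Morisita–Horn index
`C = 2 Σ p_i q_i / (Σ p_i² + Σ q_i²)` on vectors aligned over the union
clonotype set. All unordered sample pairs are computed and partitioned into
within-group and between-group lists (3+3 designs give 3/3/9 pairs, 4+4
give 6/6/16). Significance testing of within-vs-between differences is
left to the caller; the value lists are emitted for that purpose.

## Classification

All classifiers are presence-based: a clonotype is present in a sample if
it has at least `min_umi` molecules (default 1; the threshold is exposed
because no abundance floor is inherent to the definitions). *Recurrent*
clonotypes appear in ≥ `min_samples` (default 3) of all samples. Among
recurrent clonotypes, *dependent* means present in ≥ 1 sample of group A
and absent from every group-B sample, *newcomer* is the mirror image, and
*shared* means present in at least one sample of each. "Present in a
group" = detected in at least one of its samples; this reading makes the
three classes partition the recurrent set and yields the identity
|A| + |B| − |A∩B| = |recurrent|, which the tests enforce on every input.
Natural CD5lo/CD5hi classification requires presence in ≥ `min_present`
(default 3) samples of one sorted extreme and absence from all samples of
the other; everything else is unassigned.

Cross-assignment matches query clones into a labelled inventory by exact
key. Because it is not obvious whether unmatched query clones belong in
the denominator of derived fractions, both denominators (matched-only and
all-query) are reported. Top-k expanded clones are ranked by mean relative
frequency across replicate samples, with a pooled-count ranking available
behind a flag and ties broken by the lexicographic clonotype key. Public
paired clonotypes are the intersection of the per-genotype unions of
per-mouse clonotype sets, with each clone counted once per mouse.

## Junction and positional statistics

The junction edit count of a rearrangement is the sum of nucleotides
deleted from the germline V and J segments plus P and N nucleotides added
at the joint; a missing annotation field is an error, distinct from zero.
Positional V/J usage maps genes to indices along the locus, by default
parsing the numeric suffix of IMGT names (TRAVn-k → n + k/100), with a
user-supplied TSV able to override the map. "Distal" is a direction
convention recorded on the map (default: higher index = more distal,
i.e. farther from the recombination-proximal end of the locus). Group
comparisons use the difference of means with a label-permutation null
(default 1,000 shuffles, two-sided, +1 smoothing) rather than a named
parametric test — the statistic's null distribution under exchangeable
labels is exactly what the permutation draws. The pooled values are sorted
before permuting so the null stream is invariant to input order; swapping
the group labels therefore flips the sign of the statistic but leaves the
p-value unchanged when group sizes are equal.

## Synthetic data generator

The generator's defaults encode the study design the analysis targets: a
pool of 1,000 clonotypes of which 500 are selectable only in genotype A,
100 only in genotype B and 400 in both; 3 replicate samples per genotype,
each a multinomial draw of 50,000 molecules from the availability-
restricted pool; and an optional 4+4 CD5-sorted design in which every
clonotype carries a fixed latent CD5 class (lo with probability 0.5) and
sorted samples draw only from matching clones — the class is a property of
clone identity, not a per-cell coin flip.

Clone relative abundances are log-normal with σ = 1 (clone sizes spanning
roughly two orders of magnitude, a realistic skew for a selected αβ
repertoire; a Pareto power-law option exists). Junction edits are Poisson
with mean λ = 1 split uniformly over the four annotation fields, raised by
δ_edit = 2 for newcomers; positional gene indices are discretized normals
(V: center 15, sd 4 on 1–40; J: center 30, sd 8 on 1–60), mean-shifted by
δ_pos = 2 for newcomers. UMIs are unique per molecule by default, with a
collision-rate knob that duplicates rows to exercise the collapse path,
and a paralog-ambiguity fraction that turns clones into comma-joined
paralog keys. All randomness derives from one seed through CRC-named
substreams per sample, so any sample regenerates identically regardless of
generation order.

The generator does not attempt sequence-level realism: CDR3s are random
amino-acid strings, there is no germline reference, no PCR/sequencing error
model and no biological V–J pairing structure. Passing recovery tests
therefore demonstrates the correctness of the set-theoretic and statistical
machinery under the assumed sampling model, not robustness to alignment or
annotation artefacts in real data.

The paired-chain generator plants a configurable number of public clones
in at least one mouse of each genotype and keeps private pools disjoint,
so the recovered shared set must equal the planted set exactly.

## Pipeline and problem sizes

The `run` pipeline executes input → diversity → overlap → classification →
junctions and emits a JSON summary with version, seed and config hash;
floats are serialized at 12 significant digits so reruns are bit-identical.
`scripts/acceptance.py` recomputes the headline quantities at the default
study conditions; recovery checks in the test suite use 10 seeds at the
full 50,000-molecule depth and a depth grid of 1k/5k/25k/50k molecules per
sample, with false-dependent rates averaged over seeds because individual
rates at saturating depth are at or near zero.

## Known limitations

- Exact-key clonotype matching only; no sequence-similarity clustering.
- No extrapolated richness/diversity estimators; analyses presume
  near-saturating coverage.
- The deposited-data benchmark requires externally downloaded tables
  converted to the package's TSV formats; the relevant loaders are in
  `clonalholes.benchmark` and the corresponding acceptance test fails
  until those files are present.
- Junction statistics consume annotation columns; the package never
  reconstructs deletions/insertions from nucleotide sequence.
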
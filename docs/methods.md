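# Methods

## The mapping model

The package treats ligand–target annotation as a transfer problem: a
binding event recorded against a single-domain protein localises the
interaction to that protein's one Pfam-A family, and families validated
this way ("seed" domains) are then the only credible binding sites when
they appear inside multi-domain architectures. The model's assumptions,
in decreasing order of strength:

1. Small-molecule binding occurs within Pfam-A domain boundaries rather
   than in linker or disordered regions. Residue-overlap validation is
   the empirical check on this assumption, not a premise of the code.
2. Domain annotation of the target set is essentially complete; a
   missing domain annotation can silently re-route a mapping (this is
   why curated fragment accessions are excluded up front).
3. When exactly one validated family occurs in an architecture, it —
   and not any co-occurring never-validated family — mediates binding.
   Architectures with two or more validated families are left unmapped
   rather than guessed at.

The estimator surface (`DomainLigandMapper.fit` / `.predict`) separates
seed derivation from mapping so a seed set fitted on one activity export
can annotate another.

### Filter parameters

| parameter | default | meaning |
|---|---|---|
| `assay_type` | `"B"` | direct binding assays only |
| `threshold_molar` | `5e-5` (50 µM) | inclusive potency cut-off |
| `allowed_activity_types` | Ki, Kd, IC50, EC50, −Log Ki, pKd, pA2, pI, pKa | controlled vocabulary |
| `log_types` | −Log Ki, pKd, pA2, pI, pKa | compared as −log₁₀(molar) against 4.301 |

Concentration units M, mM, µM (also spelled `uM`/`μM`), nM and pM are
converted to molar; a record with any other unit is rejected with a
logged reason rather than guessed at. pI, pA2 and pKa are compared on
the same −log₁₀(molar) scale as pKd even though their physical meaning
differs; the vocabulary carries a single threshold, and a debug log line
marks such comparisons. The boundary is inclusive on both scales (50 µM
and 4.30103 both qualify).

### Co-occurrence review

Families that never occur alone can never seed themselves. The
co-occurrence report lists them with their target counts and flags
those at or above `min_cooccurrence` (default 100) as candidates for
manual promotion — the route by which a tyrosine-kinase-like family,
always fused to other domains, enters the seed set with `manual`
provenance. Manual seeds persist regardless of activity data;
a manual entry that the data also derives keeps `data_derived`
provenance.

## Overlap validation

`fraction_within` is the number of binding-site residues inside the
evaluated family's intervals (union over copies) divided by all
binding-site residues; a prediction is correct when the fraction is at
least 0.5, with the boundary counted as correct. Per-family shares use
the same denominator, so shares need not sum to one (residues can fall
outside every domain, and overlapping annotations may double-cover).

Choices where the design was open:

* The within/outside ratio used for survival curves is +∞ when every
  residue is inside; the curve is reported over the finite observed
  grid and the all-within mass appears as the curve's plateau. Capping
  at an arbitrary large value would distort the tail.
* Interface detection flags a site when at least `min_families`
  (default 2) families each hold a share ≥ `min_share` (default 0.30,
  chosen because observed interface cases all show per-domain shares of
  0.30 or more; both configurable).
* Coverage ratios merge overlapping/adjacent intervals before counting,
  making the ratio invariant to splitting one interval into contiguous
  pieces.

## Discrete power-law protocol

Counts (domain occurrences, ligands per family/target) are positive
integers, so the reference model is the zeta-normalised discrete power
law on {x_min, x_min+1, …}. Estimation follows the standard tail
recipe:

* **α | x_min** by maximising the exact discrete log-likelihood
  −α·Σlog xᵢ − n·log ζ(α, x_min), with scipy's Hurwitz zeta
  (Euler–Maclaurin evaluation) and bounded scalar optimisation on
  α ∈ (1.0001, 20], tolerance 10⁻⁶.
* **x_min** by scanning observed values whose tail holds at least 8
  observations (smaller tails give KS estimates too noisy to compare)
  and minimising the tail KS distance; ties break to the smallest
  x_min. The KS distance compares both the step tops and step feet of
  the discrete CDFs. Note that when the data truly follow the law from
  x_min, every larger candidate is also correctly specified, so the
  scan has an intrinsic upward ambiguity of a few values at realistic
  n; pooled over simulations the median estimate sits at the true
  value.
* **Goodness of fit** by semi-parametric bootstrap: each replicate
  mixes empirical below-x_min data (binomially, with the observed
  proportion) with exact inverse-CDF draws from the fitted tail, and is
  re-fitted *the same way the observed fit was made* — free x_min by
  default, fixed via `refit="fixed"` when the observed fit fixed it.
  Re-fitting replicates differently from the original fit would target
  the wrong null distribution. The p-value is the fraction of
  replicates with KS ≥ observed; on true-model data it is approximately
  uniform (verified by a 200-replicate calibration experiment).
  Default 1,000 replicates; a seed is required for reproducibility.
* **Alternatives** (lognormal, exponential, Weibull) are discretised
  onto the integers ≥ x_min via p(x) = [F(x+½) − F(x−½)] / S(x_min−½),
  which normalises exactly over the support, and fitted by Nelder–Mead
  on the discretised likelihood. This keeps both models in the
  comparison genuinely discrete; comparing a discrete power law against
  continuous-density alternatives would bias the likelihood ratio by
  the discretisation mass. The Vuong statistic R/(s_d·√n) is signed so
  positive favours the power law; its two-sided normal p-value says
  whether the sign is informative. Raw statistics are reported —
  no yes/no decision rule is imposed.

A caveat the geometric-misfit test documents: with free x_min the
protocol may legitimately retreat to the far tail of a non-power-law
distribution and find the remaining tail plausible. Testing whether a
*whole* distribution is power-law requires fixing x_min at the support
minimum.

## Descriptor-space PCA

Six descriptors per compound (MW, ALogP, PSA, rotatable bonds, HBD,
HBA) are pooled across the selected families into one decomposition.
Outlier trimming removes a row when *any* descriptor falls strictly
outside its [1st, 99th] percentile band (percentiles over the full
input, single pass; rows are the only coherent removal unit for PCA).
Scaling centres and divides by the sample standard deviation (ddof=1);
a zero-variance descriptor is an error naming the column. The
decomposition is an SVD of the centred scaled matrix (numerically safer
than forming the covariance); loading columns are signed so each
column's largest-magnitude entry is positive, making loadings
comparable across runs. Family separation is assessed by Welch's
unequal-variance t-test on PC1 scores for every family pair, p-values
multiplied by the number of pairs and capped at 1 (Bonferroni);
families with fewer than 3 scored compounds are excluded with a
warning.

## Synthetic fixtures

The generator is a pure function of config + seed and plants the
structure the pipeline is supposed to recover:

* **Architectures** — `n_targets` (default 200) targets over
  `n_families` (default 40) families; family popularity is heavy-tailed
  (discrete power law, exponent `family_frequency_alpha`, default 2.0);
  about half the targets are multi-domain (`p_multidomain` = 0.5,
  matching the roughly 50 % multi-domain share of real target
  dictionaries); ~15 % of domain placements add a tandem copy of the
  same family. Intervals never overlap within a target and sequence
  lengths cover all intervals.
* **Activities** — every mappable or conflicted target receives 1–3
  qualifying records (spanning concentration types, an exact-50 µM
  boundary record, and log-scale types); distractors each violate
  exactly one filter dimension (wrong assay type, aggregation flag,
  too weak, disallowed type).
* **Binding sites** — k = 10 residues inside the planted family plus
  round(k·f/(1−f)) outside it, so the within-fraction is (1−f) exactly
  up to rounding; f = `noise_fraction` (default 0).
* **Descriptors** — per-family multivariate Gaussians with count
  columns rounded and clipped at zero.

What the fixtures deliberately do *not* emulate: real potency value
distributions beyond the threshold dimension, inter-domain sequence
homology, incomplete domain annotation, and annotation errors other
than the planted noise. Passing the planted-truth experiments therefore
shows the machinery is self-consistent and the rules are implemented
exactly; it does not measure accuracy on real database exports, where
assumption 2 of the mapping model is the binding constraint.

## Problem sizes and numerical choices

The acceptance experiments use 100 fixtures of 60 targets for the
oracle-equivalence check, 150 targets for planted-truth recovery, 20
simulations of n = 5,000 for α/x_min recovery, and 200 replicates of
n = 600 with 100 bootstrap draws each for GoF calibration — sizes at
which every stochastic criterion is comfortably identified while the
whole script runs in well under a minute on one CPU. n = 600 also
guarantees the ≥ 10-distinct-values precondition for free-x_min
estimation at α = 2.5. All randomness flows through
numpy `default_rng` seeds derived from one base seed.

Degenerate inputs are errors, not guesses: all-identical samples,
zero-variance descriptor columns, empty residue sets, missing sequence
lengths, non-normalisable exponents (α ≤ 1), and sub-minimal tails all
raise with a message naming the offending quantity.

## Known limitations

* Case-iii (multi-seed) targets are never mapped; resolving them would
  require structural evidence the heuristic deliberately does not use.
* Seed validation is binary — one qualifying ligand suffices — so a
  single mis-annotated activity can promote a family.
* The x_min scan inherits the finite-sample upward ambiguity discussed
  above.
* Pfam accession↔id resolution, coordinate translation from PDB
  numbering, and live database queries are out of scope; inputs must
  already be in Uniprot residue coordinates and one family namespace.
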
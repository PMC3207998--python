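# Methods

This note records the model implemented by `seedvar`, the parameter
defaults, the simulator's scope, and the numerical/design decisions a reader
needs to interpret the outputs.

## Seed-site model

A mature miR of length ≥ 8 defines four site patterns on the mRNA
(DNA alphabet, U→T at ingestion):

| class   | mRNA pattern (5'→3')                       |
|---------|--------------------------------------------|
| 6mer    | revcomp(miR 2–7)                           |
| 7mer-A1 | revcomp(miR 2–7) + `A`                     |
| 7mer-m8 | comp(miR 8) + revcomp(miR 2–7)             |
| 8mer    | comp(miR 8) + revcomp(miR 2–7) + `A`       |

The A opposite miR position 1 is a literal `A` regardless of the miR's
first base (the A1 rule).  Classification always operates on a fixed
8-position frame: frame base at mRNA index *u* (1-based, 5'→3') pairs miR
position 9−*u*.  The class hierarchy is
`8mer > 7mer-m8 > 7mer-A1 > 6mer > none`; a window's class is the highest
pattern it matches.  `N` is a sentinel that never matches and never pairs.

Coordinates are 1-based inclusive internally; BED I/O converts to 0-based
half-open.  For a UTR placed on the minus strand, mRNA position *u* maps to
genomic position `end − u + 1`, and forward-strand VCF alleles are
complemented onto the mRNA before substitution.

Optional per-site annotations filter scan results the way the survey did:
PhastCons conservation ≥ 0.57 and mirSVR down-regulation score ≤ −0.6.
These scores are consumed as input; `seedvar` does not compute them.

## Disruption calls

For a SNP inside a site's frame, the 8-base window is re-classified under
each allele.  Verdicts compare class ranks: equal → `unchanged`, higher →
`upgraded`, lower with no class left → `abolished`, lower otherwise →
`downgraded`.  The reported `pos_in_mre` uses miR numbering by default
(position *k* pairs miR position *k*; the mRNA's 3'-most frame base is
position 1); `numbering="mrna"` counts 5'→3' along the mRNA instead.  A VCF
ref allele that contradicts the UTR sequence raises a data-integrity error
rather than silently producing a call.

## Created sites (CNM SNPs)

Each SNP is centred in a 45-base mRNA window (22-base flanks, sentinel-padded
at UTR ends).  Only the eight frames containing the SNP are examined; the
alternate allele must achieve a strictly higher class than the reference
allele at the same frame.  Candidates are then filtered by a **proxy duplex
scorer**: an antiparallel Smith–Waterman local alignment of the full miR
against the window (Watson–Crick +5, G:U +2, mismatch −3, gap −8,
contributions from miR seed positions 2–8 doubled) and an energy proxy
−(3·GC + 2·AT + 1·GU) pseudo-kcal/mol summed over the paired positions of
the optimal alignment.  Defaults: score ≥ 70, energy ≤ −20.  These
thresholds play the same *role* as the alignment-score ≥ 150 and ΔG ≤ −20
kcal/mol cutoffs of classical target-prediction tools but are calibrated to
this scorer's own scale (a perfect 21-nt duplex scores 140, about twice the
cutoff, mirroring the classical ratio); the scores are filters, not
quantitative outputs.

## SNP density

For every site, a 6-base window slides over 18 bases upstream of the first
seed base, the seed, and 18 bases downstream (37 offsets, −18…+18).
`density(offset) = count · 1000 / (n_sites · 6)` in SNPs/kb, pooling
(site, SNP) co-occurrences; when contig lengths are supplied, sites whose
window would run off the contig are excluded from that offset's denominator.
The headline "seed density" is the mean over offsets 0–5.

## GWAS/LD enrichment

Catalog associations with p < 1e-5 are kept.  Each catalog SNP expands to a
proxy set: itself plus direct LD neighbours with r² **strictly** > 0.8 (no
transitive closure).  Catalog SNPs linked at r² > 0.8 are merged into loci
(connected components); the number of loci sets the per-replicate draw size.
The observed statistic is the number of unique seed-site (disrupting +
creating) SNPs captured by any proxy set.  The null redraws that many SNPs
without replacement from the universe of SNPs whose folded MAF (maximum
across populations) is ≥ 1%, expands LD identically, and recounts; 1000
replicates by default.  Reported are `p_empirical = (1 + #{null ≥ obs}) /
(reps + 1)` (add-one, never exactly 0) and the normal upper tail at
`z = (obs − mean)/sd` (undefined when sd = 0).

## Population differentiation

Per-SNP F_ST is the multi-population Weir–Cockerham θ computed from
per-group allele counts with heterozygosity taken under Hardy–Weinberg
proportions (inputs are frequencies, not genotypes); `n` individuals =
alleles/2; negative estimates are clamped to 0, monomorphic loci return 0.
The θ distribution is Box-Cox transformed with λ chosen by
profile-likelihood grid search over [−3, 3] in steps of 0.01 (zeros offset
by 1e-6).  Seed-site vs background groups are compared with an unpaired
equal-variance t-test on the transformed scale; outliers are flagged at
mean + 2 SD (upper tail, transformed scale, within the group supplied);
summary histograms use 10 equal-width bins on [0, 1] with the background
down-sampled to the seed-site group's size.

## Simulator scope and limits

`simulate_world` fabricates the complete input bundle with recorded truth:

* planted sites whose class is *exactly* the requested class at the frame
  (slot-based placement; infeasible requests raise);
* disruption SNPs at seed positions whose alt allele always abolishes;
* creation events embedding the full reverse complement of a miR with one
  seed base broken by the ref allele and restored by the alt, guaranteeing
  the default duplex filters pass (scores ≈ 119–140, energies ≤ −38);
* Balding–Nichols per-population frequencies (Beta around an ancestral
  frequency drawn U(0.05, 0.95); F = 0.2 for seed-site SNPs, 0.1 otherwise)
  with binomial allele counts over 4 populations × 200 alleles;
* LD fabricated at the r² summary level by correlated allele copying within
  blocks of 5 consecutive SNPs over 200 virtual haplotypes (target r² 0.9;
  the reported r² is the empirical haplotype correlation);
* a GWAS catalog drawn from the MAF-eligible universe by weighted sampling
  without replacement (exponential-key method) with odds multiplied by
  `enrichment_factor` for SNPs whose block contains a seed-site SNP.

Default problem sizes (8 miRs × 21 nt, 30 UTRs × 1500 nt, 120 planted
sites, 60 creation events, ~500 background SNPs, catalog of 40) are the
package's own choice: large enough for stable statistics, small enough that
the full pipeline and test suite run in seconds.  The simulator is a
*mechanism* model for testing, not a population-genetics simulator: LD has
no recombination map, haplotypes are discarded, and sequence composition is
uniform.

## Numerical choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipeline outputs embed the seed and thresholds in a metadata line
  and reruns are byte-identical.
* The Smith–Waterman traceback breaks ties toward the diagonal, making the
  energy proxy deterministic.
* Empirical p-values use the add-one estimator; at reps = 1000 the smallest
  reportable p is ≈ 0.001.
* Box-Cox λ is reported at grid resolution 0.01; scipy's continuous MLE
  agrees within that resolution (tested).

## Design decisions

* **Library + examples + thin CLI.**  The artifact is a pipeline tool, so a
  `seedvar` console entry point orchestrates the stages, but all logic is
  importable and the `examples/` scripts are the narrative documentation.
* **Position-in-MRE numbering.**  Published tables number MRE positions by
  the miR base they pair.  That convention is the default
  (`numbering="mir"`), with `"mrna"` available because 5'→3' mRNA counting
  is what coordinate arithmetic produces naturally.
* **Rare/common MAF boundary.**  Reported frequencies above 0.5 are folded
  to the minor allele; "rare" is folded MAF strictly < 0.02.  The strict
  inequality is the only reading that reproduces the quoted 9-rare /
  13-common split of the worked-example table, which contains a SNP at
  exactly 0.02.
* **Proxy duplex scorer.**  The original score/energy filters came from a
  closed-source alignment tool; re-implementing it exactly is neither
  possible nor the point.  The proxy preserves the decision structure
  (two-threshold filter, seed-weighted pairing, wobble tolerance) on a
  documented scale.
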
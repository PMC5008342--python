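# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that make runs reproducible.

## Study design

The design object fixes a panel of cell lines whose *position in the list is
its metastatic rank*; the default panel is Hep3B (rank 0, non-metastatic
control), MHCC97L, MHCC97H, HCCLM3.  The secretome arm uses 3 biological
replicates × 12 peptide fractions per line; the glyco arm uses 2 replicates
and no fractionation.  All trend statements ("increased", "decreased") are
relative to this rank ordering.

## Peptide FDR and quality control

q-values follow the standard target-decoy construction: PSMs are sorted by
descending ion score, FDR(t) = #decoys(score ≥ t) / max(1, #targets(score ≥ t))
is evaluated along the sorted list, and the q-value of a PSM is the minimum
FDR at any threshold at or below its score.  Two tie conventions make the
estimate conservative and order-independent: decoys sort before targets at
equal score, and the decoy count at a score always includes the full tie
group.  On instances small enough to enumerate, the q-values equal
brute-force threshold enumeration exactly (tested).

The stepwise filter accepts a target PSM that clears **either** tier of
(score > 30, q < 0.01) / (score > 40, q < 0.05).  The union reading is a
design choice: the two published pairs could also be applied sequentially,
but the union is the only interpretation that makes both pairs active
simultaneously; both tiers are configurable.  Peptides shorter than 7
residues are dropped regardless of score, matching the search-engine floor.

## Parsimony inference

Peptide→protein mapping is exact substring search; isoleucine and leucine
are treated as distinct residues (configurable at the data level: collapse
them in the FASTA if desired).  Grouping proceeds in three deterministic
passes: merge proteins with identical peptide sets; remove proteins whose
peptide set is a strict subset of another's; greedily cover the remaining
peptides, preferring groups with more uncovered peptides, then more PSMs,
then the lexicographically smallest accession.  Greedy set cover is not
guaranteed minimal in general; on random instances small enough for
exhaustive search the tests compare its size against the true minimum.
Uniqueness is evaluated *after* collapsing to gene products, so a peptide
shared only between isoforms of one gene still counts as unique — the
quantification unit is the GP, not the accession.

## Spectral-count quantification

The theoretical tryptic peptide count uses zero missed cleavages (cleave
after K/R not followed by P) and a 7-residue minimum; positional segments
are counted, so repeated sequences count once per position.  The search
itself allowed missed cleavages, but the normalization denominator
deliberately uses the unique full cleavage products — allowing missed
cleavages would roughly triple every denominator and cancel out of NSAF5
anyway.  For a GP group the denominator comes from the longest member's
sequence.

SAF1 = 10 · PSM/theo and NSAF5 = 10^5 · SAF1/ΣSAF1 per run.  Each PSM is
attributed to exactly one GP (unique peptides to their GP; shared peptides
to the largest claiming group, deterministically), so per-run totals are
conserved and the column-sum contract (Σ NSAF5 = 10^5, relative error
≤ 1e−9) holds by construction.  A GP absent from a run scores 0 — absence
is zero spectral evidence, not missing data, which is the usual
spectral-count convention and what makes the ANOVA below well defined.

The differential screen is a plain one-way ANOVA on raw NSAF5 values (four
groups × replicates) at α = 0.05 with **no** multiple-testing correction and
no log transform; both choices mirror the upstream protocol this pipeline
reproduces rather than best current practice, and a degenerate
(zero-variance) GP is flagged and never called significant.  Replicate
agreement is summarized by Pearson correlation over GPs quantified in both
runs of a pair (≥ 3 shared GPs required, else undefined).

## Trend clustering and candidates

Replicates are averaged per line, each GP profile is z-scored, and Euclidean
k-means (k = 3 secretome, k = 2 glyco; best of 20 restarts, seeded) partitions
the profiles.  A cluster is labelled by its centroid: strictly increasing
along the ranks → "increased", strictly decreasing → "decreased", anything
with a tie or reversal → "mixed".  Strict monotonicity is the most literal
reading of "continuously increased" on a 4-point profile.

Note a consequence of per-profile z-scoring: a constant profile maps to the
origin, but arbitrarily small noise on a flat profile is amplified to unit
scale, so flat-but-noisy profiles are *not* a compact cluster.  This is why
clustering runs on the differential subset only.  In the glyco arm the same
one-way ANOVA screen (α = 0.05) is applied to the normalized site table
before clustering; without it the majority of flat sites wash the two
centroids out to "mixed" and the candidate set collapses.  Candidates are
the exact intersection of the GPs in "increased" secretome clusters and the
GPs owning sites in "increased" glyco clusters, sorted for determinism.

## N-glycosite validation and quantification

A glyco-PSM is accepted when every flagged asparagine, translated to protein
coordinates via the peptide's (first) occurrence, lands on an N-!P-[S/T]
sequon, and the reported mass delta equals n_sites × shift within
n_sites × tolerance.  The shift defaults to 2.9848 Da — the value the
upstream search pipeline printed — while the chemically expected
deamidation-plus-^18^O shift is ≈ 2.9883 Da; the default 0.01 Da tolerance
accepts either, and both knobs are exposed.  Flags on non-asparagine
residues are malformed input (an error, not a rejection).  Peptides mapping
to several proteins yield one record per protein marked ambiguous; ambiguous
records are excluded from the quantitative table by default.

Site quantification divides the site's summed peptide areas by the run's
total identified-peptide area; ratios are taken against the mean of the
reference line (default: the rank-0 control, since the upstream protocol
does not name its denominator).  Sites with zero reference signal keep
their normalized values with the ratio flagged unavailable.

## Secretion categorization

The decision tree is: signal peptide ∧ no TM helix → Part 4 (classical);
else any TM helix → Part 3 (membrane); else SecretomeP > 0.5 (strict) →
Part 1 (non-classical); else Part 2 (other).  The precedence — signal first,
TM overriding — is a reconstruction from the stated cutoffs and category
names; a protein with both a signal peptide and TM helices is Part 3 here.
The classifier never runs the predictors; their outputs are inputs.

## Clinical contingency statistics

`pearson_chi2` implements χ² = Σ (|O−E| − c)²/E with E from the product of
margins, c = 0.5 only for 2×2 tables with the continuity correction
requested (clamped at zero so the correction cannot overshoot), df =
(r−1)(k−1), and the upper-tail chi-square p-value.  `fisher_exact_2x2` sums
hypergeometric probabilities over the margin-preserving support for all
tables no more probable than the observed one (relative tolerance 1e−7 on
the comparison).  All three variants are exposed because published crosstab
p-values in this setting are a mix of plain, Yates-corrected and exact
results; the package pins each variable to the variant that reproduces it.
r×k exact tests (Freeman–Halton) are out of scope.

## Synthetic data: what it emulates, and what it does not

Abundance follows base × fold^(±rank) for increased/decreased proteins and
base for flat ones — the simplest model producing monotone trends.  Defaults
(the study conditions exercised by the acceptance checks): 300 proteins of
200–400 residues, 10% increased / 10% decreased, fold step 2, base abundance
log-uniform in [0.5, 2], sequon rate 1 per 100 residues, PSM depth 2 per
abundance unit, decoy fraction 10%, replicate noise mean-one log-normal with
σ = 0.2, area noise σ = 0.25, glyco detection depth 3, glyco contaminant
fraction 10%.  Ion scores are Normal(45, 8) for targets and Normal(20, 8)
for decoys, truncated at zero — arbitrary but yielding realistic FDR curves.
Secretion classes are drawn at 52/13/14/21% (Part 1/2/3/4), the reported
category mix.  Fractions are assigned uniformly (no isoelectric-point
structure).

Glyco-PSM areas: a site is detected in a run with probability 1 − e^(−depth),
and a detected site contributes **one** precursor-area record per run
(log-normal around abundance), mirroring extracted-ion-chromatogram
quantification where a peptide has one area per run.  An earlier per-PSM
area model was discarded: summing Poisson-many independent areas injects
counting noise (~0.6 CV at depth 3) that has no counterpart in area-based
quantification and swamps the modelled replicate noise.

Not emulated: spectra, retention times, isotope envelopes, pI-based
fractionation, peptide-detectability bias, shared peptides between unrelated
proteins (random sequences make them vanishingly rare), protein isoforms
sharing a gene, and heavy-tailed abundance distributions.  Passing tests
therefore demonstrate the *pipeline logic* — filtering, inference,
normalization, clustering, validation — under controlled noise, not
performance on real LC-MS/MS data, where inference ambiguity and
detectability effects dominate.

## Problem sizes and seeds

The end-to-end evaluation uses 300 proteins (≈ 160k PSMs over 144 run
fractions), the null-cohort calibration 500 cohorts of 75 patients, and the
contaminant benchmark 80 proteins (≈ 3k glyco-PSMs); each completes in
seconds to tens of seconds.  Every stochastic component draws from
`numpy.random.default_rng` seeded from a single run seed (stage offsets
+1…+3 keep streams independent); k-means uses the same seed for restarts.
Identical configuration and seed reproduce byte-identical reports.

## Known limitations

* Greedy set cover can retain one more group than the true minimum on
  adversarial instances.
* The glyco arm's 2-replicate ANOVA screen has limited power; it is the
  main loss mechanism in candidate recovery (≈ 80–97% across seeds rather
  than 100%).
* The raw-scale ANOVA on compositional NSAF5 values lets strong trends in a
  few GPs induce opposite apparent trends in flat GPs (closure effect);
  this is faithful to the reproduced protocol but inflates the significant
  set.
* The pTNM-stage row of the clinical table is not reproduced by any
  implemented variant (plain chi-square gives ≈ 0.033); the original
  computation for that row is not recoverable and no test pins it.
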
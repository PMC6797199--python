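# Methods

This note documents the models and procedures implemented in `httscan`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions at the edges.

## Screening

Two filtering rounds precede any statistics.

**First round** (`screening.filter_hits`, `extract_hit_region`,
`filter_min_homology`, `merge_identical_by_species`): homology hits are kept
when the bit score is strictly above `min_score` (default 50) and the
E-value strictly below `max_evalue` (default 1e-5); both inequalities are
strict by a literal reading of the thresholds. Retained hit regions are
extracted with `flank_bp` (default 2000) bases on each side, clipped to the
scaffold, and reverse-complemented for minus-strand hits (BLAST tabular
coordinates are 1-based inclusive; internally all arithmetic is 0-based
half-open). Fragments with fewer than `min_homology_bp` (default 300)
confirmed-homology bases to their best query are withdrawn; "confirmed"
counts aligned non-gap columns by default, with an identical-columns switch
because the looser definition is not the only defensible one. Byte-identical
sequences (compared gap-stripped, uppercased, so alignment padding cannot
defeat deduplication) from the *same* species collapse to one
representative; identical sequences from different species are never merged,
since cross-species identity is precisely the signal of interest.

**Second round** (`classify.collapse_intraspecific`): on the rooted TE tree,
every maximal clade whose leaves all belong to one species is reduced to the
leaf with the shortest path to the clade's MRCA — the copy most similar to
the inferred ancestral sequence. Ties break lexicographically by id for
determinism.

Codon alignments are validated, not repaired
(`screening.validate_codon_alignment`): length divisible by 3, gap runs
codon-shaped (start on a codon boundary, length a multiple of 3), no
internal in-frame stop. Automated frame repair is refused because any repair
policy would be arbitrary; a `drop_violating` helper removes offending
records instead.

## Distances

`distances` implements the Nei–Gojobori (NG86) estimator. Per sense codon,
the synonymous site count s is the number of the nine single-nucleotide
changes that preserve the amino acid, divided by 3 (changes creating stop
codons are not synonymous); n = 3 − s exactly. Differences between a codon
pair with k differing positions are averaged over all k! single-step
pathway orderings; orderings passing through a stop codon are excluded
(uniform weights over the rest; if every ordering is blocked, all are used).
Sites S are averaged over the two sequences. Codon columns containing a gap,
an N, or a stop in either sequence are excluded pairwise (whole-codon
exclusion), matching the common default for pairwise distances; a complete-
deletion alternative was considered unnecessary because every downstream
statistic is pairwise. Proportions are corrected with Jukes–Cantor,
d = −(3/4) ln(1 − (4/3)p), undefined at p ≥ 3/4; undefined pairs are
flagged and skipped (and tallied) by the scan rather than clamped.

A subtlety worth recording: S<sub>d</sub> can exceed S on very short
sequences (one AAA/AAG pair gives S<sub>d</sub> = 1 against S = 1/3), so the
container does not enforce S<sub>d</sub> ≤ S; the Jukes–Cantor domain check
is the meaningful guard. No variance estimation is provided — downstream
inference uses the exact test on counts, not dS standard errors.

Amino-acid distances use the Poisson correction d = −ln(1 − p) with pairwise
deletion of columns containing `-` or `X`; pairs with p ≥ 1 or no comparable
columns are NaN and treated as "too divergent" wherever a threshold
comparison occurs.

## Subfamily delineation

`classify.delineate_subfamilies` walks the rooted, outgroup-free tree in
pre-order. At each node, if the clade's divergence statistic is below
`subfamily_threshold` (default 0.3, i.e. 30% amino-acid divergence), the
clade is emitted whole and not descended into; otherwise recursion continues
and isolated leaves become monotypic subfamilies. Emitted subfamilies are
therefore maximal reciprocally monophyletic groups. The statistic defaults
to the **mean** pairwise Poisson distance within the clade — summary tables
of between-group distances are conventionally means, and monophyly (not
distance alone) is what separates adjacent groups — with max-pairwise
available as a strict mode. Polytomy children are visited in input order, so
numbering is deterministic for a fixed input file. Rooting places the root
at the midpoint of the outgroup leaf's branch.

## The transfer test

For every unordered cross-species TE copy pair and every host gene with
orthologs in both species, NG86 counts of the TE pair and the gene pair form
the contingency table ((Sd_te, S_te − Sd_te), (Sd_gene, S_gene − Sd_gene)).
Fractional NG counts are rounded half-away-from-zero; the one-tailed
Fisher's exact p-value is the hypergeometric tail P(X ≤ Sd_te) with margins
fixed (alternative: the TE has proportionally fewer synonymous
differences). A comparison is flagged iff p < α **and** dS_te < dS_gene.
No multiple-testing correction is applied by default — the scan is a
screening device and per-comparison p-values are reported so any correction
can be applied downstream. Same-species pairs are skipped; comparisons with
an undefined dS on either side are skipped and counted.

Divergence dating: T = dS / (2r) by default (a pairwise dS is accumulated
along two lineages), with a per-lineage-off switch giving T = dS / r; the
default r is 0.016 synonymous substitutions/site/Myr per lineage.

## The simulator

`synthetic` generates data with exactly the structure the analysis assumes.
Species trees are pure-birth (Yule) topologies rescaled to a requested
root-to-tip depth (default 35 Myr — a Drosophilidae-scale radiation), so the
trees are ultrametric with branch lengths in Myr. Sequences evolve by an
accept/reject codon process: single-nucleotide proposals arrive as a Poisson
process at 3·C·r proposals per Myr for C codons, which makes the accepted
synonymous substitution rate exactly r per synonymous site regardless of
composition; synonymous proposals are always accepted, nonsynonymous ones
with probability ω (default 0.1, strong purifying selection appropriate for
a functional RT domain), and proposals creating stops are rejected. Host
genes evolve strictly vertically, one ortholog per species. TE copies evolve
vertically too, except that each transfer event copies the donor lineage's
sequence state at the event time into the recipient, where it evolves
independently to the present. Extra within-species copies (optional)
duplicate at a fixed age (default 1 Mya) on the terminal branch. Event times
must fall within both species' terminal branches, the conservative reading
of "contemporaneous lineages". The true copy genealogy is emitted as newick
(`true_te_tree`) alongside the sequences and the event table, and every
output is byte-deterministic for a fixed seed (per-branch RNG streams keyed
by a preorder node index).

What the simulator does **not** emulate: indels (the statistics operate on
gap-resolved codon alignments, so a substitution-only process keeps every
stage exercisable while avoiding an arbitrary alignment step), codon-usage
bias, rate variation across sites or lineages, copy-number dynamics, and
ancestral polymorphism. Passing tests therefore demonstrate correctness of
the statistical chain under its own model assumptions, not robustness to
alignment error or rate heterogeneity in real data.

Defaults of 300 codons mirror RT-domain fragment sizes (~900 bp); at this
length a 1.5-Mya transfer corresponds to roughly 10 expected synonymous
differences, so recovered transfer ages carry a sampling standard deviation
of roughly 0.45 Myr per pair — visible in single worked examples and
averaged away over replicates.

## Verification experiments

The acceptance script and `tests/test_acceptance.py` recompute, from
scratch:

- **Scan-summary arithmetic**: the per-gene percentage of significant
  comparisons from the published comparison counts (96/4367, 266/4370,
  207/4558 → 2.2%, 6.1%, 4.5%).
- **Oracle equivalences**: NG86 counting vs an explicit pathway-recursion
  oracle (1,000 random codon pairs, 1e-12); the Fisher p-value vs exhaustive
  fixed-margin enumeration (every 2×2 table with row totals ≤ 30);
  delineation vs an exhaustive maximal-clade search (200 random 8-leaf
  trees).
- **Type-I calibration**: 500 vertical-only datasets (8 species, 35 Myr
  deep, 300 codons), one cross-species TE pair vs one gene each — one test
  per dataset so the tests are independent, as the binomial reference
  interval assumes. The flag rate at α = 0.05 must lie in the exact binomial
  99% interval around 0.05; observed rates run slightly conservative
  (~3–4%), as expected for an exact conditional test.
- **Power and recovery**: 100 datasets with one transfer at 1.5 Mya between
  species diverged 20 Mya; the transferred pair must be flagged for all
  three genes in ≥ 90% of replicates (observed: all), and the mean recovered
  age must be within 1.5 ± 0.45 Myr.
- **Clock arithmetic**: dS = 0.048 → 1.5 Myr, dS = 0.04 → 1.25 Myr at
  r = 0.016.
- **Screening boundaries**: score-50 and E-value-1e-5 hits excluded, 299 bp
  homology withdrawn vs 300 bp kept, same-species-only merging.

Problem sizes (500/100/200 replicates, 300 codons, margins ≤ 30) are the
package's chosen verification scale; each experiment completes in seconds on
one core.

## Known limitations

- The headline counts of the empirical study this pipeline mirrors
  (sequence tallies, 20 subfamilies, per-gene comparison counts) depend on
  genome-database downloads and cannot be recomputed from code alone; the
  package verifies the computational chain, not the data acquisition.
- Whether the subfamily criterion should use mean or maximum within-clade
  divergence is genuinely open; both are provided, mean is the default
  (documented above).
- The dS-contrast test detects transfers only when they are recent relative
  to host divergence; transfers between recently diverged hosts have little
  power, and saturation (pS ≥ 3/4) removes the most divergent pairs from
  testing entirely.
- The Fisher test conditions on the synonymous-site totals of the specific
  pair of alignments; heterogeneity of synonymous rates between a TE and a
  host gene (e.g. codon-bias differences) would violate the null even under
  vertical transmission. Using three genes and requiring agreement
  mitigates, but does not remove, this.
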
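# Methods

This note records the models, conventions and design choices behind
`convscan`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, and where the genuinely open choices
were resolved.

## Substitution model and likelihoods

Amino-acid evolution is modelled as a reversible continuous-time Markov
chain. An empirical exchangeability matrix *S* (symmetric, non-negative
off-diagonal) and stationary frequencies π define the generator
Q_ij = S_ij π_j (i ≠ j), rows summing to zero, normalised so that
−Σ_i π_i Q_ii = 1 — branch lengths are therefore expected substitutions per
site. LG, WAG and JTT are shipped as PAML-format `.dat` text files
(lower-triangle exchangeabilities plus frequencies); the loader also accepts
any user-supplied file in that format, an alignment-derived "+F" frequency
override, and arbitrary state alphabets (the test suite uses two-state
models extensively because they admit exhaustive enumeration).

Transition matrices P(t) = exp(Qt) come from the symmetric
eigendecomposition of diag(π)^{1/2} Q diag(π)^{−1/2}, exact for reversible
Q. Entries that round below zero by < 1e-9 are clipped and rows
renormalised; anything worse raises. Site likelihoods use the pruning
(sum-product) algorithm with per-node, per-site rescaling, so deep trees do
not underflow. Gaps, `X` and `*` at tips are treated as uninformative
(partial vector of ones).

Rate heterogeneity is an optional mean-one discrete gamma (equal-weight
quantile bins, category means in closed form); it is **off by default**
because the convergence scan is defined on reconstructed states, not on
rate estimates, and a rate model would be an additional assumption the
scan does not need. When enabled, site likelihoods are category means and
posteriors are category mixtures weighted by per-category site likelihoods.

A global branch-length multiplier can be fitted by bounded 1-D maximisation
of the total log-likelihood (`fit_branch_scale`) for user trees whose
lengths are not in substitution units; an alignment without variable sites
returns 1.0 with a warning (the likelihood is flat-to-decreasing in the
multiplier there).

## Marginal ancestral reconstruction

For every internal node and site the exact posterior over states given all
tip data is computed by an inside–outside pass: inside partials from
pruning, outside partials propagated root-ward from the stationary prior,
their product normalised per site. MAP states are recorded with their
posterior; ties (within 1e-9) are broken lexicographically by one-letter
code *and flagged*, and tied reconstructions disqualify the branch in the
scan by default — deterministic behaviour was preferred over arbitrary tie
resolution. Agreement with brute-force enumeration over all internal-node
assignments is part of the test suite (≤ 1e-8 absolute).

The reconstruction is marginal, not joint: each node is maximised
independently, which is the appropriate object for per-branch substitution
calls (parent state vs tip state) and matches standard practice for
convergence scans.

## The identical-substitution scan

A substitution is assessed on terminal foreground branches only: the
reconstructed MAP state of the tip's parent versus the observed tip
residue, requiring the tip residue to be one of the 20 standard amino
acids and the parent's MAP to be untied. For each site and derived amino
acid, the maximal subset (≥ 2) of foreground tips substituting to that
residue is emitted as one record — a three-way hit is not additionally
reported as its three pairs, but the summary table reports both the
"exact subset" and the "at least subset" counting conventions, since both
are in circulation. Records are classed *parallel* (all ancestral states
identical), *convergent* (all pairwise distinct) or *mixed*.

Exclusivity ("the derived residue occurs in no non-foreground taxon") is
evaluated over extant non-foreground tips only, not over reconstructed
outgroup ancestors: taxa are observed, ancestors are estimates whose
confidence would otherwise leak into the rule. At least two non-foreground
tips must carry a non-missing residue at the site for exclusivity to be
assessable (echoing the two-outgroup retention rule); sites failing that
are not called when exclusivity is required. An optional minimum ancestral
posterior (default 0.0, i.e. no confidence gate) filters branches before
subset formation.

Reported coordinates are 1-based columns of the *original* alignment,
recovered through the column map that every masking operation composes.

## Quality control

Filters run in the order of the upstream workflow they mirror:
premature-stop exclusion (CDS level; a single terminal stop is trimmed,
out-of-frame records are removed with reason "frame" rather than raising)
→ short/low-coverage sequence removal (< 20 non-gap residues, < 30%
coverage, alignments dropped below 2 taxa) → conserved-block masking →
≥ 90%-missing removal. Each stage emits an audit log of (sequence, stage,
reason). All filters are idempotent, which the suite checks.

The 90% boundary is read inclusively (missing fraction ≥ 0.90 removes); a
flag flips it to strict. Note an interaction the tests make explicit: a
≥ 90%-missing sequence necessarily also fails the 30%-coverage rule, so
which stage removes it depends on stage order; the audit log records the
stage that fired.

The block masker is a deliberate, documented **dialect** of the classic
conserved-block filter, not a byte-exact re-implementation (the original
program's internal tie-breaking is unpublished): a column's conservation is
the count of its majority residue, compared against b1 = ⌊0.75·n⌋+1
(conserved) and b2 = ⌈0.85·n⌉ (highly conserved); a column with gaps in
more than ⌊n/2⌋ sequences is never conserved (gap mode "half"); runs of
more than b3 = 2 contiguous nonconserved columns are rejected; remaining
segments are trimmed to highly-conserved anchors at both flanks; blocks
shorter than b4 = 5 are discarded. The dialect is deterministic and
idempotent, and preserves the published parameter semantics.

Backtranslation maps each amino-acid column to its source codon (gap →
`---`), requiring the CDS translation to equal the ungapped row and naming
the first mismatching position otherwise. It therefore applies *before*
masking, or after it with a correspondingly trimmed CDS; the commutation of
the two routes is a tested property.

## Ortholog delineation

Gene trees are taken as rooted as read (an unstated upstream rooting
protocol cannot be reconstructed; trees from rooted pipelines pass through
unchanged). The tree is scanned root-ward for maximal clades with support
≥ 0.95 containing ≥ 4 species, where same-species tips are admissible only
if monophyletic (in-paralogs), collapsing to one operational unit
represented by the longest sequence (falling back to the lexicographically
smallest id without length information). Unlabelled nodes count as support
0 and cannot anchor a clade — the conservative reading of a support
threshold. A qualifying clade nested in a larger qualifying clade is
absorbed by the larger one, so returned sets are leaf-disjoint. Single-copy
selection then requires exactly one copy per target species and ≥ 2
distinct outgroup species. Every rule here is cross-checked against a
brute-force enumerator of all clades on random gene trees.

## Statistics

The branch-site LRT statistic 2ΔlnL is tested against the boundary null:
an equal mixture of a point mass at zero and χ²₁, so p = 1 at 0 and
p = ½·Pr(χ²₁ ≥ x) otherwise. Small negative statistics (optimiser noise in
external fits) are clamped to zero with a warning. Multiple testing uses
Benjamini–Hochberg step-up q-values (via statsmodels) at FDR 0.05; BH is
the assumed procedure where the upstream description says only "FDR".
Enrichment is the classical hypergeometric upper tail against a custom
background (the single-copy gene universe), with BH across terms; no
GO-graph decorrelation is attempted and results should be labelled
"classical" accordingly. Term-to-gene maps are taken as given — ancestor
propagation in an ontology is the caller's responsibility.

## Synthetic data and the neutral null

The simulator draws root states from π and evolves each branch by P(Qt),
returning tips plus the full true node labelling; all randomness flows from
one integer seed, with per-replicate/per-orthogroup streams derived as
seed + index so any subset of a run reproduces in isolation. The default
topology places three foreground taxa in three separate clades with six
outgroups — one adapted lineage per order, as in the comparative design the
package targets — with branch lengths of order 0.1 substitutions/site.

Planting overwrites foreground tips with the derived residue at chosen
sites, verifying the *true* parent states satisfy the requested mode
(identical for parallel, pairwise distinct for convergent; a violating site
is re-drawn). Outgroup tips carrying the derived residue at a planted site
are resampled from π excluding it, so planted sites are exclusive by
construction; a flag plants deliberate outgroup sharing for false-positive
accounting. Planting edits tips only — ancestral truth refers to the
pre-edit simulation, since planting intentionally breaks the generative
model locally. Contaminant injection (short sequences, ≥ 90% gap flooding,
internal stop codons, in-paralog grafts into trees) carries a manifest
against which filter output is compared exactly.

The neutral null distribution runs simulate → reconstruct → scan per
replicate and returns the count distribution; an observed count's
empirical p is the fraction of replicates at least as large. On
configurations small enough to enumerate (the tests use 4 taxa × 2
states), the Monte-Carlo mean is checked against the exact expectation
obtained by summing, over every tip pattern, pattern probability × scan
outcome. This is the quantitative form of the standard caveat that
stochastic convergence is common enough that raw counts must be calibrated
before interpretation.

What the simulator does **not** emulate: indels (gaps appear only via
contaminant injection), among-site rate variation by default, codon-level
structure, selection, or alignment error. Passing tests therefore
demonstrate correctness of the machinery under the stated model, not
robustness to misalignment or model violation on real genomes.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small configurations chosen so
that exhaustive oracles remain exact: two-state models for pattern
enumeration, trees of 4–12 leaves for brute-force clade and posterior
checks, 9 taxa × 200 sites for planted-recovery runs, 2,000 replicates ×
100 sites for null calibration. Tolerances: pruning vs enumeration 1e-10
relative; posteriors 1e-8 absolute; frequency/normalisation invariants
1e-10–1e-12; `.dat` frequency vectors are renormalised when they miss 1 by
≤ 1e-4 (published files routinely do). MAP ties use a 1e-9 posterior
window. The pipeline's outputs are byte-deterministic under a fixed config
and seed.

## Known limitations

- Exclusivity ignores reconstructed outgroup ancestors (by design; see
  above) — a derived residue present in an outgroup ancestor but lost in
  all sampled outgroup tips will not block a call.
- Internal foreground branches are out of scope; the scan targets
  species-level (terminal-branch) convergence.
- The block masker is a dialect; column-level agreement with the original
  program on real data is expected to be close but is not guaranteed.
- Branch-site model fitting, tree inference, alignment computation and
  orthogroup graph clustering are external: the package consumes their
  outputs (trees, alignments, count tables, lnL pairs) and never re-runs
  them.
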
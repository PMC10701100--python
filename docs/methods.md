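# Methods

## Coordinates and formats

All residue coordinates are 1-based inclusive, matching protein variant
nomenclature (T368M means the 368th residue). Sequences are FASTA;
mutations, PTM sites, per-residue tracks, drug responses, motif
definitions, and all outputs are tab-separated UTF-8 with a header row and
`#` comments. Loaders validate rather than coerce: a PTM site on the wrong
residue class or a track of the wrong length is a load error, while
individually implausible mutation rows (reference mismatch, synonymous,
out of bounds) are dropped with per-reason counts so that nothing
disappears silently. The unknown residue `X` is allowed in sequences but
never satisfies a motif literal or class — only a wildcard, on the
reasoning that a wildcard means "any residue" and an unknown residue is
some residue.

## Motif grammar and scanning

Degron consensus patterns use a deliberately minimal ELM-like grammar —
literals, `x`/`.` wildcards, `[...]`/`[^...]` classes, and bounded
repetition `{m,n}` with n ≤ 10 — rather than full regular expressions, so
pattern files stay auditable. `x` is normalised to the wildcard token at
compile time, and every motif must be able to match at least 3 residues.
Scanning reports one greedy-longest match per (motif, start offset);
overlapping placements are all kept. With `internal_only` (the default in
the CLI), matches touching the first or last residue are discarded,
restricting analysis to internal degrons; terminal (N-/C-end) degron
classes are out of scope throughout.

The scanner is verified against an independent token-walking oracle that
tests the pattern at every offset with explicit descending-order
backtracking over repetition counts.

As a false-positive diagnostic, the Pearson correlation between
per-protein match count and protein length is computed before and after
classifier filtering; chance matches accumulate with length, genuine
degrons need not, so effective filtering lowers the correlation. Proteins
with zero matches are included at count 0 — dropping them would bias the
diagnostic toward its own conclusion.

## Feature construction

Each candidate span is summarised into a 13-dimensional vector: means of
the per-residue tracks (disorder, accessibility, coil/helix/sheet,
rigidity, stabilisation, domain flag) over the span; a conservation
contrast (span mean minus the mean over the two ±`flank` windows, default
flank 11, clipped at termini — positive means the candidate is more
conserved than its neighbourhood); phosphorylation and ubiquitination
site counts in the flanked window; and the count of and minimum distance
to flanking lysines (potential ubiquitin acceptors). When no flank lysine
exists the distance is conventionally 0, with the count doubling as the
presence flag. Structural and evolutionary tracks are *inputs*: the
toolkit does not bundle any external predictor, and a missing track is
imputed with a supplied (typically proteome-wide) mean and the vector
flagged, so downstream models can exclude imputed rows.

Background peptides for training are drawn length-matched on the same
substrate proteins, uniformly over placements that overlap no annotated
degron of that protein; when too few placements exist, fewer peptides are
returned with a warning, never an overlapping one.

For positional amino-acid preference matrices (sequence logos), degrons
are unified into fixed-length fragments (default 20) centred on the span
midpoint, with even-length spans rounding the midpoint toward the
N-terminus — stated explicitly because either convention is defensible —
and `X`-padded beyond the termini. Frequency columns exclude `X` mass and
renormalise; a pure-padding column is flagged undefined instead of
propagating NaN.

## The ensemble classifier

Training data are degron-positive versus background feature vectors
(default 1 positive : 10 background; the ratio is configurable because no
canonical value exists). Hyperparameters (tree depth, learning rate,
number of trees, subsample) are selected once by stratified 5-fold
cross-validation over a small declared grid, then 10 gradient-boosted
classifiers are each fit on an independent bootstrap resample — with
replacement, size equal to the full training set (the classical
bootstrap). A candidate's probability is the arithmetic mean of the 10
member scores, making it invariant to member order; the call threshold is
strictly greater than 0.5, including for the embedding fallback. The
training manifest (seed, member seeds, bootstrap indices, chosen
hyperparameters, feature registry) is stored in the model bundle and
suffices to retrain bit-compatibly with the same library versions.
Degenerate inputs error out rather than silently degrade: fewer than 20
rows per class, class imbalance beyond 100:1, single-class labels, or an
all-constant feature.

High-priority ranking marks candidates whose probability exceeds the
lowest probability among verified degrons of the same motif class; a class
with no verified degron cannot anchor the rule, so its candidates stay
non-priority with a warning.

The sequence-only fallback embeds a 50-residue window centred on the
candidate midpoint (`X`-padded at termini) and scores it with a dense head
fixed at 128-ReLU → 64-ReLU → 1-sigmoid, trained with binary cross-entropy
and early stopping on a held-out split. The embedding provider is
injectable; the built-in default is a deterministic per-position
physicochemical encoding (normalised hydropathy, charge, normalised
side-chain volume, hydropathy sign, known-residue indicator, concatenated
over the window plus mean/max pools). It is position-resolved, so motif
placement is learnable, but it is a simple hand-crafted encoding: a
pretrained protein-language-model embedding (e.g. 1,024-dimensional) can
be plugged in through the same interface and should be preferred when
available.

## Mutation categories

A mutation maps to a degron when its position falls in
[start − flank, end + flank] (flank 11, clipped to the protein); a
mutation hitting k degrons yields k annotations, preserving per-record
granularity. Classification applies the first matching rule in a
configurable precedence order; the default puts the PTM-blocking rules
first because they name a specific documented mechanism, but no canonical
tie-break exists, so the order is explicit configuration, logged and
testable — flipping it is one config edit. The PTM-blocking rules accept
annotated sites anywhere in the flanked window, not only inside the
degron; this too is configurable by precedence design. Because a fallback
rule always applies, the five categories partition every mapped pair, and
`category_summary` counts always sum to the number of annotations.

## Impact scores

`score = w_category + w_biochem · mean(|Δhydropathy|/9.0, |Δcharge|/2.0,
|Δvolume|/167.7)`, clamped to [0, 1]; actionable iff score > 0.5
(strict). The three property scales are standard tables shipped in-repo:
Kyte–Doolittle hydropathy, formal side-chain charge at pH 7 (His treated
as neutral), and Zamyatnin side-chain volumes. The default category
weights (0.6 for motif-altering and both PTM-blocking categories, 0.4 for
flanking-lysine substitution, 0.2 for network rewiring, with biochemical
weight 0.4) are **reimplementation defaults**, chosen to respect the
qualitative ordering of the categories; they are not calibrated against
any published weight table, and the whole scheme is config-driven with
validation that the maximum attainable raw score is exactly 1.
Normalisation is therefore by construction, not per-batch min–max, so a
score never depends on what else was scored alongside it.

## Resistance calls

A treatment is a (drug, degron substrate, cancer type) combination,
analysed only when the drug has a target mapping onto a degron substrate.
G1 holds the cohort's cell lines with at least one mutation in any degron
window of the substrate; G2 the rest; the two groups always partition the
cohort. Resistance means the arithmetic mean IC50 of G1 on the linear μM
scale strictly exceeding that of G2 — matching the worked example, where
one mutant line at 31.88 μM against a 3.46 μM wild-type mean is a
9.21-fold shift. `min_group` defaults to 1 so that single-mutant-line
comparisons reproduce; the rule attaches no significance test, and the
test suite documents that under a true fold-change of 1 it flags ≈50% of
treatments. An optional rank-sum p-value column can be requested for
context but never changes the flag. A log-scale mean comparison would be
more robust to IC50 skew; it is deliberately not the default because the
rule is defined on the linear mean.

## Synthetic fixtures

The generators emulate the statistical structure the analysis assumes,
with every planted truth recorded in a manifest so recovery tests read
the manifest rather than re-deriving it:

* proteomes of uniform-random sequences (uniform residue usage keeps
  chance-match rates analyzable; a custom frequency table can be
  supplied), with exactly `round(rate·n)` proteins receiving one
  uniformly instantiated motif implant at a uniform internal position;
* tracks as clipped Gaussians (baselines 0.3–0.5, noise SD 0.1) with a
  configurable additive effect inside implanted spans — the default +0.4
  on disorder, accessibility and conservation produces cleanly separable
  classes, which the recovery studies use as their operating point;
* PTM sites placed per eligible residue with a higher rate near implants
  (default 0.25 vs 0.01 background);
* mutations constructed by inverting the classification rules so the
  intended category is the one the default precedence assigns;
* IC50 tables as lognormal baselines with designated mutant lines
  multiplied by an engineered fold change.

What the fixtures deliberately do not emulate: real residue composition,
correlated track structure along the chain, realistic mutation spectra,
isoform ambiguity, or dose–response curve shape. Passing recovery tests
therefore demonstrates that the machinery is correct and well-calibrated
under its own assumptions, not that the classifier's headline accuracy
transfers to real proteomes, where effect sizes are smaller and features
are correlated.

## Problem sizes and numerical choices

The recovery study runs 200 proteins (lengths 80–400) with 100 implants,
5 background peptides per positive, and a permissive decoy motif to
supply length-dependent chance matches; resistance recovery uses 200
simulated treatments at 5 lines per group. These sizes give stable
statistics while keeping the full suite fast. Rank tests are two-tailed
Mann–Whitney: exact enumeration of all group assignments (correct under
ties) up to a combined n of 12, tie-corrected normal approximation with
continuity correction beyond; the switch point is configurable. Pearson
correlations raise an explicit error on zero-variance input rather than
returning NaN. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; every generator and trainer is a pure
function of (inputs, seed).

## Known limitations

* The degron catalog and trained models here are synthetic-fixture
  artifacts; producing a real proteome-wide catalog requires curated
  degron instances and real structural/evolutionary tracks as inputs.
* "Rigidity" and "stabilization" are registry slots whose definition is
  delegated to the track producer.
* Each protein id is treated as an independent sequence; multi-isoform
  mapping is the caller's responsibility.
* The resistance rule is a raw mean comparison by definition; treat
  single-line calls as hypotheses, not findings.
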
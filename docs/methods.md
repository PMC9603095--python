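# Methods

## Cascade model

`rlpcascade` classifies protein sequences in three gated stages. Stage 1
separates receptor-like-protein (RLP) architectures from the background
proteome; stage 2 separates RLPs from receptor-like kinases (RLKs); stage 3
assigns an RLP subfamily. The positive training class for all three stages
is the *kinase-truncated RLK*: residues 1..(kinase-domain start − 1) of an
RLK that carries a signal peptide and exactly one TM segment. This exploits
the fact that an RLP is, architecturally, an RLK without its kinase domain,
so abundant well-annotated RLKs supply training signal for the scarce,
poorly conserved RLPs. Stage-1 negatives are background sequences split
into three disjoint subsets (3 splits × 6 feature encodings = 18 training
sets); stage 2 uses full-length RLKs as negatives (6 sets); stage 3 labels
the truncations by ectodomain subfamily in 10 subsets (60 sets), with any
class above a 500-member cap independently down-sampled per subset.

### Feature encodings

Six frequency encodings per sequence: amino-acid composition (20),
composition of the N- and C-terminal halves (40; odd lengths give the
N-half the extra residue), overlapping dipeptide (400) and tripeptide
(8000) frequencies, and the frequency of side-chain chemical-property
groups over the full length (CPAASC, 9) and per half (18). Unknown
residues (`X`) are excluded from every numerator and denominator; k-mer
windows containing `X` are skipped and the denominator counts valid
windows only. The 9 property groups (positively/negatively charged, polar
uncharged, aromatic, nonpolar aliphatic, hydrophobic, large volume, large
mass, special) are a standard biochemical grouping chosen to produce the
fixed 9-feature dimensionality; groups overlap, so CPAASC vectors need not
sum to 1. The whole table is configurable if a user prefers a different
grouping.

### Member classifiers and champion selection

The algorithm registry holds AdaBoost, a calibrated linear SVM, gradient
boosting, k-nearest neighbours, linear and quadratic discriminant
analysis, cross-validated logistic regression, and a small feed-forward
network (one hidden layer of 64 units — no deeper architecture is needed
at these feature dimensions). Hyperparameters are scikit-learn defaults,
recorded verbatim in the bundle manifest. Per training set, candidates are
scored by cross-validation on a pooled out-of-fold confusion matrix and
the champion is the best Matthews correlation coefficient (MCC), ties
broken by accuracy then registry order. The default training roster is
(LDA, KNN) with 3-fold selection: both are deterministic and fast, and on
separable composition data additional members do not change the
near-ceiling champion MCC; the full registry and the 10-fold protocol are
a config switch (`algorithms`, `crossval_folds`) and are used by the
`crossval` command. Metrics {ACC, F1, FDR, MCC, precision, sensitivity,
specificity} are computed from the confusion matrix in closed form;
multiclass problems are scored one-vs-rest and macro-averaged
(`metrics_average: micro` switches to pooled counts). Zero denominators
yield 0 with a warning.

### Class balancing

SMOTE brings every class up to the majority count: a synthetic row is
x + u·(x_nn − x) with u ~ U[0,1), x a minority row and x_nn one of its k=5
(or minority−1, if smaller) nearest minority neighbours. Balancing is
applied to training folds only, never to validation folds — balancing
before the split would leak interpolants of validation points into
training. Original rows are never modified.

### Topology gating

External annotations (signal-peptide flag, TM intervals, kinase-domain
interval, as produced by standard predictors and re-expressed as TSV)
always win; absence of a TM segment in external output is treated as
information, not as a gap to fill. The fallback heuristic marks TM
segments as maximal runs covered by a 19-residue Kyte–Doolittle window
with mean hydropathy > 1.6, merging runs separated by < 5 residues and
discarding runs shorter than 15. A signal peptide is an N-terminal
h-region: ≥ 8 contiguous residues starting within the first 30 whose
running mean hydropathy exceeds 1.6, extended over further hydrophobic
residues, ending before position 35 (a run reaching position 35 is taken
to be the first TM helix instead); the cleavage site is the first small
residue (A/G/S) after the h-region. All four thresholds are config keys.
At *training-set construction* an RLK must have a signal peptide and
exactly one TM segment; at *prediction* only TM absence vetoes a receptor
call — characterised RLPs without predicted signal peptides exist, so SP
absence merely lowers the decision probability.

### Bayesian vote combination and decision

Member votes are combined by exact conjugate updates: Beta(α₀+x, β₀+n−x)
for a binary stage with x successes in n votes, Dirichlet(α₀+x) for the
subfamily count vector. Priors default to uniform (Beta(1,1),
Dirichlet(1,…,1)); the update is closed-form, so no sampling enters the
prediction path. An independent random-walk Metropolis sampler (logit /
softmax parametrisation, 10,000 iterations, 2,000 burn-in, 4 chains, the
proposal adapted during burn-in only) is included solely as a numerical
cross-check of the conjugate means; the test suite verifies agreement
within 0.01.

The categorical decision: NRLP if no TM segment or stage-1/stage-2
posterior mean < 0.6; else `Undefined` if the maximum subfamily posterior
mean < 0.7; else that subfamily. The reported stage-2 label is `RLK-like`
when stage 2 fails. The numeric *decision probability* is the mean of a
Beta(a₀ + Σwᵢvᵢ, b₀ + Σwᵢ(1−vᵢ)) posterior over the 5-bit evidence vector
v = (SP, TM, stage-1 pass, stage-2 pass, subfamily pass), with unit
weights and a Jeffreys Beta(½,½) prior. This summary is
implementation-defined: it is monotone in every piece of evidence and is
reported for ranking, while all contractual behaviour rests on the
categorical classification.

With the default member rosters the attainable posterior means are
bounded by the vote counts: 18 unanimous stage-1 votes give 19/20 = 0.95,
6 unanimous stage-2 votes give 7/8 = 0.875, and 60 unanimous subfamily
votes over 16 classes give 61/76 ≈ 0.80 — comfortably above the 0.7
cutoff, but a subfamily needs ≥ 53/60 votes to clear it, so the
`Undefined` class absorbs genuinely ambiguous sequences. The property-group
encodings (9/18 features) cannot separate 16 classes whose signature
residues collide in property space (aspartate- and glutamate-enriched
families both land in the negatively-charged group, for example), so those
members scatter their votes and the affected subfamilies fall to
`Undefined` more often — confident calls remain correct, they are just
rarer for such families.

## Synthetic corpus

The generator emulates the anatomy the cascade assumes, not protein
biophysics. Each of the 16 default subfamily profiles has one enriched
signature residue (30% frequency; the other 19 residues uniform) and a
5-residue consensus motif implanted at a random position with a 10%
per-position substitution rate; ectodomains are 120–300 residues.
RLK-like sequences are SP block (M + charged residue + 12–18 hydrophobic
residues + ASA cleavage zone) + ectodomain + 21-residue hydrophobic TM +
10–30-residue juxtamembrane + a fixed 250-residue synthetic kinase-domain
consensus with 10% substitutions; RLP-like sequences replace the
juxtamembrane+kinase tail with a short (≤ 30) cytoplasmic tail. The kinase
block is a synthetic consensus, not a real kinase profile: its only
contractual role is to make the kinase-bearing and kinase-free
architectures distinguishable and the truncation rule exercisable.
Backgrounds are globular (typical globular residue frequencies, no
SP/TM), secreted (SP only), polytopic (three TM helices) and
uniform-random decoys (lengths 200–600). The default corpus holds 24 RLKs
and 24 RLPs per subfamily and 288 sequences per background group —
3 × 384 backgrounds, exactly supporting the three disjoint stage-1
negative splits. These sizes are the package's study conditions: large
enough that champion MCCs sit near ceiling and the full fit runs in about
a minute on one core, and they are what every test and the acceptance
script use.

What passing on this corpus shows — and does not. Signature-residue
profiles make subfamilies separable by composition almost by
construction; real ectodomain families overlap far more, share homologous
repeats, and carry length/indel structure the i.i.d. sampler lacks.
Passing therefore validates the *pipeline* (feature contracts, set
assembly, fold hygiene, vote combination, decision logic), not
genome-scale accuracy. Conversely the permutation control (champion MCC ≈
0 under shuffled labels) shows the pipeline cannot manufacture signal.

## Numerical and design choices

- Redundancy filtering replaces word-filter clustering heuristics with
  greedy longest-first clustering under exact global alignment (match 1,
  mismatch 0, gap open −10, extend −1; identity = matches / alignment
  columns, keep at ≤ 0.85 identity to everything kept so far; ties on
  length break by id). It is off by default in the training pipeline —
  i.i.d.-sampled synthetic sequences share no identity, so it is an O(n²)
  no-op there — and is enabled by `redundancy_filter: true` for real
  corpora.
- The subfamily scheme is data-driven (`ClassScheme.from_counts`: the 15
  largest subfamilies with ≥ 20 members are named, the rest group to
  `Other-RLP`); `ClassScheme.default()` pins the canonical 15 + 1 labels.
- Stage-2 negatives reuse source proteins of the positives (truncated vs
  full-length), so negative row ids carry an `RLK:` prefix to keep the
  class membership of every row unambiguous.
- Degenerate inputs that cannot be featurised (e.g. shorter than one
  tripeptide window) are reported as NRLP with a warning rather than
  aborting a batch — such sequences are decoys by definition.
- All randomness flows from one seed per entry point, expanded into
  per-component streams; fitted bundles record seeds, algorithms and
  hyperparameters in their manifest.

## Known limitations

- The hydropathy heuristics are deliberately simple stand-ins for HMM
  topology predictors; on real proteomes users should supply external
  annotations (about 9% of uniform-random decoys still show a spurious
  heuristic TM, which is exactly why the stage-1 classifier, not the TM
  gate alone, carries the negative control).
- The decision-probability formula is a documented convention, not an
  estimate of calibration error.
- No orientation (in/out) prediction, no GenBank/EMBL parsing, no
  nucleotide support, and no attempt to reproduce numbers that depend on
  a proprietary-scale training corpus.
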
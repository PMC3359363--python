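# Methods

## Problem and model

An intein insertion site is specified by its +1 residue — the cysteine,
serine or threonine whose side-chain nucleophile initiates splicing — so
every C/S/T position of a host protein whose seven-residue window −3..+4
lies fully inside the sequence is a candidate.  Positions are 1-based
throughout, matching residue naming such as C64 or S158; insertion occurs
between the −1 and +1 residues.  Candidates whose window is clipped by a
terminus are excluded because the cassette encoding (below) is undefined
without all six flanking residues.

Four features of native insertion sites are computed per candidate and
thresholded into calls; a configurable conjunction of calls gives the
combined verdict.

### Conservation rank

From a PSI-BLAST PSSM, the per-position amino-acid probabilities are taken
from the weighted-observed-percentage block (the file's second 20-column
block), divided by 100 and renormalised; an all-zero percentage row is
mapped to the uniform distribution — the maximum-entropy, least-conserved
fallback, so missing profile information can never make a site look
conserved.  Entropy is `S_i = -Σ_j p_ij ln p_ij` in natural log; the base
only rescales entropies and cannot change any rank.  A candidate's
conservation rank is the fraction of the *other* C/S/T candidates of the
same extein with strictly higher entropy, ties counted half, so ranks lie
in [0, 1] with 1 the most conserved.  Mid-ranking of ties keeps the
statistic deterministic and symmetric; the rank is computed over C/S/T
candidates only, not all residues.  Running PSI-BLAST itself is out of
scope: the package consumes the ASCII matrix file, keeping the core free
of network and database dependencies (the documented search settings —
two passes, E-threshold 1e-15 — belong to the profile-generation step a
user runs separately).

### Cassette SVM

The six flanking residues (−3, −2, −1, +2, +3, +4; the +1 identity is
deliberately not encoded) are one-hot encoded into a 120-component binary
vector, blocks in that order, residues alphabetically within a block.  Any
consistent ordering yields an equivalent model; fixing one makes weights
comparable across runs.  An unknown residue (X) leaves its block all-zero
rather than dropping the example, keeping the dimension fixed.

Training uses a linear-kernel soft-margin SVM with positive-class hinge
errors weighted 3× (the cost-factor), compensating the 1:3 imbalance of
one native cassette to three decoys per extein.  The regularisation
constant defaults to `C = 1/mean(‖v‖²)` over the training set — for
complete cassettes `‖v‖² = 6`, so `C = 1/6` — and is exposed as a knob.
The optimisation is delegated to libsvm via scikit-learn's `SVC`; a test
verifies the weighted soft-margin solution against an independently solved
dual quadratic program.  Duplicate native cassettes (identical on the six
encoded positions) are removed before training, keeping the copy on the
longest extein (ties broken by extein id for determinism).

The leave-one-extein-out protocol holds out one extein, trains on all
other exteins' native cassettes plus three freshly drawn decoy cassettes
per extein (uniform, without replacement, from non-native candidates),
scores every candidate of the held-out extein, and records the fraction of
its decoy sites scoring strictly below the native site (ties half).  The
protocol repeats 25 times by default, re-sampling the training decoys each
repeat — the only random element, since the positives are fixed — and
reports the mean.  Decoys are presumed, not proven, negatives: an
unannotated C/S/T site may well support splicing, which bounds the
achievable separation on real data.

### Structural context

*Junction distance.*  Stride/DSSP codes are coarse-grained: H → helix,
E → sheet, T/S/C → loop, G/I/B (3₁₀-helix, π-helix, bridges) and anything
unrecognised → other.  The junction distance of a site is the minimum
sequence separation to a residue of a different helix/sheet/loop group,
scanning outward in both directions; an "other" (or unassigned) residue
terminates the scan in that direction without defining a junction.  Sites
within 2 residues of a helix↔loop (sheet↔loop) contact are binned
AH/L-junction (BS/L-junction); when both junction types are within reach
the nearer wins and an exact tie goes to the sheet junction, the class
enriched at native sites; otherwise sites are mid-helix / mid-sheet /
mid-loop by their own group, and "other"-group sites get the sixth bin.
Distances are reported at the granularity 1, 2, ">2".  Whether the
distance should count to the boundary bond or to the first residue of the
other group is genuinely ambiguous at this granularity; the
residue-separation definition used here is the one consistent with a
minimum value of 1.

*Cβ density.*  Burial is the count of other residues' Cβ atoms within a
closed 8 Å ball of the site's Cβ, with the Cα substituted for glycine
(standard practice) and, with a warning, for any residue whose Cβ is
missing from the coordinates.

*Functional-residue distance.*  Minimum Cα–Cα distance from the site to
annotated active-site residues, dimer-interface residues, or — the form
used by the predictor — the union of both, since either kind of proximity
lets an unspliced intein block function.  An empty annotation set makes
the feature *missing*, never zero.  Structure-to-sequence numbering is
always an explicit offset or map supplied by the caller, never inferred.

*Flexibility.*  Given S aligned trajectory snapshots, each snapshot is
rigid-body superposed (Kabsch, via SVD with reflection excluded) onto the
first, and a site's flexibility is
`rmsd_i = sqrt((1/S) Σ_s ‖x_{i,s} − x_{i,1}‖²)`, the reference term
contributing zero.  Normalising by S−1 instead is available as a flag.
This feature did not discriminate native from background sites and is
reported but not part of the combined rule.

### Cutoffs, ROC and the combined rule

Calls use the operating points from the native-set ROC analysis — distance
< 14.1 Å, SVM score > 0, junction ≤ 2 residues, conservation rank > 0.61 —
with the boundary semantics fixed by how each cutoff is stated (strict
for "closer than", "greater than" and "above", closed for "within").  ROC
curves sweep a cutoff grid (defaults: 0–30 Å by 0.1, −10–10 by 0.01, 0–5
by 1, 0–1 by 0.01, all configurable), classify by the feature's
orientation, and integrate AUC by the trapezoid rule over (FPR, TPR)
anchored at (0,0) and (1,1); a test pins the trapezoid AUC to the
Mann–Whitney pair-counting statistic on data-derived grids.  The reported
operating point maximises Youden's J = TPR − FPR (the point furthest from
the chance diagonal; perpendicular distance is J/√2 with the same argmax),
ties resolved toward the more stringent cutoff.  Rates are printed as
whole percentages; full precision is kept internally.  A missing feature
conservatively fails its call (flagged, never imputed), and the ranked
report orders sites by satisfied calls, then conservation rank — the
strongest single sequence-only predictor in the case study — then
position.

Enrichment statistics use the two-sided Wilcoxon rank-sum test (exact
enumeration for tie-free samples up to n = 20, otherwise the
tie-corrected normal approximation) and Pearson's chi-squared test
without continuity correction.

## Packaged case-study table

The package ships the 20-row XynB xylanase feature table (distance to the
nearest active-site residue, SVM score, junction distance, conservation
rank, experimental splicing outcome for each of 20 C/S/T sites between
residues 64 and 206 of the catalytic domain; 11 sites spliced).  The
loader re-checks the table's internal tallies (row count, splice count,
per-cutoff counts) on every load and raises on any discrepancy rather
than silently correcting.  The table's SVM scores are stored values from
the original screen — the published model is not shipped — so the loader
passes them through; freshly trained models produce their own scores.

## Synthetic data

The single-extein generator (`generate_synthetic_case`) emulates the
inputs the predictor consumes: a sequence whose only C/S/T residues are
one planted site plus a chosen number of decoy sites (spaced ≥ 8 residues
so cassettes stay free of other candidates); a PSSM whose background
columns mix at most 50% one-hot mass into uniform (entropy ≥ ~2 nats)
while the planted column is 97% one-hot (~0.2 nats), guaranteeing the
planted site the best conservation rank; a self-avoiding Cα random walk
(3.8 Å steps, 4 Å clash distance) with pseudo-Cβ atoms 1.53 Å off the
local chain axis; Stride-style codes with a sheet/loop boundary forced one
residue from the planted site; active-site annotations two residues up-
and downstream of it; and snapshot sets that jitter the trace (σ = 0.5 Å)
under random rigid-body motions, exercising the superposition path.  All
randomness flows from one seed; regeneration is byte-identical, and the
requested planted profile is re-verified on the output before it is
returned.

The family generator (`generate_extein_set`) plants a shared two-residue
cassette motif (G at −1, P at +2 by default) at the native site of each
extein, which is what the cassette SVM is designed to detect.  The
label-shuffled control moves each native label to a random decoy while
leaving the motif in place, so a model trained on shuffled labels sees
only noise.

What passing these benchmarks does and does not show: synthetic cassettes
carry a clean, fully penetrant motif on an i.i.d. background, so the
LOOCV benchmark demonstrates the protocol's correctness (near-1 mean
native rank with signal, chance-level ~0.5 without), not the accuracy
attainable on curated intein databases, where motifs are soft, decoy
labels are noisy, and homology links exteins.  Likewise the random-walk
"structures" have realistic local geometry but no tertiary fold, so
structural features are exercised numerically, not biophysically.

## Problem sizes and numerical choices

The planted-motif benchmark uses 15 exteins × 12 candidate sites with 5
decoy-resampling repeats per held-out extein, averaged over 50 seeds —
sizes chosen to give the mean-rank statistics comfortable margins (s.e.
of the 50-seed mean ≈ 0.01) at desk scale.  PSSM rows must sum to 1
within 1e-9 at construction (no silent renormalisation downstream);
entropy treats 0·ln 0 as 0; superposition requires ≥ 3 non-collinear
reference atoms and refuses reflections; libsvm tolerance is 1e-6, at
which training is deterministic and order-invariant to ~1e-6 in scores.
Seeds are accepted everywhere randomness exists.

## Known limitations

- The native-set results (AUCs of the four features on hundreds of
  exteins, mean native conservation rank, mean distances, enrichment
  p-values) require a database-wide PSI-BLAST and homology-modelling
  pipeline and are not recomputed here; the package validates its
  operations against oracles and reproduces the desk-scale XynB case
  study exactly.
- Active-site and dimer-interface annotations, secondary-structure
  assignments and PSSMs are inputs; the package does not mine feature
  tables, run Stride, or search sequence databases.
- The cassette SVM treats decoy sites as negatives by construction; the
  XynB screen itself shows unannotated sites can splice, so scores near
  the boundary should be read as uncertain.
- Junction distances inherit the coarse 1/2/">2" granularity; two
  conventions for counting to a boundary differ by one residue and cannot
  be distinguished at that granularity.
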
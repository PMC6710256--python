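# Methods

`sspred` is a trainable, desk-scale implementation of profile-based protein
secondary-structure (SS) prediction with cascaded bidirectional-recurrent and
convolutional networks, together with the input encodings, training regime,
evaluation scores and synthetic data needed to exercise every stage without
external databases or alignment tools.

## Problem and labels

Each residue of a protein chain carries one of eight DSSP states
(H α-helix, G 3₁₀-helix, I π-helix, E strand, B bridge, T turn, S bend,
C other).  The 3-state problem merges {H,G,I}→helix, {E,B}→sheet and the
rest→coil; a second dialect (`g_to_coil`), used by some benchmark sets,
assigns G to coil instead.  Both mappings are explicit parameters
throughout.  Unassigned DSSP characters (blank, `-`, `~`, `.`) are
normalized to C on read.

## Input encodings

Per-residue inputs come in the widths 20/22/25/44/47:

* **one-hot (20)** — standard residues as unit vectors; the six
  non-standard codes (B, J, O, U, Z, X) as zero vectors;
* **plain profile (22)** — per alignment column, 20 standard-residue
  frequencies plus one pooled non-standard frequency, normalized over
  non-gap characters, and an independently normalized gap frequency.
  Alignments are query-anchored and the ungapped query is always included
  as the first row, so no column is empty;
* **weighted profile (22)** — each alignment row is weighted by
  `W_seq = Σ_n −log f[aa_seq(n)]`, the sum over the row's non-gap positions
  of the negative log relative frequency of its residue in that column.
  Divergent sequences weigh more, flattening (entropy-maximizing) the
  profile.  The log base cancels in the normalization (tested).  Gap rows
  of a sequence that lie outside its aligned span ("external" gaps — the
  maximal gap runs touching the row's first or last position) are excluded
  from both sides of the gap fraction.  If every weight is zero (all rows
  identical) the weights fall back to uniform;
* **clipping** — the component of the query's own residue is overwritten
  with 1 and nothing is renormalized, so the encoding carries the query
  identity *and* the full profile: the pre-clip value is recoverable as
  1 − (sum of the other 20 of the first 21).  Non-standard query residues
  clip the pooled component;
* **combination** — two alignment sources can be merged at the alignment
  level (union of rows, or intersection on ungapped sequence identity) or
  the profile level (componentwise average, or 44-wide concatenation);
* **3-state augmentation (25/47)** — for the 8-state cascade, the 3-state
  ensemble's per-residue distribution is appended to the profile.

The canonical residue order is `ACDEFGHIKLMNPQRSTVWY`.

## Architectures

**Window FFNN.** The baseline reads the symmetric window
`I(n) = v_{n−l} … v_{n+l}` (out-of-range rows are zero), applies 1–3 fully
connected tanh layers and a softmax.  *Incremental deepening* replaces a
converged FFNN's softmax with a fresh hidden+softmax block, trains the new
block with everything below bit-frozen, then lifts the freeze for a brief
end-to-end refinement.

**CBRCNN.** Two cascaded stages, each consisting of:

1. a forward memory chain (size NF) updated left→right by a transition
   network reading `[previous memory, current input]` through two tanh
   hidden layers of size NHF, and an independent backward chain (NB, NHB)
   right→left; both start from zero memories;
2. a 1-D convolution with kernel 2·CoFB+1 (default 7) over the
   concatenated `[forward, backward]` memories into NHY tanh units;
3. a kernel-1 convolution to the class softmax.

Stage 2 repeats the topology at ceil-half sizes.  Its input at position n
is the stage-1 class distribution averaged over Cseg contiguous blocks of
Cwin positions tiled around n (middle block centred on n; for even Cseg
the extra block sits to the right; positions beyond the termini count as
zero rows, i.e. every block divides by Cwin).  The defaults Cseg=15,
Cwin=21 summarize 315 positions per prediction.  The published
hyperparameter table for the deployed ensembles lists Cseg=10, Cwin=7 in
two rows that conflict with the prose description; we follow the prose
(whose kernel-size statement agrees with the table elsewhere) and expose
both via configuration.

The exact wiring of the "two-layered" recurrent cells is not specified by
the source description; among the candidate readings we adopted the one
whose instantiations of the published hyperparameter sets land closest to
the published average free-parameter counts (~39k for 3-state models,
~58k for 8-state; this implementation: 38.7k and 53.3k).  `count_parameters`
reports the exact count for any configuration and is cross-checked against
hand enumeration and checkpoint contents.

A configuration flag (`conv_sees_input`, default off) optionally feeds the
raw input window to the convolution as well; with the recurrent transitions
zeroed this makes the receptive field exactly the conv window, which the
locality test exploits.

Argmax class assignment breaks ties toward the lowest class index
(H before E before C; 8-state order HGIEBTSC).

## Training

Stochastic gradient descent with momentum 0.9.  Gradients are averaged over
the residues of a minibatch of 10 proteins (last partial batch kept); the
protein order is reshuffled each epoch; the learning rate is halved
whenever the training cross-entropy has not improved on its best value for
100 epochs (counter resets on improvement and after each halving; drops
are exactly ×0.5 and the rate never increases).  Weights start from a
symmetric uniform distribution scaled by 1/√fan-in; biases start at zero.
Everything is reproducible bit-for-bit from the training seed; a non-finite
loss aborts with a diagnostic rather than returning a partial model.

For the CBRCNN both stages' softmax outputs are scored against the labels
and the sum of the two cross-entropies is minimized end to end.  The
stage-1 term matters: the only other gradient reaching stage 1 is filtered
through the segment averaging and the stage-1 softmax, and is so weak at
desk scale that training stalls at the uniform output (loss ≈ ln 3) without
direct supervision.  The stage-2 output remains the model's prediction.

The default initial learning rate is 0.01 on the per-residue-averaged
gradient scale; the desk-scale experiments use 0.03 (CBRCNN) and 0.2
(FFNN), chosen by a learning-rate scan for stable convergence — 0.05 and
above can collapse the tanh chains mid-training at momentum 0.9.

**Ensembles.**  Member softmax outputs are averaged componentwise.  The
deployed composition is 7 models per task: 3 trained on each of two
alignment sources plus 1 on their 44-wide concatenation.  The 8-state
cascade augments each member's profile with the 3-state output of the
*matching source group*; the concatenated member receives the average of
all seven 3-state members (the source-matched rule is only defined for the
single-source groups; this extension is configurable).  Refinement —
continuing training from a checkpoint trained on another source — is
`train(init=...)`; cross-validation uses seeded k-fold partitions with
sizes differing by at most one.

## Evaluation

* **Q3/Q8** — per-residue accuracy, pooled over residues ("per AA") or
  averaged per protein; the two differ whenever accuracy correlates with
  length.
* **SOV'99** — segment-level overlap: per class, every overlapping
  (observed, predicted) segment pair contributes
  `len(s1)·(minov+δ)/maxov` with
  `δ = min(maxov−minov, minov, ⌊len(s1)/2⌋, ⌊len(s2)/2⌋)`; the normalizer
  adds `len(s1)` per pair plus unpaired observed segments, and the overall
  score pools numerators and normalizers across classes.
* **refined SOV** — SOV'99's allowance can fully forgive a small end
  deviation: observed `HHH` against predicted `HHE` scores a perfect 100.
  The refined variant removes this: same pair structure, allowance
  `δ = λ·(minov/maxov)·(maxov−minov)` (λ = 1 by default), proportional to
  the overlap ratio and strictly below `maxov−minov` whenever the overlap
  is imperfect.  The defining publication of the refined score was not
  available when this package was written; this is the package's own
  definition, satisfying the documented contract (exactly 100 iff the
  segmentations coincide — verified exhaustively for all 3-class strings up
  to length 6 — and λ→0 recovers the bare overlap ratio).  Values of the
  refined score should be compared only against this definition.
* **significance** — the two-proportion threshold
  `1.96·√(2p(1−p)/n)` in percentage points; at the benchmark operating
  points (p=0.8419, n=651,594) and (p=0.8381, n=497,142) it gives 0.125
  and 0.145.

Both SOV scores are tested against independent brute-force oracles built on
position sets.

## Synthetic data

The generator emulates the statistical structure the method exploits,
without pretending to be real proteins:

* **segments** — a semi-Markov chain over helix/sheet/coil with geometric
  segment lengths (means H:10, E:5, C:6) and class weights 38/22/40%,
  echoing large structure-derived set compositions; the no-self-transition
  visit rates are calibrated numerically so residue-level fractions hit the
  weights.  Within a class, 8-state sub-labels are drawn i.i.d. (e.g. most
  helix residues H, some G, almost no I);
* **emission** — residues are drawn from a per-class propensity table
  (helix formers A/L/M/E/Q/K, sheet formers V/I/F/Y/W/T, coil formers
  G/P/N/D/S at 2.5× preference, normalized);
* **homologs** — per position: gap with the indel rate, else substitution
  with the substitution rate (drawn from the emitting class's propensity
  row), else the query residue.  No insertions are generated, so rows stay
  query-anchored.  Source A (30 homologs, substitution 0.50) emulates a
  deep search full of distant homologs; source B (10 homologs, 0.35) a
  shallower one, making source-combination experiments meaningful.

What this does *not* model: phylogenetic correlation between homologs,
position-specific rate variation, indel blocks, sequence-composition
autocorrelation, and the long-range contact structure of real proteins.
Passing desk-scale tests therefore demonstrates that the machinery learns
profile and context signal of the assumed form, not that it reaches
published accuracies on real data — those require structure-derived
training sets and real alignments, which are out of scope here.

Profile columns average many draws from the emitting class's propensity
row, so they estimate the class far better than a single residue does (the
mutual-information sanity test); this is what makes the published ordering
— constant baselines < sequence-only FFNN < profile-based CBRCNN —
reproducible on synthetic data.  The shipped benchmark uses 200 proteins of
length 50–150 (160 train / 40 test), a small CBRCNN (~5.8k parameters) on
clipped weighted profiles versus a one-hot window FFNN (~6.1k parameters);
these sizes keep the full benchmark around five minutes on one CPU core.

## Numerical and design notes

* Checkpoints are npz containers with a versioned JSON manifest; the
  write→read round trip is bit-exact and truncated or mismatched files are
  rejected whole.
* Degenerate inputs: all-gap homolog rows contribute nothing to profiles
  (the query row keeps every column non-empty); all-identical alignments
  fall back to uniform sequence weights; single-class generator configs
  permit self-transitions.
* A3M lowercase insertion states are deleted to keep query coordinates;
  `.` ≡ `-`; parsing is case-insensitive except in A3M, where case is
  semantic.
* Records with ≥10 consecutive undetermined residues are skipped at
  dataset read time with a warning, mirroring the curation rule used for
  structure-derived sets.
* The flat dataset format (3 lines per protein) is this package's own; the
  layouts of published training sets are not reproduced.
* Validation of probability rows uses 1e-6 tolerance; profile
  normalization is tested at 1e-9.

## Known limitations

* No GPU or parallel training; pure NumPy on one core.
* The cell wiring and the Cseg/Cwin defaults are this package's resolution
  of ambiguities in the source description (see above); the 8-state mean
  parameter count lands ~8% under the published figure under every wiring
  we tried.
* Training at momentum 0.9 is sensitive to the initial learning rate;
  the scheduler only ever lowers the rate, so a too-large initial rate is
  not recovered from.
* Published headline accuracies (e.g. ~84% Q3) are not reproducible at desk
  scale and are not claimed by any test.
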
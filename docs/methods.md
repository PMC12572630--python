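# Methods

`mimiclens` quantifies Batesian mimicry between the five Chinese
subspecies of *Papilio bootes* (mimics) and thirteen *Byasa* species
(models) through two parallel channels: a computer-aided channel built on
image feature vectors and cosine similarity, and a human-perception channel
built on screened Likert questionnaires.  Because the original specimen
photographs and survey respondents are not redistributable, the package
ships a synthetic specimen generator and a respondent simulator that
emulate the study conditions, and every analysis step is exercised end to
end against them.

## Synthetic specimens

`synthetic_wings` renders 256×256 RGB images of spread, dorsal-side
specimens on a paper-white background (channel values ≥ 245).  A
`TaxonTemplate` controls the morphological axes of the real system:

- **hindwing white discal spots** — count 0–4 (the key mimicry trait),
  drawn on a fixed arc through the discal region with rejection sampling so
  spots never overlap; spot diameter is a fraction of hindwing width
  (default 0.15, i.e. ≈10 px);
- **red submarginal marks** (0–7) and an optional red tail spot, with a
  0–1 intensity;
- **ground colour** (RGB, near-black to reddish-brown), **tails**, and
  ellipse-based **wing shape** controls;
- per-parameter **jitter** standard deviations producing intra-taxon
  variability; the jittered integer spot count is a rounded truncated
  normal clamped to [0, 4].

Specimens are bilaterally symmetric; `hindwing_mask` annotates the right
hindwing and the spot counter operates on that single wing, matching how
the trait is scored per wing on real specimens.  Spots render creamy-white
(235, 235, 230): above the counting threshold (all channels ≥ 200) but
below the background tolerance, as on real set specimens.  Counting uses
8-connected component labelling with a minimum area of 0.1 % of the
hindwing; overlapping spots merged into one blob count once, which is the
stated behaviour, not an error.

The builtin 18-taxon system (`taxa.default_templates`) transcribes the
published trait structure: four-spotted western taxa (*mindoni*,
*parcesquamata*; *B. latreillei*, *B. polla*, *B. genestieri*,
*B. nevilli*), spotless northeastern taxa (*dealbatus*; *B. plutonius*,
*B. impediens*, *B. daemonius*, *B. confusus*, ...), and the variable
*B. polyeuctes* and *nigricauda* in between.  Distribution ranges are
condensed to five region labels (Dulongjiang-Irrawaddy, Nujiang-Salween,
Lancang-Mekong/Red River, upper Yangtze, Qinling); two taxa are sympatric
iff their region sets intersect.  What the generator does **not** emulate:
venation, ventral-specific patterns, photographic exposure variation, or
continuous geographic clines — so green tests demonstrate the pipeline's
correctness on controlled pattern variation, not performance on real
photographs.

## Feature extraction

Two pluggable backends map images to fixed-length vectors
(`feature_extraction`):

**Morphometric backend** (deterministic, 58-d): per-channel 16-bin soft
histograms of the specimen silhouette, the hindwing white-spot count,
white-spot and red-mark area fractions, and the 7 Hu moments of the
silhouette.  Three scale choices matter and are deliberate: (1) the white
background is excluded — it carries no signal and otherwise dominates
every cosine; (2) histograms are linearly interpolated ("soft") so a
ground colour sitting near a bin edge does not flip bins under jitter;
(3) histogram blocks are area fractions (each sums to 1), keeping all
blocks at O(1) magnitude so colour composition, the 0–4 spot trait and
coverage fractions all contribute to cosine similarity.

**SwAV-mini backend** (self-supervised): a desk-scale trainer in the style
of swapped-prediction prototype learning.  Each batch yields 2 global
(crop scale 0.6–1.0) and 2 local (0.25–0.5) crops with flips and colour
jitter, resized to 32×32.  The encoder is a frozen random ReLU feature
layer (3072→256) followed by a trainable linear projection (256→128,
L2-normalized); 8 unit-norm prototypes are learned jointly.  Cluster
assignments are balanced by Sinkhorn–Knopp (ε = 0.05, 3 iterations,
targets stop-gradiented) and every view predicts every other global view's
assignment through a temperature-0.1 softmax.  Gradients for the
projection and prototypes are analytic; SGD with learning rate 0.1
(chosen for stable loss descent at this scale), 5 epochs, batch 16.  The
trainer is pure numpy and deterministic per seed.

Either backend can be lifted to the conventional 2048-d interface by a
fixed seeded Gaussian random projection, which approximately preserves
cosine geometry (Johnson–Lindenstrauss); all downstream analysis is
cosine-based, so results are insensitive to this lift.

**Robustness** is implemented as nearest-centroid test accuracy: test
specimens are assigned to the taxon with the closest (cosine) train-set
mean feature, after a taxon-stratified 8:1:1 train/val/test split (floor
rounding, remainder to train).  Note that on the full 18-taxon system this
number is intentionally low (≈ 10–30 %): most spotless *Byasa* models are
near-duplicates of one another *by design* — that is what a mimicry ring
is — so per-specimen classification among them is close to chance, while
the five spot-count classes separate essentially perfectly (≥ 95 % at low
jitter).

## Taxon similarity and flows

For taxa k = 1..K with mean feature vectors f̄_k (`similarity`):

- S_ij = f̄_i·f̄_j / (‖f̄_i‖‖f̄_j‖), the cosine similarity between taxon
  profiles (symmetric, unit diagonal);
- Q_ij = −ln(1 − S_ij), the Sankey flow width in nats.  The natural log is
  used; negative similarities clamp to width 0 (bands cannot be negative)
  and similarities within 1e−6 of 1 are clamped with a warning;
- heatmap ordering by average-linkage agglomeration on distance 1 − S
  (scipy linkage; taxa pre-sorted by name for deterministic tie-breaks);
- flow tables restricted to sympatric mimic–model pairs (current mimicry)
  or all pairs (probing historical, nonsympatric mimicry), exported as TSV
  and as nodes/links JSON for standard Sankey renderers.

## Embedding (SNE)

`embedding` implements conditional stochastic neighbour embedding from
first principles: p_{j|i} ∝ exp(−‖f_i−f_j‖²/2σ_i²) with σ_i calibrated by
bisection until the realized perplexity 2^H(P_i) matches the target
(default min(30, (n−1)/3)) within 1e−5; q_{j|i} ∝ exp(−‖y_i−y_j‖²) with a
fixed unit bandwidth; objective C = Σ_i KL(P_i‖Q_i), minimized by gradient
descent with momentum 0.5→0.8 (switch at iteration 250), 1000 iterations,
d = 3 by default.  The analytic gradient
∂C/∂y_i = 2 Σ_j (p_{j|i} − q_{j|i} + p_{i|j} − q_{i|j})(y_i − y_j) is
verified against central finite differences in the tests.

Numerical choices: the Gaussian low-dimensional kernel makes the repulsive
force grow linearly with the coordinate scale, so *any* fixed learning
rate eventually destabilizes once clusters separate.  The optimizer
therefore uses learning rate 2.0 plus a backtracking safeguard: a step
that would increase C (or underflow an affinity row) is rejected, the step
scale halves and momentum resets; accepted steps slowly regrow the scale.
This makes the KL trace non-increasing by construction while remaining a
faithful gradient method.  Duplicate input points are jittered with a
warning (bisection is otherwise unbounded).  A `student-t` variant
(symmetrized joint affinities, (1+‖·‖²)⁻¹ kernel, as in t-SNE) is
available behind a flag for users who want the conventional modern
embedding; the Gaussian conditional form is the default because it is the
form the flow analysis is defined with.

## Survey channel

`survey` models the questionnaire protocol: testing questions pair each
mimic with model species on a 1–10 scale; every **control set** holds
three questions sharing one designed (low) answer, built from butterfly
pairs that are totally different from both focal groups; **similar sets**
duplicate a testing pair to probe self-consistency.  A simulated cohort
draws honest respondents who answer round(latent + N(0, σ)) clipped to
[1, 10] and answer controls exactly, and careless respondents (Bernoulli
fraction) who break every control set and contradict every similar set;
ground-truth labels are returned so screening can be validated.

Screening codifies the published rules: a response is invalid iff its
three control answers are not all equal, or it contradicts two or more
similar sets.  "Contradiction" is quantified as an answer gap ≥ 4 on the
10-point scale (configurable; the protocol's prose does not quantify it).
Mean scores per pair are computed over valid respondents only.
Demographics (gender, age band, education, familiarity) are generated and
retained in outputs but not used in scoring.

In the pipeline, the cohort's latent similarity for each pair derives from
the distance between the taxa's wing-pattern parameters (0.6 weight on the
spot-count gap, 0.2 each on spot-size and ground-colour gaps, mapped to
[1, 10]), so both channels observe the same underlying morphology through
different noise processes.

## Pipeline and reproducibility

`pipeline.run_pipeline` chains the stages from one config and a single
master seed fanned out to named per-stage substreams
(`numpy.random.SeedSequence`).  Every tabular artifact embeds a hash of
the analysis parameters in a header comment; reruns with the same config
are byte-identical.  Channel agreement is summarized by the Spearman rank
correlation between computer-channel flow widths and survey mean scores
over common pairs.

Default problem sizes (18 taxa × 5 specimens, 50 respondents, 500
embedding iterations) complete in seconds; the test suite and the
acceptance script use 4–10 specimens per taxon and 10–20 seed replicates,
sizes at which every stochastic check is stable across reruns.

## Known limitations

- The generator's taxa are caricatures on four trait axes; real specimens
  vary continuously and photographs add exposure and pose noise.
- The SwAV-mini encoder is a desk-scale stand-in trained from scratch; it
  demonstrates the algorithmic loop (multi-crop, balanced assignment,
  swapped prediction), not ImageNet-scale representation quality.
- Survey simulation assumes a shared latent similarity per pair; real
  respondent heterogeneity (demographic or expertise effects) is not
  modelled, only collected.
- Nearest-centroid "robustness" is one possible reading of a test-set
  performance figure; alternatives (k-NN, linear probe) would give
  different absolute numbers.
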
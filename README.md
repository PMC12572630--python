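# mimiclens

Quantitative assessment of Batesian mimicry between the Tailed Redbreast
*Papilio bootes* and *Byasa* species, combining a computer-aided channel
(image features → taxon similarity) with a human-perception channel
(screened Likert surveys).

Across western China, five *P. bootes* subspecies converge on the
unpalatable *Byasa* species they co-occur with — most visibly in the
number of hindwing white discal spots (0–4).  `mimiclens` turns that
comparison into a reproducible pipeline.  For taxa with mean feature
vectors f̄₁…f̄ₖ it computes

- cosine similarity  S_ij = f̄_i·f̄_j / (‖f̄_i‖‖f̄_j‖),
- Sankey flow widths  Q_ij = −ln(1 − S_ij), filtered to sympatric
  mimic–model pairs (current mimicry) or all pairs (historical mimicry),
- a similarity heatmap ordering by average-linkage clustering on 1 − S,
- a 3-D stochastic neighbour embedding minimizing
  C = Σᵢ KL(Pᵢ‖Qᵢ) with per-point bandwidths calibrated by perplexity
  bisection,

and, in parallel, designs and scores 10-point-scale similarity
questionnaires with the published screening rules (three-question control
sets with one designed answer; responses contradicting two or more sets of
highly similar questions are discarded).  Feature vectors come from a
pluggable extractor: a deterministic morphometric backend or a desk-scale
self-supervised trainer (multi-crop views, Sinkhorn–Knopp-balanced
prototype assignment, swapped-prediction loss).  Because the original
photographs and respondents are private, the package includes a synthetic
specimen generator and a respondent simulator covering the same trait
axes, and validates the whole pipeline against them.

## Worked example

Run both channels on the builtin 18-taxon system (5 mimic subspecies,
13 model species, 5 synthetic specimens each, 50 simulated respondents):

```sh
mimiclens -v run-all --seed 42 --out demo_out
```

```
INFO stage data: 90 images, 18 taxa (2.9s)
INFO stage features: morphometric -> 58 dims, robustness nan (0.5s)
INFO stage similarity: 18 taxa, 32 sympatric flows (0.0s)
INFO stage embedding: n=90, final KL 4.1744 (0.1s)
INFO stage survey: 50 collected, 46 valid (0.1s)
INFO pipeline complete: 18 artifacts (3.6s total)
```

`demo_out/report.json` summarizes the run:

```json
{
 "channel_spearman_rho": 0.819954,
 "n_specimens": 90,
 "n_taxa": 18,
 "survey_collected": 50,
 "survey_valid": 46,
 "final_kl": 4.174357
}
```

`channel_spearman_rho` is the rank agreement between the two channels over
all mimic–model pairs: 0.82 means the computer-derived flows and the
simulated human ratings largely agree on who mimics whom.  The sympatric
flow table (`demo_out/flows_sympatric.tsv`) reads, for example:

```
mimic_taxon         model_taxon    width
P_bootes_mindoni    B_nevilli      6.972
P_bootes_mindoni    B_latreillei   5.193
P_bootes_mindoni    B_polla        5.134
P_bootes_mindoni    B_plutonius    0.267
P_bootes_dealbatus  B_plutonius    4.522
P_bootes_dealbatus  B_polyeuctes   0.646
```

i.e. the four-spotted *mindoni* flows overwhelmingly to the four-spotted
models it co-occurs with (*B. nevilli*, *B. latreillei*, *B. polla*) and
barely at all to the spotless *B. plutonius*, while the spotless
*dealbatus* shows the reverse preference — the geographic spot-matching
pattern the system is known for.  Other artifacts include the S and Q
matrices (CSV), heatmap ordering and PNG, Sankey JSON documents, 3-D
embedding coordinates with the KL trace, and the survey response,
validation and score tables.

The library mirrors the CLI one-to-one (`mimiclens.run_pipeline`,
`cosine_similarity_matrix`, `run_embedding`, `validate_responses`, ...);
see `docs/methods.md` for the model, parameter and design details.

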
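# Methods

## The question and the statistic

Given a family of orthologous proteins, the pipeline asks whether the
ability to form amyloid — operationalized as carrying at least one
high-scoring β-arch (strand–loop–strand) motif inside an intrinsically
disordered region — is conserved across the family, and whether it is
conserved *more strongly than the sequence itself*.

The central quantity is the per-alignment-column **amyloid fraction**: the
fraction of sequences whose residue at that column (where one exists) falls
inside an amyloidogenic region of that sequence. Columns are compared
against the **modal-residue identity**, the fraction of non-gap residues
equal to the column's most common residue. Gap-rich columns carry little
homology signal and are masked, not interpreted.

## Thresholds and comparison conventions

| parameter | default | units | origin |
|---|---|---|---|
| `arch_threshold` | 0.575 | score | predictor's published operating point; comparison is **≥** (configurable to strict) |
| `disorder_cutoff` | 0.3 | score | predictor's published operating point; comparison is **strictly >** ("more than") |
| `overlap_fraction` | 0.5 | fraction of arch residues | "located in an unstructured region" quantified as a majority rule; 1.0 = full containment, ε→0 = any overlap |
| `gap_mask_fraction` | 0.5 | fraction of rows | "a lot of gaps" quantified as a majority rule |
| `conservation_threshold` | 0.7 | amyloid fraction | package convention for "present in almost all sequences" |
| `min_conserved_run` | 5 | columns | suppresses single-column flickers |
| `length_outlier_ratio` | 1.5 | × median length | quantifies "significantly longer" |
| `fragment_min_fraction` | 0.5 | × median length | quantifies "short" for fragment removal |

The first two are inherited from the upstream predictors' documented
operating points; the remaining six quantify rules that are stated only
qualitatively in the protocols this pipeline mirrors, and are this
package's declared conventions. Every output manifest echoes all eight
with their provenance.

Interval semantics everywhere: coordinates are 1-based inclusive; called
region lists are sorted and pairwise disjoint; raising any threshold can
only shrink (never grow) the called set. BED export converts to 0-based
half-open.

## Curation

Filter order is fixed: manual exclusion list → one record per species
(keep the longest, ties to the lexicographically smallest id) → C-terminal
fragments (short **and**, when an alignment is available, first aligned
column in the C-terminal half of the columns; without an alignment the
length rule alone applies, with a warning) → length outliers. Each filter
is **single-pass**: its median is computed once over its own input, before
any drop. This makes the chain deterministic and order-stable; it also
means a second application to an already-filtered set is a no-op under
realistic length distributions but is not guaranteed to be one for
adversarial inputs (re-running the filters after large removals recomputes
the median over the survivors).

## Stand-in scorers

The bundled scorers exist so the pipeline is runnable and testable without
external predictor binaries; they are **not** reimplementations of those
predictors, and their tracks are tagged `standin-simplified`.

* **Arch scanner.** Exhaustive enumeration of strand–loop–strand windows
  (strands 4–9 residues, loops 1–15). Raw score = mean β-arch propensity
  over the two strands − 0.5 per strand proline; normalized with a
  logistic centred at 0.60 with width 0.08. The shipped propensity scale
  (`data/beta_arch_propensity.tsv`) is a synthetic composite — high for
  β-branched hydrophobics, aromatics, Q/N; low for charged residues and
  proline. The constants place poly-Q/poly-N windows (raw 0.80) at ≈ 0.92,
  comfortably above the 0.575 operating point, and poly-E (raw 0.12) near
  0; these calibration anchors are asserted by the test suite.
* **Cumulative track.** The per-residue reduction over arches is
  **max over covering candidates** (0 where uncovered). Max — rather than
  a sum or count — preserves the "at least one arch" semantics of the
  amyloid call; the true reduction used by the external predictor is not
  documented, so this is a declared convention.
* **Disorder profile.** Windowed mean (default window 21, truncated at the
  termini) of a synthetic disorder-propensity scale, min–max rescaled per
  sequence so the 0.3 cutoff is meaningful for an arbitrary scale; a
  compositionally constant sequence rescales to a flat 0.5.

`X` residues take each scale's mean propensity.

## The synthetic family generator

`FamilySpec` defaults define the study conditions: 20 species, 600-residue
ancestor, motifs at (150, length 60) and (320, length 40), background
substitution probability 0.3 per site, motif substitution 0.1 per site
(drawn **within** the aggregation-prone residue class, so propensity
survives where identity does not), indel probability 0.02 per site
(lengths 1–5, insertions and deletions equally likely), 2 species-level
duplicates, 1 C-terminal fragment (last 30% of the protein), 1 over-long
outlier (an internal disordered expansion of 80% of the ancestral length,
placed between the ordered N-terminal stub and the first motif so the
alignment's terminal structure stays honest). The background alphabet is
disorder-biased (G/S/Q/N/E/K/P-heavy) with FG dipeptides every 25 residues
outside motifs; motifs draw from a Q/N/hydrophobic class. Motif placement
echoes the scale of real nucleoporin findings (a main amyloidogenic
fragment of roughly 60 residues in the 150–210 range of a ~600-residue
protein).

Descent is a **star phylogeny** — independent descendants of one ancestor.
That is sufficient for column statistics (which are row-permutation
invariant) and keeps homology bookkeeping exact; it does not model
lineage-correlated substitutions. Indels are forbidden inside motifs so
each truth region stays one contiguous interval; insertions from different
sequences get private (non-homologous) alignment columns. Because every
residue's ancestral coordinate is recorded, the generator emits the *true*
alignment and the exact set of motif-homologous columns.

`simulate_tracks` replaces the stand-in scorers under synthetic
conditions: arch score 0.8 inside truth regions vs 0.3 outside, disorder
0.6 everywhere except an ordered 50-residue N-terminal stub at 0.2, plus
Gaussian noise (sd 0.1) clipped to [0, 1]. The levels straddle the 0.575
and 0.3 operating points by >2 noise SDs on each side, emulating a
predictor that is informative but imperfect.

What passing tests on this generator show — and what they do not: the
pipeline's interval algebra, projection arithmetic, curation rules and
thresholds behave exactly as specified, and the end-to-end chain recovers
implanted signal under realistic noise. They do not validate the stand-in
scorers against real predictors, nor alignment quality (the generator
provides the true alignment; real analyses inherit their aligner's
errors), nor tree-structured evolution.

## Pipeline composition

After curation the surviving rows keep their original alignment columns
(realignment is out of scope); columns left all-gap by the dropped rows
become masked. On synthetic data this also keeps called columns directly
comparable to truth columns. The per-protein amyloid calls of the kept
sequences are projected onto those columns, profiled, and scanned for
conserved runs; each conserved region is also back-projected onto every
member sequence for BED export.

## Determinism and problem sizes

All simulator randomness flows through one `numpy.random.default_rng`
seed, recorded in the run manifest; two runs with the same seed produce
byte-identical text outputs (asserted by test). The replicate analyses in
`scripts/acceptance.py` and the test suite use 20 seeds at the default
family size (24 records × ~600 residues, ~1400 alignment columns), which
the full pipeline processes in well under a second per replicate.

## Known limitations

* The stand-in scorers are propensity heuristics; absolute scores are not
  comparable to any external predictor's, only the pipeline's treatment of
  tracks is.
* Identity is the only sequence-conservation baseline computed; a
  similarity-matrix variant would score conservative substitutions more
  charitably and would shrink the amyloid-vs-identity contrast.
* No statistical test accompanies the contrast; it is reported
  descriptively, per region.
* Fragment detection needs an alignment to distinguish C-terminal from
  N-terminal fragments; without one it degrades to a pure length rule.
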
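# Methods

This note documents the statistical and geometric procedures implemented in
phixlink, the defaults they run with, the behaviour of the synthetic-data
generators used to test them, and the numerical choices made where the
design was genuinely open.

## Quantitative AP-MS enrichment

The enrichment stage operates on a protein × sample intensity matrix with a
group label per sample (missing values are NaN; zeros on the raw scale are
treated as missing, following label-free quantification convention).

1. **Completeness filter.** A protein is retained when it is observed in at
   least `completeness_min` (default 0.8) of the replicates of at least one
   group. Filtering per group, rather than overall, keeps proteins present
   exclusively in the pulldown arm — the biologically interesting case.
2. **Normalization.** Default `log2_median`: log2 transform, then subtract
   each sample's median, removing multiplicative between-sample effects.
   A `glog` option applies the generalized log
   `log2((x + sqrt(x² + c²)) / 2)` with the per-sample offset `c` set to the
   5th percentile of that sample's observed raw intensities, then
   median-centers; this flattens the variance–mean trend of additive +
   multiplicative noise. It is a moment-matching surrogate for a full
   variance-stabilizing fit, not a maximum-likelihood VSN; the exact fit
   used upstream of such datasets is tool-specific, so the simple transform
   is the documented default behaviour here.
3. **Mixed imputation.** A missing cell is *MAR* when its protein has at
   least one observed replicate in the same group, and is replaced by the
   mean of those replicates. Otherwise it is *MNAR* — the protein was below
   the detection limit in that whole group — and is drawn from
   `Normal(m_s − 1.8·s_s, (0.3·s_s)²)`, where `m_s`, `s_s` are the mean and
   SD of the *sample's* observed values (per-sample, not global, so samples
   with different depth get appropriately placed draws). Draws come from
   one seeded generator consumed in protein-major order, so imputation is
   reproducible and independent of row insertion order. A fully observed
   matrix is returned unchanged; a sample with fewer than two observed
   values makes the MNAR SD undefined and is an error.
4. **Testing and calling.** Per protein, a two-tailed Welch *t*-test
   (Welch–Satterthwaite degrees of freedom) of test vs control; when both
   groups are constant and equal the protein is assigned t = 0, p = 1.
   P-values are Benjamini–Hochberg adjusted; the enriched set is
   `log2FC ≥ 2 AND p_adj < 0.05` (depletion is the mirrored call, reported
   separately).

**Statistical behaviour worth knowing.** With three replicates per group —
a common AP-MS design — the Welch approximation is *conservative*: on null
data the raw p < 0.05 rate is ≈ 0.034, not 0.05 (at ten replicates per
group it is nominal). Type-I error is therefore controlled one-sidedly at
small n. The flip side is limited power: with replicate SD 0.5 and a
planted log2 effect of 3 at n = 3, the per-protein p-values center around
4 × 10⁻³, so BH across ~2000 proteins of which only a small fraction are
truly enriched passes few of them (recall near 5 % when 5 % of proteins are
planted). This is a property of the test-plus-correction at that design,
not of the implementation; studies relying on this call either accept high
precision / low recall (the observed regime: empirical FDR ≈ 0 in our
simulations) or increase replication.

## Hierarchical crosslink FDR

Candidate matches are prefiltered on fragment evidence (strictly more than
two fragments carrying non-cleaved crosslinker, and at least five matched
fragments on each peptide), then collapsed to unique residue pairs in
canonical endpoint order (lexicographic by accession then residue), keeping
the best score per pair.

**Estimator.** For reversed-sequence decoy databases, a false match takes
classes TT : TD : DD in 1 : 2 : 1 expectation, so `TD − DD` estimates the
false matches hiding in the TT class and

```
FDR(t) = max(0, TD(t) − DD(t)) / TT(t)        at score ≥ t
```

**Threshold selection.** The score cutoff is chosen by scanning from the
best score downward and growing the accepted set while the running estimate
stays within the target, ignoring the burn-in region `TT < 1/target` where
a single decoy necessarily overshoots the target and the estimator has no
resolution. The naive alternative — the lowest threshold whose estimate is
≤ target anywhere on the curve — systematically selects points where the
estimate dipped below target by chance and is measurably anti-conservative
(realized FDR ≈ 0.021 at nominal 0.02 and ≈ 0.062 at nominal 0.05 over 200
simulated searches); the stopping rule restores calibration (0.0197 and
0.049) at nearly identical acceptance. If a decoy excess at the very top of
the list aborts the scan before anything passes (rare), selection falls
back to the naive rule rather than returning an empty result.

**Hierarchy.** Residue pairs passing the 2 % level are aggregated into PPI
edges (self-links are excluded from edges but kept in residue-pair output);
an edge scores the *sum* of its members' scores, carries the worst decoy
class among members, and the edge set is thresholded the same way at 5 %.
Final outputs are target-only; an inter-protein residue pair is reported
only when its edge passed the PPI level. *Boosting* grid-searches the
residue-pair cutoff over all reachable thresholds to maximize accepted
target PPIs subject to both constraints (a one-dimensional version of the
multi-dimensional boost in dedicated FDR tools).

**Merging.** Datasets merge by canonical residue pair (best score kept,
provenance unioned into a `;`-separated dataset list); the combined PPI FDR
is re-estimated from the pooled TT/TD/DD edge counts of the merged set, not
averaged across runs.

**AP-MS filtering.** Edges whose non-core partners were all called enriched
in the matching AP-MS experiment are retained; core–core edges (between
listed canonical subunits) are exempt. This removes PPI-level false
positives, which concentrate among non-complex proteins.

## Distance restraints on structures and ensembles

Crosslink tables address residues by 1-based position in the full-length
canonical sequence; structures keep author numbering. Each chain assigned
to an accession is globally aligned (free end gaps) against the canonical
sequence; the resulting map sends sequence positions to author residue
numbers. Identity is counted as identical positions divided by the *chain
length* — with free end gaps, a short perfect overlap of an unrelated
sequence would otherwise fake perfect identity — and maps below 0.95
identity are discarded. Chains can also be auto-assigned to the
best-identity sequence when the chain→protein mapping is absent.

A crosslink is measured as the Euclidean Cα–Cα distance minimized over all
chain-copy combinations (all ordered placements for self-links on
multi-copy proteins, intra- and inter-copy; per-copy distances are
retained for ambiguity reporting). The minimum-over-copies convention
treats a crosslink as evidence of proximity *somewhere* in the particle,
which is the correct reading for, e.g., doubly-capped assemblies. A
crosslink is **satisfied** at distance ≤ 27 Å — inclusive, matching the SDA
spacer reach; the threshold is configurable. The three-way distance bands
used for visualization are `< 21.5 Å`, `[21.5, 28.5) Å`, `≥ 28.5 Å`
(lower-inclusive middle band).

Over an ensemble, a crosslink is *ensemble-satisfied* when satisfied on at
least one member; the summary is the fraction of ensemble-satisfied
crosslinks among those mappable on at least one member. Violated crosslinks
sharing a protein pair are clustered by linking two violations when both
endpoint positions lie within a 10-residue window on their respective
proteins; connected components of size ≥ 3 are reported largest-first. The
window and size floor are heuristic knobs (configurable) that operationalize
"co-located violations"; clusters indicate conformations absent from the
ensemble, not errors.

Pseudobond export writes one ChimeraX line per mapped crosslink
(`/<chain>:<res>@CA /<chain>:<res>@CA <color>`) at the minimizing copy
pair; binary coloring is blue/red at the cutoff, banded coloring uses the
band edges. Unmapped crosslinks are skipped and counted.

## Predicted-complex confidence and validation

Per model, confidence is `0.8·ipTM + 0.2·pTM`; a prediction is
high-confidence when the mean over *all* supplied models (typically five)
is strictly greater than 0.65. Crosslink validation maps the observed
restraints onto one model's coordinates with the machinery above;
restraints with an endpoint outside the modeled region (trimmed disordered
tails) are excluded from the denominator and reported separately, so a
"30/31 satisfied" statement always refers to mappable restraints. Ranking
orders by (high-confidence, mean confidence, satisfied fraction), ties
broken lexicographically by pair.

## Synthetic data: what it emulates, and what it does not

- `generate_toy_complex` builds chains as self-avoiding random walks with
  exact 3.8 Å Cα steps (≥ 3.4 Å self-avoidance) docked to share an
  interface (minimum inter-chain distance in (3.4, 10] Å). It reproduces
  the *geometry* a restraint mapper cares about — copies, interfaces,
  author numbering — not protein-like secondary structure or realistic
  packing density.
- `simulate_crosslinks` samples true links uniformly from chemistry-eligible
  pairs (one NHS-reactive side: K/S/T/Y or the N-terminus; one
  diazirine-reactive side: the broad SDA insertion set or a terminus)
  within the cutoff, and false links strictly beyond cutoff + 5 Å — the
  guard band keeps truth labels unambiguous at the threshold. Scores follow
  a right-skewed Gumbel null (location 3, scale 1) and a shifted Gaussian
  signal (mean 8, SD 1.5), chosen once to create realistic overlap; decoys
  are relabeled pairs with null scores, TD : DD at 2 : 1.
- `simulate_candidate_scores` emulates a search at the scale of a real
  crosslinking study (defaults used in calibration: 2,500 true residue
  pairs concentrated on ~300 true PPIs at ~8 pairs each, 15 % false
  targets, decoys at the 1:2:1 false-class expectation), which is what
  makes `E[TD − DD]` equal the number of false targets.
- `simulate_quant_matrix` plants per-protein baselines `Normal(25, 2)` on
  the log2 scale, replicate noise `Normal(0, sd)` (default 0.5), a planted
  log2 effect (default 3) in the test group for a 5 % subset (default
  100/2000 — a realistic enriched fraction for a tagged-complex pulldown),
  uniform MAR masking (default 5 %) and MNAR masking of the lowest-intensity
  5 % of cells, emulating the detection limit. It does not model
  peptide-level effects, shared peptides, or batch structure.

Because the generators are the test bed, passing tests demonstrate
correctness of the *procedures* under the stated noise models; they do not
certify performance on real spectra, real score distributions, or real
structures.

## Numerical choices and degenerate inputs

- Satisfaction cutoff inclusive (≤ 27 Å); band middle lower-inclusive.
- FDR threshold selection: stopping rule with `TT < 1/target` burn-in and
  naive-rule fallback (rationale above); estimator clamped at zero;
  undefined (reported as null) when no targets pass.
- Welch test: both-groups-constant-and-equal → t = 0, p = 1; constant but
  unequal → ±inf, p = 0.
- BH adjustment: standard step-up, capped at 1, original order restored.
- Alignment scoring: match 2, mismatch −1, gap open −5, extend −0.5, free
  end gaps; identity over chain length.
- Structure parsing keeps only residues with a carbon Cα atom, resolves
  altlocs to highest occupancy then first-listed, reads the first model
  only, and drops duplicate/decreasing author numbers within a chain.
- Problem sizes in tests and the acceptance script (100 toy complexes,
  200 calibration seeds, 2000-protein matrices, 10⁵ imputation draws) were
  chosen as the smallest sizes at which the Monte-Carlo error of each
  check is comfortably below its tolerance.

## Known limitations

- Euclidean Cα distances only; solvent-accessible surface distance (SASD)
  is not computed, so buried shortcuts through the protein are not
  penalized.
- Ambiguous diazirine-side localizations are taken at their reported
  position; no expansion to alternative placements.
- The PPI boost is a one-dimensional cutoff search, not the richer
  multi-dimensional boost of dedicated tools.
- Enrichment power at n = 3 with BH across thousands of proteins is low at
  moderate effect sizes (see above); the Welch null is conservative at that
  depth.
- The exact variance-stabilizing normalization used by upstream tools is
  approximated by `glog`/`log2_median`.
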
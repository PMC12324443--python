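# phixlink

Analysis toolkit for in-situ photo-crosslinking mass spectrometry (XL-MS)
of protein complexes, written for structural interactomics studies in which
a tagged assembly (for example the 26S proteasome) is crosslinked in cells
with the heterobifunctional photo-crosslinker SDA, affinity-purified, and
characterized by quantitative AP-MS and crosslinking MS. The package covers
the four computational stages such a study needs after the search engines
have done their work:

1. **AP-MS differential enrichment** (`phixlink.enrichment`) — per-group
   completeness filtering (≥ 80 % of replicates observed in at least one
   group), log2/median or generalized-log normalization, mixed MAR/MNAR
   imputation (group means for values missing at random; draws from a
   down-shifted Gaussian, shift 1.8 SD and width 0.3 SD of the sample's
   observed values, for values missing not at random), a two-tailed Welch
   *t*-test, Benjamini–Hochberg adjustment, and the enrichment call
   |log2FC| ≥ 2 with adjusted p < 0.05.
2. **Hierarchical crosslink FDR** (`phixlink.xlfdr`) — fragment-evidence
   prefiltering (> 2 non-cleaved SDA fragments, ≥ 5 matched fragments per
   peptide), collapse to unique residue pairs, target-decoy FDR with the
   reversed-decoy estimator FDR = max(0, TD − DD)/TT thresholded at 2 % on
   residue pairs and 5 % on protein–protein interaction (PPI) edges, with
   optional PPI boosting, dataset merging with pooled-decoy combined FDR,
   and AP-MS-based filtering of the PPI network.
3. **Distance restraints on ensembles** (`phixlink.restraints`) — crosslink
   endpoints are reconciled with author-numbered chains by global sequence
   alignment; each crosslink is measured as the minimum Cα–Cα Euclidean
   distance over all chain-copy combinations, satisfied at ≤ 27 Å (the SDA
   reach), evaluated per structure and over conformational ensembles
   (satisfied-in-any-state), with detection of co-located clusters of
   overlength crosslinks that signal unmodeled conformations, and ChimeraX
   pseudobond export.
4. **Predicted-complex filtering** (`phixlink.models`) — model confidence
   0.8·ipTM + 0.2·pTM averaged over all models, high-confidence strictly
   above 0.65, and validation of predictions against the observed
   crosslinks.

A seeded synthetic-data module (`phixlink.synthetic`) generates toy
multi-chain complexes, crosslink sets sampled under the SDA side chemistry
with planted false positives and decoys, candidate score tables for FDR
calibration, and quantification matrices with planted fold changes — so
every statistical guarantee of the pipeline is testable at desk scale with
known ground truth.

## Worked example

Mapping 100 simulated crosslinks — 90 formed in conformer A, 10 only
geometrically possible in conformer B — onto one structure versus the
two-state ensemble (`examples/03_restraint_mapping.py`):

```text
satisfied (<= 27 A) on state A alone: 0.90
satisfied on at least one of {A, B}:      1.00
violation cluster: SYNP01–SYNP03, 4 links, spans (1, 6) / (1, 12)
wrote 100 pseudobonds (blue = satisfied, red = violated) for ChimeraX to state_a_pseudobonds.pb
```

Reading: a single structure explains only 90 % of the restraints, and the
violations are not scattered — they cluster between one protein pair in
narrow sequence windows, which is exactly the signature of a second
conformational state; adding that state explains every restraint.

Hierarchical FDR filtering of a simulated candidate table
(`examples/02_crosslink_fdr.py`):

```text
residue-pair level: threshold 4.68, TT/TD/DD = (2545, 127, 77), estimated FDR 0.020
PPI level:          threshold 6.00, TT/TD/DD = (331, 34, 18), estimated FDR 0.048
accepted: 2492 residue pairs in 331 PPIs
realized PPI FDR against ground truth: 0.060
```

TT/TD/DD are the target–target, target–decoy and decoy–decoy counts above
each score threshold; the realized error of the accepted set, measurable
here because the truth is planted, tracks the estimate.

The other examples cover enrichment analysis (`01`), predicted-model
scoring and crosslink validation (`04`) and the end-to-end pipeline with
its YAML run configuration and manifest (`05`). A thin CLI mirrors the
stages:

```bash
phixlink simulate --seed 5 --out-dir suite/
phixlink run-all --config suite/run_config.yaml
phixlink enrich --quant q.tsv --groups g.tsv --control WT --test TAG --scale raw --out res.tsv
phixlink xlfdr --candidates matches.tsv --rp-fdr 0.02 --ppi-fdr 0.05 --out-dir fdr/
```

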
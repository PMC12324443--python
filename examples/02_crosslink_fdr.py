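"""Hierarchical target-decoy FDR filtering of crosslink identifications.

Simulates a candidate-match table emulating a search against a
target+reversed-decoy database (true matches on a set of genuine protein
pairs, false matches and decoys from a shared null score distribution),
then filters to 2 % residue-pair and 5 % PPI FDR and compares the realized
error of the accepted set against ground truth.
"""

from phixlink.synthetic import simulate_candidate_scores
from phixlink.xlfdr import hierarchical_filter, merge_datasets

matches, truth = simulate_candidate_scores(
    n_true_targets=2500, n_false_targets=375, n_decoys=1125, seed=0,
    n_complex_proteins=40, n_background_proteins=400)
result = hierarchical_filter(matches, rp_fdr=0.02, ppi_fdr=0.05)

rp, ppi = result.rp_report, result.ppi_report
print(f"residue-pair level: threshold {rp.threshold_score:.2f}, "
      f"TT/TD/DD = {rp.counts}, estimated FDR {rp.fdr_est:.3f}")
print(f"PPI level:          threshold {ppi.threshold_score:.2f}, "
      f"TT/TD/DD = {ppi.counts}, estimated FDR {ppi.fdr_est:.3f}")
print(f"accepted: {len(result.residue_pairs)} residue pairs in "
      f"{len(result.ppi_edges)} PPIs")

false_ppis = sum(e.pair not in truth.true_ppis for e in result.ppi_edges)
print(f"realized PPI FDR against ground truth: "
      f"{false_ppis / len(result.ppi_edges):.3f}")

# Merging two acquisitions pools their decoy counts for a combined estimate:
merged, combined = merge_datasets([result.residue_pairs,
                                   result.residue_pairs])
print(f"\nmerge of two identical runs: {len(merged)} non-redundant pairs "
      f"(idempotent), combined PPI FDR {combined.fdr_est:.3f}")
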
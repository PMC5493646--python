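"""Generate a four-batch synthetic cohort and remove batch effects with
the two-step SVD eigengene filter.

Prints the within-minus-between batch correlation gap before and after
merging: a large positive gap means samples cluster by batch; a gap near
zero means batches are mixed and biology can dominate.
"""

import numpy as np

from eigensig import SimConfig, generate_batches, merge, sample_correlation_pcs, two_step_merge


def corr_gap(m, labels):
    C = sample_correlation_pcs(m, n_pcs=7).to_numpy()
    lab = np.asarray(labels)
    iu = np.triu_indices(len(lab), 1)
    same = lab[iu[0]] == lab[iu[1]]
    return C[iu][same].mean() - C[iu][~same].mean()


config = SimConfig(seed=0)  # 4 batches x 20 samples, 500 genes, offsets of scale 3
batches, truth = generate_batches(config)

raw = merge(batches)
merged, report = two_step_merge(batches)

print(f"eigengenes removed per batch (l - 1): {[e - 1 for e in report.per_batch_ell]}")
print(f"eigengenes removed after merging:     {report.merged_ell - 1}")
print(f"batch correlation gap, raw merge:     {corr_gap(raw, raw.provenance):+.3f}")
print(f"batch correlation gap, after filter:  {corr_gap(merged, merged.provenance):+.3f}")
print(f"phenotype correlation gap, after:     {corr_gap(merged, merged.metadata['status']):+.3f}")
print()
print("Batch structure dominates the raw concatenation (large first gap);")
print("after the two-step merge the batch gap collapses and samples")
print("correlate by lean/obese status instead.")
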
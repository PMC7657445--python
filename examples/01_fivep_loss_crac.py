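"""Recover a planted loss of 5'-end binding from simulated CRAC libraries.

Builds a toy genome with an rRNA-like background locus, plants a glucose-
starvation-like stress (the 5' occupancy component of every mRNA drops to a
known retention fraction), simulates one sequencing library per condition,
runs preprocessing, alignment and transcript-level quantification, and
compares the recovered median 5' log2 fold change with the planted value.
"""

import numpy as np

from stress5p.experiments import retention_recovery

out = retention_recovery(seed=1, n_reads=25_000)

print("planted retention -> recovered median 5' log2FC (expected log2 retention)")
for retention, median in sorted(out["median_fivep_log2fc"].items()):
    print(f"  {retention:4.2f} -> {median:+.2f}  (expected {np.log2(retention):+.2f})")
drop = out["metagene_fivep_ratio_fold_drop"]
print(f"metagene 5'/downstream mass ratio drops {drop:.1f}-fold at retention 0.1")
print(
    "\nEach recovered value sits close to log2 of the planted retention: the\n"
    "pipeline reads the planted loss of scanning-factor binding at mRNA 5'\n"
    "ends straight out of the sequencing data, and the metagene profile\n"
    "around the start codon collapses accordingly."
)
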
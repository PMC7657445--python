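"""Measure global mRNA decay with a fixed spike-in species.

Simulates two-species RNA-seq (study yeast plus a spike-in at 2% of the
molar input) under planted decay models: a uniform 2-fold depletion, a
heat-shock-like collapse of the ribosomal-protein (RP) and ribosome-
biogenesis (RiBi) regulons (x 1/16), and a cycloheximide-like rescue.
Per-sample scale factors anchored to the constant spike reveal the global
changes that within-sample normalization is blind to.
"""

from stress5p.experiments import spike_recovery

out = spike_recovery(seed=1, n_reads=50_000)

print("spike-in scale factors (reference = control):")
for sample, factor in out["scale_factors"].items():
    print(f"  {sample:13s} {factor:5.3f}")
print(f"uniform 2-fold depletion: adjusted total-mRNA ratio "
      f"{out['adjusted_total_ratio_uniform_half']:.3f} "
      f"(unadjusted {out['unadjusted_total_ratio_uniform_half']:.3f})")
print(f"cycloheximide rescue:     adjusted ratio {out['adjusted_total_ratio_cyh']:.3f}")
print("heat shock, per-regulon median log2 fold change:")
for reg, med in out["regulon_median_log2fc_heat"].items():
    print(f"  {reg:5s} {med:+.2f}")
print(
    "\nWithout the spike anchor the uniform depletion is invisible (ratio\n"
    "~1); with it the planted 0.5 is recovered, and the RP/RiBi regulons\n"
    "show their planted ~16-fold (-4 log2) depletion."
)
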
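"""Read preprocessing accounting and coverage-track summit calling.

Simulates a deliberately messy CRAC library (40% PCR duplicates, 10%
low-complexity contaminants), runs the preprocessing chain, and prints the
per-stage read accounting; then aligns the survivors, builds an RPM-scaled
coverage track and calls the strongest crosslinking summit per transcript.
"""

from stress5p import (
    SimulationConfig,
    align_reads,
    build_toy_genome,
    compute_coverage,
    find_summits,
    make_binding_truth,
    run_preprocess,
    simulate_crac_reads,
)
from stress5p.preprocess import ReadRecord

bundle = build_toy_genome(n_study=4, seed=5)
truth = make_binding_truth(bundle, {"fivep_share": 0.9}, seed=5)
config = SimulationConfig(
    seed=5, n_reads=8_000, pcr_duplication_rate=0.4, contaminant_rate=0.1,
    barcode_table={"control": "GTGAGC"},
)
records, _ = simulate_crac_reads(truth, bundle, "control", config)
reads = [ReadRecord(id=i, sequence=s, qualities=q) for i, s, q in records]
surviving, stats = run_preprocess(reads, {"control": "GTGAGC"})

ss = stats.samples["control"]
print("preprocessing accounting (reads):")
for field in ("demux_assigned", "adapter_trimmed", "discarded_short",
              "duplicates_removed", "entropy_removed", "surviving"):
    print(f"  {field:18s} {getattr(ss, field):6d}")

alns, unmapped = align_reads(surviving["control"], bundle, seed=5)
track = compute_coverage(alns, bundle, normalization="rpm")
print(f"\n{len(alns)} aligned ({unmapped} unmapped); RPM scale {track.scale_factor:.1f}")
print("strongest crosslinking site per transcript (position, RPM height):")
for t in bundle.study_transcripts:
    summit = find_summits(track, t.chrom, t.strand, t.span, top_k=1)[0]
    offset = t.offset_of(summit[0])
    print(f"  {t.id}: transcript offset {offset:4d} (5' region ends at "
          f"{t.fivep_region_len()}), height {summit[1]:.0f}")
print(
    "\nDuplicates collapse to their UMI-distinct molecules, homopolymer\n"
    "contaminants are removed by the entropy filter, and the summits fall\n"
    "inside the 5' region where the factor's occupancy was planted."
)
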
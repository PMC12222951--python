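"""Copy-number estimation and gel quantification.

The ddPCR assay counts 5' junctions per genome (normalized to two RPP30
copies); long-read sequencing tells us what fraction of ddPCR-detectable
integrations are actually full-length, which scales the junction copy
number into a full-length copy number.
"""

from r2scribe import (DdPCRMeasurement, LaneProfile, ddpcr_copies_per_genome,
                      estimate_full_length_copies, percent_processed_bottom,
                      percent_processed_top)

# ddPCR concentrations (copies/uL) from the droplet reader
m = DdPCRMeasurement(target_conc=19.0, rpp30_conc=10.0)
junctions = ddpcr_copies_per_genome(m)
print(f"ddPCR junction copies per genome: {junctions:.1f}")

# long-read counts: 452 of 519 ddPCR-detectable reads were full-length
est = estimate_full_length_copies(junction_copies=junctions,
                                  n_detectable=519, n_full=452)
print(f"full-length copies per genome: "
      f"{est.full_length_copies_per_genome:.4f} (~{est.rounded})")

# gel densitometry of an in-vitro TPRT reaction
lane = LaneProfile(uncleaved=8.0, cleaved=6.0, tprt=84.0, other=2.0)
print(f"top strand processed:    {percent_processed_top(lane):.1f}%")
print(f"bottom strand processed: {percent_processed_bottom(lane):.1f}%")
print("\nThe bottom strand counts both the cleaved band and the TPRT")
print("extension product; template-jumping bands count toward total only.")
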
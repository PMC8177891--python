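"""The closed-form random-placement topology benchmark.

With 8/12/6/6 electrodes in sDH/dDH/IG/VH, the expected share of each
region-pair category under uniform random unit placement is the ratio of the
electrodes represented in that comparison to the 128 represented across all
ten comparisons. These are the percentages an observed connectivity map is
judged against: an excess of within-region connections over the 25% benchmark
indicates spatially structured (non-random) coupling.
"""

import spinefc as sfc

geometry = sfc.default_geometry()
counts = geometry.region_electrode_counts()
print("electrodes per region:", counts,
      f"(denominator {sfc.theoretical_proportions(counts).denominator})")

summary = sfc.theoretical_proportions(counts)
print("\nexpected category percentages under random placement:")
for cat, pct in summary.rounded(1).items():
    marker = "within " if cat in sfc.geometry.WITHIN_CATEGORIES else "between"
    print(f"  {cat:<8} {pct:5.1f}%  ({marker})")
print(f"\nwithin-region total:  {summary.within_total:.1f}%")
print(f"between-region total: {summary.between_total:.1f}%")
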
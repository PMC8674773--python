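"""Band counts, extremes and regional medians on the packaged reference
estimates (per-country natural-food supply, 2004–2013 and 2014–2017).

Each country's period-mean supply is rounded to one decimal and placed
in one of six bands; the counts show how many countries sit below
common intake recommendations.
"""
from vitdsupply import band_counts, extremes, region_summary, round1
from vitdsupply.reference import load_region_map, reference_means

for period in ("2004-2013", "2014-2017"):
    means = reference_means(period, "excl_ohd")
    counts = band_counts(means)
    (lo, lo_c), (hi, hi_c) = extremes(means)
    print(f"{period} (n={len(means)} countries): "
          + ", ".join(f"{b}: {c}" for b, c in counts.items()))
    print(f"  lowest {lo} µg/d ({'/'.join(lo_c)}), "
          f"highest {hi} µg/d ({'/'.join(hi_c)})")

print("\nRegional medians, 2004-2013 (µg/d):")
means = reference_means("2004-2013", "excl_ohd")
for s in region_summary(means, load_region_map()):
    print(f"  {s.region:9s} {round1(s.median):4.1f}  (n={s.n_countries})")
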
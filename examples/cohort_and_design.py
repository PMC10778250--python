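"""Cohort descriptives and imaging bookkeeping of the study design."""

from equilunge import cohort_fixture, descriptive_cohort, imaging_bookkeeping

table = descriptive_cohort(cohort_fixture())
print("Cohort (n = 13):")
for _, row in table.iterrows():
    print(f"  {row['variable']:<12} {row['mean']:7.2f} +/- {row['sd']:.2f}")

counts = imaging_bookkeeping()
print("\nImaging bookkeeping (13 horses x 4 conditions x 2 time points):")
print(f"  visible light: {counts.visible_captured} captured, "
      f"{counts.visible_selected} selected")
print(f"  infrared:      {counts.infrared_captured} captured, "
      f"{counts.infrared_selected} selected")

# Means use the sample SD (n - 1); the selected counts are one image per
# occasion, i.e. one per horse x condition x time point.
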
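"""Scaled-down reference (null) distribution of ring-pair orientations.

Enumerates conformations of two ideal phenylalanine side groups — uniform
random rotations times a translation lattice strictly inside the 7 Å contact
sphere — and prints the orientation-class fractions with and without the
steric ball filter.  At full scale the same computation uses ~8x10^5 sifted
rotation matrices and a 0.5 Å lattice (~10^10 conformations).
"""

from aromstack import bin_fractions, enumerate_histograms, random_rotations, translation_grid

rotations = random_rotations(2000, seed=7)
grid = translation_grid(step=1.0, rmax=7.0)
hist_all, hist_keep = enumerate_histograms(rotations, grid)

print(f"conformations: {hist_all.total} total, {hist_keep.total} non-overlapping "
      f"({100 * hist_keep.total / hist_all.total:.1f}% survive)")
for label in hist_all.class_counts:
    fa = 100 * bin_fractions(hist_all)[label]
    fk = 100 * bin_fractions(hist_keep)[label]
    print(f"  {label:>13s}: {fa:5.1f}%  ->  {fk:5.1f}% after steric filter")

# The parallel class sits near the sine-law limit 1 - cos(15 deg) = 3.4% and
# the perpendicular class near cos(75 deg) = 25.9%; the steric filter removes
# about two thirds of conformations while barely moving these two fractions.
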
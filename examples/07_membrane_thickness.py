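"""Bilayer thickness on a lateral grid and inter-leaflet distances.

A synthetic bilayer with 4 nm headgroup separation, antiphase undulation
and z-noise is gridded 100x100; each cell holds the z-difference of the
laterally nearest headgroups of the two leaflets.
"""

from tcrdyn.membrane import (
    assign_leaflets,
    bilayer_distance_series,
    thickness_comparison,
    thickness_map,
)
from tcrdyn.synthetic import BilayerSpec, make_bilayer

spec = BilayerSpec(
    lx=10.0, ly=10.0, separation=4.0,
    undulation_amplitude=0.3, undulation_wavelength=5.0, phase="anti",
    noise_sigma=0.05, lipids_per_leaflet=1600, n_frames=10,
)
top, ens = make_bilayer(spec, seed=12)

upper, lower = assign_leaflets(ens)
print(f"leaflets: {len(upper)} upper / {len(lower)} lower headgroups")

tm = thickness_map(ens, n_x=100, n_y=100)
print(f"thickness grid 100x100: mean {tm.mean:.3f} nm, "
      f"min {tm.values.min():.3f}, max {tm.values.max():.3f}")
# mean recovers the planted 4 nm; min/max span the antiphase undulation
# envelope 4 +/- 2*0.3 nm plus noise

halves = thickness_comparison(ens)
print(f"half-trajectory means: {halves['first_half_mean']:.3f} vs "
      f"{halves['second_half_mean']:.3f} nm (difference {halves['difference']:+.4f})")
# a stationary membrane shows no drift between trajectory halves

dist = bilayer_distance_series(ens, "upper", "lower")
print(f"min upper-lower headgroup distance, frame 0: "
      f"{dist['min_distance_nm'].iloc[0]:.3f} nm")
# the closest cross-leaflet approach, periodic-image aware
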
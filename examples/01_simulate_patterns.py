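"""Simulate clustered and random membrane point patterns with blinking.

Builds a Thomas-process ground truth, emits a blinking localization table,
and prints the basic bookkeeping a PALM/STORM acquisition would yield.
"""

import smlmq

truth = smlmq.simulate_molecules(
    "clustered",
    field_width_nm=10_000.0,
    field_height_nm=10_000.0,
    molecule_density_um2=100.0,
    parent_density_um2=50.0,
    displacement_scale_nm=25.0,
    seed=1,
)
table = smlmq.simulate_localizations(
    truth, mean_blinks=4.0, precision_sigma_nm=20.0, frames_total=30_000, seed=2
)

print(f"molecules: {len(truth)} in {truth.area_um2:.0f} um^2 "
      f"({len(truth) / truth.area_um2:.0f} /um^2)")
print(f"localizations: {len(table)} "
      f"({len(table) / len(truth):.2f} blinks per molecule on average)")
print(f"mean precision: {table.df['precision_nm'].mean():.1f} nm")
# A molecule blinking B times appears as B localizations scattered by the
# precision, so the localization density overcounts the molecular density
# by the mean blink number.
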
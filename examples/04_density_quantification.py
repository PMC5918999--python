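"""Membrane density quantification: ROI mean-of-means and group statistics.

Simulates control and "transfected" cells (63% denser), quantifies each
with 5 automatically placed ROIs, normalizes to control and runs one-way
ANOVA across the groups.
"""

import numpy as np

import smlmq

groups = {"control": 1.0, "transfected_41h": 1.63}
per_image = {}
for g_idx, (label, rel_density) in enumerate(groups.items()):
    means = []
    for cell in range(6):
        truth = smlmq.simulate_molecules("random", 12_000.0, 12_000.0,
                                         molecule_density_um2=120.0 * rel_density,
                                         seed=100 * g_idx + cell)
        table = smlmq.simulate_localizations(truth, mean_blinks=4.0,
                                             precision_sigma_nm=12.0,
                                             frames_total=30_000,
                                             seed=100 * g_idx + cell + 50)
        rois = smlmq.select_rois(table, seed=cell)
        means.append(smlmq.image_mean_density(table, rois))
    per_image[label] = means

report = smlmq.summarize_groups(per_image, control_label="control")
for row in report.per_group.itertuples():
    print(f"{row.label:>16}: {row.mean_per_um2:7.0f} +/- {row.sem_per_um2:4.0f} "
          f"events/um^2  ({row.percent_of_control:.0f}% of control)")
print(f"one-way ANOVA: F({report.anova_df[0]},{report.anova_df[1]}) = "
      f"{report.anova_F:.1f}, p = {report.anova_p:.2e}")
# Densities are localized events per um^2 (not molecules); with identical
# blinking statistics across groups the percent-of-control ratio is
# unaffected by the overcounting.
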
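"""Potassium-efficiency metrics and group statistics on plant records.

KUpE = plant K / available K, KUE = biomass / available K,
KUtE = biomass / plant K, with KUE = KUpE * KUtE exactly.
"""

import numpy as np

from rhizohair import PlantRecord, k_efficiencies, one_way_anova, two_sample_t

rng = np.random.default_rng(0)


def make_group(treatment, k_level, n=6):
    records = []
    for i in range(n):
        shoot_dw = rng.normal(0.25, 0.03)
        root_dw = rng.normal(0.05, 0.008)
        records.append(PlantRecord(
            plant_id=f"{treatment}_{i}", treatment=treatment,
            root_fw_g=root_dw / 0.05, shoot_fw_g=shoot_dw / 0.10,
            root_dw_g=root_dw, shoot_dw_g=shoot_dw,
            root_k_mmol_per_g_dw=rng.normal(k_level, 0.2),
            shoot_k_mmol_per_g_dw=rng.normal(k_level * 1.2, 0.2),
            available_k_mmol=1.5))
    return records


control = make_group("control", 3.0)
low_k = make_group("low_K", 1.0)

for rec in (control[0], low_k[0]):
    eff = k_efficiencies(rec)
    print(f"{rec.plant_id}: KUpE={eff.kupe:.3f}  KUE={eff.kue:.3f} g/mmol  "
          f"KUtE={eff.kute:.3f} g/mmol  (KUpE*KUtE={eff.kupe * eff.kute:.3f})")

root_k = two_sample_t([r.root_k_mmol_per_g_dw for r in control],
                      [r.root_k_mmol_per_g_dw for r in low_k],
                      labels=("control", "low_K"))
print(f"root K content, control vs low K: t = {root_k.statistic:.2f}, "
      f"p = {root_k.p_value:.2g} [{root_k.code}]")

anova = one_way_anova({
    "control": [k_efficiencies(r).kute for r in control],
    "low_K": [k_efficiencies(r).kute for r in low_k],
})
print(f"KUtE one-way ANOVA: F = {anova.statistic:.2f}, p = {anova.p_value:.2g}, "
      f"letters = {anova.letters}")
# Stars follow * p<0.05, ** p<0.01, *** p<0.005; groups sharing no
# letter differ at alpha = 0.05 (Tukey HSD).
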
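"""Plant-level trait integration and group statistics.

Combines per-plant biomass and tissue K⁺ contents into the three
potassium-efficiency metrics used in nutrient-use physiology,

    KUpE = plant K / available K      (uptake efficiency, dimensionless)
    KUE  = biomass / available K      (use efficiency, g/mmol)
    KUtE = biomass / plant K          (utilization efficiency, g/mmol)

with the exact identity KUE = KUpE × KUtE, and provides the two group
comparisons used for such trait tables: two-tailed Student's t
(pooled variance by default, Welch optional) and one-way ANOVA with a
Tukey-HSD compact letter display.  Significance stars follow the
convention * p<0.05, ** p<0.01, *** p<0.005.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlantRecord",
    "KEfficiencies",
    "GroupComparison",
    "k_efficiencies",
    "allocation_ratios",
    "two_sample_t",
    "one_way_anova",
    "significance_code",
    "compact_letter_display",
    "records_from_csv",
]


@dataclass(frozen=True)
class PlantRecord:
    """One plant's biomass and K⁺ data.

    Masses in g; K contents in mmol per g dry weight; ``available_k_mmol``
    is the K⁺ delivered by the watering solution over the growth period
    (concentration × delivered volume).  ``grain_k_offset_mmol`` can
    subtract the seed's K contribution (at most ~10% of plant K in
    practice); it defaults to 0.
    """

    plant_id: str
    genotype: str = ""
    treatment: str = "control"
    root_fw_g: float = 0.0
    shoot_fw_g: float = 0.0
    root_dw_g: float = 0.0
    shoot_dw_g: float = 0.0
    root_k_mmol_per_g_dw: float = 0.0
    shoot_k_mmol_per_g_dw: float = 0.0
    available_k_mmol: float = 0.0
    grain_k_offset_mmol: float = 0.0

    def __post_init__(self):
        for name in ("root_fw_g", "shoot_fw_g", "root_dw_g", "shoot_dw_g",
                     "root_k_mmol_per_g_dw", "shoot_k_mmol_per_g_dw",
                     "available_k_mmol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.root_dw_g > self.root_fw_g > 0 or self.shoot_dw_g > self.shoot_fw_g > 0:
            raise ValueError("dry weight cannot exceed fresh weight")

    @property
    def biomass_g(self) -> float:
        return self.root_dw_g + self.shoot_dw_g

    @property
    def plant_k_mmol(self) -> float:
        k = (self.root_k_mmol_per_g_dw * self.root_dw_g
             + self.shoot_k_mmol_per_g_dw * self.shoot_dw_g)
        return k - self.grain_k_offset_mmol


@dataclass(frozen=True)
class KEfficiencies:
    kupe: float                 # plant K per available K
    kue: float                  # biomass per available K (g/mmol)
    kute: float | None          # biomass per plant K (g/mmol); None if plant K = 0


def k_efficiencies(record: PlantRecord) -> KEfficiencies:
    """KUpE, KUE and KUtE for one plant.

    Requires ``available_k_mmol > 0``.  When plant K is 0 the
    utilization efficiency is undefined and returned as None; the
    identity KUE = KUpE × KUtE holds exactly otherwise.
    """
    if record.available_k_mmol <= 0:
        raise ValueError("available_k_mmol must be > 0")
    plant_k = record.plant_k_mmol
    kupe = plant_k / record.available_k_mmol
    kue = record.biomass_g / record.available_k_mmol
    kute = record.biomass_g / plant_k if plant_k > 0 else None
    return KEfficiencies(kupe=kupe, kue=kue, kute=kute)


def allocation_ratios(record: PlantRecord) -> dict:
    """Root:shoot dry-weight ratio plus per-organ DW:FW ratios.

    Zero denominators yield NaN rather than raising — trait tables keep
    the row and mark the value missing.
    """
    def safe(a, b):
        return a / b if b > 0 else float("nan")
    return {
        "root_shoot_dw_ratio": safe(record.root_dw_g, record.shoot_dw_g),
        "root_dw_fw_ratio": safe(record.root_dw_g, record.root_fw_g),
        "shoot_dw_fw_ratio": safe(record.shoot_dw_g, record.shoot_fw_g),
    }


def significance_code(p: float) -> str:
    """Star coding: *** p<0.005, ** p<0.01, * p<0.05, else 'ns'."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Result of a t-test or one-way ANOVA on trait groups."""

    labels: list[str]
    n: list[int]
    means: list[float]
    sems: list[float]
    test: str                      # 't' | 'welch-t' | 'one-way ANOVA'
    statistic: float
    p_value: float
    code: str = ""
    letters: dict[str, str] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significance": self.code,
        }
        for lab, n, m, s in zip(self.labels, self.n, self.means, self.sems):
            row[f"mean_{lab}"] = m
            row[f"sem_{lab}"] = s
            row[f"n_{lab}"] = n
            if self.letters:
                row[f"letters_{lab}"] = self.letters.get(lab, "")
        return row


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


def two_sample_t(
    group_a, group_b, labels=("A", "B"), pooled: bool = True
) -> GroupComparison:
    """Two-tailed Student's t-test between two trait groups.

    Pooled-variance (classical Student) by default; ``pooled=False``
    switches to Welch's unequal-variance form.  Each group needs n >= 2.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=pooled)
    t, p = float(t), float(p)
    if np.isnan(p):  # both groups constant and equal
        t, p = 0.0, 1.0
    return GroupComparison(
        labels=list(labels), n=[len(a), len(b)],
        means=[float(a.mean()), float(b.mean())], sems=[_sem(a), _sem(b)],
        test="t" if pooled else "welch-t",
        statistic=t, p_value=p, code=significance_code(p),
    )


def compact_letter_display(labels, p_matrix: np.ndarray, alpha: float = 0.05) -> dict:
    """Assign letters so groups sharing no letter differ at level alpha.

    Standard insert-and-absorb procedure on the pairwise significance
    matrix: start with one letter covering everything, split it wherever
    a significant pair shares a letter, absorb redundant letters.
    """
    k = len(labels)
    cols = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if p_matrix[i, j] < alpha:
                for col in list(cols):
                    if i in col and j in col:
                        cols.remove(col)
                        c1, c2 = col - {j}, col - {i}
                        for c in (c1, c2):
                            if not any(c <= other for other in cols):
                                cols.append(c)
    cols.sort(key=lambda c: min(c))
    out = {lab: "" for lab in labels}
    for letter_i, col in enumerate(cols):
        letter = chr(ord("a") + letter_i)
        for g in sorted(col):
            out[labels[g]] += letter
    return out


def one_way_anova(groups: dict, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA across named groups with a Tukey letter display.

    ``groups`` maps label → 1-D samples (each n >= 2).  F and p come
    from the between/within sums of squares; the compact letter display
    is derived from Tukey-HSD pairwise comparisons at ``alpha``.
    Degenerate all-constant data reports p = 0 when means differ and
    p = 1 when they are all equal.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], float) for g in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    within_var = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    means = [float(a.mean()) for a in arrays]
    if within_var == 0:
        all_equal = max(means) == min(means)
        F = 0.0 if all_equal else float("inf")
        p = 1.0 if all_equal else 0.0
        p_matrix = np.ones((len(arrays), len(arrays)))
        if not all_equal:
            for i in range(len(arrays)):
                for j in range(len(arrays)):
                    if i != j and means[i] != means[j]:
                        p_matrix[i, j] = 0.0
    else:
        F, p = stats.f_oneway(*arrays)
        F, p = float(F), float(p)
        p_matrix = np.asarray(stats.tukey_hsd(*arrays).pvalue)
    letters = compact_letter_display(labels, p_matrix, alpha=alpha)
    return GroupComparison(
        labels=labels, n=[len(a) for a in arrays], means=means,
        sems=[_sem(a) for a in arrays], test="one-way ANOVA",
        statistic=F, p_value=p, code=significance_code(p), letters=letters,
    )


def records_from_csv(path) -> list[PlantRecord]:
    """Load a per-plant trait table (one row per plant) into records."""
    df = pd.read_csv(path)
    fields = {f for f in PlantRecord.__dataclass_fields__}
    records = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if k in fields}
        kwargs["plant_id"] = str(kwargs.get("plant_id", ""))
        records.append(PlantRecord(**kwargs))
    return records


def efficiency_table(records: list[PlantRecord]) -> pd.DataFrame:
    """Per-plant K-efficiency and allocation table."""
    rows = []
    for r in records:
        eff = k_efficiencies(r)
        row = {
            "plant_id": r.plant_id, "genotype": r.genotype,
            "treatment": r.treatment, "biomass_g": r.biomass_g,
            "plant_k_mmol": r.plant_k_mmol,
            "KUpE": eff.kupe, "KUE": eff.kue, "KUtE": eff.kute,
        }
        row.update(allocation_ratios(r))
        rows.append(row)
    return pd.DataFrame(rows)
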
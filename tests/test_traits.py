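"""K-efficiency algebra and group-statistics oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizohair import (
    PlantRecord,
    allocation_ratios,
    compact_letter_display,
    k_efficiencies,
    one_way_anova,
    significance_code,
    two_sample_t,
)

positive = st.floats(0.01, 10.0, allow_nan=False)


def _record(root_dw=0.2, shoot_dw=1.0, root_k=2.0, shoot_k=3.0, avail=5.0,
            root_fw=None, shoot_fw=None):
    return PlantRecord(
        plant_id="p", root_fw_g=root_fw if root_fw is not None else root_dw * 20,
        shoot_fw_g=shoot_fw if shoot_fw is not None else shoot_dw * 10,
        root_dw_g=root_dw, shoot_dw_g=shoot_dw,
        root_k_mmol_per_g_dw=root_k, shoot_k_mmol_per_g_dw=shoot_k,
        available_k_mmol=avail,
    )


class TestKEfficiencies:
    def test_uptake_efficiency_is_one_when_all_available_k_taken(self):
        r = _record(root_dw=1.0, shoot_dw=0.0, root_k=5.0, avail=5.0)
        assert k_efficiencies(r).kupe == pytest.approx(1.0)

    def test_utilization_closed_form(self):
        # biomass 2 g with 1 mmol plant K -> KUtE = 2 g/mmol
        r = _record(root_dw=1.0, shoot_dw=1.0, root_k=0.5, shoot_k=0.5, avail=4.0)
        assert k_efficiencies(r).kute == pytest.approx(2.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(positive, positive, positive, positive, positive)
    def test_kue_identity_to_machine_precision(self, rdw, sdw, rk, sk, avail):
        eff = k_efficiencies(_record(rdw, sdw, rk, sk, avail))
        assert eff.kue == pytest.approx(eff.kupe * eff.kute, rel=1e-12)

    def test_zero_available_k_is_an_error(self):
        with pytest.raises(ValueError):
            k_efficiencies(_record(avail=0.0))

    def test_zero_plant_k_makes_kute_missing(self):
        r = _record(root_k=0.0, shoot_k=0.0)
        assert k_efficiencies(r).kute is None

    def test_dw_cannot_exceed_fw(self):
        with pytest.raises(ValueError):
            PlantRecord(plant_id="x", root_fw_g=0.1, root_dw_g=0.5,
                        shoot_fw_g=1.0, shoot_dw_g=0.2)


class TestAllocation:
    def test_equal_dw_gives_unit_ratio(self):
        r = _record(root_dw=0.4, shoot_dw=0.4)
        assert allocation_ratios(r)["root_shoot_dw_ratio"] == pytest.approx(1.0)

    def test_dw_fw_ratios_match_reference_conversion(self):
        # typical conversions: root DW:FW ~ 5%, shoot ~ 10%
        r = _record(root_dw=0.05, shoot_dw=0.2, root_fw=1.0, shoot_fw=2.0)
        ratios = allocation_ratios(r)
        assert ratios["root_dw_fw_ratio"] == pytest.approx(0.05)
        assert ratios["shoot_dw_fw_ratio"] == pytest.approx(0.10)

    def test_zero_denominators_yield_missing(self):
        r = PlantRecord(plant_id="z")
        assert math.isnan(allocation_ratios(r)["root_shoot_dw_ratio"])


def _pooled_t_oracle(a, b):
    """Textbook pooled-variance Student t with two-tailed p."""
    from scipy.stats import t as t_dist
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def _anova_oracle(groups):
    """Between/within sums of squares F and p."""
    from scipy.stats import f as f_dist
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, f_dist.sf(F, dfb, dfw)


class TestTwoSampleT:
    def test_identical_groups_give_zero_t_unit_p(self):
        g = [1.0, 2.0, 3.0]
        cmp = two_sample_t(g, g)
        assert cmp.statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)
        assert cmp.code == "ns"

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1.3, 9)
        cmp = two_sample_t(a, b)
        t, p = _pooled_t_oracle(a, b)
        assert cmp.statistic == pytest.approx(t, abs=1e-9)
        assert cmp.p_value == pytest.approx(p, abs=1e-9)

    def test_swapping_groups_negates_t_and_preserves_p(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        c1, c2 = two_sample_t(a, b), two_sample_t(b, a)
        assert c1.statistic == pytest.approx(-c2.statistic, abs=1e-12)
        assert c1.p_value == pytest.approx(c2.p_value, abs=1e-12)

    def test_group_sem_is_sd_over_sqrt_n(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        cmp = two_sample_t(a, a + 1)
        assert cmp.sems[0] == pytest.approx(np.std(a, ddof=1) / 2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


@pytest.mark.parametrize("p, code", [
    (0.2, "ns"), (0.049, "*"), (0.02, "*"), (0.009, "**"), (0.003, "***"),
])
def test_significance_star_convention(p, code):
    assert significance_code(p) == code


class TestOneWayAnova:
    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(29)
        groups = {k: rng.normal(mu, 1.0, 9) for k, mu in
                  zip("abc", (0.0, 0.5, 1.2))}
        cmp = one_way_anova(groups)
        F, p = _anova_oracle(list(groups.values()))
        assert cmp.statistic == pytest.approx(F, abs=1e-9)
        assert cmp.p_value == pytest.approx(p, abs=1e-9)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 7), rng.normal(0.6, 1, 10)
        F = one_way_anova({"a": a, "b": b}).statistic
        t = two_sample_t(a, b).statistic
        assert F == pytest.approx(t**2, abs=1e-9)

    def test_identical_constant_groups_share_a_letter(self):
        cmp = one_way_anova({"a": [2.0, 2.0], "b": [2.0, 2.0], "c": [2.0, 2.0]})
        assert cmp.p_value == 1.0
        assert len(set(cmp.letters.values())) == 1

    def test_zero_variance_with_different_means_is_certain(self):
        cmp = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert cmp.p_value == 0.0
        assert cmp.letters["a"] != cmp.letters["b"]

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(8)
        groups = {
            "low": rng.normal(0.0, 0.1, 10),
            "mid": rng.normal(5.0, 0.1, 10),
            "high": rng.normal(10.0, 0.1, 10),
        }
        cmp = one_way_anova(groups)
        assert len({cmp.letters[g] for g in groups}) == 3

    def test_f_invariant_to_shift_and_scale(self):
        rng = np.random.default_rng(31)
        groups = [rng.normal(m, 1, 8) for m in (0, 1, 2)]
        F0 = one_way_anova({str(i): g for i, g in enumerate(groups)}).statistic
        F1 = one_way_anova({str(i): g + 100 for i, g in enumerate(groups)}).statistic
        F2 = one_way_anova({str(i): g * 7.5 for i, g in enumerate(groups)}).statistic
        assert F1 == pytest.approx(F0, rel=1e-9)
        assert F2 == pytest.approx(F0, rel=1e-9)


def test_compact_letter_display_partial_overlap():
    # a != c significant, b overlaps both -> a:'a', b:'ab', c:'b'
    p = np.ones((3, 3))
    p[0, 2] = p[2, 0] = 0.01
    letters = compact_letter_display(["a", "b", "c"], p, alpha=0.05)
    assert set(letters["a"]) & set(letters["c"]) == set()
    assert set(letters["b"]) & set(letters["a"])
    assert set(letters["b"]) & set(letters["c"])


def test_efficiency_table_round_trip(tmp_path):
    import pandas as pd

    from rhizohair.traits import efficiency_table, records_from_csv
    rows = []
    for i in range(4):
        rows.append({
            "plant_id": f"p{i}", "genotype": "g", "treatment": "control",
            "root_fw_g": 1.0, "shoot_fw_g": 2.0, "root_dw_g": 0.05,
            "shoot_dw_g": 0.2, "root_k_mmol_per_g_dw": 2.0,
            "shoot_k_mmol_per_g_dw": 3.0, "available_k_mmol": 4.0,
        })
    pd.DataFrame(rows).to_csv(tmp_path / "traits.csv", index=False)
    records = records_from_csv(tmp_path / "traits.csv")
    table = efficiency_table(records)
    assert len(table) == 4
    assert np.allclose(table["KUE"], table["KUpE"] * table["KUtE"])
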
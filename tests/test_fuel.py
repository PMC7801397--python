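"""Biodiesel fuel-property correlations and standards compliance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algafame import (
    FameProfile,
    StandardSpec,
    builtin_standards,
    cetane_number,
    cfpp,
    degree_of_unsaturation,
    estimate_fuel_properties,
    evaluate_standards,
    iodine_value,
    lcsf,
    methyl_ester_mass,
    parse_shorthand,
    saponification_value,
)

# The thirteen species named across the composition report: seven major and
# six minor fatty acids.
SPECIES = [
    "C16:0", "C18:0", "C24:0", "C21:0", "C18:1", "C18:3n3", "C18:2",
    "C8:0", "C12:0", "C14:0", "C15:0", "C20:0", "C20:1",
]


# ---------------------------------------------------------------------------
# Independent oracle: literal per-term arithmetic, separate from the
# implementation path (no shared coefficient tables).

def _oracle_mass(n: int, d: int) -> float:
    return (n + 1) * 12.011 + (2 * (n + 1) - 2 * d) * 1.008 + 2 * 15.999


def _oracle_all(comp: dict[str, float]) -> dict[str, float]:
    def nd(name):
        body = name[1:].split("n")[0]
        n, d = body.split(":")
        return int(n), int(d)

    cn = 55.87
    cn_terms = {
        (12, 0): 0.0747, (14, 0): 0.098, (16, 0): 0.164, (18, 0): 0.176,
        (16, 1): -0.050, (18, 1): 0.001, (18, 2): -0.140, (18, 3): -0.273,
    }
    du = sv = iv = lc = 0.0
    for name, pct in comp.items():
        n, d = nd(name)
        cn += cn_terms.get((n, d), 0.0) * pct
        if d == 1:
            du += pct
        elif d == 2:
            du += 2 * pct
        elif d == 3:
            du += 3 * pct
        m = _oracle_mass(n, d)
        sv += 560.0 * pct / m
        iv += 254.0 * d * pct / m
        if d == 0:
            lc += {16: 0.1, 18: 0.5, 20: 1.0, 22: 1.5, 24: 2.0}.get(n, 0.0) * pct
    return {"cn": cn, "du": du, "sv": sv, "iv": iv, "lcsf": lc}


class TestMethylEsterMass:
    @pytest.mark.parametrize(
        "shorthand, expected",
        [("C16:0", 270.46), ("C18:1", 296.49), ("C18:0", 298.51)],
    )
    def test_formula_masses(self, shorthand, expected):
        assert methyl_ester_mass(parse_shorthand(shorthand)) == pytest.approx(
            expected, abs=0.005
        )

    def test_impossible_unsaturation_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            parse_shorthand("C4:3").methyl_ester_mass


class TestCetaneNumber:
    def test_intercept_for_profile_outside_model_terms(self):
        p = FameProfile.from_pairs([("C21:0", 1.2), ("C24:0", 0.5), ("C20:1", 0.4)])
        assert cetane_number(p) == pytest.approx(55.87)

    def test_pure_palmitic(self):
        p = FameProfile.from_pairs([("C16:0", 100.0)])
        assert cetane_number(p) == pytest.approx(72.27)

    def test_mixed_profile(self, mixed_profile):
        assert cetane_number(mixed_profile) == pytest.approx(62.073)

    def test_trienoic_isomers_aggregate(self):
        a = FameProfile.from_pairs([("C18:3n3", 10.0)])
        b = FameProfile.from_pairs([("C18:3", 10.0)])
        assert cetane_number(a) == pytest.approx(cetane_number(b))

    @settings(derandomize=True, max_examples=30)
    @given(base=st.floats(0, 5), extra=st.floats(0.5, 10))
    def test_monotone_in_key_species(self, base, extra):
        lo3 = FameProfile.from_pairs([("C18:3n3", base)])
        hi3 = FameProfile.from_pairs([("C18:3n3", base + extra)])
        assert cetane_number(hi3) < cetane_number(lo3)
        lo16 = FameProfile.from_pairs([("C16:0", base)])
        hi16 = FameProfile.from_pairs([("C16:0", base + extra)])
        assert cetane_number(hi16) > cetane_number(lo16)


class TestUnsaturationMeasures:
    def test_du_zero_for_saturated(self, saturated_profile):
        assert degree_of_unsaturation(saturated_profile) == 0.0

    def test_du_weighted_sum(self):
        p = FameProfile.from_pairs([("C18:1", 45.0), ("C18:2", 4.0), ("C18:3n3", 2.0)])
        assert degree_of_unsaturation(p) == pytest.approx(59.0)

    def test_du_mufa_identity(self):
        assert degree_of_unsaturation(
            FameProfile.from_pairs([("C18:1", 40.0)])
        ) == pytest.approx(40.0)

    def test_iv_zero_iff_du_zero(self, saturated_profile, mixed_profile):
        assert iodine_value(saturated_profile) == 0.0
        assert degree_of_unsaturation(saturated_profile) == 0.0
        assert iodine_value(mixed_profile) > 0
        assert degree_of_unsaturation(mixed_profile) > 0

    def test_iv_pure_oleate(self):
        p = FameProfile.from_pairs([("C18:1", 100.0)])
        assert iodine_value(p) == pytest.approx(85.67, abs=0.01)

    def test_iv_mixed_terms(self):
        p = FameProfile.from_pairs([("C18:1", 45.0), ("C18:2", 4.0), ("C18:3n3", 2.0)])
        assert iodine_value(p) == pytest.approx(38.55 + 6.90 + 5.21, abs=0.01)


class TestSaponification:
    def test_empty_profile(self):
        assert saponification_value(FameProfile("NS", 0, 1, {})) == 0.0

    def test_pure_palmitate(self):
        p = FameProfile.from_pairs([("C16:0", 100.0)])
        assert saponification_value(p) == pytest.approx(207.06, abs=0.01)

    def test_two_species_sum(self):
        p = FameProfile.from_pairs([("C16:0", 50.0), ("C18:1", 50.0)])
        assert saponification_value(p) == pytest.approx(103.53 + 94.44, abs=0.01)


class TestLcsf:
    def test_zero_for_unsaturated_only(self):
        p = FameProfile.from_pairs([("C18:1", 45.0), ("C18:2", 4.0)])
        assert lcsf(p) == 0.0

    def test_table_consistent_coefficients(self):
        p = FameProfile.from_pairs([("C16:0", 40.0), ("C18:0", 4.5), ("C24:0", 0.5)])
        assert lcsf(p, "table_consistent") == pytest.approx(4.0 + 2.25 + 1.0)

    def test_as_printed_coefficients(self):
        p = FameProfile.from_pairs([("C16:0", 40.0), ("C18:0", 4.5), ("C24:0", 0.5)])
        assert lcsf(p, "as_printed") == pytest.approx(24.0 + 2.25 + 1.0)

    def test_only_saturated_species_counted(self):
        # C16:1 and C20:1 share the carbon numbers but are unsaturated
        p = FameProfile.from_pairs([("C16:1", 10.0), ("C20:1", 5.0)])
        assert lcsf(p) == 0.0

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError, match="coefficient set"):
            lcsf(FameProfile("NS", 0, 1, {}), "bogus")

    def test_coefficient_set_diagnosis(self):
        """A realistic palmitic-dominated profile exposes the published
        C16 weight as inconsistent with the tabulated LCSF magnitudes."""
        p = FameProfile.from_pairs(
            [("C16:0", 40.0), ("C18:0", 4.5), ("C21:0", 1.2), ("C24:0", 0.6),
             ("C18:1", 45.0), ("C18:2", 3.0), ("C18:3n3", 2.0)]
        )
        assert lcsf(p, "as_printed") > 20.0
        assert 7.2 <= lcsf(p, "table_consistent") <= 16.4


class TestCfpp:
    @pytest.mark.parametrize("lcsf_value, expected", [(8.0, 8.7), (7.2, 6.1)])
    def test_affine_relation_at_reporting_precision(self, lcsf_value, expected):
        assert round(cfpp(lcsf_value), 1) == pytest.approx(expected)

    def test_intercept(self):
        assert cfpp(0.0) == pytest.approx(-16.477)

    @settings(derandomize=True, max_examples=30)
    @given(a=st.floats(0, 20), delta=st.floats(0.1, 5))
    def test_strictly_increasing_with_slope(self, a, delta):
        assert cfpp(a + delta) - cfpp(a) == pytest.approx(3.1417 * delta)


class TestAdditivity:
    @settings(derandomize=True, max_examples=30)
    @given(alpha=st.floats(0.0, 1.0))
    def test_sv_iv_additive_over_mixtures(self, alpha):
        p = {"C16:0": 40.0, "C18:1": 50.0}
        q = {"C18:0": 30.0, "C18:3n3": 20.0}
        keys = set(p) | set(q)
        mix = {
            k: alpha * p.get(k, 0.0) + (1 - alpha) * q.get(k, 0.0) for k in keys
        }
        fp_p = FameProfile("NS", 0, 1, p)
        fp_q = FameProfile("NS", 0, 1, q)
        fp_m = FameProfile("NS", 0, 1, mix)
        assert saponification_value(fp_m) == pytest.approx(
            alpha * saponification_value(fp_p) + (1 - alpha) * saponification_value(fp_q)
        )
        assert iodine_value(fp_m) == pytest.approx(
            alpha * iodine_value(fp_p) + (1 - alpha) * iodine_value(fp_q)
        )


class TestOracleEquivalence:
    def test_random_profiles_match_brute_force(self):
        """Implementation agrees with the literal per-term sums to 1e-9
        relative over random 13-species profiles."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            raw = rng.dirichlet(np.ones(len(SPECIES))) * rng.uniform(80, 100)
            comp = dict(zip(SPECIES, raw))
            profile = FameProfile("NS", 0, 1, comp)
            expected = _oracle_all(comp)
            got = estimate_fuel_properties(profile)
            assert got.cn == pytest.approx(expected["cn"], rel=1e-9)
            assert got.du == pytest.approx(expected["du"], rel=1e-9)
            assert got.sv == pytest.approx(expected["sv"], rel=1e-9)
            assert got.iv == pytest.approx(expected["iv"], rel=1e-9)
            assert got.lcsf == pytest.approx(expected["lcsf"], rel=1e-9)
            assert got.cfpp == pytest.approx(3.1417 * expected["lcsf"] - 16.477, rel=1e-9)


class TestStandards:
    def test_builtin_registry_contents(self):
        specs = {s.code: s for s in builtin_standards()}
        assert specs["EN 14214: 2008"].cn_min == 51
        assert specs["EN 14214: 2008"].cfpp_max == 0
        assert specs["ASTM D6751"].cn_min == 47
        assert specs["RANP/2008"].cfpp_max is None
        assert specs["SIRIM MS 123: 2005"].cfpp_max == 15

    def test_tropical_spec_passes_late_starvation_values(self):
        from algafame.fuel import FuelProperties

        props = FuelProperties(cn=62.9, du=0, sv=0, iv=0, lcsf=7.8, cfpp=8.0)
        report = evaluate_standards(props)
        by_code = report.set_index("code")
        assert by_code.at["SIRIM MS 123: 2005", "passes"]
        assert not by_code.at["EN 14214: 2008", "cfpp_pass"]
        assert by_code.at["EN 14214: 2008", "cn_pass"]

    def test_cn_boundary(self):
        from algafame.fuel import FuelProperties

        props = FuelProperties(cn=50.0, du=0, sv=0, iv=0, lcsf=0, cfpp=-5.0)
        report = evaluate_standards(props).set_index("code")
        assert not report.at["EN 14214: 2008", "cn_pass"]
        assert report.at["ASTM D6751", "cn_pass"]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            StandardSpec(code="X", region="Y", cn_min=51, cfpp_min=5, cfpp_max=0)

    def test_rounding_half_up_to_reporting_precision(self):
        from algafame.fuel import FuelProperties

        props = FuelProperties(cn=62.05, du=57.35, sv=199.05, iv=41.85, lcsf=8.65, cfpp=8.65)
        r = props.rounded()
        assert (r.cn, r.du, r.sv, r.iv, r.lcsf, r.cfpp) == (
            62.1, 57.4, 199.1, 41.9, 8.7, 8.7
        )
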
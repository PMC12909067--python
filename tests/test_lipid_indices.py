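"""Ring Index, crenarchaeol fraction and detectability statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from springlipids.lipid_indices import (
    SPECIES,
    RING_WEIGHTS,
    EmptyProfileError,
    normalize_abundances,
    ring_index,
    cren_fraction,
    detectability_stats,
    add_index_columns,
)


def naive_ring_index(abunds, include_cren):
    """Independent sum-of-products oracle over the explicit species list."""
    if include_cren:
        keep = list(SPECIES)
    else:
        keep = [s for s in SPECIES if s.startswith("G")]
    total = sum(abunds.get(s, 0.0) for s in keep)
    return sum(abunds.get(s, 0.0) * RING_WEIGHTS[s] for s in keep) / total


class TestNormalize:
    def test_symmetric_split(self):
        p = normalize_abundances({"G0": 2, "G4": 2})
        assert p.abundances["G0"] == pytest.approx(0.5)
        assert p.abundances["G4"] == pytest.approx(0.5)
        assert p.abundances["Cren"] == 0.0

    def test_proportional_split(self):
        p = normalize_abundances({"G0": 1, "Cren": 3})
        assert p.abundances["G0"] == pytest.approx(0.25)
        assert p.abundances["Cren"] == pytest.approx(0.75)

    def test_sums_to_one(self):
        p = normalize_abundances({"G1": 3.2, "G5": 0.7, "CrenIso": 1.1})
        assert p.total == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_is_error(self):
        with pytest.raises(EmptyProfileError):
            normalize_abundances({s: 0.0 for s in SPECIES})

    def test_negative_area_is_error(self):
        with pytest.raises(ValueError, match="negative"):
            normalize_abundances({"G0": 1.0, "G2": -0.1})

    def test_unknown_species_is_error(self):
        with pytest.raises(ValueError, match="unknown"):
            normalize_abundances({"GDGT-0": 1.0})


class TestRingIndex:
    @pytest.mark.parametrize("include_cren", [True, False])
    def test_zero_and_max_ring_cases(self, include_cren):
        assert ring_index({"G0": 1.0}, include_cren) == 0.0
        assert ring_index({"G8": 1.0}, include_cren) == 8.0

    @pytest.mark.parametrize("include_cren", [True, False])
    def test_equal_quarters(self, include_cren):
        prof = {"G0": 0.25, "G1": 0.25, "G2": 0.25, "G3": 0.25}
        assert ring_index(prof, include_cren) == pytest.approx(1.5)

    def test_cren_counts_as_four_rings_only_when_included(self):
        prof = {"G0": 0.5, "Cren": 0.5}
        assert ring_index(prof, include_cren=True) == pytest.approx(2.0)
        assert ring_index(prof, include_cren=False) == pytest.approx(0.0)

    def test_isomer_also_weighted_four(self):
        prof = {"CrenIso": 1.0}
        assert ring_index(prof, include_cren=True) == pytest.approx(4.0)

    def test_cren_only_without_cren_is_error(self):
        with pytest.raises(EmptyProfileError):
            ring_index({"Cren": 0.7, "CrenIso": 0.3}, include_cren=False)

    def test_custom_weight_table(self):
        prof = {"G0": 0.5, "Cren": 0.5}
        w = dict(RING_WEIGHTS, Cren=5.0)
        assert ring_index(prof, include_cren=True, weights=w) == pytest.approx(2.5)

    @pytest.mark.parametrize("include_cren", [True, False])
    def test_matches_oracle_on_random_dirichlet_profiles(self, include_cren):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            vals = rng.dirichlet(np.full(len(SPECIES), 0.5))
            prof = dict(zip(SPECIES, vals))
            if not include_cren and sum(
                prof[s] for s in SPECIES if s.startswith("G")
            ) == 0:
                continue
            assert ring_index(prof, include_cren) == pytest.approx(
                naive_ring_index(prof, include_cren), abs=1e-12
            )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        vals=st.lists(
            st.floats(0.0, 100.0, allow_nan=False), min_size=11, max_size=11
        ).filter(lambda v: sum(v[:9]) > 1e-6),
        scale=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance_and_bounds(self, vals, scale):
        prof = dict(zip(SPECIES, vals))
        scaled = {s: v * scale for s, v in prof.items()}
        for inc in (True, False):
            ri = ring_index(prof, inc)
            assert 0.0 <= ri <= 8.0
            assert ring_index(scaled, inc) == pytest.approx(ri, rel=1e-9)


class TestCrenFraction:
    def test_half(self):
        assert cren_fraction({"G0": 0.5, "Cren": 0.5}) == pytest.approx(0.5)

    def test_absent(self):
        assert cren_fraction({"G0": 1.0}) == 0.0

    def test_isomer_excluded_from_numerator_by_default(self):
        prof = {"G0": 0.6, "Cren": 0.3, "CrenIso": 0.1}
        assert cren_fraction(prof) == pytest.approx(0.3)
        assert cren_fraction(prof, include_isomer=True) == pytest.approx(0.4)

    def test_empty_profile_is_error(self):
        with pytest.raises(EmptyProfileError):
            cren_fraction({s: 0.0 for s in SPECIES})

    def test_complements_other_fractions(self):
        rng = np.random.default_rng(3)
        vals = rng.dirichlet(np.ones(len(SPECIES)))
        prof = dict(zip(SPECIES, vals))
        others = sum(v for s, v in prof.items() if s != "Cren")
        assert cren_fraction(prof) + others == pytest.approx(1.0)


class TestDetectability:
    def test_hand_counted_group(self):
        s = detectability_stats([0.0, 0.1, 0.0])
        assert s["n_total"] == 3
        assert s["n_detect"] == 1
        assert s["n_nondetect"] == 2
        assert s["fraction_detect"] == pytest.approx(1 / 3)
        assert s["mean_fraction"] == pytest.approx(0.1 / 3)
        assert s["mean_fraction_excluding_zeros"] == pytest.approx(0.1)

    def test_empty_group_flagged_undefined(self):
        s = detectability_stats([])
        assert s["n_total"] == 0
        assert s["mean_fraction"] is None
        assert s["fraction_detect"] is None

    def test_threshold_moves_the_detect_line(self):
        s = detectability_stats([0.005, 0.1], detect_threshold=0.01)
        assert s["n_detect"] == 1


class TestAddIndexColumns:
    def test_appends_columns_and_flags(self, survey300):
        for col in ("ri_with_cren", "ri_without_cren", "cren_fraction",
                    "detect_flag"):
            assert col in survey300.columns
        assert survey300["ri_with_cren"].between(0, 8).all()
        assert (
            survey300["detect_flag"] == (survey300["cren_fraction"] > 0)
        ).all()

    def test_missing_species_columns_warn_and_count_zero(self, survey300):
        partial = survey300[
            ["site_id", "ph"] + [f"G{i}" for i in range(9)]
        ].head(5)
        with pytest.warns(UserWarning, match="Cren"):
            out = add_index_columns(partial)
        assert (out["cren_fraction"] == 0.0).all()
        assert (out["ri_with_cren"] == out["ri_without_cren"]).all()
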
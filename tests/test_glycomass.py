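"""Mass-engine tests: residue masses, intact-glycan and fragment ions, registry."""

import math

import pytest
import yaml
from hypothesis import given, strategies as st

from glycosnog import glycomass as gm
from glycosnog.glycomass import (
    GlycanComposition,
    default_registry,
    format_composition,
    load_registry,
    oxonium_mz,
    parse_composition,
    reduced_glycan_mh,
    residue_mass,
    save_registry,
)

# independent elemental oracle: atomic masses typed in here, not imported
_H, _C, _N, _O = 1.00782503207, 12.0, 14.0030740048, 15.9949146196

_FORMULAE = {
    "Hex": (6, 10, 0, 5),
    "HexNAc": (8, 13, 1, 5),
    "dHex": (6, 10, 0, 4),
    "Neu5Ac": (11, 17, 1, 8),
    "Neu5Gc": (11, 17, 1, 9),
    "HexA": (6, 8, 0, 6),
}


def _oracle_mass(c, h, n, o):
    return c * _C + h * _H + n * _N + o * _O


@pytest.mark.parametrize("name,formula", _FORMULAE.items())
def test_residue_masses_match_elemental_composition(name, formula):
    assert residue_mass(name) == pytest.approx(_oracle_mass(*formula), abs=1e-5)


def test_unknown_residue_rejected():
    with pytest.raises(KeyError):
        residue_mass("Pent")


@pytest.mark.parametrize(
    "comp,printed",
    [
        ("Hex5HexNAc4Fuc1Neu5Ac2", 2371.9),
        ("Hex5HexNAc4Fuc1Neu5Gc2", 2403.9),
        ("Hex5HexNAc4Fuc1Neu5Ac1Neu5Gc1", 2387.9),
        ("Hex5HexNAc4Neu5Gc2", 2257.8),
        ("Hex7HexNAc4Fuc1", 2113.8),
        ("Hex6HexNAc3Fuc1Neu5Ac1", 2039.7),
        ("Hex6HexNAc3Fuc1Neu5Gc1", 2055.7),
        ("Hex5HexNAc4Fuc1", 1789.7),
        ("Hex5HexNAc5Fuc3", 2284.9),
    ],
)
def test_reduced_glycan_mh_reproduces_printed_precursors(comp, printed):
    """Intact reduced-glycan [M+H]+ values agree at 0.1-Da rounding."""
    assert round(reduced_glycan_mh(parse_composition(comp)), 1) == printed


def test_man5_mh_two_decimals():
    assert round(reduced_glycan_mh(parse_composition("Hex5HexNAc2")), 2) == 1237.46


@pytest.mark.parametrize(
    "comp,printed",
    [
        ("HexNAc1", "204.0867"),
        ("Hex1HexNAc1", "366.1395"),
        ("Fuc1Hex1HexNAc1", "512.1974"),
        ("Hex2HexNAc1", "528.1923"),
        ("Fuc1HexNAc2", "553.224"),
        ("Fuc2Hex1HexNAc1", "658.2553"),
        ("Neu5Ac1", "292.1027"),
        ("Neu5Gc1", "308.0976"),
        ("Neu5Ac1Ac1", "334.1133"),
        ("Neu5Gc1Ac1", "350.1082"),
        ("Neu5Ac1HexNAc1", "495.1821"),
        ("Neu5Gc1HexNAc1", "511.177"),
        ("Neu5Ac1Hex1HexNAc1", "657.2349"),
        ("Neu5Gc1Hex1HexNAc1", "673.2298"),
        ("Neu5Ac1HexNAc2", "698.2615"),
        ("Neu5Gc1HexNAc2", "714.2564"),
        ("Fuc1Hex1HexNAc2", "715.27677"),
        ("Neu5Ac1Fuc1Hex1HexNAc1", "803.2928"),
        ("Neu5Ac1Hex1HexNAc2", "860.31427"),
        ("Neu5Gc1Hex1HexNAc2", "876.30917"),
        ("Neu5Ac2Hex1HexNAc1", "948.3303"),
        ("Neu5Gc2Hex1HexNAc1", "980.3201"),
        ("HexNAc1SO41", "284.0435"),
        ("Hex1HexNAc1SO41", "446.09627"),
        ("HexA1Hex1HexNAc1", "542.1716"),
        ("HexA1Hex1HexNAc1SO41", "622.1284"),
        ("Hex1HexNAc2", "569.21887"),
        ("Hex2HexNAc2", "731.27167"),
        ("Fuc1Hex2HexNAc2", "877.32957"),
        ("Fuc2Hex2HexNAc2", "1023.38747"),
        ("Fuc3Hex2HexNAc2", "1169.44537"),
    ],
)
def test_oxonium_mz_reproduces_printed_fragment_ions(comp, printed):
    """Non-reduced B-ion m/z agrees with the printed value within one unit
    of its last printed digit (floor 5e-5: the five-decimal figures carry a
    small constant offset from a different proton-mass convention)."""
    decimals = len(printed.split(".")[1])
    tol = max(10.0 ** (-decimals), 5e-5)
    assert oxonium_mz(parse_composition(comp)) == pytest.approx(float(printed), abs=tol)


@pytest.mark.parametrize(
    "comp,printed",
    [("Neu5Ac1", 274.0921), ("Neu5Gc1", 290.087)],
)
def test_water_loss_sialic_ions(comp, printed):
    got = oxonium_mz(parse_composition(comp)) - gm.WATER
    assert got == pytest.approx(printed, abs=1e-4)


def test_reduced_end_ion_theoretical_value():
    # alditol HexNAc fragment: theoretical 224.1129 (the printed 224.1118 is
    # ~0.001 below; the ±0.05 matching tolerance absorbs the difference)
    got = oxonium_mz(parse_composition("HexNAc1"), reduced_end=True)
    assert got == pytest.approx(224.1129, abs=1e-4)
    assert abs(got - 224.1118) < 0.05


_COMP_STRATEGY = st.builds(
    GlycanComposition,
    counts=st.fixed_dictionaries(
        {},
        optional={
            "Hex": st.integers(1, 12),
            "HexNAc": st.integers(1, 8),
            "dHex": st.integers(0, 6),
            "Neu5Ac": st.integers(0, 4),
            "Neu5Gc": st.integers(0, 4),
            "HexA": st.integers(0, 2),
        },
    ).filter(lambda d: sum(d.values()) >= 1),
)


@given(_COMP_STRATEGY)
def test_reduction_plus_water_offset(c):
    """Intact reduced [M+H]+ minus the plain B-ion is always water + 2H."""
    delta = reduced_glycan_mh(c) - oxonium_mz(c, reduced_end=False)
    assert math.isclose(delta, gm.WATER + gm.REDUCTION, abs_tol=1e-6)


@given(_COMP_STRATEGY, _COMP_STRATEGY)
def test_mass_additivity_under_composition_union(c1, c2):
    merged = GlycanComposition(
        {k: c1[k] + c2[k] for k in set(c1.counts) | set(c2.counts)},
        n_sulfate=c1.n_sulfate + c2.n_sulfate,
        n_acetyl=c1.n_acetyl + c2.n_acetyl,
    )
    expected = (reduced_glycan_mh(c1) + reduced_glycan_mh(c2)
                - (gm.WATER + gm.REDUCTION + gm.PROTON))
    assert math.isclose(reduced_glycan_mh(merged), expected, abs_tol=1e-6)


@given(_COMP_STRATEGY)
def test_composition_string_round_trip(c):
    assert parse_composition(format_composition(c)).counts == c.counts


@pytest.mark.parametrize(
    "s,expected_counts,n_sulfate",
    [
        ("Hex5HexNAc4Fuc1Neu5Ac2", {"Hex": 5, "HexNAc": 4, "dHex": 1, "Neu5Ac": 2}, 0),
        ("Hex3HexNAc2", {"Hex": 3, "HexNAc": 2}, 0),
        ("Hex5HexNAc4Fuc1SO41", {"Hex": 5, "HexNAc": 4, "dHex": 1}, 1),
        ("Hex_5_HexNAc_4_", {"Hex": 5, "HexNAc": 4}, 0),  # underscore style
        ("Hex1dHex1", {"Hex": 1, "dHex": 1}, 0),  # dHex synonym
    ],
)
def test_parse_composition_examples(s, expected_counts, n_sulfate):
    c = parse_composition(s)
    assert c.counts == expected_counts
    assert c.n_sulfate == n_sulfate


def test_parse_rejects_unknown_token():
    with pytest.raises(ValueError, match="Pent"):
        parse_composition("Hex2Pent1")


def test_composition_validation():
    with pytest.raises(ValueError):
        GlycanComposition({})  # empty
    with pytest.raises(ValueError):
        GlycanComposition({"Hex": 2}, n_acetyl=1)  # acetyl without sialic acid


# ---------------------------------------------------------------------------
# registry

# the full diagnostic-ion m/z list, frozen verbatim
PRINTED_REGISTRY = [
    167.0914, 183.0863, 204.0867, 222.0972, 224.1118, 243.0264, 274.0921,
    284.0435, 290.087, 292.1027, 308.0976, 312.1289, 316.1027, 328.1238,
    332.0976, 334.1133, 350.1082, 366.1395, 370.1697, 407.1661, 495.1821,
    511.177, 512.1974, 528.1923, 542.1716, 553.224, 569.21887, 622.1284,
    657.2349, 658.2553, 673.2298, 698.2615, 699.2455, 714.2564, 715.2404,
    715.27677, 792.3234, 803.2928, 819.2877, 860.31427, 876.30917, 948.3303,
    980.3201, 446.09627, 649.17567, 731.27167, 877.32957, 1023.38747,
    1169.44537,
]


def test_default_registry_matches_printed_list(registry):
    assert sorted(i.mz for i in registry) == sorted(PRINTED_REGISTRY)


def test_registry_mz_unique_and_thresholds_valid(registry):
    mzs = sorted(i.mz for i in registry)
    assert all(b - a > 0.001 for a, b in zip(mzs, mzs[1:]))
    assert all(0.0 <= i.esnog_threshold <= 1.0 for i in registry)


def test_registry_category_assignments(registry):
    by_mz = {i.mz: i.category for i in registry}
    assert by_mz[792.3234] == "bisect"
    assert by_mz[948.3303] == "disialyl_lewisC_ac"
    assert by_mz[512.1974] == "distal_fucose"
    assert by_mz[284.0435] == "sulfo_hexnac"
    assert by_mz[224.1118] == "reduced_hexnac"


@pytest.mark.parametrize("suffix", ["yaml", "json"])
def test_registry_round_trip_bit_exact(tmp_path, registry, suffix):
    path = tmp_path / f"registry.{suffix}"
    save_registry(registry, path)
    loaded = load_registry(path)
    assert loaded == registry  # dataclass equality: floats compared exactly
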
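"""Feature encoders: composition, pseudo-composition, propensity matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pseui.errors import ValidationError
from pseui.encoders import (
    DI_INDEX,
    FeatureRecipe,
    PseDNCConfig,
    PhysicochemicalTable,
    encode,
    encode_dc,
    encode_nc,
    encode_psdp,
    encode_psednc,
    encode_psnp,
    fit_propensity,
    load_property_table,
    normalize_properties,
)
from pseui.segments_io import NT_INDEX, LabeledDataset, RNASegment

from conftest import random_dataset, random_segment

segments = st.builds(
    lambda codes, xi: RNASegment(
        "".join("ACGU"[c] for c in codes[:xi] + [3] + codes[xi : 2 * xi]), xi
    ),
    codes=st.lists(st.integers(0, 3), min_size=30, max_size=30),
    xi=st.integers(2, 15),
)


#: ξ=1 toy with hand-enumerable frequencies:
#: positives {AUA, AUA}, negatives {GUC, AUA}
def _toy_dataset():
    segs = [RNASegment(s, 1) for s in ("AUA", "AUA", "GUC", "AUA")]
    return LabeledDataset(segs, np.array([True, True, False, False]), xi=1)


class TestComposition:
    def test_nc_counts(self):
        np.testing.assert_allclose(
            encode_nc(RNASegment("UAUAU", 2)), [0.4, 0, 0, 0.6]
        )

    def test_nc_homopolymer(self):
        np.testing.assert_allclose(
            encode_nc(RNASegment("UUUUU", 2)), [0, 0, 0, 1]
        )

    def test_dc_overlapping_pairs(self):
        v = encode_dc(RNASegment("UAUAU", 2))
        assert v[DI_INDEX["UA"]] == pytest.approx(0.5)
        assert v[DI_INDEX["AU"]] == pytest.approx(0.5)
        assert v.sum() == pytest.approx(1.0)

    def test_dc_homopolymer(self):
        v = encode_dc(RNASegment("UUUUU", 2))
        assert v[DI_INDEX["UU"]] == pytest.approx(1.0)

    @given(segments)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dc_equals_pair_enumeration(self, seg):
        """Oracle: count overlapping pairs directly from the string."""
        v = encode_dc(seg)
        s = seg.sequence
        pairs = [s[i : i + 2] for i in range(len(s) - 1)]
        for d, idx in DI_INDEX.items():
            assert v[idx] == pytest.approx(pairs.count(d) / len(pairs))
        assert encode_nc(seg).sum() == pytest.approx(1.0)


class TestPropertyTable:
    def test_shipped_table_raw_values(self):
        table = load_property_table()
        np.testing.assert_allclose(
            table.values[DI_INDEX["GG"]], [-3.260, 0.170, -11.100]
        )

    def test_normalization_zero_mean_unit_sd(self):
        norm = normalize_properties(load_property_table())
        np.testing.assert_allclose(norm.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(norm.values.std(axis=0), 1, atol=1e-9)

    def test_normalized_gg_free_energy(self):
        # oracle: arithmetic over the free-energy column typed independently
        col = np.array([
            -0.93, -2.24, -2.08, -1.10, -2.11, -3.26, -2.36, -2.08,
            -2.35, -3.42, -3.26, -2.24, -1.33, -2.35, -2.11, -0.93,
        ])  # lexicographic AA..UU
        expected = (-3.260 - col.mean()) / col.std()
        norm = normalize_properties(load_property_table())
        assert norm.values[DI_INDEX["GG"], 0] == pytest.approx(expected)

    def test_incomplete_table_rejected(self, tmp_path):
        p = tmp_path / "table.csv"
        p.write_text("dinucleotide,free_energy\nAA,-0.93\n")
        with pytest.raises(ValidationError, match="missing"):
            load_property_table(p)


class TestPseDNC:
    def test_lambda_zero_equals_dc(self, rng):
        for _ in range(10):
            seg = random_segment(rng, xi=6)
            np.testing.assert_allclose(
                encode_psednc(seg, PseDNCConfig(lam=0)), encode_dc(seg)
            )

    def test_homopolymer_thetas_vanish(self):
        seg = RNASegment("UUUUUUU", 3)
        v = encode_psednc(seg, PseDNCConfig(lam=3, w=0.7))
        np.testing.assert_allclose(v[:16], encode_dc(seg))
        np.testing.assert_allclose(v[16:], 0, atol=1e-12)

    def test_matches_brute_force_formula(self):
        """Oracle: evaluate theta_1 by direct loops on a 5-nt toy with one
        property, then assemble the vector from the displayed formula."""
        seg = RNASegment("GAUCU", 2)
        table = normalize_properties(
            load_property_table().select(["free_energy"])
        )
        P = {d: table.values[i, 0] for d, i in DI_INDEX.items()}
        s = seg.sequence
        dis = [s[i : i + 2] for i in range(4)]
        theta1 = np.mean([(P[dis[i]] - P[dis[i + 1]]) ** 2 for i in range(3)])
        f = encode_dc(seg)
        w = 0.5
        expected = np.concatenate([f, [w * theta1]]) / (f.sum() + w * theta1)
        got = encode_psednc(
            seg, PseDNCConfig(lam=1, w=w, properties=("free_energy",))
        )
        np.testing.assert_allclose(got, expected)

    @given(segments, st.integers(1, 5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_simplex_and_dc_proportionality(self, seg, lam):
        v = encode_psednc(seg, PseDNCConfig(lam=lam))
        assert (v >= 0).all()
        assert v.sum() == pytest.approx(1.0)
        dc = encode_dc(seg)
        # first 16 entries proportional to DC
        nz = dc > 0
        ratios = v[:16][nz] / dc[nz]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_lambda_too_large_rejected(self):
        with pytest.raises(ValidationError, match="lambda"):
            encode_psednc(RNASegment("AUA", 1), PseDNCConfig(lam=2))


class TestPropensity:
    def test_identical_classes_give_zero_matrix(self, rng):
        segs = [random_segment(rng, 3) for _ in range(5)]
        ds = LabeledDataset(segs * 2, np.array([True] * 5 + [False] * 5), xi=3)
        for kind in ("PSNP", "PSDP"):
            np.testing.assert_allclose(fit_propensity(ds, kind).Z, 0, atol=1e-12)

    def test_toy_psdp_entries(self):
        m = fit_propensity(_toy_dataset(), "PSDP")
        Z = m.Z
        assert Z[DI_INDEX["AU"], 0] == pytest.approx(0.5)
        assert Z[DI_INDEX["GU"], 0] == pytest.approx(-0.5)
        assert Z[DI_INDEX["UA"], 1] == pytest.approx(0.5)
        assert Z[DI_INDEX["UC"], 1] == pytest.approx(-0.5)
        assert np.count_nonzero(Z) == 4

    def test_toy_psnp_encoding(self):
        m = fit_propensity(_toy_dataset(), "PSNP")
        np.testing.assert_allclose(
            encode_psnp(RNASegment("AUA", 1), m), [0.5, 0.0, 0.5]
        )

    def test_toy_psdp_encoding(self):
        m = fit_propensity(_toy_dataset(), "PSDP")
        np.testing.assert_allclose(
            encode_psdp(RNASegment("AUA", 1), m), [0.5, 0.5]
        )

    def test_column_stochastic_and_difference_invariants(self, rng):
        ds = random_dataset(rng, xi=4, n_pos=17, n_neg=13)
        for kind in ("PSNP", "PSDP"):
            m = fit_propensity(ds, kind)
            np.testing.assert_allclose(m.Z_plus.sum(axis=0), 1, atol=1e-9)
            np.testing.assert_allclose(m.Z_minus.sum(axis=0), 1, atol=1e-9)
            np.testing.assert_allclose(m.Z.sum(axis=0), 0, atol=1e-9)
            assert (np.abs(m.Z) <= 1 + 1e-12).all()
        # center column of PSNP is exactly zero: center invariantly U
        np.testing.assert_array_equal(
            fit_propensity(ds, "PSNP").Z[:, ds.xi], 0
        )

    def test_single_class_rejected(self, rng):
        ds = random_dataset(rng, xi=3, n_pos=4, n_neg=3)
        bad = LabeledDataset(ds.segments, np.ones(7, dtype=bool), xi=3)
        with pytest.raises(ValidationError):
            fit_propensity(bad, "PSNP")

    def test_xi_mismatch_rejected(self, rng):
        m = fit_propensity(random_dataset(rng, xi=3, n_pos=4, n_neg=4), "PSNP")
        with pytest.raises(ValidationError, match="xi"):
            encode_psnp(random_segment(rng, xi=5), m)


class TestRecipeEncoding:
    @pytest.mark.parametrize(
        "names,xi,lam,expected_dim",
        [
            (("PSNP", "DC"), 10, 2, 37),
            (("NC",), 10, 2, 4),
            (("DC", "PSNP", "pseDNC"), 15, 2, 65),
            (("NC", "DC", "pseDNC", "PSNP", "PSDP"), 10, 3, 80),
        ],
    )
    def test_dimensions(self, rng, names, xi, lam, expected_dim):
        ds = random_dataset(rng, xi=xi, n_pos=6, n_neg=6)
        recipe = FeatureRecipe(names, psednc=PseDNCConfig(lam=lam))
        fitted = {k: fit_propensity(ds, k) for k in recipe.required_matrices()}
        v = encode(ds.segments[0], recipe, fitted)
        assert v.shape == (expected_dim,)
        assert recipe.dimension(xi) == expected_dim

    def test_single_feature_recipe_equals_direct_encoder(self, rng):
        seg = random_segment(rng, 5)
        np.testing.assert_array_equal(
            encode(seg, FeatureRecipe(("NC",))), encode_nc(seg)
        )

    def test_concatenation_order_is_recipe_order(self, rng):
        ds = random_dataset(rng, xi=4, n_pos=5, n_neg=5)
        fitted = {"PSNP": fit_propensity(ds, "PSNP")}
        seg = ds.segments[0]
        v = encode(seg, FeatureRecipe(("PSNP", "NC")), fitted)
        np.testing.assert_array_equal(v[:9], encode_psnp(seg, fitted["PSNP"]))
        np.testing.assert_array_equal(v[9:], encode_nc(seg))

    def test_missing_matrix_rejected(self, rng):
        with pytest.raises(ValidationError, match="PSNP"):
            encode(random_segment(rng, 3), FeatureRecipe(("PSNP",)), {})

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValidationError):
            FeatureRecipe(("DC", "DC"))
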
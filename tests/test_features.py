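"""Scale normalisation and the mutation feature encodings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from easemm.features import (
    FeatureDescriptor, all_descriptors, canonical_order, delta_M, delta_param,
    encode, window_stats,
)
from easemm.io import PSSMatrix, PSSM_ALPHABET
from easemm.scales import (
    AMINO_ACIDS, AAParameterTable, RAW_SCALES, SCALE_NAMES, normalize_scale,
)

aa_letters = st.sampled_from(AMINO_ACIDS)
scale_names = st.sampled_from(SCALE_NAMES)


class TestNormalization:
    def test_endpoints_and_midpoint(self, rng):
        raw = rng.normal(size=20)
        norm = normalize_scale(raw)
        assert norm[np.argmin(raw)] == pytest.approx(-0.9)
        assert norm[np.argmax(raw)] == pytest.approx(0.9)
        mid = (raw.min() + raw.max()) / 2
        mapped = -0.9 + 1.8 * (mid - raw.min()) / (raw.max() - raw.min())
        assert mapped == pytest.approx(0.0)

    def test_constant_scale_rejected(self):
        with pytest.raises(ValueError):
            normalize_scale([1.0] * 20)

    def test_table_invariants(self, table):
        # every scale spans exactly [-0.9, 0.9] and attains both endpoints
        assert len(table.scales) == 11
        for scale in table.scales:
            vals = table.values(scale)
            assert vals.min() == pytest.approx(-0.9)
            assert vals.max() == pytest.approx(0.9)
            assert np.all((-0.9 - 1e-12 <= vals) & (vals <= 0.9 + 1e-12))

    def test_table_matches_independent_affine_map(self, table):
        # independent oracle: apply the affine formula directly to the raw
        # literature values
        for scale in SCALE_NAMES:
            raw = np.array([RAW_SCALES[scale][aa] for aa in AMINO_ACIDS])
            expected = -0.9 + 1.8 * (raw - raw.min()) / (raw.max() - raw.min())
            np.testing.assert_allclose(table.values(scale), expected)

    def test_round_trip(self, table, tmp_path):
        table.write(tmp_path / "scales.txt")
        back = AAParameterTable.read(tmp_path / "scales.txt")
        for scale in table.scales:
            np.testing.assert_allclose(back.values(scale), table.values(scale),
                                       atol=1e-6)


class TestDeltaParam:
    def test_extremes_give_full_range(self, table):
        for scale in SCALE_NAMES:
            vals = table.values(scale)
            lo_aa = AMINO_ACIDS[int(np.argmin(vals))]
            hi_aa = AMINO_ACIDS[int(np.argmax(vals))]
            assert delta_param(table, scale, lo_aa, hi_aa) == pytest.approx(1.8)

    def test_direct_lookup_oracle(self, table):
        got = delta_param(table, "hydrophobicity", "A", "V")
        expected = table.value("hydrophobicity", "V") - table.value("hydrophobicity", "A")
        assert got == pytest.approx(expected)
        assert abs(got) <= 1.8

    @given(scale_names, aa_letters, aa_letters)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, scale, a, b):
        table = AAParameterTable()
        assert delta_param(table, scale, a, b) == pytest.approx(
            -delta_param(table, scale, b, a))

    def test_unknown_inputs(self, table):
        with pytest.raises(KeyError):
            delta_param(table, "hydrophobicity", "B", "V")
        with pytest.raises(KeyError):
            delta_param(table, "not_a_scale", "A", "V")


class TestWindowStats:
    def test_homopolymer(self, table):
        m, lo, hi = window_stats("AAAAAAA", 4, table, "volume")
        v = table.value("volume", "A")
        assert m == pytest.approx(v) and lo == pytest.approx(v) and hi == pytest.approx(v)

    def test_terminal_truncation(self, table):
        # position 1: only the 3 right-side neighbours (positions 2-4) remain
        seq = "ACDEFGHIKL"
        m, lo, hi = window_stats(seq, 1, table, "hydrophobicity")
        vals = [table.value("hydrophobicity", aa) for aa in seq[1:4]]
        assert m == pytest.approx(np.mean(vals))
        assert lo == pytest.approx(min(vals)) and hi == pytest.approx(max(vals))

    def test_interior_six_neighbours(self, table):
        # "GAVLIPF" position 4: neighbours are G,A,V (left) and I,P,F (right)
        seq = "GAVLIPF"
        m, lo, hi = window_stats(seq, 4, table, "bulkiness")
        vals = [table.value("bulkiness", aa) for aa in "GAVIPF"]
        assert m == pytest.approx(np.mean(vals))
        assert lo == pytest.approx(min(vals)) and hi == pytest.approx(max(vals))

    def test_site_letter_irrelevant(self, table):
        base = window_stats("GAVLIPF", 4, table, "volume")
        mutated = window_stats("GAVWIPF", 4, table, "volume")
        assert base == mutated

    @given(st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=30), st.data())
    @settings(max_examples=50, deadline=None)
    def test_min_mean_max_order(self, seq, data):
        pos = data.draw(st.integers(1, len(seq)))
        table = AAParameterTable()
        m, lo, hi = window_stats(seq, pos, table, "flexibility")
        assert lo <= m + 1e-12 and m <= hi + 1e-12

    def test_no_neighbours(self, table):
        with pytest.raises(ValueError):
            window_stats("A", 1, table, "volume")


class TestDeltaM:
    def make_pssm(self, rng):
        seq = "MKVAW"
        return PSSMatrix("P1", seq, rng.integers(-8, 11, size=(5, 20)))

    def test_formula(self, rng):
        pssm = self.make_pssm(rng)
        # brute-force oracle: direct column lookup, stated arithmetic
        wt, mut, pos = "V", "W", 3
        expected = (pssm.scores[2, PSSM_ALPHABET.index(mut)]
                    - pssm.scores[2, PSSM_ALPHABET.index(wt)]) / 10.0
        assert delta_M(pssm, pos, wt, mut) == pytest.approx(expected)

    def test_stated_example_arithmetic(self):
        scores = np.zeros((1, 20))
        scores[0, PSSM_ALPHABET.index("A")] = 5    # deleted residue
        scores[0, PSSM_ALPHABET.index("W")] = -3   # introduced residue
        pssm = PSSMatrix("P", "A", scores)
        assert delta_M(pssm, 1, "A", "W") == pytest.approx(-0.8)
        assert delta_M(pssm, 1, "A", "C") == pytest.approx(-0.5)

    @given(aa_letters, aa_letters, st.integers(1, 5))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b, pos):
        pssm = self.make_pssm(np.random.default_rng(42))
        assert delta_M(pssm, pos, a, b) == pytest.approx(-delta_M(pssm, pos, b, a))

    def test_out_of_range(self, rng):
        with pytest.raises(IndexError):
            delta_M(self.make_pssm(rng), 6, "A", "V")


class TestEncode:
    def test_full_vector_has_51_values(self, small_bundle, small_design, table):
        rec = small_design["records"][0]
        fv = encode(rec, small_bundle.sequences[rec.protein_id],
                    small_bundle.pssms[rec.protein_id], small_bundle.providers,
                    table)
        assert len(fv.values) == 51  # 1+1+11+33+3+1+1
        assert len(fv.names) == 51

    def test_single_descriptor_passthrough(self, small_bundle, small_design, table):
        rec = small_design["records"][0]
        fv = encode(rec, small_bundle.sequences[rec.protein_id],
                    small_bundle.pssms[rec.protein_id], small_bundle.providers,
                    table, wanted=[FeatureDescriptor("sift_score")])
        assert len(fv.values) == 1
        assert fv.values[0] == pytest.approx(
            small_bundle.providers.get_sift(rec.protein_id, rec.position, rec.mut_aa))

    def test_order_is_canonical_and_deterministic(self, small_bundle, small_design, table):
        rec = small_design["records"][1]
        wanted = [FeatureDescriptor("disorder"), FeatureDescriptor("sift_score"),
                  FeatureDescriptor("window", "volume")]
        args = (rec, small_bundle.sequences[rec.protein_id],
                small_bundle.pssms[rec.protein_id], small_bundle.providers, table)
        fv1 = encode(*args, wanted=wanted)
        fv2 = encode(*args, wanted=list(reversed(wanted)))
        assert fv1.names == fv2.names  # canonical, not request, order
        np.testing.assert_array_equal(fv1.values, fv2.values)

    def test_missing_provider_is_an_error(self, small_bundle, small_design, table):
        from easemm.io import ProviderError, ProviderTable
        rec = small_design["records"][0]
        with pytest.raises(ProviderError, match="SIFT"):
            encode(rec, small_bundle.sequences[rec.protein_id],
                   small_bundle.pssms[rec.protein_id], ProviderTable(), table,
                   wanted=[FeatureDescriptor("sift_score")])

    def test_subset_extraction(self, small_bundle, small_design, table):
        rec = small_design["records"][2]
        fv = encode(rec, small_bundle.sequences[rec.protein_id],
                    small_bundle.pssms[rec.protein_id], small_bundle.providers,
                    table)
        sub = fv.subset([FeatureDescriptor("rasa")])
        assert sub[0] == pytest.approx(
            small_bundle.providers.get_rasa(rec.protein_id, rec.position))

    def test_descriptor_catalogue(self):
        descs = all_descriptors()
        assert len(descs) == 27
        assert sum(d.arity for d in descs) == 51
        assert canonical_order(list(reversed(descs))) == descs
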
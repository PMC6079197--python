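import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pipel import Peptide, apply_normalizer, fit_normalizer
from pipel.encoders import (AAINDEX_IDS, AAINDEX_SCALED, CTD_GROUPS,
                            DIPEPTIDES, EncodingError, encode_aac, encode_aai,
                            encode_ctd, encode_dpc, encode_hybrid, encode_pcp)
from pipel.io_core import CANONICAL_ALPHABET

peptide_seqs = st.text(alphabet=CANONICAL_ALPHABET, min_size=2, max_size=25)


class TestAAC:
    def test_homopolymer(self):
        v = encode_aac(Peptide("p", "AAAAA"))
        assert v.values[0] == 1.0 and v.values[1:].sum() == 0.0

    def test_direct_counts(self):
        v = dict(zip(encode_aac(Peptide("p", "ACACA")).names,
                     encode_aac(Peptide("p", "ACACA")).values))
        assert v["AAC_A"] == pytest.approx(0.6)
        assert v["AAC_C"] == pytest.approx(0.4)
        assert sum(x for k, x in v.items() if k not in ("AAC_A", "AAC_C")) == 0

    @given(peptide_seqs)
    @settings(max_examples=50, deadline=None)
    def test_length_and_sum(self, seq):
        v = encode_aac(Peptide("p", seq))
        assert len(v) == 20
        assert v.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (v.values >= 0).all()


class TestDPC:
    def test_single_dipeptide_type(self):
        v = encode_dpc(Peptide("p", "AAA"))
        assert v.values[0] == 1.0 and v.values.sum() == 1.0

    def test_two_overlapping_pairs(self):
        v = dict(zip(DIPEPTIDES, encode_dpc(Peptide("p", "ACA")).values))
        assert v["AC"] == pytest.approx(0.5) and v["CA"] == pytest.approx(0.5)

    def test_too_short_errors(self):
        with pytest.raises(EncodingError):
            encode_dpc(Peptide("p", "A"))

    def test_against_pair_enumeration_oracle(self):
        """DPC must equal brute-force enumeration of all L-1 adjacent pairs."""
        rng = np.random.default_rng(11)
        alphabet = list(CANONICAL_ALPHABET)
        for _ in range(1000):
            L = int(rng.integers(2, 26))
            seq = "".join(rng.choice(alphabet, L))
            got = dict(zip(DIPEPTIDES, encode_dpc(Peptide("p", seq)).values))
            expected = {dp: 0.0 for dp in DIPEPTIDES}
            for i in range(L - 1):
                expected[seq[i:i + 2]] += 1.0 / (L - 1)
            for dp in DIPEPTIDES:
                assert got[dp] == pytest.approx(expected[dp], abs=1e-12)

    @given(peptide_seqs)
    @settings(max_examples=50, deadline=None)
    def test_length_and_sum(self, seq):
        v = encode_dpc(Peptide("p", seq))
        assert len(v) == 400
        assert v.values.sum() == pytest.approx(1.0, abs=1e-9)


def _ctd_distribution_oracle(seq, residues):
    """Position-enumeration oracle for one group's D block."""
    L = len(seq)
    positions = [i + 1 for i, aa in enumerate(seq) if aa in residues]
    if not positions:
        return [0.0] * 5
    n = len(positions)
    out = [100.0 * positions[0] / L]
    for q in (0.25, 0.5, 0.75):
        k = max(1, int(np.floor(q * n + 0.5)))
        out.append(100.0 * positions[k - 1] / L)
    out.append(100.0 * positions[-1] / L)
    return out


class TestCTD:
    def test_group_tables_partition_alphabet(self):
        for attr, groups in CTD_GROUPS.items():
            merged = "".join(groups.values())
            assert sorted(merged) == sorted(CANONICAL_ALPHABET), attr

    def test_homopolymer_hydrophobicity_block(self):
        v = dict(zip(*[(fv.names, fv.values) for fv in [encode_ctd(Peptide("p", "LLLLL"))]][0]))
        assert v["CTD_hydrophobicity_C_polar"] == 0.0
        assert v["CTD_hydrophobicity_C_neutral"] == 0.0
        assert v["CTD_hydrophobicity_C_hydrophobic"] == 100.0
        assert all(v[k] == 0.0 for k in v if "_T_" in k and "hydrophobicity" in k)
        d = [v[f"CTD_hydrophobicity_D_hydrophobic_{q}"] for q in (0, 25, 50, 75, 100)]
        assert d == [20.0, 20.0, 60.0, 80.0, 100.0]
        assert all(v[f"CTD_hydrophobicity_D_polar_{q}"] == 0.0
                   for q in (0, 25, 50, 75, 100))

    @given(peptide_seqs)
    @settings(max_examples=50, deadline=None)
    def test_dimension_and_composition_sums(self, seq):
        v = encode_ctd(Peptide("p", seq))
        assert len(v) == 147
        vals = dict(zip(v.names, v.values))
        for attr in CTD_GROUPS:
            csum = sum(x for k, x in vals.items() if f"{attr}_C_" in k)
            assert csum == pytest.approx(100.0, abs=1e-9)

    def test_transitions_zero_when_group_constant(self):
        # all residues hydrophobic under the hydrophobicity attribute
        v = dict(zip(*[(fv.names, fv.values)
                       for fv in [encode_ctd(Peptide("p", "CLVIMFW"))]][0]))
        assert all(v[k] == 0.0 for k in v if "hydrophobicity_T_" in k)

    def test_distribution_against_position_scan_oracle(self):
        rng = np.random.default_rng(5)
        alphabet = list(CANONICAL_ALPHABET)
        for _ in range(200):
            seq = "".join(rng.choice(alphabet, int(rng.integers(5, 26))))
            v = dict(zip(*[(fv.names, fv.values)
                           for fv in [encode_ctd(Peptide("p", seq))]][0]))
            for attr, groups in CTD_GROUPS.items():
                for gname, residues in groups.items():
                    got = [v[f"CTD_{attr}_D_{gname}_{q}"] for q in (0, 25, 50, 75, 100)]
                    assert got == pytest.approx(_ctd_distribution_oracle(seq, residues))

    def test_distribution_values_in_range(self):
        v = encode_ctd(Peptide("p", "ARNDCEQGHILKMFPSTWYV"))
        d_vals = [x for name, x in zip(v.names, v.values) if "_D_" in name]
        assert all(0.0 < x <= 100.0 for x in d_vals)  # every group occurs here


class TestAAI:
    def test_dimensions(self):
        p = Peptide("p", "ACDEF")
        assert len(encode_aai(p)) == 20
        assert len(encode_aai(p, full=True)) == 160

    def test_scaled_rows_attain_bounds(self):
        assert len(AAINDEX_IDS) == 8
        assert AAINDEX_SCALED.shape == (8, 20)
        assert np.allclose(AAINDEX_SCALED.min(axis=1), 0.0)
        assert np.allclose(AAINDEX_SCALED.max(axis=1), 1.0)

    def test_homopolymer_mean_of_scaled_indices(self):
        v = encode_aai(Peptide("p", "AAAAA"))
        expected = AAINDEX_SCALED[:, 0].mean()  # residue A is column 0
        assert v.values[0] == pytest.approx(expected)
        assert np.all(v.values[1:] == 0.0)

    def test_full_form_is_composition_weighted(self):
        p = Peptide("p", "ACACA")
        aac = np.zeros(20)
        aac[0], aac[1] = 0.6, 0.4
        full = encode_aai(p, full=True).values.reshape(8, 20)
        assert np.allclose(full, AAINDEX_SCALED * aac)


class TestPCP:
    def test_homopolymer_fractions(self):
        v = dict(zip(encode_pcp(Peptide("p", "DDDDD")).names,
                     encode_pcp(Peptide("p", "DDDDD")).values))
        assert v["PCP_negative_frac"] == 1.0
        assert v["PCP_positive_frac"] == 0.0
        assert v["PCP_turn_frac"] == 0.0

    def test_aliphatic_index_printed_formula(self):
        v = dict(zip(encode_pcp(Peptide("p", "AVAV")).names,
                     encode_pcp(Peptide("p", "AVAV")).values))
        assert v["PCP_aliphatic_index"] == pytest.approx((2 + 2.9 * 2) / 4)

    def test_turn_forming_complete(self):
        v = dict(zip(encode_pcp(Peptide("p", "GNPS")).names,
                     encode_pcp(Peptide("p", "GNPS")).values))
        assert v["PCP_turn_frac"] == 1.0

    def test_molecular_weight_known_value(self):
        # di-glycine: 2 x 57.0519 + water
        v = dict(zip(encode_pcp(Peptide("p", "GG")).names,
                     encode_pcp(Peptide("p", "GG")).values))
        assert v["PCP_molecular_weight"] == pytest.approx(2 * 57.0519 + 18.01528)

    def test_abs_charge(self):
        v = dict(zip(encode_pcp(Peptide("p", "RKDE")).names,
                     encode_pcp(Peptide("p", "RKDE")).values))
        assert v["PCP_abs_charge_per_residue"] == pytest.approx(abs(0.0 - 0.03))


class TestHybridAndInvariances:
    def test_hybrid_length_and_order(self):
        p = Peptide("p", "ACDEFGHIK")
        h = encode_hybrid(p)
        assert len(h) == 596
        assert np.allclose(h.values[:20], encode_aac(p).values)
        assert np.allclose(h.values[20:420], encode_dpc(p).values)

    def test_determinism(self):
        a = encode_hybrid(Peptide("p", "ACDEFGHIK")).values
        b = encode_hybrid(Peptide("q", "ACDEFGHIK")).values
        assert np.array_equal(a, b)

    @given(peptide_seqs)
    @settings(max_examples=30, deadline=None)
    def test_permutation_leaves_composition_features_unchanged(self, seq):
        rng = np.random.default_rng(0)
        perm = "".join(rng.permutation(list(seq)))
        p, q = Peptide("p", seq), Peptide("q", perm)
        assert np.allclose(encode_aac(p).values, encode_aac(q).values)
        assert np.allclose(encode_pcp(p).values, encode_pcp(q).values)


class TestNormalization:
    def test_min_max_definition(self):
        stats = fit_normalizer(np.array([[2.0], [4.0], [6.0]]))
        out = apply_normalizer(stats, np.array([[2.0], [4.0], [6.0]]))
        assert out.ravel() == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        stats = fit_normalizer(np.array([[3.0], [3.0], [3.0]]))
        out = apply_normalizer(stats, np.array([[3.0], [7.0]]))
        assert np.all(out == 0.0)

    def test_unseen_values_clipped(self):
        stats = fit_normalizer(np.array([[0.0], [6.0]]))
        out = apply_normalizer(stats, np.array([[10.0], [-5.0]]))
        assert out.ravel() == pytest.approx([1.0, 0.0])

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.zeros((0, 3)))

    def test_training_matrix_spans_unit_interval(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 8))
        out = apply_normalizer(fit_normalizer(X), X)
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1.0)
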
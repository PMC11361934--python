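"""Descriptor correctness: table arithmetic, closed-form indices, invariants."""
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_family, read_raw_table
from tcrh import descriptors as d

PEPTIDE = st.text(alphabet=d.ALPHABET, min_size=1, max_size=23)


class TestValidation:
    def test_case_and_whitespace_normalization(self):
        assert d.validate_sequence("casslgf") == "CASSLGF"
        assert d.validate_sequence("  CASS LGF \n") == "CASSLGF"

    def test_nonstandard_residue_named_with_position(self):
        with pytest.raises(d.SequenceError, match="'X' at position 3"):
            d.validate_sequence("CA XS")

    @pytest.mark.parametrize("bad", ["", "   ", "CASB", "CAS*", "CAS1", "CASU"])
    def test_rejects_bad_input(self, bad):
        with pytest.raises(d.SequenceError):
            d.validate_sequence(bad)

    @given(PEPTIDE)
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_valid_sequences_round_trip(self, seq):
        assert d.validate_sequence(seq.lower()) == seq


class TestScaleAverages:
    def test_homopolymer_equals_table_value(self):
        table = d.load_scale("kyte_doolittle")
        assert d.scale_average("GGGG", table) == pytest.approx(table.values["G"])

    def test_two_term_mean(self):
        table = d.load_scale("eisenberg")
        expect = (table.values["A"] + table.values["G"]) / 2
        assert d.scale_average("AG", table) == pytest.approx(expect)

    def test_average_within_table_range(self, random_sequences):
        for fam in d.FAMILY_ORDER:
            for t in d.load_family(fam):
                lo, hi = t.array.min(), t.array.max()
                for seq in random_sequences[:20]:
                    assert lo - 1e-12 <= d.scale_average(seq, t) <= hi + 1e-12

    def test_family_dimensions(self):
        dims = {fam: len(d.load_family(fam)) for fam in d.FAMILY_ORDER}
        assert dims == {"blosum": 10, "cruciani": 3, "fasgai": 6, "kidera": 10,
                        "mswhim": 3, "pcp": 5, "physical": 2, "protfp": 8,
                        "sneath": 4, "svger": 11, "st": 8, "t": 5, "vhse": 8,
                        "z": 5}
        assert sum(dims.values()) == 88

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            d.family_descriptors("ARN", "atchley")

    def test_family_homopolymer_identity(self):
        kf = d.family_descriptors("AAAA", "kidera")
        table = read_raw_table("kidera.csv")
        np.testing.assert_allclose(kf, table.loc["A"].to_numpy(), atol=1e-12)

    def test_vhse_tripeptide_against_hand_lookup(self):
        got = d.family_descriptors("ARN", "vhse")
        expect = brute_force_family("ARN", "vhse.csv")
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_brute_force_oracle_all_families(self, random_sequences):
        """Every family descriptor equals per-residue table recomputation."""
        for seq in random_sequences[:50]:
            for fam, (fname, _) in d.FAMILY_FILES.items():
                np.testing.assert_allclose(
                    d.family_descriptors(seq, fam),
                    brute_force_family(seq, fname), atol=1e-9)


class TestChargeAndIsoelectricPoint:
    def test_lysine_at_ph0_close_to_plus_two(self):
        assert d.net_charge("K", 0.0) == pytest.approx(2.0, abs=1e-3)

    def test_glutamate_at_ph7_hand_computed(self):
        # three ionizable groups: N-terminus 8.6, C-terminus 3.6, side chain 4.1
        expect = (1 / (1 + 10 ** (7.0 - 8.6))
                  - 1 / (1 + 10 ** (3.6 - 7.0))
                  - 1 / (1 + 10 ** (4.1 - 7.0)))
        assert d.net_charge("E", 7.0) == pytest.approx(expect, abs=1e-12)

    @given(PEPTIDE)
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_strictly_decreasing_in_ph(self, seq):
        phs = np.linspace(0.0, 14.0, 15)
        q = [d.net_charge(seq, p) for p in phs]
        assert all(a > b for a, b in zip(q, q[1:]))

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            d.net_charge("ACD", -1.0)

    def test_isoelectric_point_brackets_zero(self, random_sequences):
        for seq in random_sequences[:20]:
            pi = d.isoelectric_point(seq, tol=1e-4)
            assert d.net_charge(seq, pi - 1e-3) > 0 > d.net_charge(seq, pi + 1e-3)

    def test_glycine_pi_matches_grid_search(self):
        grid = np.linspace(0.0, 14.0, 140001)
        charges = np.array([d.net_charge("G", p) for p in grid])
        zero_crossing = grid[np.argmin(np.abs(charges))]
        assert d.isoelectric_point("G", tol=1e-6) == pytest.approx(
            zero_crossing, abs=1e-3)

    def test_polylysine_pi_basic(self):
        assert d.isoelectric_point("KKKK") > 7.0


class TestScalarIndices:
    def test_boman_single_residue_and_homopolymer(self):
        table = read_raw_table("boman.csv")["value"]
        assert d.boman("R") == pytest.approx(table["R"])
        assert d.boman("RRRR") == pytest.approx(table["R"])
        assert d.boman("FF") == pytest.approx(d.boman("F"))

    def test_hydrophobicity_hand_lookup(self):
        kd = read_raw_table("kyte_doolittle.csv")["value"]
        assert d.hydrophobicity("IL") == pytest.approx((kd["I"] + kd["L"]) / 2)
        assert d.hydrophobicity("VVV") == pytest.approx(kd["V"])

    def test_hydrophobicity_unknown_scale(self):
        with pytest.raises(FileNotFoundError):
            d.hydrophobicity("IL", scale_name="nonexistent_scale")

    def test_moment_single_residue_is_abs_eisenberg(self):
        eis = read_raw_table("eisenberg.csv")["value"]
        assert d.hydrophobic_moment("R") == pytest.approx(abs(eis["R"]))

    def test_moment_angle_zero_is_abs_window_mean(self):
        eis = read_raw_table("eisenberg.csv")["value"]
        seq = "ILKAM"
        expect = abs(np.mean([eis[a] for a in seq]))
        assert d.hydrophobic_moment(seq, angle_deg=0.0) == pytest.approx(expect)

    def test_moment_11mer_direct_trig_oracle(self):
        eis = read_raw_table("eisenberg.csv")["value"]
        seq = "ILKAMWFGSTY"
        delta = math.radians(100.0)
        s = sum(eis[a] * math.sin(i * delta) for i, a in enumerate(seq))
        c = sum(eis[a] * math.cos(i * delta) for i, a in enumerate(seq))
        expect = math.sqrt(s * s + c * c) / len(seq)
        assert d.hydrophobic_moment(seq) == pytest.approx(expect, abs=1e-12)

    def test_instability_dipeptide_cases(self):
        from Bio.SeqUtils.ProtParamData import DIWV
        assert d.instability_index("GG") == pytest.approx(5.0 * DIWV["G"]["G"])
        assert d.instability_index("WW") == pytest.approx(5.0 * DIWV["W"]["W"])

    def test_instability_5mer_hand_sum_and_biopython(self):
        from Bio.SeqUtils.ProtParamData import DIWV
        seq = "CASSF"
        expect = 2.0 * sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
        assert d.instability_index(seq) == pytest.approx(expect, abs=1e-9)
        assert d.instability_index(seq) == pytest.approx(
            ProteinAnalysis(seq).instability_index(), abs=1e-6)

    def test_instability_length_one_warns_zero(self):
        with pytest.warns(UserWarning):
            assert d.instability_index("G") == 0.0

    def test_molecular_weight_glycine(self):
        assert d.molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_molecular_weight_monotone_in_appending(self):
        assert d.molecular_weight("CASSF") > d.molecular_weight("CASS")

    def test_molecular_weight_against_biopython(self, random_sequences):
        for seq in random_sequences[:20]:
            ours = d.molecular_weight(seq)
            assert ours == pytest.approx(ProteinAnalysis(seq).molecular_weight(),
                                         rel=1e-4)

    def test_mass_over_charge(self):
        mw = d.molecular_weight("G")
        assert d.mass_over_charge("G", 1) == pytest.approx(mw + 1.00728)
        assert d.mass_over_charge("CASSF", 2) < d.mass_over_charge("CASSF", 1)
        with pytest.raises(ValueError):
            d.mass_over_charge("G", 0)


NON_PERMUTATION_INVARIANT = {"hydrophobic_moment", "instability_index"}


class TestFeatureVector:
    def test_census_96_named_finite(self, random_sequences):
        for seq in random_sequences[:5]:
            fv = d.feature_vector(seq)
            assert len(fv) == 96
            assert list(fv.index) == d.FEATURE_NAMES
            assert np.isfinite(fv.to_numpy()).all()

    def test_deterministic(self):
        a = d.feature_vector("CASSLGFYEQYF")
        b = d.feature_vector("CASSLGFYEQYF")
        pd.testing.assert_series_equal(a, b)

    def test_family_blocks_match_standalone_calls(self):
        seq = "SIINFEKL"
        fv = d.feature_vector(seq)
        offset = 0
        for fam in d.FAMILY_ORDER:
            block = d.family_descriptors(seq, fam)
            np.testing.assert_allclose(
                fv.iloc[offset:offset + len(block)].to_numpy(), block)
            offset += len(block)

    def test_permutation_invariance_per_descriptor(self):
        rng = np.random.default_rng(3)
        seq = "CASSLGFYEQYFW"
        shuffled = "".join(rng.permutation(list(seq)))
        a, b = d.feature_vector(seq), d.feature_vector(shuffled)
        for name in d.FEATURE_NAMES:
            if name in NON_PERMUTATION_INVARIANT:
                continue
            assert a[name] == pytest.approx(b[name], abs=1e-9), name

    def test_pair_has_192_with_prefixed_blocks(self):
        pair = d.featurize_pair("SIINFEKL", "CASSLGF")
        assert len(pair) == 192
        epi_block = pair[[f"epi_{n}" for n in d.FEATURE_NAMES]]
        np.testing.assert_allclose(epi_block.to_numpy(),
                                   d.feature_vector("SIINFEKL").to_numpy())

    def test_pair_swap_symmetry(self):
        ab = d.featurize_pair("SIINFEKL", "CASSLGF")
        ba = d.featurize_pair("CASSLGF", "SIINFEKL")
        np.testing.assert_allclose(
            ab[[f"epi_{n}" for n in d.FEATURE_NAMES]].to_numpy(),
            ba[[f"cdr_{n}" for n in d.FEATURE_NAMES]].to_numpy())

    def test_featurize_pairs_matches_per_pair(self):
        epis, cdrs = ["SIINFEKL", "GILGFVFTL"], ["CASSLGF", "CASSIRSSYEQYF"]
        X = d.featurize_pairs(epis, cdrs)
        assert X.shape == (2, 192)
        np.testing.assert_allclose(
            X.iloc[1].to_numpy(), d.featurize_pair(epis[1], cdrs[1]).to_numpy())
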
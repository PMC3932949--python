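import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnakit import features as feat
from srnakit.structures import HairpinRecord, decompose, parse_dot_bracket

from _oracles import fscore_oracle


class TestComposition:
    def test_gcgc(self):
        values = feat.composition_features("GCGC")
        assert values["%(|G|+|C|)"] == 100.0
        assert values["%GC"] == pytest.approx(200 / 3)
        assert values["%CG"] == pytest.approx(100 / 3)
        assert sum(values[f"%{xy}"] for xy in feat.DINUCLEOTIDES
                   if xy not in ("GC", "CG")) == 0.0

    def test_homopolymer(self):
        values = feat.composition_features("AAAA")
        assert values["%(|G|+|C|)"] == 0.0
        assert values["%AA"] == 100.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            feat.composition_features("A")


class TestPairing:
    def test_simple_hairpin(self):
        pt = parse_dot_bracket("((((...))))")
        values = feat.pairing_features(pt, decompose(pt))
        assert values["r_p_n"] == pytest.approx(8 / 11)
        assert values["r_unp_n"] == pytest.approx(3 / 11)
        assert values["r_p_unp"] == pytest.approx(8 / 3)
        assert values["dP"] == pytest.approx(4 / 11)
        assert values["avg_bp_stem"] == 4.0
        assert values["n_bulge"] == 0.0
        assert values["MCPN"] == 4.0

    def test_bulged_hairpin(self):
        pt = parse_dot_bracket("((..((...))..))")
        values = feat.pairing_features(pt, decompose(pt))
        assert values["n_bulge"] == 1.0
        assert values["r_unp_bulge"] == 7.0  # 7 unpaired nt / 1 bulge

    def test_fully_unpaired_zero_policy(self):
        pt = parse_dot_bracket("......")
        values = feat.pairing_features(pt, decompose(pt))
        assert values["r_p_n"] == 0.0
        assert values["r_p_unp"] == 0.0  # 0 paired over 6 unpaired
        assert values["dP"] == 0.0
        assert values["avg_bp_stem"] == 0.0  # zero stems -> defined 0


class TestTriplets:
    def test_unpaired_homopolymer(self):
        values = feat.triplet_features("AAAA", "....")
        assert values["A..."] == 1.0
        assert sum(v for k, v in values.items() if k != "A...") == 0.0

    def test_paired_dimer(self):
        values = feat.triplet_features("GCGC", "(())")
        assert values["C((("] == 0.5
        assert values["G((("] == 0.5

    def test_too_short(self):
        with pytest.raises(ValueError):
            feat.triplet_features("AC", "..")


class TestEnergy:
    def test_ratios(self):
        pt = parse_dot_bracket("((((...))))")
        el = decompose(pt)
        values = feat.energy_features(-30.0, 60, 50.0, pt, el)
        assert values["dG"] == pytest.approx(-0.5)
        assert values["MFE1"] == pytest.approx(-0.01)
        assert values["MFE4"] == pytest.approx(-30.0 / 4)
        assert values["MFE5"] == 0.0  # no bulges -> defined 0

    def test_mfe4_with_20_pairs(self):
        structure = "(" * 20 + "..." + ")" * 20
        pt = parse_dot_bracket(structure)
        values = feat.energy_features(-30.0, len(structure), 50.0, pt, decompose(pt))
        assert values["MFE4"] == pytest.approx(-1.5)


class TestFullVector:
    def test_vector_order_and_determinism(self, hairpin_sets):
        rec = hairpin_sets[0][0]
        v1, v2 = feat.extract_all(rec), feat.extract_all(rec)
        assert list(v1) == list(feat.FEATURE_NAMES)
        assert len(v1) == 65
        assert v1 == v2

    def test_invariants_on_random_structures(self, random_structure_bank):
        """Dinucleotides sum to 100, triplets to 1, pairing ratios are consistent."""
        matrix = feat.feature_matrix(random_structure_bank)
        dinu = matrix[[f"%{xy}" for xy in feat.DINUCLEOTIDES]]
        assert np.allclose(dinu.sum(axis=1), 100.0, atol=1e-9)
        assert ((dinu.values >= 0) & (dinu.values <= 100)).all()
        triplets = matrix[list(feat.TRIPLET_ELEMENTS)]
        assert np.allclose(triplets.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(matrix["r_p_n"] + matrix["r_unp_n"], 1.0, atol=1e-9)
        assert np.allclose(matrix["dP"], matrix["r_p_n"] / 2, atol=1e-9)
        lengths = np.array([r.length for r in random_structure_bank])
        pt_bps = np.array(
            [parse_dot_bracket(r.structure).n_basepairs for r in random_structure_bank]
        )
        assert np.allclose(matrix["dP"] * lengths, pt_bps, atol=1e-9)


class TestFScore:
    def test_hand_example(self):
        assert feat.fscore([2, 0], [-2, 0]) == pytest.approx(0.5)

    def test_equal_means_zero_numerator(self):
        assert feat.fscore([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_degenerate_variances(self):
        assert feat.fscore([1, 1], [2, 2]) == math.inf
        assert feat.fscore([1, 1], [1, 1]) == 0.0

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pos = rng.normal(1, 2, size=8).tolist()
            neg = rng.normal(-0.5, 1, size=6).tolist()
            assert feat.fscore(pos, neg) == pytest.approx(fscore_oracle(pos, neg))

    @settings(max_examples=50, deadline=None)
    @given(
        pos=st.lists(st.floats(-50, 50), min_size=3, max_size=10),
        neg=st.lists(st.floats(-50, 50), min_size=3, max_size=10),
        scale=st.floats(0.01, 100),
    )
    def test_symmetry_and_scale_invariance(self, pos, neg, scale):
        f = feat.fscore(pos, neg)
        assert f >= 0
        assert feat.fscore(neg, pos) == pytest.approx(f, rel=1e-9, abs=1e-12)
        scaled = feat.fscore([x * scale for x in pos], [x * scale for x in neg])
        if math.isfinite(f):
            assert scaled == pytest.approx(f, rel=1e-6, abs=1e-9)


class TestRankFeatureSets:
    def _toy(self):
        rng = np.random.default_rng(0)
        n = 30
        matrix = pd.DataFrame(
            {
                "strong": np.r_[rng.normal(3, 1, n), rng.normal(-3, 1, n)],
                "weak": np.r_[rng.normal(0.3, 1, n), rng.normal(0, 1, n)],
                "noise1": rng.normal(0, 1, 2 * n),
                "noise2": rng.normal(0, 1, 2 * n),
                "paired_a": np.r_[rng.normal(1, 1, n), rng.normal(-1, 1, n)],
                "paired_b": np.r_[rng.normal(0.5, 1, n), rng.normal(-0.5, 1, n)],
            }
        )
        labels = np.array([1] * n + [-1] * n)
        catalog = feat.FeatureSetCatalog(
            sets={
                "strong": ("strong",),
                "weak": ("weak",),
                "noise": ("noise1", "noise2"),
                "pair_block": ("paired_a", "paired_b"),
            }
        )
        return matrix, labels, catalog

    def test_matches_bruteforce_averaging(self):
        matrix, labels, catalog = self._toy()
        ranking = feat.rank_feature_sets(matrix, labels, catalog, k=4)
        expected = {}
        for set_id, members in catalog.sets.items():
            scores = [
                fscore_oracle(
                    matrix.loc[labels == 1, m].tolist(),
                    matrix.loc[labels == -1, m].tolist(),
                )
                for m in members
            ]
            expected[set_id] = sum(scores) / len(scores)
        got = dict(zip(ranking.set_id, ranking.mean_fscore))
        for set_id, value in expected.items():
            assert got[set_id] == pytest.approx(value)
        assert list(ranking.set_id) == sorted(expected, key=expected.get, reverse=True)

    def test_k_truncation_and_zero_rank(self):
        matrix, labels, catalog = self._toy()
        full = feat.rank_feature_sets(matrix, labels, catalog, k=99)
        assert len(full) == 4
        top1 = feat.rank_feature_sets(matrix, labels, catalog, k=1)
        assert list(top1.set_id) == ["strong"]
        assert full.iloc[-1].set_id == "noise"

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            feat.FeatureSetCatalog(sets={"empty": ()})

    def test_default_catalog_partitions_features(self):
        catalog = feat.FeatureSetCatalog.default()
        members = [m for s in catalog.sets.values() for m in s]
        assert sorted(members) == sorted(feat.FEATURE_NAMES)
        assert len(catalog.sets["dinucleotides"]) == 16
        assert len(catalog.sets["triplet_elements"]) == 32
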
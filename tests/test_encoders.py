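"""Feature-encoder correctness against closed-form examples and independent
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from promoter70 import encoders as enc
from promoter70.encoders import (
    DINUCS,
    TRINUCS,
    EncoderConfig,
    PSTNPTable,
    dac,
    dacc,
    dcc,
    eiip_pse,
    encode_all,
    feature_names,
    kmer_counts,
    mac,
    mono_composition,
    motif_counts,
    nmbac,
    pc_pse_tnc,
    pstnp_encode,
    pstnp_fit,
    skews,
)
from promoter70.seqio import WINDOW_LEN, NucleotideSequence

from conftest import random_seq


def _seq(s):
    return NucleotideSequence("t", s)


def di_dicts(cfg):
    return oracles.props_as_dicts(cfg.di_prop_names, cfg.di_props, DINUCS)


def tri_dicts(cfg):
    return oracles.props_as_dicts(cfg.tri_prop_names, cfg.tri_props, TRINUCS)


class TestCompositionFamilies:
    def test_mono_trivial(self):
        assert mono_composition(_seq("AAAA")).tolist() == [1, 0, 0, 0]
        assert mono_composition(_seq("ACGT")).tolist() == [0.25] * 4

    def test_kmer_trivial(self):
        c2 = kmer_counts(_seq("AAAA"), 2)
        assert c2[0] == 3 and c2.sum() == 3
        c3 = kmer_counts(_seq("ACGT"), 3)
        assert c3[TRINUCS.index("ACG")] == 1
        assert c3[TRINUCS.index("CGT")] == 1
        assert c3.sum() == 2

    def test_kmer_too_short(self):
        with pytest.raises(ValueError, match="shorter than k"):
            kmer_counts(_seq("AC"), 3)

    @pytest.mark.parametrize(
        "seq,gc,at",
        [("GGCC", 0.0, 0.0), ("GGGC", 0.5, 0.0), ("AAAA", 0.0, 1.0)],
    )
    def test_skews_trivial(self, seq, gc, at):
        assert skews(_seq(seq)) == (gc, at)

    def test_eiip_homopolymer(self, cfg):
        v = eiip_pse(_seq("AAAAA"), cfg)
        assert v[0] == pytest.approx(3 * 0.1260, abs=1e-12)
        assert np.count_nonzero(v) == 1

    def test_motif_overlapping(self, cfg):
        counts = motif_counts(_seq("TATAATATAAT"), cfg)
        assert counts[list(cfg.motifs).index("TATAAT")] == 2
        assert counts[list(cfg.motifs).index("TTGACA")] == 0


class TestPSTNP:
    def test_identical_classes_zero_table(self, rng):
        seqs = [random_seq(rng, ident=f"s{i}") for i in range(5)]
        z = pstnp_fit(seqs, list(seqs)).z
        assert np.all(z == 0)

    def test_single_sequence_unit_entries(self):
        pos = [_seq("A" * WINDOW_LEN)]
        neg = [_seq("C" * WINDOW_LEN)]
        table = pstnp_fit(pos, neg)
        assert table.z[0, TRINUCS.index("AAA")] == 1.0
        assert table.z[0, TRINUCS.index("CCC")] == -1.0

    def test_rows_sum_to_zero(self, rng):
        pos = [random_seq(rng, ident=f"p{i}") for i in range(10)]
        neg = [random_seq(rng, ident=f"n{i}") for i in range(10)]
        z = pstnp_fit(pos, neg).z
        assert np.abs(z.sum(axis=1)).max() < 1e-12
        assert z.min() >= -1 and z.max() <= 1

    def test_fit_matches_counting_oracle(self, rng):
        pos = [random_seq(rng, ident=f"p{i}") for i in range(10)]
        neg = [random_seq(rng, ident=f"n{i}") for i in range(10)]
        z = pstnp_fit(pos, neg).z
        zo = oracles.oracle_pstnp([s.seq for s in pos], [s.seq for s in neg])
        np.testing.assert_allclose(z, zo, atol=1e-12)

    def test_encode_matches_lookup_oracle(self, rng):
        z = rng.uniform(-1, 1, (WINDOW_LEN - 2, 64))
        table = PSTNPTable(z)
        s = random_seq(rng)
        np.testing.assert_allclose(
            pstnp_encode(s, table), oracles.oracle_pstnp_encode(s.seq, z.tolist()),
            atol=1e-12,
        )

    def test_training_positive_under_identical_sets_encodes_zero(self, rng):
        seqs = [random_seq(rng, ident=f"s{i}") for i in range(4)]
        table = pstnp_fit(seqs, list(seqs))
        assert np.all(pstnp_encode(seqs[0], table) == 0)

    def test_empty_class_and_length_errors(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            pstnp_fit([], [random_seq(rng)])
        bad = NucleotideSequence("bad", "ACGT")
        with pytest.raises(ValueError, match="bad"):
            pstnp_fit([bad], [random_seq(rng)])


class TestAutocorrelationFamilies:
    def test_homopolymer_all_zero(self, cfg):
        s = _seq("A" * WINDOW_LEN)
        np.testing.assert_allclose(dac(s, cfg), 0, atol=1e-12)
        np.testing.assert_allclose(dcc(s, cfg), 0, atol=1e-12)
        assert np.all(mac(s, cfg) == 0)  # zero-variance convention is exact
        # NMBAC of a constant standardized value c is c^2 at every lag
        c = cfg.di_props[:, 0]  # property values of dinucleotide AA
        expected = np.repeat(c**2, cfg.lag_max)
        np.testing.assert_allclose(nmbac(s, cfg), expected, atol=1e-12)

    def test_single_term_lag(self, cfg):
        # L - d - 1 = 1: the sum collapses to a single product
        cfg3 = EncoderConfig(lag_max=2)
        s = _seq("ACGT")  # L=4, d=2 -> one term
        P = cfg3.di_props[:, [DINUCS.index(s.seq[i : i + 2]) for i in range(3)]]
        got = dac(s, cfg3)
        for u in range(P.shape[0]):
            mean = P[u].mean()
            expected = (P[u, 0] - mean) * (P[u, 2] - mean)
            assert got[u * 2 + 1] == pytest.approx(expected, abs=1e-12)

    def test_dcc_collapses_to_dac_for_cloned_property(self):
        base = EncoderConfig()
        twist = base.di_props[0:1]
        cloned = EncoderConfig(
            di_prop_names=["Twist", "TwistClone"],
            di_props=np.vstack([twist, twist]),
        )
        s = NucleotideSequence("t", "ACGTTGACATATAATGG")
        d = dcc(s, cloned)
        a = dac(s, cloned)
        np.testing.assert_allclose(d[: cloned.lag_max], a[: cloned.lag_max], atol=1e-12)

    def test_dacc_is_concatenation(self, cfg, rng):
        s = random_seq(rng)
        out = dacc(s, cfg)
        assert len(out) == len(cfg.di_prop_names) ** 2 * cfg.lag_max == 72
        np.testing.assert_array_equal(out[:12], dac(s, cfg))
        np.testing.assert_array_equal(out[12:], dcc(s, cfg))

    @pytest.mark.parametrize("family,oracle", [
        (dac, oracles.oracle_dac),
        (dcc, oracles.oracle_dcc),
        (mac, oracles.oracle_mac),
        (nmbac, oracles.oracle_nmbac),
    ])
    def test_matches_bruteforce_oracle(self, cfg, rng, family, oracle):
        props = di_dicts(cfg)
        for _ in range(25):
            s = random_seq(rng)
            np.testing.assert_allclose(
                family(s, cfg), oracle(s.seq, props, cfg.lag_max), atol=1e-9
            )


class TestPcPseTnc:
    def test_w_zero_collapses_to_frequencies(self, rng):
        cfg0 = EncoderConfig(pse_weight=0.0)
        s = random_seq(rng)
        out = pc_pse_tnc(s, cfg0)
        np.testing.assert_allclose(out[:64], kmer_counts(s, 3) / 79.0, atol=1e-12)
        assert np.all(out[64:] == 0)

    @given(st.text(alphabet="ACGT", min_size=10, max_size=81))
    @settings(max_examples=40, derandomize=True)
    def test_sums_to_one(self, seq):
        cfg = EncoderConfig()
        out = pc_pse_tnc(NucleotideSequence("h", seq), cfg)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= 0)

    def test_matches_bruteforce_oracle(self, cfg, rng):
        tri = tri_dicts(cfg)
        for _ in range(25):
            s = random_seq(rng)
            np.testing.assert_allclose(
                pc_pse_tnc(s, cfg),
                oracles.oracle_pc_pse_tnc(s.seq, tri, cfg.pse_lambda, cfg.pse_weight),
                atol=1e-9,
            )


class TestEncodeAll:
    def test_deterministic_and_dimension(self, cfg, rng):
        pos = [random_seq(rng, ident=f"p{i}") for i in range(4)]
        neg = [random_seq(rng, ident=f"n{i}") for i in range(4)]
        table = pstnp_fit(pos, neg)
        m1 = encode_all(pos + neg, cfg, table)
        m2 = encode_all(pos + neg, cfg, table)
        np.testing.assert_array_equal(m1.values, m2.values)
        # family dimensions: 16+64+2+64+79+12+60+72+12+12+66+2
        assert m1.values.shape == (8, 461)
        assert len(set(m1.feature_names)) == 461

    def test_family_slices_equal_standalone_ops(self, cfg, rng):
        pos = [random_seq(rng, ident=f"p{i}") for i in range(3)]
        neg = [random_seq(rng, ident=f"n{i}") for i in range(3)]
        table = pstnp_fit(pos, neg)
        m = encode_all(pos, cfg, table).to_dataframe()
        s = pos[0]
        np.testing.assert_allclose(
            m.loc[s.id, [f"TNC|{w}" for w in TRINUCS]].to_numpy(),
            kmer_counts(s, 3), atol=0,
        )
        np.testing.assert_allclose(
            m.loc[s.id, [n for n in m.columns if n.startswith("PSTNP|")]].to_numpy(),
            pstnp_encode(s, table), atol=0,
        )
        np.testing.assert_allclose(
            m.loc[s.id, [n for n in m.columns if n.startswith("MAC|")]].to_numpy(),
            mac(s, cfg), atol=0,
        )

    def test_pstnp_block_optional(self, cfg, rng):
        m = encode_all([random_seq(rng)], cfg, table=None)
        assert m.values.shape[1] == 461 - 79
        assert not any(n.startswith("PSTNP|") for n in m.feature_names)

    def test_wrong_length_names_record(self, cfg):
        with pytest.raises(ValueError, match="shorty"):
            encode_all([NucleotideSequence("shorty", "ACGT")], cfg)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            EncoderConfig(lag_max=0)
        with pytest.raises(ValueError):
            EncoderConfig(pse_weight=1.5)
        with pytest.raises(ValueError):
            EncoderConfig(pse_lambda=WINDOW_LEN)

    def test_config_roundtrips_via_flat_dict(self):
        cfg = EncoderConfig(lag_max=3, pse_lambda=4, pse_weight=0.1,
                            motifs=("TATAAT",))
        back = EncoderConfig.from_dict(cfg.to_dict())
        assert back.lag_max == 3 and back.pse_lambda == 4
        assert back.pse_weight == 0.1 and back.motifs == ("TATAAT",)
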
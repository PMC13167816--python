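import numpy as np
import pytest

import optxfe as ox
from optxfe.dlob import (
    ALPHABET,
    DEFAULT_LUT,
    build_dlob_string,
    dlob_connectome,
    dlob_entropy,
    dlob_histogram,
    dlob_report,
    index_to_channel_pair,
    parse_dlob_string,
    validate_lut,
)


class TestLut:
    def test_default_lut_shape(self):
        assert len(DEFAULT_LUT) == 35
        assert len(set(DEFAULT_LUT)) == 13
        assert set(DEFAULT_LUT) == set(ALPHABET)

    def test_position_17_is_tr(self):
        assert DEFAULT_LUT[16] == "TR"

    def test_bad_lut_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            validate_lut(("FL", "XX"))
        with pytest.raises(ValueError, match="channels"):
            validate_lut(("FL", "FR"), cn=3)


class TestIndexArithmetic:
    @pytest.mark.parametrize(
        "ind,cn,expected",
        [(1, 35, (1, 1)), (36, 35, (2, 1)), (6125, 35, (35, 35)), (2, 35, (1, 2))],
    )
    def test_examples(self, ind, cn, expected):
        assert index_to_channel_pair(ind, cn) == expected

    def test_operator_blocks_fold_onto_same_grid(self):
        for cn in (2, 5):
            for u in range(1, cn * cn + 1):
                pairs = {index_to_channel_pair(u + b * cn * cn, cn) for b in range(5)}
                assert len(pairs) == 1

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            index_to_channel_pair(0, 35)


class TestStringBuild:
    def test_two_symbols_per_feature(self):
        symbols = build_dlob_string([1, 36, 6125], DEFAULT_LUT)
        assert len(symbols) == 6
        # ind 1 -> channels (1, 1) -> FL FL; ind 6125 -> (35, 35) -> TR TR
        assert symbols[:2] == ("FL", "FL")
        assert symbols[4:] == ("TR", "TR")

    def test_channel_17_pair_gives_trtr(self):
        ind = (17 - 1) * 35 + 17  # cell (q=17, w=17)
        assert build_dlob_string([ind], DEFAULT_LUT) == ("TR", "TR")

    def test_empty_selection(self):
        assert build_dlob_string([], DEFAULT_LUT) == ()

    def test_duplicates_kept(self):
        assert len(build_dlob_string([5, 5, 5], DEFAULT_LUT)) == 6


class TestParse:
    def test_simple_split(self):
        assert parse_dlob_string("TRCRTRFz") == ("TR", "CR", "TR", "Fz")

    def test_empty(self):
        assert parse_dlob_string("") == ()

    def test_trailing_period_and_whitespace_tolerated(self):
        assert parse_dlob_string(" TRCR\n.") == ("TR", "CR")

    def test_unknown_chunk_names_offset(self):
        with pytest.raises(ValueError, match="offset 2"):
            parse_dlob_string("TRXX")

    def test_reference_sentence_has_144_symbols(self, reference_symbols):
        assert len(reference_symbols) == 144


class TestStatistics:
    def test_histogram_counts(self):
        h = dlob_histogram(("TR", "CR", "TR"))
        assert h[ALPHABET.index("TR")] == 2
        assert h[ALPHABET.index("CR")] == 1
        assert h.sum() == 3

    def test_histogram_conservation(self, reference_symbols):
        assert dlob_histogram(reference_symbols).sum() == len(reference_symbols)

    def test_reference_argmax_is_tr(self, reference_symbols):
        h = dlob_histogram(reference_symbols)
        assert ALPHABET[int(np.argmax(h))] == "TR"

    def test_connectome_counts(self):
        cd = dlob_connectome(("TR", "CR", "TR"))
        i, j = ALPHABET.index("TR"), ALPHABET.index("CR")
        assert cd[i, j] == 1 and cd[j, i] == 1
        assert cd.sum() == 2

    def test_connectome_conservation(self, reference_symbols):
        assert dlob_connectome(reference_symbols).sum() == len(reference_symbols) - 1

    def test_reference_tr_dominates_connectome(self, reference_symbols):
        cd = dlob_connectome(reference_symbols)
        strength = cd.sum(axis=0) + cd.sum(axis=1)
        tr = ALPHABET.index("TR")
        others = np.delete(strength, tr)
        assert strength[tr] > others.max()

    def test_connectome_needs_two_symbols(self):
        with pytest.raises(ValueError):
            dlob_connectome(("TR",))

    def test_uniform_entropy_is_maximal(self):
        ent, ratio = dlob_entropy(np.ones(13))
        assert ent == pytest.approx(3.7004, abs=5e-5)
        assert ratio == pytest.approx(100.0)

    def test_degenerate_entropy_zero(self):
        h = np.zeros(13)
        h[4] = 99
        ent, ratio = dlob_entropy(h)
        assert ent == 0.0 and ratio == 0.0

    def test_entropy_bounds_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            h = rng.integers(0, 20, size=13)
            if h.sum() == 0:
                continue
            ent, ratio = dlob_entropy(h)
            assert 0.0 <= ent <= np.log2(13) + 1e-12
            assert 0.0 <= ratio <= 100.0 + 1e-9

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            dlob_entropy(np.zeros(13))

    def test_reference_entropy_and_ratio(self, reference_symbols):
        rep = dlob_report(reference_symbols)
        assert rep.entropy_bits == pytest.approx(2.4015, abs=5e-4)
        assert rep.complexity_ratio_percent == pytest.approx(64.90, abs=0.05)

    def test_report_json_roundtrip_fields(self, reference_symbols):
        d = dlob_report(reference_symbols).to_json_dict()
        assert d["n_symbols"] == 144
        assert sum(d["histogram"].values()) == 144
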
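"""Feature construction: block contents, padding, layout widths, weighting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_chain
from rsapred.errors import ConfigurationError, MissingInputError
from rsapred.feature_encoding import (
    ALL_BLOCKS,
    WindowSpec,
    apply_window_weighting,
    assemble_features,
    encode_disorder_window,
    encode_physchem_window,
    encode_pssm_window,
    encode_sequence_features,
    encode_ss_global,
    encode_ss_local,
    expected_width,
    logistic_normalize,
    window_multipliers,
)
from rsapred.io_formats import ChainRecord
from rsapred.window_weights import WindowWeights


class TestLogistic:
    def test_zero_maps_to_half(self):
        assert logistic_normalize(0.0) == pytest.approx(0.5)

    def test_known_value(self):
        # independent scalar evaluation of 1/(1+e^-2)
        assert logistic_normalize(2.0) == pytest.approx(0.880797, abs=1e-6)

    @given(st.floats(min_value=-50, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, x):
        assert logistic_normalize(x) + logistic_normalize(-x) == pytest.approx(1.0)

    def test_non_finite_raises(self):
        with pytest.raises(ConfigurationError):
            logistic_normalize(float("nan"))


@pytest.mark.parametrize("n", [5, 7, 9, 11, 13])
def test_block_widths_for_every_window(n, scales):
    """Widths are 21N, 3N, 6, 3N, 1, 1, 6N; total 33N + 8."""
    chain = make_chain("ACDEFGHIKLMNPQRSTVWY")
    spec = WindowSpec(n)
    fm = assemble_features(chain, spec, scales)
    widths = dict(fm.layout)
    assert widths["pssm_window"] == 21 * n
    assert widths["ss_local"] == 3 * n
    assert widths["ss_global"] == 6
    assert widths["disorder"] == 3 * n
    assert widths["seq_len"] == 1
    assert widths["seq_pos"] == 1
    assert widths["physchem"] == 6 * n
    assert fm.width == 33 * n + 8 == expected_width(spec)


class TestPssmWindow:
    def test_window9_length_and_terminal_padding(self):
        chain = make_chain("ACDEFGHIKL", pssm_scores=np.ones((10, 20)))
        vec = encode_pssm_window(chain, 0, WindowSpec(9))
        assert vec.shape == (189,)
        for w in range(4):  # positions -4..-1 are pseudo residues
            sub = vec[21 * w : 21 * (w + 1)]
            assert np.array_equal(sub[:20], np.zeros(20))
            assert sub[20] == 1.0
        real = vec[21 * 4 : 21 * 5]
        assert np.allclose(real[:20], logistic_normalize(1.0))
        assert real[20] == 0.0

    def test_real_values_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        chain = make_chain("ACDEFGHIKL", pssm_scores=rng.normal(0, 3, (10, 20)))
        vec = encode_pssm_window(chain, 5, WindowSpec(5))
        values = vec.reshape(5, 21)[:, :20]
        assert np.all((values > 0) & (values < 1))

    def test_degenerate_window_of_one(self):
        chain = make_chain("ACD", pssm_scores=np.full((3, 20), 2.0))
        vec = encode_pssm_window(chain, 1, WindowSpec(1))
        assert vec.shape == (21,)
        assert np.allclose(vec[:20], logistic_normalize(2.0))
        assert vec[20] == 0.0

    def test_missing_profile_raises(self):
        chain = ChainRecord("c1", "ACD")
        with pytest.raises(MissingInputError):
            encode_pssm_window(chain, 0, WindowSpec(5))

    def test_optional_real_terminal_flag(self):
        chain = make_chain("ACDEF")
        vec = encode_pssm_window(chain, 0, WindowSpec(1), flag_real_terminals=True)
        assert vec[20] == 1.0
        vec_mid = encode_pssm_window(chain, 2, WindowSpec(1), flag_real_terminals=True)
        assert vec_mid[20] == 0.0


class TestSsLocal:
    def test_certain_coil_interior(self):
        chain = make_chain("ACDEFGH")
        vec = encode_ss_local(chain, 3, WindowSpec(5))
        assert vec.shape == (15,)
        assert np.array_equal(vec.reshape(5, 3), np.tile([1, 0, 0], (5, 1)))

    def test_padding_triples_are_zero(self):
        chain = make_chain("ACDEF")
        vec = encode_ss_local(chain, 0, WindowSpec(5))
        assert np.array_equal(vec[:6], np.zeros(6))

    def test_window_of_one(self):
        chain = make_chain("ACD", states="CHE")
        assert np.array_equal(encode_ss_local(chain, 1, WindowSpec(1)), [0, 1, 0])


class TestSsGlobal:
    def test_single_type_sequence(self):
        vec = encode_ss_global(make_chain("ACDEF", states="CCCCC"))
        assert np.allclose(vec, [0, 0, 1, 0, 0, 1])

    def test_hand_counted_contents_and_segments(self):
        # H:4/8, E:1/8, C:3/8; runs H,E,C -> one segment each
        vec = encode_ss_global(make_chain("ACDEFGHI", states="HHHHECCC"))
        assert np.allclose(vec[:3], [0.5, 0.125, 0.375])
        assert np.allclose(vec[3:], [1 / 3, 1 / 3, 1 / 3])

    def test_short_helix_replaced_by_coil_for_segments(self):
        # contents from raw string; HH run <= 2 becomes C for segment counting
        vec = encode_ss_global(make_chain("ACDEFGH", states="CCHHCCC"))
        assert np.allclose(vec[:3], [2 / 7, 0, 5 / 7])
        assert np.allclose(vec[3:], [0, 0, 1])

    @given(st.text(alphabet="CHE", min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_triples_each_sum_to_one(self, states):
        chain = make_chain("A" * len(states), states=states)
        vec = encode_ss_global(chain)
        assert vec[:3].sum() == pytest.approx(1.0)
        assert vec[3:].sum() == pytest.approx(1.0)


class TestDisorderWindow:
    def test_fully_ordered_interior(self):
        chain = make_chain("ACDEFGH")
        vec = encode_disorder_window(chain, 3, WindowSpec(3)).reshape(3, 3)
        assert np.array_equal(vec, np.tile([0, 1, 0], (3, 1)))

    def test_padding_positions_zero(self):
        chain = make_chain("ACD")
        vec = encode_disorder_window(chain, 0, WindowSpec(3))
        assert np.array_equal(vec[:3], np.zeros(3))

    def test_threshold_rule_in_triple(self):
        chain = make_chain("ACD", p_disorder=[0.0, 0.7, 0.0])
        vec = encode_disorder_window(chain, 1, WindowSpec(1))
        assert np.allclose(vec, [0.7, 0.3, 1.0])


class TestSequenceFeatures:
    def test_centre_position_is_one(self):
        chain = make_chain("A" * 11)
        assert encode_sequence_features(chain, 5)[1] == pytest.approx(1.0)

    def test_first_residue_hand_value(self):
        chain = make_chain("A" * 11)
        # 1 - |1 - 6| / 5.5
        assert encode_sequence_features(chain, 0)[1] == pytest.approx(0.090909, abs=1e-6)

    def test_length_normalised_by_thousand(self):
        chain = make_chain("A" * 500)
        assert encode_sequence_features(chain, 0)[0] == pytest.approx(0.5)


class TestPhyschem:
    def test_poly_a_interior_repeats_a_vector(self, scales):
        chain = make_chain("AAAAAAA")
        vec = encode_physchem_window(chain, 3, WindowSpec(3), scales).reshape(3, 6)
        assert np.allclose(vec, np.tile(scales.vector("A"), (3, 1)))

    def test_padding_positions_zero(self, scales):
        chain = make_chain("AAA")
        vec = encode_physchem_window(chain, 0, WindowSpec(3), scales)
        assert np.array_equal(vec[:6], np.zeros(6))

    def test_window_of_one(self, scales):
        chain = make_chain("W")
        vec = encode_physchem_window(chain, 0, WindowSpec(1), scales)
        assert np.allclose(vec, scales.vector("W"))

    def test_scales_normalised_to_unit_interval(self, scales):
        for name, table in scales.normalized.items():
            vals = [table[a] for a in "ARNDCQEGHILKMFPSTWYV"]
            assert min(vals) == 0.0 and max(vals) == 1.0, name


class TestWeighting:
    def _weights(self, coeffs):
        return WindowWeights(window=len(coeffs) + 1, coefficients=np.array(coeffs),
                             intercept=0.0)

    def test_uniform_coefficients_are_identity(self):
        w = self._weights([0.3, 0.3, 0.3, 0.3])
        vec = np.arange(10.0)
        out = apply_window_weighting(vec, WindowSpec(5), w, mode="max")
        assert np.allclose(out, vec)

    def test_zero_off_centre_keeps_only_centre(self):
        w = self._weights([0.0, 0.0, 0.0, 0.0])
        vec = np.ones(10)
        out = apply_window_weighting(vec, WindowSpec(5), w, mode="raw").reshape(5, 2)
        assert np.allclose(out[2], 1.0)
        assert np.allclose(np.delete(out, 2, axis=0), 0.0)

    def test_fitted_shape_scales_far_neighbours_least(self):
        # decreasing influence away from the centre, echoing fitted profiles
        w = self._weights([0.04, 0.14, 0.27, 0.39, 0.39, 0.26, 0.14, 0.04])
        m = window_multipliers(WindowSpec(9), w, mode="max")
        assert m[4] == 1.0
        assert m[0] == min(m) and m[8] == pytest.approx(m[0], abs=0.01)

    def test_window_mismatch_raises(self):
        w = self._weights([0.1] * 4)
        with pytest.raises(ConfigurationError):
            apply_window_weighting(np.ones(14), WindowSpec(7), w)


class TestAssemble:
    def test_full_layout_width_for_window9(self, scales, spec9):
        chain = make_chain("ACDEFGHIKLMNPQRSTVWY")
        fm = assemble_features(chain, spec9, scales)
        assert fm.width == 305

    def test_pssm_only_layout(self, scales, spec9):
        chain = make_chain("ACDEFGHIKL")
        fm = assemble_features(chain, spec9, scales, blocks=("pssm_window",))
        assert fm.width == 189

    def test_single_residue_chain(self, scales, spec9):
        fm = assemble_features(make_chain("A"), spec9, scales)
        assert fm.values.shape == (1, 305)
        flags = fm.block("pssm_window").reshape(9, 21)[:, 20]
        assert np.array_equal(flags, [1, 1, 1, 1, 0, 1, 1, 1, 1])

    def test_all_values_finite(self, scales, spec9, small_chains):
        fm = assemble_features(small_chains[0], spec9, scales)
        assert np.all(np.isfinite(fm.values))

    def test_position_locality(self, scales):
        """Residue i's windowed features ignore residues beyond the half-window."""
        spec = WindowSpec(5)
        rng = np.random.default_rng(3)
        seq = "ACDEFGHIKLMN"
        scores = rng.normal(0, 2, (12, 20))
        chain_a = make_chain(seq, pssm_scores=scores)
        altered = scores.copy()
        altered[11] += 5.0  # |i - j| = 6 > half = 2 for i = 5
        chain_b = make_chain(seq, pssm_scores=altered)
        blocks = ("pssm_window", "ss_local", "disorder", "seq_len", "seq_pos", "physchem")
        fa = assemble_features(chain_a, spec, scales, blocks=blocks)
        fb = assemble_features(chain_b, spec, scales, blocks=blocks)
        assert np.array_equal(fa.values[5], fb.values[5])
        assert not np.array_equal(fa.values[11], fb.values[11])

    def test_missing_profile_named_in_error(self, scales, spec9):
        chain = ChainRecord("c1", "ACDEF")
        with pytest.raises(MissingInputError, match="PSSM"):
            assemble_features(chain, spec9, scales)
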
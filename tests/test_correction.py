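"""NIA correction matrices, the NNLS solve, and enrichment arithmetic."""

import itertools
import math

import numpy as np
import pytest

from aspenrich.correction import (
    StandardCertificate,
    build_matrix,
    correct,
    e13c_of,
    expected_e13c,
    tracer_excess,
)
from aspenrich.fragments import FragmentSpec
from aspenrich.isotopes import NATURAL_13C, isotope_table, parse_formula
from aspenrich.simulate import simulate_mid


def brute_force_pattern(formula_text: str) -> dict[int, float]:
    """Independent oracle: enumerate isotope placements per element with
    multinomial weights instead of convolving per-atom patterns."""
    formula = parse_formula(formula_text)
    table = isotope_table()
    dist = {0: 1.0}
    for element, count in formula.counts.items():
        isotopes = table[element]
        new: dict[int, float] = {}
        for combo in itertools.product(range(count + 1), repeat=len(isotopes)):
            if sum(combo) != count:
                continue
            weight = math.factorial(count)
            prob = 1.0
            offset = 0
            for n_k, (off_k, _m, p_k) in zip(combo, isotopes):
                weight //= math.factorial(n_k)
                prob *= p_k**n_k
                offset += n_k * off_k
            for base_offset, base_prob in dist.items():
                key = base_offset + offset
                new[key] = new.get(key, 0.0) + base_prob * weight * prob
        dist = new
    return dist


def single_carbon_fragment() -> FragmentSpec:
    return FragmentSpec(
        "test", 12, None, parse_formula("C"), frozenset({1}), ionization="EI"
    )


class TestBuildMatrix:
    def test_single_carbon_closed_form(self):
        M = build_matrix(single_carbon_fragment(), 2)
        np.testing.assert_allclose(
            M.matrix, [[0.9893, 0.0], [0.0107, 1.0]], atol=1e-12
        )

    def test_columns_are_forward_images_of_unit_vectors(self, frag_by_label):
        M = build_matrix(frag_by_label(232), 7).matrix
        for j in range(M.shape[1]):
            e_j = np.zeros(M.shape[1])
            e_j[j] = 1.0
            np.testing.assert_allclose(M @ e_j, M[:, j], atol=1e-15)

    def test_column_sums_near_one(self, registry):
        for frag in registry:
            if frag.ion_formula is None:
                continue
            M = build_matrix(frag, frag.n_tracer + 4).matrix
            sums = M.sum(axis=0)
            assert np.all(sums <= 1.0 + 1e-12)
            assert np.all(sums >= 0.99)

    def test_unlabeled_column_matches_brute_force_enumeration(self, frag_by_label):
        # column 0 is the full natural envelope of C9H22NO2Si2
        frag = frag_by_label(232)
        M = build_matrix(frag, 7).matrix
        oracle = brute_force_pattern("C9H22NO2Si2")
        for offset in range(4):
            # 1e-8 slack: the matrix pattern is tail-pruned and renormalized
            assert M[offset, 0] == pytest.approx(oracle[offset], abs=1e-8)

    def test_too_few_measured_masses_rejected(self, frag_by_label):
        with pytest.raises(ValueError):
            build_matrix(frag_by_label(232), 3)


class TestCorrect:
    def _forward(self, frag, x):
        """Forward mixture via the simulator (independent code path):
        population j has j positions fully labelled, the rest natural."""
        positions = sorted(frag.backbone_positions)
        envelope = np.zeros(frag.n_tracer + 4)
        for j, weight in enumerate(x):
            labelled = {p: 1.0 for p in positions[:j]}
            envelope += weight * simulate_mid(frag, labelled, 1.0).abundances
        return envelope

    def test_natural_sample_has_zero_enrichment(self, frag_by_label):
        frag = frag_by_label(349)
        raw = simulate_mid(frag, {}, 1e6)
        corrected = correct(raw, build_matrix(frag, len(raw.abundances)))
        assert corrected.e13c == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "x", [(0.0, 0.0, 0.0, 1.0), (0.5, 0.0, 0.0, 0.5), (0.1, 0.2, 0.3, 0.4)]
    )
    def test_round_trip_recovers_tracer_fractions(self, frag_by_label, x):
        frag = frag_by_label(232)
        raw = self._forward(frag, x)
        M = build_matrix(frag, len(raw))
        corrected = correct(raw, M)
        np.testing.assert_allclose(corrected.fractions, x, atol=1e-6)
        assert corrected.e13c == pytest.approx(e13c_of(x, 3), abs=1e-6)

    def test_nnls_and_lstsq_agree_noise_free(self, frag_by_label):
        frag = frag_by_label(349)
        raw = self._forward(frag, (0.2, 0.3, 0.1, 0.25, 0.15))
        M = build_matrix(frag, len(raw))
        np.testing.assert_allclose(
            correct(raw, M).fractions,
            correct(raw, M, method="lstsq").fractions,
            atol=1e-9,
        )

    def test_carbon_only_formula_matches_binomial_deconvolution(self):
        # without Si/H/N/O the matrix is the classical binomial carbon
        # matrix; invert it independently from binomial coefficients
        frag = FragmentSpec(
            "test", 48, None, parse_formula("C4"), frozenset({1, 2, 3, 4}),
            ionization="EI",
        )
        x_true = np.array([0.3, 0.1, 0.2, 0.15, 0.25])
        a = NATURAL_13C
        B = np.zeros((5, 5))
        for j in range(5):
            for i in range(j, 5):
                B[i, j] = math.comb(4 - j, i - j) * a ** (i - j) * (1 - a) ** (4 - i)
        measured = B @ x_true
        corrected = correct(measured, build_matrix(frag, 5))
        np.testing.assert_allclose(corrected.fractions, x_true, atol=1e-9)

    def test_short_measurement_truncates_matrix_with_flag(self, frag_by_label):
        frag = frag_by_label(232)
        raw = self._forward(frag, (1.0, 0.0, 0.0, 0.0))[:5]
        corrected = correct(raw, build_matrix(frag, 7))
        assert "matrix_truncated" in corrected.flags
        assert corrected.fractions[0] == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_vector_rejected(self, frag_by_label):
        frag = frag_by_label(232)
        with pytest.raises(ValueError):
            correct(np.zeros(7), build_matrix(frag, 7))


def test_corrected_table_export(frag_by_label):
    from aspenrich.correction import corrected_to_frame

    frag = frag_by_label(349)
    mid = simulate_mid(frag, {1: 0.5}, 1e6, sample_id="s1")
    corrected = correct(mid, build_matrix(frag, len(mid.abundances)))
    frame = corrected_to_frame([corrected])
    assert list(frame.columns) == [
        "sample_id", "fragment", "fractions", "e13c_percent", "residual", "flags"
    ]
    assert frame.loc[0, "fragment"] == "aspartic acid 3TMS m/z 349"
    assert frame.loc[0, "e13c_percent"] == pytest.approx(
        100 * tracer_excess(0.5) / 4, abs=1e-3
    )


class TestEnrichmentArithmetic:
    @pytest.mark.parametrize(
        "fractions, n, expected",
        [
            ((1, 0, 0, 0, 0), 4, 0.0),
            ((0, 0, 0, 0, 1), 4, 1.0),
            ((0.25, 0.25, 0.25, 0.25), 3, 0.5),
        ],
    )
    def test_e13c_examples(self, fractions, n, expected):
        assert e13c_of(fractions, n) == pytest.approx(expected)

    def test_e13c_rejects_zero_carbons(self):
        with pytest.raises(ValueError):
            e13c_of([1.0], 0)

    def test_expected_e13c_of_certificates(self):
        u13c = StandardCertificate(frozenset({1, 2, 3, 4}), purity=0.990)
        assert expected_e13c(u13c, "whole", 1.0) == pytest.approx(0.990)
        c2 = StandardCertificate(frozenset({2}), purity=0.997)
        assert expected_e13c(c2, 2, 0.5) == pytest.approx(0.4985)
        assert expected_e13c(c2, 3, 0.5) == 0.0
        assert expected_e13c(c2, 2, 0.0) == 0.0

    def test_certificate_purity_bounds(self):
        with pytest.raises(ValueError):
            StandardCertificate(frozenset({1}), purity=0.0)

    def test_tracer_excess_of_natural_is_zero(self):
        assert tracer_excess(NATURAL_13C) == 0.0
        assert tracer_excess(1.0) == 1.0
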
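"""Falconer decomposition, dominance typing and effect grading."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snptrait.assoc import AlleleFreqs
from snptrait.falconer import (
    COMPLETE_DOMINANCE,
    NO_DOMINANCE,
    OVERDOMINANCE,
    PARTIAL_DOMINANCE,
    EffectGradeCutoffs,
    PooledGenotypeMeans,
    classify_dominance,
    falconer_decompose,
    grade_effect_size,
    pool_stratum_means,
)
from snptrait.io import DataError


def decompose(means3, ns3, counts2, **kwargs):
    means = PooledGenotypeMeans(
        mean_major_homo=means3[0],
        mean_het=means3[1],
        mean_minor_homo=means3[2],
        n_major_homo=ns3[0],
        n_het=ns3[1],
        n_minor_homo=ns3[2],
    )
    return falconer_decompose(means, AlleleFreqs(*counts2), **kwargs)


class TestPooling:
    def test_weighted_mean(self):
        n, mean = pool_stratum_means([(76, 2.11), (107, 0.15)])
        assert n == 183
        assert round(mean, 4) == 0.9640

    def test_single_stratum_identity(self):
        assert pool_stratum_means([(42, 1.23)]) == (42, 1.23)

    def test_equal_means_any_weights(self):
        _, mean = pool_stratum_means([(10, 2.5), (1000, 2.5), (1, 2.5)])
        assert mean == pytest.approx(2.5, abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            pool_stratum_means([])


class TestDecompose:
    def test_lepr_scale_example(self):
        # pooled stratum means for the three genotype classes, allele
        # counts 653/581
        m_majhomo = pool_stratum_means([(76, 2.11), (107, 0.15)])[1]
        m_het = pool_stratum_means([(127, 2.14), (138, 0.13)])[1]
        m_minhomo = pool_stratum_means([(50, 2.07), (99, -0.05)])[1]
        eff = decompose((m_majhomo, m_het, m_minhomo), (183, 265, 149), (653, 581))
        assert round(eff.additive, 2) == -0.15
        assert round(eff.dominance, 2) == 0.28
        assert round(eff.population_mean, 2) == 0.81
        assert eff.dominance_type == OVERDOMINANCE

    def test_mc4r_scale_example(self):
        eff = decompose((1.4600, 1.46633, 1.79263), (220, 109, 19), (554, 150))
        assert round(eff.additive, 2) == 0.17
        assert round(eff.dominance, 2) == -0.16
        assert round(eff.minor_avg_effect, 2) == 0.06
        assert eff.dominance_type == COMPLETE_DOMINANCE

    def test_purely_additive_toy(self):
        eff = decompose((-1.0, 0.0, 1.0), (10, 10, 10), (15, 5))
        assert eff.midpoint == 0.0
        assert eff.additive == 1.0
        assert eff.dominance == 0.0
        assert eff.alpha == 1.0  # additive limit: alpha = a for any freqs

    def test_symmetric_overdominance_toy(self):
        eff = decompose((0.0, 1.0, 0.0), (10, 10, 10), (20, 20))
        assert eff.additive == 0.0
        assert eff.dominance == 1.0
        assert eff.dominance_type == OVERDOMINANCE

    def test_empty_class_rejected(self):
        with pytest.raises(DataError, match="minor homozygote"):
            decompose((0.0, 1.0, 2.0), (10, 10, 0), (20, 20))

    def test_freq_weighted_mean_equals_expectation(self):
        eff = decompose((10.0, 12.5, 11.0), (50, 30, 20), (130, 70))
        p, q = eff.p_major, eff.q_minor
        expected = (
            p * p * 10.0 + 2 * p * q * 12.5 + q * q * 11.0
        )
        assert eff.freq_weighted_mean == pytest.approx(expected, rel=1e-12)


@st.composite
def random_instances(draw):
    means = [draw(st.floats(-5, 5)) for _ in range(3)]
    count_major = draw(st.integers(10, 500))
    count_minor = draw(st.integers(10, 500))
    if count_minor > count_major:
        count_major, count_minor = count_minor, count_major
    return means, (count_major, count_minor)


class TestInvariants:
    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(random_instances())
    def test_reconstruction_identity(self, instance):
        means, counts = instance
        eff = decompose(tuple(means), (10, 10, 10), counts)
        rec = eff.genotype_means()
        np.testing.assert_allclose(rec, means, rtol=1e-12, atol=1e-12)

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(random_instances())
    def test_allele_orientation_equivariance(self, instance):
        (m0, m1, m2), (cmaj, cmin) = instance
        eff = decompose((m0, m1, m2), (10, 10, 10), (cmaj, cmin))
        flipped = decompose((m2, m1, m0), (10, 10, 10), (cmin, cmaj))
        assert flipped.additive == pytest.approx(-eff.additive, rel=1e-12, abs=1e-12)
        assert flipped.alpha == pytest.approx(-eff.alpha, rel=1e-12, abs=1e-12)
        assert flipped.midpoint == pytest.approx(eff.midpoint, rel=1e-12, abs=1e-12)
        assert (flipped.p_major, flipped.q_minor) == (eff.q_minor, eff.p_major)
        np.testing.assert_allclose(
            sorted(flipped.genotype_means()), sorted(eff.genotype_means()), rtol=1e-12, atol=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(random_instances())
    def test_sign_equivariance(self, instance):
        (m0, m1, m2), counts = instance
        eff = decompose((m0, m1, m2), (10, 10, 10), counts)
        neg = decompose((-m0, -m1, -m2), (10, 10, 10), counts)
        assert neg.additive == pytest.approx(-eff.additive, rel=1e-12, abs=1e-12)
        assert neg.dominance == pytest.approx(-eff.dominance, rel=1e-12, abs=1e-12)
        assert neg.alpha == pytest.approx(-eff.alpha, rel=1e-12, abs=1e-12)
        assert neg.dominance_type == eff.dominance_type
        if "increase" in eff.effect_grade:
            assert "decrease" in neg.effect_grade
        elif "decrease" in eff.effect_grade:
            assert "increase" in neg.effect_grade


class TestClassifyDominance:
    @pytest.mark.parametrize(
        "a, d, expected",
        [
            (-0.15, 0.28, OVERDOMINANCE),
            (0.06, -0.07, COMPLETE_DOMINANCE),
            (0.17, -0.16, COMPLETE_DOMINANCE),
            (-1.12, 0.68, PARTIAL_DOMINANCE),
            (1.0, 0.0, NO_DOMINANCE),
            (1.0, 0.25, NO_DOMINANCE),  # boundary of the no-dominance band
            (1.0, 0.5, PARTIAL_DOMINANCE),
            (1.0, 1.0, COMPLETE_DOMINANCE),
            (1.0, 1.3, OVERDOMINANCE),
            (0.0, 0.4, OVERDOMINANCE),  # infinite ratio
            (0.0, 0.0, NO_DOMINANCE),  # degenerate
        ],
    )
    def test_classification(self, a, d, expected):
        assert classify_dominance(a, d) == expected


class TestGrading:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (0.03, "very weak increase"),
            (-0.09, "weak decrease"),
            (0.05, "weak increase"),  # boundary assigned upward
            (0.2, "medium increase"),
            (-0.8, "strong decrease"),
            (0.0, "very weak"),
            (-0.5, "medium decrease"),
        ],
    )
    def test_grades(self, x, expected):
        assert grade_effect_size(x) == expected

    def test_cutoffs_must_increase(self):
        with pytest.raises(DataError):
            EffectGradeCutoffs(very_weak_max=0.3, weak_max=0.2, medium_max=0.8)
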
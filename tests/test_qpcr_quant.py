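import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from g4enrich import (
    ChipMeasurement,
    QpcrMeasurement,
    delta_cq,
    fold_over_reference,
    generate_qpcr_dataset,
    percent_input,
    relative_expression_ddcq,
    t_test_delta_cq,
)
from g4enrich.qpcr_quant import read_cq_table


def _m(sample, gene, *cqs):
    return QpcrMeasurement(sample, gene, tuple(cqs))


def textbook_t_test(a, b):
    """Independent oracle: pooled-variance t from the classical formulas."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


class TestRelativeExpression:
    def test_calibrator_against_itself_is_one(self):
        t = _m("s", "tg", 25.0, 25.2, 24.8)
        h = _m("s", "hk", 20.0, 20.1, 19.9)
        assert relative_expression_ddcq(t, h, t, h) == 1.0

    def test_ddcq_minus_three_is_eightfold(self):
        fold = relative_expression_ddcq(
            _m("s", "tg", 22.0), _m("s", "hk", 20.0),
            _m("c", "tg", 25.0), _m("c", "hk", 20.0),
        )
        assert fold == pytest.approx(8.0)

    def test_63_percent_reduction(self):
        """ddCq of +1.434 corresponds to 2^-1.434 = 0.37, i.e. about a 63%
        drop versus the calibrator condition."""
        fold = relative_expression_ddcq(
            _m("s", "tg", 26.434), _m("s", "hk", 20.0),
            _m("c", "tg", 25.0), _m("c", "hk", 20.0),
        )
        assert fold == pytest.approx(2 ** -1.434)
        assert 1 - fold == pytest.approx(0.63, abs=0.005)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            QpcrMeasurement("s", "g", ())

    def test_nonpositive_cq_rejected(self):
        with pytest.raises(ValueError):
            QpcrMeasurement("s", "g", (20.0, -1.0))


class TestPercentInput:
    def test_equal_cq_recovers_the_input_fraction(self):
        m = ChipMeasurement("ab", "locus", cq_ip=24.0, cq_input=24.0, input_fraction=0.02)
        assert percent_input(m) == pytest.approx(2.0)

    def test_full_recovery(self):
        m = ChipMeasurement("ab", "locus", cq_ip=24.0 - math.log2(1 / 0.02),
                            cq_input=24.0, input_fraction=0.02)
        assert percent_input(m) == pytest.approx(100.0)

    def test_one_cycle_halves_recovery(self):
        m = ChipMeasurement("ab", "locus", cq_ip=25.0, cq_input=24.0, input_fraction=0.02)
        assert percent_input(m) == pytest.approx(1.0)

    @given(st.floats(-5, 5), st.floats(15, 30), st.floats(0, 8))
    def test_shift_invariance(self, shift, cq_input, delta):
        a = ChipMeasurement("ab", "l", cq_input + delta, cq_input, 0.05)
        b = ChipMeasurement("ab", "l", cq_input + delta + shift, cq_input + shift, 0.05)
        assert percent_input(a) == pytest.approx(percent_input(b))

    def test_invalid_input_fraction(self):
        with pytest.raises(ValueError):
            ChipMeasurement("ab", "l", 24.0, 24.0, 0.0)


class TestFoldOverReference:
    @pytest.mark.parametrize(
        "target,reference,expected", [(0.52, 0.20, 2.6), (1.16, 0.20, 5.8), (0.7, 0.7, 1.0)]
    )
    def test_ratios(self, target, reference, expected):
        assert fold_over_reference(target, reference) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_over_reference(1.0, 0.0)


class TestTTest:
    def test_identical_groups(self):
        t, p = t_test_delta_cq([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_clear_separation(self):
        _, p = t_test_delta_cq([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.001

    def test_matches_textbook_formula(self):
        a, b = [4.1, 4.3, 4.2], [5.0, 5.2, 5.1]
        t, p = t_test_delta_cq(a, b)
        t_ref, p_ref = textbook_t_test(a, b)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    @given(
        st.lists(st.floats(1, 10), min_size=2, max_size=8),
        st.lists(st.floats(1, 10), min_size=2, max_size=8),
    )
    def test_antisymmetric_under_group_swap(self, a, b):
        if np.std(a + b) == 0:
            return  # degenerate: zero pooled variance
        t1, p1 = t_test_delta_cq(a, b)
        t2, p2 = t_test_delta_cq(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            t_test_delta_cq([1.0], [1.0, 2.0])


class TestQpcrDataset:
    def test_noiseless_identity_fold(self):
        ms = {(m.sample, m.gene): m for m in generate_qpcr_dataset(3, 1.0, 0.0, seed=1)}
        fold = relative_expression_ddcq(
            ms[("treated", "target")], ms[("treated", "housekeeping")],
            ms[("calibrator", "target")], ms[("calibrator", "housekeeping")],
        )
        assert fold == 1.0

    @pytest.mark.parametrize("true_fold", [8.0, 0.37, 2.6])
    def test_noiseless_fold_recovered_exactly(self, true_fold):
        ms = {(m.sample, m.gene): m for m in generate_qpcr_dataset(3, true_fold, 0.0, seed=1)}
        fold = relative_expression_ddcq(
            ms[("treated", "target")], ms[("treated", "housekeeping")],
            ms[("calibrator", "target")], ms[("calibrator", "housekeeping")],
        )
        assert fold == pytest.approx(true_fold, rel=1e-12)

    def test_monte_carlo_recovery_with_noise(self):
        """Mean recovered fold over seeded replicates within 3 SE of truth."""
        true_fold = 0.37
        folds = []
        for seed in range(400):
            ms = {(m.sample, m.gene): m
                  for m in generate_qpcr_dataset(3, true_fold, 0.1, seed=seed)}
            folds.append(relative_expression_ddcq(
                ms[("treated", "target")], ms[("treated", "housekeeping")],
                ms[("calibrator", "target")], ms[("calibrator", "housekeeping")],
            ))
        mean = float(np.mean(folds))
        se = float(np.std(folds, ddof=1) / np.sqrt(len(folds)))
        # 2^-ddCq is lognormal in the noise, so the mean sits slightly
        # above the true fold; 3 SE around the analytic mean
        sigma_ddcq = 0.1 * np.sqrt(4 / 3)
        analytic_mean = true_fold * np.exp((np.log(2) * sigma_ddcq) ** 2 / 2)
        assert abs(mean - analytic_mean) < 3 * se

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_qpcr_dataset(1, 2.0, 0.1)
        with pytest.raises(ValueError):
            generate_qpcr_dataset(3, 0.0, 0.1)


def test_read_cq_table_groups_replicates(tmp_path):
    p = tmp_path / "cq.tsv"
    p.write_text(
        "sample\tgene\treplicate\tcq\n"
        "ctrl\tGAPDH\t1\t20.1\nctrl\tGAPDH\t2\t20.3\n"
        "ctrl\tIFNB1\t1\t27.0\n"
    )
    ms = read_cq_table(p)
    assert [(m.sample, m.gene, len(m.cq_values)) for m in ms] == [
        ("ctrl", "GAPDH", 2), ("ctrl", "IFNB1", 1)
    ]
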
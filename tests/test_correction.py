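"""Cause classification and the four-step count correction."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apcmort import (
    CauseClass,
    CorrectionFactors,
    apply_completeness,
    classify_cause,
    correct_pipeline,
    correct_tabulation,
    redistribute_ill_defined,
    redistribute_incomplete_cancer,
    tabulate_records,
)
from apcmort.correction import CAUSE_COLUMNS, ClassificationError

B = CauseClass.BREAST.value
OC = CauseClass.OTHER_DEFINED_CANCER.value
IC = CauseClass.INCOMPLETE_CANCER.value
ILL = CauseClass.ILL_DEFINED.value
ON = CauseClass.OTHER_DEFINED_NATURAL.value
NN = CauseClass.NON_NATURAL.value


def one_stratum(**counts):
    row = {"unit": "X", "year": 1987, "age_group_start": 50}
    row.update({c: 0.0 for c in CAUSE_COLUMNS})
    row.update(counts)
    return pd.DataFrame([row])


class TestClassifyCause:
    @pytest.mark.parametrize(
        "code,rev,expected",
        [
            ("C50", 10, CauseClass.BREAST),
            ("C509", 10, CauseClass.BREAST),
            ("174", 9, CauseClass.BREAST),
            ("174.9", 9, CauseClass.BREAST),
            ("C76", 10, CauseClass.INCOMPLETE_CANCER),
            ("C79", 10, CauseClass.INCOMPLETE_CANCER),
            ("C80", 10, CauseClass.INCOMPLETE_CANCER),
            ("C97", 10, CauseClass.INCOMPLETE_CANCER),
            ("195", 9, CauseClass.INCOMPLETE_CANCER),
            ("199", 9, CauseClass.INCOMPLETE_CANCER),
            ("R98", 10, CauseClass.ILL_DEFINED),
            ("R00", 10, CauseClass.ILL_DEFINED),
            ("780", 9, CauseClass.ILL_DEFINED),
            ("799.9", 9, CauseClass.ILL_DEFINED),
            ("E812", 9, CauseClass.NON_NATURAL),
            ("850", 9, CauseClass.NON_NATURAL),
            ("X95", 10, CauseClass.NON_NATURAL),
            ("V89", 10, CauseClass.NON_NATURAL),
            ("S02", 10, CauseClass.NON_NATURAL),
            ("162", 9, CauseClass.OTHER_DEFINED_CANCER),
            ("C34", 10, CauseClass.OTHER_DEFINED_CANCER),
            ("D20", 10, CauseClass.OTHER_DEFINED_CANCER),
            ("D50", 10, CauseClass.OTHER_DEFINED_NATURAL),
            ("I21", 10, CauseClass.OTHER_DEFINED_NATURAL),
            ("410", 9, CauseClass.OTHER_DEFINED_NATURAL),
            ("V10", 9, CauseClass.OTHER_DEFINED_NATURAL),
        ],
    )
    def test_icd_mapping(self, code, rev, expected):
        assert classify_cause(code, rev) is expected

    @pytest.mark.parametrize("code,rev", [("", 10), ("17", 9), ("C5", 10), ("C50", 8)])
    def test_unparseable_codes_raise(self, code, rev):
        with pytest.raises(ClassificationError):
            classify_cause(code, rev)


class TestRedistributeIllDefined:
    def test_proportional_share(self):
        tab = one_stratum(**{B: 20.0, OC: 30.0, ON: 50.0, ILL: 40.0})
        out = redistribute_ill_defined(tab, fraction=0.5)
        assert out[B].iloc[0] == pytest.approx(24.0)
        assert out[OC].iloc[0] == pytest.approx(36.0)
        assert out[ON].iloc[0] == pytest.approx(60.0)
        assert out[ILL].iloc[0] == pytest.approx(20.0)

    def test_no_ill_defined_is_identity(self):
        tab = one_stratum(**{B: 20.0, OC: 30.0, ON: 50.0})
        pd.testing.assert_frame_equal(redistribute_ill_defined(tab), tab)

    def test_single_class_absorbs_all_at_fraction_one(self):
        tab = one_stratum(**{ON: 7.0, ILL: 13.0})
        out = redistribute_ill_defined(tab, fraction=1.0)
        assert out[ON].iloc[0] == pytest.approx(20.0)
        assert out[ILL].iloc[0] == pytest.approx(0.0)

    def test_empty_denominator_leaves_deaths_in_place(self, caplog):
        tab = one_stratum(**{ILL: 9.0, NN: 4.0})
        with caplog.at_level("WARNING"):
            out = redistribute_ill_defined(tab)
        pd.testing.assert_frame_equal(out, tab)
        assert "unredistributed" in caplog.text

    @given(
        counts=st.lists(
            st.floats(min_value=0, max_value=1e4, allow_nan=False), min_size=6, max_size=6
        ),
        fraction=st.floats(min_value=0, max_value=1),
    )
    def test_grand_total_conserved(self, counts, fraction):
        tab = one_stratum(**dict(zip(CAUSE_COLUMNS, counts)))
        out = redistribute_ill_defined(tab, fraction=fraction)
        assert out[CAUSE_COLUMNS].to_numpy().sum() == pytest.approx(
            tab[CAUSE_COLUMNS].to_numpy().sum(), rel=1e-12, abs=1e-9
        )
        assert out[NN].iloc[0] == tab[NN].iloc[0]  # external causes untouched


class TestRedistributeIncomplete:
    def test_proportional_share(self):
        tab = one_stratum(**{B: 20.0, OC: 30.0, IC: 10.0})
        out = redistribute_incomplete_cancer(tab)
        assert out[B].iloc[0] == pytest.approx(24.0)
        assert out[OC].iloc[0] == pytest.approx(36.0)
        assert out[IC].iloc[0] == 0.0

    def test_no_incomplete_is_identity(self):
        tab = one_stratum(**{B: 20.0, OC: 30.0})
        pd.testing.assert_frame_equal(redistribute_incomplete_cancer(tab), tab)

    def test_zero_breast_share_stays_zero(self):
        tab = one_stratum(**{OC: 30.0, IC: 10.0})
        out = redistribute_incomplete_cancer(tab)
        assert out[B].iloc[0] == 0.0
        assert out[OC].iloc[0] == pytest.approx(40.0)

    @given(
        counts=st.lists(
            st.floats(min_value=0, max_value=1e4, allow_nan=False), min_size=6, max_size=6
        )
    )
    def test_grand_total_conserved(self, counts):
        tab = one_stratum(**dict(zip(CAUSE_COLUMNS, counts)))
        out = redistribute_incomplete_cancer(tab)
        assert out[CAUSE_COLUMNS].to_numpy().sum() == pytest.approx(
            tab[CAUSE_COLUMNS].to_numpy().sum(), rel=1e-12, abs=1e-9
        )


class TestCompleteness:
    def test_multiplication_without_rounding(self):
        out = apply_completeness([40.0], [1985], CorrectionFactors.uniform({1980: 1.25}))
        assert out[0] == pytest.approx(50.0)

    def test_identity_factor(self):
        out = apply_completeness([7.3], [2003], CorrectionFactors.identity())
        assert out[0] == pytest.approx(7.3)

    def test_year_maps_to_its_decade(self):
        factors = CorrectionFactors.uniform({1980: 2.0, 1990: 3.0})
        assert apply_completeness([1.0], [1987], factors)[0] == pytest.approx(2.0)
        assert apply_completeness([1.0], [1990], factors)[0] == pytest.approx(3.0)

    def test_missing_decade_raises(self):
        with pytest.raises(KeyError):
            apply_completeness([1.0], [1975], CorrectionFactors.uniform({1980: 1.0}))

    def test_subunity_factor_rejected(self):
        with pytest.raises(ValueError):
            CorrectionFactors.uniform({1980: 0.8})


class TestPipeline:
    def test_hand_enumerated_stratum(self):
        # breast 20 gains 40*0.5*(20/100)=4 from step i and 10*(20/50)=4
        # from step ii; (20+4+4) * 1.2 = 33.6
        tab = one_stratum(**{B: 20.0, OC: 30.0, ON: 50.0, ILL: 40.0, IC: 10.0})
        res = correct_tabulation(
            tab, CorrectionFactors.uniform({1980: 1.2}),
            age_group_starts=[50], period_starts=[1985],
        )
        assert res.table["deaths_corrected"].iloc[0] == pytest.approx(33.6, abs=1e-12)
        assert res.table["deaths_raw"].iloc[0] == pytest.approx(20.0)

    def test_identity_when_nothing_to_correct(self):
        tab = one_stratum(**{B: 17.0, OC: 3.0, ON: 9.0})
        res = correct_tabulation(
            tab, CorrectionFactors.identity(), age_group_starts=[50], period_starts=[1985]
        )
        assert res.table["deaths_corrected"].iloc[0] == pytest.approx(17.0)

    def test_idempotent_once_garbage_is_gone(self):
        # after one pass with fraction 1 there are no garbage classes
        # left; a second pass with identity factors changes nothing
        tab = one_stratum(**{B: 20.0, OC: 30.0, ON: 50.0, ILL: 40.0, IC: 10.0})
        once = redistribute_incomplete_cancer(redistribute_ill_defined(tab, fraction=1.0))
        twice = redistribute_incomplete_cancer(redistribute_ill_defined(once, fraction=1.0))
        pd.testing.assert_frame_equal(once, twice)

    @pytest.mark.parametrize("bump", [("ILL_DEFINED", 10.0), ("INCOMPLETE_CANCER", 5.0)])
    def test_corrected_count_monotone_in_garbage_and_factor(self, bump):
        base = {B: 20.0, OC: 30.0, ON: 50.0, ILL: 40.0, IC: 10.0}
        col, delta = bump
        more = dict(base)
        more[col] = base[col] + delta

        def corrected(counts, factor):
            res = correct_tabulation(
                one_stratum(**counts), CorrectionFactors.uniform({1980: factor}),
                age_group_starts=[50], period_starts=[1985],
            )
            return res.table["deaths_corrected"].iloc[0]

        assert corrected(more, 1.2) > corrected(base, 1.2)
        assert corrected(base, 1.3) > corrected(base, 1.2)

    def test_record_level_equals_aggregated_path(self, rng):
        rows = []
        codes = [("C50", 10), ("C34", 10), ("R99", 10), ("C80", 10), ("I21", 10), ("X95", 10)]
        for _ in range(500):
            code, rev = codes[rng.integers(len(codes))]
            rows.append(
                {
                    "unit": "A",
                    "year": int(rng.choice([2001, 2003, 2008])),
                    "age_years": int(rng.choice([42, 47, 55])),
                    "icd_revision": rev,
                    "icd_code": code,
                }
            )
        records = pd.DataFrame(rows)
        factors = CorrectionFactors.uniform({2000: 1.1})
        ages = [40, 45, 50, 55]
        periods = [2000, 2005]
        via_records = correct_pipeline(records, factors, ages, periods)
        tab = tabulate_records(records, age_group_starts=ages)
        via_tab = correct_tabulation(tab, factors, ages, periods)
        pd.testing.assert_frame_equal(via_records.table, via_tab.table)

    def test_grids_shape_and_unit_selection(self):
        tab = pd.concat(
            [one_stratum(**{B: 5.0}), one_stratum(**{B: 7.0}).assign(unit="Y")],
            ignore_index=True,
        )
        res = correct_tabulation(
            tab, CorrectionFactors.identity(), age_group_starts=[50], period_starts=[1985]
        )
        with pytest.raises(ValueError):
            res.grids()
        raw, cor = res.grids(unit="Y")
        assert raw.shape == (1, 1) and raw[0, 0] == 7.0
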
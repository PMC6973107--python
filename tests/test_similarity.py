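"""Sufficient-similarity distance, SMRI, hazard index, cohort aggregation."""

import numpy as np
import pandas as pd
import pytest

from smach.constants import BeEntry, BeTable
from smach.similarity import (
    ReferenceMixture,
    SubjectMixture,
    cohort_summary,
    decide_similarity,
    distance_upper_limit,
    hazard_index,
    hazard_index_cohort,
    mixture_distance,
    score_cohort,
    smri,
)

REF = ReferenceMixture(
    components=("dbp", "bbzp", "dehp", "dinp"),
    proportions=(0.33, 0.16, 0.21, 0.30),
    t_r=2.1,
    se_tr=0.33,
    df=62,
)


def _subject(exposures, sid="s1"):
    return SubjectMixture(subject_id=sid, components=REF.components,
                         exposures=tuple(exposures))


class TestMixtureDistance:
    def test_identical_proportions_give_zero(self):
        subj = _subject(np.array(REF.proportions) * 5.0)
        assert mixture_distance(subj, REF) == pytest.approx(0.0, abs=1e-12)

    def test_worked_subject(self):
        subj = _subject((0.40, 0.10, 0.20, 0.30))
        assert mixture_distance(subj, REF) == pytest.approx(0.1948, abs=1e-3)

    def test_scales_linearly_in_t_r(self):
        subj = _subject((0.40, 0.10, 0.20, 0.30))
        ref2 = ReferenceMixture(REF.components, REF.proportions, 4.2, 0.33, 62)
        assert mixture_distance(subj, ref2) == pytest.approx(
            2 * mixture_distance(subj, REF)
        )

    def test_component_mismatch_rejected(self):
        subj = SubjectMixture("s1", ("a", "b", "c", "d"), (1.0, 1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="mismatch"):
            mixture_distance(subj, REF)


class TestUpperLimit:
    def test_worked_subject(self):
        subj = _subject((0.40, 0.10, 0.20, 0.30))
        d = mixture_distance(subj, REF)
        assert distance_upper_limit(d, subj, REF) == pytest.approx(0.2459, abs=1e-3)

    def test_zero_se_returns_distance(self):
        ref0 = ReferenceMixture(REF.components, REF.proportions, 2.1, 0.0, 62)
        subj = _subject((0.40, 0.10, 0.20, 0.30))
        d = mixture_distance(subj, ref0)
        assert distance_upper_limit(d, subj, ref0) == d

    def test_monotone_in_se(self):
        subj = _subject((0.40, 0.10, 0.20, 0.30))
        uls = []
        for se in (0.1, 0.3, 0.6):
            ref = ReferenceMixture(REF.components, REF.proportions, 2.1, se, 62)
            uls.append(distance_upper_limit(mixture_distance(subj, ref), subj, ref))
        assert uls[0] < uls[1] < uls[2]


class TestDecision:
    def test_worked_subject_is_similar(self):
        dec = decide_similarity("s1", 0.1948, 0.2459, 0.56)
        assert dec.similar

    def test_boundary_is_strict(self):
        assert not decide_similarity("s1", 0.5, 0.56, 0.56).similar

    def test_zero_radius_admits_nothing(self):
        assert not decide_similarity("s1", 0.0, 0.0, 0.0).similar

    def test_monotone_in_ul_and_radius(self):
        assert decide_similarity("s", 0.1, 0.3, 0.4).similar
        assert decide_similarity("s", 0.1, 0.2, 0.4).similar  # smaller ul
        assert decide_similarity("s", 0.1, 0.3, 0.5).similar  # larger radius


class TestSmri:
    def test_single_component_reference_at_bmd_scores_one(self):
        ref = ReferenceMixture(("a",), (1.0,), 2.0, 0.1, 10)
        subj = SubjectMixture("s1", ("a",), (2.0,))
        assert smri(subj, ref).smri == pytest.approx(1.0)

    def test_zero_exposures_score_zero(self):
        assert smri(_subject((0.0, 0.0, 0.0, 0.0)), REF).smri == 0.0

    def test_homogeneous_in_exposure(self):
        s1 = smri(_subject((1e-8, 2e-8, 1e-8, 3e-8)), REF).smri
        s2 = smri(_subject((2e-8, 4e-8, 2e-8, 6e-8)), REF).smri
        assert s2 == pytest.approx(2 * s1)

    def test_reference_subject_at_bmd_scores_component_count(self):
        # each quotient E_j/(a_rj T_r) is exactly 1 -> sum is 4
        exposures = tuple(a * REF.t_r for a in REF.proportions)
        val = smri(_subject(exposures), REF)
        assert val.smri == pytest.approx(4.0)
        assert val.exceeds_one
        assert smri(_subject(exposures), REF, normalize=True).smri == pytest.approx(1.0)

    def test_zero_reference_proportion_with_exposure_rejected(self):
        ref = ReferenceMixture(("a", "b"), (1.0, 0.0), 2.0, 0.1, 10)
        subj = SubjectMixture("s1", ("a", "b"), (1.0, 0.5))
        with pytest.raises(ValueError, match="undefined"):
            smri(subj, ref)


class TestHazardIndex:
    BE = BeTable(entries={
        "dbp": BeEntry("dbp", 2700.0, ("mbp",)),
        "bbzp": BeEntry("bbzp", 3800.0, ("mbzp",)),
        "dehp": BeEntry("dehp", 400.0, ("mehp", "mehhp", "meohp", "mecpp")),
        "dinp": BeEntry("dinp", 390.0, ("mciop",)),
    })

    def test_upper_percentile_worked_example(self):
        # 95th-percentile urinary levels against the published guidelines
        conc = {"mbp": 233.0, "mbzp": 101.0, "dehp": 191.0, "mciop": 78.0}
        assert hazard_index(conc, self.BE) == pytest.approx(0.7904, abs=1e-4)

    def test_concentrations_at_guidelines_sum_to_count(self):
        conc = {"mbp": 2700.0, "mbzp": 3800.0, "dehp": 400.0, "mciop": 390.0}
        assert hazard_index(conc, self.BE) == pytest.approx(4.0)

    def test_all_zero_gives_zero(self):
        conc = {"mbp": 0.0, "mbzp": 0.0, "dehp": 0.0, "mciop": 0.0}
        assert hazard_index(conc, self.BE) == 0.0

    def test_missing_basis_rejected(self):
        with pytest.raises(KeyError, match="dinp"):
            hazard_index({"mbp": 1.0, "mbzp": 1.0, "dehp": 1.0}, self.BE)

    def test_cohort_variant_sums_multi_metabolite_basis(self):
        tab = pd.DataFrame({
            "mbp": [233.0], "mbzp": [101.0],
            "mehp": [91.0], "mehhp": [50.0], "meohp": [25.0], "mecpp": [25.0],
            "mciop": [78.0],
        })
        assert hazard_index_cohort(tab, self.BE).iloc[0] == pytest.approx(0.7904, abs=1e-4)


class TestScoreCohortAndSummary:
    def test_reference_itself_is_always_similar(self):
        expo = pd.DataFrame(
            [np.array(REF.proportions) * REF.t_r / 10.0],
            columns=REF.components, index=["ref_like"],
        )
        scores = score_cohort(expo, REF, radius=0.56)
        assert scores.loc["ref_like", "d_hat"] == pytest.approx(0.0, abs=1e-12)
        assert bool(scores.loc["ref_like", "similar"])

    def test_all_zero_subject_reported_separately(self):
        expo = pd.DataFrame(
            [np.zeros(4), np.array(REF.proportions)],
            columns=REF.components, index=["empty", "ok"],
        )
        scores = score_cohort(expo, REF, radius=0.56)
        assert not scores.loc["empty", "scored"]
        assert np.isnan(scores.loc["empty", "d_hat"])
        summary = cohort_summary(scores)
        assert summary["n_scored"] == 1
        assert summary["n_unscored"] == 1

    def test_planted_fractions_recovered(self):
        # 60 similar/low dose, 30 similar/high dose (SMRI > 1), 10 dissimilar
        rows, idx = [], []
        a_r = np.array(REF.proportions)
        for i in range(60):
            rows.append(a_r * REF.t_r * 0.1)
            idx.append(f"low{i}")
        for i in range(30):
            rows.append(a_r * REF.t_r * 0.5)  # SMRI = 4 * 0.5 = 2
            idx.append(f"high{i}")
        for i in range(10):
            rows.append(np.array([1.0, 0.0, 0.0, 0.0]) * REF.t_r * 0.1)
            idx.append(f"far{i}")
        expo = pd.DataFrame(rows, columns=REF.components, index=idx)
        scores = score_cohort(expo, REF, radius=0.56)
        summary = cohort_summary(scores)
        assert summary["fraction_similar"] == pytest.approx(0.9)
        assert summary["fraction_smri_gt1_of_similar"] == pytest.approx(30 / 90)
        assert summary["fraction_smri_gt1_of_all"] == pytest.approx(30 / 100)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary(pd.DataFrame(columns=["similar", "smri", "scored"]))
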
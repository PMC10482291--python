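import datetime

import numpy as np
import pytest

from featherid import (
    Category,
    ClassifierConfig,
    IdentificationResult,
    PhenologyStatus,
    PhenologyTable,
    PhenologyWindow,
    PrimerSet,
    SampleRead,
    blind_test_compare,
    categorize,
    identify_sample,
    phenology_status,
    rescue_rate,
    round_percent,
    summarize_categories,
)

from oracles import categorize_tier_table


def _date(day_of_year):
    return datetime.date(2021, 1, 1) + datetime.timedelta(days=day_of_year - 1)


def _table(*windows):
    return PhenologyTable([PhenologyWindow(*w) for w in windows])


class TestPhenologyStatus:
    def test_inside_expected_window_consistent(self):
        t = _table(("sp", "r", 60, 120, "expected"))
        assert phenology_status("sp", _date(90), "r", t) == PhenologyStatus.CONSISTENT

    def test_within_buffer_of_boundary_unlikely(self):
        t = _table(("sp", "r", 60, 120, "expected"))
        assert phenology_status("sp", _date(130), "r", t, 14) == PhenologyStatus.UNLIKELY

    def test_far_outside_window_inconsistent(self):
        t = _table(("sp", "r", 60, 120, "expected"))
        assert phenology_status("sp", _date(250), "r", t, 14) == PhenologyStatus.INCONSISTENT

    def test_wrapping_window_modular(self):
        t = _table(("sp", "r", 300, 60, "expected"))
        assert phenology_status("sp", _date(350), "r", t) == PhenologyStatus.CONSISTENT

    def test_marginal_window_unlikely(self):
        t = _table(("sp", "r", 60, 120, "marginal"))
        assert phenology_status("sp", _date(90), "r", t) == PhenologyStatus.UNLIKELY

    def test_absent_species_unknown(self):
        t = _table(("other", "r", 1, 366, "expected"))
        assert phenology_status("sp", _date(90), "r", t) == PhenologyStatus.UNKNOWN


class TestCategorize:
    @pytest.mark.parametrize(
        "identity,coverage,hq,phen,expected",
        [
            (98, 60, 30, PhenologyStatus.CONSISTENT, Category.POSITIVE),
            (98, 40, 30, PhenologyStatus.CONSISTENT, Category.QUESTIONABLE),
            (94, 90, 90, PhenologyStatus.CONSISTENT, Category.NO_IDENTIFICATION),
            # boundary values fall in the questionable tier (strict positives)
            (97, 90, 90, PhenologyStatus.CONSISTENT, Category.QUESTIONABLE),
            (95, 90, 90, PhenologyStatus.CONSISTENT, Category.QUESTIONABLE),
            (98, 50, 90, PhenologyStatus.CONSISTENT, Category.QUESTIONABLE),
            (98, 30, 90, PhenologyStatus.CONSISTENT, Category.QUESTIONABLE),
            (98, 60, 20, PhenologyStatus.CONSISTENT, Category.QUESTIONABLE),
            # phenology rules
            (98, 60, 30, PhenologyStatus.UNKNOWN, Category.POSITIVE),
            (98, 60, 30, PhenologyStatus.UNLIKELY, Category.QUESTIONABLE),
            (98, 60, 30, PhenologyStatus.INCONSISTENT, Category.NO_IDENTIFICATION),
            # missing HQ (FASTA input) can never be positive
            (98, 60, None, PhenologyStatus.CONSISTENT, Category.QUESTIONABLE),
            # no hit
            (None, None, 90, PhenologyStatus.CONSISTENT, Category.NO_IDENTIFICATION),
        ],
    )
    def test_tier_table(self, identity, coverage, hq, phen, expected):
        assert categorize(identity, coverage, hq, phen) == expected

    def test_agrees_with_rule_table_oracle_on_boundary_grid(self):
        """Full grid of boundary-straddling values x phenology states."""
        values = [0.0, 19.9, 20.0, 20.1, 29.9, 30.0, 30.1, 49.9, 50.0, 50.1,
                  94.9, 95.0, 95.1, 96.9, 97.0, 97.1, 100.0]
        for ident in values:
            for cov in values:
                for hq in values + [None]:
                    for phen in PhenologyStatus:
                        got = categorize(ident, cov, hq, phen).value
                        want = categorize_tier_table(ident, cov, hq, phen.value)
                        assert got == want, (ident, cov, hq, phen)


def _mk_read(seq, sample_id="s1", pset=PrimerSet.SET1, q=40):
    return SampleRead(
        sample_id, f"{sample_id}|{pset.value}|merged", seq,
        qualities=(q,) * len(seq), primer_set=pset,
    )


class TestIdentifySample:
    def test_exact_set1_read_positive(self, small_db):
        refs, truth = small_db
        sp = next(s for s in truth.species if not s.sister_partner)
        res = identify_sample(
            "s1", {PrimerSet.SET1: [_mk_read(sp.amplicon(PrimerSet.SET1))]}, refs
        )
        assert res.category == Category.POSITIVE
        assert res.candidates == (sp.species,)
        assert res.primer_set_used == "set1"

    def test_set1_failure_rescued_by_set2(self, small_db):
        refs, truth = small_db
        sp = next(s for s in truth.species if not s.sister_partner)
        res = identify_sample(
            "s1",
            {PrimerSet.SET2: [_mk_read(sp.amplicon(PrimerSet.SET2), pset=PrimerSet.SET2)]},
            refs,
        )
        assert res.category == Category.POSITIVE
        assert res.primer_set_used == "set2"

    def test_both_sets_failing_reports_both_failed(self, small_db):
        refs, _ = small_db
        # random junk: no hit at >= 95% identity from either set
        rng = np.random.default_rng(0)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        res = identify_sample(
            "s1",
            {
                PrimerSet.SET1: [_mk_read(junk)],
                PrimerSet.SET2: [_mk_read(junk, pset=PrimerSet.SET2)],
            },
            refs,
        )
        assert res.category == Category.NO_IDENTIFICATION
        assert res.primer_set_used == "both_failed"

    def test_recorded_amplification_failure_allowed(self, small_db):
        refs, _ = small_db
        res = identify_sample("s1", {}, refs, amplification_failed=True)
        assert res.category == Category.NO_IDENTIFICATION
        assert res.primer_set_used == "both_failed"

    def test_zero_reads_without_record_is_error(self, small_db):
        refs, _ = small_db
        with pytest.raises(ValueError, match="no reads"):
            identify_sample("s1", {}, refs)

    def test_questionable_set1_not_overridden_by_set2(self, small_db):
        """The fallback fires only on no-identification outcomes."""
        refs, truth = small_db
        sp = next(s for s in truth.species if not s.sister_partner)
        # low-quality set1 read: categorizes questionable (HQ tier), so the
        # perfect set2 read must not be consulted
        res = identify_sample(
            "s1",
            {
                PrimerSet.SET1: [_mk_read(sp.amplicon(PrimerSet.SET1), q=10)],
                PrimerSet.SET2: [_mk_read(sp.amplicon(PrimerSet.SET2), pset=PrimerSet.SET2)],
            },
            refs,
        )
        assert res.category == Category.QUESTIONABLE
        assert res.primer_set_used == "set1"


class TestSummaries:
    def test_category_partition_and_percentages(self):
        counts = {
            Category.POSITIVE: 668,
            Category.QUESTIONABLE: 71,
            Category.NO_IDENTIFICATION: 55,
        }
        s = summarize_categories(counts)
        assert s.percentages[Category.POSITIVE] == 84.1
        assert s.percentages[Category.QUESTIONABLE] == 8.9
        assert s.percentages[Category.NO_IDENTIFICATION] == 6.9
        assert s.identified_percent == 93.1
        assert s.n_total == 794

    def test_degenerate_tally(self):
        s = summarize_categories({Category.POSITIVE: 1})
        assert s.percentages[Category.POSITIVE] == 100.0
        assert s.percentages[Category.QUESTIONABLE] == 0.0

    def test_empty_results_error(self):
        with pytest.raises(ValueError):
            summarize_categories([])

    def test_round_percent_half_up(self):
        assert round_percent(794, 4383, 2) == 18.12
        assert round_percent(1, 8) == 12.5
        assert round_percent(5, 1000) == 0.5

    def test_rescue_rate(self):
        assert rescue_rate(14, 37) == 37.8


def _res(sample_id, candidates, category=Category.POSITIVE):
    return IdentificationResult(
        sample_id, category, candidates, 99.0, 98.0, 90.0,
        PhenologyStatus.CONSISTENT, "set1",
    )


class TestBlindTest:
    def test_planted_mismatches_and_tie(self):
        results = []
        morph = {}
        for i in range(48):
            sid = f"spec{i:02d}"
            if i < 5:  # clean mismatches
                results.append(_res(sid, ("Species_b",)))
                morph[sid] = "Species_a"
            elif i == 5:  # ambiguous sister tie containing the morph call
                results.append(_res(sid, ("Sialia_currucoides", "Sialia_mexicana")))
                morph[sid] = "Sialia_currucoides"
            else:
                results.append(_res(sid, ("Species_a",)))
                morph[sid] = "Species_a"
        rep = blind_test_compare(morph, results)
        assert rep.n_specimens == 48
        assert rep.n_match == 42
        assert rep.n_mismatch == 5 and rep.n_ambiguous == 1
        assert rep.mismatch_percent == 12.5

    def test_all_matching_zero(self):
        results = [_res("a", ("X_y",))]
        assert blind_test_compare({"a": "X_y"}, results).mismatch_percent == 0.0

    def test_missing_result_is_error(self):
        with pytest.raises(ValueError):
            blind_test_compare({"a": "X_y"}, [])

    def test_planted_error_rate_recovered(self):
        """Recovered mismatch rate tracks the planted rate binomially."""
        rng = np.random.default_rng(9)
        rate, n = 0.15, 200
        results, morph = [], {}
        planted = 0
        for i in range(n):
            sid = f"s{i}"
            results.append(_res(sid, ("True_species",)))
            if rng.random() < rate:
                morph[sid] = "Wrong_species"
                planted += 1
            else:
                morph[sid] = "True_species"
        rep = blind_test_compare(morph, results)
        assert rep.n_mismatch == planted
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(rep.mismatch_percent / 100.0 - rate) <= 3 * se


def test_set2_fallback_never_decreases_positive_count(small_db, small_survey):
    """Enabling the second primer set can only add positive identifications."""
    from featherid import identify_survey

    refs, _ = small_db
    with_fallback = identify_survey(
        small_survey.reads, small_survey.metadata, refs, small_survey.phenology,
        primer_set_policy="auto",
    )
    set1_only = identify_survey(
        small_survey.reads, small_survey.metadata, refs, small_survey.phenology,
        primer_set_policy="1",
    )
    n_pos = lambda rs: sum(r.category == Category.POSITIVE for r in rs)
    assert n_pos(with_fallback) >= n_pos(set1_only)


def test_results_partition_into_exactly_one_category(small_db, small_survey):
    from featherid import identify_survey

    refs, _ = small_db
    results = identify_survey(
        small_survey.reads, small_survey.metadata, refs, small_survey.phenology
    )
    s = summarize_categories(results)
    assert sum(s.counts.values()) == len(results)
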
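import numpy as np
import pytest

from featherid import (
    AlignmentHit,
    PrimerSet,
    ScoringScheme,
    local_align,
    reverse_complement,
    search_database,
    top_candidates,
)
from featherid.formats_io import BarcodeReference, EcoGroup, RegionLabel

from oracles import sw_affine_oracle


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestLocalAlign:
    def test_identical_sequences_perfect_metrics(self):
        rng = np.random.default_rng(0)
        s = _rand_seq(rng, 100)
        hit = local_align(s, s)
        assert hit.score == 200  # 100 matches x +2
        assert hit.identity_percent == 100.0
        assert hit.coverage_percent == 100.0

    def test_exact_substring_full_coverage(self):
        rng = np.random.default_rng(1)
        subject = _rand_seq(rng, 200)
        query = subject[60:110]
        hit = local_align(query, subject)
        assert hit.identity_percent == 100.0
        assert hit.coverage_percent == 100.0
        assert hit.subject_span == (60, 110)

    def test_specific_pair_matches_independent_dp(self):
        score, matches, aligned, qspan, sspan = sw_affine_oracle("ACGTACGT", "ACGAACGT")
        hit = local_align("ACGTACGT", "ACGAACGT")
        assert hit.score == score
        assert hit.identity_percent == pytest.approx(100.0 * matches / aligned)
        assert hit.query_span == qspan and hit.subject_span == sspan

    def test_gap_cost_convention(self):
        # deleting 2 bases: 8 matches +16, gap open -5, extend -2 => 9
        hit = local_align("AAAACCCC", "AAAAGGCCCC", ScoringScheme())
        assert hit.score == 16 - 5 - 2

    def test_identity_symmetric_for_full_overlap(self):
        # equal-length sequences differing by a few substitutions align end
        # to end, where identity must be direction-independent
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = _rand_seq(rng, 80)
            b = list(a)
            for pos in rng.integers(0, 80, 4):
                b[pos] = "ACGT"[rng.integers(4)]
            b = "".join(b)
            assert (
                local_align(a, b).identity_percent
                == local_align(b, a).identity_percent
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")


def _ref(ref_id, species, seq):
    return BarcodeReference(
        ref_id, species, species, "Passeriformes", "F", EcoGroup.SONGBIRD,
        RegionLabel.FULL, seq,
    )


class TestSearchDatabase:
    def test_exact_reference_ranks_first(self, small_db):
        refs, truth = small_db
        target = truth.species[0]
        query = target.amplicon(PrimerSet.SET1)
        hits = search_database(query, refs)
        top_ref = next(r for r in refs if r.ref_id == hits[0].ref_id)
        assert top_ref.species in (target.species, target.sister_partner)
        assert hits[0].identity_percent == 100.0

    def test_sister_pair_shares_metrics_at_top(self, small_db):
        refs, truth = small_db
        sister = next(s for s in truth.species if s.sister_partner)
        hits = search_database(sister.amplicon(PrimerSet.SET1), refs)
        assert hits[0].identity_percent == hits[1].identity_percent == 100.0
        assert hits[0].coverage_percent == hits[1].coverage_percent
        species = {
            next(r for r in refs if r.ref_id == h.ref_id).species for h in hits[:2]
        }
        assert species == {sister.species, sister.sister_partner}

    def test_reverse_complement_query_same_best_species(self, small_db):
        refs, truth = small_db
        query = truth.species[2].amplicon(PrimerSet.SET1)
        fwd = search_database(query, refs)
        rc = search_database(reverse_complement(query), refs)
        assert fwd[0].ref_id == rc[0].ref_id
        assert rc[0].orientation == "-"

    def test_ranking_equals_allpairs_oracle(self, small_db):
        """Ranking equals sorting independent oracle alignments by
        (identity, coverage, score)."""
        refs, truth = small_db
        rng = np.random.default_rng(8)
        for _ in range(3):
            sp = truth.species[rng.integers(len(truth.species))]
            amp = sp.amplicon(PrimerSet.SET1)
            # lightly corrupted query, forward orientation
            q = list(amp)
            for pos in rng.integers(0, len(q), 5):
                q[pos] = "ACGT"[rng.integers(4)]
            query = "".join(q)
            hits = search_database(query, refs, min_report_identity=0.0,
                                   try_reverse_complement=False)
            oracle_rows = []
            for ref in refs:
                score, matches, aligned, qspan, _ = sw_affine_oracle(query, ref.sequence)
                ident = 100.0 * matches / aligned if aligned else 0.0
                cov = 100.0 * (qspan[1] - qspan[0]) / len(query)
                oracle_rows.append((-ident, -cov, -score, ref.ref_id))
            oracle_rows.sort()
            assert [h.ref_id for h in hits] == [row[3] for row in oracle_rows]

    def test_empty_reference_set_is_error(self):
        with pytest.raises(ValueError):
            search_database("ACGT", [])

    def test_min_report_identity_filters(self, small_db):
        refs, truth = small_db
        query = truth.species[0].amplicon(PrimerSet.SET1)
        hits = search_database(query, refs, min_report_identity=99.0)
        assert all(h.identity_percent >= 99.0 for h in hits)


def _hit(ref_id, ident, cov, score=100):
    return AlignmentHit(ref_id, score, ident, cov, (0, 100), (0, 100))


class TestTopCandidates:
    SPECIES = {"r1": "Aves_una", "r2": "Aves_dua", "r3": "Aves_tria"}

    def test_runner_up_outside_epsilon_excluded(self):
        hits = [_hit("r1", 99.8, 90.0), _hit("r2", 97.0, 99.0)]
        cands = top_candidates(hits, self.SPECIES, 0.5)
        assert cands.species == ("Aves_una",)

    def test_metric_identical_species_co_reported(self):
        hits = [_hit("r1", 100.0, 100.0), _hit("r2", 100.0, 100.0)]
        cands = top_candidates(hits, self.SPECIES, 0.5)
        assert cands.species == ("Aves_dua", "Aves_una")

    def test_coverage_preferred_within_epsilon(self):
        hits = [_hit("r1", 98.6, 80.0), _hit("r2", 98.3, 95.0)]
        cands = top_candidates(hits, self.SPECIES, 0.5)
        assert cands.species == ("Aves_dua",)
        assert cands.best.coverage_percent == 95.0

    def test_empty_hits_empty_candidates(self):
        assert not top_candidates([], self.SPECIES)


def test_mean_best_identity_monotone_in_substitution_rate(small_db):
    """Heavier degradation can only lower the mean best-hit identity."""
    from featherid import SimulationConfig, simulate_survey

    _, truth = small_db
    means = []
    for rate in (0.0, 0.02, 0.06):
        cfg = SimulationConfig(
            n_species=12, n_samples=40, seed=19, substitution_rate=rate,
            truncation_rate=0.0, duplicate_rate=0.0, pcr_failure_rate=0.0,
        )
        survey = simulate_survey(truth, cfg)
        refs, _ = small_db
        idents = [
            search_database(r.sequence, refs)[0].identity_percent
            for r in survey.reads
        ]
        means.append(sum(idents) / len(idents))
    assert means[0] >= means[1] >= means[2]


class TestOracleEquivalence:
    def test_random_pairs_match_independent_dp_exactly(self):
        """Implementation score/identity equals the pure-Python DP oracle on
        short random pairs (spot check; the large sweep lives in the
        acceptance suite)."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            a = _rand_seq(rng, int(rng.integers(5, 80)))
            b = _rand_seq(rng, int(rng.integers(5, 80)))
            score, matches, aligned, qspan, sspan = sw_affine_oracle(a, b)
            hit = local_align(a, b)
            assert hit.score == score
            got_ident = hit.identity_percent
            want_ident = 100.0 * matches / aligned if aligned else 0.0
            assert got_ident == pytest.approx(want_ident, abs=1e-12)
            assert hit.query_span == qspan and hit.subject_span == sspan
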
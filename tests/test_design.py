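"""Guide design: enumeration, ranking, filters, duplex transformation."""

import warnings

import pytest

import shmirkit as sk
from shmirkit.design import (
    ConfigError,
    ContractError,
    offtarget_scan,
    target_window22,
)


def _random_target(rng, n=100, name="ref"):
    return sk.NucSequence(name, "".join(rng.choice(list("ACGT"), n)))


class TestEnumerate:
    def test_window_count_and_starts(self, rng):
        target = _random_target(rng, 100)
        cands = sk.enumerate_candidates(target)
        assert len(cands) == 78
        assert [c.start for c in cands] == list(range(2, 80))

    def test_minimal_target(self, rng):
        target = _random_target(rng, 23)
        (cand,) = sk.enumerate_candidates(target)
        assert cand.start == 2

    def test_windows_equal_target_substrings(self, rng):
        target = _random_target(rng, 80)
        for c in sk.enumerate_candidates(target):
            assert c.sense21 == target.seq[c.start : c.start + 21]

    def test_too_short_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert sk.enumerate_candidates(sk.NucSequence("s", "ACGT" * 5)) == []

    def test_hard_masked_windows_skipped(self):
        seq = "ACGT" * 6 + "N" + "ACGT" * 6
        target = sk.NucSequence("m", seq, allow_n=True)
        for c in sk.enumerate_candidates(target):
            assert "N" not in target.seq[c.start - 2 : c.start + 20]


class TestRanking:
    def test_constant_scorer_keeps_enumeration_order(self, rng):
        cands = sk.enumerate_candidates(_random_target(rng, 60))
        ranked = sk.rank_candidates(cands, "constant")
        assert [c.start for c in ranked] == [c.start for c in cands]

    def test_deterministic(self, rng):
        cands = sk.enumerate_candidates(_random_target(rng, 90))
        a = sk.rank_candidates(cands, "heuristic")
        b = sk.rank_candidates(cands, "heuristic")
        assert [(c.start, c.score) for c in a] == [(c.start, c.score) for c in b]

    def test_injected_scores_reverse_order(self, rng):
        cands = sk.enumerate_candidates(_random_target(rng, 60))
        scores = {c.start: i for i, c in enumerate(cands)}  # ascending with start
        ranked = sk.rank_candidates(cands, "external", external_scores=scores)
        assert [c.start for c in ranked] == [c.start for c in reversed(cands)]

    def test_unknown_scorer(self, rng):
        cands = sk.enumerate_candidates(_random_target(rng, 40))
        with pytest.raises(ConfigError):
            sk.rank_candidates(cands, "dsir")


class TestIsoformCoverage:
    def test_shared_core_covered(self, planted_txome):
        txome, truth, _ = planted_txome
        isoforms = txome.target_isoforms()
        ref = max(isoforms, key=len)
        # a window safely inside the shared CDS
        cds_start = ref.seq.find(truth["cds"])
        cand = sk.GuideCandidate(ref.id, cds_start + 50, ref.seq[cds_start + 50 : cds_start + 71])
        assert sk.check_isoform_coverage(cand, isoforms, ref)

    def test_junction_window_not_covered(self, planted_txome):
        txome, truth, _ = planted_txome
        isoforms = txome.target_isoforms()
        ref = max(isoforms, key=len)
        # a window straddling the reference's private 5' UTR / CDS junction
        cds_start = ref.seq.find(truth["cds"])
        cand = sk.GuideCandidate(ref.id, cds_start - 10, ref.seq[cds_start - 10 : cds_start + 11])
        assert not sk.check_isoform_coverage(cand, isoforms, ref)

    def test_single_isoform_always_true(self, rng):
        target = _random_target(rng, 60)
        for c in sk.enumerate_candidates(target):
            assert sk.check_isoform_coverage(c, [target], target)


class TestOfftargetScan:
    def _candidate_at(self, txome, start):
        ref = max(txome.target_isoforms(), key=len)
        return sk.GuideCandidate(ref.id, start, ref.seq[start : start + 21]), ref

    def test_planted_16_run_fails_with_exact_run(self, planted_txome):
        txome, _, _ = planted_txome
        index = sk.build_kmer_index(txome)
        cand, ref = self._candidate_at(txome, 300)
        res = offtarget_scan(cand, index, ref, compute_max_run=True)
        assert not res.passed
        assert res.max_run == 16
        # cross-check with the LCS oracle against every decoy
        w = target_window22(cand, ref)
        lcs = max(sk.longest_common_substring(w, t.seq) for t in txome.non_target_transcripts())
        assert lcs == 16

    def test_planted_15_run_passes(self, planted_txome):
        txome, _, _ = planted_txome
        index = sk.build_kmer_index(txome)
        cand, ref = self._candidate_at(txome, 200)
        res = offtarget_scan(cand, index, ref, compute_max_run=True)
        assert res.passed
        assert res.max_run == 15

    def test_targets_only_transcriptome_passes(self, rng):
        target = _random_target(rng, 80)
        txome = sk.Transcriptome([target], target_ids={target.id}, k=16)
        index = sk.build_kmer_index(txome)
        for c in sk.enumerate_candidates(target):
            assert offtarget_scan(c, index, target).passed


class TestDuplexConstruction:
    def test_worked_example(self):
        target = sk.NucSequence("toy", "AAACCCGGGTTTAAACCCGGGTTTAAA")
        cand = sk.GuideCandidate("toy", 2, target.seq[2:23])
        guide = sk.make_mirE_duplex(cand, target)
        assert guide.sense22_raw == "AAACCCGGGTTTAAACCCGGGT"
        assert guide.antisense22 == "ACCCGGGTTTAAACCCGGGTTT"
        assert guide.antisense22 == sk.reverse_complement(guide.sense22_raw)

    def test_window_algebra(self, rng):
        target = _random_target(rng, 70)
        for c in sk.enumerate_candidates(target):
            g = sk.make_mirE_duplex(c, target)
            assert len(g.sense22_raw) == 22
            assert g.antisense22 == sk.reverse_complement(g.sense22_raw)
            # 3'-trimmed 21-mer sits at offset 2
            assert g.sense22_raw[2:22] == c.sense21[0:20]

    def test_start_without_context_rejected(self, rng):
        target = _random_target(rng, 40)
        cand = sk.GuideCandidate(target.id, 1, target.seq[1:22])
        with pytest.raises(ContractError):
            sk.make_mirE_duplex(cand, target)


class TestSenseMismatch:
    @pytest.mark.parametrize("first,expected", [("C", "A"), ("G", "A"), ("A", "C"), ("T", "C")])
    def test_exhaustive_first_base_map(self, first, expected):
        s = first + "ACGT" * 5 + "A"
        out = sk.apply_sense_mismatch(s)
        assert out[0] == expected
        assert out[1:] == s[1:]

    def test_exactly_one_difference(self, rng):
        s = "".join(rng.choice(list("ACGT"), 22))
        out = sk.apply_sense_mismatch(s)
        assert sum(a != b for a, b in zip(s, out)) == 1

    def test_length_contract(self):
        with pytest.raises(ContractError):
            sk.apply_sense_mismatch("ACGT")


class TestPipeline:
    def test_planted_offtarget_window_excluded(self, planted_txome):
        txome, _, _ = planted_txome
        result = sk.design_guides(txome.target_isoforms(), txome, n_select=1000)
        starts = {g.origin.start for g in result.guides}
        # runs of 16 and 17 nt planted at candidate starts 300 and 400
        assert 300 not in starts and 400 not in starts
        # runs of 14 and 15 nt are tolerated
        audit = result.audit.set_index("start")
        assert audit.loc[200, "offtarget_pass"]
        assert audit.loc[100, "offtarget_pass"]

    def test_top3_when_all_survive(self, rng):
        target = _random_target(rng, 120)
        txome = sk.Transcriptome([target], target_ids={target.id}, k=16)
        result = sk.design_guides([target], txome)
        assert len(result.guides) == 3
        ranked = sk.rank_candidates(sk.enumerate_candidates(target), "heuristic")
        assert [g.origin.start for g in result.guides] == [c.start for c in ranked[:3]]

    def test_deterministic(self, planted_txome):
        txome, _, _ = planted_txome
        a = sk.design_guides(txome.target_isoforms(), txome)
        b = sk.design_guides(txome.target_isoforms(), txome)
        assert [g.sense22 for g in a.guides] == [g.sense22 for g in b.guides]
        assert a.audit.equals(b.audit)

    def test_emitted_guide_invariants(self, planted_txome):
        txome, _, _ = planted_txome
        isoforms = txome.target_isoforms()
        ref = max(isoforms, key=len)
        index = sk.build_kmer_index(txome)
        result = sk.design_guides(isoforms, txome)
        assert result.guides
        for g in result.guides:
            assert len(g.origin.sense21) == 21
            assert len(g.sense22) == len(g.antisense22) == 22
            assert sk.check_isoform_coverage(g.origin, isoforms, ref)
            assert offtarget_scan(g.origin, index, ref).passed
            assert sum(a != b for a, b in zip(g.sense22, g.sense22_raw)) == 1

    def test_fewer_survivors_warns(self, rng):
        target = _random_target(rng, 30)  # only 8 candidate windows
        txome = sk.Transcriptome([target], target_ids={target.id}, k=16)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            result = sk.design_guides([target], txome, n_select=50)
        assert len(result.guides) < 50
        assert any("survive" in str(w.message) for w in rec)
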
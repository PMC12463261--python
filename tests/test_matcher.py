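"""Similarity scorer, best-match search and the matching cascade."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mednorm.cache import CacheSet
from mednorm.fixtures import DATA_DIR, NoiseModel, corrupt_name, gen_vocabulary
from mednorm.matcher import (
    MatchStage,
    MatchStatus,
    best_match,
    match_batch,
    match_cascade,
    similarity,
)
from mednorm.preprocess import RuleSet, normalize
from mednorm.vocab import Tier, load_vocabulary
from tests.conftest import DEMO_NAMES


def _levenshtein(a: str, b: str) -> int:
    """Reference DP edit distance, independent of the scorer's library."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def _shares_token(query: str, name: str) -> bool:
    return any(
        _levenshtein(qt, nt) <= 1
        for qt in query.split()
        for nt in name.split()
    )


def _similarity_oracle(a: str, b: str) -> float:
    if not a and not b:
        return 0.0
    ta, tb = set(a.split()), set(b.split())
    token = len(ta & tb) / len(ta | tb) if ta | tb else 0.0
    char = 1.0 - _levenshtein(a, b) / max(len(a), len(b)) if (a or b) else 0.0
    return 0.5 * token + 0.5 * char


class TestSimilarity:
    def test_identity_is_one(self):
        assert similarity("metformin", "metformin") == 1.0

    def test_single_edit_disjoint_tokens(self):
        # token sets disjoint, edit distance 1 over length 9
        assert similarity("metformn", "metformin") == pytest.approx(
            0.5 * 0 + 0.5 * (1 - 1 / 9)
        )

    def test_token_reorder_scores_above_half(self):
        s = similarity("losartan hctz", "hctz losartan")
        assert s > 0.5
        assert s == pytest.approx(_similarity_oracle("losartan hctz", "hctz losartan"))

    def test_both_empty_is_zero(self):
        assert similarity("", "") == 0.0

    @settings(max_examples=300, deadline=None)
    @given(
        st.text(alphabet="abcdef ", max_size=20),
        st.text(alphabet="abcdef ", max_size=20),
    )
    def test_symmetric_bounded_and_matches_oracle(self, a, b):
        a, b = " ".join(a.split()), " ".join(b.split())
        s = similarity(a, b)
        assert s == pytest.approx(similarity(b, a))
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(_similarity_oracle(a, b))
        if a == b and a:
            assert s == 1.0


class TestBestMatch:
    def test_exact_synonym_short_circuits(self, primary):
        hit = best_match(primary, normalize("tylenol"), 0.4)
        assert hit.concept.concept_id == "B01"
        assert hit.score == 1.0

    def test_misspelling_scored(self, primary):
        hit = best_match(primary, normalize("metformn"), 0.4)
        assert hit.concept.concept_id == "I02"
        assert hit.score == pytest.approx(similarity("metformn", "metformin"))

    def test_device_below_threshold(self, primary, rules):
        assert best_match(primary, normalize("ACCU-CHEK AVIVA PLUS", rules), 0.4) is None

    def test_empty_name_returns_nothing(self, primary):
        assert best_match(primary, normalize(""), 0.4) is None

    def test_threshold_validation(self, primary):
        with pytest.raises(ValueError):
            best_match(primary, normalize("x"), 0.0)

    def test_equals_exhaustive_search(self, tmp_path, rules):
        """Brute-force max-similarity over every vocabulary name agrees
        with the indexed search whenever the winner shares a token."""
        gen_vocabulary(11, 25, 25, 8, 0.2, tmp_path / "v")
        store = load_vocabulary(tmp_path / "v", Tier.PRIMARY, rules)
        model = NoiseModel(p_typo=1.0, p_dose_suffix=0.3, rng_seed=5)
        queries = [
            normalize(corrupt_name(name, model).raw, rules).text
            for names in store.names.values()
            for name in names
        ]
        for q in queries:
            got = best_match(store, q, 0.35)
            want = None
            for cid in sorted(store.concepts):
                for name in store.names[cid]:
                    s = _similarity_oracle(q, name)
                    if s < 0.35:
                        continue
                    key = (-s, len(name), cid)
                    if want is None or key < want[0]:
                        want = (key, cid, name, s)
            if want is None:
                assert got is None
            elif _shares_token(q, want[2]):
                # the indexed search guarantees equality with exhaustive
                # search whenever the winner shares a token (exact or at
                # edit distance 1) with the query
                assert got is not None
                assert got.concept.concept_id == want[1]
                assert got.score == pytest.approx(want[3])


class TestCascade:
    @pytest.mark.parametrize("raw, status, concept_id", DEMO_NAMES)
    def test_demo_names(self, raw, status, concept_id, primary, extended, rules):
        res = match_cascade(raw, primary, extended, None, rules)
        assert res.status.value == status
        assert res.concept_id == concept_id

    def test_fallback_secondary_stage(self, primary, extended, rules):
        res = match_cascade("adriblastina", primary, extended, None, rules)
        assert res.status is MatchStatus.MATCHED
        assert res.stage is MatchStage.FALLBACK_SECONDARY
        assert res.concept_id == "I06"  # anchored back into the primary tier

    def test_unmatched_has_stage_none(self, primary, extended, rules):
        res = match_cascade("????", primary, extended, None, rules)
        assert res.status is MatchStatus.UNMATCHED
        assert res.stage is MatchStage.NONE
        assert res.concept_id is None

    def test_result_cached_including_negative(self, primary, extended, rules, cache_dir):
        cache = CacheSet(cache_dir)
        match_cascade("????", primary, extended, cache, rules)
        match_cascade("tylenol", primary, extended, cache, rules)
        reopened = CacheSet(cache_dir)
        assert reopened.get("match", "????")["status"] == "UNMATCHED"
        assert reopened.get("match", "tylenol")["concept_id"] == "B01"

    def test_monotone_under_vocabulary_growth(self, rules, tmp_path):
        """Adding primary concepts never turns a matched name unmatched."""
        gen_vocabulary(3, 10, 5, 2, 0.0, tmp_path / "small")
        gen_vocabulary(3, 10, 5, 2, 0.0, tmp_path / "big")
        extra = "\n".join(
            ["Z9001\tzzextraone\tINGREDIENT\tprimary",
             "Z9002\tzzextratwo\tBRAND\tprimary", ""]
        )
        with open(tmp_path / "big" / "concepts.tsv", "a") as fh:
            fh.write(extra)
        small = load_vocabulary(tmp_path / "small", Tier.PRIMARY, rules)
        big = load_vocabulary(tmp_path / "big", Tier.PRIMARY, rules)
        model = NoiseModel(p_typo=1.0, rng_seed=2)
        for names in small.names.values():
            for name in names:
                raw = corrupt_name(name, model).raw
                before = match_cascade(raw, small, None, None, rules)
                after = match_cascade(raw, big, None, None, rules)
                if before.status is MatchStatus.MATCHED:
                    assert after.status is MatchStatus.MATCHED


class TestBatch:
    def test_demo_batch_match_rate(self, primary, extended, rules):
        names = [raw for raw, _, _ in DEMO_NAMES]
        results, summary = match_batch(names, primary, extended, None, rules)
        assert [r.raw_name for r in results] == names
        assert summary.distinct == 7
        assert summary.matched_distinct == 5
        assert summary.match_rate == pytest.approx(100 * 5 / 7)

    def test_empty_batch_reports_na(self, primary, extended, rules):
        _, summary = match_batch([], primary, extended, None, rules)
        assert summary.match_rate is None
        assert summary.match_rate_display == "n/a"

    def test_repeated_name_served_from_cache(self, primary, extended, rules, cache_dir):
        cache = CacheSet(cache_dir)
        results, summary = match_batch(
            ["tylenol"] * 100, primary, extended, cache, rules
        )
        assert all(r.status is MatchStatus.MATCHED for r in results)
        assert summary.stage_counts.get("CACHE", 0) >= 99

    def test_warm_cache_reproduces_stable_fields(self, primary, extended, rules, cache_dir):
        names = [raw for raw, _, _ in DEMO_NAMES]
        cold, _ = match_batch(names, primary, extended, CacheSet(cache_dir), rules)
        warm, summary = match_batch(names, primary, extended, CacheSet(cache_dir), rules)
        for c, w in zip(cold, warm):
            assert (c.status, c.concept_id, c.standardized_name, c.score,
                    c.normalized) == (
                w.status, w.concept_id, w.standardized_name, w.score,
                w.normalized)
        # matched names report stage CACHE; unmatched keep stage NONE
        n_matched = sum(1 for r in warm if r.status is MatchStatus.MATCHED)
        assert summary.stage_counts.get("CACHE", 0) == n_matched == 5
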
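"""ORF trimming, alignment identity, greedy binning, universal types."""

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from scatyper import clustering, synthetic
from scatyper.clustering import (
    IdentityCache,
    Rejection,
    SeqRecord,
    greedy_cluster,
    pairwise_identity,
    threshold_sweep,
    trim_to_orf,
    universal_types,
)
from scatyper.errors import ConsistencyError, InvalidParameterError
from tests.conftest import to_records


class TestTrimToOrf:
    def test_hand_example(self):
        out = trim_to_orf(SeqRecord("r", "CCATGAAATTTTAA"), min_length=6)
        assert out.sequence == "ATGAAATTT"

    def test_idempotent_on_trimmed_orf(self):
        orf = "ATG" + "GCT" * 30
        once = trim_to_orf(SeqRecord("r", orf))
        assert once.sequence == orf

    def test_all_stop_sequence_rejected(self):
        out = trim_to_orf(SeqRecord("r", "TAATAGTGA" * 10))
        assert isinstance(out, Rejection)

    def test_short_orf_rejected_with_reason(self):
        out = trim_to_orf(SeqRecord("r", "CCCATGAAATAAGGG" * 5))
        assert isinstance(out, Rejection)
        assert "below minimum" in out.reason

    def test_longest_frame_consistent_orf_wins(self):
        # frame 1 holds a long ORF; frame 0 a short one
        long_orf = "ATG" + "GAA" * 40
        seq = "ATGTAA" + "C" + long_orf
        out = trim_to_orf(SeqRecord("r", seq))
        assert out.sequence.startswith("ATG" + "GAA")
        assert len(out.sequence) == len(long_orf)


def _enumerate_alignments(a: str, b: str):
    """All global alignments of a and b as (cols_a, cols_b) gapped strings."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) and j == len(b):
            return [("", "")]
        outs = []
        if i < len(a) and j < len(b):
            outs += [(a[i] + x, b[j] + y) for x, y in rec(i + 1, j + 1)]
        if i < len(a):
            outs += [(a[i] + x, "-" + y) for x, y in rec(i + 1, j)]
        if j < len(b):
            outs += [("-" + x, b[j] + y) for x, y in rec(i, j + 1)]
        return outs

    return rec(0, 0)


def _score_alignment(ga: str, gb: str) -> float:
    """Score with the package's declared scheme: match +1, mismatch -1,
    affine gaps (open -5, extend -2), end-gap runs extend at -0.5."""
    score = 0.0
    for row_self, row_other in ((ga, gb), (gb, ga)):
        runs = []
        i = 0
        while i < len(row_self):
            if row_self[i] == "-":
                j = i
                while j < len(row_self) and row_self[j] == "-":
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        for lo, hi in runs:
            terminal = lo == 0 or hi == len(row_self)
            extend = -0.5 if terminal else -2.0
            score += -5.0 + extend * (hi - lo - 1)
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            score += 1.0 if x == y else -1.0
    return score


def _identity_of(ga: str, gb: str) -> float:
    start = max(len(ga) - len(ga.lstrip("-")), len(gb) - len(gb.lstrip("-")))
    end = min(len(ga.rstrip("-")), len(gb.rstrip("-")))
    if end <= start:
        return 0.0
    matches = sum(
        1 for x, y in zip(ga[start:end], gb[start:end]) if x == y and x != "-"
    )
    return matches / (end - start)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_hand_substitution(self):
        assert pairwise_identity("AAAA", "AAAT") == 0.75

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=40))
            b = "".join(rng.choice(list("ACGT"), size=35))
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a), abs=1e-12
            )

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            pairwise_identity("", "ACGT")

    def test_exhaustive_alignment_oracle_tiny_pairs(self):
        """Identity agrees with brute-force enumeration of every global
        alignment under the same scoring scheme (optimal-score alignments)."""
        rng = np.random.default_rng(13)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 7))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 7))))
            alignments = _enumerate_alignments(a, b)
            scores = [_score_alignment(ga, gb) for ga, gb in alignments]
            best = max(scores)
            best_identities = {
                round(_identity_of(ga, gb), 12)
                for (ga, gb), s in zip(alignments, scores)
                if s == pytest.approx(best, abs=1e-9)
            }
            assert round(pairwise_identity(a, b), 12) in best_identities

    def test_truncated_sequence_keeps_high_identity(self):
        """A clone truncated mid-ORF still matches its full-length founder
        (end-gap exclusion)."""
        rng = np.random.default_rng(77)
        full = "".join(rng.choice(list("ACGT"), size=400))
        prefix = full[:150]
        assert pairwise_identity(prefix, full) == 1.0


def _make_variant(rng, base, n_subs):
    """Mutate exactly n_subs distinct positions of base."""
    s = list(base)
    for i in rng.choice(len(base), size=n_subs, replace=False):
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


class TestGreedyCluster:
    def test_single_record_single_bin(self):
        cs = greedy_cluster([SeqRecord("a", "ATGC" * 10)], 70.0)
        assert cs.s_obs == 1 and cs.bins[0].name == "a"

    def test_first_qualifying_bin_rule(self):
        """Designed identities: A-B ~95%, A-C & B-C ~60%; at 70% B joins A's
        bin and C founds its own."""
        rng = np.random.default_rng(50)
        base = "".join(rng.choice(list("ACGT"), size=100))
        a = base
        b = _make_variant(rng, base, 5)  # ~95% to A
        c = _make_variant(rng, base, 45)  # far from both
        assert pairwise_identity(a, b) >= 0.9
        assert pairwise_identity(a, c) < 0.7 and pairwise_identity(b, c) < 0.7
        cs = greedy_cluster(
            [SeqRecord("A", a), SeqRecord("B", b), SeqRecord("C", c)], 70.0
        )
        assert [(x.name, sorted(x.member_ids)) for x in cs.bins] == [
            ("A", ["A", "B"]), ("C", ["C"])
        ]

    def test_threshold_100_exact_duplicates_cobin(self):
        seq1, seq2 = "ACGT" * 10, "TTTTACGT" * 5
        records = [
            SeqRecord("a", seq1), SeqRecord("b", seq1), SeqRecord("c", seq2)
        ]
        cs = greedy_cluster(records, 100.0)
        assert [sorted(b.member_ids) for b in cs.bins] == [["a", "b"], ["c"]]

    def test_partition_property(self, clone_library):
        records = to_records(clone_library[:150])
        for threshold in (99.0, 70.0, 40.0):
            cs = greedy_cluster(records, threshold)
            members = sorted(m for b in cs.bins for m in b.member_ids)
            assert members == sorted(r.id for r in records)

    def test_founders_below_threshold_with_earlier_founders(self, clone_library):
        records = to_records(clone_library[:120])
        threshold = 70.0
        cs = greedy_cluster(records, threshold)
        cache = IdentityCache()
        founders = [b.founder for b in cs.bins]
        for i, f in enumerate(founders):
            assert pairwise_identity(f.sequence, f.sequence) == 1.0
            for earlier in founders[:i]:
                assert 100 * cache.identity(f, earlier) < threshold

    def test_invalid_threshold(self):
        with pytest.raises(InvalidParameterError):
            greedy_cluster([SeqRecord("a", "ACGT")], 0.0)


class TestThresholdSweep:
    def test_all_identical_input(self):
        records = [SeqRecord(f"r{i}", "ATG" + "AAA" * 30) for i in range(5)]
        table, clusters = threshold_sweep(records)
        assert (table["s_obs"] == 1).all()

    def test_s_obs_non_increasing_down_the_sweep(self, clone_library):
        records = to_records(clone_library[:200])
        table, _ = threshold_sweep(records)
        s = table.sort_values("threshold", ascending=False)["s_obs"].tolist()
        assert s == sorted(s, reverse=True)

    def test_diversity_columns_attached(self, clone_library):
        table, _ = threshold_sweep(to_records(clone_library[:60]))
        assert {"threshold", "n_sequences", "s_obs", "chao1",
                "chao1_bias_corrected", "shannon"} <= set(table.columns)
        assert (table["chao1"] >= table["s_obs"] - 1e-9).all()


class TestUniversalTypes:
    def _meta(self, mapping):
        return pd.DataFrame.from_dict(mapping, orient="index")

    def test_single_animal_all_universal(self):
        cs = greedy_cluster(
            [SeqRecord("a", "ACGT" * 10), SeqRecord("b", "TGCA" * 10)], 99.0
        )
        meta = self._meta({
            "a": {"animal": 8, "week": 2, "hour": 1, "fraction": "fiber"},
            "b": {"animal": 8, "week": 2, "hour": 1, "fraction": "liquid"},
        })
        summary = universal_types(cs, meta)
        assert sorted(summary.universal) == ["a", "b"]

    def test_three_animal_toy(self):
        x, y = "ACGT" * 15, "GGCC" * 15
        records = [
            SeqRecord("x8", x), SeqRecord("x64", x), SeqRecord("x71", x),
            SeqRecord("y8", y),
        ]
        meta = self._meta({
            rid: {"animal": a, "week": 2, "hour": 1, "fraction": "fiber"}
            for rid, a in [("x8", 8), ("x64", 64), ("x71", 71), ("y8", 8)]
        })
        summary = universal_types(greedy_cluster(records, 99.0), meta)
        assert summary.universal == ["x8"]
        assert summary.universal_share_by_animal[8] == pytest.approx(0.5)
        assert summary.universal_share_by_animal[64] == pytest.approx(1.0)

    def test_unmapped_clone_rejected(self):
        cs = greedy_cluster([SeqRecord("a", "ACGT" * 10)], 99.0)
        with pytest.raises(ConsistencyError, match="a"):
            universal_types(cs, self._meta({}))

    def test_noise_free_universal_set_matches_truth(self, community,
                                                    type_sequences):
        """With no sequencing error the universal set equals the set of types
        sampled in every animal."""
        clones = synthetic.simulate_clone_library(
            community, type_sequences, depth=12, seed=9, error_rate=0.0
        )
        records = to_records(clones)
        cs = greedy_cluster(records, 70.0)
        meta = community.design.loc[[c.sample_id for c in clones]].copy()
        meta.index = [c.clone_id for c in clones]
        summary = universal_types(cs, meta)

        truth_by_clone = {c.clone_id: c.true_type for c in clones}
        observed = {}
        for c in clones:
            animal = community.design.loc[c.sample_id, "animal"]
            observed.setdefault(c.true_type, set()).add(animal)
        true_universal = {t for t, animals in observed.items() if len(animals) == 3}
        found_universal = {truth_by_clone[name] for name in summary.universal}
        assert found_universal == true_universal
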
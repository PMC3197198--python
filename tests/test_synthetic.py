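"""Synthetic community generator: invariants, determinism, noise models."""

import numpy as np
import pandas as pd
import pytest

from scatyper import digest, synthetic
from scatyper.errors import ConsistencyError, InvalidParameterError
from tests.conftest import to_records


class TestCommunity:
    def test_single_type_is_degenerate_simplex(self):
        truth = synthetic.simulate_community(1, seed=0)
        assert (truth.abundance.to_numpy() == 1.0).all()

    def test_rows_on_simplex(self, community):
        sums = community.abundance.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (community.abundance.to_numpy() >= 0).all()

    def test_full_crossing_design(self, community):
        assert len(community.design) == 36
        combos = community.design[["animal", "week", "hour", "fraction"]]
        assert not combos.duplicated().any()

    def test_deterministic_for_fixed_seed(self):
        a = synthetic.simulate_community(7, seed=42)
        b = synthetic.simulate_community(7, seed=42)
        pd.testing.assert_frame_equal(a.abundance, b.abundance)

    def test_invalid_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthetic.simulate_community(0)

    def test_fraction_enrichment_montecarlo(self):
        """A type given log-fold 2.0 is fiber-enriched in >=95% of seeds."""
        lf = np.zeros(20)
        lf[3] = 2.0
        wins = 0
        for seed in range(100):
            truth = synthetic.simulate_community(
                20, effects=synthetic.Effects(fraction_logfold=lf), seed=seed
            )
            fiber = truth.design["fraction"] == "fiber"
            t = truth.abundance["T003"]
            wins += t[fiber].mean() > t[~fiber].mean()
        assert wins >= 95


class TestTypeSequences:
    def test_zero_rate_identity(self, type_model):
        from dataclasses import replace

        model0 = replace(type_model, between_type_substitution_rate=0.0)
        seqs = synthetic.simulate_type_sequences(model0, 4, seed=1)
        assert all(s == type_model.base_sequence for s in seqs.values())

    def test_primer_sites_intact(self, type_sequences, type_model):
        fwd = type_model.forward_primer
        for s in type_sequences.values():
            assert digest.match_degenerate_primer(s, fwd)[0] == 0

    def test_substitution_count_matches_hand_count(self, type_model):
        """Pairwise identity (via the clustering module) agrees with a direct
        site-by-site count of differing positions (no indels by design)."""
        from scatyper.clustering import pairwise_identity

        seqs = synthetic.simulate_type_sequences(type_model, 2, seed=3)
        a, b = seqs["T000"], seqs["T001"]
        hand = sum(x == y for x, y in zip(a, b)) / len(a)
        assert pairwise_identity(a, b) >= hand  # alignment can only improve
        assert abs(pairwise_identity(a, b) - hand) < 0.05

    def test_divergence_concentrated_in_variable_span(self, type_model):
        seqs = synthetic.simulate_type_sequences(type_model, 10, seed=5)
        base = type_model.base_sequence
        lo, hi = type_model.variable_span
        clo, chi = type_model.conserved_span
        var_div = np.mean(
            [sum(s[i] != base[i] for i in range(lo, hi)) / (hi - lo)
             for s in seqs.values()]
        )
        cons_div = np.mean(
            [sum(s[i] != base[i] for i in range(clo, chi)) / (chi - clo)
             for s in seqs.values()]
        )
        assert var_div > 5 * cons_div

    def test_orf_preserved(self, type_sequences, type_model):
        lo, hi = type_model.orf_span
        for s in type_sequences.values():
            assert s[lo : lo + 3] == "ATG"
            codons = [s[i : i + 3] for i in range(lo + 3, hi - 2, 3)]
            assert not any(c in {"TAA", "TAG", "TGA"} for c in codons)

    def test_bad_span_rejected(self, type_model):
        from dataclasses import replace

        with pytest.raises(InvalidParameterError):
            replace(type_model, variable_span=(0, 10_000))


class TestCloneLibrary:
    def test_zero_error_single_type_identical_clones(self):
        truth = synthetic.simulate_community(1, seed=0)
        seqs = {"T000": "ATG" + "ACG" * 30 + "TAA"}
        clones = synthetic.simulate_clone_library(
            truth, seqs, depth=10, seed=0, error_rate=0.0
        )
        per_sample = {c.sample_id for c in clones}
        assert len(clones) == 10 * 36
        assert len({c.sequence for c in clones}) == 1
        assert per_sample == set(truth.abundance.index)

    def test_count_contract_and_ids(self, community, type_sequences, type_model):
        clones = synthetic.simulate_clone_library(
            community, type_sequences, depth=5, seed=1, model=type_model
        )
        assert len(clones) == 5 * 36
        for c in clones:
            assert c.clone_id.startswith(c.sample_id)
            assert c.sample_id in community.abundance.index

    def test_multinomial_sampling_matches_binomial_oracle(self):
        """Observed type proportions fall within 3 SE of (0.9, 0.1)."""
        design = synthetic.full_design(animals=(8,), weeks=(2,), hours=(1,),
                                       fractions=("fiber",))
        truth = synthetic.CommunityTruth(
            types=["T000", "T001"],
            abundance=pd.DataFrame(
                [[0.9, 0.1]], index=design.index, columns=["T000", "T001"]
            ),
            design=design,
        )
        seqs = {"T000": "ATGAAA" * 20, "T001": "ATGCCC" * 20}
        clones = synthetic.simulate_clone_library(
            truth, seqs, depth=1000, seed=2, error_rate=0.0
        )
        p_hat = np.mean([c.true_type == "T000" for c in clones])
        se = np.sqrt(0.9 * 0.1 / 1000)
        assert abs(p_hat - 0.9) <= 3 * se

    def test_unknown_type_rejected(self, community):
        with pytest.raises(ConsistencyError):
            synthetic.simulate_clone_library(community, {"T000": "ATG"}, depth=1)


class TestPeakTables:
    def test_noise_free_sizes_and_heights(self, community, scac_trfs):
        noise = synthetic.NoiseModel(0.0, 0.0, 0.0, 100_000.0)
        tables = synthetic.simulate_peak_tables(
            community, scac_trfs["AluI"], "AluI", noise=noise, seed=0
        )
        assert len(tables) == 2 * 36  # two dye channels per sample
        predicted = {
            "NED": {p.forward_trf for p in scac_trfs["AluI"].values()},
            "6FAM": {p.reverse_trf for p in scac_trfs["AluI"].values()},
        }
        for t in tables:
            for size, height in t.peaks:
                assert size in {float(v) for v in predicted[t.dye]}
                assert height == int(height) and height >= 1
            # heights proportional to abundance up to integer rounding
            total = sum(h for _, h in t.peaks)
            assert abs(total - 100_000) < 2 * len(t.peaks)

    def test_zero_abundance_emits_no_peak(self, scac_trfs):
        design = synthetic.full_design(animals=(8,), weeks=(2,), hours=(1,),
                                       fractions=("fiber",))
        types = sorted(scac_trfs["AluI"])
        abund = pd.DataFrame(
            [[0.0] * len(types)], index=design.index, columns=types
        )
        abund.iloc[0, 0] = 1.0
        truth = synthetic.CommunityTruth(types=types, abundance=abund, design=design)
        noise = synthetic.NoiseModel(0.0, 0.0, 0.0, 10_000.0)
        tables = synthetic.simulate_peak_tables(
            truth, scac_trfs["AluI"], "AluI", noise=noise, seed=0
        )
        for t in tables:
            assert len(t.peaks) == 1

    def test_size_jitter_sd_montecarlo(self, scac_trfs):
        """Empirical sd of replicate size calls matches the generating sd."""
        design = synthetic.full_design()  # 36 samples as replicates
        types = sorted(scac_trfs["AluI"])
        abund = pd.DataFrame(
            np.tile(np.ones(len(types)) / len(types), (36, 1)),
            index=design.index, columns=types,
        )
        truth = synthetic.CommunityTruth(types=types, abundance=abund, design=design)
        noise = synthetic.NoiseModel(0.3, 0.0, 0.0, 50_000.0)
        deviations = []
        for seed in range(2):
            tables = synthetic.simulate_peak_tables(
                truth, scac_trfs["AluI"], "AluI", noise=noise, seed=seed
            )
            for t in tables:
                true_sizes = {
                    "NED": sorted(p.forward_trf for p in scac_trfs["AluI"].values()),
                    "6FAM": sorted(p.reverse_trf for p in scac_trfs["AluI"].values()),
                }[t.dye]
                for (size, _), true in zip(t.peaks, sorted(true_sizes)):
                    deviations.append(size - true)
        assert len(deviations) >= 1000
        assert 0.25 <= np.std(deviations) <= 0.35

    def test_missing_enzyme_predictions_rejected(self, community, scac_trfs):
        partial = dict(list(scac_trfs["AluI"].items())[:3])
        with pytest.raises(ConsistencyError):
            synthetic.simulate_peak_tables(community, partial, "AluI")


class TestReferenceLibrary:
    def test_records_carry_primer_sites(self):
        records = synthetic.simulate_reference_library(5, seed=0)
        fwd, rev = digest.PRIMERS["16S"]
        assert len(records) == 5
        for rec in records:
            seq = str(rec.seq)
            assert digest.match_degenerate_primer(seq, fwd)[0] == 0
            rc = digest.Primer("rc", digest.reverse_complement(rev.sequence))
            assert digest.match_degenerate_primer(seq, rc)
            assert "p__" in rec.description

    def test_byte_identical_on_repeat(self, tmp_path):
        from Bio import SeqIO

        for name in ("a.fasta", "b.fasta"):
            SeqIO.write(
                synthetic.simulate_reference_library(8, seed=3),
                tmp_path / name, "fasta",
            )
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_digest_matches_substring_scan(self):
        records = synthetic.simulate_reference_library(5, seed=1)
        alu = digest.ENZYMES["AluI"]
        for rec in records:
            seq = str(rec.seq)
            expected = [i + 2 for i in range(len(seq)) if seq[i : i + 4] == "AGCT"]
            assert digest.cut_positions(seq, alu) == expected


class TestNoiseFreeRoundTrip:
    def test_pipeline_recovers_types_and_proportions(self, community,
                                                     type_sequences, type_model):
        """With all noise off, clustering the clone library at 70% recovers
        one bin per sampled type and the exact per-sample clone proportions."""
        from scatyper import clustering

        clones = synthetic.simulate_clone_library(
            community, type_sequences, depth=12, seed=9, error_rate=0.0
        )
        cs = clustering.greedy_cluster(to_records(clones), 70.0)
        sampled_types = {c.true_type for c in clones}
        assert cs.s_obs == len(sampled_types)
        truth_by_clone = {c.clone_id: c.true_type for c in clones}
        for b in cs.bins:
            assert len({truth_by_clone[m] for m in b.member_ids}) == 1
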
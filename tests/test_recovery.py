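from collections import Counter

import numpy as np
import pytest

from ribovar import (
    Amplicon,
    CommunitySpec,
    ReadSimSpec,
    RecoveryConfig,
    SwarmCluster,
    abundance_gate,
    dereplicate,
    detect_chimeras,
    edit_distance,
    length_filter,
    make_chimera,
    recover_copies,
    reference_filter,
    reverse_complement,
    simulate_community,
    simulate_hifi_reads,
    swarm_cluster,
    trim_primers,
)
from ribovar.recovery import consensus_polish, two_means_split
from ribovar.simulate import mutate_sequence, random_sequence

FWD = "ACGTACCGTT"
REV = "TTGCAACGGA"


def _config(**kw):
    base = dict(
        fwd_primer=FWD,
        rev_primer=REV,
        max_primer_mismatches=2,
        min_length=1,
        max_length=10_000,
    )
    base.update(kw)
    return RecoveryConfig(**base)


class TestTrimPrimers:
    def test_constructed_read_yields_insert(self):
        insert = "AAACCCGGGTTTAAA"
        read = FWD + insert + reverse_complement(REV)
        res = trim_primers(read, _config())
        assert res.ok and res.insert == insert

    def test_missing_reverse_primer_rejected(self):
        res = trim_primers(FWD + "AAACCCGGGTTT" + "GGGGGGGGGG", _config())
        assert not res.ok and res.reason == "no_rev"

    def test_missing_forward_primer_rejected(self):
        res = trim_primers("GGGGGGGGGG" + "AAACCC" + reverse_complement(REV), _config())
        assert not res.ok and res.reason == "no_fwd"

    def test_reverse_complemented_read_gives_same_insert(self):
        insert = "AAACCCGGGTTTAAA"
        read = FWD + insert + reverse_complement(REV)
        fwd_res = trim_primers(read, _config())
        rc_res = trim_primers(reverse_complement(read), _config())
        assert rc_res.ok and rc_res.insert == fwd_res.insert

    def test_mismatches_tolerated_up_to_limit(self):
        insert = "AAACCCGGGTTTAAA"
        fwd_mut = "TT" + FWD[2:]  # 2 mismatches
        read = fwd_mut + insert + reverse_complement(REV)
        assert trim_primers(read, _config()).ok
        fwd_bad = "TTT" + FWD[3:]  # 3 mismatches
        assert not trim_primers(fwd_bad + insert + reverse_complement(REV), _config()).ok

    def test_no_primers_configured_passthrough(self):
        res = trim_primers("ACGT", RecoveryConfig())
        assert res.ok and res.insert == "ACGT"


class TestLengthFilter:
    def test_window_and_n_rule(self):
        kept, rejected = length_filter(["ACGT", "ACGTACGT", "ACNT"], 4, 5)
        assert kept == ["ACGT"]
        assert sorted(r for _, r in rejected) == ["contains_N", "length"]

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            length_filter([], 10, 5)

    def test_simulated_amplicons_mostly_retained(self, small_truth):
        reads, _ = simulate_hifi_reads(
            small_truth,
            ReadSimSpec(depth=10, chimera_rate=0.0, contaminant_fraction=0.0, seed=31),
        )
        cfg = _config(
            fwd_primer=ReadSimSpec().fwd_primer, rev_primer=ReadSimSpec().rev_primer
        )
        trimmed = [trim_primers(r.residues, cfg).insert for r in reads]
        trimmed = [t for t in trimmed if t]
        kept, _ = length_filter(trimmed, 2500, 3800)
        assert len(kept) / len(trimmed) > 0.99


class TestDereplicate:
    def test_identical_reads_collapse(self):
        amps = dereplicate(["ACGT"] * 10)
        assert len(amps) == 1 and amps[0].abundance == 10

    def test_tie_broken_by_sequence(self):
        amps = dereplicate(["TTTT"] * 3 + ["AAAA"] * 3)
        assert [a.sequence for a in amps] == ["AAAA", "TTTT"]

    def test_matches_counting_oracle(self, rng):
        pool = [random_sequence(8, rng) for _ in range(5)]
        reads = [pool[i] for i in rng.integers(0, 5, size=200)]
        amps = dereplicate(reads)
        expected = Counter(reads)
        assert {a.sequence: a.abundance for a in amps} == dict(expected)
        assert sum(a.abundance for a in amps) == 200

    def test_empty_input(self):
        assert dereplicate([]) == []


class TestDetectChimeras:
    def _parents(self, rng, divergence=0.05, length=1200):
        a = random_sequence(length, rng)
        b, _ = mutate_sequence(a, divergence, 0.0, rng)
        return a, b

    def test_no_eligible_parents_all_clean(self):
        amps = [Amplicon("a1", "ACGTACGTAC", 5), Amplicon("a2", "TGCATGCATG", 5)]
        verdicts = detect_chimeras(amps)
        assert not any(v.chimeric for v in verdicts.values())

    def test_fifty_fifty_chimera_found_with_parents(self, rng):
        a, b = self._parents(rng)
        chim = make_chimera(a, b, len(a) // 2)
        amps = dereplicate([a] * 10 + [b] * 10 + [chim] * 2)
        verdicts = detect_chimeras(amps, skew=2.0)
        by_seq = {amp.sequence: verdicts[amp.id] for amp in amps}
        assert by_seq[chim].chimeric
        assert not by_seq[a].chimeric and not by_seq[b].chimeric
        parent_seqs = {
            next(x.sequence for x in amps if x.id == pid)
            for pid in by_seq[chim].parents
        }
        assert parent_seqs == {a, b}

    def test_candidate_identical_to_parent_clean(self, rng):
        a, b = self._parents(rng)
        amps = dereplicate([a] * 10 + [b] * 10 + [a] * 1)  # derep merges; craft manually
        amps = [
            Amplicon("p1", a, 10),
            Amplicon("p2", b, 10),
            Amplicon("c", a, 1),
        ]
        verdicts = detect_chimeras(amps)
        assert not verdicts["c"].chimeric

    def test_low_abundance_parents_not_eligible(self, rng):
        a, b = self._parents(rng)
        chim = make_chimera(a, b, len(a) // 2)
        amps = [Amplicon("p1", a, 2), Amplicon("p2", b, 2), Amplicon("c", chim, 2)]
        verdicts = detect_chimeras(amps, skew=2.0)
        assert not verdicts["c"].chimeric


class TestSwarmCluster:
    def test_distant_amplicons_stay_apart(self):
        amps = [
            Amplicon("a", "AAAAAAAAAA", 5),
            Amplicon("b", "TTTTTTTTTT", 4),
            Amplicon("c", "CCCCCCCCCC", 3),
        ]
        clusters = swarm_cluster(amps, d=1)
        assert len(clusters) == 3

    def test_chain_links_through_intermediates(self):
        # A-B and B-C are 1 edit apart, A-C two: d=1 still joins all three
        a, b, c = "AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT"
        amps = [Amplicon("a", a, 5), Amplicon("b", b, 3), Amplicon("c", c, 2)]
        assert edit_distance(a, c) == 2
        clusters = swarm_cluster(amps, d=1)
        assert len(clusters) == 1
        assert clusters[0].seed.id == "a"

    def test_d_zero_keeps_amplicons_separate(self):
        amps = [Amplicon("a", "AAAA", 2), Amplicon("b", "AAAT", 1)]
        assert len(swarm_cluster(amps, 0)) == 2

    def test_matches_connected_components_oracle(self, rng):
        from scipy.sparse.csgraph import connected_components

        for _ in range(10):
            n = int(rng.integers(5, 25))
            seqs = list({random_sequence(12, rng) for _ in range(n)})
            amps = dereplicate(
                [s for s in seqs for _ in range(int(rng.integers(1, 4)))]
            )
            d = int(rng.integers(1, 4))
            adj = np.zeros((len(amps), len(amps)), dtype=int)
            for i in range(len(amps)):
                for j in range(len(amps)):
                    adj[i, j] = int(
                        edit_distance(amps[i].sequence, amps[j].sequence) <= d
                    )
            _, comp = connected_components(adj, directed=False)
            expected = {}
            for amp, c in zip(amps, comp):
                expected.setdefault(c, set()).add(amp.id)
            got = {frozenset(m.id for m in cl.members) for cl in swarm_cluster(amps, d)}
            assert got == {frozenset(v) for v in expected.values()}

    def test_invariant_to_read_order(self, rng):
        pool = [random_sequence(15, rng) for _ in range(6)]
        reads = [pool[i] for i in rng.integers(0, 6, size=60)]
        c1 = swarm_cluster(dereplicate(reads), 2)
        c2 = swarm_cluster(dereplicate(reads[::-1]), 2)
        as_sets = lambda cs: {frozenset(m.sequence for m in c.members) for c in cs}
        assert as_sets(c1) == as_sets(c2)


class TestReferenceFilter:
    def test_identical_seed_retained(self):
        cl = SwarmCluster(seed=Amplicon("a", "ACGTACGTAC", 3), members=[Amplicon("a", "ACGTACGTAC", 3)])
        kept, removed = reference_filter([cl], ["ACGTACGTAC"], 0.8)
        assert kept and not removed

    def test_divergent_contaminant_removed(self, rng):
        panel = [random_sequence(500, rng)]
        alien = random_sequence(500, rng)
        cl = SwarmCluster(seed=Amplicon("x", alien, 3), members=[Amplicon("x", alien, 3)])
        kept, removed = reference_filter([cl], panel, 0.8)
        assert removed and not kept

    def test_threshold_zero_retains_all(self, rng):
        alien = random_sequence(100, rng)
        cl = SwarmCluster(seed=Amplicon("x", alien, 1), members=[Amplicon("x", alien, 1)])
        kept, _ = reference_filter([cl], ["ACGT" * 25], 0.0)
        assert kept

    def test_empty_panel_rejected(self):
        cl = SwarmCluster(seed=Amplicon("a", "ACGT", 1), members=[Amplicon("a", "ACGT", 1)])
        with pytest.raises(ValueError):
            reference_filter([cl], [], 0.8)


def _cluster(abundance, seq="ACGTACGT", name="c"):
    amp = Amplicon(name, seq, abundance)
    return SwarmCluster(seed=amp, members=[amp])


class TestAbundanceGate:
    def test_clear_bimodal_split(self):
        clusters = [
            _cluster(a, name=f"c{i}")
            for i, a in enumerate([1000, 900, 800, 5, 3, 2])
        ]
        kept, removed = abundance_gate(clusters, mode="two_means")
        assert sorted(c.total_abundance for c in kept) == [800, 900, 1000]
        # exhaustive 1-D 2-partition oracle: minimise within-group variance
        values = np.log10([1000, 900, 800, 5, 3, 2])
        best_cut, best_ss = None, np.inf
        order = np.sort(values)
        for cut in range(1, len(order)):
            lo, hi = order[:cut], order[cut:]
            ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if ss < best_ss:
                best_cut, best_ss = cut, ss
        assert len(kept) == len(values) - best_cut

    def test_single_cluster_retained(self):
        kept, removed = abundance_gate([_cluster(7)], mode="two_means")
        assert len(kept) == 1 and not removed

    def test_equal_abundances_all_retained(self):
        clusters = [_cluster(5, name=f"c{i}") for i in range(4)]
        kept, removed = abundance_gate(clusters, mode="two_means")
        assert len(kept) == 4 and not removed

    def test_fixed_min_mode(self):
        clusters = [_cluster(a, name=f"c{i}") for i, a in enumerate([10, 2, 1])]
        kept, _ = abundance_gate(clusters, mode="fixed_min", fixed_min=2)
        assert sorted(c.total_abundance for c in kept) == [2, 10]

    def test_two_means_split_keeps_extremes_apart(self, rng):
        x = np.concatenate([rng.normal(0.3, 0.1, 5), rng.normal(1.6, 0.1, 5)])
        mask = two_means_split(x)
        assert mask.sum() == 5
        assert set(np.nonzero(mask)[0]) == set(range(5, 10))


class TestConsensusPolish:
    def test_majority_vote_recovers_truth(self, rng):
        truth = random_sequence(800, rng)
        reads = [mutate_sequence(truth, 0.002, 0.0005, rng)[0] for _ in range(25)]
        amps = dereplicate(reads)
        clusters = swarm_cluster(amps, 16)
        assert len(clusters) == 1
        assert consensus_polish(clusters[0]) == truth

    def test_singleton_cluster_returns_seed(self):
        amp = Amplicon("a", "ACGTACGT", 3)
        assert consensus_polish(SwarmCluster(seed=amp, members=[amp])) == "ACGTACGT"


class TestRecoverCopies:
    def _sim(self, seed, **read_kw):
        truth = simulate_community(
            CommunitySpec(n_species=1, strains_per_species=1, seed=seed)
        )
        spec = ReadSimSpec(seed=seed + 1000, **read_kw)
        reads, origins = simulate_hifi_reads(truth, spec)
        cfg = RecoveryConfig(
            fwd_primer=spec.fwd_primer or "",
            rev_primer=spec.rev_primer or "",
            min_length=2500,
            max_length=3800,
            reference_panel=[truth.strains[0].copies[0].sequence],
        )
        return truth, reads, cfg

    def test_error_free_run_recovers_exact_copies(self):
        truth, reads, cfg = self._sim(
            41,
            depth=20,
            substitution_error=0.0,
            indel_error=0.0,
            chimera_rate=0.0,
            contaminant_fraction=0.0,
        )
        res = recover_copies(reads, cfg)
        expected = set(truth.strains[0].distinct_copy_sequences())
        assert {c.residues for c in res.copies} == expected

    def test_identical_copies_are_indistinguishable(self):
        # two identical copies collapse: the pipeline reports one fewer
        truth = simulate_community(
            CommunitySpec(
                n_species=1,
                strains_per_species=1,
                copies_per_strain=(8, 8),
                per_locus_copy_divergence={
                    "SSU": 0.0, "ITS1": 0.0, "5.8S": 0.0, "ITS2": 0.0, "LSU": 0.0,
                },
                indel_prob=0.0,
                seed=42,
            )
        )
        spec = ReadSimSpec(
            depth=20,
            substitution_error=0.0,
            indel_error=0.0,
            chimera_rate=0.0,
            contaminant_fraction=0.0,
            seed=43,
        )
        reads, _ = simulate_hifi_reads(truth, spec)
        cfg = RecoveryConfig(
            fwd_primer=spec.fwd_primer,
            rev_primer=spec.rev_primer,
            min_length=2500,
            max_length=3800,
        )
        res = recover_copies(reads, cfg)
        assert len(truth.strains[0].copies) == 8
        assert len(res.copies) == len(truth.strains[0].distinct_copy_sequences()) == 1

    def test_default_error_run_close_to_truth(self):
        truth, reads, cfg = self._sim(44, depth=30)
        res = recover_copies(reads, cfg)
        distinct = truth.strains[0].distinct_copy_sequences()
        assert abs(len(res.copies) - len(distinct)) <= 1
        for copy in res.copies:
            assert min(edit_distance(copy.residues, t) for t in distinct) <= 1

    def test_stage_conservation(self):
        _, reads, cfg = self._sim(45, depth=15)
        res = recover_copies(reads, cfg)
        report = res.report.set_index("stage")
        for stage in report.index:
            row = report.loc[stage]
            assert row["n_in"] == row["n_retained"] + row["n_rejected"]
        assert report.loc["trim_primers", "n_in"] == len(reads)

    def test_empty_input_names_failing_stage(self):
        res = recover_copies([], RecoveryConfig(fwd_primer=FWD, rev_primer=REV))
        assert res.failing_stage == "trim_primers"
        assert res.copies == []
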
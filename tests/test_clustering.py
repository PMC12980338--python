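import numpy as np
import pytest

import promtok as pt
from promtok.clustering import write_clstr


def _random_seq(rng, length=601):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pt.pairwise_identity("ACGT" * 10, "ACGT" * 10) == 1.0

    def test_fully_different(self):
        assert pt.pairwise_identity("AAAA", "CCCC") == 0.0

    def test_601nt_pair_with_120_mismatches(self):
        rng = np.random.default_rng(0)
        a = list(_random_seq(rng))
        b = list(a)
        pos = rng.choice(601, size=120, replace=False)
        for p in pos:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        ident = pt.pairwise_identity("".join(a), "".join(b))
        assert ident == pytest.approx(481 / 601)

    def test_n_matches_nothing(self):
        assert pt.pairwise_identity("NNNN", "NNNN") == 0.0

    def test_case_insensitive(self):
        assert pt.pairwise_identity("acgt", "ACGT") == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pt.pairwise_identity("ACG", "ACGT")


class TestGreedyCluster:
    def test_all_identical_form_one_cluster(self):
        seqs = {f"s{i}": "ACGT" * 150 for i in range(5)}
        clusters = pt.greedy_cluster(seqs)
        assert len(clusters) == 1
        assert clusters[0].size == 5

    def test_all_dissimilar_stay_singletons(self):
        rng = np.random.default_rng(1)
        seqs = {f"s{i}": _random_seq(rng) for i in range(10)}
        clusters = pt.greedy_cluster(seqs)
        assert all(c.size == 1 for c in clusters)
        assert len(clusters) == 10

    def test_recovers_planted_families(self):
        rng = np.random.default_rng(2)
        base = [
            pt.PromoterWindow(
                id=f"w{i:02d}", organism="reference",
                sequence=_random_seq(rng), label="positive", source="epd_like",
            )
            for i in range(12)
        ]
        wins, families = pt.inject_redundancy(base, 4, 3, 0.9, seed=3)
        clusters = pt.greedy_cluster({w.id: w.sequence for w in wins})
        member_map = {m: c.id for c in clusters for m in c.member_ids}
        for fam in families.values():
            assert len({member_map[m] for m in fam}) == 1

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(4)
        seqs = {f"s{i}": _random_seq(rng) for i in range(30)}
        a = pt.greedy_cluster(seqs)
        b = pt.greedy_cluster(seqs)
        assert [(c.representative_id, c.member_ids) for c in a] == [
            (c.representative_id, c.member_ids) for c in b
        ]


class TestClstrIO:
    CLSTR = (
        ">Cluster 0\n"
        "0\t601nt, >alpha... *\n"
        "1\t601nt, >beta... at 91.18%\n"
        ">Cluster 1\n"
        "0\t601nt, >gamma... *\n"
    )

    def test_round_trip_of_hand_built_fixture(self, tmp_path):
        path = tmp_path / "toy.clstr"
        path.write_text(self.CLSTR)
        clusters = pt.read_clstr(path)
        assert len(clusters) == 2
        assert clusters[0].representative_id == "alpha"
        assert clusters[0].member_ids == ["alpha", "beta"]
        assert clusters[1].member_ids == ["gamma"]

    def test_writer_output_parses_back(self, tmp_path):
        clusters = [
            pt.Cluster(0, "a", ["a", "b", "c"]),
            pt.Cluster(1, "d", ["d"]),
        ]
        write_clstr(clusters, tmp_path / "w.clstr")
        back = pt.read_clstr(tmp_path / "w.clstr")
        assert [(c.representative_id, c.member_ids) for c in back] == [
            ("a", ["a", "b", "c"]),
            ("d", ["d"]),
        ]

    def test_empty_file_yields_empty_list(self, tmp_path):
        path = tmp_path / "empty.clstr"
        path.write_text("")
        assert pt.read_clstr(path) == []

    def test_cluster_without_representative_rejected(self, tmp_path):
        path = tmp_path / "norep.clstr"
        path.write_text(">Cluster 0\n0\t601nt, >alpha... at 90.00%\n")
        with pytest.raises(ValueError, match="representative"):
            pt.read_clstr(path)

    def test_member_before_header_rejected(self, tmp_path):
        path = tmp_path / "orphan.clstr"
        path.write_text("0\t601nt, >alpha... *\n")
        with pytest.raises(ValueError, match="header"):
            pt.read_clstr(path)


class TestAccumulateSplit:
    def _clusters(self, sizes):
        out = []
        for i, s in enumerate(sizes):
            ids = [f"c{i}_{j}" for j in range(s)]
            out.append(pt.Cluster(i, ids[0], ids))
        return out

    def test_hand_traced_worked_example(self):
        # sizes [1,1,2,2,4,10], 20 records, targets: test 4, val 3
        # ascending fill: test gets 1+1+2=4; val gets 2 then 4 (overshoot
        # allowed, stop at >= 3); train gets the 10
        clusters = self._clusters([1, 1, 2, 2, 4, 10])
        asg = pt.accumulate_split(clusters, (0.65, 0.15, 0.20))
        counts = {p: 0 for p in ("train", "validation", "test")}
        for part in asg.partition.values():
            counts[part] += 1
        assert counts == {"test": 4, "validation": 6, "train": 10}

    def test_single_giant_cluster_goes_to_test_with_warning(self, caplog):
        clusters = self._clusters([50])
        with caplog.at_level("WARNING"):
            asg = pt.accumulate_split(clusters)
        assert set(asg.partition.values()) == {"test"}
        assert "degenerate" in caplog.text

    def test_no_cluster_spans_partitions(self):
        rng = np.random.default_rng(5)
        clusters = self._clusters(rng.integers(1, 9, size=40))
        asg = pt.accumulate_split(clusters)
        for c in clusters:
            assert len({asg.partition[m] for m in c.member_ids}) == 1

    def test_achieved_fractions_sum_to_one(self):
        clusters = self._clusters([1, 2, 3, 4, 5, 6])
        asg = pt.accumulate_split(clusters)
        assert sum(asg.achieved_fractions.values()) == pytest.approx(1.0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            pt.accumulate_split(self._clusters([1]), (0.5, 0.2, 0.2))


class TestPropagatePairs:
    def _paired(self, n=6):
        rng = np.random.default_rng(6)
        pos, neg = [], []
        for i in range(n):
            p = pt.PromoterWindow(
                id=f"p{i}", organism="reference", sequence=_random_seq(rng),
                label="positive", source="epd_like",
            )
            pos.append(p)
            neg.append(
                pt.PromoterWindow(
                    id=f"p{i}_neg", organism="reference",
                    sequence=_random_seq(rng), label="negative",
                    source="fragment_negative", paired_positive_id=p.id,
                )
            )
        return pos, neg

    def test_negatives_follow_their_positive(self):
        pos, neg = self._paired()
        clusters = [pt.Cluster(i, p.id, [p.id]) for i, p in enumerate(pos)]
        asg = pt.accumulate_split(clusters)
        full = pt.propagate_pairs(asg, pos + neg)
        for n in neg:
            assert full.partition[n.id] == full.partition[n.paired_positive_id]

    def test_class_balance_preserved_per_partition(self):
        pos, neg = self._paired(10)
        clusters = [pt.Cluster(i, p.id, [p.id]) for i, p in enumerate(pos)]
        full = pt.propagate_pairs(pt.accumulate_split(clusters), pos + neg)
        for part in ("train", "validation", "test"):
            ids = full.ids(part)
            n_pos = sum(1 for i in ids if not i.endswith("_neg"))
            assert n_pos * 2 == len(ids)

    def test_orphan_negative_rejected(self):
        pos, neg = self._paired(3)
        neg[0].paired_positive_id = "missing"
        clusters = [pt.Cluster(i, p.id, [p.id]) for i, p in enumerate(pos)]
        asg = pt.accumulate_split(clusters)
        with pytest.raises(KeyError, match="missing"):
            pt.propagate_pairs(asg, pos + neg)


class TestFilterExternal:
    def _win(self, wid, seq):
        return pt.PromoterWindow(
            id=wid, organism="dog_like", sequence=seq,
            label="positive", source="epd_like",
        )

    def test_n_containing_sequences_dropped(self):
        rng = np.random.default_rng(7)
        seq = _random_seq(rng)
        ext = [self._win("e0", "N" + seq[1:]), self._win("e1", _random_seq(rng))]
        kept = pt.filter_external(ext, [])
        assert [w.id for w in kept] == ["e1"]

    def test_training_duplicate_dropped_dissimilar_kept(self):
        rng = np.random.default_rng(8)
        train_seq = _random_seq(rng)
        train = [
            pt.PromoterWindow(
                id="t0", organism="reference", sequence=train_seq,
                label="positive", source="epd_like",
            )
        ]
        ext = [
            self._win("e_dup", train_seq),
            self._win("e_far", _random_seq(rng)),
        ]
        kept = pt.filter_external(ext, train)
        assert [w.id for w in kept] == ["e_far"]

    def test_external_only_cluster_survives_even_if_multi_member(self):
        rng = np.random.default_rng(9)
        seq = _random_seq(rng)
        ext = [self._win("e0", seq), self._win("e1", seq)]
        kept = pt.filter_external(ext, [])
        assert {w.id for w in kept} == {"e0", "e1"}
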
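"""Paralog profiling, greedy dereplication, majority-rules assignment."""

import itertools

import pytest
from Bio import Align

from sagpipe.io import Hit, HitTable
from sagpipe.paralogs import (
    LineageCluster,
    UNASSIGNED,
    dereplicate,
    majority_rules_assign,
    pairwise_identity,
    paralog_fraction,
    recruit_by_models,
)
from sagpipe.synthetic import generate_paralog_families


def reference_identity(a, b):
    """Independent identity oracle: raw Biopython alignment, same scoring."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    return aln.counts().identities / aln.length


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDEFGHIK", "ACDEFGHIK") == 1.0

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAA", "GGGG") == 0.0

    def test_hand_alignment(self):
        assert pairwise_identity("ACDEFG", "ACDEYG") == pytest.approx(5 / 6)

    def test_symmetric(self):
        a, b = "MKTAYIAKQR", "MKTEYIAKQ"
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_identity("", "ACDE")


class TestParalogFraction:
    def test_two_identical_genes(self):
        profile = paralog_fraction({"a": "MKTAYIAK", "b": "MKTAYIAK"}, [0.5, 0.9, 1.0])
        assert profile.fraction_with_paralog == [1.0, 1.0, 1.0]

    def test_unique_random_proteome_near_zero_at_high_threshold(self):
        fams = generate_paralog_families(6, 1, 1.0, length=120, seed=3)
        proteome = dict(zip(fams["seq_id"], fams["sequence"]))
        profile = paralog_fraction(proteome, [0.9])
        assert profile.fraction_with_paralog[0] == 0.0

    def test_matches_bruteforce_all_vs_all(self):
        fams = generate_paralog_families(3, 2, 0.9, length=80, seed=5)
        proteome = dict(zip(fams["seq_id"], fams["sequence"]))
        thresholds = [0.5, 0.7, 0.85, 0.95]
        profile = paralog_fraction(proteome, thresholds)
        # oracle: exhaustive pair loop with the reference aligner
        best = {g: 0.0 for g in proteome}
        for a, b in itertools.combinations(sorted(proteome), 2):
            ident = reference_identity(proteome[a], proteome[b])
            best[a] = max(best[a], ident)
            best[b] = max(best[b], ident)
        for t, fraction in zip(thresholds, profile.fraction_with_paralog):
            assert fraction == sum(1 for v in best.values() if v >= t) / len(best)

    def test_monotone_non_increasing(self):
        fams = generate_paralog_families(4, 3, 0.9, length=80, seed=6)
        proteome = dict(zip(fams["seq_id"], fams["sequence"]))
        profile = paralog_fraction(proteome, [0.2, 0.4, 0.6, 0.8, 0.95])
        fr = profile.fraction_with_paralog
        assert all(y <= x for x, y in zip(fr, fr[1:]))

    def test_single_gene_warns(self):
        with pytest.warns(UserWarning, match="< 2"):
            profile = paralog_fraction({"only": "MKTAYI"}, [0.5])
        assert profile.fraction_with_paralog == [0.0]

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            paralog_fraction({"a": "MKT", "b": "MKT"}, [0.9, 0.5])


def greedy_oracle(sequences, threshold):
    """Brute-force reimplementation of the greedy centroid pass."""
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    clusters = []  # list of (centroid_id, [members])
    for sid in order:
        for entry in clusters:
            if reference_identity(sequences[entry[0]], sequences[sid]) >= threshold:
                entry[1].append(sid)
                break
        else:
            clusters.append((sid, [sid]))
    return [(cid, tuple(members)) for cid, members in clusters]


class TestDereplicate:
    def test_identical_sequences_single_cluster(self):
        seqs = {f"s{i}": "MKTAYIAKQRQISFVK" for i in range(5)}
        clusters = dereplicate(seqs, 0.9)
        assert len(clusters) == 1
        assert clusters[0].consensus == "MKTAYIAKQRQISFVK"
        assert sorted(clusters[0].member_ids) == sorted(seqs)

    def test_threshold_one_on_distinct_sequences(self):
        fams = generate_paralog_families(4, 1, 1.0, length=60, seed=9)
        seqs = dict(zip(fams["seq_id"], fams["sequence"]))
        clusters = dereplicate(seqs, 1.0)
        assert len(clusters) == 4

    def test_matches_greedy_oracle(self):
        fams = generate_paralog_families(4, 3, 0.85, length=60, seed=13)
        seqs = dict(zip(fams["seq_id"], fams["sequence"]))
        assert len(seqs) <= 20
        clusters = dereplicate(seqs, 0.8)
        oracle = greedy_oracle(seqs, 0.8)
        assert [(c.centroid_id, tuple(c.member_ids)) for c in clusters] == oracle

    def test_partition_property(self):
        fams = generate_paralog_families(3, 4, 0.9, length=60, seed=17)
        seqs = dict(zip(fams["seq_id"], fams["sequence"]))
        clusters = dereplicate(seqs, 0.8)
        seen = [m for c in clusters for m in c.member_ids]
        assert sorted(seen) == sorted(seqs)  # every sequence in exactly one cluster
        assert 1 <= len(clusters) <= len(seqs)

    def test_lower_threshold_never_more_clusters(self):
        fams = generate_paralog_families(4, 3, 0.9, length=60, seed=19)
        seqs = dict(zip(fams["seq_id"], fams["sequence"]))
        sizes = [len(dereplicate(seqs, t)) for t in (0.95, 0.8, 0.5, 0.2)]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_consensus_majority_overrides_centroid(self):
        # centroid has a minority residue at one site: consensus takes the majority
        seqs = {
            "a": "MKTAYIAKQR",  # centroid (first in canonical order by id)
            "b": "MKTCYIAKQR",
            "c": "MKTCYIAKQR",
        }
        clusters = dereplicate(seqs, 0.8)
        assert len(clusters) == 1
        assert clusters[0].centroid_id == "a"
        assert clusters[0].consensus == "MKTCYIAKQR"

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            dereplicate({"a": "MKT"}, 0.0)


class TestMajorityRules:
    def make_cluster(self, members):
        return LineageCluster("lin0", members[0], list(members), consensus="")

    def test_majority(self):
        cluster = self.make_cluster(["A", "B", "C"])
        fam = majority_rules_assign(cluster, {"A": "fam1", "B": "fam1", "C": "fam2"})
        assert fam == "fam1"
        assert not cluster.tie

    def test_tie_breaks_lexicographically_and_flags(self):
        cluster = self.make_cluster(["A", "B"])
        fam = majority_rules_assign(cluster, {"A": "fam2", "B": "fam1"})
        assert fam == "fam1"
        assert cluster.tie

    def test_hand_tally_three_families(self):
        members = [f"m{i}" for i in range(10)]
        hits = {m: ("famX" if i < 5 else "famY" if i < 8 else "famZ") for i, m in enumerate(members)}
        cluster = self.make_cluster(members)
        assert majority_rules_assign(cluster, hits) == "famX"
        assert cluster.family_votes == {"famX": 5, "famY": 3, "famZ": 2}

    def test_all_unlabeled(self):
        cluster = self.make_cluster(["A", "B"])
        assert majority_rules_assign(cluster, {}) == UNASSIGNED

    def test_vote_partition_identity(self):
        # lineages assigned to one family plus lineages assigned elsewhere
        # always reconstitute the full lineage count
        fams = generate_paralog_families(5, 3, 0.95, length=60, seed=23)
        seqs = dict(zip(fams["seq_id"], fams["sequence"]))
        truth = dict(zip(fams["seq_id"], fams["family_id"]))
        clusters = dereplicate(seqs, 0.8)
        for c in clusters:
            majority_rules_assign(c, truth)
        focal = sum(1 for c in clusters if c.assigned_family == "fam000")
        others = sum(1 for c in clusters if c.assigned_family != "fam000")
        assert focal + others == len(clusters)


class TestRecruitByModels:
    def tables(self):
        return {
            "modelX": HitTable(
                [
                    Hit("s1", "modelX", 0, 0, 200, 1e-40),
                    Hit("s2", "modelX", 0, 0, 150, 1e-30),
                    Hit("s4", "modelX", 0, 0, 90, 1e-3),  # fails cutoff
                ]
            ),
            "modelY": HitTable(
                [
                    Hit("s1", "modelY", 0, 0, 150, 1e-35),
                    Hit("s3", "modelY", 0, 0, 120, 1e-20),
                ]
            ),
        }

    def test_unhit_sequence_not_recruited(self):
        assigned = recruit_by_models(self.tables())
        assert "s5" not in assigned
        assert "s4" not in assigned  # only hit fails the e-value cutoff

    def test_best_model_by_bitscore(self):
        assigned = recruit_by_models(self.tables())
        assert assigned["s1"] == "modelX"  # 200 beats 150
        assert assigned["s2"] == "modelX"
        assert assigned["s3"] == "modelY"

    def test_matches_exhaustive_filter(self):
        tables = self.tables()
        assigned = recruit_by_models(tables, evalue_cutoff=1e-5)
        oracle = {}
        for model, table in sorted(tables.items()):
            for h in table:
                if h.evalue <= 1e-5:
                    if h.query not in oracle or h.bitscore > oracle[h.query][0]:
                        oracle[h.query] = (h.bitscore, model)
        assert assigned == {q: m for q, (_s, m) in oracle.items()}

    def test_bitscore_tie_goes_to_smaller_model_id(self):
        tables = {
            "mB": HitTable([Hit("s1", "mB", 0, 0, 100, 1e-20)]),
            "mA": HitTable([Hit("s1", "mA", 0, 0, 100, 1e-20)]),
        }
        assert recruit_by_models(tables)["s1"] == "mA"


class TestPlantedTruthRecovery:
    def test_exact_partition_and_labels(self):
        fams = generate_paralog_families(6, [3, 4, 2, 5, 3, 4], 0.95, length=150, seed=29)
        seqs = dict(zip(fams["seq_id"], fams["sequence"]))
        truth = dict(zip(fams["seq_id"], fams["family_id"]))
        clusters = dereplicate(seqs, 0.8)
        recovered = sorted(tuple(sorted(c.member_ids)) for c in clusters)
        planted = sorted(
            tuple(sorted(grp["seq_id"])) for _, grp in fams.groupby("family_id")
        )
        assert recovered == planted
        for c in clusters:
            assert majority_rules_assign(c, truth) == truth[c.centroid_id]
            assert not c.tie
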
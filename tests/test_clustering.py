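import numpy as np
import pytest

from smdiv.clustering import (
    alignment_score,
    build_otu_table,
    greedy_cluster,
    pairwise_identity,
    pick_representatives,
    shared_with_reference,
)
from smdiv.seqprep import AmpliconRead

from _oracles import best_global


def read(rid, seq, size=1, sample="s1"):
    return AmpliconRead(id=rid, sequence=seq, size=size, sample_id=sample)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(100):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 30)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 30)))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_matches_exhaustive_alignment_enumeration(self, rng):
        """Score and identity agree with full enumeration of all affine-gap
        global alignments on short sequences."""
        for _ in range(25):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(3, 7)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(3, 7)))
            oracle_score, oracle_idents = best_global(a, b)
            assert alignment_score(a, b) == pytest.approx(oracle_score)
            ident = pairwise_identity(a, b)
            assert any(ident == pytest.approx(x) for x in oracle_idents), (a, b)

    def test_named_worked_example(self):
        score, idents = best_global("ACGT", "TGCA")
        assert alignment_score("ACGT", "TGCA") == pytest.approx(score)
        assert any(
            pairwise_identity("ACGT", "TGCA") == pytest.approx(x) for x in idents
        )


def diverged_pair(rng, length=100, target_identity=0.80):
    """A sequence pair with ungapped (hence alignment) identity ~target."""
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    n_mut = round((1 - target_identity) * length)
    pos = rng.choice(length, size=n_mut, replace=False)
    b = list(a)
    for p in pos:
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    return a, "".join(b)


class TestGreedyCluster:
    def test_duplicates_form_one_cluster(self):
        reads = [read(f"r{i}", "ACGT" * 25) for i in range(5)]
        assert len(greedy_cluster(reads, 0.97)) == 1

    def test_threshold_splits_pair_at_known_identity(self, rng):
        a, b = diverged_pair(rng, 100, 0.80)
        ident = pairwise_identity(a, b)
        assert 0.76 <= ident <= 0.84  # verified band around the planted 0.80
        reads = [read("a", a, size=2), read("b", b, size=1)]
        assert len(greedy_cluster(reads, 0.75)) == 1
        assert len(greedy_cluster(reads, 0.85)) == 2

    def test_cluster_count_monotone_in_threshold(self, clean_community):
        reads = [
            AmpliconRead(id=fid, sequence=seq) for fid, seq in clean_community.families
        ]
        counts = [
            len(greedy_cluster(reads, t)) for t in (0.97, 0.90, 0.85, 0.75)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_members_within_threshold_of_centroid(self, rng):
        reads = []
        for i in range(8):
            a, b = diverged_pair(rng, 80, 0.98)
            reads.append(read(f"a{i}", a, size=2))
            reads.append(read(f"b{i}", b, size=1))
        for cl in greedy_cluster(reads, 0.9):
            for m in cl.members:
                assert pairwise_identity(m.sequence, cl.centroid_seq) >= 0.9

    def test_recovers_planted_families_exactly(self, clean_community):
        """Error-free reads cluster back to the exact planted family count."""
        from smdiv.seqprep import dereplicate

        spec = clean_community.spec
        for sample_id, rlist in list(clean_community.reads.items())[:3]:
            uniques = dereplicate(rlist, min_size=1)
            clusters = greedy_cluster(uniques, spec.cluster_identity)
            truth = clean_community.truth
            true_n = truth[truth.read_id.str.startswith(sample_id)].family_id.nunique()
            assert len(clusters) == true_n


class TestOtuTable:
    def test_cell_sums_member_sizes(self):
        reads = [
            AmpliconRead(id="a", sequence="ACGT" * 25, size=3, sample_sizes={"s1": 3}),
            AmpliconRead(id="b", sequence="ACGT" * 25, size=2, sample_sizes={"s2": 2}),
        ]
        (cl,) = greedy_cluster(reads, 0.97)
        table = build_otu_table([cl], ["s1", "s2"])
        assert table.loc[cl.cluster_id].tolist() == [3, 2]

    def test_column_sums_conserve_read_mass(self, clean_community):
        from smdiv.seqprep import dereplicate

        all_reads = [r for rl in clean_community.reads.values() for r in rl]
        uniques = dereplicate(all_reads, min_size=1)
        clusters = greedy_cluster(uniques, 0.95)
        table = build_otu_table(clusters)
        per_sample_mass = {}
        for r in uniques:
            for s, n in r.sample_sizes.items():
                per_sample_mass[s] = per_sample_mass.get(s, 0) + n
        for s in table.columns:
            assert table[s].sum() == per_sample_mass[s]

    def test_empty_cluster_list_gives_empty_table(self):
        assert build_otu_table([]).empty


class TestRepresentatives:
    def test_one_record_per_cluster_with_roundtrip_headers(self, tmp_path, small_metadata):
        reads = [
            AmpliconRead(id=f"r{i}", sequence=seq * 25, size=1,
                         sample_sizes={"P1_eme_1": 1})
            for i, seq in enumerate(["ACGT", "GGCC", "TTAA"])
        ]
        clusters = greedy_cluster(reads, 0.97)
        reps = pick_representatives(clusters, small_metadata)
        assert len(reps) == 3
        from smdiv import io_formats

        p = tmp_path / "reps.fasta"
        io_formats.write_fasta(reps, p)
        assert io_formats.read_fasta(p) == reps

    def test_majority_site_tie_breaks_by_label_order(self, small_metadata):
        reads = [
            AmpliconRead(
                id="r0", sequence="ACGT" * 25, size=2,
                sample_sizes={"P2_eme_1": 1, "P1_eme_1": 1},
            )
        ]
        clusters = greedy_cluster(reads, 0.97)
        ((header, _),) = pick_representatives(clusters, small_metadata)
        assert "site=P1" in header


class TestSharedWithReference:
    def test_disjoint_sets_share_nothing(self, rng):
        qs = [(f"q{i}", "".join("ACGT"[x] for x in rng.integers(0, 4, 100))) for i in range(3)]
        rs = [(f"r{i}", "".join("TGCA"[x] for x in rng.integers(0, 4, 40)) + "A" * 60) for i in range(3)]
        df = shared_with_reference(qs, rs, [0.9])
        assert df.loc[0, "shared"] == 0

    def test_query_subset_of_reference(self):
        seqs = [(f"x{i}", s * 25) for i, s in enumerate(["ACGT", "GGCC"])]
        df = shared_with_reference(seqs, seqs, [0.97])
        assert df.loc[0, "query_only"] == 0
        assert df.loc[0, "shared"] == 2

    def test_counts_partition_total(self, clean_community, rng):
        fams = clean_community.families
        query = [(f, s) for f, s in fams[:6]]
        ref = [(f, s) for f, s in fams[4:10]]
        df = shared_with_reference(query, ref, [0.97, 0.85, 0.75])
        for _, row in df.iterrows():
            assert row["query_only"] + row["reference_only"] + row["shared"] == row["total"]

    def test_planted_shared_families_counted(self, clean_community):
        """Identical family sequences in both sets are exactly the shared clusters."""
        fams = dict(clean_community.families)
        ids = sorted(fams)
        query = [(f"Q_{f}", fams[f]) for f in ids[:5]]
        ref = [(f"R_{f}", fams[f]) for f in ids[3:8]]
        df = shared_with_reference(query, ref, [clean_community.spec.cluster_identity])
        assert df.loc[0, "shared"] == 2
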
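import numpy as np
import pytest

from paleosieve.classifier import (
    KmerDatabase,
    _canonical_kmers,
    build_alt_consensus,
    build_database,
    classify_file,
    classify_read,
)
from paleosieve.seqio import revcomp, write_fasta
from paleosieve.taxonomy import taxonomy_from_records

from oracles import canon, classify_by_path_enumeration, random_tree

TREE = taxonomy_from_records(
    [(1, 1, "root"), (2, 1, "genus"), (8, 2, "species"), (9, 2, "species")]
)


def fasta(tmp_path, name, seq):
    p = tmp_path / f"{name}.fasta"
    write_fasta(p, [(name, seq)])
    return p


class TestBuildDatabase:
    def test_enumerated_windows_single_genome(self, tmp_path):
        # "ACGTACGT" with k=4: windows ACGT,CGTA,GTAC,TACG,ACGT → ≤5 canonical keys
        db = build_database([(fasta(tmp_path, "g", "ACGTACGT"), 9)], TREE, k=4)
        expected = {canon("ACGTACGT"[i : i + 4]) for i in range(5)}
        assert set(db.entries) == expected
        assert set(db.entries.values()) == {9}

    def test_shared_sequence_lca_is_genus(self, tmp_path):
        seq = "ACGTACGTCCAGTTGACA"
        db = build_database(
            [(fasta(tmp_path, "a", seq), 8), (fasta(tmp_path, "b", seq), 9)], TREE, k=5
        )
        assert set(db.entries.values()) == {2}

    def test_ambiguous_bases_void_windows(self, tmp_path):
        db = build_database([(fasta(tmp_path, "g", "ACGTNACGT"), 9)], TREE, k=4)
        # windows touching the N contribute nothing: only ACGT remains (twice)
        assert set(db.entries) == {canon("ACGT")}

    def test_insertion_order_invariance(self, tmp_path):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(2)]
        shared = seqs[0][10:40]
        seqs[1] = seqs[1][:20] + shared + seqs[1][20:]
        a = fasta(tmp_path, "a", seqs[0])
        b = fasta(tmp_path, "b", seqs[1])
        db1 = build_database([(a, 8), (b, 9)], TREE, k=7)
        db2 = build_database([(b, 9), (a, 8)], TREE, k=7)
        assert db1.entries == db2.entries

    def test_unknown_taxon_rejected(self, tmp_path):
        with pytest.raises(KeyError):
            build_database([(fasta(tmp_path, "g", "ACGTACGT"), 77)], TREE, k=4)

    def test_save_load_round_trip(self, tmp_path):
        db = build_database([(fasta(tmp_path, "g", "ACGTACGTAC"), 9)], TREE, k=4)
        path = tmp_path / "db.tsv"
        db.save(path)
        back = KmerDatabase.load(path, TREE)
        assert back.k == db.k and back.entries == db.entries
        assert back.source_manifest == db.source_manifest


class TestClassifyRead:
    def test_verbatim_read_hits_source_leaf(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 500))
        db = build_database([(fasta(tmp_path, "g", seq), 9)], TREE, k=11)
        res = classify_read(db, seq[100:160])
        assert res.status == "C" and res.taxon_id == 9
        assert res.hit_kmers == res.total_kmers == 50

    def test_no_hits_is_unclassified(self, tmp_path):
        db = build_database([(fasta(tmp_path, "g", "A" * 50), 9)], TREE, k=11)
        res = classify_read(db, "C" * 40)
        assert res.status == "U" and res.taxon_id is None

    def test_short_read_unclassified_not_error(self, tmp_path):
        db = build_database([(fasta(tmp_path, "g", "ACGTACGTACGT"), 9)], TREE, k=11)
        res = classify_read(db, "ACGT")
        assert res.status == "U" and res.total_kmers == 0

    def test_reverse_complement_symmetry(self, tmp_path):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 300))
        db = build_database([(fasta(tmp_path, "g", seq), 9)], TREE, k=9)
        for start in range(0, 200, 37):
            read = seq[start : start + 45]
            fwd = classify_read(db, read)
            rev = classify_read(db, revcomp(read))
            assert (fwd.status, fwd.taxon_id) == (rev.status, rev.taxon_id)

    def test_confidence_walks_toward_root_or_unclassifies(self):
        # hand-built database: 2 k-mers of the read hit the leaf, 8 miss
        parents = {1: 1, 2: 1, 3: 2}
        tree = taxonomy_from_records([(t, p, "no rank") for t, p in parents.items()])
        read = "AACCGGTTACGCAT"  # 10 distinct windows at k=5
        kmers = _canonical_kmers(read, 5)
        db = KmerDatabase(k=5, entries={kmers[0]: 3, kmers[1]: 3}, taxonomy=tree)
        assert classify_read(db, read, confidence=0.0).taxon_id == 3
        assert classify_read(db, read, confidence=0.2).taxon_id == 3
        assert classify_read(db, read, confidence=0.5).status == "U"

    def test_matches_exhaustive_path_score_oracle(self):
        """Random small instances against root-to-leaf path enumeration."""
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        agree = 0
        for trial in range(400):
            n = int(rng.integers(2, 21))
            parents = random_tree(rng, n)
            tree = taxonomy_from_records([(t, p, "no rank") for t, p in parents.items()])
            read = "".join(rng.choice(bases, int(rng.integers(8, 101))))
            k = 5
            entries = {}
            # seed entries from the read's own windows so hits actually occur
            for i in range(0, len(read) - k + 1):
                if rng.random() < 0.35:
                    entries[canon(read[i : i + k])] = int(rng.integers(1, n + 1))
            db = KmerDatabase(k=k, entries=entries, taxonomy=tree)
            got = classify_read(db, read)
            expected = classify_by_path_enumeration(parents, entries, read, k)
            assert (got.taxon_id if got.status == "C" else None) == expected
            agree += 1
        assert agree == 400


class TestClassifyFile:
    def test_empty_fastq_gives_empty_table(self, tmp_path):
        db = build_database([(fasta(tmp_path, "g", "ACGTACGTACGT"), 9)], TREE, k=5)
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        out = tmp_path / "out.tsv"
        assert classify_file(db, fq, out=out) == []
        assert out.read_text() == ""

    def test_row_order_and_format(self, tmp_path):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 400))
        db = build_database([(fasta(tmp_path, "g", seq), 9)], TREE, k=9)
        fq = tmp_path / "reads.fastq"
        fq.write_text(
            f"@r1\n{seq[0:40]}\n+\n{'I'*40}\n"
            f"@r2\n{'A'*35}\n+\n{'I'*35}\n"
            f"@r3\n{seq[50:90]}\n+\n{'I'*40}\n"
        )
        out = tmp_path / "out.tsv"
        classify_file(db, fq, out=out)
        lines = out.read_text().splitlines()
        assert [ln.split("\t")[1] for ln in lines] == ["r1", "r2", "r3"]
        assert lines[0].startswith("C\tr1\t9\t40\t32/32")
        assert lines[1].startswith("U\tr2\t0\t35")

    def test_malformed_fastq_reports_record_index(self, tmp_path):
        db = build_database([(fasta(tmp_path, "g", "ACGTACGTACGT"), 9)], TREE, k=5)
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r1\nACGT\n+\nIIII\nnot_a_header\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="index 1"):
            classify_file(db, fq)


def write_vcf(path, records, contig="chr1", length=100):
    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={contig},length={length}>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    body = "".join(
        f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n" for pos, ref, alt in records
    )
    path.write_text(header + body)
    return path


class TestAltConsensus:
    def test_empty_vcf_is_identity(self, tmp_path):
        ref = fasta(tmp_path, "chr1", "ACGTACGTAC")
        vcf = write_vcf(tmp_path / "v.vcf", [], length=10)
        out = tmp_path / "out.fasta"
        counts = build_alt_consensus(ref, vcf, out)
        assert counts == {"applied": 0, "skipped": 0, "ref_mismatch": 0}
        from paleosieve.seqio import read_fasta

        (name, seq), = read_fasta(out)
        assert seq == "ACGTACGTAC" and name == "chr1_alt"

    def test_single_snp_substitution(self, tmp_path):
        ref = fasta(tmp_path, "chr1", "ACGTACGTAC")
        vcf = write_vcf(tmp_path / "v.vcf", [(5, "A", "G")], length=10)
        out = tmp_path / "out.fasta"
        counts = build_alt_consensus(ref, vcf, out)
        from paleosieve.seqio import read_fasta

        (_name, seq), = read_fasta(out)
        assert seq == "ACGTGCGTAC" and counts["applied"] == 1

    def test_ref_mismatch_and_non_snp_counted_not_fatal(self, tmp_path):
        ref = fasta(tmp_path, "chr1", "ACGTACGTAC")
        vcf = write_vcf(
            tmp_path / "v.vcf",
            [(1, "C", "T"), (2, "CG", "C"), (3, "G", "A")],
            length=10,
        )
        out = tmp_path / "out.fasta"
        counts = build_alt_consensus(ref, vcf, out)
        assert counts == {"applied": 1, "skipped": 1, "ref_mismatch": 1}

    def test_hamming_distance_equals_accepted_records(self, tmp_path):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        ref = fasta(tmp_path, "chr1", seq)
        positions = rng.choice(np.arange(1, 2001), size=100, replace=False)
        records = []
        for pos in sorted(positions):
            r = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != r])
            records.append((int(pos), r, alt))
        vcf = write_vcf(tmp_path / "v.vcf", records, length=2000)
        out = tmp_path / "out.fasta"
        counts = build_alt_consensus(ref, vcf, out)
        from paleosieve.seqio import read_fasta

        (_name, new_seq), = read_fasta(out)
        hamming = sum(a != b for a, b in zip(seq, new_seq))
        assert hamming == counts["applied"] == 100

    def test_same_taxon_augmentation_preserves_taxon_set(self, tmp_path):
        from paleosieve.classifier import add_genome

        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 500))
        ref = fasta(tmp_path, "chr1", seq)
        vcf = write_vcf(tmp_path / "v.vcf", [(50, seq[49], "ACGT"[("ACGT".index(seq[49]) + 1) % 4])], length=500)
        alt = tmp_path / "alt.fasta"
        build_alt_consensus(ref, vcf, alt)
        db = build_database([(ref, 9)], TREE, k=11)
        n_before = len(db)
        add_genome(db, alt, 9)
        assert db.taxa() == {9}
        assert len(db) >= n_before
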
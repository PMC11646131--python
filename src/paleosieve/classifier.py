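"""Exact canonical k-mer → LCA database and read classification.

The database maps every canonical k-mer observed in a set of taxon-labelled
genomes to the lowest common ancestor of all taxa whose genomes contain it.
A read is classified by looking up each of its k-mer windows and scoring
every hit-bearing taxon by the total number of hits on its root-to-taxon
path; the deepest maximal-score taxon wins, with ties across incomparable
taxa resolved to their LCA. This is the classic k-mer/LCA scheme of
Kraken-style classifiers, with an exact hash in place of a probabilistic
compact one: identical inputs always classify identically, and a read drawn
verbatim from a database genome can never be unclassified.

Two k values matter in practice: 35 (specific, but blind to fragments
shorter than 35 bp) and 29 (classifies shorter, damaged fragments at the
cost of specificity) — the trade-off that drives the choice between
negative and positive filtering databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .seqio import canonical, read_fasta, read_fastq
from .taxonomy import TaxonomyTree, UnknownTaxonError, lca, lca_of_set

_VALID = frozenset("ACGT")


@dataclass
class KmerDatabase:
    k: int
    entries: dict[str, int]
    taxonomy: TaxonomyTree
    source_manifest: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def taxa(self) -> set[int]:
        return set(self.entries.values())

    # -- serialization: sorted text dump, round-trip tested -----------------

    FORMAT_VERSION = 1

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#paleosieve-kmerdb\tv{self.FORMAT_VERSION}\tk={self.k}\n")
            for genome, taxid in self.source_manifest:
                fh.write(f"#source\t{genome}\t{taxid}\n")
            for kmer in sorted(self.entries):
                fh.write(f"{kmer}\t{self.entries[kmer]}\n")

    @classmethod
    def load(cls, path: str | Path, taxonomy: TaxonomyTree) -> "KmerDatabase":
        entries: dict[str, int] = {}
        manifest: list[tuple[str, int]] = []
        k = None
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#paleosieve-kmerdb"):
                raise ValueError(f"{path}: not a paleosieve k-mer database")
            k = int(header.rstrip().rsplit("k=", 1)[1])
            for line in fh:
                if line.startswith("#source"):
                    _, genome, taxid = line.rstrip("\n").split("\t")
                    manifest.append((genome, int(taxid)))
                    continue
                kmer, taxid = line.split()
                entries[kmer] = int(taxid)
        return cls(k=k, entries=entries, taxonomy=taxonomy, source_manifest=manifest)


@dataclass
class ClassificationResult:
    read_id: str
    status: str  # "C" or "U"
    taxon_id: int | None
    hit_counts: dict[int, int]
    total_kmers: int
    hit_kmers: int


def _canonical_kmers(seq: str, k: int) -> list[str | None]:
    """Canonical k-mer per window, None where the window holds an ambiguous base."""
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return []
    out: list[str | None] = []
    # track the rightmost invalid base to void windows cheaply
    last_bad = -1
    for i, ch in enumerate(seq[: k - 1]):
        if ch not in _VALID:
            last_bad = i
    for start in range(0, n - k + 1):
        end = start + k
        ch = seq[end - 1]
        if ch not in _VALID:
            last_bad = end - 1
        if last_bad >= start:
            out.append(None)
        else:
            out.append(canonical(seq[start:end]))
    return out


def build_database(
    genomes: Sequence[tuple[str | Path, int]],
    taxonomy: TaxonomyTree,
    k: int,
) -> KmerDatabase:
    """Build a canonical k-mer → LCA database from taxon-labelled FASTA files.

    Insertion order does not matter: the per-k-mer value is the LCA over
    all contributing taxa, and LCA is associative and commutative.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    entries: dict[str, int] = {}
    manifest: list[tuple[str, int]] = []
    for path, taxid in genomes:
        if taxid not in taxonomy:
            raise UnknownTaxonError(f"taxon {taxid} not in taxonomy")
        manifest.append((str(path), taxid))
        for _name, seq in read_fasta(path):
            for kmer in _canonical_kmers(seq, k):
                if kmer is None:
                    continue
                prev = entries.get(kmer)
                if prev is None:
                    entries[kmer] = taxid
                elif prev != taxid:
                    entries[kmer] = lca(taxonomy, prev, taxid)
    return KmerDatabase(k=k, entries=entries, taxonomy=taxonomy, source_manifest=manifest)


def add_genome(db: KmerDatabase, path: str | Path, taxid: int) -> None:
    """Fold one more genome into an existing database (same LCA rule)."""
    if taxid not in db.taxonomy:
        raise UnknownTaxonError(f"taxon {taxid} not in taxonomy")
    db.source_manifest.append((str(path), taxid))
    for _name, seq in read_fasta(path):
        for kmer in _canonical_kmers(seq, db.k):
            if kmer is None:
                continue
            prev = db.entries.get(kmer)
            if prev is None:
                db.entries[kmer] = taxid
            elif prev != taxid:
                db.entries[kmer] = lca(db.taxonomy, prev, taxid)


def _resolve(
    tree: TaxonomyTree, hit_counts: dict[int, int]
) -> tuple[int, dict[int, int]]:
    """Deepest maximal path-score taxon; ties across incomparable taxa → LCA.

    Returns (assigned taxon, per-candidate path scores). Candidates are the
    hit-bearing taxa; the score of t is the sum of hits over the
    root-to-t path, i.e. over ancestors-or-self of t.
    """
    scores: dict[int, int] = {}
    for t in hit_counts:
        s = 0
        for anc in tree.lineage(t):
            s += hit_counts.get(anc, 0)
        scores[t] = s
    best = max(scores.values())
    winners = [t for t, s in scores.items() if s == best]
    assigned = winners[0] if len(winners) == 1 else lca_of_set(tree, winners)
    return assigned, scores


def _clade_hits(tree: TaxonomyTree, hit_counts: dict[int, int], clade_root: int) -> int:
    from .taxonomy import is_in_clade

    return sum(c for t, c in hit_counts.items() if is_in_clade(tree, t, clade_root))


def classify_read(
    db: KmerDatabase,
    seq: str,
    confidence: float = 0.0,
    read_id: str = "",
) -> ClassificationResult:
    """Classify one sequence against the database.

    A read shorter than k, or with no database hit, is unclassified (not an
    error). With ``confidence`` > 0 the assignment is walked rootward until
    the fraction of k-mers hitting within the assigned clade reaches the
    threshold, and becomes unclassified if even the root fails.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 <= confidence <= 1.0:
        raise ValueError(f"confidence must be in [0,1], got {confidence}")
    kmers = _canonical_kmers(seq, db.k)
    total = sum(1 for km in kmers if km is not None)
    hit_counts: dict[int, int] = {}
    lookup = db.entries.get
    for km in kmers:
        if km is None:
            continue
        t = lookup(km)
        if t is not None:
            hit_counts[t] = hit_counts.get(t, 0) + 1
    hits = sum(hit_counts.values())
    if hits == 0:
        return ClassificationResult(read_id, "U", None, {}, total, 0)
    assigned, _scores = _resolve(db.taxonomy, hit_counts)
    if confidence > 0:
        tree = db.taxonomy
        cur = assigned
        while _clade_hits(tree, hit_counts, cur) / total < confidence:
            if cur == tree.root_id:
                return ClassificationResult(read_id, "U", None, hit_counts, total, hits)
            cur = tree.parent(cur)
        assigned = cur
    return ClassificationResult(read_id, "C", assigned, hit_counts, total, hits)


def classify_file(
    db: KmerDatabase,
    reads: str | Path,
    confidence: float = 0.0,
    out: str | Path | None = None,
) -> list[ClassificationResult]:
    """Classify a FASTQ file; optionally write Kraken-style columnar text.

    Output columns: status (C/U), read id, taxon id (0 if unclassified),
    read length, hit_kmers/total_kmers. Row order == input order.
    """
    results = []
    rows = []
    for read_id, seq, _qual in read_fastq(reads):
        res = classify_read(db, seq, confidence=confidence, read_id=read_id)
        results.append(res)
        rows.append(
            f"{res.status}\t{read_id}\t{res.taxon_id or 0}\t{len(seq)}\t"
            f"{res.hit_kmers}/{res.total_kmers}\n"
        )
    if out is not None:
        with open(out, "w") as fh:
            fh.writelines(rows)
    return results


def write_classifications(results: Sequence[ClassificationResult], lengths: Sequence[int], out: str | Path) -> None:
    with open(out, "w") as fh:
        for res, ln in zip(results, lengths):
            fh.write(
                f"{res.status}\t{res.read_id}\t{res.taxon_id or 0}\t{ln}\t"
                f"{res.hit_kmers}/{res.total_kmers}\n"
            )


def read_classifications(path: str | Path) -> list[tuple[str, str, int]]:
    """Parse a classification table into (status, read_id, taxon_id) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            status, read_id, taxid, _rest = line.split("\t", 3)
            rows.append((status, read_id, int(taxid)))
    return rows


def build_alt_consensus(
    reference: str | Path,
    variants: str | Path,
    out: str | Path,
    suffix: str = "_alt",
) -> dict[str, int]:
    """Write a copy of the reference with biallelic-SNP ALT alleles substituted.

    Augmenting a classification database with such a consensus adds the
    k-mers around known alternate alleles, so reads carrying non-reference
    variation still find exact matches — the guard against reference bias
    in positive filtering. Non-SNP and multiallelic records are skipped;
    records whose REF disagrees with the reference base are rejected.
    Returns counts: {"applied": n, "skipped": n, "ref_mismatch": n}.
    """
    import pysam

    from .seqio import write_fasta

    contigs = {name: list(seq) for name, seq in read_fasta(reference)}
    counts = {"applied": 0, "skipped": 0, "ref_mismatch": 0}
    with pysam.VariantFile(str(variants)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in _VALID
                or alts[0] not in _VALID
            ):
                counts["skipped"] += 1
                continue
            if rec.chrom not in contigs:
                counts["skipped"] += 1
                continue
            pos0 = rec.pos - 1  # VCF is 1-based
            seq = contigs[rec.chrom]
            if pos0 >= len(seq) or seq[pos0] != rec.ref:
                counts["ref_mismatch"] += 1
                continue
            seq[pos0] = alts[0]
            counts["applied"] += 1
    write_fasta(out, [(name + suffix, "".join(seq)) for name, seq in contigs.items()])
    return counts
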
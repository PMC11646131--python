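"""Minimal deterministic seed-and-extend read mapper with SAM output.

This is a stand-in aligner for benchmarking pre-mapping filters, not a
reimplementation of bwa: candidate loci come from exact seed hits, the
extension is ungapped (+1 match / −3 mismatch), and a read is mapped when
its best locus has at most ``ceil(rate * length)`` mismatches. MapQ is a
monotone uniqueness score, ``min(60, 4 * (best − second_best))`` and 0 on
ties — downstream analysis only ever thresholds it (MapQ > 20), so any
deterministic uniqueness measure serves.

Competitive mapping is the same machinery over a composite index whose
contigs carry a genome label (e.g. target + human): a contaminant read
whose best alignment lands on the non-target genome is thereby excluded
from target-genome analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .readprep import MergedRead
from .seqio import read_fasta, revcomp

_VALID = frozenset("ACGT")


@dataclass
class ReferenceIndex:
    contigs: list[tuple[str, str, str]]  # (name, sequence, genome label)
    seed_len: int
    seed_table: dict[str, list[tuple[int, int]]] = field(repr=False, default_factory=dict)
    _arrays: list[np.ndarray] = field(repr=False, default_factory=list)

    def labels(self) -> set[str]:
        return {label for _n, _s, label in self.contigs}

    def contig_label(self, contig_name: str) -> str:
        for name, _seq, label in self.contigs:
            if name == contig_name:
                return label
        raise KeyError(contig_name)


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    contig: str | None  # None when unmapped
    pos: int  # 1-based leftmost, SAM convention; 0 when unmapped
    strand: str  # "+", "-" or "." when unmapped
    score: int
    mapq: int
    cigar: str
    is_mapped: bool
    n_mismatch: int = 0
    genome_label: str | None = None


def build_index(
    fastas: Sequence[tuple[str | Path, str]],
    seed_len: int = 13,
) -> ReferenceIndex:
    """Exhaustive forward-strand seed table over one or more labelled FASTAs.

    Reverse-strand hits are found by also searching the reverse complement
    of the query, so only forward seeds are stored. Duplicate contig names
    across genomes are renamed with a label prefix.
    """
    if seed_len < 8:
        raise ValueError(f"seed_len must be >= 8, got {seed_len}")
    contigs: list[tuple[str, str, str]] = []
    seen_names: set[str] = set()
    for path, label in fastas:
        for name, seq in read_fasta(path):
            if name in seen_names:
                name = f"{label}:{name}"
            seen_names.add(name)
            contigs.append((name, seq, label))
    table: dict[str, list[tuple[int, int]]] = {}
    for ci, (_name, seq, _label) in enumerate(contigs):
        for pos in range(len(seq) - seed_len + 1):
            seed = seq[pos : pos + seed_len]
            if not _VALID.issuperset(seed):
                continue
            table.setdefault(seed, []).append((ci, pos))
    arrays = [np.frombuffer(seq.encode(), dtype="S1") for _n, seq, _l in contigs]
    return ReferenceIndex(contigs=contigs, seed_len=seed_len, seed_table=table, _arrays=arrays)


def _count_mismatches(index: ReferenceIndex, ci: int, start: int, query: np.ndarray) -> int:
    ref = index._arrays[ci][start : start + len(query)]
    return int((ref != query).sum())


def map_read(
    index: ReferenceIndex,
    read: MergedRead | tuple[str, str],
    max_mismatch_rate: float = 0.04,
) -> AlignmentRecord:
    """Best ungapped alignment of one read over both strands.

    Candidate loci are every (contig, diagonal, strand) implied by an exact
    seed hit at any query offset; each is scored full-length. Equal-score
    candidates are broken deterministically by (contig, position, strand),
    and the runner-up score on a *different* locus sets MapQ.
    """
    if isinstance(read, MergedRead):
        read_id, seq = read.read_id, read.sequence
    else:
        read_id, seq = read
    L = len(seq)
    k = index.seed_len
    unmapped = AlignmentRecord(read_id, None, 0, ".", 0, 0, "*", False)
    if L < k:
        return unmapped
    max_mm = int(np.ceil(max_mismatch_rate * L))

    queries = {"+": seq, "-": revcomp(seq)}
    candidates: set[tuple[int, int, str]] = set()
    table = index.seed_table
    for strand, q in queries.items():
        for off in range(0, L - k + 1):
            hits = table.get(q[off : off + k])
            if not hits:
                continue
            for ci, pos in hits:
                start = pos - off
                if start >= 0 and start + L <= len(index.contigs[ci][1]):
                    candidates.add((ci, start, strand))
    if not candidates:
        return unmapped

    qarr = {s: np.frombuffer(q.encode(), dtype="S1") for s, q in queries.items()}
    scored: list[tuple[int, int, int, int, str]] = []  # (score, ci, start, mm, strand)
    for ci, start, strand in candidates:
        mm = _count_mismatches(index, ci, start, qarr[strand])
        if mm <= max_mm:
            scored.append((L - 4 * mm, ci, start, mm, strand))
    if not scored:
        return unmapped
    # best = max score; tie-break by (contig, pos, strand) for determinism
    scored.sort(key=lambda t: (-t[0], t[1], t[2], t[4]))
    best = scored[0]
    if len(scored) > 1:
        second_score = scored[1][0]
        mapq = 0 if second_score == best[0] else min(60, 4 * (best[0] - second_score))
    else:
        mapq = 60
    score, ci, start, mm, strand = best
    name, _seq, label = index.contigs[ci]
    return AlignmentRecord(
        read_id=read_id,
        contig=name,
        pos=start + 1,
        strand=strand,
        score=score,
        mapq=mapq,
        cigar=f"{L}M",
        is_mapped=True,
        n_mismatch=mm,
        genome_label=label,
    )


def map_file(
    index: ReferenceIndex,
    reads: Iterable[MergedRead],
    out_sam: str | Path,
    mode: str = "single",
    target_label: str | None = None,
    max_mismatch_rate: float = 0.04,
) -> list[AlignmentRecord]:
    """Map reads and emit SAM (text, flags 0/4/16), in input order.

    In competitive mode ``target_label`` must name one of the index's
    genome labels; alignments are reported wherever they fall, and the
    evaluation stage treats best hits on non-target contigs as not mapped
    to the target.
    """
    if mode not in ("single", "competitive"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "competitive":
        if target_label is None or target_label not in index.labels():
            raise ValueError(f"target_label {target_label!r} not among {sorted(index.labels())}")
    records = []
    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq, label in index.contigs:
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:paleosieve\tPN:paleosieve\n")
        for read in reads:
            rec = map_read(index, read, max_mismatch_rate)
            records.append(rec)
            qual = read.qualities if isinstance(read, MergedRead) else "*"
            seq = read.sequence if isinstance(read, MergedRead) else read[1]
            if not rec.is_mapped:
                fh.write(f"{rec.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                continue
            flag = 16 if rec.strand == "-" else 0
            out_seq = revcomp(seq) if rec.strand == "-" else seq
            out_qual = qual[::-1] if (rec.strand == "-" and qual != "*") else qual
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.contig}\t{rec.pos}\t{rec.mapq}\t"
                f"{rec.cigar}\t*\t0\t0\t{out_seq}\t{out_qual}\t"
                f"AS:i:{rec.score}\tNM:i:{rec.n_mismatch}\n"
            )
    return records
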
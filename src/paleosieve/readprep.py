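"""Adapter trimming and paired-end read merging.

Ancient-DNA fragments are mostly shorter than the read length, so R1 and
R2 overlap (often completely, running through into the adapter). Merging
reconstructs the original fragment and is a precondition for mapping here:
unmerged pairs are discarded by default, mirroring workflows that map only
collapsed reads. Thresholds follow common aDNA practice: minimum retained
length 30 bp, minimum base quality 20 for end-trimming, merge overlap at
least 11 bases, merged qualities capped at 41.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .seqio import FastqWriter, read_fastq, revcomp

MIN_OVERLAP = 11
MAX_MISMATCH_FRACTION = 0.10
QUALITY_CAP = 41


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    sequence: str
    qualities: str
    merged: bool = True


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(seq: str, qual: str, adapter: str) -> tuple[str, str]:
    """Trim the best adapter suffix-prefix overlap (<=10% mismatches).

    Scans trim positions left to right, so the longest acceptable overlap
    wins; chance matches of a base or two at the read end may be trimmed,
    which the merge step recovers via the partner read.
    """
    n = len(seq)
    for s in range(n):
        ov = min(n - s, len(adapter))
        if _mismatches(seq[s : s + ov], adapter[:ov]) <= MAX_MISMATCH_FRACTION * ov:
            return seq[:s], qual[:s]
    return seq, qual


def _quality_trim(seq: str, qual: str, min_quality: int) -> tuple[str, str]:
    lo, hi = 0, len(seq)
    while lo < hi and ord(qual[lo]) - 33 < min_quality:
        lo += 1
    while hi > lo and ord(qual[hi - 1]) - 33 < min_quality:
        hi -= 1
    return seq[lo:hi], qual[lo:hi]


def trim_and_merge(
    r1: tuple[str, str],
    r2: tuple[str, str],
    adapters: tuple[str, str],
    min_length: int = 30,
    min_quality: int = 20,
    read_id: str = "",
) -> MergedRead | None:
    """Adapter-trim a pair, merge on overlap, quality-trim, length-filter.

    Returns None when the pair does not overlap by at least 11 bases or the
    final merged read is shorter than ``min_length``. In the overlap the
    higher-quality base wins and its quality becomes the max of the two
    (capped at 41).
    """
    seq1, qual1 = r1
    seq2, qual2 = r2
    if len(seq1) != len(qual1) or len(seq2) != len(qual2):
        raise ValueError(f"seq/qual length mismatch for read {read_id!r}")

    seq1, qual1 = trim_adapter(seq1, qual1, adapters[0])
    seq2, qual2 = trim_adapter(seq2, qual2, adapters[1])
    rc2 = revcomp(seq2)
    rcq2 = qual2[::-1]

    n1, n2 = len(seq1), len(rc2)
    merged_seq: str | None = None
    for s in range(0, n1 - MIN_OVERLAP + 1):
        ov = min(n1 - s, n2)
        if ov < MIN_OVERLAP:
            break
        if _mismatches(seq1[s : s + ov], rc2[:ov]) <= MAX_MISMATCH_FRACTION * ov:
            cons = []
            consq = []
            for i in range(ov):
                b1, q1 = seq1[s + i], ord(qual1[s + i]) - 33
                b2, q2 = rc2[i], ord(rcq2[i]) - 33
                if b1 == b2:
                    cons.append(b1)
                else:
                    cons.append(b1 if q1 >= q2 else b2)
                consq.append(chr(min(max(q1, q2), QUALITY_CAP) + 33))
            merged_seq = seq1[:s] + "".join(cons) + rc2[ov:]
            merged_qual = qual1[:s] + "".join(consq) + rcq2[ov:]
            break
    if merged_seq is None:
        return None

    merged_seq, merged_qual = _quality_trim(merged_seq, merged_qual, min_quality)
    if len(merged_seq) < min_length:
        return None
    return MergedRead(read_id, merged_seq, merged_qual, merged=True)


def prep_file(
    r1_path: str | Path,
    r2_path: str | Path,
    adapters: tuple[str, str],
    out: str | Path | None = None,
    min_length: int = 30,
    min_quality: int = 20,
    keep_unmerged: bool = False,
) -> list[MergedRead]:
    """Trim/merge an entire pair of FASTQ files; optionally write FASTQ.

    With ``keep_unmerged`` the trimmed, quality-trimmed R1 of a
    non-overlapping pair is retained (flagged ``merged=False``) instead of
    discarded.
    """
    merged: list[MergedRead] = []
    for (id1, s1, q1), (id2, s2, q2) in zip(
        read_fastq(r1_path), read_fastq(r2_path), strict=True
    ):
        if id1 != id2:
            raise ValueError(f"read name mismatch: {id1!r} vs {id2!r}")
        m = trim_and_merge((s1, q1), (s2, q2), adapters, min_length, min_quality, id1)
        if m is None and keep_unmerged:
            seq, qual = trim_adapter(s1, q1, adapters[0])
            seq, qual = _quality_trim(seq, qual, min_quality)
            if len(seq) >= min_length:
                m = MergedRead(id1, seq, qual, merged=False)
        if m is not None:
            merged.append(m)
    if out is not None:
        with FastqWriter(out) as w:
            for m in merged:
                w.write(m.read_id, m.sequence, m.qualities)
    return merged
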
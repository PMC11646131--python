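"""Small sequence I/O and k-mer helpers shared across modules.

FASTA/FASTQ parsing delegates to Biopython; gzip is handled transparently
by extension. Writers set gzip mtime to 0 so fixed-seed runs are
byte-identical.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic min (A<C<G<T) of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime=0 and no embedded filename => deterministic bytes for a fixed seed
            raw = open(path, "wb")
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            close_gz = gz.close

            def _close() -> None:
                close_gz()
                raw.close()

            gz.close = _close  # type: ignore[method-assign]
            return gz  # type: ignore[return-value]
        return gzip.open(path, "rt")
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All (name, uppercase sequence) records of a FASTA file."""
    with _open_text(path) as fh:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality string) in file order."""
    with _open_text(path) as fh:
        i = 0
        while True:
            header = fh.readline()
            if isinstance(header, bytes):  # pragma: no cover - gzip text wrap below
                header = header.decode()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"{path}: truncated FASTQ record at index {i}")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record at index {i}")
            if len(seq) != len(qual):
                raise ValueError(f"{path}: seq/qual length mismatch at record {i}")
            yield header[1:].split()[0], seq.upper(), qual
            i += 1


class FastqWriter:
    """Deterministic FASTQ writer (gzip mtime 0 when path ends in .gz)."""

    def __init__(self, path: str | Path):
        self._binary = str(path).endswith(".gz")
        self._fh = _open_text(path, "wt" if not self._binary else "wb")

    def write(self, read_id: str, seq: str, qual: str) -> None:
        rec = f"@{read_id}\n{seq}\n+\n{qual}\n"
        self._fh.write(rec.encode() if self._binary else rec)  # type: ignore[arg-type]

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
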
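"""Ancient-DNA shotgun read simulator with known per-read truth.

Generates paired-end Illumina-style reads from a mixture of genomes:
an endogenous (ancient, damaged) component plus modern and ancient
contaminants. Fragment lengths follow a truncated lognormal; cytosine
deamination follows an exponentially decaying terminal profile; fragments
shorter than the read length run through into the adapter, exactly the
situation adapter trimming and pair merging must recover from.

Truth is carried in the read name — ``taxid|contig|start|end|strand|serial``
— and mirrored in a TSV, so the downstream benchmark can score every read
against its actual origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .seqio import FastqWriter, read_fasta, revcomp

# Illumina TruSeq adapters (kept in config, never hard-coded in the logic)
TRUSEQ_ADAPTER1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
TRUSEQ_ADAPTER2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class DamageModel:
    """Terminal deamination profile.

    Position-i damage probability from an end is ``background +
    p_max * exp(-decay * i)``. Double-stranded libraries show C→T at the
    5' end and G→A at the 3' end; single-stranded libraries show C→T at
    both ends. UDG treatment removes uracils: "full" zeroes both terminal
    maxima (the constant background floor remains), "half" halves them.
    """

    library: Literal["single-strand", "double-strand"] = "single-strand"
    udg: Literal["none", "half", "full"] = "none"
    p5_max: float = 0.3
    p3_max: float = 0.3
    decay: float = 0.5
    background: float = 0.01

    def __post_init__(self) -> None:
        for name in ("p5_max", "p3_max", "background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        if self.background + max(self.p5_max, self.p3_max) > 1.0:
            raise ValueError("background + p_max exceeds 1")

    def effective_maxima(self) -> tuple[float, float]:
        scale = {"none": 1.0, "half": 0.5, "full": 0.0}[self.udg]
        return self.p5_max * scale, self.p3_max * scale


#: partial-UDG single-stranded library profile used for ancient components
DEFAULT_ANCIENT_DAMAGE = DamageModel(
    library="single-strand", udg="half", p5_max=0.3, p3_max=0.3, decay=0.5, background=0.01
)


@dataclass(frozen=True)
class FragmentLengthModel:
    """Lognormal fragment-size distribution truncated to [min_len, max_len].

    Defaults (median 55 bp, sigma 0.35, range 30–150) emulate the short,
    right-skewed fragment sizes of degraded aDNA libraries; the 30 bp floor
    sits at the conventional minimum-length cut so the prep filter is
    exercised.
    """

    mu: float = float(np.log(55.0))
    sigma: float = 0.35
    min_len: int = 30
    max_len: int = 150

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("require 1 <= min_len <= max_len")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            L = int(round(np.exp(self.mu)))
            L = min(max(L, self.min_len), self.max_len)
            return np.full(n, L, dtype=np.int64)
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.lognormal(self.mu, self.sigma, size=max(n - filled, 16))
            L = np.rint(draw).astype(np.int64)
            ok = L[(L >= self.min_len) & (L <= self.max_len)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out

    def truncated_mean(self) -> float:
        """Numeric mean of round(lognormal) conditioned on [min_len, max_len]."""
        from scipy import stats

        lengths = np.arange(self.min_len, self.max_len + 1)
        # P(round(X) == L) = F(L + 0.5) - F(L - 0.5)
        dist = stats.lognorm(s=self.sigma, scale=np.exp(self.mu))
        p = dist.cdf(lengths + 0.5) - dist.cdf(lengths - 0.5)
        return float((lengths * p).sum() / p.sum())


@dataclass(frozen=True)
class MixtureComponent:
    taxon_id: int
    genome: str | Path
    fraction: float
    damage: DamageModel | None = None  # None => modern (undamaged)


@dataclass(frozen=True)
class ReadSimConfig:
    n_pairs: int = 10_000
    read_len: int = 75
    frag_len: FragmentLengthModel = field(default_factory=FragmentLengthModel)
    adapter1: str = TRUSEQ_ADAPTER1
    adapter2: str = TRUSEQ_ADAPTER2
    base_error: float = 0.001
    quality: int = 37  # constant Phred, capped 41, +33 encoding
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 1 or self.n_pairs < 0:
            raise ValueError("read_len >= 1 and n_pairs >= 0 required")
        if not 0.0 <= self.base_error < 1.0:
            raise ValueError("base_error in [0,1) required")


def sample_fragments(
    genome: Sequence[tuple[str, str]],
    n: int,
    frag_model: FragmentLengthModel,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, str]]:
    """Sample ``n`` fragment intervals (contig, start, end, strand).

    Intervals are 0-based half-open; contigs are chosen with probability
    proportional to length; strands are equiprobable.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    usable = [(name, seq) for name, seq in genome if len(seq) >= frag_model.min_len]
    if not usable:
        raise ValueError("no contig long enough for the minimum fragment length")
    weights = np.array([len(seq) for _n, seq in usable], dtype=float)
    weights /= weights.sum()
    contig_idx = rng.choice(len(usable), size=n, p=weights)
    lengths = frag_model.sample(n, rng)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    out = []
    for i in range(n):
        name, seq = usable[contig_idx[i]]
        L = int(min(lengths[i], len(seq)))
        start = int(rng.integers(0, len(seq) - L + 1))
        out.append((name, start, start + L, str(strands[i])))
    return out


def damage_probabilities(model: DamageModel, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position (5'→3') C→T and 3'-end probabilities for a fragment."""
    p5, p3 = model.effective_maxima()
    i = np.arange(length, dtype=float)
    prob5 = model.background + p5 * np.exp(-model.decay * i)
    prob3 = model.background + p3 * np.exp(-model.decay * i[::-1])
    return np.clip(prob5, 0, 1), np.clip(prob3, 0, 1)


def apply_damage(frag_seq: str, model: DamageModel, rng: np.random.Generator) -> str:
    """Apply deamination to a fragment given in 5'→3' source-strand orientation.

    C→T with probability decaying from the 5' end. At the 3' end,
    double-stranded libraries accumulate G→A (damage on the complementary
    strand) while single-stranded libraries show C→T again.
    """
    if not frag_seq:
        return frag_seq
    arr = np.frombuffer(frag_seq.encode(), dtype="S1").copy()
    p5, p3 = model.effective_maxima()
    i = np.arange(len(arr), dtype=float)
    from5 = p5 * np.exp(-model.decay * i)
    from3 = p3 * np.exp(-model.decay * i[::-1])
    if model.library == "single-strand":
        # both ends deaminate the same strand: one C→T draw per position
        prob_ct = np.clip(model.background + from5 + from3, 0, 1)
        u = rng.random(len(arr))
        arr[(arr == b"C") & (u < prob_ct)] = b"T"
    else:
        prob_ct = np.clip(model.background + from5, 0, 1)
        prob_ga = np.clip(model.background + from3, 0, 1)
        u = rng.random(len(arr))
        arr[(arr == b"C") & (u < prob_ct)] = b"T"
        u2 = rng.random(len(arr))
        arr[(arr == b"G") & (u2 < prob_ga)] = b"A"
    return arr.tobytes().decode()


def _sequencing_errors(seq: str, base_error: float, rng: np.random.Generator) -> str:
    if base_error <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < base_error)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def render_pair(
    frag_seq: str, cfg: ReadSimConfig, rng: np.random.Generator
) -> tuple[tuple[str, str], tuple[str, str]]:
    """Render a fragment as an R1/R2 pair with qualities.

    R1 reads the fragment 5'→3'; R2 reads the reverse complement. A
    fragment shorter than the read length runs through into the adapter,
    padded with random bases if the adapter itself is exhausted.
    """
    if not frag_seq:
        raise ValueError("empty fragment")
    L, R = len(frag_seq), cfg.read_len

    def build(template: str, adapter: str) -> str:
        if len(template) >= R:
            read = template[:R]
        else:
            read = template + adapter[: R - len(template)]
            if len(read) < R:
                read += _random_bases(R - len(read), rng)
        return _sequencing_errors(read, cfg.base_error, rng)

    qual = chr(min(cfg.quality, 41) + 33) * R
    r1 = build(frag_seq, cfg.adapter1)
    r2 = build(revcomp(frag_seq), cfg.adapter2)
    return (r1, qual), (r2, qual)


def _apportion(fractions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n pairs across components."""
    exact = [f * n for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    rem = n - sum(counts)
    order = sorted(range(len(exact)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def simulate_dataset(
    components: Sequence[MixtureComponent],
    cfg: ReadSimConfig,
    out_prefix: str | Path,
) -> tuple[Path, Path, Path]:
    """Simulate a full mixture dataset: R1/R2 FASTQ (gzip) plus truth TSV.

    Read names encode provenance ``taxid|contig|start|end|strand|serial``.
    Per-component pair counts follow largest-remainder apportionment, so
    they sum exactly to ``cfg.n_pairs``. Deterministic for a fixed seed.
    """
    total_frac = sum(c.fraction for c in components)
    if abs(total_frac - 1.0) > 1e-9:
        raise ValueError(f"component fractions sum to {total_frac}, expected 1")
    rng = np.random.default_rng(cfg.seed)
    counts = _apportion([c.fraction for c in components], cfg.n_pairs)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    r1_path = Path(str(out_prefix) + ".r1.fastq.gz")
    r2_path = Path(str(out_prefix) + ".r2.fastq.gz")
    truth_path = Path(str(out_prefix) + ".truth.tsv")

    serial = 0
    with FastqWriter(r1_path) as w1, FastqWriter(r2_path) as w2, open(
        truth_path, "w"
    ) as truth:
        truth.write("read_id\ttaxon_id\tcontig\tstart\tend\tstrand\tfrag_len\n")
        for comp, n in zip(components, counts):
            if n == 0:
                continue
            genome = read_fasta(comp.genome)
            seqs = dict(genome)
            frags = sample_fragments(genome, n, cfg.frag_len, rng)
            for contig, start, end, strand in frags:
                frag = seqs[contig][start:end]
                if strand == "-":
                    frag = revcomp(frag)
                if comp.damage is not None:
                    frag = apply_damage(frag, comp.damage, rng)
                (s1, q1), (s2, q2) = render_pair(frag, cfg, rng)
                name = f"{comp.taxon_id}|{contig}|{start}|{end}|{strand}|{serial}"
                w1.write(name, s1, q1)
                w2.write(name, s2, q2)
                truth.write(
                    f"{name}\t{comp.taxon_id}\t{contig}\t{start}\t{end}\t{strand}\t{end - start}\n"
                )
                serial += 1
    return r1_path, r2_path, truth_path


def simulate_damaged_alignments(
    genome: Sequence[tuple[str, str]],
    n: int,
    damage: DamageModel,
    frag_model: FragmentLengthModel,
    seed: int,
    out_sam: str | Path,
) -> Path:
    """Sample damaged fragments and write them as SAM at their true coordinates.

    Used to measure a damage model's misincorporation profile without an
    aligner in the loop: mapping preferentially drops heavily damaged
    reads, which would bias terminal rates downward, whereas the true
    coordinates are exact by construction.
    """
    rng = np.random.default_rng(seed)
    seqs = dict(genome)
    frags = sample_fragments(genome, n, frag_model, rng)
    out_sam = Path(out_sam)
    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genome:
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for serial, (contig, start, end, strand) in enumerate(frags):
            frag = seqs[contig][start:end]
            if strand == "-":
                frag = revcomp(frag)
            frag = apply_damage(frag, damage, rng)
            # SAM stores the forward-reference orientation
            sam_seq = revcomp(frag) if strand == "-" else frag
            flag = 16 if strand == "-" else 0
            L = end - start
            fh.write(
                f"frag{serial}\t{flag}\t{contig}\t{start + 1}\t60\t{L}M\t*\t0\t0\t"
                f"{sam_seq}\t{'F' * L}\n"
            )
    return out_sam


def parse_truth_name(read_id: str) -> tuple[int, str, int, int, str, int]:
    taxid, contig, start, end, strand, serial = read_id.split("|")
    return int(taxid), contig, int(start), int(end), strand, int(serial)
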
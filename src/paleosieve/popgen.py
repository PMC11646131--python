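"""Reference-bias detection via pseudo-haploid calls and f4 statistics.

Classification-based filtering keys on exact k-mer matches to database
sequences, so reads carrying non-reference alleles are at risk of being
dropped preferentially — reference bias. The test: call pseudo-haploid
genotypes from alignments made with and without filtering, then compute

    f4(Filtered, Unfiltered; reference-like, outgroup)

over a panel of sites ascertained as heterozygous in an outgroup
individual. Under the null (filtering removes reads independently of the
allele they carry) f4 is zero in expectation; a significantly positive
value (block-jackknife Z > 3) means the filtered calls share excess drift
with the reference-like population, i.e. filtering pushed the sample
toward the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

MISSING = -1.0  # marker inside frequency vectors

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class Site:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class SitePanel:
    sites: list[Site]

    def __post_init__(self) -> None:
        seen = set()
        for s in self.sites:
            key = (s.contig, s.pos)
            if key in seen:
                raise ValueError(f"duplicate site {key}")
            seen.add(key)
            if s.ref not in _VALID or s.alt not in _VALID or s.ref == s.alt:
                raise ValueError(f"invalid alleles at {key}: {s.ref}/{s.alt}")

    def __len__(self) -> int:
        return len(self.sites)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tpos\tref\talt\n")
            for s in self.sites:
                fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SitePanel":
        sites = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("contig"):
                raise ValueError(f"{path}: expected header contig/pos/ref/alt")
            for line in fh:
                contig, pos, ref, alt = line.split()
                sites.append(Site(contig, int(pos), ref, alt))
        return cls(sites)


def ascertain_sites(
    genotypes: Sequence[tuple[str, int, str, tuple[str, str]]],
) -> tuple[SitePanel, int]:
    """Panel of sites where the designated individual is heterozygous.

    ``genotypes`` rows are (contig, pos 1-based, ref allele, (allele1,
    allele2)) diploid calls. Sites with indel or non-ACGT alleles are
    skipped and counted. Returns (panel, n_skipped).
    """
    sites = []
    skipped = 0
    for contig, pos, ref, (a1, a2) in genotypes:
        if a1 == a2:
            continue
        if not ({a1, a2} <= _VALID) or ref not in _VALID:
            skipped += 1
            continue
        alt = a2 if a1 == ref else a1
        if alt == ref or (a1 != ref and a2 != ref):
            # neither allele matches the reference: not a usable ref/alt site
            skipped += 1
            continue
        sites.append(Site(contig, pos, ref, alt))
    return SitePanel(sites), skipped


def ascertain_sites_vcf(vcf_path: str | Path, sample: str) -> tuple[SitePanel, int]:
    """Het-site ascertainment straight from a VCF sample's genotypes."""
    import pysam

    rows = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                continue
            gt = rec.samples[sample]["GT"]
            if gt is None or None in gt:
                continue
            alleles = tuple(rec.alleles[i] for i in gt)
            rows.append((rec.chrom, rec.pos, rec.ref, alleles))
    return ascertain_sites(rows)


def pseudo_haploid_call(
    sam: str | Path,
    panel: SitePanel,
    seed: int,
    min_mapq: int = 20,
    min_baseq: int = 20,
    replicates: int = 3,
) -> np.ndarray:
    """Sample one qualifying allele per site per replicate.

    Returns an array of shape (replicates, n_sites) with values 1 (alt),
    0 (ref) or MISSING. Bases must match ref or alt, come from alignments
    with MapQ >= ``min_mapq``, and have base quality >= ``min_baseq``.
    Replicates differ only in the sampling draw.
    """
    import pysam

    site_index: dict[str, dict[int, int]] = {}
    for j, s in enumerate(panel.sites):
        site_index.setdefault(s.contig, {})[s.pos] = j

    piles: list[list[int]] = [[] for _ in panel.sites]  # alt-dosage per base
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            by_pos = site_index.get(rec.reference_name)
            if not by_pos:
                continue
            start = rec.reference_start  # 0-based
            seq = rec.query_sequence
            quals = rec.query_qualities
            for offset in range(rec.query_length):
                pos1 = start + offset + 1
                j = by_pos.get(pos1)
                if j is None:
                    continue
                if quals is not None and quals[offset] < min_baseq:
                    continue
                base = seq[offset]
                site = panel.sites[j]
                if base == site.alt:
                    piles[j].append(1)
                elif base == site.ref:
                    piles[j].append(0)

    rng = np.random.default_rng(seed)
    calls = np.full((replicates, len(panel.sites)), MISSING)
    for j, bases in enumerate(piles):
        if not bases:
            continue
        arr = np.asarray(bases)
        for r in range(replicates):
            calls[r, j] = arr[rng.integers(0, len(arr))]
    return calls


@dataclass(frozen=True)
class F4Result:
    f4: float
    se: float
    z: float
    n_sites: int
    n_blocks: int


def f4_stat(
    pA: np.ndarray,
    pB: np.ndarray,
    pC: np.ndarray,
    pD: np.ndarray,
    block_size_sites: int = 200,
) -> F4Result:
    """f4 = mean over sites of (pA−pB)(pC−pD), with block-jackknife SE.

    Sites where any population is missing (MISSING or NaN) are dropped.
    The SE comes from a delete-one weighted block jackknife over contiguous
    blocks of ``block_size_sites`` sites (the last block may be short);
    with equal blocks this reduces to the textbook delete-one jackknife.
    """
    vecs = [np.asarray(v, dtype=float) for v in (pA, pB, pC, pD)]
    n0 = len(vecs[0])
    if any(len(v) != n0 for v in vecs):
        raise ValueError("frequency vectors must share one panel")
    ok = np.ones(n0, dtype=bool)
    for v in vecs:
        ok &= np.isfinite(v) & (v != MISSING)
    a, b, c, d = (v[ok] for v in vecs)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no sites usable in all four populations")
    per_site = (a - b) * (c - d)
    theta = float(per_site.mean())

    starts = list(range(0, n, block_size_sites))
    m = len(starts)
    if m < 2:
        raise ValueError(f"need >= 2 jackknife blocks, got {m} (n={n}, block={block_size_sites})")
    total = per_site.sum()
    block_sums = np.array([per_site[s : s + block_size_sites].sum() for s in starts])
    block_n = np.array(
        [min(block_size_sites, n - s) for s in starts], dtype=float
    )
    theta_del = (total - block_sums) / (n - block_n)  # delete-one-block means

    # weighted jackknife (Busing et al. 1999); h_j = n / m_j
    h = n / block_n
    theta_J = m * theta - float(((1.0 - block_n / n) * theta_del).sum())
    pseudo = h * theta - (h - 1.0) * theta_del
    var = float((((pseudo - theta_J) ** 2) / (h - 1.0)).sum() / m)
    se = float(np.sqrt(var))
    z = theta / se if se > 0 else (0.0 if theta == 0 else float(np.inf) * np.sign(theta))
    return F4Result(f4=theta, se=se, z=float(z), n_sites=n, n_blocks=m)


@dataclass(frozen=True)
class BiasTestResult:
    result: F4Result
    verdict: str  # "biased" | "not biased"


def bias_test(
    calls_filtered: np.ndarray,
    calls_unfiltered: np.ndarray,
    ref_pop: np.ndarray,
    outgroup_pop: np.ndarray,
    block_size: int = 200,
) -> BiasTestResult:
    """One-sided reference-bias test: f4(Filt, Unfilt; ref-like, outgroup).

    Verdict is "biased" iff Z > 3 — a significantly *positive* f4 means
    the filtered calls lean toward the reference-like population. |Z| is
    available from the embedded :class:`F4Result`.
    """
    res = f4_stat(calls_filtered, calls_unfiltered, ref_pop, outgroup_pop, block_size)
    return BiasTestResult(result=res, verdict="biased" if res.z > 3 else "not biased")


def simulated_bias_trial(
    n_sites: int,
    alt_drop_rate: float,
    seed: int,
    mean_depth: float = 5.0,
    random_drop_rate: float = 0.0,
    p_ref_pop: float = 0.1,
    p_outgroup: float = 0.8,
    block_size: int = 200,
) -> BiasTestResult:
    """One calibration trial of the bias test on synthetic pileups.

    The sample is heterozygous at every panel site (the het-ascertained
    regime where reference bias can act). Per site, ``depth`` bases are
    drawn 50/50 ref/alt; the *filtered* pileup drops alt-carrying bases
    with probability ``alt_drop_rate`` (planted reference bias) and all
    bases with probability ``random_drop_rate`` (allele-blind loss — the
    null when ``alt_drop_rate`` is 0). One allele per pileup is sampled as
    the pseudo-haploid call; the reference-like and outgroup populations
    are Bernoulli pseudo-haploid draws at ``p_ref_pop`` and
    ``p_outgroup`` alt-allele frequency.
    """
    rng = np.random.default_rng(seed)
    calls_f = np.full(n_sites, MISSING)
    calls_u = np.full(n_sites, MISSING)
    depth = rng.poisson(mean_depth, size=n_sites) + 1
    for j in range(n_sites):
        bases = rng.integers(0, 2, size=depth[j])  # alt dosage per read base
        calls_u[j] = bases[rng.integers(0, len(bases))]
        keep = rng.random(len(bases)) >= random_drop_rate
        if alt_drop_rate > 0:
            keep &= ~((bases == 1) & (rng.random(len(bases)) < alt_drop_rate))
        kept = bases[keep]
        if len(kept):
            calls_f[j] = kept[rng.integers(0, len(kept))]
    ref_pop = (rng.random(n_sites) < p_ref_pop).astype(float)
    outgroup = (rng.random(n_sites) < p_outgroup).astype(float)
    return bias_test(calls_f, calls_u, ref_pop, outgroup, block_size=block_size)
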
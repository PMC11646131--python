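"""Classification-based read filtering and mapping benchmark metrics.

Two filtering strategies, applied before mapping:

* **positive** — keep only reads *classified* inside the target clade
  (paired in practice with a small target-taxa database at k-mer 29);
* **negative** — remove reads classified *outside* the target clade, i.e.
  keep in-clade reads *and unclassified* reads (paired with a
  comprehensive contaminant database at k-mer 35).

"In the target clade" means at the clade root or any rank below it —
subtree membership, not rank-name comparison.

The benchmark scores every simulated read against its truth: a read is a
true positive when it is endogenous, survived filtering, and mapped to the
target with MapQ above the threshold; precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 their harmonic mean. Reads lost during read prep
or left unmapped charge recall, because the recall denominator is all
endogenous reads in the dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import read_fasta, revcomp
from .taxonomy import TaxonomyTree, UnknownTaxonError, is_in_clade


@dataclass(frozen=True)
class FilterPolicy:
    strategy: str  # "positive" | "negative"
    clade_root: int

    def __post_init__(self) -> None:
        if self.strategy not in ("positive", "negative"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @property
    def keep_unclassified(self) -> bool:
        return self.strategy == "negative"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Precision/recall/F1; ``None`` marks an undefined (0/0) value."""

    precision: float | None
    recall: float | None
    f1: float | None


def apply_filter(
    classifications: Iterable[tuple[str, str, int]],
    policy: FilterPolicy,
    taxonomy: TaxonomyTree,
) -> tuple[set[str], set[str]]:
    """Partition read ids into (retained, removed) under a filter policy.

    ``classifications`` rows are (status "C"/"U", read_id, taxon_id).
    """
    clade_members: dict[int, bool] = {}
    retained: set[str] = set()
    removed: set[str] = set()
    unknown: list[int] = []
    for status, read_id, taxid in classifications:
        if status == "U":
            (retained if policy.keep_unclassified else removed).add(read_id)
            continue
        if taxid not in clade_members:
            if taxid not in taxonomy:
                unknown.append(taxid)
                continue
            clade_members[taxid] = is_in_clade(taxonomy, taxid, policy.clade_root)
        (retained if clade_members[taxid] else removed).add(read_id)
    if unknown:
        raise UnknownTaxonError(f"classified taxa not in taxonomy: {sorted(set(unknown))}")
    return retained, removed


# ---------------------------------------------------------------------------
# truth / SAM joining


def load_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_sam_records(sam: str | Path) -> dict[str, tuple[int, str, int]]:
    """read_id → (mapq, contig, read length) for mapped primary records."""
    import pysam

    out: dict[str, tuple[int, str, int]] = {}
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            out[rec.query_name] = (rec.mapping_quality, rec.reference_name, rec.query_length)
    return out


def categorize(
    truth: pd.DataFrame,
    retained: set[str],
    sam: Mapping[str, tuple[int, str, int]],
    taxonomy: TaxonomyTree,
    endogenous_clade: int,
    mapq_threshold: int = 20,
    contig_labels: Mapping[str, str] | None = None,
    target_label: str | None = None,
) -> ConfusionCounts:
    """Tally the TP/FP/TN/FN confusion counts for one method condition.

    A read counts as mapped only when present in the SAM with
    MapQ > ``mapq_threshold``; in competitive mode (``contig_labels`` and
    ``target_label`` given) its best hit must additionally fall on a
    target-labelled contig. Reads in the SAM but absent from truth are a
    consistency error.
    """
    truth_ids = set(truth["read_id"])
    stray = set(sam) - truth_ids
    if stray:
        raise ValueError(f"{len(stray)} SAM reads missing from truth, e.g. {sorted(stray)[:3]}")
    clade_cache: dict[int, bool] = {}
    tp = fp = tn = fn = 0
    for read_id, taxid in zip(truth["read_id"], truth["taxon_id"]):
        taxid = int(taxid)
        if taxid not in clade_cache:
            clade_cache[taxid] = is_in_clade(taxonomy, taxid, endogenous_clade)
        endog = clade_cache[taxid]
        hit = sam.get(read_id)
        mapped = hit is not None and hit[0] > mapq_threshold
        if mapped and target_label is not None and contig_labels is not None:
            mapped = contig_labels.get(hit[1]) == target_label
        positive = mapped and read_id in retained
        if endog:
            tp, fn = (tp + 1, fn) if positive else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if positive else (fp, tn + 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Precision, recall and F1 with explicit undefined markers on 0/0."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(precision=precision, recall=recall, f1=f1)


DEFAULT_LENGTH_BINS: tuple[tuple[int, int | None], ...] = (
    (30, 40),
    (41, 50),
    (51, 60),
    (61, None),
)


def stratify_by_length(
    truth: pd.DataFrame,
    retained: set[str],
    sam: Mapping[str, tuple[int, str, int]],
    taxonomy: TaxonomyTree,
    endogenous_clade: int,
    mapq_threshold: int = 20,
    bins: Sequence[tuple[int, int | None]] = DEFAULT_LENGTH_BINS,
    contig_labels: Mapping[str, str] | None = None,
    target_label: str | None = None,
) -> dict[tuple[int, int | None], tuple[ConfusionCounts, MetricSet]]:
    """Per-length-bin confusion counts and metrics.

    A read's length is its merged-read length when it reached the SAM,
    otherwise its true fragment length. Bins are inclusive [lo, hi]
    (hi None = open-ended) and must not overlap.
    """
    edges = sorted(bins)
    for (lo1, hi1), (lo2, _hi2) in zip(edges, edges[1:]):
        if hi1 is None or hi1 >= lo2:
            raise ValueError(f"overlapping length bins: {(lo1, hi1)} and {(lo2, _hi2)}")

    def bin_of(length: int) -> tuple[int, int | None] | None:
        for lo, hi in bins:
            if length >= lo and (hi is None or length <= hi):
                return (lo, hi)
        return None

    out = {}
    for b in bins:
        mask = []
        for read_id, frag_len in zip(truth["read_id"], truth["frag_len"]):
            hit = sam.get(read_id)
            length = hit[2] if hit is not None else int(frag_len)
            mask.append(bin_of(length) == b)
        sub = truth[pd.Series(mask, index=truth.index)]
        c = categorize(
            sub, retained, {r: v for r, v in sam.items() if r in set(sub["read_id"])},
            taxonomy, endogenous_clade, mapq_threshold, contig_labels, target_label,
        )
        out[b] = (c, metrics(c))
    return out


# ---------------------------------------------------------------------------
# damage profiles


def misincorporation_profile(
    sam: str | Path,
    reference: str | Path,
    n_positions: int = 25,
) -> pd.DataFrame:
    """Terminal misincorporation rates from ungapped alignments.

    Returns one row per (end, position): C→T rates measured from the 5'
    end of each read and G→A rates from the 3' end (the complementary-
    strand signature of a double-stranded library; single-stranded
    libraries show C→T at both ends instead, which appears here as 3'
    C→T). ``rate = mismatches / aligned reference bases of the source
    allele at that distance``.

    Columns: end (5p|3p), position, substitution (CT|GA), rate, depth.
    """
    import pysam

    ref_seqs = dict(read_fasta(reference))
    ct5_num = np.zeros(n_positions, dtype=np.int64)
    ct5_den = np.zeros(n_positions, dtype=np.int64)
    ga3_num = np.zeros(n_positions, dtype=np.int64)
    ga3_den = np.zeros(n_positions, dtype=np.int64)
    ct3_num = np.zeros(n_positions, dtype=np.int64)
    ct3_den = np.zeros(n_positions, dtype=np.int64)

    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.reference_name not in ref_seqs:
                raise ValueError(f"contig {rec.reference_name!r} absent from reference")
            refseg = ref_seqs[rec.reference_name][
                rec.reference_start : rec.reference_start + rec.query_length
            ]
            readseq = rec.query_sequence
            if rec.is_reverse:
                # restore original read orientation
                refseg = revcomp(refseg)
                readseq = revcomp(readseq)
            L = len(readseq)
            for i in range(min(n_positions, L)):
                r5, q5 = refseg[i], readseq[i]
                if r5 == "C":
                    ct5_den[i] += 1
                    if q5 == "T":
                        ct5_num[i] += 1
                r3, q3 = refseg[L - 1 - i], readseq[L - 1 - i]
                if r3 == "G":
                    ga3_den[i] += 1
                    if q3 == "A":
                        ga3_num[i] += 1
                if r3 == "C":
                    ct3_den[i] += 1
                    if q3 == "T":
                        ct3_num[i] += 1

    rows = []
    for i in range(n_positions):
        for end, sub, num, den in (
            ("5p", "CT", ct5_num[i], ct5_den[i]),
            ("3p", "GA", ga3_num[i], ga3_den[i]),
            ("3p", "CT", ct3_num[i], ct3_den[i]),
        ):
            rows.append(
                {
                    "end": end,
                    "position": i,
                    "substitution": sub,
                    "rate": (num / den) if den else np.nan,
                    "depth": int(den),
                }
            )
    return pd.DataFrame(rows)


def fit_exponential_decay(
    positions: np.ndarray, rates: np.ndarray
) -> tuple[float, float, float]:
    """Fit rate(i) = amplitude * exp(-decay * i) + floor; returns (amplitude, decay, floor)."""
    from scipy.optimize import curve_fit

    positions = np.asarray(positions, dtype=float)
    rates = np.asarray(rates, dtype=float)
    ok = np.isfinite(rates)

    def model(x, a, b, c):
        return a * np.exp(-b * x) + c

    p0 = (max(rates[ok].max() - rates[ok].min(), 1e-3), 0.3, max(rates[ok].min(), 0.0))
    popt, _ = curve_fit(model, positions[ok], rates[ok], p0=p0, maxfev=20000)
    return float(popt[0]), float(popt[1]), float(popt[2])


def metrics_table(
    conditions: Mapping[str, tuple[ConfusionCounts, MetricSet]],
) -> pd.DataFrame:
    """One row per named method condition, undefined metrics as NaN."""
    rows = []
    for name, (c, m) in conditions.items():
        rows.append(
            {
                "condition": name,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "precision": math.nan if m.precision is None else m.precision,
                "recall": math.nan if m.recall is None else m.recall,
                "f1": math.nan if m.f1 is None else m.f1,
            }
        )
    return pd.DataFrame(rows)
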
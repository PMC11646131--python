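"""Deterministic toy genomes, taxonomies and scenario configurations.

Real benchmarks of pre-mapping filtering use full genome assemblies; this
module generates desk-scale stand-ins with the same *structure*: a target
species, a within-order sibling sharing exact sequence with it (the
wolf/dingo analog — creates genus-valued LCA k-mers and belongs in the
positive-filter database), a cross-order contaminant carrying *diverged*
copies of target regions (the human-vs-dog analog — the source of
spurious cross-species mappings that filtering should remove), unrelated
cross-order vertebrate contaminants, and a pool of microbial genomes.

Everything is seeded and byte-identical across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seqio import write_fasta
from .taxonomy import TaxonomyTree, taxonomy_from_records

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed taxon ids of the toy taxonomy
ROOT = 1
ORDER_A = 2  # target's order ("Carnivora" analog)
GENUS_A = 3
TARGET = 4
SIBLING = 5  # within-order relative, exact shared ancestry
ORDER_B = 6  # contaminant order ("Primates" analog)
CROSSORDER = 7  # human-analog contaminant with diverged target homology
VERT1 = 8
VERT2 = 9
MICROBE_DOMAIN = 10
MICROBES = (11, 12, 13)


def toy_taxonomy() -> TaxonomyTree:
    records = [
        (ROOT, ROOT, "root", "root"),
        (ORDER_A, ROOT, "order", "Ferricarnivora"),
        (GENUS_A, ORDER_A, "genus", "Canivulpes"),
        (TARGET, GENUS_A, "species", "Canivulpes primus"),
        (SIBLING, GENUS_A, "species", "Canivulpes secundus"),
        (ORDER_B, ROOT, "order", "Simiiformes-like"),
        (CROSSORDER, ORDER_B, "species", "Homo analogus"),
        (VERT1, ORDER_B, "species", "Ovis analogus"),
        (VERT2, ORDER_B, "species", "Bos analogus"),
        (MICROBE_DOMAIN, ROOT, "domain", "Bacteria-like"),
        *[(m, MICROBE_DOMAIN, "species", f"Microbium sp{m}") for m in MICROBES],
    ]
    return taxonomy_from_records(records)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the toy dataset.

    ``shared_fraction`` is the proportion of the sibling genome copied
    verbatim from the target (drives genus-level LCA entries);
    ``crossorder_shared_fraction`` is the proportion of the cross-order
    contaminant copied from the target and then mutated at
    ``crossorder_divergence`` per base (drives spurious mappings that a
    classifier can still separate).
    """

    target_length: int = 40_000
    other_length: int = 20_000
    shared_fraction: float = 0.5
    crossorder_shared_fraction: float = 0.3
    crossorder_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shared_fraction", "crossorder_shared_fraction", "crossorder_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.target_length < 400 or self.other_length < 400:
            raise ValueError("genome lengths must be at least 400 bp")


@dataclass
class Fixture:
    taxonomy: TaxonomyTree
    genomes: dict[int, Path]  # taxon id → FASTA path
    taxonomy_tsv: Path
    scenario_configs: dict[str, Path]
    shared_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    # shared_intervals keys: "target", "sibling" — coordinates of the
    # exact-copy block in each genome (0-based half-open)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    hit = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return out


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> Fixture:
    """Generate taxonomy TSV, per-taxon FASTA files and scenario configs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    tree = toy_taxonomy()

    target = _random_seq(rng, spec.target_length)

    # sibling: exact copy of a target block (same genus — wolf analog)
    sibling = _random_seq(rng, spec.other_length)
    share_len = int(spec.shared_fraction * spec.other_length)
    shared_intervals: dict[str, tuple[int, int]] = {}
    if share_len > 0:
        t_start = int(rng.integers(0, spec.target_length - share_len + 1))
        s_start = int(rng.integers(0, spec.other_length - share_len + 1))
        sibling[s_start : s_start + share_len] = target[t_start : t_start + share_len]
        shared_intervals["target"] = (t_start, t_start + share_len)
        shared_intervals["sibling"] = (s_start, s_start + share_len)
    else:
        t_start = t_end = 0

    # cross-order contaminant: diverged copies of target regions *outside*
    # the sibling-shared block, so its homology is target-private
    crossorder = _random_seq(rng, spec.other_length)
    co_len = int(spec.crossorder_shared_fraction * spec.other_length)
    if co_len > 0:
        lo, hi = shared_intervals.get("target", (0, 0))
        # choose a target window avoiding the sibling-shared block
        free = [(0, lo), (hi, spec.target_length)]
        free = [(a, b) for a, b in free if b - a >= co_len]
        if not free:
            raise ValueError("cannot place cross-order homology outside the shared block")
        a, b = free[int(rng.integers(0, len(free)))]
        c_start = int(rng.integers(a, b - co_len + 1))
        block = _mutate(target[c_start : c_start + co_len], spec.crossorder_divergence, rng)
        x_start = int(rng.integers(0, spec.other_length - co_len + 1))
        crossorder[x_start : x_start + co_len] = block

    genomes_arrays: dict[int, np.ndarray] = {
        TARGET: target,
        SIBLING: sibling,
        CROSSORDER: crossorder,
        VERT1: _random_seq(rng, spec.other_length),
        VERT2: _random_seq(rng, spec.other_length),
    }
    for m in MICROBES:
        genomes_arrays[m] = _random_seq(rng, spec.other_length)

    genome_paths: dict[int, Path] = {}
    for taxid, arr in genomes_arrays.items():
        path = outdir / f"taxon{taxid}.fasta"
        write_fasta(path, [(f"tax{taxid}_contig1", arr.tobytes().decode())])
        genome_paths[taxid] = path

    taxonomy_tsv = outdir / "taxonomy.tsv"
    tree.to_tsv(taxonomy_tsv)

    configs = {
        "scenario1-analog": _scenario_config(
            outdir, genome_paths, name="scenario1-analog",
            fractions={TARGET: 0.05, CROSSORDER: 0.20, VERT1: 0.075, VERT2: 0.075,
                       MICROBES[0]: 0.20, MICROBES[1]: 0.20, MICROBES[2]: 0.20},
        ),
        "scenario2-analog": _scenario_config(
            outdir, genome_paths, name="scenario2-analog",
            fractions={TARGET: 0.20, CROSSORDER: 0.02, VERT1: 0.015, VERT2: 0.015,
                       MICROBES[0]: 0.25, MICROBES[1]: 0.25, MICROBES[2]: 0.25},
        ),
    }
    return Fixture(
        taxonomy=tree,
        genomes=genome_paths,
        taxonomy_tsv=taxonomy_tsv,
        scenario_configs=configs,
        shared_intervals=shared_intervals,
    )


#: components simulated with the ancient (damaged) profile
ANCIENT_TAXA = frozenset({TARGET, *MICROBES})


def _scenario_config(
    outdir: Path,
    genome_paths: dict[int, Path],
    name: str,
    fractions: dict[int, float],
) -> Path:
    """Write one scenario config (YAML). Fractions must sum to 1."""
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name}: fractions sum to {total}")
    cfg = {
        "name": name,
        "taxonomy": str(outdir / "taxonomy.tsv"),
        "read_len": 75,
        "components": [
            {
                "taxon_id": taxid,
                "genome": str(genome_paths[taxid]),
                "fraction": frac,
                "damage": "ancient" if taxid in ANCIENT_TAXA else "none",
            }
            for taxid, frac in fractions.items()
        ],
        "databases": {
            "positive": {"k": 29, "taxa": [TARGET, SIBLING]},
            "negative": {"k": 35, "taxa": [TARGET, SIBLING, CROSSORDER, VERT1, VERT2, *MICROBES]},
        },
        "filter_clade": ORDER_A,
        "endogenous_clade": ORDER_A,
        "target_taxon": TARGET,
        "competitive_taxa": [TARGET, CROSSORDER],
        "genomes": {str(t): str(p) for t, p in genome_paths.items()},
    }
    path = outdir / f"{name}.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
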
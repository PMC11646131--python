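"""End-to-end benchmark workflow: simulate → prep → classify → filter →
map → evaluate.

One scenario config drives all six method conditions reported by the
benchmark: mapping only, competitive mapping, positive filtering, negative
filtering, and each filtering strategy combined with competitive mapping.
Since filtering only ever subsets the read set, each read is mapped once
per reference (single and composite) and the six conditions are scored by
intersecting retained sets with the two alignment tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import classifier, filter_eval, mapper, readprep, simulate
from .filter_eval import ConfusionCounts, FilterPolicy, MetricSet
from .taxonomy import TaxonomyTree, load_taxonomy

log = logging.getLogger("paleosieve")

CONDITIONS = (
    "map_only",
    "competitive",
    "positive",
    "positive_competitive",
    "negative",
    "negative_competitive",
)


@dataclass
class WorkflowResult:
    outdir: Path
    metrics: pd.DataFrame  # one row per condition
    counts: dict[str, int]  # stage conservation counters
    by_condition: dict[str, tuple[ConfusionCounts, MetricSet]]


def load_scenario(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("components", "databases", "filter_clade", "endogenous_clade", "target_taxon"):
        if key not in cfg:
            raise ValueError(f"scenario config missing {key!r}")
    return cfg


def run_workflow(
    config: dict | str | Path,
    outdir: str | Path,
    n_pairs: int = 50_000,
    seed: int = 0,
    mapq_threshold: int = 20,
    filtering: bool = True,
) -> WorkflowResult:
    """Execute the full benchmark for one scenario configuration."""
    if not isinstance(config, dict):
        config = load_scenario(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    taxonomy = load_taxonomy(config["taxonomy"])
    counts: dict[str, int] = {}

    # -- simulate -----------------------------------------------------------
    damage_profiles = {
        "ancient": simulate.DEFAULT_ANCIENT_DAMAGE,
        "none": None,
    }
    components = [
        simulate.MixtureComponent(
            taxon_id=int(c["taxon_id"]),
            genome=c["genome"],
            fraction=float(c["fraction"]),
            damage=damage_profiles[c.get("damage", "none")],
        )
        for c in config["components"]
    ]
    cfg = simulate.ReadSimConfig(
        n_pairs=n_pairs, read_len=int(config.get("read_len", 75)), seed=seed
    )
    r1, r2, truth_path = simulate.simulate_dataset(components, cfg, outdir / "sim")
    truth = filter_eval.load_truth(truth_path)
    counts["simulated_pairs"] = len(truth)
    log.info("simulate: %d pairs (seed %d)", len(truth), seed)

    # -- prep ---------------------------------------------------------------
    merged = readprep.prep_file(
        r1, r2, (cfg.adapter1, cfg.adapter2), out=outdir / "merged.fastq.gz"
    )
    counts["merged_reads"] = len(merged)
    log.info("prep: %d/%d pairs merged and retained", len(merged), len(truth))

    # -- classification databases ------------------------------------------
    genome_by_taxon = {int(t): p for t, p in config["genomes"].items()}
    retained_sets: dict[str, set[str]] = {"none": {m.read_id for m in merged}}
    if filtering:
        for strategy in ("positive", "negative"):
            db_cfg = config["databases"][strategy]
            db = classifier.build_database(
                [(genome_by_taxon[int(t)], int(t)) for t in db_cfg["taxa"]],
                taxonomy,
                k=int(db_cfg["k"]),
            )
            results = [
                classifier.classify_read(db, m.sequence, read_id=m.read_id) for m in merged
            ]
            classifier.write_classifications(
                results, [len(m.sequence) for m in merged],
                outdir / f"classifications.{strategy}.tsv",
            )
            policy = FilterPolicy(strategy=strategy, clade_root=int(config["filter_clade"]))
            retained, removed = filter_eval.apply_filter(
                ((r.status, r.read_id, r.taxon_id or 0) for r in results), policy, taxonomy
            )
            retained_sets[strategy] = retained
            counts[f"retained_{strategy}"] = len(retained)
            log.info(
                "filter %s (clade %s, k=%d): retained %d removed %d",
                strategy, config["filter_clade"], db.k, len(retained), len(removed),
            )

    # -- mapping ------------------------------------------------------------
    target_taxon = int(config["target_taxon"])
    single_index = mapper.build_index([(genome_by_taxon[target_taxon], "target")])
    competitive_sources = [
        (genome_by_taxon[int(t)], "target" if int(t) == target_taxon else f"tax{t}")
        for t in config.get("competitive_taxa", [target_taxon])
    ]
    competitive_index = mapper.build_index(competitive_sources)

    mapper.map_file(single_index, merged, outdir / "single.sam", mode="single")
    mapper.map_file(
        competitive_index, merged, outdir / "competitive.sam",
        mode="competitive", target_label="target",
    )
    sam_single = filter_eval.load_sam_records(outdir / "single.sam")
    sam_comp = filter_eval.load_sam_records(outdir / "competitive.sam")
    counts["mapped_single"] = len(sam_single)
    counts["mapped_competitive"] = len(sam_comp)
    comp_labels = {name: label for name, _seq, label in competitive_index.contigs}

    # -- evaluation ---------------------------------------------------------
    endog_clade = int(config["endogenous_clade"])
    plan = {
        "map_only": ("none", sam_single, None),
        "competitive": ("none", sam_comp, "target"),
        "positive": ("positive", sam_single, None),
        "positive_competitive": ("positive", sam_comp, "target"),
        "negative": ("negative", sam_single, None),
        "negative_competitive": ("negative", sam_comp, "target"),
    }
    by_condition: dict[str, tuple[ConfusionCounts, MetricSet]] = {}
    for name, (which, sam, target_label) in plan.items():
        if which not in retained_sets:
            continue
        c = filter_eval.categorize(
            truth, retained_sets[which], sam, taxonomy, endog_clade,
            mapq_threshold=mapq_threshold,
            contig_labels=comp_labels if target_label else None,
            target_label=target_label,
        )
        by_condition[name] = (c, filter_eval.metrics(c))
    table = filter_eval.metrics_table(by_condition)
    table.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    return WorkflowResult(outdir=outdir, metrics=table, counts=counts, by_condition=by_condition)
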
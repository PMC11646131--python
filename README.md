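# paleosieve

Pre-mapping metagenomic filtering for ancient DNA, as a self-contained,
fully testable toolkit.

Ancient DNA libraries are dominated by exogenous sequences — environmental
microbes, handler DNA, reagent contamination, related vertebrate species —
and some of those contaminant reads align convincingly to the target
reference genome, especially when fragments are short and the contaminant
is a close relative. `paleosieve` implements and benchmarks the strategy of
removing contaminants *before* mapping with a k-mer/LCA taxonomic
classifier, instead of relying on mapping specificity alone:

* **positive filtering** — classify reads against a small database of the
  target taxon and its close relatives (k-mer 29) and map *only classified
  reads* that fall at the target's order or below;
* **negative filtering** — classify against a comprehensive database of
  target plus contaminant genomes (k-mer 35) and remove reads classified
  *outside* the target clade, keeping unclassified reads;
* **competitive mapping** — align against a composite target+contaminant
  reference and keep only reads whose best hit lands on the target.

"At the order or below" is implemented as taxonomy subtree membership, not
rank-name comparison.

Everything needed to study these strategies end to end is included:

| module | what it does |
| --- | --- |
| `taxonomy` | NCBI-dmp/TSV taxonomy trees, LCA, clade membership |
| `classifier` | exact canonical k-mer → LCA database, Kraken-style read classification, ALT-allele consensus augmentation |
| `simulate` | paired-end aDNA simulator: truncated-lognormal fragments, exponential-decay deamination, adapter read-through, per-read truth |
| `readprep` | adapter trimming + overlap merging (minlength 30, minquality 20) |
| `mapper` | deterministic seed-and-extend mapper, single or competitive composite reference, SAM output |
| `filter_eval` | filtering policies, TP/FP/TN/FN categorisation, precision/recall/F1 (also length-stratified), terminal misincorporation profiles |
| `popgen` | pseudo-haploid calls, f4 with weighted block-jackknife Z, reference-bias verdict |
| `fixtures` / `workflow` | deterministic toy genomes + scenario configs, one-command benchmark of all six method conditions |

The statistics, in the field's notation:

```
Precision = TP / (TP + FP)        Recall = TP / (TP + FN)
F1 = 2·P·R / (P + R)
f4(A, B; C, D) = mean over sites of (pA − pB)(pC − pD),  Z = f4 / SE_blockjackknife
```

A read is a TP when it is endogenous (truth taxon inside the target
clade), survived filtering, and mapped to the target with MapQ > 20; reads
lost in read prep or filtering charge recall.

## Worked example

```bash
paleosieve make-fixture --out fx --seed 1
paleosieve run --config fx/scenario1-analog.yaml --n-pairs 50000 --seed 2 --out run1
```

The scenario-1 analog mixes 5% endogenous (ancient, damaged), 20%
cross-order relative contamination with diverged target homology, 15%
other vertebrates, and 60% microbial reads. A run at 50 000 pairs prints a
table like:

```
           condition   tp   fp    tn  fn  precision  recall       f1
            map_only 2486 1941 45559  14   0.561554  0.9944 0.717771
         competitive 2403    0 47500  97   1.000000  0.9612 0.980216
            positive 2410 1305 46195  90   0.648721  0.9640 0.775543
positive_competitive 2330    0 47500 170   1.000000  0.9320 0.964803
            negative 2470  137 47363  30   0.947449  0.9880 0.967300
negative_competitive 2402    0 47500  98   1.000000  0.9608 0.980008
```

Reading it: mapping alone accepts ~1900 contaminant alignments
(precision 0.56) because reads from the diverged relative still align
within the mapper's mismatch budget. Both filtering strategies remove a
large share of those before mapping — negative filtering almost all of
them (precision 0.95) at a 1.2-point recall cost, positive filtering a
smaller share (its small database cannot reject homologous reads that
carry exact target k-mers) at a 3-point cost. Competitive mapping resolves
the rest, because those reads match their own genome better than the
target.

The same machinery is scriptable from Python:

```python
from paleosieve.fixtures import FixtureSpec, make_fixture
from paleosieve.workflow import run_workflow

fx = make_fixture(FixtureSpec(seed=1), "fx")
res = run_workflow(fx.scenario_configs["scenario1-analog"], "run1",
                   n_pairs=50_000, seed=2)
print(res.metrics)
```

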
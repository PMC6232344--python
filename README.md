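# herbnet

Network-pharmacology analysis of multi-ingredient herbal prescriptions:
from a compound catalog to screened candidates, compound–target networks,
pathway over-representation, and factorial analysis of compound-combination
bioassays.

The package grew around the analysis of the eight-ingredient Liangxue
Tongyu prescription (LP) against intracerebral hemorrhage (ICH), and ships
that study's candidate-compound table and factorial OD450 plate summaries
as reference fixtures — but every stage is generic and driven by plain
TSV/GMT/YAML inputs.

## What it computes

**Screening.** A compound is *drug-like* if its molecular-property vector
*a* resembles the average property vector *b* of approved drugs, measured
by Tanimoto similarity

```
f(a, b) = a·b / (|a|² + |b|² − a·b)   ∈ [0, 1]
```

The screen keeps compounds with oral bioavailability OB ≥ 30% and
drug-likeness DL ≥ 0.1 (both inclusive); compounds failing the rule can be
*rescued* by literature evidence (an explicit whitelist or per-compound
evidence flag) rather than by rule.

**Networks.** Compound–target (C-T) networks are undirected bipartite
graphs between compounds and official gene symbols; the P-T-D extension
annotates targets with pathology categories (inflammation, apoptosis,
coagulation, …). Reported statistics are degree bookkeeping: node/edge
counts, per-node degree, mean compound degree, and per-category target
fractions (half-up rounding to two decimals).

**Enrichment.** Over-representation of a query gene list (size *n*) against
a gene-set catalog over a universe of *N* genes uses the upper-tail
hypergeometric probability P(X ≥ k) of the realized overlap *k* with each
term (size *K*), Benjamini–Hochberg adjustment, and then groups significant
terms by Cohen's kappa agreement of their gene memberships (threshold 0.4,
connected components; each group led by its most significant term).

**Factorial combination analysis.** A 2^k two-level design over k compounds
is analyzed by contrast algebra: for each term T,
`contrast(T) = Σ_cells (∏ coded signs) · cell mean`,
`effect(T) = contrast(T)/2^(k−1)`, `SS(T) = n·contrast(T)²/2^k`, with a
pooled within-cell error `SS_within = Σ (n−1)·sd²` on `2^k(n−1)` df. This
reconstruction from published (n, mean, ±sd) cell summaries is exactly the
classical replicate-level ANOVA for any balanced design, so printed tables
can be re-analyzed without raw data.

**Synthetic data.** Seeded generators produce every input the pipeline
consumes — compound libraries, bipartite edges, gene-set catalogs with
planted enriched terms, and factorial plates with planted effects — so all
statistical behaviour (type-I error, power, recovery) is testable offline.

## Worked example

```python
import herbnet as hn
from herbnet import datasets
import pandas as pd

# 1. screen the packaged 32-compound candidate table (+ 2 animal compounds)
table = hn.CompoundTable(pd.concat(
    [datasets.load_potential_compounds().df, datasets.load_animal_compounds().df],
    ignore_index=True))
res = hn.screen_compounds(table, ob_min=30, dl_min=0.1,
                          whitelist=datasets.rescue_whitelist())
print(len(res.passed), len(res.rescued), len(res.potential))
# 22 12 34
#   -> 22 compounds meet OB>=30 and DL>=0.1 outright; 12 more are rescued by
#      literature evidence, giving 34 potential compounds.

# 2. factorial ANOVA of the Taurine/Paeonol/Geniposide OD450 block
design, frame = datasets.load_factorial_block("taurine")
anova = hn.anova_from_summary(design, frame, dispersion_is="sd")
row = anova.term("Taurine", "Paeonol")
print(f"effect {row['effect']:.4f}  F {row['F']:.2f}  p {row['p']:.4f}")
# effect -0.0665  F 9.49  p 0.0042
#   -> a first-order Taurine x Paeonol interaction, negative (the combined
#      high doses lower OD450 more than additivity predicts), p < 0.01.

# 3. category fractions of an annotated target set
print(hn.category_fraction(681, 1436))   # 47.42  (% of disease genes)
```

The same stages are scriptable from a shell:

```
herbnet screen compounds.tsv --ob-min 30 --dl-min 0.1 --whitelist ids.txt
herbnet network build edges.tsv --annotate categories.tsv --export graphml --out net.graphml
herbnet enrich query.txt --gmt catalog.gmt --alpha 0.05 --kappa 0.4
herbnet factorial cells.tsv --dispersion sd --alpha 0.01
herbnet simulate catalog --seed 17 --out sim/
```

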
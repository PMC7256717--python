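# acurules

Association-rule mining of acupoint prescriptions, treating each clinical
study's acupuncture prescription as a market-basket transaction. The package
was built around a concrete question from complementary-medicine research on
chronic obstructive pulmonary disease (COPD): across the randomized
controlled trials of acupuncture for stable COPD, which acupoints are
habitually prescribed *together*, and which combinations form the core of the
therapy? It ships the 12-trial COPD prescription table as a bundled fixture,
so the entire analysis is reproducible from a fresh install with one command.

It is aimed at researchers doing treatment-combination analyses of
prescription data (acupoints, herbs, drug co-prescriptions): anything that
reduces to small transaction databases over modest item universes.

## The method

Each study *i* contributes a transaction `T_i ⊆ U`, the set of acupoint codes
in its prescription (`U` is the item universe; codes follow the WHO standard,
e.g. `BL13`, `ST36`, `CV17`). For itemsets `X, Y ⊆ U` with `X ∩ Y = ∅`, the
rule `X ⇒ Y` is scored by four values, all computed here as exact rationals
of transaction counts:

- **support** `supp(X ⇒ Y) = P(X ∪ Y)` — fraction of transactions containing
  both sides;
- **confidence** `conf(X ⇒ Y) = P(Y | X) = supp(X ∪ Y) / supp(X)`;
- **expected confidence** `P(Y)` — the confidence the rule would have if `X`
  told you nothing about `Y`;
- **lift** `conf / P(Y)` — 1 under independence, symmetric in `X` and `Y`.

Frequent itemsets are found with the classic level-wise Apriori algorithm
(downward-closure pruning, bitset counting, exact `count/n ≥ min_support`
comparison so threshold boundaries are inclusive and float-free). Rules are
every split of a frequent itemset into an antecedent and a fixed-size
consequent that meets the confidence threshold. Defaults mirror the R
`arules` stack this kind of analysis is usually run in: `min_support = 0.2`,
`min_confidence = 0.8`, single-item consequents, rules up to 5 items, empty
antecedents permitted (a `{} ⇒ {Y}` rule is just `Y`'s marginal support).

A deliberately naive brute-force enumerator (`brute_force_frequent`) serves
as an oracle in the test suite, and a planted-core synthetic generator
(`PlantedModel` / `generate_db`) provides databases with known structure for
calibration and recovery checks.

## Worked example

```python
from acurules import (MiningParams, load_fixture, mine_rules,
                      rank_rules, count_rules)

db = load_fixture()
print(db.n, len(db.universe))          # 12 27

ruleset = mine_rules(db, MiningParams())
print(count_rules(ruleset))            # 2444

pairwise = mine_rules(db, MiningParams(max_len=2, min_antecedent_size=1))
for r in rank_rules(pairwise, 3):
    print(r, float(r.support), float(r.confidence), float(r.lift))
# {BL23} => {BL13} 0.75 1.0 1.2
# {BL13} => {BL23} 0.75 0.9 1.2
# {CV17} => {ST36} 0.6666666666666666 1.0 1.3333333333333333
```

Reading: 12 trials use 27 distinct acupoints; 2444 rules clear the
support/confidence thresholds under the default convention. Among rules
between individual acupoints, every trial prescribing BL23 also prescribed
BL13 (confidence 1.0), and the pair co-occurs in 9 of 12 trials (support
0.75) — 1.2 times as often as independence would predict (lift 1.2).
Composite rules such as `{ST36,BL12} ⇒ {CV17}` (confidence 5/6) and
`{EXB1,BL12} ⇒ {ST36}` (confidence 1) are retrieved with
`ruleset.get({"ST36","BL12"}, {"CV17"})` or `query_rules`.

The same analysis from a shell:

```sh
acurules mine --fixture --out-dir out --summary-json
# {"n_transactions": 12, "n_items": 27, "n_itemsets": 779, "n_rules": 2444, ...}
```

which writes `frequencies.csv`, `itemsets.csv`, `rules.csv`, `scatter.csv`,
`top_rules.csv` and `grouped_rules.json` under `out/`. `acurules freq`,
`acurules simulate` (planted-core synthesis + recovery report) and
`acurules export` (dialect conversion) cover the rest of the workflow.

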
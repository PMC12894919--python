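# co2fix

Rule-based prediction of the seven known natural CO₂ fixation pathways in
microbial genomes, from KEGG Orthology (KO) profiles.

## The problem

Autotrophic CO₂ fixation runs through seven characterized pathways — the
Calvin–Benson–Bassham cycle (CBB), the reductive TCA cycle (rTCA), the
Wood–Ljungdahl pathway (WL), the 3-hydroxypropionate bicycle (3HP), the
3-hydroxypropionate/4-hydroxybutyrate cycle (3HP/4HB), the
dicarboxylate/4-hydroxybutyrate cycle (DC/4HB), and the reductive glycine
pathway (rGly). Deciding which of them a genome (or metagenome-assembled
genome) encodes is awkward: pathways come in mechanistically distinct
variants with different enzymes, and some genes are shared across pathways.
`co2fix` targets microbiologists and metagenomicists who want an
interpretable first-pass screen for autotrophic potential from ordinary KO
annotation.

## The model

Each pathway is a small boolean formula over marker KOs:

* **clause** — a quantifier over KO ids:
  * `one_of(K…)` — any one suffices (evolutionarily distinct enzymes for
    the same reaction, e.g. the three fumarate-hydratase KOs in DC/4HB);
  * `all_of(K…)` — all required (multi-subunit complexes, e.g. the
    five-subunit archaeal CODH/ACS complex in WL-II);
  * `at_least(k of n)` — a subunit quorum (e.g. rGly requires ≥3 of 4
    glycine cleavage system KOs and ≥5 of 7 glycine reductase KOs);
* **variant** — a conjunction of clauses (e.g. `rTCA-I` vs `rTCA-II`);
* **pathway** — present iff at least one variant is satisfied.

A genome's KO profile is a plain set of K##### identifiers, read from a
one-KO-per-line list or from KofamScan detail-TSV output using the adaptive
threshold rule (starred hits are assigned; a gene with no hit above
threshold contributes its single top-scoring KO). The built-in rule set
covers all seven pathways with 42 distinct marker KOs (per-pathway census
3, 5, 7, 3, 7, 7, 11) and ships as editable JSON.

Calls are strictly binary: no completeness scores, no flux directionality.
Presence of markers means genetic potential, not active autotrophy.

## Worked example

```python
from co2fix import KOProfile, builtin_ruleset, predict

rules = builtin_ruleset()
profile = KOProfile("calvin_organism", frozenset({"K00855", "K01601", "K01783"}))
pred = predict(profile, rules)
print([p for p, c in pred.calls.items() if c])   # ['CBB']

rhp = KOProfile("rhp_like_archaeon", frozenset({"K00855", "K01601"}))
print(predict(rhp, rules).calls["CBB"])          # False
```

The first genome carries phosphoribulokinase (K00855), the RubisCO large
subunit (K01601) and ribulose-phosphate 3-epimerase (K01783) — the full CBB
marker set. The second carries only PRK + RubisCO, the signature shared
with the archaeal reductive hexulose-phosphate (RHP) pathway, so it is
deliberately **not** called CBB.

The same is available from the shell:

```sh
$ co2fix validate-rules
CBB: 3 unique KOs (1 variant(s))
rTCA: 5 unique KOs (2 variant(s))
...
shared: K14534 appears in 3HP4HB, DC4HB
OK: 7 pathways, 42 distinct marker KOs

$ co2fix predict genomeA.txt            # one KO per line
genome_id	CBB	rTCA	WL	3HP	3HP4HB	DC4HB	rGly
genomeA	1	0	0	0	0	0	0
```

Subcommands: `predict`, `parse-kofamscan`, `validate-rules`, `benchmark`
(per-pathway precision/recall/F1 of one or more tools' binary matrices
against curated labels), and `simulate` (seeded synthetic corpora with
known truth). See `examples/` for narrative scripts covering each
capability, including a full simulate → predict → benchmark loop.

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch: it builds
seeded synthetic corpora with the built-in rules, checks the marker-KO
census, verifies noise-free corpora are recovered with perfect
precision/recall/F1, verifies precision stays perfect under marker dropout,
and round-trips a mock KofamScan TSV. Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
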
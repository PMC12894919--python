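# Methods

## Prediction model

A pathway call is the evaluation of a fixed boolean formula over the
genome's KO set. Three quantifiers express the biology:

* `one_of` — phylogenetically distinct enzymes catalysing the same
  reaction carry different KO ids; any one is sufficient evidence for the
  reaction (DC/4HB's fumarate hydratase K01676/K01677/K01678 and
  4-hydroxybutyrate-CoA ligase K18861/K14467).
* `all_of` — multi-subunit complexes are required in full (e.g. the
  ATP-citrate lyase pair K15230+K15231 for rTCA-I; the archaeal CODH/ACS
  subunits for WL-II).
* `at_least(k of n)` — where individual subunit essentiality is uncertain
  a quorum is required instead; rGly uses ≥3 of the 4 glycine cleavage
  system KOs and ≥5 of the 7 glycine reductase subunit KOs.

A **variant** (a mechanistic form such as rTCA-I vs rTCA-II, bacterial vs
archaeal WL) is the conjunction of its clauses; a **pathway** is present
iff any variant is satisfied. Consequences worth knowing:

* All quantifiers are monotone in the profile, so the predictor is
  monotone: adding annotation can only add calls. This is load-bearing for
  the synthetic-noise analysis below.
* Calls are binary. There is no partial-completeness score, and evidence
  (which variants fired, which marker KOs matched) is reported alongside
  the calls as an explanatory extra, not as a confidence measure.
* The rule set cannot discriminate pathways that lack unique markers by
  construction: a reversible TCA cycle running on ordinary citrate synthase
  is out of scope, and the CBB rules deliberately require
  ribulose-phosphate 3-epimerase so that the PRK+RubisCO pair alone (also
  the reductive hexulose-phosphate signature) is not called CBB.

### Built-in rule set

Seven pathways, 42 distinct marker KOs, census 3 (CBB), 5 (rTCA), 7 (WL),
3 (3HP), 7 (3HP/4HB), 7 (DC/4HB), 11 (rGly). Exactly one KO — K14534,
4-hydroxybutanoyl-CoA dehydratase — is shared between two pathways
(3HP/4HB and DC/4HB); the validator reports shared KOs without rejecting
them. Machine-readable pathway ids use slash-free tokens (`3HP4HB`,
`DC4HB`); display names keep the conventional slashes. Pathways whose
definition has a single form are modelled as one variant whose id equals
the pathway id.

The set is stored as JSON (`src/co2fix/data/co2_fixation_rules.json`) in a
schema validated by a hand-written loader that reports the JSON path of any
violation. Serialization is canonical (stable key and list order), so
serialize → load → serialize is byte-stable and rule files diff cleanly.

## KofamScan ingestion

Only the detail-TSV layout is supported (significance mark, gene, KO,
adaptive threshold, bit score, E-value, definition): it is the only
KofamScan output carrying the threshold and score the assignment rule
needs. Assignment is per gene: every starred (above-threshold) hit
contributes its KO; a gene with hits but none starred contributes exactly
one fallback KO — its top-scoring hit, with ties broken by lowest E-value,
then lexicographically smallest KO id (the tie order is a package choice;
some total order is required for determinism). A "-" threshold is treated
as never significant, hence fallback-eligible. If a file carries no
asterisks at all it is assumed to come from a dialect without significance
marks and significance is recomputed as score > threshold; this is exact
for well-formed detail TSVs, where the star encodes precisely that
comparison. Profiles are sets — copy number is discarded because no rule
uses it. An upstream curation step (excluding KOs judged unrelated to a
pathway) is human judgement and is not mechanised; users can simply omit
such KOs from their lists.

## Benchmarking

Predictions and curated labels are binary genome × pathway matrices joined
by genome id (rows present in only one matrix are dropped and logged —
positional joins are unsafe). Per pathway: TP/FP/FN/TN, precision
TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean. Zero denominators
score 0 rather than NaN, and a pathway absent from a tool's matrix is
scored 0 with `supported=false`; the same convention is applied uniformly
so tools are comparable. True negatives are computed although the headline
metrics ignore them; they cost nothing and enable specificity extensions.
Mapping third-party tools' native outputs (e.g. MetaCyc pathway ids) onto
the seven columns is left to user-prepared matrices.

## Synthetic corpora

The generator emulates a labelled benchmark corpus without any downloads.
Per pathway it emits:

* **positives** — the minimal canonical profile of a variant (all `all_of`
  KOs, the first `one_of` KO, the first `min_count` KOs of an `at_least`),
  plus `background_k` decoy KOs, then each *marker* KO independently
  deleted with probability `dropout_p`;
* **near-miss negatives** — the minimal profile with one critical KO
  removed, chosen so the whole pathway (not just the variant) turns off;
* **multi-pathway genomes** — unions of two satisfying profiles
  (CBB+WL and WL+rGly by default, mirroring real co-occurrences).

Defaults: `n_per_pathway=50` replicates per variant, `variant_choice="all"`
(so second variants such as rTCA-II, WL-II and 3HP/4HB-II are exercised,
not just the first), `dropout_p=0` (noise is opt-in), `background_k=20`
decoys per genome, `negatives_per_pathway=10`, five combo genomes per pair.
Decoys are drawn from K90000–K90999, outside real KOfam space, guaranteeing
disjointness from every marker KO without consulting KEGG.

Two deliberate properties make the corpus a sharp test instrument:

* Truth labels record the **intended** pathway before dropout, so dropout
  degrades recall but can never touch precision — the two metrics are
  isolated.
* With `dropout_p=0`, predictions reproduce truth exactly and every metric
  is 1; any regression in the engine shows up as a clean diff.

The expected recall under dropout has a closed form. For a genome whose
marker set is M and dropout probability p, the detection probability is
computed by exact enumeration over surviving subsets of M (M is small —
at most 8 KOs for minimal profiles). For a purely conjunctive variant of m
markers this reduces to (1−p)^m; for an `at_least(k of n)` clause with all
n markers present, to the Binomial(n, 1−p) upper tail. Enumeration is used
rather than the per-clause product because clauses may share KOs, where the
product is only approximate. The acceptance suite checks observed
per-variant recall at 500 replicates against this closed form within 3
binomial standard errors (a ~0.3% false-alarm rate per variant by
construction).

What a green synthetic test does **not** establish: performance on real
genomes. The generator does not simulate protein sequences, realistic HMM
score distributions, annotation cross-talk between homologous families, or
any correlation structure in gene loss; its dropout is independent per KO.
It validates the engine's logic and the benchmark plumbing, not the
biological adequacy of the marker definitions.

## Numerical and design choices

* Determinism: every stochastic component takes an explicit seed or
  `numpy.random.Generator`; the same (config, rules, seed) reproduces a
  corpus byte for byte. Seeds are kept below 2^31.
* Evaluation is order-independent; rule order only fixes serialization and
  the order of evidence lists and matrix columns.
* Duplicate genome ids are rejected in batch prediction and matrix
  parsing; malformed KO tokens in KO lists are skipped with a warning
  (non-fatal), while malformed TSV rows are fatal with a line number.
* CLI exit codes: 0 success, 1 input/validation error, 2 usage error.
  Logs go to stderr, data to stdout or `--output`.

## Known limitations

* The marker set is a fixed transcription of a curated table; no automatic
  derivation from KEGG modules, and no modelling of hybrid WL forms mixing
  bacterial and archaeal CODH/ACS subunits (rGly's acetyl-CoA-route
  auxiliary markers are likewise not enumerated in the source table and are
  not included).
* Genome incompleteness is modelled only as independent per-KO dropout.
* Binary presence ≠ activity: reversible pathways (notably WL) can run in
  either direction; no flux inference is attempted.
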
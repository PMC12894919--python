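"""Predict CO2 fixation pathways for a few hand-built KO profiles.

Builds three small genomes — a Calvin-cycle organism, one carrying only the
RubisCO/PRK pair (the RHP signature, deliberately NOT called as CBB), and an
acetogen-style Wood-Ljungdahl genome — and prints the binary call matrix.
"""

from co2fix import KOProfile, builtin_ruleset, matrix_to_tsv, predict_batch

rules = builtin_ruleset()

profiles = [
    KOProfile("calvin_organism", frozenset({"K00855", "K01601", "K01783"})),
    KOProfile("rhp_like_archaeon", frozenset({"K00855", "K01601"})),
    KOProfile("acetogen", frozenset({"K00198", "K14138", "K90001", "K90002"})),
]

result = predict_batch(profiles, rules)
print(matrix_to_tsv(result.matrix))
for pred in result.predictions:
    satisfied = {p: list(v) for p, v in pred.evidence.items() if v}
    print(f"{pred.genome_id}: satisfied variants {satisfied or 'none'}")

# A 1 in the matrix means at least one variant of that pathway's marker rules
# is satisfied by the genome's KO set.  The RHP-like genome stays all-zero
# because ribulose-phosphate 3-epimerase (K01783) is required to call CBB,
# and the acetogen's two decoy KOs (K9xxxx) are ignored.
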
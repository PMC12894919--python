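"""Turn KofamScan detail-TSV output into a KO profile and predict from it.

Shows the two assignment rules: hits starred as exceeding the adaptive
threshold all contribute their KO, while a gene with only sub-threshold
hits contributes exactly one KO — that of its top-scoring hit.
"""

from co2fix import assign_kos, builtin_ruleset, parse_kofam_tsv, predict

KOFAM_TSV = """\
# gene name\tKO\tthresholds\tscore\tE-value\tKO definition
*\tgene_001\tK00855\t120.3\t250.1\t1e-50\tphosphoribulokinase
*\tgene_002\tK01601\t200.0\t310.5\t1e-80\tRuBisCO large subunit
*\tgene_003\tK01783\t90.0\t150.2\t1e-40\tribulose-phosphate 3-epimerase
\tgene_004\tK03671\t100.0\t35.0\t1e-03\tthioredoxin (sub-threshold)
\tgene_004\tK00384\t100.0\t48.0\t1e-05\tthioredoxin reductase (sub-threshold)
"""

hits = parse_kofam_tsv(KOFAM_TSV)
profile = assign_kos(hits, genome_id="example_genome")
print(f"assigned KOs: {sorted(profile.kos)}")

calls = predict(profile, builtin_ruleset()).calls
print("pathways present:", [p for p, c in calls.items() if c])

# gene_004 has two sub-threshold hits; only the top scorer (K00384, 48.0
# bits) is assigned.  The three starred genes complete the CBB marker set,
# so the genome is called CBB-positive.
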
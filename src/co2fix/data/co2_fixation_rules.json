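{
  "version": "1.0",
  "pathways": [
    {
      "pathway_id": "CBB",
      "display_name": "Calvin-Benson-Bassham cycle",
      "variants": [
        {
          "variant_id": "CBB",
          "clauses": [
            {"quantifier": "all_of", "kos": ["K00855"]},
            {"quantifier": "all_of", "kos": ["K01601"]},
            {"quantifier": "all_of", "kos": ["K01783"]}
          ]
        }
      ]
    },
    {
      "pathway_id": "rTCA",
      "display_name": "reductive tricarboxylic acid cycle",
      "variants": [
        {
          "variant_id": "rTCA-I",
          "clauses": [
            {"quantifier": "all_of", "kos": ["K15230", "K15231"]}
          ]
        },
        {
          "variant_id": "rTCA-II",
          "clauses": [
            {"quantifier": "all_of", "kos": ["K15233", "K15232"]},
            {"quantifier": "all_of", "kos": ["K15234"]}
          ]
        }
      ]
    },
    {
      "pathway_id": "WL",
      "display_name": "Wood-Ljungdahl pathway",
      "variants": [
        {
          "variant_id": "WL-I",
          "clauses": [
            {"quantifier": "all_of", "kos": ["K00198"]},
            {"quantifier": "all_of", "kos": ["K14138"]}
          ]
        },
        {
          "variant_id": "WL-II",
          "clauses": [
            {"quantifier": "all_of", "kos": ["K00192", "K00195"]},
            {"quantifier": "all_of", "kos": ["K00193", "K00194", "K00197"]}
          ]
        }
      ]
    },
    {
      "pathway_id": "3HP",
      "display_name": "3-hydroxypropionate bicycle",
      "variants": [
        {
          "variant_id": "3HP",
          "clauses": [
            {"quantifier": "all_of", "kos": ["K14468"]},
            {"quantifier": "all_of", "kos": ["K14471", "K14472"]}
          ]
        }
      ]
    },
    {
      "pathway_id": "3HP4HB",
      "display_name": "3-hydroxypropionate/4-hydroxybutyrate cycle",
      "variants": [
        {
          "variant_id": "3HP4HB-I",
          "clauses": [
            {"quantifier": "all_of", "kos": ["K15017"]},
            {"quantifier": "all_of", "kos": ["K15039"]},
            {"quantifier": "all_of", "kos": ["K14534"]}
          ]
        },
        {
          "variant_id": "3HP4HB-II",
          "clauses": [
            {"quantifier": "all_of", "kos": ["K18603", "K18604", "K18605"]},
            {"quantifier": "all_of", "kos": ["K18602"]},
            {"quantifier": "all_of", "kos": ["K14534"]}
          ]
        }
      ]
    },
    {
      "pathway_id": "DC4HB",
      "display_name": "dicarboxylate/4-hydroxybutyrate cycle",
      "variants": [
        {
          "variant_id": "DC4HB",
          "clauses": [
            {"quantifier": "all_of", "kos": ["K01595"]},
            {"quantifier": "one_of", "kos": ["K01676", "K01677", "K01678"]},
            {"quantifier": "one_of", "kos": ["K18861", "K14467"]},
            {"quantifier": "all_of", "kos": ["K14534"]}
          ]
        }
      ]
    },
    {
      "pathway_id": "rGly",
      "display_name": "reductive glycine pathway",
      "variants": [
        {
          "variant_id": "rGly",
          "clauses": [
            {"quantifier": "at_least", "kos": ["K00283", "K00282", "K02437", "K00605"], "min_count": 3},
            {"quantifier": "at_least", "kos": ["K10671", "K10672", "K00384", "K21577", "K21576", "K03671", "K10670"], "min_count": 5}
          ]
        }
      ]
    }
  ]
}
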
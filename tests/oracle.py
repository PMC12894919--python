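"""Hand-coded boolean oracle for the seven pathways.

Each function is a direct transcription of the marker logic as plain Python
set expressions, written independently of the rule engine so the two can be
checked against each other on arbitrary KO subsets.
"""

GLYCINE_CLEAVAGE = {"K00283", "K00282", "K02437", "K00605"}
GLYCINE_REDUCTASE = {"K10671", "K10672", "K00384", "K21577", "K21576", "K03671", "K10670"}


def cbb(s: set) -> bool:
    return {"K00855", "K01601", "K01783"} <= s


def rtca(s: set) -> bool:
    type_i = {"K15230", "K15231"} <= s
    type_ii = {"K15233", "K15232", "K15234"} <= s
    return type_i or type_ii


def wl(s: set) -> bool:
    bacterial = {"K00198", "K14138"} <= s
    archaeal = {"K00192", "K00195", "K00193", "K00194", "K00197"} <= s
    return bacterial or archaeal


def hp3(s: set) -> bool:
    return {"K14468", "K14471", "K14472"} <= s


def hp4hb(s: set) -> bool:
    variant_i = {"K15017", "K15039", "K14534"} <= s
    variant_ii = {"K18603", "K18604", "K18605", "K18602", "K14534"} <= s
    return variant_i or variant_ii


def dc4hb(s: set) -> bool:
    return (
        "K01595" in s
        and bool(s & {"K01676", "K01677", "K01678"})
        and bool(s & {"K18861", "K14467"})
        and "K14534" in s
    )


def rgly(s: set) -> bool:
    return len(s & GLYCINE_CLEAVAGE) >= 3 and len(s & GLYCINE_REDUCTASE) >= 5


ORACLES = {
    "CBB": cbb,
    "rTCA": rtca,
    "WL": wl,
    "3HP": hp3,
    "3HP4HB": hp4hb,
    "DC4HB": dc4hb,
    "rGly": rgly,
}
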
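"""Rule-definition data model for CO2 fixation pathway markers.

The presence of a metabolic pathway is encoded as a small boolean formula
over KEGG Orthology (KO) identifiers:

* a **clause** is a quantifier over a list of KOs — ``one_of`` (any listed
  KO suffices, used for evolutionarily distinct enzymes catalysing the same
  reaction), ``all_of`` (every listed KO required, used for multi-subunit
  complexes), or ``at_least`` (a minimum number of listed KOs, used where
  subunit essentiality is uncertain);
* a **variant** (e.g. the bacterial vs archaeal forms of the
  Wood-Ljungdahl pathway) is the conjunction of its clauses;
* a **pathway** is present iff at least one of its variants is satisfied.

A built-in rule set covering the seven known natural CO2 fixation pathways
ships with the package as JSON (``data/co2_fixation_rules.json``) and is the
default used throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "KO_PATTERN",
    "PATHWAY_IDS",
    "Clause",
    "Variant",
    "PathwayDefinition",
    "RuleSet",
    "RuleSetError",
    "builtin_ruleset",
    "load_ruleset",
    "read_ruleset",
    "serialize_ruleset",
    "marker_ko_union",
    "shared_kos",
]

KO_PATTERN = re.compile(r"^K[0-9]{5}$")

#: Canonical order of the seven pathways in the built-in rule set.
PATHWAY_IDS = ("CBB", "rTCA", "WL", "3HP", "3HP4HB", "DC4HB", "rGly")

QUANTIFIERS = ("one_of", "all_of", "at_least")

_BUILTIN_RESOURCE = "co2_fixation_rules.json"


class RuleSetError(ValueError):
    """A rule document violated the schema.

    ``path`` locates the offending element, e.g.
    ``pathways[2].variants[0].clauses[1].min_count``.
    """

    def __init__(self, message: str, path: str = "$"):
        self.path = path
        super().__init__(f"{path}: {message}")


def _check_ko(ko: object, path: str) -> str:
    if not isinstance(ko, str) or not KO_PATTERN.match(ko):
        raise RuleSetError(f"malformed KO identifier {ko!r} (expected K#####)", path)
    return ko


@dataclass(frozen=True)
class Clause:
    """A single quantified condition over KO identifiers."""

    quantifier: str
    kos: tuple[str, ...]
    min_count: int | None = None

    def __post_init__(self) -> None:
        if self.quantifier not in QUANTIFIERS:
            raise RuleSetError(f"unknown quantifier {self.quantifier!r}", "quantifier")
        if not self.kos:
            raise RuleSetError("clause has no KOs", "kos")
        if len(set(self.kos)) != len(self.kos):
            raise RuleSetError("duplicate KOs in clause", "kos")
        for ko in self.kos:
            _check_ko(ko, "kos")
        if self.quantifier == "at_least":
            if self.min_count is None:
                raise RuleSetError("at_least clause requires min_count", "min_count")
            if not 1 <= self.min_count <= len(self.kos):
                raise RuleSetError(
                    f"min_count {self.min_count} out of range 1..{len(self.kos)}",
                    "min_count",
                )
        elif self.min_count is not None:
            raise RuleSetError(
                f"min_count is only valid for at_least, not {self.quantifier}",
                "min_count",
            )


@dataclass(frozen=True)
class Variant:
    """A mechanistic form of a pathway; satisfied iff every clause holds."""

    variant_id: str
    clauses: tuple[Clause, ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise RuleSetError("variant has no clauses", "clauses")

    @property
    def kos(self) -> frozenset[str]:
        return frozenset(ko for c in self.clauses for ko in c.kos)


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway; predicted present iff at least one variant is satisfied."""

    pathway_id: str
    display_name: str
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise RuleSetError("pathway has no variants", "variants")

    @property
    def kos(self) -> frozenset[str]:
        return frozenset(ko for v in self.variants for ko in v.kos)


@dataclass(frozen=True)
class RuleSet:
    """An ordered collection of pathway definitions."""

    version: str
    pathways: tuple[PathwayDefinition, ...]
    _by_id: dict[str, PathwayDefinition] = field(
        init=False, repr=False, compare=False, hash=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        seen: dict[str, PathwayDefinition] = {}
        for p in self.pathways:
            if p.pathway_id in seen:
                raise RuleSetError(
                    f"duplicate pathway_id {p.pathway_id!r}", "pathways"
                )
            seen[p.pathway_id] = p
        object.__setattr__(self, "_by_id", seen)

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(p.pathway_id for p in self.pathways)

    def pathway(self, pathway_id: str) -> PathwayDefinition:
        try:
            return self._by_id[pathway_id]
        except KeyError:
            raise KeyError(
                f"unknown pathway {pathway_id!r}; valid ids: "
                + ", ".join(self.pathway_ids)
            ) from None

    def __iter__(self) -> Iterator[PathwayDefinition]:
        return iter(self.pathways)

    @property
    def all_marker_kos(self) -> frozenset[str]:
        return frozenset(ko for p in self.pathways for ko in p.kos)


def marker_ko_union(rules: RuleSet, pathway_id: str) -> frozenset[str]:
    """Distinct KOs appearing in any clause of any variant of one pathway."""
    return rules.pathway(pathway_id).kos


def shared_kos(rules: RuleSet) -> dict[str, tuple[str, ...]]:
    """KOs appearing in more than one pathway, mapped to the pathways.

    Sharing is legitimate (the built-in set shares the 4-hydroxybutanoyl-CoA
    dehydratase KO K14534 between the 3HP/4HB and DC/4HB cycles) but worth
    surfacing: a shared KO alone can never discriminate the pathways.
    """
    owners: dict[str, list[str]] = {}
    for p in rules.pathways:
        for ko in sorted(p.kos):
            owners.setdefault(ko, []).append(p.pathway_id)
    return {ko: tuple(ps) for ko, ps in sorted(owners.items()) if len(ps) > 1}


# ---------------------------------------------------------------------------
# JSON loading / serialization


def _expect_mapping(obj: object, path: str) -> Mapping:
    if not isinstance(obj, Mapping):
        raise RuleSetError(f"expected an object, got {type(obj).__name__}", path)
    return obj


def _expect_list(obj: object, path: str) -> list:
    if not isinstance(obj, list) or not obj:
        raise RuleSetError("expected a non-empty array", path)
    return obj


def _expect_str(obj: object, path: str) -> str:
    if not isinstance(obj, str) or not obj:
        raise RuleSetError("expected a non-empty string", path)
    return obj


def _load_clause(doc: object, path: str) -> Clause:
    m = _expect_mapping(doc, path)
    extra = set(m) - {"quantifier", "kos", "min_count"}
    if extra:
        raise RuleSetError(f"unknown fields {sorted(extra)}", path)
    quant = m.get("quantifier")
    if quant not in QUANTIFIERS:
        raise RuleSetError(
            f"invalid quantifier {quant!r} (must be one of {', '.join(QUANTIFIERS)})",
            f"{path}.quantifier",
        )
    kos_raw = _expect_list(m.get("kos"), f"{path}.kos")
    kos = tuple(
        _check_ko(ko, f"{path}.kos[{i}]") for i, ko in enumerate(kos_raw)
    )
    if len(set(kos)) != len(kos):
        raise RuleSetError("duplicate KOs in clause", f"{path}.kos")
    min_count = m.get("min_count")
    if quant == "at_least":
        if not isinstance(min_count, int) or isinstance(min_count, bool):
            raise RuleSetError("min_count must be an integer", f"{path}.min_count")
        if not 1 <= min_count <= len(kos):
            raise RuleSetError(
                f"min_count {min_count} out of range 1..{len(kos)}",
                f"{path}.min_count",
            )
    elif min_count is not None:
        raise RuleSetError(
            "min_count is only valid for at_least clauses", f"{path}.min_count"
        )
    return Clause(quantifier=quant, kos=kos, min_count=min_count)


def load_ruleset(source: str | bytes | Mapping) -> RuleSet:
    """Parse and validate a rule document (JSON text or parsed mapping).

    Raises :class:`RuleSetError` naming the offending element on any schema
    violation: missing field, bad quantifier, min_count out of range,
    malformed KO identifier, or duplicate pathway_id.
    """
    if isinstance(source, (str, bytes)):
        doc: object = json.loads(source)
    else:
        doc = source
    top = _expect_mapping(doc, "$")
    version = _expect_str(top.get("version"), "$.version")
    pathways_raw = _expect_list(top.get("pathways"), "$.pathways")
    pathways = []
    seen_ids: set[str] = set()
    for i, p_doc in enumerate(pathways_raw):
        p_path = f"$.pathways[{i}]"
        pm = _expect_mapping(p_doc, p_path)
        pid = _expect_str(pm.get("pathway_id"), f"{p_path}.pathway_id")
        if pid in seen_ids:
            raise RuleSetError(f"duplicate pathway_id {pid!r}", f"{p_path}.pathway_id")
        seen_ids.add(pid)
        display = _expect_str(pm.get("display_name"), f"{p_path}.display_name")
        variants_raw = _expect_list(pm.get("variants"), f"{p_path}.variants")
        variants = []
        for j, v_doc in enumerate(variants_raw):
            v_path = f"{p_path}.variants[{j}]"
            vm = _expect_mapping(v_doc, v_path)
            vid = _expect_str(vm.get("variant_id"), f"{v_path}.variant_id")
            clauses_raw = _expect_list(vm.get("clauses"), f"{v_path}.clauses")
            clauses = tuple(
                _load_clause(c_doc, f"{v_path}.clauses[{k}]")
                for k, c_doc in enumerate(clauses_raw)
            )
            variants.append(Variant(variant_id=vid, clauses=clauses))
        pathways.append(
            PathwayDefinition(
                pathway_id=pid, display_name=display, variants=tuple(variants)
            )
        )
    return RuleSet(version=version, pathways=tuple(pathways))


def read_ruleset(path) -> RuleSet:
    """Load a rule set from a JSON file on disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return load_ruleset(fh.read())


def serialize_ruleset(rules: RuleSet, *, indent: int = 2) -> str:
    """Emit the canonical JSON dialect with stable key and list order.

    Two serializations of equal rule sets are byte-identical, and
    ``load_ruleset(serialize_ruleset(r))`` is structurally equal to ``r``.
    """
    doc = {
        "version": rules.version,
        "pathways": [
            {
                "pathway_id": p.pathway_id,
                "display_name": p.display_name,
                "variants": [
                    {
                        "variant_id": v.variant_id,
                        "clauses": [
                            (
                                {
                                    "quantifier": c.quantifier,
                                    "kos": list(c.kos),
                                    "min_count": c.min_count,
                                }
                                if c.quantifier == "at_least"
                                else {
                                    "quantifier": c.quantifier,
                                    "kos": list(c.kos),
                                }
                            )
                            for c in v.clauses
                        ],
                    }
                    for v in p.variants
                ],
            }
            for p in rules.pathways
        ],
    }
    return json.dumps(doc, indent=indent, ensure_ascii=False) + "\n"


def builtin_ruleset() -> RuleSet:
    """The built-in marker definitions for the seven CO2 fixation pathways.

    Covers, in order: CBB, rTCA (types I/II), WL (bacterial/archaeal),
    3HP bicycle, 3HP/4HB (variants I/II), DC/4HB, and rGly — 42 distinct
    marker KOs in total.
    """
    text = (
        resources.files(__package__)
        .joinpath("data", _BUILTIN_RESOURCE)
        .read_text(encoding="utf-8")
    )
    return load_ruleset(text)
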
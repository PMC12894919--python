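"""Evaluate marker rules against KO profiles.

All three quantifiers are monotone in the profile: adding KOs to a genome
can only turn pathways on, never off.  Calls are strictly binary per
pathway — there is no partial-completeness score and no inference of flux
directionality; satisfied variant ids and matched marker KOs are reported
as supporting evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .kofam import KOProfile
from .rules import Clause, RuleSet, Variant, marker_ko_union

__all__ = [
    "PathwayPrediction",
    "BatchResult",
    "eval_clause",
    "eval_variant",
    "predict",
    "predict_batch",
    "matrix_to_tsv",
]


def eval_clause(clause: Clause, profile: KOProfile | frozenset[str] | set[str]) -> bool:
    """True iff the clause's quantified condition holds for the profile."""
    kos = profile.kos if isinstance(profile, KOProfile) else profile
    present = sum(1 for ko in clause.kos if ko in kos)
    if clause.quantifier == "one_of":
        return present >= 1
    if clause.quantifier == "all_of":
        return present == len(clause.kos)
    return present >= clause.min_count  # at_least


def eval_variant(variant: Variant, profile: KOProfile | frozenset[str] | set[str]) -> bool:
    """True iff every clause of the variant is satisfied (conjunction)."""
    return all(eval_clause(c, profile) for c in variant.clauses)


@dataclass(frozen=True)
class PathwayPrediction:
    """Presence/absence calls for one genome, with evidence.

    ``calls[p]`` is true iff ``evidence[p]`` (the satisfied variant ids, in
    rule order) is non-empty; ``matched_kos[p]`` lists the profile KOs that
    occur anywhere in pathway ``p``'s definition, present or not.
    """

    genome_id: str
    calls: Mapping[str, bool]
    evidence: Mapping[str, tuple[str, ...]]
    matched_kos: Mapping[str, frozenset[str]]


def predict(profile: KOProfile, rules: RuleSet) -> PathwayPrediction:
    """Call each pathway present iff at least one variant is satisfied.

    KOs in the profile that appear in no rule are ignored (they are ordinary
    background annotation).
    """
    calls: dict[str, bool] = {}
    evidence: dict[str, tuple[str, ...]] = {}
    matched: dict[str, frozenset[str]] = {}
    for pathway in rules:
        satisfied = tuple(
            v.variant_id for v in pathway.variants if eval_variant(v, profile)
        )
        calls[pathway.pathway_id] = bool(satisfied)
        evidence[pathway.pathway_id] = satisfied
        matched[pathway.pathway_id] = frozenset(
            marker_ko_union(rules, pathway.pathway_id) & profile.kos
        )
    return PathwayPrediction(
        genome_id=profile.genome_id, calls=calls, evidence=evidence, matched_kos=matched
    )


@dataclass(frozen=True, eq=False)
class BatchResult:
    """Predictions for a set of genomes plus the binary summary matrix.

    ``matrix`` has one row per genome (input order) and one 0/1 column per
    pathway (rule-set order).  ``unmatched_ko_counts`` records, per genome,
    how many profile KOs appeared in no rule — a diagnostic only.
    """

    predictions: tuple[PathwayPrediction, ...]
    matrix: pd.DataFrame
    unmatched_ko_counts: Mapping[str, int]

    def to_json_report(self) -> list[dict]:
        return [
            {
                "genome_id": p.genome_id,
                "calls": {k: bool(v) for k, v in p.calls.items()},
                "evidence": {k: list(v) for k, v in p.evidence.items()},
                "matched_kos": {k: sorted(v) for k, v in p.matched_kos.items()},
                "unmatched_ko_count": self.unmatched_ko_counts[p.genome_id],
            }
            for p in self.predictions
        ]


def predict_batch(profiles: Sequence[KOProfile] | Iterable[KOProfile],
                  rules: RuleSet) -> BatchResult:
    """Predict every profile and summarize into a genome x pathway matrix."""
    profiles = list(profiles)
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate genome_id(s): {', '.join(dup)}")
    marker_universe = rules.all_marker_kos
    predictions = tuple(predict(p, rules) for p in profiles)
    matrix = pd.DataFrame(
        [[int(pred.calls[pid]) for pid in rules.pathway_ids] for pred in predictions],
        index=pd.Index(ids, name="genome_id"),
        columns=list(rules.pathway_ids),
        dtype="int8",
    )
    unmatched = {
        p.genome_id: len(p.kos - marker_universe) for p in profiles
    }
    return BatchResult(
        predictions=predictions, matrix=matrix, unmatched_ko_counts=unmatched
    )


def matrix_to_tsv(matrix: pd.DataFrame) -> str:
    """Render a binary matrix in the canonical TSV dialect."""
    return matrix.to_csv(sep="\t", index_label="genome_id")
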
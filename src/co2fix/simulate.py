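"""Seeded synthetic KO profiles with known pathway ground truth.

This generator stands in for a curated benchmark corpus: it emits, per
pathway, genomes built from a minimal marker set satisfying one variant,
padded with decoy background KOs, optionally degraded by independent
per-marker-KO dropout (a crude model of genome incompleteness), plus
near-miss negatives (a satisfying profile with one critical KO removed) and
multi-pathway genomes.  Truth labels record the INTENDED pathway before
dropout, so dropout degrades recall but can never hurt precision — the
decoy pool (K90000-K90999) is disjoint from every real marker KO.

Everything is a pure function of (config, rules): the same seed reproduces
the corpus byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kofam import KOProfile, write_ko_list
from .predict import eval_variant
from .rules import RuleSet, Variant, marker_ko_union

__all__ = [
    "DECOY_POOL",
    "SimulationConfig",
    "Corpus",
    "minimal_satisfying_profile",
    "near_miss_profile",
    "generate_corpus",
    "write_mock_kofam_tsv",
    "write_corpus",
    "detection_probability",
]

#: Decoy background KOs, deliberately outside real KOfam space.
DECOY_POOL: tuple[str, ...] = tuple(f"K{90000 + i:05d}" for i in range(1000))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic corpus.

    ``n_per_pathway`` is the number of positive replicate genomes per
    pathway — per variant when ``variant_choice="all"``, so every
    mechanistic variant gets the full replicate count.  ``dropout_p`` is the
    independent deletion probability applied to each marker KO of a positive
    genome; ``background_k`` decoys are added to every genome;
    ``negatives_per_pathway`` near-miss genomes are emitted per pathway
    (per variant under ``"all"``).  ``combo_pairs`` adds multi-pathway
    genomes built by unioning two satisfying profiles, mirroring real
    organisms that harbor two CO2 fixation pathways.
    """

    seed: int = 0
    n_per_pathway: int = 50
    variant_choice: str = "all"
    dropout_p: float = 0.0
    background_k: int = 20
    negatives_per_pathway: int = 10
    combo_pairs: tuple[tuple[str, str], ...] = (("CBB", "WL"), ("WL", "rGly"))
    combos_per_pair: int = 5

    def __post_init__(self) -> None:
        if self.variant_choice not in ("first", "random", "all"):
            raise ValueError("variant_choice must be 'first', 'random' or 'all'")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_per_pathway < 1:
            raise ValueError("n_per_pathway must be positive")
        if min(self.background_k, self.negatives_per_pathway, self.combos_per_pair) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True, eq=False)
class Corpus:
    """Synthetic profiles, their truth matrix, and per-genome metadata.

    ``metadata`` has one row per genome: role (pos/neg/combo), pathway_id
    and variant_id of the generating template (combo rows join the two
    pathway ids with '+').
    """

    profiles: tuple[KOProfile, ...]
    truth: pd.DataFrame
    metadata: pd.DataFrame
    manifest: dict


def _get_variant(rules: RuleSet, pathway_id: str, variant_id: str) -> Variant:
    pathway = rules.pathway(pathway_id)
    for v in pathway.variants:
        if v.variant_id == variant_id:
            return v
    raise KeyError(
        f"unknown variant {variant_id!r} for pathway {pathway_id!r}; valid: "
        + ", ".join(v.variant_id for v in pathway.variants)
    )


def _minimal_kos(variant: Variant) -> frozenset[str]:
    kos: set[str] = set()
    for clause in variant.clauses:
        if clause.quantifier == "all_of":
            kos.update(clause.kos)
        elif clause.quantifier == "one_of":
            kos.add(clause.kos[0])
        else:  # at_least
            kos.update(clause.kos[: clause.min_count])
    return frozenset(kos)


def minimal_satisfying_profile(rules: RuleSet, pathway_id: str, variant_id: str,
                               genome_id: str | None = None) -> KOProfile:
    """Smallest canonical profile satisfying the chosen variant.

    Per clause: all KOs for ``all_of``, the first KO for ``one_of``, the
    first ``min_count`` KOs for ``at_least``.
    """
    variant = _get_variant(rules, pathway_id, variant_id)
    kos = _minimal_kos(variant)
    assert eval_variant(variant, kos)
    return KOProfile(
        genome_id=genome_id or f"min__{pathway_id}__{variant_id}", kos=kos
    )


def near_miss_profile(rules: RuleSet, pathway_id: str, variant_id: str,
                      rng: np.random.Generator,
                      genome_id: str | None = None) -> KOProfile:
    """Minimal profile minus one KO chosen so the whole pathway turns off.

    Candidate removals: any member of an ``all_of`` clause, the single
    included member of a ``one_of`` clause, or one included member of an
    ``at_least`` clause (dropping the satisfied count to min_count - 1).
    A removal that leaves the pathway satisfied through another variant is
    rejected; the first (seeded-shuffled) removal that kills the call wins.
    """
    variant = _get_variant(rules, pathway_id, variant_id)
    base = _minimal_kos(variant)
    candidates = sorted(base)
    rng.shuffle(candidates)
    pathway = rules.pathway(pathway_id)
    for ko in candidates:
        reduced = base - {ko}
        if not any(eval_variant(v, reduced) for v in pathway.variants):
            return KOProfile(
                genome_id=genome_id or f"miss__{pathway_id}__{variant_id}",
                kos=frozenset(reduced),
            )
    raise ValueError(
        f"no single-KO removal turns pathway {pathway_id!r} off from variant "
        f"{variant_id!r}"
    )


def _chosen_variants(rules: RuleSet, pathway_id: str, config: SimulationConfig,
                     rng: np.random.Generator) -> list[str]:
    ids = [v.variant_id for v in rules.pathway(pathway_id).variants]
    if config.variant_choice == "first":
        return [ids[0]]
    if config.variant_choice == "all":
        return ids
    return [ids[int(rng.integers(len(ids)))]]


def _decoys(rng: np.random.Generator, k: int) -> frozenset[str]:
    if k == 0:
        return frozenset()
    idx = rng.choice(len(DECOY_POOL), size=k, replace=False)
    return frozenset(DECOY_POOL[i] for i in idx)


def generate_corpus(config: SimulationConfig, rules: RuleSet) -> Corpus:
    """Generate the full corpus with its truth matrix and metadata."""
    rng = np.random.default_rng(config.seed)
    marker_universe = rules.all_marker_kos
    assert not marker_universe & set(DECOY_POOL)

    profiles: list[KOProfile] = []
    truth_rows: list[dict] = []
    meta_rows: list[dict] = []

    def add(genome_id: str, kos: frozenset[str], present: Iterable[str],
            role: str, pathway_label: str, variant_label: str) -> None:
        profiles.append(KOProfile(genome_id=genome_id, kos=kos))
        row = {pid: 0 for pid in rules.pathway_ids}
        for pid in present:
            row[pid] = 1
        truth_rows.append({"genome_id": genome_id, **row})
        meta_rows.append(
            {"genome_id": genome_id, "role": role,
             "pathway_id": pathway_label, "variant_id": variant_label}
        )

    def dropout(kos: frozenset[str]) -> frozenset[str]:
        if config.dropout_p == 0.0:
            return kos
        kept = set(kos)
        for ko in sorted(kos & marker_universe):
            if rng.random() < config.dropout_p:
                kept.discard(ko)
        return frozenset(kept)

    for pathway in rules:
        pid = pathway.pathway_id
        # positives
        if config.variant_choice == "random":
            reps = [
                (vid, i)
                for i in range(config.n_per_pathway)
                for vid in _chosen_variants(rules, pid, config, rng)
            ]
        else:
            reps = [
                (vid, i)
                for vid in _chosen_variants(rules, pid, config, rng)
                for i in range(config.n_per_pathway)
            ]
        counters: dict[str, int] = {}
        for vid, _ in reps:
            i = counters.get(vid, 0)
            counters[vid] = i + 1
            base = minimal_satisfying_profile(rules, pid, vid).kos
            kos = dropout(base) | _decoys(rng, config.background_k)
            add(f"pos__{pid}__{vid}__{i:04d}", kos, [pid], "pos", pid, vid)
        # near-miss negatives
        for vid in _chosen_variants(rules, pid, config, rng):
            for i in range(config.negatives_per_pathway):
                miss = near_miss_profile(rules, pid, vid, rng).kos
                kos = frozenset(miss) | _decoys(rng, config.background_k)
                add(f"neg__{pid}__{vid}__{i:04d}", kos, [], "neg", pid, vid)

    # multi-pathway genomes (first variant of each member)
    for pid_a, pid_b in config.combo_pairs:
        va = rules.pathway(pid_a).variants[0].variant_id
        vb = rules.pathway(pid_b).variants[0].variant_id
        for i in range(config.combos_per_pair):
            base = (
                minimal_satisfying_profile(rules, pid_a, va).kos
                | minimal_satisfying_profile(rules, pid_b, vb).kos
            )
            kos = dropout(base) | _decoys(rng, config.background_k)
            add(
                f"combo__{pid_a}+{pid_b}__{i:04d}", kos, [pid_a, pid_b],
                "combo", f"{pid_a}+{pid_b}", f"{va}+{vb}",
            )

    truth = pd.DataFrame(truth_rows).set_index("genome_id").astype("int8")
    metadata = pd.DataFrame(meta_rows).set_index("genome_id")
    manifest = {
        "config": dataclasses.asdict(config),
        "ruleset_version": rules.version,
        "n_genomes": len(profiles),
    }
    return Corpus(
        profiles=tuple(profiles), truth=truth, metadata=metadata, manifest=manifest
    )


def detection_probability(rules: RuleSet, pathway_id: str,
                          marker_kos: Iterable[str], dropout_p: float) -> float:
    """Exact probability the pathway stays detected under per-KO dropout.

    Enumerates all surviving subsets of the profile's marker KOs for the
    pathway (exact even when clauses share KOs, where the per-clause
    product formula is only approximate).  For a purely conjunctive variant
    over m markers this reduces to (1-p)^m; for an at_least(k of n) clause
    with all n markers present, to the Binomial(n, 1-p) upper tail.
    """
    markers = sorted(set(marker_kos) & marker_ko_union(rules, pathway_id))
    if len(markers) > 20:
        raise ValueError("marker set too large for exact enumeration")
    pathway = rules.pathway(pathway_id)
    total = 0.0
    for r in range(len(markers) + 1):
        for kept in combinations(markers, r):
            kept_set = frozenset(kept)
            if any(eval_variant(v, kept_set) for v in pathway.variants):
                total += (1 - dropout_p) ** r * dropout_p ** (len(markers) - r)
    return total


def write_mock_kofam_tsv(profile: KOProfile, rng: np.random.Generator,
                         fallback_kos: Sequence[str] = ()) -> str:
    """Render a profile as a synthetic KofamScan detail TSV.

    Each profile KO gets one gene with a starred hit whose score exceeds its
    synthetic adaptive threshold.  Each ``fallback_kos`` entry gets an extra
    gene with only non-significant hits whose top-scoring KO is that entry,
    exercising the top-hit fallback; parsing and assignment then recover
    exactly ``profile.kos`` plus the fallback KOs.
    """
    lines = ["# gene name\tKO\tthresholds\tscore\tE-value\tKO definition"]
    for i, ko in enumerate(sorted(profile.kos)):
        threshold = float(np.round(50.0 + 200.0 * rng.random(), 1))
        score = float(np.round(threshold + 5.0 + 100.0 * rng.random(), 1))
        lines.append(
            f"*\t{profile.genome_id}_g{i:05d}\t{ko}\t{threshold:.1f}"
            f"\t{score:.1f}\t1e-{int(rng.integers(20, 100))}\tsynthetic marker hit"
        )
    for j, ko in enumerate(sorted(set(fallback_kos))):
        gene = f"{profile.genome_id}_orphan{j:05d}"
        # two sub-threshold hits; the intended KO scores highest
        lines.append(
            f"\t{gene}\t{ko}\t500.0\t40.0\t1e-05\tsynthetic sub-threshold best hit"
        )
        other = "K90000" if ko != "K90000" else "K90001"
        lines.append(
            f"\t{gene}\t{other}\t500.0\t25.0\t1e-03\tsynthetic sub-threshold hit"
        )
    return "\n".join(lines) + "\n"


def write_corpus(corpus: Corpus, outdir) -> None:
    """Materialize a corpus on disk: KO lists, truth TSV and a manifest."""
    outdir = os.fspath(outdir)
    ko_dir = os.path.join(outdir, "ko_lists")
    os.makedirs(ko_dir, exist_ok=True)
    for profile in corpus.profiles:
        path = os.path.join(ko_dir, f"{profile.genome_id}.txt")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(write_ko_list(profile))
    corpus.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t")
    corpus.metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t")
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(corpus.manifest, fh, indent=2)
        fh.write("\n")
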
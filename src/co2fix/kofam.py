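"""Parse KofamScan detail-TSV output and build per-genome KO profiles.

KofamScan scores each protein against KOfam HMM profiles, each of which
carries a precomputed adaptive bit-score threshold; hits above the threshold
are marked with an asterisk in the first column of the detail TSV.  KO
assignment here follows that convention, with a top-hit fallback: a gene
with hits but none significant contributes the KO of its single best hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .rules import KO_PATTERN

__all__ = ["KofamHit", "KOProfile", "parse_kofam_tsv", "assign_kos", "read_ko_list",
           "write_ko_list"]

logger = logging.getLogger(__name__)


class KofamParseError(ValueError):
    """Malformed KofamScan detail-TSV row; message carries the line number."""


@dataclass(frozen=True)
class KofamHit:
    """One data row of a KofamScan detail TSV.

    ``threshold`` is ``None`` when KofamScan prints "-" (no adaptive
    threshold available for that KOfam profile); such hits are never
    significant and remain eligible only for the top-hit fallback.
    """

    significant: bool
    gene_id: str
    ko: str
    threshold: float | None
    score: float
    evalue: float
    definition: str = ""


@dataclass(frozen=True)
class KOProfile:
    """Presence/absence KO content of one genome (multiplicity discarded)."""

    genome_id: str
    kos: frozenset[str] = field(default_factory=frozenset)

    def __contains__(self, ko: str) -> bool:
        return ko in self.kos

    def __len__(self) -> int:
        return len(self.kos)


def _lines(stream: Iterable[str] | str) -> Iterable[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream


def _float(token: str, name: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise KofamParseError(
            f"line {lineno}: cannot parse {name} field {token!r}"
        ) from None


def parse_kofam_tsv(stream: Iterable[str] | str) -> list[KofamHit]:
    """Parse detail-TSV text into hits, in file order.

    Layout per data row (tab-separated): significance mark ("*" or blank),
    gene id, KO id, adaptive threshold ("-" if absent), bit score, E-value,
    and free-text definition.  Lines starting with "#" are skipped.

    If no row in the file carries an asterisk, the file is assumed to come
    from a dialect without significance marks and significance is recomputed
    as score > threshold (absent thresholds stay non-significant).
    """
    hits: list[KofamHit] = []
    saw_star = False
    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise KofamParseError(
                f"line {lineno}: expected >=6 tab-separated fields, got {len(fields)}"
            )
        mark = fields[0].strip()
        if mark not in ("", "*"):
            raise KofamParseError(
                f"line {lineno}: significance column must be '*' or blank, got {mark!r}"
            )
        ko = fields[2].strip()
        if not KO_PATTERN.match(ko):
            raise KofamParseError(f"line {lineno}: malformed KO identifier {ko!r}")
        threshold = (
            None if fields[3].strip() == "-"
            else _float(fields[3], "threshold", lineno)
        )
        hit = KofamHit(
            significant=(mark == "*"),
            gene_id=fields[1].strip(),
            ko=ko,
            threshold=threshold,
            score=_float(fields[4], "score", lineno),
            evalue=_float(fields[5], "E-value", lineno),
            definition="\t".join(fields[6:]).strip(),
        )
        saw_star = saw_star or hit.significant
        hits.append(hit)
    if hits and not saw_star:
        hits = [
            KofamHit(
                significant=(h.threshold is not None and h.score > h.threshold),
                gene_id=h.gene_id,
                ko=h.ko,
                threshold=h.threshold,
                score=h.score,
                evalue=h.evalue,
                definition=h.definition,
            )
            for h in hits
        ]
    return hits


def assign_kos(hits: Iterable[KofamHit], genome_id: str) -> KOProfile:
    """Adaptive-threshold KO assignment with top-hit fallback.

    Per gene: every significant hit contributes its KO; a gene whose hits
    are all non-significant contributes exactly one KO, that of its
    top-scoring hit (ties broken by lowest E-value, then lexicographically
    smallest KO id).  The profile is the union over genes.
    """
    by_gene: dict[str, list[KofamHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    kos: set[str] = set()
    for gene_hits in by_gene.values():
        sig = [h.ko for h in gene_hits if h.significant]
        if sig:
            kos.update(sig)
        else:
            best = min(gene_hits, key=lambda h: (-h.score, h.evalue, h.ko))
            kos.add(best.ko)
    return KOProfile(genome_id=genome_id, kos=frozenset(kos))


def read_ko_list(stream: Iterable[str] | str, genome_id: str) -> KOProfile:
    """Read a plain KO list (one K##### per line; '#' lines ignored).

    Tokens not matching the KO pattern are skipped with a warning naming the
    line number; duplicates collapse.
    """
    kos: set[str] = set()
    for lineno, raw in enumerate(_lines(stream), start=1):
        token = raw.strip()
        if not token or token.startswith("#"):
            continue
        if KO_PATTERN.match(token):
            kos.add(token)
        else:
            logger.warning(
                "%s line %d: skipping malformed KO token %r", genome_id, lineno, token
            )
    return KOProfile(genome_id=genome_id, kos=frozenset(kos))


def write_ko_list(profile: KOProfile) -> str:
    """Render a profile as a sorted, newline-terminated KO list."""
    return "".join(f"{ko}\n" for ko in sorted(profile.kos))
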
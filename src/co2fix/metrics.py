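"""Per-pathway precision/recall/F1 against a curated label matrix.

Both predictions and truth are binary genome x pathway matrices; genomes
are joined by id, and metrics are computed per pathway over the shared
genome set.  Zero denominators score 0 rather than NaN, and pathways a tool
does not claim to support (column absent from its matrix) are scored 0 with
``supported=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ConfusionCounts",
    "read_matrix",
    "confusion_counts",
    "precision_recall_f1",
    "benchmark_tools",
    "benchmark_to_tsv",
]

logger = logging.getLogger(__name__)

BENCHMARK_COLUMNS = (
    "tool", "pathway", "tp", "fp", "fn", "tn", "precision", "recall", "f1", "supported"
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


class MatrixError(ValueError):
    """Malformed presence/absence matrix."""


def read_matrix(stream) -> pd.DataFrame:
    """Read a binary genome x pathway TSV into an int8 DataFrame.

    First column is the genome id; remaining columns are pathways (unknown
    pathway names are preserved).  Cells must be 0 or 1; a bad cell or a
    duplicated genome row is rejected with its coordinates.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise MatrixError(f"duplicate genome row(s): {', '.join(map(str, dups))}")
    if df.isna().any().any():
        raise MatrixError("matrix contains missing cells")
    for col in df.columns:
        bad = df.index[~df[col].isin(["0", "1"])]
        if len(bad):
            raise MatrixError(
                f"non-binary cell {df.loc[bad[0], col]!r} at genome "
                f"{bad[0]!r}, pathway {col!r}"
            )
    df.index.name = "genome_id"
    return df.astype("int8")


def confusion_counts(pred: pd.DataFrame, truth: pd.DataFrame,
                     pathway_id: str) -> ConfusionCounts:
    """TP/FP/FN/TN for one pathway over the genomes common to both matrices.

    Genomes are matched by id, not position; genomes present in only one
    matrix are dropped (logged).
    """
    for name, m in (("predictions", pred), ("truth", truth)):
        if pathway_id not in m.columns:
            raise MatrixError(f"pathway {pathway_id!r} absent from {name} matrix")
    common = pred.index.intersection(truth.index)
    if len(common) == 0:
        raise MatrixError("prediction and truth matrices share no genomes")
    dropped = (len(pred.index) - len(common)) + (len(truth.index) - len(common))
    if dropped:
        logger.info("dropped %d genome rows present in only one matrix", dropped)
    p = pred.loc[common, pathway_id].astype(bool)
    t = truth.loc[common, pathway_id].astype(bool)
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Standard per-pathway metrics with the zero-denominator-scores-0 rule."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def benchmark_tools(predictions: Mapping[str, pd.DataFrame],
                    truth: pd.DataFrame,
                    pathway_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Score one or more tools' matrices against the curated truth matrix.

    Returns a long-format table (one row per tool x pathway) with counts,
    precision, recall, F1 and a ``supported`` flag.  Pathways missing from a
    tool's matrix are scored 0 and flagged unsupported.
    """
    if not predictions:
        raise ValueError("at least one tool's prediction matrix is required")
    pathways = list(pathway_ids) if pathway_ids is not None else list(truth.columns)
    rows = []
    for tool, pred in predictions.items():
        for pid in pathways:
            if pid not in pred.columns:
                rows.append((tool, pid, 0, 0, 0, 0, 0.0, 0.0, 0.0, False))
                continue
            c = confusion_counts(pred, truth, pid)
            prec, rec, f1 = precision_recall_f1(c.tp, c.fp, c.fn)
            rows.append((tool, pid, c.tp, c.fp, c.fn, c.tn, prec, rec, f1, True))
    return pd.DataFrame(rows, columns=list(BENCHMARK_COLUMNS))


def benchmark_to_tsv(table: pd.DataFrame) -> str:
    """Long-format TSV with metrics printed to 4 decimal places."""
    out = table.copy()
    for col in ("precision", "recall", "f1"):
        out[col] = out[col].map(lambda x: f"{x:.4f}")
    out["supported"] = out["supported"].map(lambda b: "true" if b else "false")
    return out.to_csv(sep="\t", index=False)
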
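"""Reading and writing annotated posts and evaluation reports.

Annotated posts travel as JSONL (one object per line with keys ``id``,
``text``, ``drug_start``, ``drug_end``, ``event_start``, ``event_end``,
``label``) or as TSV with the same columns and a header row. The writer
mirrors the reader exactly: ``read_posts(write_posts(posts))`` is the
identity. Malformed lines are reported with their line numbers and abort the
read unless ``skip_bad=True``, in which case they are counted and logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence

from .classifier import TrainedModel
from .evaluation import EvaluationReport
from .exceptions import InvalidInputError
from .segmentation import AnnotatedPost

__all__ = [
    "read_posts",
    "write_posts",
    "write_fold_tsv",
    "write_summary_tsv",
    "write_pattern_weights",
]

logger = logging.getLogger("adrcause")

COLUMNS = ("id", "text", "drug_start", "drug_end", "event_start", "event_end", "label")


def _post_from_fields(fields: dict, where: str) -> AnnotatedPost:
    try:
        label = fields.get("label")
        if label in (None, "", "None", "null"):
            label = None
        else:
            label = int(label)
        return AnnotatedPost(
            id=str(fields["id"]),
            text=str(fields["text"]),
            drug_span=(int(fields["drug_start"]), int(fields["drug_end"])),
            event_span=(int(fields["event_start"]), int(fields["event_end"])),
            label=label,
        )
    except (KeyError, TypeError, ValueError, InvalidInputError) as exc:
        raise InvalidInputError(f"{where}: {exc}") from None


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "tsv"):
            raise InvalidInputError(f"unknown format {fmt!r}")
        return fmt
    if path.suffix.lower() in (".tsv", ".tab"):
        return "tsv"
    return "jsonl"


def read_posts(path, fmt: Optional[str] = None, skip_bad: bool = False) -> List[AnnotatedPost]:
    """Read annotated posts from a JSONL or TSV file."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    posts: List[AnnotatedPost] = []
    n_bad = 0
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if fmt == "tsv":
        if not lines:
            raise InvalidInputError(f"{path}: empty TSV file")
        header = lines[0].split("\t")
        if tuple(header) != COLUMNS:
            raise InvalidInputError(f"{path}:1: expected header {COLUMNS}, got {tuple(header)}")
        body = list(enumerate(lines[1:], start=2))
    else:
        body = list(enumerate(lines, start=1))
    for lineno, line in body:
        if not line.strip():
            continue
        try:
            if fmt == "tsv":
                cells = line.split("\t")
                if len(cells) != len(COLUMNS):
                    raise InvalidInputError(f"expected {len(COLUMNS)} columns, got {len(cells)}")
                fields = dict(zip(COLUMNS, cells))
            else:
                fields = json.loads(line)
                if not isinstance(fields, dict):
                    raise InvalidInputError("line is not a JSON object")
            posts.append(_post_from_fields(fields, f"{path}:{lineno}"))
        except (json.JSONDecodeError, InvalidInputError) as exc:
            if skip_bad:
                n_bad += 1
                logger.warning("skipping bad record at %s:%d: %s", path, lineno, exc)
            else:
                raise InvalidInputError(f"{path}:{lineno}: {exc}") from None
    if n_bad:
        logger.info("skipped %d malformed records in %s", n_bad, path)
    return posts


def write_posts(posts: Sequence[AnnotatedPost], path, fmt: Optional[str] = None) -> None:
    """Write posts in the same schema the reader accepts."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    lines: List[str] = []
    if fmt == "tsv":
        lines.append("\t".join(COLUMNS))
    for p in posts:
        if fmt == "tsv" and ("\t" in p.text or "\n" in p.text):
            raise InvalidInputError(f"post {p.id!r} contains tab/newline; use JSONL")
        fields = {
            "id": p.id,
            "text": p.text,
            "drug_start": p.drug_span[0],
            "drug_end": p.drug_span[1],
            "event_start": p.event_span[0],
            "event_end": p.event_span[1],
            "label": p.label,
        }
        if fmt == "tsv":
            fields["label"] = "" if p.label is None else str(p.label)
            lines.append("\t".join(str(fields[c]) for c in COLUMNS))
        else:
            lines.append(json.dumps(fields, ensure_ascii=False))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fold_tsv(reports: Sequence[EvaluationReport], path) -> None:
    """Per-fold detail: method, fold, n_test, accuracy."""
    lines = ["method\tfold\tn_test\taccuracy"]
    for r in reports:
        for f in r.folds:
            lines.append(f"{r.method}\t{f.fold}\t{f.n_test}\t{f.accuracy:.4f}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def write_summary_tsv(reports: Sequence[EvaluationReport], path) -> None:
    """Summary: method, pooled accuracy, CP interval, significance vs majority.

    A method is flagged significant when its pooled accuracy lies above the
    upper bound of the majority baseline's interval (requires a ``majority``
    report in ``reports``; otherwise the flag column is empty).
    """
    majority = next((r for r in reports if r.method == "majority"), None)
    maj_upper = majority.ci[1] if majority is not None else None
    lines = ["method\taccuracy\tci_lower\tci_upper\tsignificant_vs_majority"]
    for r in reports:
        lo, hi = r.ci
        if maj_upper is None or r.method == "majority":
            flag = ""
        else:
            flag = "yes" if r.pooled_accuracy > maj_upper else "no"
        lines.append(f"{r.method}\t{r.pooled_accuracy:.4f}\t{lo:.4f}\t{hi:.4f}\t{flag}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pattern_weights(model: TrainedModel, path, decimals: int = 4) -> None:
    """Dump every pattern with its weight, sorted by weight descending."""
    if model.vocabulary is None:
        raise InvalidInputError("model has no vocabulary")
    pairs = sorted(
        zip(model.vocabulary.labels, model.weights), key=lambda kv: (-kv[1], kv[0])
    )
    with open(path, "w", encoding="utf-8") as fh:
        for label, w in pairs:
            fh.write(f"{label}\t{w:.{decimals}f}\n")
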
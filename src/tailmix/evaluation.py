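"""Head / tail / overall top-1 accuracy reporting.

Head and tail accuracies are macro averages (mean of per-class accuracies);
on a class-balanced test set micro and macro coincide, and the overall
accuracy equals the class-count-weighted mean of the head and tail figures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EvalReport", "evaluate", "report_table"]


@dataclass
class EvalReport:
    """Top-1 accuracies in percent, plus the per-class breakdown."""

    overall: float
    head: float
    tail: float
    per_class: dict[int, float]
    n_head: int
    n_tail: int
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "overall": self.overall,
                    "head": self.head,
                    "tail": self.tail,
                    "per_class": {str(k): v for k, v in self.per_class.items()},
                    "n_head": self.n_head,
                    "n_tail": self.n_tail,
                    "metadata": self.metadata,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        d = json.loads(Path(path).read_text())
        return cls(
            overall=d["overall"],
            head=d["head"],
            tail=d["tail"],
            per_class={int(k): v for k, v in d["per_class"].items()},
            n_head=d["n_head"],
            n_tail=d["n_tail"],
            metadata=d.get("metadata", {}),
        )


def evaluate(
    model,
    X_test,
    y_test,
    head_classes: list[int],
    tail_classes: list[int],
    metadata: dict | None = None,
) -> EvalReport:
    """Top-1 accuracy overall and macro-averaged over head/tail classes."""
    y_test = np.asarray(y_test, dtype=int)
    X = np.asarray(X_test, dtype=np.float64)
    if X.ndim > 2:
        X = X.reshape(len(X), -1)
    present = set(int(c) for c in np.unique(y_test))
    covered = set(int(c) for c in head_classes) | set(int(c) for c in tail_classes)
    missing = present - covered
    if missing:
        raise ValueError(f"test classes not covered by head/tail split: {sorted(missing)}")

    pred = np.asarray(model.predict(X))
    per_class: dict[int, float] = {}
    for c in sorted(present):
        mask = y_test == c
        per_class[c] = float(100.0 * np.mean(pred[mask] == c))

    def macro(classes: list[int]) -> float:
        accs = [per_class[c] for c in classes if c in per_class]
        return float(np.mean(accs)) if accs else float("nan")

    return EvalReport(
        overall=float(100.0 * np.mean(pred == y_test)),
        head=macro(list(head_classes)),
        tail=macro(list(tail_classes)),
        per_class=per_class,
        n_head=len(head_classes),
        n_tail=len(tail_classes),
        metadata=metadata or {},
    )


def report_table(
    reports: list[EvalReport],
    fmt: str = "markdown",
) -> str:
    """Render method-per-row Head/Tail/Overall tables.

    Markdown mode bolds the best value per column; TSV mode is a plain
    numeric round-trippable table.
    """
    if not reports:
        raise ValueError("need at least one report")
    names = [r.metadata.get("method", f"run{i}") for i, r in enumerate(reports)]
    cols = {
        "Head": [r.head for r in reports],
        "Tail": [r.tail for r in reports],
        "Overall": [r.overall for r in reports],
    }
    if fmt == "tsv":
        lines = ["method\thead\ttail\toverall"]
        for i, name in enumerate(names):
            lines.append(
                f"{name}\t{cols['Head'][i]:.4f}\t{cols['Tail'][i]:.4f}"
                f"\t{cols['Overall'][i]:.4f}"
            )
        return "\n".join(lines) + "\n"
    if fmt != "markdown":
        raise ValueError(f"unknown table format: {fmt!r}")
    best = {k: max(v) for k, v in cols.items()}
    lines = [
        "| Method | Head | Tail | Overall |",
        "|---|---|---|---|",
    ]
    for i, name in enumerate(names):
        cells = []
        for key in ("Head", "Tail", "Overall"):
            val = cols[key][i]
            text = f"{val:.1f}"
            if val == best[key]:
                text = f"**{text}**"
            cells.append(text)
        lines.append(f"| {name} | {cells[0]} | {cells[1]} | {cells[2]} |")
    return "\n".join(lines) + "\n"
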
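"""Benchmark workflow and report rendering.

``run_benchmark`` ties the stages together for one dataset pair: build the
four provenance-explicit subsets (A∩B, B∩A, A\\B, B\\A), fit a chain-length
baseline on each overlap, evaluate it in the fitting procedure and by
leave-one-out cross-validation on its training overlap, evaluate it as an
external predictor on the difference subsets, and score any ingested
third-party prediction tables on the same subsets.  The result is one tidy
table with the columns the field's comparison tables use:

    model, subset, n, RMSE, PCC, RMSE_PR, PCC_PR, RMSE_cv, PCC_cv

Fit/LOO columns are populated for training rows, the _PR columns for
external rows.  Undefined correlations render as empty cells, never 0.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .datasets import PredictionTable, ProteinDataset
from .model import fit_loglinear
from .subsets import difference, overlap
from .validation import evaluate_external, evaluate_fit, loo_cv

logger = logging.getLogger(__name__)

BENCH_COLUMNS = [
    "model",
    "subset",
    "n",
    "RMSE",
    "PCC",
    "RMSE_PR",
    "PCC_PR",
    "RMSE_cv",
    "PCC_cv",
]


@dataclass
class RunManifest:
    """Provenance stamp written next to every CLI output file."""

    command: str
    inputs: dict[str, str] = dc_field(default_factory=dict)  # path -> sha256
    seed: Optional[int] = None
    config: Optional[dict] = None
    version: str = __version__
    timestamp: str = dc_field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @staticmethod
    def digest(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    @classmethod
    def for_command(cls, inputs=(), seed=None, config=None) -> "RunManifest":
        return cls(
            command=" ".join(sys.argv) if sys.argv else "",
            inputs={str(p): cls.digest(p) for p in inputs},
            seed=seed,
            config=config,
        )

    def write(self, out_path) -> Path:
        manifest_path = Path(str(out_path) + ".manifest.json")
        manifest_path.write_text(json.dumps(self.__dict__, indent=2) + "\n")
        return manifest_path


def _model_row(name, subset, fit_rep=None, loo_rep=None, ext_rep=None) -> dict:
    row = {c: None for c in BENCH_COLUMNS}
    row["model"] = name
    row["subset"] = subset
    if fit_rep is not None:
        row.update(n=fit_rep.n, RMSE=fit_rep.rmse, PCC=fit_rep.pcc)
    if loo_rep is not None:
        row["RMSE_cv"] = loo_rep.rmse
        row["PCC_cv"] = loo_rep.pcc
    if ext_rep is not None:
        row.update(n=ext_rep.n, RMSE_PR=ext_rep.rmse, PCC_PR=ext_rep.pcc)
    return row


def run_benchmark(
    pair: tuple[ProteinDataset, ProteinDataset],
    predictions: Optional[list[PredictionTable]] = None,
    min_length: Optional[int] = None,
) -> pd.DataFrame:
    """Full pairwise comparison table for (A, B); see module docstring."""
    a, b = pair
    subsets = {
        "A∩B": overlap(a, b),
        "B∩A": overlap(b, a),
        "A\\B": difference(a, b),
        "B\\A": difference(b, a),
    }
    rows: list[dict] = []

    # chain-length baselines fitted on each overlap, tested on the opposite
    # difference (the subset whose experimental data they have never seen)
    for train_key, ext_keys in (("A∩B", ["A\\B", "B\\A"]), ("B∩A", ["B\\A", "A\\B"])):
        train = subsets[train_key]
        if len(train) < 4:
            logger.warning("subset %s too small to fit; skipping", train.name)
            continue
        try:
            res = fit_loglinear(train)
        except ValueError as exc:
            logger.warning("fit on %s failed: %s", train.name, exc)
            rows.append({**_model_row(f"loglinear[{train.name}]", train.name), "n": len(train)})
            continue
        model_name = f"loglinear[{train.name}]"
        rows.append(
            _model_row(
                model_name,
                train.name,
                fit_rep=evaluate_fit(res, train),
                loo_rep=loo_cv(train),
            )
        )
        for key in ext_keys:
            ext = subsets[key]
            if len(ext) == 0:
                logger.warning("subset %s empty; no external row", ext.name)
                continue
            rows.append(
                _model_row(
                    model_name,
                    ext.name,
                    ext_rep=evaluate_external(res, ext, min_length=min_length),
                )
            )

    for table in predictions or []:
        for key in ("A∩B", "B∩A", "A\\B", "B\\A"):
            subset = subsets[key]
            if len(subset) == 0:
                continue
            try:
                rep = evaluate_external(table, subset, min_length=min_length)
            except ValueError as exc:
                logger.warning(
                    "%s on %s: %s", table.predictor_name, subset.name, exc
                )
                continue
            rows.append(_model_row(table.predictor_name, subset.name, ext_rep=rep))

    df = pd.DataFrame(rows, columns=BENCH_COLUMNS)
    return df.sort_values(["model", "subset"], kind="stable").reset_index(drop=True)


def render_report(table: pd.DataFrame, path, format: str = "tsv") -> Path:
    """Write a comparison table: 2-decimal TSV/markdown display, full-precision JSON."""
    path = Path(path)
    df = table.copy()
    if format == "json":
        records = json.loads(df.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=2) + "\n")
        return path

    display = df.copy()
    for col in display.columns:
        if display[col].dtype.kind == "f" or col in BENCH_COLUMNS[3:]:
            display[col] = [
                "" if v is None or (isinstance(v, float) and pd.isna(v)) else (
                    f"{v:.2f}" if isinstance(v, float) else v
                )
                for v in display[col]
            ]
    if format == "tsv":
        display.to_csv(path, sep="\t", index=False)
        return path
    if format == "markdown":
        cols = list(display.columns)
        lines = [
            "| " + " | ".join(cols) + " |",
            "|" + "|".join("---" for _ in cols) + "|",
        ]
        for _, row in display.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ValueError(f"unknown format {format!r}")
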
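"""Plain-text I/O: expression TSV, clinical TSV, signature JSON, risk-call TSV.

Formats
-------
Expression
    Tab-separated; genes in rows by default.  Header row holds sample ids,
    first column holds gene ids, every cell is a decimal number.  Pass
    ``orientation="samples_in_rows"`` for the transposed layout.
Clinical
    Tab-separated with mandatory columns ``sample_id``, ``age_years``,
    ``endpoint_time``, ``endpoint_event``, ``treatment``; any further columns
    are carried as categorical covariates.  The age stratum is always derived
    from ``age_years``, never read from the file.
Signature
    JSON: ``{pairs: [{gene_high, gene_low, stats_per_cohort: {name: {log_hr,
    hr, p, n}}}], k, vote_rule, training_cindex, training_population}``.
Risk calls
    Tab-separated columns ``sample_id``, ``votes``, ``k``, ``label``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalRecord,
    Cohort,
    ExpressionMatrix,
    OrientedGenePair,
    PairStats,
    RiskCall,
    RiskLabel,
    Signature,
    Treatment,
    ValidationError,
)

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("sample_id", "age_years", "endpoint_time", "endpoint_event", "treatment")


def read_expression(path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV expression matrix.

    Raises a parse error naming the offending line for ragged rows and a
    validation error naming the cell for non-numeric or missing values.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed TSV: {exc}") from exc
    if frame.empty:
        raise ValidationError(f"{path}: empty expression table")
    if orientation == "samples_in_rows":
        frame = frame.T
    if frame.isna().any().any():
        r, c = next(zip(*np.where(frame.isna())))
        raise ValidationError(
            f"{path}: missing value at gene {frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = next(zip(*np.where(numeric.isna())))
        raise ValidationError(
            f"{path}: non-numeric value {frame.iat[r, c]!r} at gene "
            f"{frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    return ExpressionMatrix.from_frame(numeric)


def write_expression(matrix: ExpressionMatrix, path, orientation: str = "genes_in_rows") -> None:
    frame = matrix.to_frame()
    if orientation == "samples_in_rows":
        frame = frame.T
    frame.to_csv(path, sep="\t", index_label="id")


def read_clinical(path) -> list[ClinicalRecord]:
    """Read a clinical TSV into validated records (age stratum derived)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {missing}")
    extra = [c for c in frame.columns if c not in CLINICAL_COLUMNS]
    records: list[ClinicalRecord] = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        event_raw = d["endpoint_event"]
        if str(event_raw) not in ("0", "1"):
            raise ValidationError(
                f"{path}: sample {d['sample_id']}: endpoint_event must be 0 or 1, got {event_raw!r}"
            )
        try:
            treatment = Treatment(d["treatment"])
        except ValueError:
            raise ValidationError(
                f"{path}: sample {d['sample_id']}: unknown treatment {d['treatment']!r}"
            ) from None
        covariates = {c: d[c] for c in extra if pd.notna(d[c])}
        records.append(
            ClinicalRecord(
                sample_id=str(d["sample_id"]),
                age_years=float(d["age_years"]),
                endpoint_time=float(d["endpoint_time"]),
                endpoint_event=int(event_raw),
                treatment=treatment,
                covariates=covariates,
            )
        )
    return records


def write_clinical(records: Sequence[ClinicalRecord], path) -> None:
    extra = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "age_years": r.age_years,
            "endpoint_time": r.endpoint_time,
            "endpoint_event": r.endpoint_event,
            "treatment": r.treatment.value,
        }
        row.update({k: r.covariates.get(k, "") for k in extra})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_cohort(expr: ExpressionMatrix, clinical: Sequence[ClinicalRecord], name: str) -> Cohort:
    """Assemble a cohort from the samples present in both inputs.

    Samples present in only one input are dropped with a logged count; an
    empty intersection is an error.
    """
    expr_ids = set(expr.sample_ids)
    kept = [r for r in clinical if r.sample_id in expr_ids]
    clin_ids = {r.sample_id for r in clinical}
    if not kept:
        raise ValidationError(f"cohort {name!r}: expression and clinical samples are disjoint")
    n_drop_clin = len(clinical) - len(kept)
    n_drop_expr = len(expr_ids - clin_ids)
    if n_drop_clin or n_drop_expr:
        logger.info(
            "cohort %s: dropped %d clinical-only and %d expression-only samples",
            name, n_drop_clin, n_drop_expr,
        )
    return Cohort(expr, kept, name)


def _pair_to_json(pair: OrientedGenePair) -> dict:
    return {
        "gene_high": pair.gene_high,
        "gene_low": pair.gene_low,
        "stats_per_cohort": {
            c: {"log_hr": s.log_hr, "hr": s.hr, "p": s.p, "n": s.n}
            for c, s in pair.stats_per_cohort.items()
        },
    }


def _pair_from_json(obj: dict) -> OrientedGenePair:
    try:
        stats = {
            c: PairStats(log_hr=float(s["log_hr"]), hr=float(s["hr"]), p=float(s["p"]), n=int(s["n"]))
            for c, s in obj.get("stats_per_cohort", {}).items()
        }
        return OrientedGenePair(str(obj["gene_high"]), str(obj["gene_low"]), stats)
    except KeyError as exc:
        raise ValidationError(f"signature pair missing field {exc}") from None


def write_signature(sig: Signature, path) -> None:
    obj = {
        "pairs": [_pair_to_json(p) for p in sig.pairs],
        "k": sig.k,
        "vote_rule": sig.vote_rule,
        "threshold": sig.threshold_rule(),
        "training_cindex": sig.training_cindex,
        "training_population": sig.training_population,
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_signature(path) -> Signature:
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: malformed JSON: {exc}") from exc
    for fld in ("pairs", "vote_rule", "training_cindex"):
        if fld not in obj:
            raise ValidationError(f"{path}: signature JSON missing field {fld!r}")
    sig = Signature(
        pairs=tuple(_pair_from_json(p) for p in obj["pairs"]),
        training_cindex=float(obj["training_cindex"]),
        training_population=str(obj.get("training_population", "")),
        vote_rule=str(obj["vote_rule"]),
    )
    if "k" in obj and int(obj["k"]) != sig.k:
        raise ValidationError(f"{path}: declared k={obj['k']} but {sig.k} pairs present")
    return sig


def write_risk_calls(calls: Sequence[RiskCall], path) -> None:
    pd.DataFrame(
        [{"sample_id": c.sample_id, "votes": c.votes, "k": c.k, "label": c.label.value} for c in calls]
    ).to_csv(path, sep="\t", index=False)


def read_risk_calls(path) -> list[RiskCall]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id", "votes", "k", "label") if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: risk-call TSV missing columns {missing}")
    return [
        RiskCall(str(r.sample_id), int(r.votes), int(r.k), RiskLabel(r.label))
        for r in frame.itertuples(index=False)
    ]
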
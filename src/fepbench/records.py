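"""Domain types and table I/O for (TKI, mutation) benchmark records.

A benchmark row joins one experimentally measured binding free-energy change
(ΔΔG, kcal/mol) for a kinase point mutation against one or more predicted
values, each with an uncertainty. Tables are plain CSV with one row per
(TKI, mutation) pair; per-method columns follow the naming convention
``{method}_ddg``, ``{method}_sigma`` and optionally ``{method}_rep1..repK``
for replicate simulation runs.
"""

from __future__ import annotations

import csv
import math
import re
import statistics
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exceptions import (
    DuplicateKeyError,
    InsufficientReplicatesError,
    ParseError,
    SchemaError,
)

MUTATION_PATTERN = re.compile(r"^[A-Z]\d+[A-Z]$")

#: Default mapping from logical fields to CSV column names.
DEFAULT_SCHEMA: dict[str, str] = {
    "tki": "tki",
    "mutation": "mutation",
    "exp_ddg": "exp_ddg",
    "exp_sigma": "exp_sigma",
    "censored": "censored",
}


class Provenance(str, Enum):
    """Where a ΔΔG value came from."""

    EXPERIMENT = "experiment"
    PRIME = "prime"
    FEP = "fep"
    CONSENSUS = "consensus"
    NAIVE = "naive"
    SYNTHETIC_TRUTH = "synthetic_truth"


@dataclass(frozen=True)
class DeltaDeltaG:
    """A binding free-energy change with uncertainty (kcal/mol).

    ``censored`` marks a value that is only a lower bound (the underlying
    assay saturated); ``sigma`` is one standard deviation. Deterministic
    single-structure rescoring (provenance ``prime``) carries no statistical
    uncertainty, so ``sigma`` must be zero there.
    """

    value: float
    sigma: float = 0.0
    censored: bool = False
    provenance: Provenance = Provenance.EXPERIMENT

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"ΔΔG value must be finite, got {self.value}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.provenance == Provenance.PRIME and self.sigma != 0:
            raise ValueError("deterministic (prime) predictions must have sigma = 0")


@dataclass(frozen=True)
class AffinityMeasurement:
    """One wild-type/mutant potency pair from a single assay source.

    Concentrations are in nM. ``censored`` means the mutant potency exceeded
    the dynamic range of the assay (e.g. IC50 > 10,000 nM), in which case
    ``assay_limit`` records the ceiling and ``mut_value`` is the reported
    bound.
    """

    tki: str
    mutation: str
    kind: str  # "IC50" or "Kd"
    wt_value: float
    mut_value: float
    censored: bool = False
    assay_limit: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("IC50", "Kd"):
            raise ValueError(f"kind must be 'IC50' or 'Kd', got {self.kind!r}")
        if self.wt_value <= 0 or self.mut_value <= 0:
            raise ValueError("potency values must be positive concentrations")
        if not MUTATION_PATTERN.match(self.mutation):
            raise ValueError(
                f"mutation {self.mutation!r} does not match 'X###Z' (e.g. T315I)"
            )
        if self.censored:
            if self.assay_limit is None:
                raise ValueError("censored measurements require assay_limit")
            if self.mut_value < self.assay_limit:
                raise ValueError("censored implies mut_value >= assay_limit")
        elif self.assay_limit is not None and self.assay_limit <= 0:
            raise ValueError("assay_limit must be positive")


@dataclass(frozen=True)
class PredictionRecord:
    """One (TKI, mutation) row: experimental ΔΔG plus per-method predictions."""

    tki: str
    mutation: str
    experimental: DeltaDeltaG
    predictions: Mapping[str, DeltaDeltaG] = field(default_factory=dict)
    replicates: Mapping[str, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if not MUTATION_PATTERN.match(self.mutation):
            raise ValueError(
                f"mutation {self.mutation!r} does not match 'X###Z' (e.g. T315I)"
            )
        for name, pred in self.predictions.items():
            if pred.provenance == Provenance.EXPERIMENT:
                raise ValueError(f"prediction {name!r} has provenance 'experiment'")
        if self.replicates:
            for name, values in self.replicates.items():
                if name not in self.predictions:
                    raise ValueError(f"replicates for unknown method {name!r}")
                mean, sigma = aggregate_replicates(values)
                pred = self.predictions[name]
                if not math.isclose(pred.value, mean, rel_tol=0, abs_tol=1e-9):
                    raise ValueError(
                        f"{name!r} value {pred.value} != replicate mean {mean}"
                    )

    @property
    def key(self) -> tuple[str, str]:
        return (self.tki, self.mutation)

    def with_prediction(
        self, name: str, pred: DeltaDeltaG, replicates: Sequence[float] | None = None
    ) -> "PredictionRecord":
        """Return a copy with an additional (or replaced) method prediction."""
        preds = dict(self.predictions)
        preds[name] = pred
        reps = dict(self.replicates) if self.replicates else {}
        if replicates is not None:
            reps[name] = list(replicates)
        return replace(self, predictions=preds, replicates=reps or None)


def aggregate_replicates(
    values: Sequence[float], standard_error: bool = False
) -> tuple[float, float]:
    """Aggregate replicate ΔΔG estimates into (mean, sigma).

    ``sigma`` is the sample standard deviation (n-1 divisor), matching the
    convention under which the 95% CI of a triplicate run is value ± 1.96σ.
    Set ``standard_error=True`` to divide by √n and obtain the standard error
    of the reported mean instead.
    """
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise InsufficientReplicatesError(
            f"need at least 2 replicates, got {len(vals)}"
        )
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("replicate values must be finite")
    mean = statistics.fmean(vals)
    sigma = statistics.stdev(vals)
    if standard_error:
        sigma /= math.sqrt(len(vals))
    return mean, sigma


def infer_provenance(method: str) -> Provenance:
    """Map a method name to a provenance tag (unknown names count as FEP-like)."""
    try:
        return Provenance(method.lower())
    except ValueError:
        return Provenance.FEP


def method_names(records: Sequence[PredictionRecord]) -> list[str]:
    """Methods present on every record, in first-seen order."""
    if not records:
        return []
    names = list(records[0].predictions)
    common = set(names)
    for rec in records[1:]:
        common &= set(rec.predictions)
    return [n for n in names if n in common]


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ParseError(row, column, raw) from None
    if not math.isfinite(value):
        raise ParseError(row, column, raw)
    return value


def _parse_bool(raw: str, row: int, column: str) -> bool:
    text = (raw or "").strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", ""):
        return False
    raise ParseError(row, column, raw)


def read_benchmark_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[PredictionRecord]:
    """Read a CSV benchmark table into prediction records.

    ``schema`` maps the logical names tki/mutation/exp_ddg/exp_sigma/censored
    to the actual column headers; prediction methods are discovered from
    columns ending in ``_ddg`` (with optional ``_sigma`` and ``_rep<k>``
    companions). Rows with unparseable numerics are rejected with their row
    index; duplicate (tki, mutation) keys raise.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for logical in ("tki", "mutation", "exp_ddg"):
            if colmap[logical] not in header:
                raise SchemaError(
                    f"missing required column {colmap[logical]!r} (for {logical})"
                )
        exp_cols = {colmap[k] for k in colmap}
        methods: list[str] = []
        for col in header:
            if col.endswith("_ddg") and col not in exp_cols:
                methods.append(col[: -len("_ddg")])
        rep_cols: dict[str, list[str]] = {}
        for m in methods:
            reps = sorted(
                (c for c in header if re.fullmatch(re.escape(m) + r"_rep\d+", c)),
                key=lambda c: int(c.rsplit("rep", 1)[1]),
            )
            if reps:
                rep_cols[m] = reps

        records: list[PredictionRecord] = []
        seen: dict[tuple[str, str], int] = {}
        duplicates: list[tuple[str, str]] = []
        for i, row in enumerate(reader):
            tki = (row.get(colmap["tki"]) or "").strip()
            mutation = (row.get(colmap["mutation"]) or "").strip()
            exp_value = _parse_float(row[colmap["exp_ddg"]], i, colmap["exp_ddg"])
            sigma_col = colmap["exp_sigma"]
            exp_sigma = (
                _parse_float(row[sigma_col], i, sigma_col)
                if sigma_col in row and (row[sigma_col] or "").strip()
                else 0.0
            )
            cens_col = colmap["censored"]
            censored = (
                _parse_bool(row[cens_col], i, cens_col) if cens_col in row else False
            )
            experimental = DeltaDeltaG(
                exp_value, exp_sigma, censored, Provenance.EXPERIMENT
            )
            predictions: dict[str, DeltaDeltaG] = {}
            replicates: dict[str, list[float]] = {}
            for m in methods:
                raw = row.get(f"{m}_ddg")
                if raw is None or not raw.strip():
                    continue
                value = _parse_float(raw, i, f"{m}_ddg")
                raw_sigma = row.get(f"{m}_sigma")
                sigma = (
                    _parse_float(raw_sigma, i, f"{m}_sigma")
                    if raw_sigma and raw_sigma.strip()
                    else 0.0
                )
                predictions[m] = DeltaDeltaG(value, sigma, False, infer_provenance(m))
                if m in rep_cols:
                    vals = [
                        _parse_float(row[c], i, c)
                        for c in rep_cols[m]
                        if (row.get(c) or "").strip()
                    ]
                    if vals:
                        replicates[m] = vals
            record = PredictionRecord(
                tki, mutation, experimental, predictions, replicates or None
            )
            if record.key in seen:
                duplicates.append(record.key)
            seen[record.key] = i
            records.append(record)
        if duplicates:
            raise DuplicateKeyError(duplicates)
    return records


def write_benchmark_table(
    records: Sequence[PredictionRecord], path: str | Path
) -> None:
    """Write records as CSV with full float precision (losslessly re-readable)."""
    if not records:
        raise ValueError("cannot write an empty record list")
    methods = []
    for rec in records:
        for m in rec.predictions:
            if m not in methods:
                methods.append(m)
    n_reps = {
        m: max(
            (len(rec.replicates[m]) for rec in records
             if rec.replicates and m in rec.replicates),
            default=0,
        )
        for m in methods
    }
    header = ["tki", "mutation", "exp_ddg", "exp_sigma", "censored"]
    for m in methods:
        header += [f"{m}_ddg", f"{m}_sigma"]
        header += [f"{m}_rep{k + 1}" for k in range(n_reps[m])]
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row: list[str] = [
                rec.tki,
                rec.mutation,
                repr(rec.experimental.value),
                repr(rec.experimental.sigma),
                str(rec.experimental.censored).lower(),
            ]
            for m in methods:
                pred = rec.predictions.get(m)
                row += [repr(pred.value), repr(pred.sigma)] if pred else ["", ""]
                reps = (rec.replicates or {}).get(m, [])
                row += [repr(v) for v in reps]
                row += [""] * (n_reps[m] - len(reps))
            writer.writerow(row)


def records_to_frame(records: Iterable[PredictionRecord]):
    """Flatten records into a pandas DataFrame (one row per record)."""
    import pandas as pd

    rows = []
    for rec in records:
        row: dict[str, object] = {
            "tki": rec.tki,
            "mutation": rec.mutation,
            "exp_ddg": rec.experimental.value,
            "exp_sigma": rec.experimental.sigma,
            "censored": rec.experimental.censored,
        }
        for m, pred in rec.predictions.items():
            row[f"{m}_ddg"] = pred.value
            row[f"{m}_sigma"] = pred.sigma
        rows.append(row)
    return pd.DataFrame(rows)
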
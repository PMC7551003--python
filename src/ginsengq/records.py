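"""Literature-record data model, CSV I/O, impact-factor binning and tabulation.

A *study record* is one curated literature entry: what was studied (a whole
ginseng extract — white, red or black — or a single ginsenoside), which of the
eight benefit categories it addresses, the journal impact factor (IF), the
experiment type on the evidence hierarchy (in vitro < in vivo < human), and
the number of bioassays/biomarkers the study reports.  Continuous IFs are
discretized into ordinal bins so that the (IF bin x experiment type) grid can
be scored by the optimal-scaling step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXTRACTS",
    "GINSENOSIDES",
    "FUNCTIONS",
    "EXPERIMENT_TYPES",
    "DEFAULT_BIN_EDGES",
    "SchemaError",
    "EmptyStratumError",
    "StudyRecord",
    "CompositionRecord",
    "FrequencyTable",
    "BinSpec",
    "RecordSchema",
    "LoadReport",
    "read_study_records",
    "write_study_records",
    "bin_impact_factor",
    "tabulate_frequencies",
    "aggregate_evidence_counts",
    "summarize_composition",
    "composition_to_amounts",
    "read_composition_records",
    "load_evidence_counts",
    "load_weighted_amounts",
    "load_composition_summary",
]

#: Whole-product processing variants of Panax ginseng.
EXTRACTS = ("white", "red", "black")

#: The twelve individually studied ginsenosides.
GINSENOSIDES = (
    "Rg1", "Re", "Rf", "Rb1", "Rc", "Rb2",
    "Rd", "Rg2", "Rh1", "Rg3", "Rk1", "Rg5",
)

#: The eight benefit categories compared between variants.
FUNCTIONS = (
    "Enhanced Immunity",
    "Fatigue Relief",
    "Enhanced Blood Flow",
    "Enhanced Memory",
    "Antioxidant",
    "Antidepressant/Antianxiety",
    "Decreased Body Fat",
    "Decreased Blood Pressure",
)

#: Evidence hierarchy, lowest reliability first.
EXPERIMENT_TYPES = ("in vitro", "in vivo", "human")

#: Default IF cut points giving five bins; the real edges used in the original
#: survey were never published, so these are a documented free parameter.
DEFAULT_BIN_EDGES = (1.0, 2.0, 4.0, 8.0)

_SUBJECTS_CANONICAL = {s.lower(): s for s in EXTRACTS + GINSENOSIDES}
_FUNCTIONS_CANONICAL = {f.lower(): f for f in FUNCTIONS}

_DEFAULT_EXPERIMENT_ALIASES = {
    "in vitro": "in vitro",
    "in-vitro": "in vitro",
    "in_vitro": "in vitro",
    "invitro": "in vitro",
    "vitro": "in vitro",
    "in vivo": "in vivo",
    "in-vivo": "in vivo",
    "in_vivo": "in vivo",
    "invivo": "in vivo",
    "vivo": "in vivo",
    "human": "human",
    "human research": "human",
    "clinical": "human",
    "clinical trial": "human",
}


class SchemaError(ValueError):
    """A required column is missing or misnamed in an input table."""


class EmptyStratumError(ValueError):
    """A filter left no records; downstream scoring/testing is undefined."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


@dataclass(frozen=True)
class StudyRecord:
    """One curated literature record.

    ``score`` is unset on load and assigned by the optimal-scaling step.
    ``group`` is the binary regression indicator (0 = black, 1 = red,
    None for white extracts and single-ginsenoside studies).
    """

    record_id: str
    subject: str
    function: str
    experiment_type: str
    n_bioassays: int
    impact_factor: float | None = None
    year: int | None = None
    score: float | None = None

    def __post_init__(self):
        if self.subject not in EXTRACTS + GINSENOSIDES:
            raise ValueError(f"unknown subject {self.subject!r}")
        if self.function not in FUNCTIONS:
            raise ValueError(f"unknown function {self.function!r}")
        if self.experiment_type not in EXPERIMENT_TYPES:
            raise ValueError(f"unknown experiment type {self.experiment_type!r}")
        if not (isinstance(self.n_bioassays, (int, np.integer)) and self.n_bioassays >= 0):
            raise ValueError(f"n_bioassays must be a nonnegative integer, got {self.n_bioassays!r}")
        if self.impact_factor is not None and self.impact_factor < 0:
            raise ValueError("impact_factor must be nonnegative")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score!r}")

    @property
    def experiment_level(self) -> int:
        """Ordinal level on the evidence hierarchy, 1-based."""
        return EXPERIMENT_TYPES.index(self.experiment_type) + 1

    @property
    def group(self) -> int | None:
        if self.subject == "black":
            return 0
        if self.subject == "red":
            return 1
        return None

    @property
    def is_extract(self) -> bool:
        return self.subject in EXTRACTS

    def with_score(self, score: float) -> "StudyRecord":
        return replace(self, score=float(score))


@dataclass(frozen=True)
class CompositionRecord:
    """Summary of one (variant, compound) pair: mean mg/g over sources."""

    variant: str
    compound: str
    mean_amount: float
    sd: float | None = None
    n_sources: int = 1

    def __post_init__(self):
        if self.variant not in EXTRACTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.compound not in GINSENOSIDES:
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.mean_amount < 0:
            raise ValueError("mean_amount must be nonnegative")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")


@dataclass(frozen=True)
class BinSpec:
    """Strictly increasing cut points defining half-open IF bins.

    ``edges = (e1, .., e_{I-1})`` gives I bins: [0, e1), [e1, e2), ...,
    [e_{I-1}, inf).  Ordinal levels are 1-based, lowest IF first.
    """

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 1:
            raise ValueError("at least one edge required")
        if any(not math.isfinite(e) for e in edges):
            raise ValueError("edges must be finite")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1


@dataclass(frozen=True)
class FrequencyTable:
    """Counts f_ij over I impact-factor bins x J experiment types."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D grid")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return self.counts.shape[0]

    @property
    def J(self) -> int:
        return self.counts.shape[1]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RecordSchema:
    """Column naming and label-alias configuration for the records CSV."""

    record_id: str = "record_id"
    subject: str = "subject"
    function: str = "function"
    impact_factor: str = "impact_factor"
    experiment_type: str = "experiment_type"
    n_bioassays: str = "n_bioassays"
    year: str = "year"
    experiment_aliases: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_EXPERIMENT_ALIASES)
    )

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (
            self.record_id,
            self.subject,
            self.function,
            self.impact_factor,
            self.experiment_type,
            self.n_bioassays,
        )


@dataclass
class LoadReport:
    """Outcome of a CSV load: parsed records plus per-row rejections."""

    records: list[StudyRecord]
    rejected: list[tuple[int, str]]

    @property
    def n_accepted(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_study_records(path, schema: RecordSchema | None = None) -> LoadReport:
    """Load study records from CSV.

    Rows with unparseable required fields are rejected and reported in the
    :class:`LoadReport`, never silently dropped.  An unknown experiment-type
    label raises immediately (it usually signals a mislabeled corpus rather
    than a bad row), citing the offending row; a missing required column
    raises :class:`SchemaError` naming the column.  Row numbers count data
    rows from 1.
    """
    schema = schema or RecordSchema()
    frame = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    for column in schema.required_columns:
        if column not in frame.columns:
            raise SchemaError(f"missing required column {column!r}")

    aliases = {k.strip().lower(): v for k, v in schema.experiment_aliases.items()}
    records: list[StudyRecord] = []
    rejected: list[tuple[int, str]] = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        raw_exp = row[schema.experiment_type]
        if _is_missing(raw_exp):
            rejected.append((pos, "missing experiment_type"))
            continue
        exp = aliases.get(str(raw_exp).strip().lower())
        if exp is None:
            raise ValueError(
                f"row {pos}: unknown experiment-type label {str(raw_exp).strip()!r}"
            )
        try:
            rid = row[schema.record_id]
            if _is_missing(rid):
                raise ValueError("missing record_id")
            subject = _SUBJECTS_CANONICAL.get(str(row[schema.subject]).strip().lower())
            if subject is None:
                raise ValueError(f"unknown subject {row[schema.subject]!r}")
            function = _FUNCTIONS_CANONICAL.get(str(row[schema.function]).strip().lower())
            if function is None:
                raise ValueError(f"unknown function {row[schema.function]!r}")
            raw_if = row[schema.impact_factor]
            impact_factor = None if _is_missing(raw_if) else float(raw_if)
            if impact_factor is not None and impact_factor < 0:
                raise ValueError("negative impact_factor")
            n_bio = float(row[schema.n_bioassays])
            if not (n_bio >= 0 and float(n_bio).is_integer()):
                raise ValueError(f"n_bioassays must be a nonnegative integer, got {n_bio!r}")
            year = None
            if schema.year in frame.columns and not _is_missing(row.get(schema.year)):
                year = int(float(row[schema.year]))
            records.append(
                StudyRecord(
                    record_id=str(rid).strip(),
                    subject=subject,
                    function=function,
                    experiment_type=exp,
                    n_bioassays=int(n_bio),
                    impact_factor=impact_factor,
                    year=year,
                )
            )
        except (ValueError, TypeError) as exc:
            rejected.append((pos, str(exc)))
    return LoadReport(records=records, rejected=rejected)


def write_study_records(records: Iterable[StudyRecord], path) -> None:
    """Write records to the CSV schema :func:`read_study_records` accepts."""
    rows = [
        {
            "record_id": r.record_id,
            "subject": r.subject,
            "function": r.function,
            "impact_factor": "" if r.impact_factor is None else repr(float(r.impact_factor)),
            "experiment_type": r.experiment_type,
            "n_bioassays": r.n_bioassays,
            "year": "" if r.year is None else r.year,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def bin_impact_factor(
    if_value: float | None,
    spec: BinSpec,
    missing: str = "lowest",
) -> int:
    """Map a journal impact factor to its 1-based ordinal bin level.

    Bins are half-open, lower-inclusive: [0, e1), [e1, e2), ..., [e_last, inf).
    A missing IF maps to level 1 by default (lowest reliability, keeps the
    record usable); pass ``missing="reject"`` to raise instead.
    """
    if if_value is None or (isinstance(if_value, float) and math.isnan(if_value)):
        if missing == "lowest":
            return 1
        raise ValueError("missing impact factor rejected (missing='reject')")
    if if_value < 0:
        raise ValueError("impact factor must be nonnegative")
    return int(np.searchsorted(spec.edges, if_value, side="right")) + 1


def tabulate_frequencies(
    records: Sequence[StudyRecord],
    spec: BinSpec,
    function: str | None = None,
    subjects: Iterable[str] | None = None,
    missing_if: str = "lowest",
) -> FrequencyTable:
    """Count records per (IF bin, experiment type) cell for one stratum.

    ``function`` and ``subjects`` filter the records before tabulation.
    Raises :class:`EmptyStratumError` when the filter leaves no records,
    mirroring benefit categories for which one product has no literature at
    all and scoring/testing is undefined.
    """
    subject_set = set(subjects) if subjects is not None else None
    counts = np.zeros((spec.n_bins, len(EXPERIMENT_TYPES)), dtype=np.int64)
    n_kept = 0
    for rec in records:
        if function is not None and rec.function != function:
            continue
        if subject_set is not None and rec.subject not in subject_set:
            continue
        i = bin_impact_factor(rec.impact_factor, spec, missing=missing_if)
        counts[i - 1, rec.experiment_level - 1] += 1
        n_kept += 1
    if n_kept == 0:
        raise EmptyStratumError(
            f"no records in stratum (function={function!r}, subjects={subjects!r})"
        )
    return FrequencyTable(counts=counts)


def aggregate_evidence_counts(table: pd.DataFrame) -> tuple[pd.Series, int]:
    """Row totals and grand total of a per-(function, source) count table.

    ``table`` has one row per benefit category and one column per study
    subject; cells are nonnegative integer paper counts.  Returns the
    per-function totals (a Series indexed like the table) and the grand total.
    """
    values = table.to_numpy()
    if np.any(values < 0):
        raise ValueError("evidence counts must be nonnegative")
    per_function = table.sum(axis=1)
    return per_function, int(per_function.sum())


def summarize_composition(
    samples: Iterable[tuple[str, str, float]],
) -> list[CompositionRecord]:
    """Summarize per-source (variant, compound, mg/g amount) measurements.

    Returns one :class:`CompositionRecord` per observed (variant, compound)
    pair with the mean, the sample SD (n-1 denominator; missing when only one
    source contributed) and the number of contributing sources.  Pairs with no
    samples are simply absent.  Output order is deterministic (variant, then
    compound, in enumeration order).
    """
    frame = pd.DataFrame(samples, columns=["variant", "compound", "amount"])
    if len(frame) and (frame["amount"] < 0).any():
        raise ValueError("amounts must be nonnegative")
    out: list[CompositionRecord] = []
    grouped = frame.groupby(["variant", "compound"])["amount"]
    stats = {key: (g.mean(), g.std(ddof=1), len(g)) for key, g in grouped}
    for variant in EXTRACTS:
        for compound in GINSENOSIDES:
            if (variant, compound) in stats:
                mean, sd, n = stats[(variant, compound)]
                out.append(
                    CompositionRecord(
                        variant=variant,
                        compound=compound,
                        mean_amount=float(mean),
                        sd=None if n == 1 else float(sd),
                        n_sources=int(n),
                    )
                )
    return out


def composition_to_amounts(
    composition: Iterable[CompositionRecord], variant: str
) -> dict[str, float]:
    """Extract the compound -> mean mg/g map for one variant."""
    return {c.compound: c.mean_amount for c in composition if c.variant == variant}


def read_composition_records(path_or_buffer) -> list[CompositionRecord]:
    """Load a composition CSV (variant, compound, mean_mg_per_g, sd_mg_per_g, n_sources).

    ``sd_mg_per_g`` may be empty (single-source pairs); (variant, compound)
    pairs must be unique.
    """
    frame = pd.read_csv(path_or_buffer, comment="#")
    for column in ("variant", "compound", "mean_mg_per_g", "sd_mg_per_g", "n_sources"):
        if column not in frame.columns:
            raise SchemaError(f"missing required column {column!r}")
    if frame.duplicated(["variant", "compound"]).any():
        raise ValueError("(variant, compound) pairs must be unique")
    return [
        CompositionRecord(
            variant=str(row.variant).strip().lower(),
            compound=_normalize_compound(row.compound),
            mean_amount=float(row.mean_mg_per_g),
            sd=None if pd.isna(row.sd_mg_per_g) else float(row.sd_mg_per_g),
            n_sources=int(row.n_sources),
        )
        for row in frame.itertuples()
    ]


def _normalize_compound(raw) -> str:
    compound = _SUBJECTS_CANONICAL.get(str(raw).strip().lower())
    if compound is None or compound in EXTRACTS:
        raise ValueError(f"unknown compound {raw!r}")
    return compound


def _data_path(name: str):
    return resources.files("ginsengq").joinpath("data", name)


def load_evidence_counts() -> pd.DataFrame:
    """Packaged published per-(function, subject) literature counts."""
    with _data_path("evidence_counts.csv").open() as fh:
        return pd.read_csv(fh, comment="#", index_col="function")


def load_weighted_amounts() -> pd.DataFrame:
    """Packaged published weighted-amount cells (long format).

    Columns: function, variant, compound, weighted_mg_per_g.  Rows with
    compound == "Total" are the printed column totals (printed rounding).
    """
    with _data_path("weighted_amounts.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def load_composition_summary() -> list[CompositionRecord]:
    """Packaged published mg/g composition summaries per variant."""
    with _data_path("composition_summary.csv").open() as fh:
        return read_composition_records(fh)
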
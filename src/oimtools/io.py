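"""Data containers and CSV I/O for consumption surveys and occurrence tables.

Two axes of a chronic dietary exposure assessment are represented here:

* :class:`ConsumerTable` — the *variability* axis: one record per surveyed
  individual with body weight (kg) and mean daily consumption (g/day) per
  (category, subcategory) food group, averaged over the surveyed days.
* :class:`OccurrenceTable` — the *uncertainty* axis: one record per analysed
  food sample with the contaminant concentration (μg/g), the limit of
  detection (μg/g) and a left-censoring flag.

CSV schemas (comma-separated, UTF-8, mandatory header, ``.`` decimal):

* consumption: ``subject_id, body_weight_kg, age_y, category, subcategory,
  amount_g, day``
* occurrence: ``sample_id, category, subcategory, value_ug_g, lod_ug_g,
  censored``
* stratum map: ``raw_label, stratum``
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyTableError, StrataError, ValidationError

log = logging.getLogger("oimtools")

CONSUMPTION_COLUMNS = (
    "subject_id",
    "body_weight_kg",
    "age_y",
    "category",
    "subcategory",
    "amount_g",
    "day",
)
OCCURRENCE_COLUMNS = (
    "sample_id",
    "category",
    "subcategory",
    "value_ug_g",
    "lod_ug_g",
    "censored",
)

_REL_TOL = 1e-9


@dataclass(frozen=True)
class WeightScheme:
    """Non-negative weights over subcategories summing to one.

    Drives the weighted mean occurrence of wsOIM.  ``label`` is free text
    (e.g. ``"w_SO"`` for a sensitivity scenario or ``"w*"`` for the
    consumption-aware scheme).
    """

    weights: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        w = {str(k): float(v) for k, v in dict(self.weights).items()}
        if not w:
            raise ValidationError("weight scheme is empty")
        if any(v < 0 for v in w.values()):
            raise ValidationError(f"negative weight in scheme {self.label!r}: {w}")
        total = sum(w.values())
        if abs(total - 1.0) > _REL_TOL * max(1.0, abs(total)):
            raise ValidationError(
                f"weights in scheme {self.label!r} sum to {total!r}, expected 1"
            )
        object.__setattr__(self, "weights", w)

    def as_vector(self, labels: "list[str] | tuple[str, ...]") -> np.ndarray:
        """Weights aligned with ``labels``; raises if the key sets differ."""
        if set(labels) != set(self.weights):
            raise StrataError(
                f"weight scheme {self.label!r} keys {sorted(self.weights)} do not "
                f"match strata {sorted(set(labels))}"
            )
        return np.array([self.weights[s] for s in labels], dtype=float)


@dataclass(frozen=True)
class ConsumerRecord:
    """One surveyed individual: body weight, age and mean daily intake.

    ``intake`` maps ``(category, subcategory)`` to mean daily consumption in
    g/day; the category total is by construction the sum of its
    subcategories.
    """

    subject_id: str
    body_weight: float
    age: float
    intake: Mapping[tuple[str, str], float]

    def category_total(self, category: str) -> float:
        return sum(v for (c, _), v in self.intake.items() if c == category)


@dataclass
class ConsumerTable:
    """Per-individual body weights and mean daily consumption.

    ``subjects`` is indexed by ``subject_id`` with columns ``body_weight``
    (kg) and ``age`` (years); ``intake`` shares the index, with a
    ``(category, subcategory)`` MultiIndex on the columns, in g/day.
    """

    subjects: pd.DataFrame
    intake: pd.DataFrame
    survey_days: "int | Mapping[str, int]" = 1

    def __post_init__(self) -> None:
        if len(self.subjects) == 0:
            raise EmptyTableError("consumer table has no subjects")
        if not self.subjects.index.is_unique:
            dupes = self.subjects.index[self.subjects.index.duplicated()].tolist()
            raise ValidationError(f"duplicate subject ids: {dupes[:5]}")
        if not self.subjects.index.equals(self.intake.index):
            raise ValidationError("subjects and intake indexes differ")
        bw = self.subjects["body_weight"]
        if bw.isna().any() or (bw <= 0).any():
            bad = self.subjects.index[bw.isna() | (bw <= 0)].tolist()
            raise ValidationError(f"non-positive/missing body weight for {bad[:5]}")
        if (self.intake.to_numpy() < 0).any():
            raise ValidationError("negative consumption amount")
        if not isinstance(self.intake.columns, pd.MultiIndex):
            raise ValidationError("intake columns must be (category, subcategory)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def categories(self) -> list[str]:
        return list(dict.fromkeys(self.intake.columns.get_level_values(0)))

    def body_weights(self) -> np.ndarray:
        return self.subjects["body_weight"].to_numpy(dtype=float)

    def category_intake(self, category: str) -> np.ndarray:
        """Per-subject mean daily consumption of ``category`` (g/day)."""
        if category not in self.categories:
            raise ValidationError(f"unknown category {category!r}")
        return self.intake[category].sum(axis=1).to_numpy(dtype=float)

    def subcategory_totals(self, category: str) -> pd.Series:
        """Across-subject total of mean daily consumption per subcategory."""
        if category not in self.categories:
            raise ValidationError(f"unknown category {category!r}")
        return self.intake[category].sum(axis=0)

    def iter_records(self) -> Iterator[ConsumerRecord]:
        for sid in self.subjects.index:
            row = self.intake.loc[sid]
            intake = {(c, s): float(v) for (c, s), v in row.items()}
            yield ConsumerRecord(
                subject_id=str(sid),
                body_weight=float(self.subjects.at[sid, "body_weight"]),
                age=float(self.subjects.at[sid, "age"]),
                intake=intake,
            )

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format frame in the consumption CSV schema (one day)."""
        rows = []
        for sid in self.subjects.index:
            bw = self.subjects.at[sid, "body_weight"]
            age = self.subjects.at[sid, "age"]
            for (cat, sub), amount in self.intake.loc[sid].items():
                rows.append((sid, bw, age, cat, sub, amount, 1))
        return pd.DataFrame(rows, columns=list(CONSUMPTION_COLUMNS))

    def to_csv(self, path: "str | Path") -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class OccurrenceTable:
    """Per-sample contaminant concentrations with censoring metadata.

    ``data`` columns: ``sample_id, category, subcategory, value, lod,
    censored`` plus optional provenance columns (``scenario`` after LOD
    substitution, ``source_label`` after stratum collapsing, ``oil_type``
    from the synthetic seed-oil fixture).  ``value`` and ``lod`` are μg/g.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        required = ("sample_id", "category", "subcategory", "value", "lod", "censored")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"occurrence table missing columns {missing}")
        if len(df) == 0:
            raise EmptyTableError("occurrence table is empty")
        bad = df.loc[df["value"].isna() | (df["value"] < 0), "sample_id"]
        if len(bad):
            raise ValidationError(
                f"negative or missing concentration for sample(s) {bad.tolist()[:5]}"
            )
        bad = df.loc[df["lod"].isna() | (df["lod"] <= 0), "sample_id"]
        if len(bad):
            raise ValidationError(
                f"non-positive or missing LOD for sample(s) {bad.tolist()[:5]}"
            )
        df["censored"] = df["censored"].astype(bool)
        self.data = df

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def categories(self) -> list[str]:
        return list(dict.fromkeys(self.data["category"]))

    @property
    def strata(self) -> dict[str, np.ndarray]:
        """Map subcategory → positional row indices, in first-appearance order."""
        out: dict[str, np.ndarray] = {}
        subs = self.data["subcategory"].to_numpy()
        for s in dict.fromkeys(subs):
            out[s] = np.flatnonzero(subs == s)
        return out

    def subset(self, category: str) -> "OccurrenceTable":
        sub = self.data[self.data["category"] == category]
        if len(sub) == 0:
            raise EmptyTableError(f"no occurrence records for category {category!r}")
        return OccurrenceTable(sub.reset_index(drop=True))

    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    def to_csv(self, path: "str | Path") -> None:
        df = self.data.rename(columns={"value": "value_ug_g", "lod": "lod_ug_g"})
        df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} file missing columns {missing}")


def _to_numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise ValidationError(
            f"malformed {col!r} value {raw[bad.idxmax()]!r} in {what} file at row {row}"
        )
    return out


def read_consumption(
    path: "str | Path",
    category_filter: "set[str] | None" = None,
    adult_only: bool = False,
    survey_days: "int | None" = None,
) -> ConsumerTable:
    """Load a consumption survey CSV into a :class:`ConsumerTable`.

    Daily amounts are averaged per subject over the surveyed days into a
    chronic mean daily consumption; days without consumption of a food group
    count as 0 g/day (the divisor is the number of distinct survey days of
    the subject, counted before any category filtering, unless
    ``survey_days`` overrides it).  Subjects with missing or non-positive
    body weight are dropped with a logged count; ``adult_only`` drops
    subjects younger than 18.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path} is empty") from None
    _require_columns(df, CONSUMPTION_COLUMNS, "consumption")
    if len(df) == 0:
        raise EmptyTableError(f"{path} has a header but no records")
    for col in ("body_weight_kg", "age_y", "amount_g", "day"):
        df[col] = _to_numeric(df, col, "consumption")
    if (df["amount_g"].dropna() < 0).any():
        raise ValidationError("negative amount_g in consumption file")

    # survey days per subject, before any filtering
    if survey_days is None:
        days = df.groupby("subject_id")["day"].nunique()
    else:
        if survey_days < 1:
            raise ValidationError("survey_days must be >= 1")
        days = None

    bw = df.groupby("subject_id")["body_weight_kg"].first()
    age = df.groupby("subject_id")["age_y"].first()
    drop = bw.index[bw.isna() | (bw <= 0)]
    if len(drop):
        log.info("dropped %d subject(s) with missing body weight", len(drop))
    keep = bw.index.difference(drop)
    if adult_only:
        minors = age.index[age < 18]
        if len(minors):
            log.info("dropped %d subject(s) younger than 18", len(minors))
        keep = keep.difference(minors)
    if len(keep) == 0:
        raise EmptyTableError("all subjects dropped during loading")

    df = df[df["subject_id"].isin(keep)]
    if category_filter is not None:
        df = df[df["category"].isin(set(category_filter))]

    # mean daily consumption per subject x (category, subcategory)
    sums = (
        df.groupby(["subject_id", "category", "subcategory"])["amount_g"]
        .sum()
        .unstack(["category", "subcategory"], fill_value=0.0)
    )
    sums = sums.reindex(sorted(keep)).fillna(0.0)
    if survey_days is None:
        divisor = days.reindex(sums.index).clip(lower=1)
        intake = sums.div(divisor, axis=0)
    else:
        intake = sums / float(survey_days)
    if intake.shape[1] == 0:
        raise EmptyTableError("no consumption records after category filtering")

    subjects = pd.DataFrame(
        {"body_weight": bw.reindex(sums.index), "age": age.reindex(sums.index)}
    )
    intake.columns = pd.MultiIndex.from_tuples(
        intake.columns, names=["category", "subcategory"]
    )
    return ConsumerTable(
        subjects=subjects,
        intake=intake,
        survey_days=(
            survey_days if survey_days is not None else days.reindex(sums.index).to_dict()
        ),
    )


def read_stratum_map(path: "str | Path") -> dict[str, str]:
    """Read a ``raw_label, stratum`` CSV into a mapping."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("raw_label", "stratum"), "stratum map")
    return dict(zip(df["raw_label"], df["stratum"]))


def read_occurrence(
    path: "str | Path",
    stratum_map: "Mapping[str, str] | str | Path | None" = None,
) -> OccurrenceTable:
    """Load an occurrence CSV into an :class:`OccurrenceTable`.

    Censored flags are preserved as-is; LOD substitution is an explicit,
    separate step (:func:`oimtools.censoring.apply_lod_scenario`).  A
    ``stratum_map`` (mapping or CSV path) collapses fine subcategory labels
    into resampling strata, keeping the original label in ``source_label``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path} is empty") from None
    _require_columns(df, OCCURRENCE_COLUMNS, "occurrence")
    for col in ("value_ug_g", "lod_ug_g"):
        df[col] = _to_numeric(df, col, "occurrence")
    df = df.rename(columns={"value_ug_g": "value", "lod_ug_g": "lod"})
    if df["censored"].dtype == object:
        df["censored"] = (
            df["censored"].astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
        )
        if df["censored"].isna().any():
            raise ValidationError("unparseable censored flag in occurrence file")
    if stratum_map is not None:
        if not isinstance(stratum_map, Mapping):
            stratum_map = read_stratum_map(stratum_map)
        df["source_label"] = df["subcategory"]
        df["subcategory"] = df["subcategory"].map(
            lambda s: stratum_map.get(s, s)
        )
    return OccurrenceTable(df)


# ---------------------------------------------------------------------------
# estimate serialization


def write_estimates(result, path: "str | Path", force: bool = False) -> None:
    """Write an :class:`~oimtools.exposure.ExposureEstimate` to CSV or JSON.

    CSV output carries metadata in ``#``-prefixed header lines and one row
    per requested percentile; floats are written with shortest round-trip
    ``repr`` so a read-back is bit-exact.  For a deterministic-only estimate
    the CI columns are omitted.  Refuses to overwrite unless ``force``.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    d = result.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
        return
    lines = ["# oimtools-estimate v1"]
    for key in ("method", "scheme", "units", "B", "level", "seed_consumers",
                "seed_occurrence"):
        if d.get(key) is not None:
            lines.append(f"# {key}={d[key]!r}")
    has_ci = d["ci"] is not None
    header = "probability,de_ug_per_kg_bw_day"
    if has_ci:
        header += ",ci_lower_ug_per_kg_bw_day,ci_upper_ug_per_kg_bw_day"
    lines.append(header)
    for p in d["probs"]:
        row = f"{p!r},{d['de'][repr(p)]!r}"
        if has_ci:
            lo, hi = d["ci"][repr(p)]
            row += f",{lo!r},{hi!r}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_estimates(path: "str | Path"):
    """Read back a file written by :func:`write_estimates`."""
    from .exposure import ExposureEstimate  # local import: avoids a cycle

    path = Path(path)
    if path.suffix.lower() == ".json":
        return ExposureEstimate.from_dict(json.loads(path.read_text()))
    meta: dict[str, object] = {}
    rows: list[list[str]] = []
    header: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("# ") and "=" in line:
            key, _, raw = line[2:].partition("=")
            import ast

            meta[key] = ast.literal_eval(raw)
        elif line.startswith("#") or not line.strip():
            continue
        elif not header:
            header = line.split(",")
        else:
            rows.append(line.split(","))
    probs = [float(r[0]) for r in rows]
    de = {repr(float(r[0])): float(r[1]) for r in rows}
    ci = None
    if len(header) == 4:
        ci = {repr(float(r[0])): [float(r[2]), float(r[3])] for r in rows}
    d = {
        "method": meta.get("method"),
        "scheme": meta.get("scheme", ""),
        "units": meta.get("units", "ug/kg bw/day"),
        "B": meta.get("B", 0),
        "level": meta.get("level"),
        "seed_consumers": meta.get("seed_consumers"),
        "seed_occurrence": meta.get("seed_occurrence"),
        "probs": probs,
        "de": de,
        "ci": ci,
    }
    return ExposureEstimate.from_dict(d)
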
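"""Survey CSV schema, run configuration, and result-table output.

The interchange format is a plain comma-separated UTF-8 file with a
header and one row per household::

    household_id,adults,kids,food_who,food_wb,total,oop,weight

``food_who`` excludes alcohol, tobacco and food away from home;
``food_wb`` includes them.  ``oop`` is out-of-pocket health payments
excluding insurance premiums and third-party-reimbursed costs.  All
monetary columns are currency per month; ``weight`` is the household
survey weight.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_COLUMNS",
    "HouseholdRecord",
    "RunConfig",
    "read_survey",
    "records_to_frame",
    "frame_to_records",
    "validate_frame",
    "write_records",
    "write_results",
]

logger = logging.getLogger("cheimp")

SCHEMA_COLUMNS = (
    "household_id",
    "adults",
    "kids",
    "food_who",
    "food_wb",
    "total",
    "oop",
    "weight",
)

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15, 0.25, 0.40)

# Optional column cross-checked against total - food_wb, then dropped.
_NONFOOD_RTOL = 1e-6


@dataclass(frozen=True)
class HouseholdRecord:
    """One survey household.

    Attributes
    ----------
    household_id
        Opaque identifier.
    adults, kids
        Persons aged 15+ and 14-and-under, respectively.
    food_who, food_wb
        Monthly food expenditure excluding / including alcohol, tobacco
        and food away from home.
    total
        Total monthly household consumption expenditure.
    oop
        Monthly out-of-pocket health payments.
    weight
        Positive survey weight.
    """

    household_id: str
    adults: int
    kids: int
    food_who: float
    food_wb: float
    total: float
    oop: float
    weight: float

    def validate(self) -> None:
        if self.adults < 0 or self.kids < 0:
            raise ValueError(f"{self.household_id}: negative person count")
        if self.adults + self.kids < 1:
            raise ValueError(f"{self.household_id}: empty household")
        if not (0 <= self.food_who <= self.food_wb <= self.total):
            raise ValueError(
                f"{self.household_id}: need 0 <= food_who <= food_wb <= total"
            )
        if not (0 <= self.oop <= self.total - self.food_wb):
            raise ValueError(
                f"{self.household_id}: OOP must lie within nonfood expenditure"
            )
        if not (np.isfinite(self.weight) and self.weight > 0):
            raise ValueError(f"{self.household_id}: weight must be positive and finite")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one analysis run.

    Defaults reproduce the standard setup: child cost ``alpha = 0.5``,
    scale economy ``theta = 0.9``, the 45th-55th percentile food-share
    band, catastrophe thresholds {5, 10, 15, 25, 40}% and all three
    capacity-to-pay methods.
    """

    alpha: float = 0.5
    theta: float = 0.9
    band_lo: float = 0.45
    band_hi: float = 0.55
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    methods: tuple[str, ...] = ("who", "wb", "nf")
    equivalise_oop: bool = False
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (0.0 < self.theta <= 1.0):
            raise ValueError("theta must lie in (0, 1]")
        if not (0.0 <= self.band_lo < self.band_hi <= 1.0):
            raise ValueError("band bounds must satisfy 0 <= lo < hi <= 1")
        ts = tuple(self.thresholds)
        if any(not (0.0 < t <= 1.0) for t in ts):
            raise ValueError("thresholds must lie in (0, 1]")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")
        unknown = set(self.methods) - {"who", "wb", "nf"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        object.__setattr__(self, "thresholds", ts)
        object.__setattr__(self, "methods", tuple(self.methods))

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from a TOML file; keyword overrides win."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("thresholds", "methods"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["methods"] = list(self.methods)
        return d


def records_to_frame(records: Iterable[HouseholdRecord]) -> pd.DataFrame:
    """Stack records into the canonical survey frame."""
    rows = list(records)
    if not rows:
        raise ValueError("no records")
    frame = pd.DataFrame([asdict(r) for r in rows], columns=list(SCHEMA_COLUMNS))
    frame["household_id"] = frame["household_id"].astype(str)
    frame["adults"] = frame["adults"].astype(int)
    frame["kids"] = frame["kids"].astype(int)
    for col in ("food_who", "food_wb", "total", "oop", "weight"):
        frame[col] = frame[col].astype(float)
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[HouseholdRecord]:
    return [
        HouseholdRecord(
            household_id=str(r.household_id),
            adults=int(r.adults),
            kids=int(r.kids),
            food_who=float(r.food_who),
            food_wb=float(r.food_wb),
            total=float(r.total),
            oop=float(r.oop),
            weight=float(r.weight),
        )
        for r in frame.itertuples(index=False)
    ]


def validate_frame(frame: pd.DataFrame, strict: bool = True) -> tuple[pd.DataFrame, int]:
    """Check every record invariant on a survey frame.

    In strict mode the first violation aborts; in lenient mode violating
    rows are dropped and the drop count returned and logged.
    """
    ok = (
        (frame["adults"] >= 0)
        & (frame["kids"] >= 0)
        & (frame["adults"] + frame["kids"] >= 1)
        & (frame["food_who"] >= 0)
        & (frame["food_who"] <= frame["food_wb"])
        & (frame["food_wb"] <= frame["total"])
        & (frame["oop"] >= 0)
        & (frame["oop"] <= frame["total"] - frame["food_wb"])
        & (frame["weight"] > 0)
        & np.isfinite(frame["weight"])
    )
    n_bad = int((~ok).sum())
    if n_bad and strict:
        bad_ids = frame.loc[~ok, "household_id"].head(5).tolist()
        raise ValueError(
            f"{n_bad} row(s) violate record invariants (first ids: {bad_ids})"
        )
    if n_bad:
        logger.info("dropped %d invalid row(s) in lenient mode", n_bad)
    return frame[ok].reset_index(drop=True), n_bad


def read_survey(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a household survey CSV.

    Returns the validated frame (lenient mode drops and logs violating
    rows).  An optional ``nonfood`` column, when present, is
    cross-checked against ``total - food_wb`` and then dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(
            path, dtype={"household_id": str}, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty survey file") from None
    if frame.empty:
        raise ValueError(f"{path}: survey file contains no rows")

    missing = set(SCHEMA_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing schema column(s) {sorted(missing)}")
    extra = set(frame.columns) - set(SCHEMA_COLUMNS) - {"nonfood"}
    if extra:
        raise ValueError(f"{path}: unexpected column(s) {sorted(extra)}")

    for col in ("adults", "kids", "food_who", "food_wb", "total", "oop", "weight"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(f"{path}: non-numeric or missing {col!r} at data row {row}")
        frame[col] = coerced
    for col in ("adults", "kids"):
        if not np.all(np.mod(frame[col], 1) == 0):
            raise ValueError(f"{path}: column {col!r} must be integral")
        frame[col] = frame[col].astype(int)

    if "nonfood" in frame.columns:
        implied = frame["total"] - frame["food_wb"]
        mismatch = ~np.isclose(frame["nonfood"], implied, rtol=_NONFOOD_RTOL, atol=0.0)
        if mismatch.any():
            raise ValueError(
                f"{path}: 'nonfood' column inconsistent with total - food_wb "
                f"in {int(mismatch.sum())} row(s)"
            )
        frame = frame.drop(columns=["nonfood"])

    frame = frame[list(SCHEMA_COLUMNS)]
    n_in = len(frame)
    frame, n_dropped = validate_frame(frame, strict=strict)
    logger.info("read %d rows from %s, kept %d", n_in, path, len(frame))
    return frame


def write_records(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a survey frame in the canonical CSV schema (round-trip exact)."""
    frame = frame[list(SCHEMA_COLUMNS)]
    # repr is the shortest decimal form that parses back to the same float
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def _estimate_rows(estimates) -> list[dict]:
    rows = []
    for e in estimates:
        rows.append(
            {
                "method": e.method,
                "threshold": e.threshold,
                "point": e.point,
                "ci_lo": e.ci_lo,
                "ci_hi": e.ci_hi,
                "n_flagged": e.n_flagged,
                "n_total": e.n_total,
            }
        )
    return rows


def _format_cell(e) -> str:
    return f"{e.point:.4f} ({e.ci_lo:.4f}, {e.ci_hi:.4f})"


def _markdown_table(estimates) -> str:
    """Incidence table: rows = thresholds, columns = methods."""
    che = [e for e in estimates if e.threshold is not None]
    imp = [e for e in estimates if e.threshold is None]
    methods = list(dict.fromkeys(e.method for e in che))
    thresholds = sorted({e.threshold for e in che})
    lines = []
    if che:
        header = "| Threshold | " + " | ".join(methods) + " |"
        sep = "|---" * (len(methods) + 1) + "|"
        lines += [header, sep]
        cells = {(e.method, e.threshold): _format_cell(e) for e in che}
        for t in thresholds:
            row = [f"≥ {100 * t:g}%"]
            row += [cells.get((m, t), "—") for m in methods]
            lines.append("| " + " | ".join(row) + " |")
    for e in imp:
        lines.append("")
        lines.append(f"Impoverished households: {_format_cell(e)}")
    return "\n".join(lines) + "\n"


def write_results(
    estimates: Sequence,
    path: str | Path,
    fmt: str = "json",
    config: RunConfig | None = None,
    poverty_line=None,
    diagnostics: dict | None = None,
) -> None:
    """Write incidence estimates to ``path`` as csv, json or markdown.

    Output is deterministic: identical inputs give byte-identical files.
    Percentages are rendered with 4 decimal places in the human-readable
    formats.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to write")
    path = Path(path)
    if fmt == "json":
        payload: dict = {"estimates": _estimate_rows(estimates)}
        if config is not None:
            payload["config"] = config.to_dict()
        if poverty_line is not None:
            payload["poverty_line"] = {
                "ell": poverty_line.ell,
                "band_lo_value": poverty_line.band_lo_value,
                "band_hi_value": poverty_line.band_hi_value,
                "n_band": poverty_line.n_band,
                "total_band_weight": poverty_line.total_band_weight,
            }
        if diagnostics is not None:
            payload["diagnostics"] = diagnostics
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        pd.DataFrame(_estimate_rows(estimates)).to_csv(path, index=False)
    elif fmt == "markdown":
        path.write_text(_markdown_table(estimates))
    else:
        raise ValueError(f"unknown output format: {fmt!r}")
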
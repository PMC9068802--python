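"""Twin-pair data model, Dutch track recoding rules, and CSV I/O.

The analysis sample is a wide table with one row per twin pair: zygosity
(MZ/DZ) plus, for each twin, secondary-school attainment on a 0-4 track
scale, a CITO-like performance score (nominal range 501-550), tracking
timing (immediate vs delayed vs missing), sex, and birth year.
Performance and birth year are mean-centered against the loaded sample;
the centering constants travel with the table so downstream fits are
reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MZ",
    "DZ",
    "IMMEDIATE",
    "DELAYED",
    "MISSING",
    "RecodingError",
    "PairTableError",
    "TwinRecord",
    "TwinPair",
    "GroupLabel",
    "PairTable",
    "score_attainment",
    "determine_tracking_timing",
    "assign_pair_group",
    "load_pair_table",
    "write_pair_table",
]

MZ = "MZ"
DZ = "DZ"
IMMEDIATE = "immediate"
DELAYED = "delayed"
MISSING = "missing"
TRACKING_LEVELS = (IMMEDIATE, DELAYED, MISSING)

#: genetic relatedness by zygosity
RELATEDNESS = {MZ: 1.0, DZ: 0.5}

BASE_COLUMNS = ["pair_id", "zygosity"] + [
    f"{col}_{i}"
    for i in (1, 2)
    for col in ("attainment", "performance", "tracking", "male", "birth_year")
]


class RecodingError(ValueError):
    """A track label or report could not be recoded."""


class PairTableError(ValueError):
    """A pair table failed validation at load time."""


# ---------------------------------------------------------------------------
# recoding rules
# ---------------------------------------------------------------------------

# Track scores: the three VMBO tracks prepare for senior secondary
# vocational school, HAVO for tertiary vocational college, VWO/Gymnasium
# for university.
_TRACK_SCORES = {
    "vmbo-b": 0.0,
    "vmbo-basis": 0.0,
    "vmbo-k": 1.0,
    "vmbo-kader": 1.0,
    "vmbo-g/t": 2.0,
    "vmbo-g": 2.0,
    "vmbo-t": 2.0,
    "vmbo-gemengd": 2.0,
    "vmbo-theoretisch": 2.0,
    "vmbo-gemengd/theoretisch": 2.0,
    "havo": 3.0,
    "vwo": 4.0,
    "gymnasium": 4.0,
    "vwo/gymnasium": 4.0,
}

# Era-specific combined answer categories.  2004-2008 surveys offered a
# single "VMBO" category (scored 1.5, the enrolment-weighted VMBO mean);
# 2009-2014 surveys offered "VMBO" (= basis/kader, scored 0.5) next to
# "VMBO-theoretisch".  The age-12 survey lists all tracks separately, so a
# bare "VMBO" is not a recognized category there.
_ERA_OVERRIDES = {
    "2004-2008": {"vmbo": 1.5},
    "2009-2014": {"vmbo": 0.5},
    "age-12-survey": {},
}


def _normalize_label(label: str) -> str:
    s = label.strip().lower()
    s = re.sub(r"[\s_]+", "-", s)
    s = re.sub(r"-+", "-", s)
    return s


def score_attainment(
    reported_tracks: Sequence[str], survey_era: str = "age-12-survey"
) -> float:
    """Numeric attainment score for one or more reported track labels.

    Scores are 0 = VMBO-b, 1 = VMBO-k, 2 = VMBO-g/t, 3 = HAVO,
    4 = VWO/Gymnasium; era-specific combined categories follow the survey
    coding rules, and multiple reported levels are averaged.  An empty
    report returns NaN (missing); an unrecognized label raises
    :class:`RecodingError` naming the label.
    """
    if survey_era not in _ERA_OVERRIDES:
        raise RecodingError(
            f"unknown survey era {survey_era!r}; expected one of {sorted(_ERA_OVERRIDES)}"
        )
    if len(reported_tracks) == 0:
        return float("nan")
    scores = []
    table = {**_TRACK_SCORES, **_ERA_OVERRIDES[survey_era]}
    for label in reported_tracks:
        key = _normalize_label(label)
        if key not in table:
            raise RecodingError(
                f"unrecognized track label {label!r} for survey era {survey_era!r}"
            )
        scores.append(table[key])
    return float(np.mean(scores))


def determine_tracking_timing(
    mother_report: int | None, father_report: int | None
) -> str:
    """Tracking timing from parental reports of track levels in the class.

    A child in a class combining two or more track levels has definitive
    tracking delayed; exactly one level means immediate tracking.  The
    mother's report takes priority; the father's is used only when the
    mother's is missing.
    """
    for report in (mother_report, father_report):
        if report is None:
            continue
        if report < 1:
            raise ValueError(f"track-level count must be >= 1, got {report}")
        return DELAYED if report >= 2 else IMMEDIATE
    return MISSING


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class TwinRecord:
    """One twin's phenotypes, moderator, tracking status, and covariates."""

    attainment: float = float("nan")
    performance: float = float("nan")
    tracking: str = MISSING
    male: float = float("nan")
    birth_year: float = float("nan")
    performance_centered: float = float("nan")

    def __post_init__(self) -> None:
        if self.tracking not in TRACKING_LEVELS:
            raise ValueError(
                f"tracking must be one of {TRACKING_LEVELS}, got {self.tracking!r}"
            )

    @property
    def attainment_missing(self) -> bool:
        return bool(np.isnan(self.attainment))

    @property
    def performance_missing(self) -> bool:
        return bool(np.isnan(self.performance))


@dataclass
class TwinPair:
    """An MZ or DZ pair; relatedness follows from zygosity."""

    pair_id: str
    zygosity: str
    twin1: TwinRecord
    twin2: TwinRecord

    def __post_init__(self) -> None:
        if self.zygosity not in RELATEDNESS:
            raise ValueError(f"zygosity must be MZ or DZ, got {self.zygosity!r}")

    @property
    def relatedness(self) -> float:
        return RELATEDNESS[self.zygosity]


@dataclass(frozen=True)
class GroupLabel:
    """Zygosity crossed with pair tracking concordance."""

    zygosity: str
    concordance: str  # both-immediate | both-delayed | discordant | tracking-missing

    def __str__(self) -> str:  # e.g. "MZ/both-immediate"
        return f"{self.zygosity}/{self.concordance}"


def assign_pair_group(pair: TwinPair) -> GroupLabel:
    """Pair-level descriptive group label.

    Concordant observed statuses map to the matching label; any pattern
    involving a missing status goes to the tracking-missing group (for
    model fitting each twin's own status still drives its parameters).
    """
    t1, t2 = pair.twin1.tracking, pair.twin2.tracking
    if MISSING in (t1, t2):
        concordance = "tracking-missing"
    elif t1 == t2:
        concordance = f"both-{t1}"
    else:
        concordance = "discordant"
    return GroupLabel(pair.zygosity, concordance)


# ---------------------------------------------------------------------------
# table container and I/O
# ---------------------------------------------------------------------------


@dataclass
class PairTable:
    """A wide pair table plus the centering constants of its sample.

    ``df`` holds the base columns (see :data:`BASE_COLUMNS`) with NaN for
    missing values and the derived ``performance_centered_1/2`` columns.
    """

    df: pd.DataFrame
    performance_mean: float = float("nan")
    birth_year_mean: float = float("nan")

    def __post_init__(self) -> None:
        missing_cols = [c for c in BASE_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise PairTableError(f"pair table is missing columns: {missing_cols}")
        self._recenter()

    def _recenter(self) -> None:
        perf = pd.concat(
            [self.df["performance_1"], self.df["performance_2"]], ignore_index=True
        )
        if np.isnan(self.performance_mean):
            self.performance_mean = float(perf.mean()) if perf.notna().any() else 0.0
        yob = pd.concat(
            [self.df["birth_year_1"], self.df["birth_year_2"]], ignore_index=True
        )
        if np.isnan(self.birth_year_mean):
            self.birth_year_mean = float(yob.mean()) if yob.notna().any() else 0.0
        for i in (1, 2):
            self.df[f"performance_centered_{i}"] = (
                self.df[f"performance_{i}"] - self.performance_mean
            )

    @property
    def n_pairs(self) -> int:
        return len(self.df)

    @property
    def n_twins(self) -> int:
        return 2 * len(self.df)

    def pairs(self) -> Iterable[TwinPair]:
        """Iterate the table as :class:`TwinPair` records."""
        for row in self.df.itertuples(index=False):
            twins = []
            for i in (1, 2):
                tracking = getattr(row, f"tracking_{i}")
                twins.append(
                    TwinRecord(
                        attainment=_nanfloat(getattr(row, f"attainment_{i}")),
                        performance=_nanfloat(getattr(row, f"performance_{i}")),
                        tracking=tracking if isinstance(tracking, str) and tracking else MISSING,
                        male=_nanfloat(getattr(row, f"male_{i}")),
                        birth_year=_nanfloat(getattr(row, f"birth_year_{i}")),
                        performance_centered=_nanfloat(
                            getattr(row, f"performance_centered_{i}")
                        ),
                    )
                )
            yield TwinPair(str(row.pair_id), row.zygosity, twins[0], twins[1])

    def group_counts(self) -> pd.Series:
        """Pair counts over the zygosity x concordance cells."""
        labels = [str(assign_pair_group(p)) for p in self.pairs()]
        return pd.Series(labels, dtype="object").value_counts().sort_index()

    def tracking_status(self, twin: int) -> pd.Series:
        """Per-twin tracking status with blanks normalized to 'missing'."""
        s = self.df[f"tracking_{twin}"]
        return s.where(s.isin([IMMEDIATE, DELAYED]), MISSING)


def _nanfloat(v) -> float:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return float("nan")
    return f


def load_pair_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> PairTable:
    """Read a wide pair-table CSV, validating structure and recoding blanks.

    ``column_map`` optionally maps file headers to the canonical names.
    Missing mandatory columns, unparseable zygosity codes, invalid
    tracking values, and duplicated pair ids raise :class:`PairTableError`
    listing the offending rows.
    """
    df = pd.read_csv(path, dtype={"pair_id": str}, keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    missing_cols = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PairTableError(f"{path}: missing mandatory columns {missing_cols}")
    df = df[BASE_COLUMNS].copy()

    bad_zyg = df.index[~df["zygosity"].isin([MZ, DZ])].tolist()
    if bad_zyg:
        raise PairTableError(f"{path}: unparseable zygosity in rows {bad_zyg}")
    dup = df.index[df["pair_id"].duplicated(keep=False)].tolist()
    if dup:
        raise PairTableError(f"{path}: duplicated pair ids in rows {dup}")

    for i in (1, 2):
        col = f"tracking_{i}"
        df[col] = df[col].fillna(MISSING).replace({"": MISSING})
        bad = df.index[~df[col].isin(TRACKING_LEVELS)].tolist()
        if bad:
            raise PairTableError(f"{path}: invalid {col} values in rows {bad}")
        for num in ("attainment", "performance", "male", "birth_year"):
            df[f"{num}_{i}"] = pd.to_numeric(df[f"{num}_{i}"], errors="raise")

    observed = np.zeros(len(df), dtype=bool)
    for i in (1, 2):
        observed |= df[f"attainment_{i}"].notna().to_numpy()
        observed |= df[f"performance_{i}"].notna().to_numpy()
    empty = df.index[~observed].tolist()
    if empty:
        raise PairTableError(f"{path}: rows with no observed phenotype: {empty}")
    return PairTable(df)


def write_pair_table(table: PairTable | pd.DataFrame, path: str | Path) -> None:
    """Write the base columns as UTF-8 CSV; missing values become empty cells."""
    df = table.df if isinstance(table, PairTable) else table
    out = df[BASE_COLUMNS].copy()
    for i in (1, 2):
        col = f"tracking_{i}"
        out[col] = out[col].replace({MISSING: ""})
    out.to_csv(path, index=False, na_rep="")
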
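"""Three-table data model for mouse-tracking classification experiments.

The interchange format is plain CSV (comma separated, UTF-8, one header
row), three tables per dataset:

``samples.csv``
    One row per cursor sample: ``participant_id, trial_id, t_ms, x_px,
    y_px``.  Within a trial ``t_ms`` starts at 0 (tracking begins when
    the cursor leaves the start button) and is strictly increasing.
``trials.csv``
    One row per trial: stimulus identity, food type (healthy/unhealthy),
    the classification made (tasty/not_tasty), which response box was
    clicked, presentation order, and the observed start/click pixels.
``participants.csv``
    One row per participant: demographics, experimental condition, the
    three explicit-scale items (1-7) and the food-frequency items (1-8).

Readers parse and normalise; cross-table invariants are checked by
:func:`validate_dataset`, which reports violations rather than raising.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError

SAMPLE_COLUMNS = ["participant_id", "trial_id", "t_ms", "x_px", "y_px"]
TRIAL_COLUMNS = [
    "participant_id", "trial_id", "stimulus_id", "food_type",
    "classification", "response_side", "presentation_index",
    "start_x_px", "start_y_px", "click_x_px", "click_y_px",
]
PARTICIPANT_BASE_COLUMNS = [
    "participant_id", "age", "gender", "education", "condition",
    "uti_item_1", "uti_item_2", "uti_item_3",
]

FOOD_TYPES = ("healthy", "unhealthy")
CLASSIFICATIONS = ("tasty", "not_tasty")
RESPONSE_SIDES = ("left", "right")
CONDITIONS = ("none", "utilitarian", "hedonic")

#: Which response box is the "tasty" box.  The task places "tasty" in
#: the upper-left corner; datasets that counterbalance sides can
#: override this in validate_dataset.
DEFAULT_TASTY_SIDE = "left"


@dataclass
class ValidationIssue:
    code: str
    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.code}] {self.location}: {self.message}"


@dataclass
class ValidationReport:
    """Outcome of cross-table validation.  ``errors`` empty iff the
    dataset satisfies every documented invariant."""

    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error_codes(self) -> list[str]:
        return [e.code for e in self.errors]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def _to_numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise FormatError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in "
                f"column {col!r} at line {line}"
            )
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise FormatError(
                f"{path}: missing value in column {col!r} at line {line}"
            )
        df[col] = converted
    return df


def _normalize_categorical(df: pd.DataFrame, col: str, allowed: tuple[str, ...],
                           path) -> pd.DataFrame:
    df = df.copy()
    df[col] = df[col].astype(str).str.strip().str.lower().str.replace(" ", "_")
    bad = ~df[col].isin(allowed)
    if bad.any():
        value = df[col][bad.idxmax()]
        raise FormatError(
            f"{path}: invalid value {value!r} in column {col!r}; "
            f"allowed values: {', '.join(allowed)}"
        )
    return df


def read_samples(path) -> pd.DataFrame:
    """Read a cursor-sample log.

    Raises :class:`FormatError` if a required column is absent or a
    coordinate fails to parse (the message names the offending line).
    Row order is preserved; monotonicity of ``t_ms`` is *not* enforced
    here — that is :func:`validate_dataset`'s job.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True, comment="#")
    _require_columns(df, SAMPLE_COLUMNS, path)
    df = _to_numeric(df, ["t_ms", "x_px", "y_px"], path)
    return df[SAMPLE_COLUMNS]


def read_trials(path) -> pd.DataFrame:
    """Read the trial table, case-folding categorical fields."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True, comment="#")
    _require_columns(df, TRIAL_COLUMNS, path)
    df = _normalize_categorical(df, "food_type", FOOD_TYPES, path)
    df = _normalize_categorical(df, "classification", CLASSIFICATIONS, path)
    df = _normalize_categorical(df, "response_side", RESPONSE_SIDES, path)
    df = _to_numeric(
        df,
        ["presentation_index", "start_x_px", "start_y_px",
         "click_x_px", "click_y_px"],
        path,
    )
    return df[TRIAL_COLUMNS]


_FFQ_RE = re.compile(r"^ffq_(\d+)$")


def ffq_columns(df: pd.DataFrame) -> list[str]:
    """FFQ item columns in item order (``ffq_1`` .. ``ffq_K``)."""
    cols = [(int(m.group(1)), c) for c in df.columns
            if (m := _FFQ_RE.match(c))]
    return [c for _, c in sorted(cols)]


def read_participants(path) -> pd.DataFrame:
    """Read the participant table (explicit-scale items, FFQ, condition,
    demographics)."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True, comment="#")
    _require_columns(df, PARTICIPANT_BASE_COLUMNS, path)
    df = _normalize_categorical(df, "condition", CONDITIONS, path)
    numeric = (["age", "uti_item_1", "uti_item_2", "uti_item_3"]
               + ffq_columns(df))
    df = _to_numeric(df, numeric, path)
    ordered = PARTICIPANT_BASE_COLUMNS + ffq_columns(df)
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def _write(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")


def write_samples(df: pd.DataFrame, path) -> None:
    _write(df[SAMPLE_COLUMNS], path)


def write_trials(df: pd.DataFrame, path) -> None:
    _write(df[TRIAL_COLUMNS], path)


def write_participants(df: pd.DataFrame, path) -> None:
    _write(df, path)


def validate_dataset(samples: pd.DataFrame, trials: pd.DataFrame,
                     participants: pd.DataFrame,
                     tasty_side: str = DEFAULT_TASTY_SIDE) -> ValidationReport:
    """Check every cross-table invariant; violations become report
    entries, never exceptions.  Inputs are not mutated."""
    report = ValidationReport(counts={
        "samples": len(samples),
        "trials": len(trials),
        "participants": len(participants),
    })
    err = report.errors.append

    # -- per-trial sample timing ------------------------------------
    sample_keys = set()
    for (pid, tid), grp in samples.groupby(["participant_id", "trial_id"],
                                           sort=False):
        sample_keys.add((pid, tid))
        loc = f"samples[{pid}/{tid}]"
        t = grp["t_ms"].to_numpy()
        if t[0] != 0:
            err(ValidationIssue("t_not_rebased", loc,
                                f"first t_ms is {t[0]}, expected 0"))
        if len(t) > 1 and not (t[1:] > t[:-1]).all():
            err(ValidationIssue("t_not_increasing", loc,
                                "t_ms is not strictly increasing"))
        if len(t) < 2:
            report.warnings.append(ValidationIssue(
                "single_sample", loc, "trial has fewer than 2 samples"))

    # -- trial table ------------------------------------------------
    trial_keys = set(zip(trials["participant_id"], trials["trial_id"]))
    for key in sorted(sample_keys - trial_keys):
        err(ValidationIssue("unknown_trial", f"samples[{key[0]}/{key[1]}]",
                            "samples refer to a trial absent from the "
                            "trial table"))
    for key in sorted(trial_keys - sample_keys):
        err(ValidationIssue("orphan_trial", f"trials[{key[0]}/{key[1]}]",
                            "trial has no cursor samples"))

    not_tasty_side = "right" if tasty_side == "left" else "left"
    expected_side = trials["classification"].map(
        {"tasty": tasty_side, "not_tasty": not_tasty_side})
    mismatch = trials["response_side"] != expected_side
    for _, row in trials[mismatch].iterrows():
        err(ValidationIssue(
            "side_mismatch",
            f"trials[{row['participant_id']}/{row['trial_id']}]",
            f"classification {row['classification']!r} is inconsistent "
            f"with response_side {row['response_side']!r} "
            f"(tasty box is on the {tasty_side})"))

    ftypes = trials.groupby("stimulus_id")["food_type"].nunique()
    for sid in ftypes[ftypes > 1].index:
        err(ValidationIssue("ambiguous_stimulus", f"trials[{sid}]",
                            "stimulus maps to more than one food_type"))

    # -- participant table ------------------------------------------
    known = set(participants["participant_id"])
    for pid in sorted(set(trials["participant_id"]) - known):
        err(ValidationIssue("unknown_participant", f"trials[{pid}]",
                            "trial participant absent from participant "
                            "table"))
    for col in ("uti_item_1", "uti_item_2", "uti_item_3"):
        bad = ~participants[col].between(1, 7)
        for _, row in participants[bad].iterrows():
            err(ValidationIssue(
                "out_of_range", f"participants[{row['participant_id']}].{col}",
                f"value {row[col]} outside the 1-7 scale range"))
    for col in ffq_columns(participants):
        bad = ~participants[col].between(1, 8)
        for _, row in participants[bad].iterrows():
            err(ValidationIssue(
                "out_of_range", f"participants[{row['participant_id']}].{col}",
                f"value {row[col]} outside the 1-8 frequency range"))

    dup = participants["participant_id"].duplicated()
    for pid in participants.loc[dup, "participant_id"]:
        err(ValidationIssue("duplicate_participant", f"participants[{pid}]",
                            "participant_id appears more than once"))

    return report
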
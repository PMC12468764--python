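"""Behavioral side of the pipeline: disfluency rates and cohort statistics.

Adults who stutter provide up to three coded speech samples (conversation,
phone call, reading passage).  For each sample a clinician counts total
syllables and the number of each disfluency type — repetitions, prolongations
and blocks.  This module converts those counts into percentage rates (per
sample and per participant, each task weighted equally), summarizes the
cohort, and computes the inter-rater reliability statistic (ICC) used to
validate the coding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeechSample",
    "BehavioralRecord",
    "DisfluencyRates",
    "DISFLUENCY_TYPES",
    "SITE_CODES",
    "percent_disfluency",
    "aggregate_rates",
    "summarize_cohort",
    "icc_agreement",
    "read_behavioral_csv",
    "write_cohort_summary",
    "load_table1",
]

logger = logging.getLogger(__name__)

#: Coded disfluency types, in canonical column order.
DISFLUENCY_TYPES = ("repetitions", "prolongations", "blocks")

#: Deterministic binary encoding of scanner site.
SITE_CODES = {"MGH": 1, "BU": 0}

#: Speech-elicitation tasks.  "combined" admits tables that pool the three
#: samples into a single row of counts (the canonical demographics table does).
TASKS = ("conversation", "phone", "reading", "combined")

#: Dominance rule applied by human coders to mixed stuttering moments; kept as
#: provenance metadata only — classification happens at coding time, not here.
MIXED_DOMINANCE_RULES = ("dominant_feature", "first_in_sequence")

SSI4_RANGE = (9, 42)

_BEHAVIORAL_COLUMNS = [
    "participant_id", "age", "gender", "site", "ssi4",
    "sample_id", "task", "total_syllables",
    "repetitions", "prolongations", "blocks",
]


@dataclass(frozen=True)
class SpeechSample:
    """One coded speech sample: syllable total and per-type disfluency counts."""

    sample_id: str
    task: str
    total_syllables: int
    repetitions: int
    prolongations: int
    blocks: int
    #: how mixed stuttering moments were classified by the coder (metadata)
    dominance_rule: str = "dominant_feature"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.dominance_rule not in MIXED_DOMINANCE_RULES:
            raise ValueError(f"unknown dominance rule {self.dominance_rule!r}")
        if self.total_syllables <= 0:
            raise ValueError("total_syllables must be positive")
        counts = (self.repetitions, self.prolongations, self.blocks)
        if any(c < 0 for c in counts):
            raise ValueError("disfluency counts must be non-negative")
        if sum(counts) > self.total_syllables:
            raise ValueError(
                "total disfluency count exceeds total syllables "
                f"({sum(counts)} > {self.total_syllables})"
            )

    def percent(self, kind: str) -> float:
        """Percentage rate of one disfluency type within this sample."""
        return percent_disfluency(getattr(self, kind), self.total_syllables)


@dataclass(frozen=True)
class BehavioralRecord:
    """One participant: demographics, SSI-4 severity, and 1-3 speech samples."""

    participant_id: str
    age: float
    gender: str
    site: str
    ssi4: float
    samples: tuple[SpeechSample, ...]

    def __post_init__(self) -> None:
        if self.site not in SITE_CODES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {sorted(SITE_CODES)}")
        if not SSI4_RANGE[0] <= self.ssi4 <= SSI4_RANGE[1]:
            raise ValueError(f"ssi4={self.ssi4} outside instrument range {SSI4_RANGE}")
        if not 1 <= len(self.samples) <= 3:
            raise ValueError("a record carries between 1 and 3 speech samples")

    @property
    def site_code(self) -> int:
        """Binary scanner code: MGH -> 1, BU -> 0."""
        return SITE_CODES[self.site]


@dataclass(frozen=True)
class DisfluencyRates:
    """Participant-level disfluency rates (percent of syllables), full precision."""

    participant_id: str
    repetition_pct: float
    prolongation_pct: float
    block_pct: float

    def __post_init__(self) -> None:
        for v in (self.repetition_pct, self.prolongation_pct, self.block_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"rate {v} outside [0, 100]")

    def get(self, outcome: str) -> float:
        """Rate for ``outcome`` in {'repetition', 'prolongation', 'block'}."""
        return getattr(self, f"{outcome}_pct")


def percent_disfluency(count: int, total_syllables: int) -> float:
    """Disfluency rate as a percentage of syllables produced.

    Returns ``100 * count / total_syllables`` at full precision; rounding to
    the two decimals used in reports happens only at serialization time.
    """
    if total_syllables <= 0:
        raise ValueError("total_syllables must be positive")
    if count < 0 or count > total_syllables:
        raise ValueError(f"count={count} outside [0, {total_syllables}]")
    return 100.0 * count / total_syllables


def aggregate_rates(record: BehavioralRecord) -> DisfluencyRates:
    """Participant-level rate: unweighted mean of per-sample percentages.

    Each task contributes equally regardless of its syllable count (samples
    are averaged, not pooled).  Records with fewer than three samples are
    averaged over the samples present, with a logged warning.
    """
    if not record.samples:
        raise ValueError("record has no speech samples")
    if len(record.samples) < 3 and record.samples[0].task != "combined":
        logger.warning(
            "participant %s has %d sample(s); averaging over those available",
            record.participant_id, len(record.samples),
        )
    means = {
        kind: float(np.mean([s.percent(kind) for s in record.samples]))
        for kind in DISFLUENCY_TYPES
    }
    return DisfluencyRates(
        participant_id=record.participant_id,
        repetition_pct=means["repetitions"],
        prolongation_pct=means["prolongations"],
        block_pct=means["blocks"],
    )


def summarize_cohort(
    records: Sequence[BehavioralRecord],
    rates: Sequence[DisfluencyRates],
) -> pd.DataFrame:
    """Cohort mean and sample SD (n-1) of SSI-4 and each disfluency rate.

    Returns a tidy frame with columns ``measure``, ``mean``, ``sd``.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records for a sample SD")
    by_id = {r.participant_id: r for r in rates}
    missing = [rec.participant_id for rec in records if rec.participant_id not in by_id]
    if missing:
        raise ValueError(f"rates missing for participants: {missing}")
    cols = {
        "ssi4": [rec.ssi4 for rec in records],
        "repetition_pct": [by_id[rec.participant_id].repetition_pct for rec in records],
        "prolongation_pct": [by_id[rec.participant_id].prolongation_pct for rec in records],
        "block_pct": [by_id[rec.participant_id].block_pct for rec in records],
    }
    rows = [
        {"measure": name, "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
        for name, v in cols.items()
    ]
    return pd.DataFrame(rows, columns=["measure", "mean", "sd"])


def icc_agreement(
    ratings: np.ndarray,
    form: Literal["ICC2", "ICC3"] = "ICC2",
) -> float:
    """Single-measure intraclass correlation for inter-rater reliability.

    ``ratings`` is an items x raters matrix with no missing cells.  The
    default form is the two-way random-effects absolute-agreement ICC(2,1);
    ``form="ICC3"`` gives the two-way mixed consistency ICC(3,1).

    Both are computed from the two-way ANOVA decomposition.  With n items,
    k raters, mean squares MSR (rows/items), MSC (columns/raters) and MSE:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D items x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 items and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if msr == 0.0:
        warnings.warn("zero between-item variance; ICC undefined, returning 0")
        return 0.0
    if form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0.0:
        warnings.warn("degenerate ANOVA decomposition; returning 0")
        return 0.0
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# I/O

def read_behavioral_csv(path: str | Path) -> list[BehavioralRecord]:
    """Read a long-format behavioral table (one row per speech sample).

    The header must be exactly the canonical column set; participant-level
    fields must be constant within a participant.
    """
    df = pd.read_csv(path)
    if list(df.columns) != _BEHAVIORAL_COLUMNS:
        raise ValueError(
            f"bad behavioral header: expected {_BEHAVIORAL_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    for pid, grp in df.groupby("participant_id", sort=True):
        for col in ("age", "gender", "site", "ssi4"):
            if grp[col].nunique() != 1:
                raise ValueError(f"participant {pid}: inconsistent {col} across samples")
        samples = tuple(
            SpeechSample(
                sample_id=str(row.sample_id),
                task=str(row.task),
                total_syllables=int(row.total_syllables),
                repetitions=int(row.repetitions),
                prolongations=int(row.prolongations),
                blocks=int(row.blocks),
            )
            for row in grp.itertuples()
        )
        first = grp.iloc[0]
        records.append(BehavioralRecord(
            participant_id=str(pid),
            age=float(first.age),
            gender=str(first.gender),
            site=str(first.site),
            ssi4=float(first.ssi4),
            samples=samples,
        ))
    return records


def write_behavioral_csv(records: Sequence[BehavioralRecord], path: str | Path) -> None:
    """Write records back to the canonical long-format CSV."""
    rows = []
    for rec in records:
        for s in rec.samples:
            rows.append({
                "participant_id": rec.participant_id,
                "age": rec.age, "gender": rec.gender,
                "site": rec.site, "ssi4": rec.ssi4,
                "sample_id": s.sample_id, "task": s.task,
                "total_syllables": s.total_syllables,
                "repetitions": s.repetitions,
                "prolongations": s.prolongations,
                "blocks": s.blocks,
            })
    pd.DataFrame(rows, columns=_BEHAVIORAL_COLUMNS).to_csv(path, index=False)


def write_cohort_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy cohort summary, rates rounded to report precision."""
    out = summary.copy()
    out["mean"] = out["mean"].round(2)
    out["sd"] = out["sd"].round(2)
    out.to_csv(path, index=False)


def load_table1() -> list[BehavioralRecord]:
    """The packaged 20-participant demographics/behavior table (combined counts)."""
    ref = resources.files("stutterconn.data") / "table1_behavioral.csv"
    with resources.as_file(ref) as p:
        return read_behavioral_csv(p)
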
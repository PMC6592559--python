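"""Core data containers and delimited-text I/O.

The pipeline starts downstream of image segmentation: its raw input is a tidy
(long-format) table with one row per (brain, ROI, frame) carrying the raw
channel intensities.  Two channels (CFP/YFP) describe a ratiometric FRET cAMP
sensor recording; a single GFP channel describes a GCaMP calcium recording.
Dormancy assays arrive as replicate-level count tables (arrested / dissected
females per vial).

All tables are plain CSV with '.' decimals.  Trace CSVs carry two metadata
comment lines (``# application_time=...`` and ``# frame_rate=...``) so a file
is self-describing and write -> read is the identity.
"""

from __future__ import annotations

import io as _stdio
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

TRACE_KEY_COLUMNS = ("brain_id", "roi_id", "treatment", "t")
FRET_CHANNELS = ("cfp", "yfp")
CALCIUM_CHANNELS = ("gfp",)
BACKGROUND_COLUMNS = ("bg_cfp", "bg_yfp", "bg_gfp")
TREATMENT_ROLES = ("negative_control", "positive_control", "experimental")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RoiTraceSet:
    """Raw per-ROI channel intensities over time plus acquisition metadata.

    ``frames`` is a tidy DataFrame with columns ``brain_id, roi_id, treatment,
    t`` plus at least one of the channel sets (``cfp``+``yfp`` for FRET,
    ``gfp`` for calcium) and optional background columns ``bg_cfp, bg_yfp,
    bg_gfp``.  ``application_time`` (s) marks bath application of the
    substance; everything before it is baseline.  ``frame_rate`` is the
    acquisition rate in Hz (0.2 Hz in the reference protocol).
    """

    frames: pd.DataFrame
    application_time: float = 100.0
    frame_rate: float = 0.2

    def __post_init__(self) -> None:
        self.frames = self.frames.reset_index(drop=True)
        self.validate()

    # -- channel inspection -------------------------------------------------
    @property
    def has_fret(self) -> bool:
        return all(c in self.frames.columns for c in FRET_CHANNELS)

    @property
    def has_calcium(self) -> bool:
        return "gfp" in self.frames.columns

    @property
    def channel_columns(self) -> list[str]:
        return [c for c in (*FRET_CHANNELS, *CALCIUM_CHANNELS) if c in self.frames.columns]

    @property
    def background_columns(self) -> list[str]:
        return [c for c in BACKGROUND_COLUMNS if c in self.frames.columns]

    @property
    def roi_keys(self) -> list[tuple[str, str]]:
        return sorted(
            {(str(b), str(r)) for b, r in zip(self.frames["brain_id"], self.frames["roi_id"])}
        )

    @property
    def n_rois(self) -> int:
        return len(self.roi_keys)

    @property
    def n_brains(self) -> int:
        return self.frames["brain_id"].nunique()

    @property
    def treatments(self) -> list[str]:
        return sorted(self.frames["treatment"].unique())

    def iter_rois(self) -> Iterable[tuple[tuple[str, str, str], pd.DataFrame]]:
        """Yield ((brain_id, roi_id, treatment), frames sorted by t) per ROI."""
        for (brain, roi), grp in self.frames.groupby(["brain_id", "roi_id"], sort=True):
            treatment = grp["treatment"].iloc[0]
            yield (str(brain), str(roi), str(treatment)), grp.sort_values("t")

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.frames
        missing = [c for c in TRACE_KEY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"trace table is missing required column(s): {', '.join(missing)}")
        if not (self.has_fret or self.has_calcium):
            raise FormatError(
                "trace table must contain either cfp+yfp (FRET) or gfp (calcium) columns"
            )
        if len(df) == 0:
            raise FormatError("trace table contains no data rows")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")

        numeric = ["t", *self.channel_columns, *self.background_columns]
        for col in numeric:
            values = df[col].to_numpy()
            if not np.all(np.isfinite(values)):
                raise ValidationError(f"column {col!r} contains non-finite values")
        for col in (*self.channel_columns, *self.background_columns):
            if (df[col].to_numpy() < 0).any():
                raise ValidationError(f"column {col!r} contains negative intensities")

        expected_dt = 1.0 / self.frame_rate
        for (brain, roi), grp in df.groupby(["brain_id", "roi_id"], sort=False):
            t = grp["t"].to_numpy(dtype=float)
            if len(t) > 1:
                dt = np.diff(t)
                if np.any(dt <= 0):
                    raise ValidationError(
                        f"time is not strictly increasing for ROI ({brain}, {roi})"
                    )
                if np.any(np.abs(dt - expected_dt) > 0.01 * expected_dt):
                    raise ValidationError(
                        f"frame spacing for ROI ({brain}, {roi}) is inconsistent with "
                        f"frame_rate={self.frame_rate} Hz (expected {expected_dt:g} s "
                        "between frames, tolerance 1%)"
                    )
            if grp["treatment"].nunique() != 1:
                raise ValidationError(
                    f"ROI ({brain}, {roi}) carries more than one treatment label"
                )


@dataclass(frozen=True)
class TreatmentDesign:
    """Role assignment of treatment labels within one experiment.

    Exactly one ``negative_control`` (the saline bath, HL3) is required;
    positive controls (adenylate-cyclase activator for cAMP, carbachol for
    Ca2+) are optional.
    """

    roles: Mapping[str, str]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t: r for t, r in self.roles.items() if r not in TREATMENT_ROLES}
        if bad:
            raise ValidationError(f"unknown treatment role(s): {bad}")
        negatives = [t for t, r in self.roles.items() if r == "negative_control"]
        if len(negatives) != 1:
            raise ValidationError(
                f"expected exactly one negative_control treatment, found {len(negatives)}"
            )

    @property
    def treatments(self) -> list[str]:
        return list(self.roles)

    @property
    def negative_control(self) -> str:
        return next(t for t, r in self.roles.items() if r == "negative_control")

    @classmethod
    def from_labels(
        cls,
        treatments: Sequence[str],
        negative_control: str,
        positive_controls: Sequence[str] = (),
    ) -> "TreatmentDesign":
        roles = {}
        for t in treatments:
            if t == negative_control:
                roles[t] = "negative_control"
            elif t in positive_controls:
                roles[t] = "positive_control"
            else:
                roles[t] = "experimental"
        return cls(roles=roles)


@dataclass
class DormancyTable:
    """Replicate-level ovarian-arrest counts.

    One row per vial: genotype, optional photoperiod, replicate id, the number
    of dissected females and the number scored as arrested (no yolk
    deposition in the ovarian follicles).
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        self.rows = self.rows.reset_index(drop=True)
        self.validate()

    @property
    def has_photoperiod(self) -> bool:
        return "photoperiod" in self.rows.columns

    def validate(self) -> None:
        df = self.rows
        required = ["genotype", "replicate", "n_dissected", "n_arrested"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(
                f"dormancy table is missing required column(s): {', '.join(missing)}"
            )
        if len(df) == 0:
            raise FormatError("dormancy table contains no replicates")
        for col in ("n_dissected", "n_arrested"):
            values = df[col].to_numpy()
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError(f"column {col!r} must contain integer counts")
        n_dis = df["n_dissected"].to_numpy(dtype=int)
        n_arr = df["n_arrested"].to_numpy(dtype=int)
        if np.any(n_dis < 1):
            raise ValidationError("n_dissected must be >= 1 for every replicate")
        if np.any(n_arr < 0) or np.any(n_arr > n_dis):
            raise ValidationError("n_arrested must satisfy 0 <= n_arrested <= n_dissected")


# ---------------------------------------------------------------------------
# trace tables
# ---------------------------------------------------------------------------

def _read_metadata_comments(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    meta[key.strip()] = float(value)
                except ValueError:
                    pass
    return meta


def read_trace_table(
    path: str | Path,
    application_time: float | None = None,
    frame_rate: float | None = None,
    delimiter: str = ",",
) -> RoiTraceSet:
    """Read a tidy ROI trace CSV into a validated :class:`RoiTraceSet`.

    ``application_time`` and ``frame_rate`` default to the ``#``-comment
    metadata embedded in the file, falling back to 100 s and 0.2 Hz.  Rows are
    grouped per ROI and sorted by time.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trace table not found: {path}")
    meta = _read_metadata_comments(path)
    if application_time is None:
        application_time = meta.get("application_time", 100.0)
    if frame_rate is None:
        frame_rate = meta.get("frame_rate", 0.2)
    try:
        df = pd.read_csv(path, comment="#", sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"trace table {path} has no data") from exc
    missing = [c for c in TRACE_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"trace table {path} is missing required column(s): {', '.join(missing)}"
        )
    df = df.sort_values(["brain_id", "roi_id", "t"], kind="mergesort").reset_index(drop=True)
    ts = RoiTraceSet(frames=df, application_time=application_time, frame_rate=frame_rate)
    logger.info(
        "read %s: %d ROIs across %d brains, %d rows, treatments=%s",
        path, ts.n_rois, ts.n_brains, len(df), ts.treatments,
    )
    return ts


def write_trace_table(traces: RoiTraceSet, path: str | Path) -> Path:
    """Write a :class:`RoiTraceSet` back to CSV (with metadata comments)."""
    path = Path(path)
    ordered = [
        c for c in ("brain_id", "roi_id", "treatment", "t", "cfp", "yfp", "gfp",
                    "bg_cfp", "bg_yfp", "bg_gfp")
        if c in traces.frames.columns
    ]
    extra = [c for c in traces.frames.columns if c not in ordered]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# application_time={traces.application_time!r}\n")
        fh.write(f"# frame_rate={traces.frame_rate!r}\n")
        traces.frames[ordered + extra].to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# dormancy tables
# ---------------------------------------------------------------------------

def read_dormancy_table(path: str | Path, delimiter: str = ",") -> DormancyTable:
    """Read a replicate-level dormancy count CSV."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"dormancy table not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"dormancy table {path} has no data (no replicates)") from exc
    if len(df) == 0:
        raise FormatError(f"dormancy table {path} contains no replicates")
    return DormancyTable(rows=df)


def write_dormancy_table(table: DormancyTable, path: str | Path) -> Path:
    path = Path(path)
    ordered = [c for c in ("genotype", "photoperiod", "replicate", "n_dissected", "n_arrested")
               if c in table.rows.columns]
    table.rows[ordered].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def write_summary_table(summaries: Sequence, path: str | Path) -> Path:
    """Serialize per-treatment summaries to a single tidy CSV.

    The file mixes two record types distinguished by the ``record`` column:
    ``score`` rows carry one per-neuron windowed maximum each; ``trace`` rows
    carry the per-timepoint mean +/- SEM trace of a treatment.  Ordering is
    deterministic (treatments sorted, then neuron key / time).
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("no treatment summaries to write")
    path = Path(path)
    records: list[dict] = []
    for summ in sorted(summaries, key=lambda s: s.treatment):
        for window in sorted(summ.scores):
            for (brain, roi), value in zip(summ.neuron_keys, summ.scores[window]):
                records.append({
                    "record": "score", "treatment": summ.treatment, "brain_id": brain,
                    "roi_id": roi, "window": window, "t": "", "value": value,
                    "sem": "", "n": summ.n_neurons,
                })
        for t, m, s in zip(summ.t, summ.mean, summ.sem):
            records.append({
                "record": "trace", "treatment": summ.treatment, "brain_id": "",
                "roi_id": "", "window": "", "t": t, "value": m, "sem": s,
                "n": summ.n_neurons,
            })
    pd.DataFrame.from_records(records).to_csv(path, index=False)
    return path


def read_summary_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a summary CSV back as ``(scores, traces)`` DataFrames."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"summary table not found: {path}")
    df = pd.read_csv(path)
    if "record" not in df.columns:
        raise FormatError(f"summary table {path} is missing the 'record' column")
    scores = df[df["record"] == "score"][
        ["treatment", "brain_id", "roi_id", "window", "value", "n"]
    ].reset_index(drop=True)
    traces = df[df["record"] == "trace"][
        ["treatment", "t", "value", "sem", "n"]
    ].reset_index(drop=True)
    return scores, traces
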
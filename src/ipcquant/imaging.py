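"""Quantification of raw sensor traces into normalized response scores.

cAMP recordings use the Epac1-camps FRET sensor: rising cAMP decreases FRET,
so the readout is the inverse FRET ratio

    iFRET(t) = CFP(t) / (YFP(t) - k * CFP(t)),        k = 0.357 by default,

computed after background correction of both channels, where ``k`` is the
spectral spillover (bleed-through) of CFP emission into the YFP channel.
Calcium recordings use a single-channel sensor (GCaMP) and the standard
percent change

    dF/F0(t) = (F(t) - F0) / F0 * 100,

with ``F0`` the mean background-corrected fluorescence over the baseline
window.  Both signal kinds are normalized to their pre-application baseline
and scored as the maximum percent change within analysis windows — by default
the full post-application window [100, 1000] s and the short/immediate window
[100, 200] s.

Per-ROI traces are averaged per treatment (mean +/- SEM across neurons, the
unit the recordings count) into :class:`TreatmentSummary` objects which feed
the statistics layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTraceError, ValidationError
from .io import RoiTraceSet, TreatmentDesign

logger = logging.getLogger(__name__)

DEFAULT_SPILLOVER = 0.357
#: floor applied to background-corrected intensities, in channel units
DEFAULT_EPSILON = 1e-9
#: reject an ROI when more than this fraction of frames has a non-positive
#: iFRET denominator
DEFAULT_MAX_INVALID_FRACTION = 0.10


@dataclass(frozen=True)
class AnalysisWindows:
    """Baseline and scoring windows in seconds.

    ``baseline`` is half-open [t0, t1) and must precede the application time;
    ``long`` and ``short`` are closed intervals over which maxima are taken.
    """

    baseline: tuple[float, float] = (0.0, 100.0)
    long: tuple[float, float] = (100.0, 1000.0)
    short: tuple[float, float] = (100.0, 200.0)

    def __post_init__(self) -> None:
        for name in ("baseline", "long", "short"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValidationError(f"window {name!r} is empty: [{lo}, {hi}]")

    @classmethod
    def for_application_time(
        cls, application_time: float, duration: float = 1000.0, short_span: float = 100.0
    ) -> "AnalysisWindows":
        return cls(
            baseline=(0.0, application_time),
            long=(application_time, duration),
            short=(application_time, application_time + short_span),
        )


@dataclass
class NormalizedResponse:
    """Baseline-normalized response of a single neuron (ROI)."""

    brain_id: str
    roi_id: str
    treatment: str
    kind: str  # "iFRET" or "dFoF"
    t: np.ndarray
    trace: np.ndarray            # percent change vs baseline; NaN at invalid frames
    valid: np.ndarray            # boolean mask of usable frames
    baseline_mean: float
    max_long: float
    max_short: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.brain_id, self.roi_id)


@dataclass
class TreatmentSummary:
    """Per-treatment mean +/- SEM trace and per-neuron score vectors."""

    treatment: str
    t: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    scores: dict[str, np.ndarray]        # window name -> per-neuron maxima
    neuron_keys: list[tuple[str, str]]
    n_neurons: int
    n_brains: int

    def __post_init__(self) -> None:
        if np.any(self.sem < 0):
            raise ValidationError("SEM must be non-negative")
        for window, vec in self.scores.items():
            if len(vec) != self.n_neurons:
                raise ValidationError(
                    f"score vector for window {window!r} does not match n_neurons"
                )


@dataclass
class QuantificationResult:
    """Accepted per-neuron responses plus the rejection report."""

    responses: list[NormalizedResponse]
    rejected: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.responses)


# ---------------------------------------------------------------------------
# elementary trace operations
# ---------------------------------------------------------------------------

def background_correct(
    raw: np.ndarray, background: np.ndarray | float, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Subtract a background trace (or scalar) from a raw channel.

    Values are floored at ``epsilon`` to keep downstream ratios finite; an
    all-floored result raises :class:`DegenerateTraceError`.
    """
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim > 0 and background.shape != raw.shape:
        raise ValidationError(
            f"background length {background.shape} does not match trace {raw.shape}"
        )
    corrected = raw - background
    floored = corrected < epsilon
    if np.all(floored):
        raise DegenerateTraceError(
            "background-corrected channel is non-positive at every frame"
        )
    if np.any(floored):
        logger.warning(
            "background correction floored %d/%d frames at epsilon=%g",
            int(floored.sum()), corrected.size, epsilon,
        )
        corrected = np.where(floored, epsilon, corrected)
    return corrected


def spillover_correct(
    yfp: np.ndarray, cfp: np.ndarray, k: float = DEFAULT_SPILLOVER
) -> np.ndarray:
    """Remove the CFP bleed-through from the YFP channel: ``yfp - k * cfp``.

    Non-positive results are returned as-is; frame validity is decided by
    :func:`compute_ifret`, which owns the invalid-frame policy.
    """
    yfp = np.asarray(yfp, dtype=float)
    cfp = np.asarray(cfp, dtype=float)
    if yfp.shape != cfp.shape:
        raise ValidationError("yfp and cfp traces must have equal length")
    if not 0.0 <= k < 1.0:
        raise ValidationError(f"spillover fraction must satisfy 0 <= k < 1, got {k}")
    out = yfp - k * cfp
    n_bad = int((out <= 0).sum())
    if n_bad:
        logger.warning("spillover correction produced %d non-positive frame(s)", n_bad)
    return out


def compute_ifret(
    cfp: np.ndarray,
    yfp: np.ndarray,
    k: float = DEFAULT_SPILLOVER,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse FRET ratio ``CFP / (YFP - k*CFP)`` on background-corrected data.

    Returns ``(ifret, valid)``; frames whose denominator is <= ``epsilon`` are
    marked invalid (NaN in the ratio) rather than producing sign-flipped
    ratios.  Callers enforce the per-ROI invalid-fraction cap.
    """
    cfp = np.asarray(cfp, dtype=float)
    yfp = np.asarray(yfp, dtype=float)
    if cfp.shape != yfp.shape:
        raise ValidationError("cfp and yfp traces must have equal length")
    if not 0.0 <= k < 1.0:
        raise ValidationError(f"spillover fraction must satisfy 0 <= k < 1, got {k}")
    denom = yfp - k * cfp
    valid = denom > epsilon
    ifret = np.full(cfp.shape, np.nan)
    np.divide(cfp, denom, out=ifret, where=valid)
    return ifret, valid


def normalize_to_baseline(
    t: np.ndarray,
    signal: np.ndarray,
    windows: AnalysisWindows,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Express a signal as percent change relative to its baseline mean.

    The baseline is the mean of valid frames with ``baseline[0] <= t <
    baseline[1]``; at least 3 such frames and a positive mean are required.
    Returns ``(percent trace, baseline_mean)``.
    """
    t = np.asarray(t, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if valid is None:
        valid = np.isfinite(signal)
    lo, hi = windows.baseline
    in_baseline = (t >= lo) & (t < hi) & valid
    if int(in_baseline.sum()) < 3:
        raise ValidationError(
            f"fewer than 3 valid baseline frames in [{lo}, {hi}) — ROI rejected"
        )
    baseline_mean = float(np.mean(signal[in_baseline]))
    if baseline_mean <= 0:
        raise ValidationError("baseline mean is non-positive — ROI rejected")
    trace = (signal / baseline_mean - 1.0) * 100.0
    return trace, baseline_mean


def max_response(
    t: np.ndarray,
    trace: np.ndarray,
    window: tuple[float, float],
    valid: np.ndarray | None = None,
) -> float:
    """Maximum of a normalized trace over the closed window ``[t0, t1]``."""
    t = np.asarray(t, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if valid is None:
        valid = np.isfinite(trace)
    t0, t1 = window
    mask = (t >= t0) & (t <= t1) & valid
    if not mask.any():
        raise ValidationError(f"no valid frames inside window [{t0}, {t1}]")
    return float(np.max(trace[mask]))


# ---------------------------------------------------------------------------
# per-ROI quantification
# ---------------------------------------------------------------------------

def _get_background(grp: pd.DataFrame, column: str, n: int) -> np.ndarray | float:
    if column in grp.columns:
        return grp[column].to_numpy(dtype=float)
    return 0.0


def quantify_fret(
    traces: RoiTraceSet,
    windows: AnalysisWindows | None = None,
    k: float = DEFAULT_SPILLOVER,
    epsilon: float = DEFAULT_EPSILON,
    max_invalid_fraction: float = DEFAULT_MAX_INVALID_FRACTION,
) -> QuantificationResult:
    """Run the full cAMP chain on every ROI of a FRET recording.

    background -> spillover -> iFRET -> % baseline normalization -> windowed
    maxima.  ROIs failing any validity rule are collected in the rejection
    report instead of aborting the run.
    """
    if not traces.has_fret:
        raise ValidationError("trace set has no cfp/yfp channels; not a FRET recording")
    if windows is None:
        windows = AnalysisWindows.for_application_time(
            traces.application_time,
            duration=float(traces.frames["t"].max()),
        )
    if not traces.background_columns:
        logger.warning("no background columns present; assuming background = 0")

    responses: list[NormalizedResponse] = []
    rejected: list[tuple[tuple[str, str], str]] = []
    for (brain, roi, treatment), grp in traces.iter_rois():
        t = grp["t"].to_numpy(dtype=float)
        try:
            cfp = background_correct(
                grp["cfp"].to_numpy(dtype=float), _get_background(grp, "bg_cfp", len(grp)),
                epsilon,
            )
            yfp = background_correct(
                grp["yfp"].to_numpy(dtype=float), _get_background(grp, "bg_yfp", len(grp)),
                epsilon,
            )
            ifret, valid = compute_ifret(cfp, yfp, k=k, epsilon=epsilon)
            invalid_fraction = 1.0 - valid.mean()
            if invalid_fraction > max_invalid_fraction:
                raise ValidationError(
                    f"{invalid_fraction:.1%} of frames have non-positive iFRET "
                    f"denominator (cap {max_invalid_fraction:.0%})"
                )
            trace, baseline_mean = normalize_to_baseline(t, ifret, windows, valid)
            trace = np.where(valid, trace, np.nan)
            responses.append(NormalizedResponse(
                brain_id=brain, roi_id=roi, treatment=treatment, kind="iFRET",
                t=t, trace=trace, valid=valid, baseline_mean=baseline_mean,
                max_long=max_response(t, trace, windows.long, valid),
                max_short=max_response(t, trace, windows.short, valid),
            ))
        except ValidationError as exc:
            logger.warning("rejecting ROI (%s, %s): %s", brain, roi, exc)
            rejected.append(((brain, roi), str(exc)))
    return QuantificationResult(responses=responses, rejected=rejected)


def delta_f_over_f(
    gfp: np.ndarray,
    t: np.ndarray,
    windows: AnalysisWindows,
) -> tuple[np.ndarray, float]:
    """Percent fluorescence change ``(F_n - F0)/F0 * 100`` of one trace.

    ``F0`` is the mean over the baseline window; identical to
    :func:`normalize_to_baseline` and shared with the iFRET path.
    """
    return normalize_to_baseline(np.asarray(t, float), np.asarray(gfp, float), windows)


def quantify_calcium(
    traces: RoiTraceSet,
    windows: AnalysisWindows | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> QuantificationResult:
    """Run the dF/F0 chain on every ROI of a single-channel calcium recording."""
    if not traces.has_calcium:
        raise ValidationError("trace set has no gfp channel; not a calcium recording")
    if windows is None:
        windows = AnalysisWindows.for_application_time(
            traces.application_time,
            duration=float(traces.frames["t"].max()),
        )
    if "bg_gfp" not in traces.frames.columns:
        logger.warning("no bg_gfp column present; assuming background = 0")

    responses: list[NormalizedResponse] = []
    rejected: list[tuple[tuple[str, str], str]] = []
    for (brain, roi, treatment), grp in traces.iter_rois():
        t = grp["t"].to_numpy(dtype=float)
        try:
            gfp = background_correct(
                grp["gfp"].to_numpy(dtype=float), _get_background(grp, "bg_gfp", len(grp)),
                epsilon,
            )
            trace, f0 = delta_f_over_f(gfp, t, windows)
            valid = np.isfinite(trace)
            responses.append(NormalizedResponse(
                brain_id=brain, roi_id=roi, treatment=treatment, kind="dFoF",
                t=t, trace=trace, valid=valid, baseline_mean=f0,
                max_long=max_response(t, trace, windows.long, valid),
                max_short=max_response(t, trace, windows.short, valid),
            ))
        except ValidationError as exc:
            logger.warning("rejecting ROI (%s, %s): %s", brain, roi, exc)
            rejected.append(((brain, roi), str(exc)))
    return QuantificationResult(responses=responses, rejected=rejected)


# ---------------------------------------------------------------------------
# treatment summaries
# ---------------------------------------------------------------------------

def summarize_treatment(
    responses: Sequence[NormalizedResponse],
    design: TreatmentDesign,
) -> list[TreatmentSummary]:
    """Average normalized traces per treatment and collect score vectors.

    The pointwise mean and SEM are taken across neurons on the common time
    grid (traces truncated to the shortest when lengths differ, with a log
    message).  SEM uses the sample standard deviation (ddof=1) and is 0 for a
    single neuron.  Treatments in the design without any accepted neuron are
    excluded with a warning.
    """
    by_treatment: dict[str, list[NormalizedResponse]] = {}
    for resp in responses:
        if resp.treatment not in design.roles:
            raise ValidationError(
                f"response treatment {resp.treatment!r} is not part of the design"
            )
        by_treatment.setdefault(resp.treatment, []).append(resp)

    summaries: list[TreatmentSummary] = []
    for treatment in design.treatments:
        group = by_treatment.get(treatment, [])
        if not group:
            logger.warning("treatment %r has no accepted neurons; excluded", treatment)
            continue
        group = sorted(group, key=lambda r: r.key)
        n_frames = min(len(r.t) for r in group)
        if any(len(r.t) != n_frames for r in group):
            logger.info(
                "treatment %r: traces truncated to common grid of %d frames",
                treatment, n_frames,
            )
        t = group[0].t[:n_frames]
        stack = np.vstack([r.trace[:n_frames] for r in group])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
            mean = np.nanmean(stack, axis=0)
            n_valid = np.sum(np.isfinite(stack), axis=0)
            sd = np.nanstd(stack, axis=0, ddof=1)
        sem = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), 0.0)
        summaries.append(TreatmentSummary(
            treatment=treatment,
            t=t,
            mean=mean,
            sem=sem,
            scores={
                "long": np.array([r.max_long for r in group]),
                "short": np.array([r.max_short for r in group]),
            },
            neuron_keys=[r.key for r in group],
            n_neurons=len(group),
            n_brains=len({r.brain_id for r in group}),
        ))
    if not summaries:
        raise ValidationError("no treatment has any accepted neuron")
    return summaries


def score_vectors(
    summaries: Sequence[TreatmentSummary], window: str = "long"
) -> dict[str, np.ndarray]:
    """Extract ``{treatment: per-neuron max scores}`` for one window."""
    return {s.treatment: np.asarray(s.scores[window], dtype=float) for s in summaries}
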
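"""Forward simulation of raw experimental inputs.

The generator produces exactly the tables the analysis consumes — raw
dual-channel FRET traces, single-channel calcium traces and binomial dormancy
count tables — from a fully explicit parameterization, so every stage of the
pipeline can be verified by parameter recovery.

The latent per-neuron response c(t) is a phenomenological kinetic model (the
source experiments report trace shapes, not equations):

    c(t) = 0                                        for t <  t_app
    c(t) = A_slow * (1 - exp(-(t - t_app)/tau_slow))
           + A_fast * alpha(t - t_app)              for t >= t_app

where ``alpha`` is a double-exponential with unit peak (rise tau_fast_rise,
decay tau_fast_decay), and the whole response is multiplied by
``exp(-(t - t_decline)/tau_decline)`` beyond an optional delayed-decline
onset.  ``ttx_blocks_fast`` zeroes the fast component, emulating TTX blocking
of the action-potential-dependent (indirect) part of a response.

Channel mixing mirrors the sensor physics the analysis inverts: rising cAMP
increases CFP and decreases YFP emission (lower FRET), and a fraction ``k``
of CFP emission bleeds into the YFP detector:

    CFP_true = C0 * (1 + g*c(t)) * bleach(t)
    YFP_true = Y0 * (1 - g*c(t)) * bleach(t)
    CFP_meas = CFP_true + bg(t) + noise
    YFP_meas = YFP_true + k*CFP_true + bg(t) + noise

Bleaching is a shared multiplicative exponential on both channels and cancels
exactly in the iFRET ratio — a testable invariant.  Per-neuron kinetic
amplitudes get a log-normal multiplicative jitter (mean 1); every neuron has
its own deterministic substream derived from (seed, treatment, brain, roi).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import DormancyTable, RoiTraceSet, TreatmentDesign


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseKinetics:
    """Latent response kinetics of one treatment class.

    Amplitudes are fractions of the baseline latent signal (dimensionless);
    times and time constants are in seconds.
    """

    t_app: float = 100.0
    a_slow: float = 0.0
    tau_slow: float = 200.0
    a_fast: float = 0.0
    tau_fast_rise: float = 10.0
    tau_fast_decay: float = 40.0
    t_decline: float | None = None
    tau_decline: float = 300.0
    ttx_blocks_fast: bool = False

    def __post_init__(self) -> None:
        for name in ("tau_slow", "tau_fast_rise", "tau_fast_decay", "tau_decline"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.a_slow < 0 or self.a_fast < 0:
            raise ValidationError("amplitudes must be non-negative")

    @property
    def effective_a_fast(self) -> float:
        return 0.0 if self.ttx_blocks_fast else self.a_fast

    def scaled(self, factor: float) -> "ResponseKinetics":
        return replace(self, a_slow=self.a_slow * factor, a_fast=self.a_fast * factor)


def _alpha_unit_peak(dt: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Double-exponential transient normalized to unit peak; 0 for dt < 0."""
    dt = np.asarray(dt, dtype=float)
    out = np.zeros_like(dt)
    pos = dt > 0
    if tau_decay == tau_rise:
        # limiting form: (dt/tau) * exp(1 - dt/tau) peaks at dt = tau
        x = dt[pos] / tau_rise
        out[pos] = x * np.exp(1.0 - x)
        return out
    t_peak = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    out[pos] = (np.exp(-dt[pos] / tau_decay) - np.exp(-dt[pos] / tau_rise)) / peak
    return out


def latent_signal(kinetics: ResponseKinetics, t) -> np.ndarray:
    """Evaluate the latent response c(t) on a time grid (seconds)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValidationError("time must be non-negative")
    dt = t - kinetics.t_app
    c = np.zeros_like(t)
    after = dt >= 0
    c[after] = kinetics.a_slow * (1.0 - np.exp(-dt[after] / kinetics.tau_slow))
    c += kinetics.effective_a_fast * _alpha_unit_peak(dt, kinetics.tau_fast_rise,
                                                      kinetics.tau_fast_decay)
    if kinetics.t_decline is not None:
        declining = t > kinetics.t_decline
        c[declining] *= np.exp(-(t[declining] - kinetics.t_decline) / kinetics.tau_decline)
    return c


def ifret_percent_from_latent(c, gain: float) -> np.ndarray:
    """Closed-form normalized iFRET percent change produced by latent c.

    With CFP ∝ (1 + g*c) and YFP ∝ (1 - g*c) and exact spillover removal, the
    baseline-normalized iFRET change is 2*g*c / (1 - g*c) * 100 percent.
    """
    x = gain * np.asarray(c, dtype=float)
    if np.any(x >= 1):
        raise ValidationError("gain * latent amplitude must stay below 1")
    return 200.0 * x / (1.0 - x)


def latent_for_ifret_percent(percent: float, gain: float) -> float:
    """Invert :func:`ifret_percent_from_latent` for a single value."""
    p = percent / 100.0
    return p / ((2.0 + p) * gain)


# ---------------------------------------------------------------------------
# experiment specification
# ---------------------------------------------------------------------------

@dataclass
class TreatmentSpec:
    kinetics: ResponseKinetics
    role: str = "experimental"


@dataclass
class SimulationSpec:
    """Complete parameterization of a synthetic imaging experiment.

    Defaults follow the reference acquisition protocol: 0.2 Hz frame rate,
    1000 s recordings, bath application at 100 s, spillover fraction 0.357.
    """

    treatments: dict[str, TreatmentSpec]
    seed: int
    n_brains: int = 5
    neurons_per_brain: int = 4
    frame_rate: float = 0.2
    duration: float = 1000.0
    application_time: float = 100.0
    baseline_cfp: float = 1000.0
    baseline_yfp: float = 1500.0
    baseline_gfp: float = 800.0
    gain: float = 0.5
    spillover: float = 0.357
    background: float = 50.0
    background_drift: float = 0.0
    noise_sd: float = 1.5
    bleach_tau: float | None = None
    neuron_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is required")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if self.baseline_cfp <= 0 or self.baseline_yfp <= 0 or self.baseline_gfp <= 0:
            raise ValidationError("baseline channel levels must be positive")
        if not 0.0 <= self.spillover < 1.0:
            raise ValidationError("spillover must satisfy 0 <= k < 1")
        if self.noise_sd < 0 or self.neuron_cv < 0:
            raise ValidationError("noise_sd and neuron_cv must be non-negative")
        if self.bleach_tau is not None and self.bleach_tau <= 0:
            raise ValidationError("bleach_tau must be positive when set")
        if not self.treatments:
            raise ValidationError("at least one treatment is required")

    @property
    def time_grid(self) -> np.ndarray:
        dt = 1.0 / self.frame_rate
        n = int(round(self.duration / dt)) + 1
        return np.arange(n) * dt

    def design(self) -> TreatmentDesign:
        return TreatmentDesign(roles={name: ts.role for name, ts in self.treatments.items()})

    # -- (de)serialization --------------------------------------------------
    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationSpec":
        raw = dict(raw)
        treatments = {}
        for name, tdef in raw.pop("treatments").items():
            tdef = dict(tdef)
            kin = ResponseKinetics(**tdef.pop("kinetics", {}))
            treatments[str(name)] = TreatmentSpec(kinetics=kin,
                                                  role=tdef.pop("role", "experimental"))
        return cls(treatments=treatments, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        raw = asdict(self)
        raw["treatments"] = {
            name: {"role": ts.role, "kinetics": asdict(ts.kinetics)}
            for name, ts in self.treatments.items()
        }
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
        return path


def kinetics_for_peak_percent(
    kinetics: ResponseKinetics, target_percent: float, spec: SimulationSpec
) -> ResponseKinetics:
    """Rescale latent amplitudes so the noiseless iFRET peak hits a target %.

    The normalized iFRET change is a monotone per-frame map of the latent
    signal, so scaling reduces to matching the latent peak on the frame grid.
    """
    if target_percent == 0:
        return kinetics.scaled(0.0)
    unit_peak = float(np.max(latent_signal(kinetics, spec.time_grid)))
    if unit_peak <= 0:
        raise ValidationError("kinetics produce no response; cannot scale to a peak")
    return kinetics.scaled(latent_for_ifret_percent(target_percent, spec.gain) / unit_peak)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _neuron_rng(seed: int, treatment: str, brain: int, roi: int) -> np.random.Generator:
    digest = zlib.crc32(f"{treatment}|{brain}|{roi}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def _jitter(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _bleach(spec: SimulationSpec, t: np.ndarray) -> np.ndarray:
    if spec.bleach_tau is None:
        return np.ones_like(t)
    return np.exp(-t / spec.bleach_tau)


def simulate_fret_experiment(spec: SimulationSpec) -> RoiTraceSet:
    """Synthesize a dual-channel FRET recording as a :class:`RoiTraceSet`.

    Each brain receives a single bath-applied treatment; each of its neurons
    shares the treatment kinetics up to a log-normal amplitude jitter.
    Background columns carry the (noise-free) background level used, as an
    ideal background-ROI estimate.
    """
    t = spec.time_grid
    bleach = _bleach(spec, t)
    bg = spec.background + spec.background_drift * t
    frames = []
    for treatment in sorted(spec.treatments):
        kin = replace(spec.treatments[treatment].kinetics, t_app=spec.application_time) \
            if spec.treatments[treatment].kinetics.t_app != spec.application_time \
            else spec.treatments[treatment].kinetics
        for b in range(spec.n_brains):
            brain_id = f"{treatment}-b{b + 1:02d}"
            for r in range(spec.neurons_per_brain):
                roi_id = f"r{r + 1:02d}"
                rng = _neuron_rng(spec.seed, treatment, b, r)
                c = latent_signal(kin.scaled(_jitter(rng, spec.neuron_cv)), t)
                x = spec.gain * c
                if np.any(x >= 0.95):
                    raise ValidationError(
                        f"treatment {treatment!r}: gain * latent signal reached "
                        ">= 0.95; reduce amplitudes or gain"
                    )
                cfp_true = spec.baseline_cfp * (1.0 + x) * bleach
                yfp_true = spec.baseline_yfp * (1.0 - x) * bleach
                cfp = cfp_true + bg + rng.normal(0.0, spec.noise_sd, t.size)
                yfp = yfp_true + spec.spillover * cfp_true + bg \
                    + rng.normal(0.0, spec.noise_sd, t.size)
                frames.append(pd.DataFrame({
                    "brain_id": brain_id, "roi_id": roi_id, "treatment": treatment,
                    "t": t, "cfp": np.maximum(cfp, 0.0), "yfp": np.maximum(yfp, 0.0),
                    "bg_cfp": bg, "bg_yfp": bg,
                }))
    return RoiTraceSet(
        frames=pd.concat(frames, ignore_index=True),
        application_time=spec.application_time,
        frame_rate=spec.frame_rate,
    )


def simulate_calcium_experiment(spec: SimulationSpec) -> RoiTraceSet:
    """Synthesize a single-channel calcium recording.

    GFP(t) = G0 * (1 + c(t)) * bleach + bg + noise, so the latent amplitude
    is directly the fractional dF/F0 (peak c = 0.034 -> 3.4 %).
    """
    t = spec.time_grid
    bleach = _bleach(spec, t)
    bg = spec.background + spec.background_drift * t
    frames = []
    for treatment in sorted(spec.treatments):
        kin = spec.treatments[treatment].kinetics
        for b in range(spec.n_brains):
            brain_id = f"{treatment}-b{b + 1:02d}"
            for r in range(spec.neurons_per_brain):
                roi_id = f"r{r + 1:02d}"
                rng = _neuron_rng(spec.seed, treatment, b, r)
                c = latent_signal(kin.scaled(_jitter(rng, spec.neuron_cv)), t)
                gfp = spec.baseline_gfp * (1.0 + c) * bleach + bg \
                    + rng.normal(0.0, spec.noise_sd, t.size)
                frames.append(pd.DataFrame({
                    "brain_id": brain_id, "roi_id": roi_id, "treatment": treatment,
                    "t": t, "gfp": np.maximum(gfp, 0.0), "bg_gfp": bg,
                }))
    return RoiTraceSet(
        frames=pd.concat(frames, ignore_index=True),
        application_time=spec.application_time,
        frame_rate=spec.frame_rate,
    )


# ---------------------------------------------------------------------------
# dormancy counts
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_dormancy_counts(
    genotype_probs: Mapping[str, float],
    photoperiod_effects: Mapping[str, float] | None = None,
    n_replicates: int = 5,
    n_per_replicate: int = 60,
    seed: int = 0,
) -> DormancyTable:
    """Binomial dormancy counts per replicate vial.

    ``genotype_probs`` maps genotype -> arrest probability; optional
    ``photoperiod_effects`` maps photoperiod label -> additive logit offset
    (probabilities of exactly 0 or 1 are kept as-is).  Draws are reproducible
    per seed.
    """
    if n_replicates < 1 or n_per_replicate < 1:
        raise ValidationError("n_replicates and n_per_replicate must be >= 1")
    for g, p in genotype_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"genotype {g!r} has invalid probability {p}")
    rng = np.random.default_rng(int(seed))
    photoperiods = list(photoperiod_effects) if photoperiod_effects else [None]
    rows = []
    for genotype in sorted(genotype_probs):
        base = genotype_probs[genotype]
        for pp in photoperiods:
            if pp is None or base in (0.0, 1.0):
                p = base
            else:
                p = _sigmoid(_logit(base) + photoperiod_effects[pp])
                if not 0.0 <= p <= 1.0:  # numerically clamped
                    p = min(1.0, max(0.0, p))
            for rep in range(n_replicates):
                row = {
                    "genotype": genotype,
                    "replicate": f"{genotype}{'' if pp is None else '-' + str(pp)}-v{rep + 1:02d}",
                    "n_dissected": n_per_replicate,
                    "n_arrested": int(rng.binomial(n_per_replicate, p)),
                }
                if pp is not None:
                    row["photoperiod"] = pp
                rows.append(row)
    df = pd.DataFrame(rows)
    if photoperiod_effects:
        df = df[["genotype", "photoperiod", "replicate", "n_dissected", "n_arrested"]]
    return DormancyTable(rows=df)


# ---------------------------------------------------------------------------
# shipped demonstration specs
# ---------------------------------------------------------------------------

def builtin_spec_path(name: str) -> Path:
    """Path of a packaged simulation spec (``default_experiment`` or
    ``null_experiment``)."""
    path = Path(__file__).parent / "specs" / f"{name}.yaml"
    if not path.exists():
        raise ValidationError(f"no built-in spec named {name!r}")
    return path


def load_builtin_spec(name: str, seed: int | None = None) -> SimulationSpec:
    spec = SimulationSpec.from_yaml(builtin_spec_path(name))
    if seed is not None:
        spec.seed = int(seed)
    return spec
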
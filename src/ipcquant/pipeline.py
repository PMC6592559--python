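"""End-to-end orchestration: config, pipelines, plots and run manifests.

A run is fully determined by (inputs, config, seed): every stochastic step
receives an explicit seed, numeric outputs are plain CSV/JSON, and a manifest
records the configuration, package version and a SHA-256 digest of every
output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .imaging import (
    AnalysisWindows,
    QuantificationResult,
    TreatmentSummary,
    quantify_calcium,
    quantify_fret,
    score_vectors,
    summarize_treatment,
)
from .io import (
    DormancyTable,
    RoiTraceSet,
    TreatmentDesign,
    write_summary_table,
)
from .dormancy import DormancyAnalysis, analyze_dormancy, ddct_ratios
from .stats import (
    ALPHA_TIERS,
    ComparisonResult,
    SynergyResult,
    pairwise_wilcoxon_bonferroni,
    select_test_path,
    synergy_excess,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    output_dir: str | Path = "ipcquant-run"
    seed: int = 0
    spillover: float = 0.357
    application_time: float = 100.0
    baseline_window: tuple[float, float] = (0.0, 100.0)
    long_window: tuple[float, float] = (100.0, 1000.0)
    short_window: tuple[float, float] = (100.0, 200.0)
    max_invalid_fraction: float = 0.10
    stats_path: str = "nonparametric"  # "nonparametric" | "auto"
    family: Sequence[tuple[str, str]] | None = None  # None = all pairs
    n_boot: int = 10_000
    alpha_tiers: tuple[float, ...] = ALPHA_TIERS
    synergy: dict | None = None  # {"combined":..., "a":..., "b":..., "window":"short"}
    make_plots: bool = True

    @property
    def windows(self) -> AnalysisWindows:
        return AnalysisWindows(
            baseline=tuple(self.baseline_window),
            long=tuple(self.long_window),
            short=tuple(self.short_window),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "family" in raw and raw["family"] is not None:
            raw["family"] = [tuple(pair) for pair in raw["family"]]
        for key in ("baseline_window", "long_window", "short_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "alpha_tiers" in raw:
            raw["alpha_tiers"] = tuple(raw["alpha_tiers"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        raw = asdict(self)
        raw["output_dir"] = str(raw["output_dir"])
        if raw["family"] is not None:
            raw["family"] = [list(p) for p in raw["family"]]
        return raw


@dataclass
class FretRunResult:
    summaries: list[TreatmentSummary]
    comparisons: dict[str, ComparisonResult]
    synergy: SynergyResult | None
    quant: QuantificationResult
    outputs: list[Path] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(output_dir: Path, config: RunConfig, outputs: Sequence[Path]) -> Path:
    manifest = {
        "package": "ipcquant",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "outputs": {str(p.relative_to(output_dir)): _sha256(p) for p in sorted(outputs)},
    }
    path = output_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _responses_frame(quant: QuantificationResult) -> pd.DataFrame:
    rows = []
    for r in quant.responses:
        rows.append(pd.DataFrame({
            "brain_id": r.brain_id, "roi_id": r.roi_id, "treatment": r.treatment,
            "kind": r.kind, "t": r.t, "normalized_pct": r.trace,
        }))
    return pd.concat(rows, ignore_index=True)


def _comparison_frame(result: ComparisonResult) -> pd.DataFrame:
    table = result.pairwise.copy()
    table.insert(0, "omnibus_p", result.omnibus_p)
    table.insert(0, "omnibus_stat", result.omnibus_stat)
    table.insert(0, "omnibus_method", result.method)
    return table


def _plot_traces(summaries: Sequence[TreatmentSummary], windows: AnalysisWindows,
                 path: Path, ylabel: str) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for summ in summaries:
        ax.plot(summ.t, summ.mean, label=f"{summ.treatment} ({summ.n_neurons})")
        ax.fill_between(summ.t, summ.mean - summ.sem, summ.mean + summ.sem, alpha=0.25)
    ax.axvline(windows.baseline[1], color="k", lw=0.8, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_score_bars(summaries: Sequence[TreatmentSummary], window: str,
                     path: Path, ylabel: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    labels, means, sems = [], [], []
    for summ in summaries:
        scores = summ.scores[window]
        labels.append(f"{summ.treatment}\n({summ.n_neurons})")
        means.append(float(np.mean(scores)))
        sems.append(float(np.std(scores, ddof=1) / np.sqrt(len(scores))) if len(scores) > 1 else 0.0)
    ax.bar(labels, means, yerr=sems, capsize=3)
    ax.set_ylabel(ylabel)
    ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def _run_imaging_pipeline(
    traces: RoiTraceSet,
    design: TreatmentDesign,
    config: RunConfig,
    mode: str,
) -> FretRunResult:
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    windows = config.windows
    if mode == "fret":
        quant = quantify_fret(
            traces, windows=windows, k=config.spillover,
            max_invalid_fraction=config.max_invalid_fraction,
        )
        ylabel = "iFRET change (%)"
    else:
        quant = quantify_calcium(traces, windows=windows)
        ylabel = "dF/F0 (%)"
    if not quant.responses:
        raise ValidationError("all ROIs were rejected; nothing to summarize")
    summaries = summarize_treatment(quant.responses, design)

    outputs: list[Path] = []
    traces_path = output_dir / "normalized_traces.csv"
    _responses_frame(quant).to_csv(traces_path, index=False)
    outputs.append(traces_path)
    summary_path = output_dir / "treatment_summary.csv"
    write_summary_table(summaries, summary_path)
    outputs.append(summary_path)

    comparisons: dict[str, ComparisonResult] = {}
    for window in ("long", "short"):
        groups = score_vectors(summaries, window)
        groups = {k: v for k, v in groups.items() if len(v) >= 3}
        if len(groups) < 2:
            logger.warning("window %r: fewer than 2 groups with n >= 3; skipping stats", window)
            continue
        if config.stats_path == "auto":
            path_used = select_test_path(groups)
            logger.info("window %r: test path selected as %s", window, path_used)
        result = pairwise_wilcoxon_bonferroni(
            groups, family=config.family, alpha_tiers=config.alpha_tiers
        )
        comparisons[window] = result
        cmp_path = output_dir / f"comparisons_{window}.csv"
        _comparison_frame(result).to_csv(cmp_path, index=False)
        outputs.append(cmp_path)

    synergy = None
    if config.synergy:
        syn = dict(config.synergy)
        window = syn.get("window", "short")
        groups = score_vectors(summaries, window)
        try:
            synergy = synergy_excess(
                groups[syn["combined"]], groups[syn["a"]], groups[syn["b"]],
                n_boot=config.n_boot, seed=config.seed,
            )
        except KeyError as exc:
            raise ValidationError(f"synergy treatment {exc} not present in summaries") from exc
        syn_path = output_dir / "synergy.json"
        with open(syn_path, "w", encoding="utf-8") as fh:
            json.dump({**asdict(synergy), "window": window,
                       "combined": syn["combined"], "a": syn["a"], "b": syn["b"]},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs.append(syn_path)

    if config.make_plots:
        plot1 = output_dir / f"mean_traces_{mode}.png"
        _plot_traces(summaries, windows, plot1, ylabel)
        outputs.append(plot1)
        for window in ("long", "short"):
            plot2 = output_dir / f"max_response_{window}_{mode}.png"
            _plot_score_bars(summaries, window, plot2, f"max {ylabel} [{window}]")
            outputs.append(plot2)

    if quant.rejected:
        rej_path = output_dir / "rejected_rois.csv"
        pd.DataFrame(
            [{"brain_id": b, "roi_id": r, "reason": reason}
             for (b, r), reason in quant.rejected]
        ).to_csv(rej_path, index=False)
        outputs.append(rej_path)

    outputs.append(write_manifest(output_dir, config, outputs))
    return FretRunResult(summaries=summaries, comparisons=comparisons,
                         synergy=synergy, quant=quant, outputs=outputs)


def run_fret_pipeline(
    traces: RoiTraceSet, design: TreatmentDesign, config: RunConfig
) -> FretRunResult:
    """Raw FRET traces -> normalized responses, summaries, stats, plots."""
    return _run_imaging_pipeline(traces, design, config, mode="fret")


def run_calcium_pipeline(
    traces: RoiTraceSet, design: TreatmentDesign, config: RunConfig
) -> FretRunResult:
    """Raw GCaMP traces -> dF/F0 responses, summaries, stats, plots."""
    return _run_imaging_pipeline(traces, design, config, mode="calcium")


def run_dormancy_pipeline(
    table: DormancyTable,
    config: RunConfig,
    two_factor: bool | None = None,
    ct_table: pd.DataFrame | None = None,
    calibrator: str | None = None,
    target_gene: str | None = None,
    reference_gene: str = "rp49",
) -> DormancyAnalysis:
    """Dormancy counts -> proportions, arcsine ANOVA (+Tukey), optional ddCt."""
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    analysis = analyze_dormancy(table, two_factor=two_factor)
    outputs: list[Path] = []
    for name, frame in (
        ("dormancy_replicates.csv", analysis.proportions),
        ("dormancy_groups.csv", analysis.group_summary),
        ("dormancy_anova.csv", analysis.anova),
    ):
        path = output_dir / name
        frame.to_csv(path, index=False)
        outputs.append(path)
    if analysis.tukey is not None:
        path = output_dir / "dormancy_tukey.csv"
        analysis.tukey.to_csv(path, index=False)
        outputs.append(path)
    if ct_table is not None:
        if calibrator is None or target_gene is None:
            raise ValidationError("ddCt analysis needs --calibrator and a target gene")
        ddct = ddct_ratios(ct_table, calibrator=calibrator, target=target_gene,
                           reference=reference_gene)
        for name, frame in (("ddct_samples.csv", ddct.per_sample),
                            ("ddct_groups.csv", ddct.group_summary)):
            path = output_dir / name
            frame.to_csv(path, index=False)
            outputs.append(path)
    if config.make_plots:
        fig, ax = plt.subplots(figsize=(6, 4))
        summ = analysis.group_summary
        labels = summ["genotype"].astype(str)
        if "photoperiod" in summ.columns:
            labels = labels + " / " + summ["photoperiod"].astype(str)
        ax.bar(labels, 100 * summ["mean_proportion"],
               yerr=100 * summ["sem_proportion"], capsize=3)
        ax.set_ylabel("dormancy (%)")
        ax.tick_params(axis="x", labelsize=7)
        fig.tight_layout()
        plot = output_dir / "dormancy_bars.png"
        fig.savefig(plot, dpi=120)
        plt.close(fig)
        outputs.append(plot)
    outputs.append(write_manifest(output_dir, config, outputs))
    return analysis


# ---------------------------------------------------------------------------
# demonstration workflow
# ---------------------------------------------------------------------------

def run_demo(output_dir: str | Path, seed: int = 2019, make_plots: bool = True) -> dict:
    """Regenerate the full synthetic workflow end to end.

    Simulates the default bath-application panel (FRET), a calcium panel and
    a two-genotype dormancy assay, then runs all three analysis pipelines.
    Returns the in-memory results keyed by stage.
    """
    from .simulate import (
        ResponseKinetics,
        SimulationSpec,
        TreatmentSpec,
        load_builtin_spec,
        simulate_calcium_experiment,
        simulate_dormancy_counts,
        simulate_fret_experiment,
    )

    output_dir = Path(output_dir)
    spec = load_builtin_spec("default_experiment", seed=seed)
    traces = simulate_fret_experiment(spec)
    fret_config = RunConfig(
        output_dir=output_dir / "fret",
        seed=seed,
        spillover=spec.spillover,
        application_time=spec.application_time,
        synergy={"combined": "sNPF+PDF", "a": "sNPF", "b": "PDF", "window": "short"},
        make_plots=make_plots,
    )
    fret = run_fret_pipeline(traces, spec.design(), fret_config)

    ca_spec = SimulationSpec(
        treatments={
            "HL3": TreatmentSpec(ResponseKinetics(), role="negative_control"),
            "CCh": TreatmentSpec(ResponseKinetics(a_slow=0.0, a_fast=0.30,
                                                  tau_fast_rise=5.0, tau_fast_decay=120.0),
                                 role="positive_control"),
            "PDF": TreatmentSpec(ResponseKinetics(), role="experimental"),
            "sNPF": TreatmentSpec(ResponseKinetics(a_fast=0.034, tau_fast_rise=15.0,
                                                   tau_fast_decay=150.0),
                                  role="experimental"),
            "sNPF+TTX": TreatmentSpec(ResponseKinetics(a_fast=0.054, tau_fast_rise=15.0,
                                                       tau_fast_decay=150.0),
                                      role="experimental"),
        },
        seed=seed + 1,
        n_brains=spec.n_brains,
        neurons_per_brain=spec.neurons_per_brain,
        noise_sd=spec.noise_sd,
        neuron_cv=spec.neuron_cv,
    )
    ca_traces = simulate_calcium_experiment(ca_spec)
    ca_config = RunConfig(output_dir=output_dir / "calcium", seed=seed + 1,
                          make_plots=make_plots)
    calcium = run_calcium_pipeline(ca_traces, ca_spec.design(), ca_config)

    dorm_table = simulate_dormancy_counts(
        genotype_probs={"control": 0.30, "mutant": 0.60},
        photoperiod_effects={"LD16:8": -0.8, "LD8:16": 0.8},
        n_replicates=5, n_per_replicate=60, seed=seed + 2,
    )
    dorm_config = RunConfig(output_dir=output_dir / "dormancy", seed=seed + 2,
                            make_plots=make_plots)
    dormancy = run_dormancy_pipeline(dorm_table, dorm_config)

    return {"fret": fret, "calcium": calcium, "dormancy": dormancy}
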
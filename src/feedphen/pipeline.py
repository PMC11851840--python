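"""End-to-end feed-efficiency phenotyping pipeline.

Stages: simulate (or load) visit records -> visit QC -> intake outlier
imputation -> daily aggregation -> per-animal robust growth fits and gating
-> population logistic growth model -> cumulative-feed-intake series and
per-animal BW-CFI lines -> population CF/A correction coefficients and
standardized 30-120 kg CFI -> sliding-window breakpoint analysis -> the
Bayesian ridge CFI predictor with k-fold cross-validation.  A second,
independently seeded herd (a different batch) is processed with the
training coefficients and model frozen, providing grouped validation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import brr, cfi, growth, intake, qc, windows
from .config import PipelineConfig
from .simulate import SimResult, simulate_population

logger = logging.getLogger(__name__)


def aggregate_daily(events: pd.DataFrame) -> pd.DataFrame:
    """Per-animal per-day aggregate: daily feed intake (kg) is the sum of
    visit intakes; the representative weight is the median visit weight."""
    grouped = events.groupby(["pig_id", "day"], sort=True)
    daily = grouped.agg(
        dfi_kg=("fiv_g", lambda v: v.sum() / 1000.0),
        bw_kg=("bw_kg", "median"),
        n_visits=("fiv_g", "size"),
    ).reset_index()
    return daily


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    elapsed_s: float


@dataclass
class PopulationResult:
    """Artifacts for one herd run through the phenotyping stages."""

    sim: SimResult
    qc_report: qc.QcReport
    clean_events: pd.DataFrame = field(repr=False)
    daily: pd.DataFrame = field(repr=False)
    growth_fits: dict = field(repr=False)
    retained_ids: list[int] = field(repr=False)
    logistic: growth.LogisticFit
    series: pd.DataFrame = field(repr=False)
    cfi_fits: dict = field(repr=False)
    corrected: pd.DataFrame = field(repr=False)
    correction_eval: cfi.CorrectionEvaluation


@dataclass
class RunReport:
    stages: list[StageRecord]
    coefficients: cfi.CorrectionCoefficients
    training: PopulationResult
    validation: PopulationResult
    window_summaries: list[windows.ModuleSizeSummary]
    breakpoint: windows.BreakpointFit
    optimal_size: int
    cv_reports: dict[int, brr.CvReport]
    model: brr.EvidenceBayesianRidge
    validation_prediction: pd.DataFrame = field(repr=False, default=None)
    validation_spearman: float = np.nan
    validation_pearson: float = np.nan

    def stage_counts_chain(self) -> bool:
        """Record counts chain consistently: each visit-level stage consumes
        exactly what the previous stage emitted, and gating stages only ever
        shrink the herd."""
        by = {s.name: s for s in self.stages}
        for tag in ("train", "validation"):
            visit_chain = (f"{tag}:simulate", f"{tag}:qc", f"{tag}:intake",
                           f"{tag}:daily")
            for a, b in zip(visit_chain, visit_chain[1:]):
                if by[a].n_out != by[b].n_in:
                    return False
            for gate in (f"{tag}:qc", f"{tag}:intake", f"{tag}:growth-gate",
                         f"{tag}:cfi-fit", f"{tag}:cfi-correct"):
                if by[gate].n_out > by[gate].n_in:
                    return False
        return True

    def to_text(self) -> str:
        lines = ["feedphen pipeline report", ""]
        for s in self.stages:
            lines.append(f"{s.name:<28} in {s.n_in:>9}  out {s.n_out:>9}  "
                         f"{s.elapsed_s:7.2f} s")
        lines += ["", self.coefficients.to_text(),
                  f"breakpoint: {self.breakpoint.breakpoint:.1f} kg "
                  f"(optimal module size {self.optimal_size} kg)", ""]
        for k, rep in self.cv_reports.items():
            lines += [rep.to_text()]
        lines += [
            "validation (frozen coefficients and model):",
            f"  corrected-vs-reference correlations:",
            self.validation.correction_eval.pearson.round(4).to_string(),
            f"  predicted CFI vs reference: Spearman "
            f"{self.validation_spearman:.3f}, Pearson "
            f"{self.validation_pearson:.3f}", "",
        ]
        return "\n".join(lines) + "\n"


def _process_population(
    sim: SimResult,
    config: PipelineConfig,
    coefficients: cfi.CorrectionCoefficients | None,
    stages: list[StageRecord],
    tag: str,
) -> tuple[PopulationResult, cfi.CorrectionCoefficients]:
    """Run one herd through QC, intake imputation, growth gating and CFI
    correction.  With ``coefficients`` given (validation mode) they are
    applied frozen; otherwise they are estimated from this herd."""

    def record(name, n_in, n_out, t0):
        stages.append(StageRecord(f"{tag}:{name}", n_in, n_out,
                                  time.perf_counter() - t0))
        logger.info("%s:%s %d -> %d", tag, name, n_in, n_out)

    t0 = time.perf_counter()
    clean, report = qc.apply_qc(sim.events)
    record("qc", len(sim.events), len(clean), t0)

    t0 = time.perf_counter()
    imputer = intake.IntakeImputer().fit(clean)
    corrected_events = imputer.transform(clean)
    record("intake", len(clean), len(corrected_events), t0)

    t0 = time.perf_counter()
    daily = aggregate_daily(corrected_events)
    record("daily", len(corrected_events), len(daily), t0)

    t0 = time.perf_counter()
    growth_fits = growth.fit_all_growth(daily, config.growth_r2_threshold)
    retained = growth.gate_animals(growth_fits, config.growth_r2_threshold)
    record("growth-gate", len(growth_fits), len(retained), t0)

    t0 = time.perf_counter()
    gated_daily = daily[daily["pig_id"].isin(retained)]
    logistic = growth.fit_logistic(gated_daily)
    series = cfi.build_cfi_series(gated_daily)
    cfi_fits = cfi.fit_all_cfi_lines(
        series, start_window=config.cfi_start_window,
        end_window=config.cfi_end_window,
        r2_threshold=config.cfi_r2_threshold)
    n_retained_cfi = sum(f.retained for f in cfi_fits.values())
    record("cfi-fit", len(retained), n_retained_cfi, t0)

    t0 = time.perf_counter()
    if coefficients is None:
        coefficients = cfi.population_coefficients(cfi_fits)
    corrected = cfi.apply_corrections(cfi_fits, coefficients)
    evaluation = cfi.evaluate_correction(corrected)
    record("cfi-correct", n_retained_cfi, len(corrected), t0)

    result = PopulationResult(
        sim=sim, qc_report=report, clean_events=corrected_events,
        daily=daily, growth_fits=growth_fits, retained_ids=retained,
        logistic=logistic, series=series, cfi_fits=cfi_fits,
        corrected=corrected, correction_eval=evaluation)
    return result, coefficients


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline on a training herd, then validate the
    frozen coefficients and predictor on an independent batch."""
    stages: list[StageRecord] = []

    t0 = time.perf_counter()
    train_sim = simulate_population(config.sim)
    stages.append(StageRecord("train:simulate", config.sim.n_pigs,
                              len(train_sim.events),
                              time.perf_counter() - t0))

    train, coefficients = _process_population(
        train_sim, config, None, stages, "train")

    # sliding-window analysis on the training herd
    t0 = time.perf_counter()
    overall_fcr = {
        f.pig_id: cfi.cfi_reg_values(f)[0] / 90.0
        for f in train.cfi_fits.values() if f.retained
    }
    summaries = windows.sliding_window_summary(
        train.series, train.growth_fits, overall_fcr,
        sizes=config.window_sizes, lo=config.weight_range[0],
        hi=config.weight_range[1])
    bp = windows.fit_breakpoint([s.size for s in summaries],
                                [s.mean_spearman for s in summaries])
    optimal = windows.select_optimal_module(bp)
    stages.append(StageRecord("train:windows", len(summaries), optimal,
                              time.perf_counter() - t0))

    # predictor on the configured window
    t0 = time.perf_counter()
    window = windows.ModuleWindow(*config.prediction_window)
    design = brr.build_design(train.series, train.growth_fits,
                              train.cfi_fits, window)
    model = brr.fit_brr(design)
    cv_reports = {k: brr.cross_validate(design, k, config.cv_seed)
                  for k in config.k_folds}
    stages.append(StageRecord("train:predict", len(design), len(design),
                              time.perf_counter() - t0))

    # ---- grouped validation: frozen coefficients, frozen model ----------
    t0 = time.perf_counter()
    val_sim = simulate_population(config.validation_sim())
    stages.append(StageRecord("validation:simulate", config.n_validation,
                              len(val_sim.events), time.perf_counter() - t0))
    validation, _ = _process_population(
        val_sim, config, coefficients, stages, "validation")

    t0 = time.perf_counter()
    val_design = brr.build_design(validation.series, validation.growth_fits,
                                  validation.cfi_fits, window)
    val_pred = val_design.copy()
    val_pred["predicted"] = brr.predict_cfi(model, val_design)
    val_spearman = float(stats.spearmanr(
        val_pred["predicted"], val_pred["target"]).statistic)
    val_pearson = float(stats.pearsonr(
        val_pred["predicted"], val_pred["target"]).statistic)
    stages.append(StageRecord("validation:predict", len(val_design),
                              len(val_pred), time.perf_counter() - t0))

    return RunReport(
        stages=stages, coefficients=coefficients, training=train,
        validation=validation, window_summaries=summaries, breakpoint=bp,
        optimal_size=optimal, cv_reports=cv_reports, model=model,
        validation_prediction=val_pred, validation_spearman=val_spearman,
        validation_pearson=val_pearson)


def summarize_correlations(vectors: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson and Spearman with two-sided p-values.

    Zero-variance vectors yield NaN entries, flagged in the log.
    """
    names = list(vectors)
    arrays = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
    lengths = {len(v) for v in arrays.values()}
    if len(lengths) != 1 or lengths.pop() < 3:
        raise ValueError("vectors must share a length >= 3")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = arrays[a], arrays[b]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("summarize_correlations: zero variance in "
                               "%s/%s pair", a, b)
                rows.append({"pair": f"{a} ~ {b}", "pearson": np.nan,
                             "pearson_p": np.nan, "spearman": np.nan,
                             "spearman_p": np.nan})
                continue
            pr = stats.pearsonr(x, y)
            sr = stats.spearmanr(x, y)
            rows.append({
                "pair": f"{a} ~ {b}",
                "pearson": float(pr.statistic), "pearson_p": float(pr.pvalue),
                "spearman": float(sr.statistic),
                "spearman_p": float(sr.pvalue),
            })
    return pd.DataFrame(rows)
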
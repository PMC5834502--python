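"""End-to-end pipeline: simulate -> extract -> analyze -> report.

``PipelineConfig`` is a single validated JSON-serializable document holding
every tunable of the three stages; ``run_pipeline`` executes them in order,
writes the CSV/JSON products and stamps each with a provenance block
(config hash, seed, package version).  Identical config implies identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from . import __version__
from .cohort import Cohort, CohortConfig, synthesize_cohort
from .extraction import ExtractionSettings, OpticalConstants, extract_subject
from .stats import (delta_spectrum, filter_subjects, minute_average_alpha,
                    pearson_correlation, plt_stratified_shift, unpaired_ttest)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class AnalysisSettings(BaseModel):
    """Filters, bins, band and test frequencies of the statistical stage."""

    rbc_filter: tuple[float, float] = (4.0, 5.0)
    plt_filter: tuple[float, float] = (100.0, 300.0)
    plt_bins: tuple[tuple[float, float], ...] = ((100.0, 200.0), (200.0, 300.0))
    band_thz: tuple[float, float] = (0.13, 1.02)
    test_freqs_thz: tuple[float, ...] = (0.2, 0.27, 0.34, 0.75, 0.82, 0.885)
    compare_groups: tuple[str, ...] = ("early_coagulated",)
    baseline_group: str = "uncoagulated"

    @model_validator(mode="after")
    def _check(self) -> "AnalysisSettings":
        if self.rbc_filter[0] >= self.rbc_filter[1] or self.plt_filter[0] >= self.plt_filter[1]:
            raise ValueError("filter ranges must be well ordered")
        return self


class PipelineConfig(BaseModel):
    cohort: CohortConfig = CohortConfig()
    extraction: ExtractionSettings = ExtractionSettings()
    analysis: AnalysisSettings = AnalysisSettings()
    seed: int = 0
    out_dir: str = "results/pipeline"
    log_level: str = "INFO"


def config_hash(config: PipelineConfig) -> str:
    """sha256 of the canonical JSON serialization of the config."""
    doc = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


def config_schema() -> dict:
    """The published JSON schema of the pipeline configuration."""
    return PipelineConfig.model_json_schema()


@dataclass
class CohortSpectra:
    """Extraction products for a whole cohort, row-aligned with metadata."""

    metadata: pd.DataFrame
    freqs_thz: np.ndarray
    alpha: np.ndarray   # (n_subjects, n_freqs)
    n: np.ndarray
    kappa: np.ndarray
    constants: list[OpticalConstants]


def extract_cohort(cohort: Cohort, settings: ExtractionSettings | None = None) -> CohortSpectra:
    """Run the minute-average + inversion for every subject of a cohort."""
    settings = settings or ExtractionSettings()
    constants = []
    for record in cohort.records:
        tr = cohort.traces[record.subject_id]
        constants.append(extract_subject(tr.reference, tr.sample,
                                         cohort.config.chamber, settings))
    if not constants:
        raise StageError("extract", "cohort is empty")
    freqs = constants[0].freqs_thz
    return CohortSpectra(
        metadata=cohort.metadata(),
        freqs_thz=freqs,
        alpha=np.vstack([c.alpha_cm1 for c in constants]),
        n=np.vstack([c.n for c in constants]),
        kappa=np.vstack([c.kappa for c in constants]),
        constants=constants,
    )


def group_mean_alpha(spectra: CohortSpectra, group: str) -> np.ndarray:
    sel = (spectra.metadata["group"] == group).to_numpy()
    if not sel.any():
        raise StageError("analyze", f"group '{group}' is empty")
    return minute_average_alpha(spectra.alpha[sel])


def _nearest(freqs: np.ndarray, target: float) -> int:
    return int(np.argmin(np.abs(freqs - target)))


def analyze_cohort(spectra: CohortSpectra, analysis: AnalysisSettings) -> dict:
    """Group comparisons, correlations and change spectra for one cohort."""
    meta = spectra.metadata
    baseline_sel = (meta["group"] == analysis.baseline_group).to_numpy()
    if not baseline_sel.any():
        raise StageError("analyze", f"group '{analysis.baseline_group}' is empty")
    alpha_blood = minute_average_alpha(spectra.alpha[baseline_sel])

    comparisons = []
    deltas = {}
    stratified = {}
    for group in analysis.compare_groups:
        sel = (meta["group"] == group).to_numpy()
        if not sel.any():
            raise StageError("analyze", f"group '{group}' is empty")
        for f in analysis.test_freqs_thz:
            i = _nearest(spectra.freqs_thz, f)
            cmp = unpaired_ttest(spectra.alpha[sel, i], spectra.alpha[baseline_sel, i],
                                 freq_thz=float(spectra.freqs_thz[i]))
            comparisons.append((group, cmp))
        deltas[group] = delta_spectrum(
            minute_average_alpha(spectra.alpha[sel]), alpha_blood,
            spectra.freqs_thz, band=analysis.band_thz,
            n_state=int(sel.sum()), n_blood=int(baseline_sel.sum()))

        filt = filter_subjects(meta[sel], analysis.rbc_filter, analysis.plt_filter)
        if len(filt) >= 3:
            rows = meta.index.get_indexer(filt.index)
            sub_alpha = spectra.alpha[rows]
            stratified[group] = plt_stratified_shift(
                filt, sub_alpha, spectra.freqs_thz, alpha_blood,
                bins=analysis.plt_bins, band=analysis.band_thz)

    correlations = []
    i270 = _nearest(spectra.freqs_thz, 0.27)
    for group in (analysis.baseline_group, *analysis.compare_groups):
        sel = (meta["group"] == group).to_numpy()
        if sel.sum() >= 3:
            correlations.append((group, "rbc_M_per_uL", pearson_correlation(
                spectra.alpha[sel, i270], meta.loc[sel, "rbc_M_per_uL"],
                name="rbc_M_per_uL", freq_thz=float(spectra.freqs_thz[i270]))))
        filt = filter_subjects(meta[sel], analysis.rbc_filter, analysis.plt_filter)
        if len(filt) >= 3:
            rows = meta.index.get_indexer(filt.index)
            correlations.append((group, "plt_K_per_uL", pearson_correlation(
                spectra.alpha[rows, i270], filt["plt_K_per_uL"],
                name="plt_K_per_uL", freq_thz=float(spectra.freqs_thz[i270]))))
    return {"comparisons": comparisons, "correlations": correlations,
            "deltas": deltas, "stratified": stratified,
            "alpha_blood": alpha_blood}


def comparisons_frame(comparisons) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": g, "freq_THz": c.freq_thz, "mean_state": c.mean_a,
        "mean_baseline": c.mean_b, "t": c.t_statistic, "p": c.p_value,
        "ci_low": c.ci_low, "ci_high": c.ci_high, "n_state": c.n_a,
        "n_baseline": c.n_b, "stars": c.stars,
    } for g, c in comparisons])


def correlations_frame(correlations) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": g, "covariate": name, "freq_THz": c.freq_thz, "r": c.r,
        "p": c.p_value, "n": c.n, "significant": c.significant,
    } for g, name, c in correlations])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> extract -> analyze and write all products."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    provenance = {"config_sha256": chash, "seed": config.seed,
                  "thzcoag_version": __version__}

    try:
        cohort = synthesize_cohort(config.cohort, config.seed)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc
    if not cohort.records:
        raise StageError("simulate", "no subjects configured")
    log.info("simulated %d subjects", len(cohort.records))

    from .io import write_metadata_csv, write_spectra_csv
    write_metadata_csv(out / "cohort_metadata.csv", cohort.metadata())

    try:
        spectra = extract_cohort(cohort, config.extraction)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("extract", str(exc)) from exc
    for record, constants in zip(cohort.records, spectra.constants):
        write_spectra_csv(out / f"spectra_{record.subject_id}.csv", constants)

    results = analyze_cohort(spectra, config.analysis)
    comparisons_frame(results["comparisons"]).to_csv(
        out / "comparisons.csv", index=False, float_format="%.8g")
    correlations_frame(results["correlations"]).to_csv(
        out / "correlations.csv", index=False, float_format="%.8g")
    delta_rows = []
    for group, d in results["deltas"].items():
        for f, v in zip(d.freqs_thz, d.delta_over_alpha):
            delta_rows.append({"group": group, "freq_THz": f, "delta_over_alpha": v})
    pd.DataFrame(delta_rows).to_csv(out / "delta_spectra.csv", index=False,
                                    float_format="%.8g")

    sizes = {g: int((spectra.metadata["group"] == g).sum())
             for g in spectra.metadata["group"].unique()}
    summary = {
        "provenance": provenance,
        "n_total": int(len(spectra.metadata)),
        "group_sizes": sizes,
        "transparency_freq_thz": {
            g: d.transparency_freq_thz for g, d in results["deltas"].items()},
        "plt_stratified": {
            g: {"shift_thz": s["shift_thz"],
                "bin_transparency_thz": [
                    b[2].transparency_freq_thz if b[2] is not None else None
                    for b in s["bins"]]}
            for g, s in results["stratified"].items()},
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
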
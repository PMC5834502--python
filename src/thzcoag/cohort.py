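"""Synthetic cohorts: hematology covariates, coagulation effect, traces.

The generator emulates an ex-vivo blood measurement campaign: each subject
contributes a reference minute (empty chamber) and a sample minute
(blood-filled chamber), 120 waveforms per arm, plus a hematology panel
(RBC, WBC, MCH, MCHC, PLT) and a group label.

Optical model of the liquid
---------------------------
The baseline is double-Debye water.  For uncoagulated blood the extinction
coefficient is scaled linearly in the RBC count,

    kappa(f) = kappa_water(f) * (1 + rbc_coeff * (RBC - rbc_ref)),

with no PLT dependence.  After the platelet-activated coagulation cascade
the RBC dependence disappears and the absorption is reshaped by a linear
normalized change,

    kappa(f) = kappa_water(f) * (1 + delta_slope * (f - f_t(PLT))),

whose zero crossing f_t — the transparency frequency — red-shifts linearly
with platelet count.  The thrombus state adds a small blue shift to f_t.
Below f_t absorption decreases ("THz defect"), above it increases
("THz excess").  Between-subject variability is a log-normal multiplicative
scale on kappa.  The real part n(f) is kept at the water value in all
states: the headline phenomenology lives in the absorption constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from . import instrument as _inst
from .chamber import ChamberGeometry, chamber_transfer
from .instrument import Arm, InstrumentModel, TimeTrace
from .water import WATER, DoubleDebyeModel, complex_index

GROUPS = ("uncoagulated", "early_coagulated", "thrombus")

METADATA_COLUMNS = [
    "subject_id", "group", "rbc_M_per_uL", "wbc_K_per_uL", "mch_pg",
    "mchc_g_per_dL", "plt_K_per_uL", "clotting_time_min",
]


class CoagulationEffect(BaseModel):
    """Linear normalized-absorption-change model of coagulated blood.

    ``transparency_freq_thz`` is the zero crossing of delta-alpha/alpha at
    the reference platelet count ``plt_ref``; it shifts by
    ``plt_slope_thz_per_50`` for every 50 K/uL of platelets (negative =
    red shift).  ``delta_slope_per_thz`` is the slope of delta-alpha/alpha
    versus frequency; ``thrombus_blue_shift_thz`` is the small extra shift
    of the late-clot state.
    """

    transparency_freq_thz: float = 0.68
    plt_ref: float = 196.5
    plt_slope_thz_per_50: float = -0.5
    delta_slope_per_thz: float = 0.13
    thrombus_blue_shift_thz: float = 0.05

    def transparency_frequency(self, plt, group: str = "early_coagulated"):
        """f_t(PLT), linear in platelet count; thrombus adds the blue shift."""
        f_t = self.transparency_freq_thz + self.plt_slope_thz_per_50 * (np.asarray(plt, dtype=float) - self.plt_ref) / 50.0
        if group == "thrombus":
            f_t = f_t + self.thrombus_blue_shift_thz
        return f_t


class CovariateModel(BaseModel):
    """Truncated-normal marginal for one hematology covariate."""

    mean: float
    sd: float
    low: float
    high: float

    @model_validator(mode="after")
    def _check(self) -> "CovariateModel":
        if self.sd <= 0 or not (self.low < self.high):
            raise ValueError("invalid covariate model")
        return self

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(size)
        filled = 0
        while filled < size:
            draw = rng.normal(self.mean, self.sd, size - filled)
            keep = draw[(draw >= self.low) & (draw <= self.high)]
            out[filled:filled + keep.size] = keep
            filled += keep.size
        return out


@dataclass
class SubjectRecord:
    """Hematology panel, group label and clotting time for one subject."""

    subject_id: str
    group: str
    rbc: float            # M/uL
    wbc: float            # K/uL
    mch: float            # pg
    mchc: float           # g/dL
    plt: float            # K/uL
    clotting_time_min: Optional[float] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("rbc", "wbc", "mch", "mchc", "plt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.clotting_time_min is not None and not (8.0 <= self.clotting_time_min <= 21.0):
            raise ValueError("clotting time must lie in [8, 21] min")


class CohortConfig(BaseModel):
    """Generator settings: group sizes, covariates, physics, instrument."""

    n_uncoagulated: int = 28
    n_early_coagulated: int = 29
    n_thrombus: int = 0

    rbc: CovariateModel = CovariateModel(mean=4.5, sd=0.5, low=3.0, high=6.0)
    wbc: CovariateModel = CovariateModel(mean=7.0, sd=1.8, low=2.0, high=15.0)
    mch: CovariateModel = CovariateModel(mean=30.0, sd=2.0, low=22.0, high=38.0)
    mchc: CovariateModel = CovariateModel(mean=34.0, sd=1.2, low=28.0, high=38.0)
    plt: CovariateModel = CovariateModel(mean=196.5, sd=31.0, low=100.0, high=400.0)

    rbc_coeff: float = 0.026       # fractional kappa change per M/uL of RBC
    rbc_ref: float = 4.5           # M/uL at which the RBC factor is 1
    subject_sigma: float = 0.03    # log-normal sd of the per-subject kappa scale
    clotting_time_range_min: tuple[float, float] = (8.0, 21.0)
    heparin_control: bool = False  # no-op: heparin has no THz effect

    water: DoubleDebyeModel = WATER
    effect: CoagulationEffect = CoagulationEffect()
    chamber: ChamberGeometry = ChamberGeometry()
    instrument: InstrumentModel = InstrumentModel()
    include_echo: bool = False

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        for name in ("n_uncoagulated", "n_early_coagulated", "n_thrombus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.subject_sigma < 0:
            raise ValueError("subject_sigma must be >= 0")
        lo, hi = self.clotting_time_range_min
        if not (8.0 <= lo <= hi <= 21.0):
            raise ValueError("clotting time range must lie within [8, 21] min")
        return self

    def group_sizes(self) -> dict[str, int]:
        return {
            "uncoagulated": self.n_uncoagulated,
            "early_coagulated": self.n_early_coagulated,
            "thrombus": self.n_thrombus,
        }


def blood_index(subject: SubjectRecord, freq_thz, water: DoubleDebyeModel,
                effect: CoagulationEffect, rbc_coeff: float, rbc_ref: float = 4.5):
    """(n, kappa) of the subject's blood at the given frequencies.

    Deterministic given the subject record; the per-subject random scale is
    applied by the cohort synthesizer, not here.
    """
    n_w, k_w = complex_index(freq_thz, water)
    if subject.group == "uncoagulated":
        factor = 1.0 + rbc_coeff * (subject.rbc - rbc_ref)
        kappa = k_w * factor
    else:
        f_t = effect.transparency_frequency(subject.plt, subject.group)
        kappa = k_w * (1.0 + effect.delta_slope_per_thz * (np.asarray(freq_thz, dtype=float) - f_t))
    if np.any(kappa <= 0):
        raise ValueError("parameterization yields non-positive kappa in the band")
    return n_w, kappa


@dataclass
class SubjectTraces:
    reference: list[TimeTrace]
    sample: list[TimeTrace]


@dataclass
class Cohort:
    """A synthesized cohort: records, latent kappa scales, raw traces."""

    records: list[SubjectRecord]
    kappa_scales: dict[str, float]
    traces: dict[str, SubjectTraces]
    config: CohortConfig
    seed: int

    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "rbc_M_per_uL": r.rbc,
                "wbc_K_per_uL": r.wbc,
                "mch_pg": r.mch,
                "mchc_g_per_dL": r.mchc,
                "plt_K_per_uL": r.plt,
                "clotting_time_min": r.clotting_time_min,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def _draw_records(config: CohortConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    records: list[SubjectRecord] = []
    idx = 0
    for group, size in config.group_sizes().items():
        if size == 0:
            continue
        cov = {name: getattr(config, name).sample(size, rng)
               for name in ("rbc", "wbc", "mch", "mchc", "plt")}
        lo, hi = config.clotting_time_range_min
        for j in range(size):
            clot = None if group == "uncoagulated" else float(rng.uniform(lo, hi))
            records.append(SubjectRecord(
                subject_id=f"S{idx:03d}", group=group,
                rbc=float(cov["rbc"][j]), wbc=float(cov["wbc"][j]),
                mch=float(cov["mch"][j]), mchc=float(cov["mchc"][j]),
                plt=float(cov["plt"][j]), clotting_time_min=clot,
            ))
            idx += 1
    return records


def subject_optics(record: SubjectRecord, scale: float, freq_thz, config: CohortConfig):
    """(n, kappa) on a grid including the subject's latent scale on kappa."""
    n, kappa = blood_index(record, freq_thz, config.water, config.effect,
                           config.rbc_coeff, config.rbc_ref)
    return n, kappa * scale


def subject_alpha(record: SubjectRecord, scale: float, freq_thz, config: CohortConfig):
    """Ground-truth absorption constant (cm^-1) of the subject's blood."""
    from .units import kappa_to_alpha_cm1

    _, kappa = subject_optics(record, scale, freq_thz, config)
    return kappa_to_alpha_cm1(freq_thz, kappa)


def synthesize_subject_traces(record: SubjectRecord, scale: float,
                              config: CohortConfig, rng: np.random.Generator) -> SubjectTraces:
    """Reference and sample minute (traces_per_minute waveforms each)."""
    inst = config.instrument
    freqs = _inst.rfft_freqs_thz(inst)
    src = _inst.source_spectrum(freqs, inst)
    # frequency 0 has zero source amplitude; evaluate optics on positive bins
    pos = freqs > 0
    nbar = np.ones_like(freqs, dtype=complex)
    n, kappa = subject_optics(record, scale, freqs[pos], config)
    nbar[pos] = n + 1j * kappa

    e_ref = src * chamber_transfer(freqs, config.chamber, filled=False,
                                   include_echo=config.include_echo)
    e_samp = src * chamber_transfer(freqs, config.chamber, nbar, filled=True,
                                    include_echo=config.include_echo)
    ref_clean = _inst.trace_from_spectrum(e_ref, inst, Arm.reference.value)
    samp_clean = _inst.trace_from_spectrum(e_samp, inst, Arm.sample.value)
    sigma = _inst.noise_sigma(e_ref, inst)
    return SubjectTraces(
        reference=_inst.noisy_copies(ref_clean, sigma, inst.traces_per_minute, rng),
        sample=_inst.noisy_copies(samp_clean, sigma, inst.traces_per_minute, rng),
    )


def synthesize_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Draw a full cohort: metadata plus both-arm trace sets per subject.

    One seed governs everything; covariates come from the root stream and
    each subject's noise from a deterministically spawned substream, so the
    output is bit-reproducible and per-subject streams are independent.
    """
    root = np.random.SeedSequence(seed)
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    records = _draw_records(config, cov_rng)
    scales = {
        r.subject_id: float(np.exp(cov_rng.normal(0.0, config.subject_sigma)))
        if config.subject_sigma > 0 else 1.0
        for r in records
    }
    traces = {}
    for child, record in zip(root.spawn(len(records) + 1)[1:], records):
        rng = np.random.default_rng(child)
        traces[record.subject_id] = synthesize_subject_traces(
            record, scales[record.subject_id], config, rng)
    return Cohort(records=records, kappa_scales=scales, traces=traces,
                  config=config, seed=seed)


def synthesize_fills(record: SubjectRecord, scale: float, config: CohortConfig,
                     seed: int, n_fills: int = 3) -> list[SubjectTraces]:
    """Repeated chamber fills for one subject (independent noise per fill).

    Emulates the assemble/inject/disassemble repeatability test; the
    liquid optics are identical across fills, only the acquisition noise
    differs.
    """
    root = np.random.SeedSequence(seed)
    return [
        synthesize_subject_traces(record, scale, config, np.random.default_rng(child))
        for child in root.spawn(n_fills)
    ]


def stratified_early_cohort(config: CohortConfig, seed: int, per_bin: int = 9,
                            bins=((100.0, 200.0), (200.0, 300.0)),
                            rbc_range=(4.0, 5.0), max_batches: int = 40) -> Cohort:
    """Early-coagulated cohort guaranteeing ``per_bin`` subjects per PLT bin.

    Subjects are drawn in batches until each platelet bin (after the RBC
    window filter) holds at least ``per_bin`` subjects; the first
    ``per_bin`` per bin are kept.  The uncoagulated control group of the
    base config is generated alongside as the alpha_blood baseline.
    """
    base = config.model_copy(update={"n_early_coagulated": 0, "n_thrombus": 0})
    control = synthesize_cohort(base, seed)

    batch_cfg = config.model_copy(update={
        "n_uncoagulated": 0, "n_thrombus": 0, "n_early_coagulated": 16})
    kept: dict[int, list] = {i: [] for i in range(len(bins))}
    batch_root = np.random.SeedSequence([seed, 1])
    for batch_seed in batch_root.generate_state(max_batches):
        batch = synthesize_cohort(batch_cfg, int(batch_seed) % (2**31 - 1))
        for rec in batch.records:
            if not (rbc_range[0] < rec.rbc <= rbc_range[1]):
                continue
            for i, (lo, hi) in enumerate(bins):
                edge_ok = rec.plt <= hi if i == len(bins) - 1 else rec.plt < hi
                if lo <= rec.plt and edge_ok and len(kept[i]) < per_bin:
                    kept[i].append((rec, batch.kappa_scales[rec.subject_id],
                                    batch.traces[rec.subject_id]))
        if all(len(v) >= per_bin for v in kept.values()):
            break
    else:
        raise RuntimeError("could not fill all PLT bins; widen max_batches")

    records = list(control.records)
    scales = dict(control.kappa_scales)
    traces = dict(control.traces)
    idx = len(records)
    for i in range(len(bins)):
        for rec, scale, tr in kept[i]:
            new_id = f"E{idx:03d}"
            records.append(SubjectRecord(new_id, rec.group, rec.rbc, rec.wbc,
                                         rec.mch, rec.mchc, rec.plt,
                                         rec.clotting_time_min))
            scales[new_id] = scale
            traces[new_id] = tr
            idx += 1
    return Cohort(records=records, kappa_scales=scales, traces=traces,
                  config=config, seed=seed)
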
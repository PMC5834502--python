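"""File dialects: two-column traces, CSV metadata/spectra, JSON config."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import METADATA_COLUMNS
from .extraction import OpticalConstants
from .instrument import InstrumentModel, TimeTrace

TRACE_HEADER = "time_ps field_au"


def write_trace(path, trace: TimeTrace) -> None:
    """Two-column delimited trace file (time_ps, field_au)."""
    np.savetxt(path, np.column_stack([trace.times_ps, trace.field]),
               fmt="%.10e", header=f"{TRACE_HEADER} arm={trace.arm} "
               f"acquisition={trace.acquisition_index} averaged={trace.n_averaged}")


def read_trace(path, arm: str = "reference", acquisition_index: int = 0) -> TimeTrace:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time_ps, field_au)")
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.split():
            if token.startswith("arm="):
                arm = token.split("=", 1)[1]
            elif token.startswith("acquisition="):
                acquisition_index = int(token.split("=", 1)[1])
    return TimeTrace(data[:, 0], data[:, 1], arm=arm, acquisition_index=acquisition_index)


def write_trace_sidecar(path, instrument: InstrumentModel, seed: int) -> None:
    """JSON sidecar recording the acquisition settings and the seed."""
    doc = {"instrument": instrument.model_dump(), "seed": seed}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_trace_sidecar(path) -> tuple[InstrumentModel, int]:
    doc = json.loads(Path(path).read_text())
    return InstrumentModel.model_validate(doc["instrument"]), int(doc["seed"])


def write_metadata_csv(path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, index=False, columns=METADATA_COLUMNS, float_format="%.6g")


def read_metadata_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spectra_csv(path, constants: OpticalConstants) -> None:
    frame = pd.DataFrame({
        "freq_THz": constants.freqs_thz,
        "n": constants.n,
        "kappa": constants.kappa,
        "alpha_cm1": constants.alpha_cm1,
        "converged": constants.converged.astype(bool),
        "iterations": constants.iterations,
    })
    frame.to_csv(path, index=False, float_format="%.8g")


def read_spectra_csv(path) -> OpticalConstants:
    frame = pd.read_csv(path)
    return OpticalConstants(
        freqs_thz=frame["freq_THz"].to_numpy(),
        n=frame["n"].to_numpy(),
        kappa=frame["kappa"].to_numpy(),
        alpha_cm1=frame["alpha_cm1"].to_numpy(),
        converged=frame["converged"].to_numpy(dtype=bool),
        iterations=frame["iterations"].to_numpy(dtype=int),
    )
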
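"""Synthetic concentration-time datasets for end-to-end testing.

The generator emulates the structure of digitized study-mean oral PK data:
a single-dose profile sampled at irregular timepoints over 0-48 h, with a
per-timepoint mean and SD for both the parent drug and its metabolite.
Observation noise is log-normal around the model value (log-SD equal to the
analyte's CV) so the generator is self-consistent with the package's
log-normal likelihood, and the published SD column is reconstructed as
CV x mean.  An outlier record can be injected to exercise the exclusion
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import COLUMNS, ConcentrationDataset, dataset_from_frame
from .model import DoseRegimen, PKParameters, solve_profile
from .reference import REFERENCE_MEDIAN_PARAMS

__all__ = ["DEFAULT_SAMPLE_TIMES", "SyntheticDesign", "generate_dataset", "inject_outlier"]

#: Irregular single-dose sampling design (h), dense around absorption.
DEFAULT_SAMPLE_TIMES = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0)


@dataclass
class SyntheticDesign:
    """Ground truth plus observation design for one synthetic study.

    Defaults: reference-median truth, 25 mg single oral dose, twelve
    sampling times over 48 h, observation CV 0.25 (parent) / 0.30
    (metabolite).
    """

    truth: PKParameters = REFERENCE_MEDIAN_PARAMS
    dose: float = 25.0
    sample_times: tuple = DEFAULT_SAMPLE_TIMES
    cv_parent: float = 0.25
    cv_metabolite: float = 0.30
    seed: int = 0

    def __post_init__(self):
        times = np.asarray(self.sample_times, dtype=float)
        if times.size == 0 or np.any(times <= 0) or np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be positive and strictly increasing")
        if self.cv_parent <= 0 or self.cv_metabolite <= 0:
            raise ValueError("observation CVs must be > 0")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")

    def cv(self, analyte: str) -> float:
        return self.cv_parent if analyte == "parent" else self.cv_metabolite


def _model_profile(design: SyntheticDesign, times: np.ndarray):
    regimen = DoseRegimen(dose=design.dose, interval=24.0, n_doses=1)
    return solve_profile(design.truth, regimen, grid=times)


def generate_dataset(design: SyntheticDesign, seed: int | None = None) -> ConcentrationDataset:
    """Simulate the truth profile and add log-normal observation noise.

    mean_i = model_i * exp(cv * z_i), sd_i = cv * mean_i; the same seed
    gives the identical dataset, and cv -> 0 recovers the model exactly.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    times = np.asarray(design.sample_times, dtype=float)
    prof = _model_profile(design, times)
    frames = []
    for analyte in ("parent", "metabolite"):
        cv = design.cv(analyte)
        model = prof.concentration(analyte)
        mean = model * np.exp(cv * rng.standard_normal(times.size))
        frames.append(
            pd.DataFrame(
                {
                    "time_h": times,
                    "mean_ng_ml": mean,
                    "sd_ng_ml": cv * mean,
                    "analyte": analyte,
                }
            )
        )
    return dataset_from_frame(pd.concat(frames, ignore_index=True))


def inject_outlier(
    ds: ConcentrationDataset,
    design: SyntheticDesign,
    analyte: str,
    time: float,
    multiplier: float,
) -> ConcentrationDataset:
    """Append a record whose mean is ``multiplier`` times the model value.

    Errors if a record for (analyte, time) already exists; multiplier 1
    appends a consistent (non-outlying) point.
    """
    exists = (ds.records["analyte"] == analyte) & np.isclose(ds.records["time_h"], time)
    if exists.any():
        raise ValueError(f"record already present at ({analyte}, {time} h)")
    prof = _model_profile(design, np.asarray([time], dtype=float))
    mean = float(prof.concentration(analyte)[0]) * multiplier
    cv = design.cv(analyte)
    row = pd.DataFrame(
        {
            "time_h": [time],
            "mean_ng_ml": [mean],
            "sd_ng_ml": [cv * mean],
            "analyte": [analyte],
        }
    )
    out = dataset_from_frame(pd.concat([ds.records[list(COLUMNS)], row], ignore_index=True))
    out.exclusions = ds.exclusions.copy()
    return out
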
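"""Cohort-level cleaning and predictor assembly.

Patients with any raw predictor more than 3 scaled median absolute
deviations from the cohort median are excluded.  The remaining 18
predictors — age-normalized ROM, ROM CV and speed to peak for each of the
six movements — are z-scored and paired with the training target, the
signed NFHAS change from baseline to follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .kinematics import MovementSummary
from .nfhas import MOVEMENTS

__all__ = [
    "AssessmentRecord",
    "ZScoreParams",
    "FEATURE_NAMES",
    "flag_outliers",
    "flag_outlier_patients",
    "zscore",
    "build_features",
    "build_target",
    "records_to_frame",
    "frame_to_records",
]

#: Gaussian-consistency constant: scaled MAD = 1.4826 * MAD estimates sigma.
MAD_SCALE = 1.4826

#: sigma estimate from the interquartile range of a normal distribution.
IQR_SCALE = 1.349

#: Fixed predictor order: blocks of normalized ROM, CV, speed; movements
#: F, E, Llb, Rlb, Lrt, Rrt within each block.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{block}_{m}"
    for block in ("rom_normalized", "cv", "speed_to_peak")
    for m in MOVEMENTS
)


class DegenerateFeatureError(ValueError):
    """A feature with zero variance cannot be z-scored."""


class IncompleteRecordError(ValueError):
    """An assessment is missing one of the six movements."""


class PairingError(ValueError):
    """Baseline and follow-up records belong to different patients."""


@dataclass(frozen=True)
class AssessmentRecord:
    """One patient at one time point: six movement summaries + demographics."""

    patient_id: str
    time_point: str  # "baseline" | "followup"
    movements: dict[str, MovementSummary]
    age: float
    sex: str  # "F" | "M"
    height: float  # m
    mass: float  # kg

    def __post_init__(self) -> None:
        if self.time_point not in ("baseline", "followup"):
            raise ValueError("time_point must be 'baseline' or 'followup'")
        if set(self.movements) != set(MOVEMENTS):
            missing = set(MOVEMENTS) - set(self.movements)
            raise IncompleteRecordError(
                f"record {self.patient_id} missing movements: {sorted(missing)}"
            )

    def raw_features(self) -> np.ndarray:
        """The 18 raw (not yet z-scored) predictors in canonical order."""
        vals = []
        for block in ("rom_normalized", "cv", "speed_to_peak"):
            for m in MOVEMENTS:
                vals.append(getattr(self.movements[m], block))
        return np.array(vals, dtype=float)

    def normalized_roms(self) -> np.ndarray:
        return np.array(
            [self.movements[m].rom_normalized for m in MOVEMENTS], dtype=float
        )


@dataclass(frozen=True)
class ZScoreParams:
    """Per-feature mean and sample standard deviation, reusable on held-out data."""

    mean: np.ndarray
    sd: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def flag_outliers(values: Sequence[float]) -> np.ndarray:
    """Boolean mask of values > 3 scaled MADs from the median.

    Scaled MAD is 1.4826 * median(|x - median|).  When the MAD is zero the
    rule degenerates, so a value is then flagged only if it deviates from
    the median at all AND a secondary scaled-IQR check (3 * IQR / 1.349)
    also flags it; constant vectors therefore produce no flags while a
    wild value among near-constants still does.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("flag_outliers requires at least one value")
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    if mad > 0:
        return dev > 3.0 * MAD_SCALE * mad
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr > 0:
        return (dev > 0) & (dev > 3.0 * iqr / IQR_SCALE)
    return dev > 0


def flag_outlier_patients(records: Sequence[AssessmentRecord]) -> np.ndarray:
    """Mask of patients with any of the 18 raw predictors flagged cohort-wide."""
    matrix = np.vstack([r.raw_features() for r in records])
    flagged = np.zeros(len(records), dtype=bool)
    for j in range(matrix.shape[1]):
        flagged |= flag_outliers(matrix[:, j])
    return flagged


def zscore(
    values: Sequence[float], name: str = "feature"
) -> tuple[np.ndarray, float, float]:
    """Standardize to mean 0, sample sd 1; returns (z, mean, sd) for reuse."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-scoring requires at least two values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateFeatureError(f"feature {name!r} has zero variance")
    return (x - mean) / sd, mean, sd


def build_features(
    cohort: Sequence[AssessmentRecord],
    params: ZScoreParams | None = None,
) -> tuple[pd.DataFrame, ZScoreParams]:
    """Assemble the 18 z-scored predictors per patient.

    With ``params`` given (fitted on a training split), the stored means
    and sds are applied; otherwise they are estimated on this cohort.
    Returns a DataFrame indexed by patient id with columns FEATURE_NAMES.
    """
    raw = np.vstack([r.raw_features() for r in cohort])
    ids = [r.patient_id for r in cohort]
    if params is None:
        means = np.empty(raw.shape[1])
        sds = np.empty(raw.shape[1])
        z = np.empty_like(raw)
        for j, name in enumerate(FEATURE_NAMES):
            z[:, j], means[j], sds[j] = zscore(raw[:, j], name)
        params = ZScoreParams(mean=means, sd=sds)
    else:
        z = params.transform(raw)
    if not np.isfinite(z).all():
        raise ValueError("non-finite feature values after z-scoring")
    return pd.DataFrame(z, index=pd.Index(ids, name="patient_id"), columns=list(FEATURE_NAMES)), params


def build_target(
    baseline: AssessmentRecord,
    followup: AssessmentRecord,
    nfhas_fn: Callable[[Sequence[float]], float],
) -> float:
    """Training target: NFHAS(follow-up) - NFHAS(baseline), in NFHAS points."""
    if baseline.patient_id != followup.patient_id:
        raise PairingError(
            f"cannot pair {baseline.patient_id} with {followup.patient_id}"
        )
    return float(
        nfhas_fn(followup.normalized_roms()) - nfhas_fn(baseline.normalized_roms())
    )


# ---------------------------------------------------------------------------
# Tabular round trip (one row per patient, 6x4 movement columns + demographics)

def records_to_frame(records: Iterable[AssessmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "time_point": r.time_point,
            "age": r.age,
            "sex": r.sex,
            "height_m": r.height,
            "mass_kg": r.mass,
        }
        for m in MOVEMENTS:
            s = r.movements[m]
            row[f"{m}_rom_deg"] = s.mean_rom
            row[f"{m}_rom_normalized_pct"] = s.rom_normalized
            row[f"{m}_cv_pct"] = s.cv
            row[f"{m}_speed_deg_s"] = s.speed_to_peak
            row[f"{m}_n_repetitions"] = s.n_repetitions
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[AssessmentRecord]:
    records = []
    for _, row in df.iterrows():
        movements = {
            m: MovementSummary(
                movement=m,
                mean_rom=float(row[f"{m}_rom_deg"]),
                rom_normalized=float(row[f"{m}_rom_normalized_pct"]),
                cv=float(row[f"{m}_cv_pct"]),
                speed_to_peak=float(row[f"{m}_speed_deg_s"]),
                n_repetitions=int(row.get(f"{m}_n_repetitions", 1)),
            )
            for m in MOVEMENTS
        }
        records.append(
            AssessmentRecord(
                patient_id=str(row["patient_id"]),
                time_point=str(row["time_point"]),
                movements=movements,
                age=float(row["age"]),
                sex=str(row["sex"]),
                height=float(row["height_m"]),
                mass=float(row["mass_kg"]),
            )
        )
    return records
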
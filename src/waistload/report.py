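"""Grid sweeps, batch assessment of worker-task tables, and test fixtures.

The sweep is the tabular twin of the model's result curves: one row per
lifting height with RWL, F(RWL), the L5-S1 stress components, and (when a
fixed object mass is given) the comfort score and lifting index at that
mass.  Batch assessment scores a CSV of worker-task rows, flagging rather
than dropping records whose heights fall outside a worker's feasible range.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anthropometry import (AnthropometricProfile, custom_profile,
                            standard_profile, GRAVITY)
from .comfort import assess
from .errors import DomainError, WaistloadError
from .posture_force import valid_height_range
from .rwl import HAND_HEIGHT_CM, rwl_chinese
from .spinal_stress import stress_decomposition

TASK_COLUMNS = ("worker_id", "stature_cm", "body_mass_kg", "object_mass_kg",
                "object_height_cm", "frequency", "duration_class")


@dataclass(frozen=True)
class SweepRow:
    h_cm: float
    rwl_kg: float
    F_at_rwl_N: float
    sigma_N: float
    tau_N: float
    resultant_N: float
    comfort_C_at_mass: float | None = None
    LI_at_mass: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TaskRecord:
    """One worker-task row for batch scoring."""

    worker_id: str
    stature_cm: float
    body_mass_kg: float
    object_mass_kg: float
    object_height_cm: float
    frequency: float = 0.2
    duration_class: str = "<=1h"

    def __post_init__(self):
        for name in ("stature_cm", "body_mass_kg", "object_height_cm"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.object_mass_kg < 0:
            raise DomainError("object_mass_kg must be non-negative")


def sweep(profile: AnthropometricProfile | None = None,
          h_start: float = 34.0, h_stop: float = 72.0, step: float = 1.0,
          fixed_mass_kg: float | None = None,
          mode: str = "published") -> list[SweepRow]:
    """Evaluate RWL, F(RWL) and L5-S1 stresses on an inclusive height grid."""
    profile = profile or standard_profile()
    if step <= 0:
        raise DomainError("step must be positive")
    if h_stop < h_start:
        raise DomainError("inverted grid: h_stop < h_start")
    n = int(round((h_stop - h_start) / step)) + 1
    heights = [h_start + i * step for i in range(n) if h_start + i * step <= h_stop + 1e-9]
    rows = []
    for h in heights:
        rwl_kg = rwl_chinese(h, profile, mode).rwl_kg
        st = stress_decomposition(rwl_kg * GRAVITY, h, profile, mode)
        # F(RWL) recoverable from sigma, but recompute the named quantity
        f_rwl = st.normal_sigma - (profile.upper_body_weight_frac
                                   * profile.weight_force_M
                                   + rwl_kg * GRAVITY) * st.posture.cos_alpha
        comfort_c = li = None
        if fixed_mass_kg is not None:
            a = assess(fixed_mass_kg, h, profile, mode)
            comfort_c, li = a.comfort_C, a.lifting_index_LI
        rows.append(SweepRow(float(h), rwl_kg, f_rwl, st.normal_sigma,
                             st.shear_tau, st.resultant_N, comfort_c, li))
    return rows


def sweep_frame(rows: list[SweepRow]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_dict() for r in rows])
    if df["comfort_C_at_mass"].isna().all():
        df = df.drop(columns=["comfort_C_at_mass", "LI_at_mass"])
    return df


def write_sweep_csv(rows: list[SweepRow], path_or_buf) -> None:
    sweep_frame(rows).to_csv(path_or_buf, index=False)


def read_sweep_csv(path_or_buf) -> list[SweepRow]:
    df = pd.read_csv(path_or_buf)
    out = []
    for _, r in df.iterrows():
        out.append(SweepRow(
            h_cm=float(r["h_cm"]), rwl_kg=float(r["rwl_kg"]),
            F_at_rwl_N=float(r["F_at_rwl_N"]), sigma_N=float(r["sigma_N"]),
            tau_N=float(r["tau_N"]), resultant_N=float(r["resultant_N"]),
            comfort_C_at_mass=(float(r["comfort_C_at_mass"])
                               if "comfort_C_at_mass" in df else None),
            LI_at_mass=(float(r["LI_at_mass"]) if "LI_at_mass" in df else None)))
    return out


def assess_batch(records: list[TaskRecord],
                 mode: str = "published") -> list[dict]:
    """Score each worker-task record; flag (never fabricate) out-of-domain rows."""
    out = []
    for rec in records:
        row = {"worker_id": rec.worker_id,
               "stature_cm": rec.stature_cm,
               "body_mass_kg": rec.body_mass_kg,
               "object_mass_kg": rec.object_mass_kg,
               "object_height_cm": rec.object_height_cm,
               "in_domain": True, "flag": ""}
        try:
            profile = custom_profile(rec.stature_cm, rec.body_mass_kg, mode)
            a = assess(rec.object_mass_kg, rec.object_height_cm, profile, mode)
            st = stress_decomposition(rec.object_mass_kg * GRAVITY,
                                      rec.object_height_cm, profile, mode)
        except WaistloadError as exc:
            row["in_domain"] = False
            row["flag"] = str(exc)
            out.append(row)
            continue
        row.update(rwl_kg=a.rwl_kg, erector_force_N=a.erector_force_F,
                   comfort_C=a.comfort_C, lifting_index_LI=a.lifting_index_LI,
                   sigma_N=st.normal_sigma, tau_N=st.shear_tau,
                   resultant_N=st.resultant_N, category=a.category)
        out.append(row)
    return out


def read_task_csv(path_or_buf) -> list[TaskRecord]:
    """Parse a worker-task CSV (columns: worker_id, stature_cm, body_mass_kg,
    object_mass_kg, object_height_cm[, frequency, duration_class])."""
    try:
        df = pd.read_csv(path_or_buf)
    except Exception as exc:  # pandas raises several parser error types
        raise WaistloadError(f"cannot parse task CSV: {exc}") from exc
    missing = [c for c in TASK_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise WaistloadError(f"task CSV is missing columns: {missing}")
    records = []
    for i, r in df.iterrows():
        try:
            records.append(TaskRecord(
                worker_id=str(r["worker_id"]),
                stature_cm=float(r["stature_cm"]),
                body_mass_kg=float(r["body_mass_kg"]),
                object_mass_kg=float(r["object_mass_kg"]),
                object_height_cm=float(r["object_height_cm"]),
                frequency=float(r.get("frequency", 0.2)),
                duration_class=str(r.get("duration_class", "<=1h"))))
        except (WaistloadError, ValueError) as exc:
            raise WaistloadError(f"task CSV line {i + 2}: {exc}") from exc
    return records


def write_task_csv(records: list[TaskRecord], path_or_buf) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path_or_buf, index=False)


def batch_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def report_json(rows) -> str:
    """Full-precision JSON for a sweep or batch report."""
    payload = [r.to_dict() if hasattr(r, "to_dict") else r for r in rows]
    return json.dumps(payload, indent=2)


def generate_fixture_tasks(seed: int, n: int,
                           mode: str = "published") -> list[TaskRecord]:
    """Deterministic pseudo-random worker-task records for tests.

    Statures in [155, 190] cm, body masses in [50, 95] kg, object heights
    inside each worker's feasible range (capped below the 74 cm hand
    height), object masses in [0, 2] x RWL at that height.
    """
    if n <= 0:
        raise DomainError("n must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        stature = float(np.round(rng.uniform(155, 190), 1))
        mass = float(np.round(rng.uniform(50, 95), 1))
        profile = custom_profile(stature, mass, mode)
        lo, hi = valid_height_range(profile, mode)
        hi = min(hi, HAND_HEIGHT_CM)
        h = float(np.round(rng.uniform(lo + 0.1, hi - 0.5), 1))
        rwl_kg = rwl_chinese(h, profile, mode).rwl_kg
        obj = float(np.round(rng.uniform(0.0, 2.0) * rwl_kg, 2))
        records.append(TaskRecord(worker_id=f"W{i:04d}", stature_cm=stature,
                                  body_mass_kg=mass, object_mass_kg=obj,
                                  object_height_cm=h))
    return records
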
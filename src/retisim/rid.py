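"""Retinol isotope dilution (RID) quantities from model trajectories.

The RID prediction equation is ``TBS (μmol) = FaS · 1/SA_p`` where

* ``SA_p`` — plasma retinol specific activity, fraction of dose per
  μmol: tracer fraction in plasma F(5) over plasma pool size M(5);
* ``Fa`` — fraction of the dose in stores at the sampling time;
* ``S = SA_p / SA_s`` with ``SA_s = Fa / TBS`` the specific activity in
  stores, so the composite coefficient ``FaS = Fa·S`` is algebraically
  ``TBS · SA_p`` — Fa cancels, and with time-matched coefficients the
  equation returns the model's stores exactly, at any time, perturbed
  or not.

Field practice instead pairs a *measured* SA_p with literature
steady-state coefficients ``FaS_ss``; the prediction error under a
perturbation is then the ratio of steady to perturbed SA_p.  Both
coefficient modes are computed here.

"Stores" follow the model-builder membership (hepatocyte + storage +
small extravascular pools; plasma optionally included) so Fa and SA_s
stay consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import Trajectory
from .model_builder import LinkedModel

__all__ = [
    "RIDSeries",
    "sa_p",
    "fraction_in_stores",
    "rid_tbs",
    "fas_timecourse",
    "rid_series",
    "ratio_diagnostics",
    "DEFAULT_SAMPLING_DAY",
]

#: conventional single-sample RID day (SA_p measured 4–5 d after dosing)
DEFAULT_SAMPLING_DAY = 4.0

_F5_FLOOR = 1e-9  # below this the dose has not reached plasma; ratios undefined


@dataclass
class RIDSeries:
    """RID quantities on the trajectory's output grid.

    All arrays align with ``times`` (days since simulation start; the
    dose is given at ``dose_day``).  Undefined points — before the
    tracer reaches plasma — are NaN, not zero.

    ``tbs_pred_tv_coeff`` uses time-variant FaS matched to the same
    model state (validation mode: always equals ``tbs_model``);
    ``tbs_pred_ss_coeff`` uses the reference steady-state FaS with the
    condition's SA_p (field mode: this is where inflammation bites).
    """

    times: np.ndarray
    sa_p: np.ndarray
    fa: np.ndarray
    sa_s: np.ndarray
    s_ratio: np.ndarray
    fas: np.ndarray
    fas_ss: np.ndarray
    tbs_pred_ss_coeff: np.ndarray
    tbs_pred_tv_coeff: np.ndarray
    tbs_model: np.ndarray
    dose_day: float = 0.0

    @property
    def time_since_dose(self) -> np.ndarray:
        return self.times - self.dose_day

    def at_day(self, day: float, *, since_dose: bool = True) -> dict[str, float]:
        """Point readout (exact grid point) ``day`` days after dosing."""
        axis = self.time_since_dose if since_dose else self.times
        k = int(np.argmin(np.abs(axis - day)))
        if abs(axis[k] - day) > 1e-6:
            raise KeyError(f"day {day} not on the output grid")
        return {
            "sa_p": float(self.sa_p[k]),
            "fa": float(self.fa[k]),
            "fas": float(self.fas[k]),
            "fas_ss": float(self.fas_ss[k]),
            "tbs_pred_ss_coeff": float(self.tbs_pred_ss_coeff[k]),
            "tbs_pred_tv_coeff": float(self.tbs_pred_tv_coeff[k]),
            "tbs_model": float(self.tbs_model[k]),
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: (time_d, quantity, value, coefficient_mode)."""
        rows = []
        for name, arr, mode in [
            ("sa_p", self.sa_p, ""),
            ("fa", self.fa, ""),
            ("sa_s", self.sa_s, ""),
            ("s_ratio", self.s_ratio, ""),
            ("fas", self.fas, "time_variant"),
            ("fas", self.fas_ss, "steady"),
            ("tbs_pred", self.tbs_pred_tv_coeff, "time_variant"),
            ("tbs_pred", self.tbs_pred_ss_coeff, "steady"),
            ("tbs_model", self.tbs_model, ""),
        ]:
            rows.append(
                pd.DataFrame(
                    {
                        "time_d": self.times,
                        "quantity": name,
                        "value": arr,
                        "coefficient_mode": mode,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def sa_p(traj: Trajectory, t: float | None = None, *, plasma_pool: float | None = None):
    """Plasma retinol specific activity F(5)/M(5), per μmol.

    For a linked-model trajectory the tracee plasma pool (15) supplies
    the denominator; for a stand-alone tracer trajectory pass the
    (constant, steady-state) ``plasma_pool`` explicitly.  Returns the
    full series, or a scalar when ``t`` is given.

    Raises
    ------
    ZeroDivisionError
        The plasma retinol pool is zero.
    """
    f5 = traj.series(5)
    if 15 in traj.index:
        m5 = traj.series(15)
    elif plasma_pool is not None:
        m5 = np.full_like(f5, float(plasma_pool))
    else:
        raise ValueError("trajectory has no tracee plasma pool; pass plasma_pool")
    if np.any(m5 <= 0):
        raise ZeroDivisionError("plasma retinol pool is zero")
    series = f5 / m5
    if t is None:
        return series
    k = int(np.argmin(np.abs(traj.times - t)))
    return float(series[k])


def fraction_in_stores(traj: Trajectory, stores: Sequence[int]) -> np.ndarray:
    """Fa(t): summed tracer fraction of dose over the store compartments."""
    return sum(traj.series(c) for c in stores)


def rid_tbs(fas, sa_p_value):
    """Apply the RID prediction equation TBS = FaS / SA_p (μmol).

    Accepts scalars or aligned arrays; requires SA_p > 0 and FaS ≥ 0.
    """
    fas_arr = np.asarray(fas, dtype=float)
    sap_arr = np.asarray(sa_p_value, dtype=float)
    if np.any(sap_arr <= 0):
        raise ValueError("SA_p must be positive")
    if np.any(fas_arr < 0):
        raise ValueError("FaS must be nonnegative")
    out = fas_arr / sap_arr
    return float(out) if out.ndim == 0 else out


def fas_timecourse(
    traj: Trajectory, model: LinkedModel, *, _check_tol: float = 1e-10
) -> np.ndarray:
    """Time-variant composite coefficient FaS(t) = Fa(t) · SA_p/SA_s.

    Computed through the definition (Fa, S and SA_s = Fa/TBS evaluated
    separately) and verified against the algebraic identity
    ``FaS = TBS(t) · SA_p(t)``; disagreement beyond ``1e-10`` relative
    signals an implementation fault and raises.  Points where Fa is
    zero are missing (NaN).
    """
    fa = fraction_in_stores(traj, model.tracer_stores)
    tbs = sum(traj.series(c) for c in model.tracee_stores)
    sap = sa_p(traj)
    with np.errstate(invalid="ignore", divide="ignore"):
        sas = np.where(fa > 0, fa / tbs, np.nan)
        s = sap / sas
        fas = fa * s
    direct = tbs * sap
    ok = fa > _F5_FLOOR
    if np.any(ok):
        rel = np.abs(fas[ok] - direct[ok]) / np.maximum(np.abs(direct[ok]), 1e-300)
        if np.nanmax(rel) > _check_tol:
            raise RuntimeError(
                "FaS routes disagree beyond tolerance: "
                f"max relative difference {np.nanmax(rel):.3e}"
            )
    return fas


def rid_series(
    traj: Trajectory,
    reference: Trajectory,
    model: LinkedModel,
    *,
    dose_day: float = 0.0,
) -> RIDSeries:
    """Full RID bookkeeping for a (possibly perturbed) trajectory.

    ``reference`` is the unperturbed steady-state run of the same model
    with the dose at the same day — it supplies ``FaS_ss``.  Both
    trajectories must share the output grid.
    """
    if len(traj.times) != len(reference.times) or not np.allclose(
        traj.times, reference.times
    ):
        raise ValueError("trajectories are on different time grids")
    f5 = traj.series(5)
    f5_ref = reference.series(5)
    valid = (f5 > _F5_FLOOR) & (f5_ref > _F5_FLOOR)

    sap = sa_p(traj)
    fa = fraction_in_stores(traj, model.tracer_stores)
    tbs_model = sum(traj.series(c) for c in model.tracee_stores)
    fas = fas_timecourse(traj, model)
    fas_ss = fas_timecourse(reference, model)

    with np.errstate(invalid="ignore", divide="ignore"):
        sas = np.where(valid & (fa > 0), fa / tbs_model, np.nan)
        s = np.where(valid, sap / sas, np.nan)
        tbs_tv = np.where(valid, fas / sap, np.nan)
        tbs_ss = np.where(valid, fas_ss / sap, np.nan)
    return RIDSeries(
        times=traj.times.copy(),
        sa_p=np.where(valid, sap, np.nan),
        fa=fa,
        sa_s=sas,
        s_ratio=s,
        fas=np.where(valid, fas, np.nan),
        fas_ss=np.where(valid, fas_ss, np.nan),
        tbs_pred_ss_coeff=tbs_ss,
        tbs_pred_tv_coeff=tbs_tv,
        tbs_model=tbs_model,
        dose_day=dose_day,
    )


def ratio_diagnostics(perturbed: Trajectory, reference: Trajectory) -> pd.DataFrame:
    """Perturbed/steady-state ratios of F(5), M(5), SA_p and the implied
    TBS-prediction ratio.

    The TBS ratio (steady-coefficient mode) is the reciprocal of the
    SA_p ratio wherever defined — SA_p sits in the denominator of the
    prediction equation, so inflammation-driven changes in SA_p map
    inversely onto predicted stores.  Near-zero denominators yield NaN.
    """
    if len(perturbed.times) != len(reference.times) or not np.allclose(
        perturbed.times, reference.times
    ):
        raise ValueError("trajectories are on different time grids")
    f5_p, f5_r = perturbed.series(5), reference.series(5)
    m5_p, m5_r = perturbed.series(15), reference.series(15)
    valid = (f5_r > _F5_FLOOR) & (f5_p > _F5_FLOOR) & (m5_r > 0) & (m5_p > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f5_ratio = np.where(valid, f5_p / f5_r, np.nan)
        m5_ratio = np.where(valid, m5_p / m5_r, np.nan)
        sap_ratio = np.where(valid, (f5_p / m5_p) / (f5_r / m5_r), np.nan)
        tbs_ratio = np.where(valid, (f5_r / m5_r) / (f5_p / m5_p), np.nan)
    return pd.DataFrame(
        {
            "time_d": perturbed.times,
            "f5_ratio": f5_ratio,
            "m5_ratio": m5_ratio,
            "sa_p_ratio": sap_ratio,
            "tbs_pred_ratio": tbs_ratio,
        }
    )
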
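"""Hill-ensemble outcome model: stimulated saliva output at 1 year post-RT.

The predicted output relative to baseline is

    S(D_1..D_18) = 1 - sum_i Delta_i * [1 - 1 / (1 + (D_i / D50_i)^n_i)]

where D_i is the mean dose to subsegment S_i, Delta_i the maximum loss
attributable to S_i at infinite dose, D50_i the dose producing half that
loss, and n_i the curve steepness.  Each per-subsegment Hill curve is fit
by least squares to responses sampled on a 0:2:40 Gy dose ladder.

The default parameter set shipped in ``data/hill_18.json`` is a synthetic
declared ground truth (the population model behind the published
parameters is not redistributable); it preserves the structure of the
ensemble, not clinical values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dosimetry import PairedTestResult, paired_t
from .subsegment import N_SUBSEGMENTS

DOSE_LADDER_GY = np.arange(0.0, 42.0, 2.0)  # 0, 2, ..., 40 Gy sampling grid


@dataclass
class HillParams:
    """Per-subsegment (Delta_i, D50_i, n_i) for the 18-term ensemble."""

    delta: np.ndarray
    d50: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.d50 = np.asarray(self.d50, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        for name, arr in (("delta", self.delta), ("d50", self.d50), ("n", self.n)):
            if arr.shape != (N_SUBSEGMENTS,):
                raise ValueError(f"{name} needs exactly 18 values")
        if np.any(self.delta < 0) or self.delta.sum() > 1.0 + 1e-9:
            raise ValueError("delta values must be >= 0 and sum to at most 1")
        if np.any(self.d50 <= 0) or np.any(self.n <= 0):
            raise ValueError("d50 and n must be strictly positive")


@dataclass
class SalivaPrediction:
    s: float                       # fraction of baseline in [1 - sum(delta), 1]
    per_subsegment_loss: np.ndarray  # 18 fractions, loss_i in [0, delta_i]


@dataclass
class HillFit:
    delta: float
    d50: float
    n: float
    r0: float
    cost: float
    identifiable: bool  # False when delta ~ 0 leaves d50/n unconstrained


class FitError(RuntimeError):
    pass


def load_hill_params(path: str | Path | None = None) -> HillParams:
    """Load Hill parameters from JSON (synthetic package default if no path)."""
    if path is None:
        text = resources.files("parotidspare.data").joinpath("hill_18.json").read_text()
    else:
        text = Path(path).read_text()
    entries = json.loads(text)
    if isinstance(entries, dict):
        entries = entries["subsegments"]
    delta = np.zeros(N_SUBSEGMENTS)
    d50 = np.zeros(N_SUBSEGMENTS)
    n = np.zeros(N_SUBSEGMENTS)
    for e in entries:
        k = int(e["rank"]) - 1
        delta[k], d50[k], n[k] = float(e["delta"]), float(e["d50_gy"]), float(e["n"])
    return HillParams(delta=delta, d50=d50, n=n)


def _hill_loss(dose: np.ndarray, delta, d50, n) -> np.ndarray:
    """Delta * [1 - 1/(1 + (D/D50)^n)], elementwise, 0 at D = 0."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / d50) ** n, 0.0)
    return delta * (1.0 - 1.0 / (1.0 + ratio))


def saliva_predict(doses: Sequence[float], params: HillParams) -> SalivaPrediction:
    """Predicted saliva output for one plan's 18 subsegment mean doses."""
    doses = np.asarray(doses, dtype=float)
    if doses.shape != (N_SUBSEGMENTS,):
        raise ValueError("need exactly 18 subsegment doses")
    if np.any(~np.isfinite(doses)) or np.any(doses < 0):
        raise ValueError("subsegment doses must be finite and non-negative")
    losses = _hill_loss(doses, params.delta, params.d50, params.n)
    return SalivaPrediction(s=float(1.0 - losses.sum()), per_subsegment_loss=losses)


def fit_hill(
    dose_points: Sequence[float],
    responses: Sequence[float],
    seed: int = 0,
    n_starts: int = 8,
) -> HillFit:
    """Least-squares Hill fit r(D) = r(0) - Delta*[1 - 1/(1+(D/D50)^n)].

    The baseline r(0) is taken from the measured response at zero dose
    (the other subsegments hold a constant dose, so the baseline need not
    be 1).  Bounds: Delta in [0, 1], D50 in (0, 200] Gy, n in (0, 20].
    Deterministic multi-start over a log-spaced D50 grid; ``seed`` is
    accepted for interface stability but the starts are fixed.
    """
    d = np.asarray(dose_points, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.shape != r.shape or d.ndim != 1 or len(d) < 5:
        raise ValueError("need >= 5 matched (dose, response) points")
    if not np.any(d == 0):
        raise ValueError("a zero-dose point is required to anchor the baseline")
    if np.any(r < -1e-9) or np.any(r > 1 + 1e-9):
        raise ValueError("responses must lie in [0, 1]")
    r0 = float(r[d == 0].mean())

    def residuals(x):
        delta, d50, n = x
        return (r0 - _hill_loss(d, delta, d50, n)) - r

    delta0 = float(np.clip(r0 - r.min(), 1e-3, 1.0))
    best = None
    d50_starts = np.geomspace(2.0, 100.0, n_starts)
    for d50_0 in d50_starts:
        try:
            res = least_squares(
                residuals,
                x0=[delta0, d50_0, 2.0],
                bounds=([0.0, 1e-6, 1e-3], [1.0, 200.0, 20.0]),
                method="trf",
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("Hill fit failed to converge from every start")
    delta, d50, n = (float(v) for v in best.x)
    return HillFit(
        delta=delta,
        d50=d50,
        n=n,
        r0=r0,
        cost=float(best.cost),
        identifiable=delta > 1e-3,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def improvement_stats(s_plan: float, s_control: float) -> tuple[int, int]:
    """(relative improvement %, absolute percentage-point increase).

    Both are rounded half-up to the nearest integer, the printed reporting
    precision (e.g. 0.54 vs 0.48 -> (13, 6)).
    """
    if s_control <= 0:
        raise ValueError("control saliva output must be positive")
    relative = 100.0 * (s_plan - s_control) / s_control
    absolute = 100.0 * (s_plan - s_control)
    return _round_half_up(relative), _round_half_up(absolute)


def cohort_response(
    subsegment_doses: Mapping[str, Sequence[Sequence[float]]],
    params: HillParams,
    control: str,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-plan-type saliva predictions and paired tests against a control.

    ``subsegment_doses`` maps plan type -> per-phantom 18-vectors of
    subsegment mean doses (same phantom order in every plan type).
    Returns a summary table (mean S, improvement %, absolute points, t,
    df, p vs the control) and the per-phantom S values per plan type.
    """
    if control not in subsegment_doses:
        raise ValueError(f"control plan type {control!r} missing")
    s_values: dict[str, np.ndarray] = {}
    for plan, dose_list in subsegment_doses.items():
        if len(dose_list) < 2:
            raise ValueError("cohort_response needs >= 2 phantoms per plan type")
        s_values[plan] = np.array(
            [saliva_predict(d, params).s for d in dose_list]
        )
    s_control = s_values[control]
    rows = []
    for plan, s in s_values.items():
        if plan == control:
            rows.append(
                {"plan": plan, "mean_s": s.mean(), "improvement_pct": np.nan,
                 "absolute_pts": np.nan, "t": np.nan, "df": np.nan, "p": np.nan}
            )
            continue
        if len(s) != len(s_control):
            raise ValueError("plan types must cover the same phantoms")
        rel, abs_pts = improvement_stats(float(s.mean()), float(s_control.mean()))
        test: PairedTestResult = paired_t(s, s_control)
        rows.append(
            {"plan": plan, "mean_s": s.mean(), "improvement_pct": rel,
             "absolute_pts": abs_pts, "t": test.t, "df": test.df, "p": test.p}
        )
    table = pd.DataFrame(rows).set_index("plan")
    return table, s_values
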
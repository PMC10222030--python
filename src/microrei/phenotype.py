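"""Residual energy intake (REI) from daily energy records.

REI is the residual of an ordinary least-squares regression of daily
metabolizable-energy intake (ME, MJ/d) on the animal's energy sinks:
energy-corrected milk (ECM, kg/d), metabolic body weight (BW^0.75, kg^0.75)
and piecewise body-weight change split into gain (>= 0) and loss (<= 0)
components.  A low REI marks an efficient animal: it ate less than the
model predicts for its level of production, maintenance and tissue change.

Daily residuals are averaged per animal over a days-in-milk window
(default DIM 3-100) and the per-animal values are cut into three
equal-quantile efficiency groups L (lowest REI, efficient), M and H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnergyRecord",
    "REIResult",
    "smooth_bw",
    "derive_bw_change",
    "fit_rei",
    "assign_groups",
]

#: Required columns of an energy-records table.
RECORD_COLUMNS = ("animal_id", "dim", "ecm", "bw", "me_intake")


@dataclass(frozen=True)
class EnergyRecord:
    """One animal-day of energy bookkeeping."""

    animal_id: str
    dim: int          # days in milk, >= 1
    ecm: float        # energy-corrected milk, kg/d
    bw: float         # body weight, kg
    me_intake: float  # metabolizable energy intake, MJ/d

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise ValueError(f"bw must be positive, got {self.bw}")
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")


@dataclass
class REIResult:
    """Fitted REI model: coefficients, daily residuals and per-animal REI."""

    rei: pd.Series                 # per-animal REI, MJ/d (index: animal_id)
    coefficients: np.ndarray       # beta0..beta4 of (1, ecm, bw^0.75, gain, loss)
    residuals: pd.DataFrame        # daily residuals (animal_id, dim, residual)
    dim_window: tuple[int, int]
    groups: pd.Series | None = field(default=None)  # L/M/H label per animal


def smooth_bw(bw: np.ndarray, window: int = 15) -> np.ndarray:
    """Smooth a daily body-weight series by a centered rolling linear fit.

    Each smoothed point is the value at the center of a local
    least-squares line fitted over ``window`` days (truncated at the
    series edges).  ``window=1`` (or ``None``) disables smoothing.
    """
    bw = np.asarray(bw, dtype=float)
    if window is None or window <= 1 or bw.size < 3:
        return bw.copy()
    half = window // 2
    n = bw.size
    out = np.empty(n)
    t = np.arange(n, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        tt = t[lo:hi] - t[i]
        yy = bw[lo:hi]
        # closed-form simple linear regression evaluated at tt=0
        tbar = tt.mean()
        denom = np.sum((tt - tbar) ** 2)
        if denom == 0:
            out[i] = yy.mean()
        else:
            slope = np.sum((tt - tbar) * (yy - yy.mean())) / denom
            out[i] = yy.mean() - slope * tbar
    return out


def derive_bw_change(
    bw: np.ndarray, window: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Split daily changes of a (smoothed) BW series into gain and loss.

    Returns ``(gain, loss)`` with ``gain_t = max(dBW_t, 0)`` and
    ``loss_t = min(dBW_t, 0)`` where ``dBW`` is the day-to-day difference
    of the smoothed trajectory; the first day has zero change.  Passing
    ``window<=1`` differences the raw series.
    """
    bw = np.asarray(bw, dtype=float)
    if bw.size < 2:
        warnings.warn("single BW observation: gain and loss set to 0")
        return np.zeros(bw.size), np.zeros(bw.size)
    smoothed = smooth_bw(bw, window=window)
    delta = np.diff(smoothed, prepend=smoothed[0])
    return np.maximum(delta, 0.0), np.minimum(delta, 0.0)


def _design_matrix(records: pd.DataFrame, smooth_window: int) -> np.ndarray:
    """Build the (1, ecm, bw^0.75, gain, loss) design, per-animal gain/loss."""
    gain = np.empty(len(records))
    loss = np.empty(len(records))
    for _, idx in records.groupby("animal_id", sort=False).groups.items():
        sub = records.loc[idx].sort_values("dim")
        g, l = derive_bw_change(sub["bw"].to_numpy(), window=smooth_window)
        gain[records.index.get_indexer(sub.index)] = g
        loss[records.index.get_indexer(sub.index)] = l
    return np.column_stack(
        [
            np.ones(len(records)),
            records["ecm"].to_numpy(),
            records["bw"].to_numpy() ** 0.75,
            gain,
            loss,
        ]
    )


_DESIGN_NAMES = ("intercept", "ecm", "metabolic_bw", "bw_gain", "bw_loss")


def fit_rei(
    records: pd.DataFrame,
    dim_window: tuple[int, int] = (3, 100),
    smooth_window: int = 15,
) -> REIResult:
    """Fit the energy-sink model and return per-animal residual energy intake.

    Parameters
    ----------
    records:
        Long table with columns ``animal_id, dim, ecm, bw, me_intake``
        (one row per animal-day).
    dim_window:
        Inclusive days-in-milk range entering the regression.
    smooth_window:
        Centered window (days) of the rolling linear BW smoother used
        before differencing; ``1`` disables smoothing.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")
    lo, hi = dim_window
    sub = records[(records["dim"] >= lo) & (records["dim"] <= hi)]
    sub = sub.reset_index(drop=True)
    if sub["animal_id"].nunique() < 2:
        raise ValueError("fit_rei requires records from at least 2 animals")
    for animal, grp in sub.groupby("animal_id"):
        if len(grp) < 2:
            raise ValueError(
                f"animal {animal!r} has fewer than 2 records in DIM window {dim_window}"
            )

    design = _design_matrix(sub, smooth_window)
    y = sub["me_intake"].to_numpy(dtype=float)

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(
            "rank-deficient REI design; collinear columns: "
            + ", ".join(_DESIGN_NAMES[j] for j in bad)
        )

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    resid_df = pd.DataFrame(
        {"animal_id": sub["animal_id"], "dim": sub["dim"], "residual": resid}
    )
    rei = resid_df.groupby("animal_id")["residual"].mean().rename("rei")
    return REIResult(
        rei=rei, coefficients=beta, residuals=resid_df, dim_window=dim_window
    )


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Greedy scan: columns lying in the span of the preceding ones."""
    bad = []
    for j in range(1, design.shape[1]):
        sub = design[:, : j + 1]
        if np.linalg.matrix_rank(sub) < min(sub.shape):
            bad.append(j)
    return bad or [design.shape[1] - 1]


def assign_groups(rei: pd.Series | np.ndarray, k: int = 3) -> pd.Series:
    """Cut REI values into ``k`` equal-quantile groups.

    Cut points are linear-interpolation quantiles at i/k; ties go to the
    lower group (label by ``value <= cutpoint``).  For ``k=3`` labels are
    ``L`` (lowest REI, efficient), ``M``, ``H``; otherwise ``G1..Gk``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = pd.Series(rei)
    if len(values) < k:
        raise ValueError(f"need at least k={k} values, got {len(values)}")
    cuts = np.quantile(values.to_numpy(dtype=float), [i / k for i in range(1, k)])
    names = ["L", "M", "H"] if k == 3 else [f"G{i + 1}" for i in range(k)]
    labels = np.full(len(values), names[-1], dtype=object)
    arr = values.to_numpy(dtype=float)
    for gi in range(k - 2, -1, -1):
        labels[arr <= cuts[gi]] = names[gi]
    return pd.Series(labels, index=values.index, name="group")
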
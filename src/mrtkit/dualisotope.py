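"""Two-window dual-isotope (In-111 / Lu-177) quantification.

The scanner is reduced to a 2x2 sensitivity/crosstalk matrix M mapping true
activities to window counts, counts = M @ (A_In, A_Lu).  M is calibrated by
least squares on a phantom ladder and inverted to unmix samples, with Poisson
error propagation and physical non-negativity clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhantomSeries", "UnmixingCalibration", "calibrate_unmixing", "unmix"]

ISOTOPES = ("In-111", "Lu-177")
WINDOWS = ("In_window", "Lu_window")


@dataclass
class PhantomSeries:
    """Calibration tubes: known activities and measured window counts.

    ``data`` columns: tube_id, A_In_MBq, A_Lu_MBq, counts_In_window,
    counts_Lu_window.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"A_In_MBq", "A_Lu_MBq", "counts_In_window", "counts_Lu_window"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"phantom table must have columns {sorted(req)}")
        if (self.data[list(req)] < 0).any().any():
            raise ValueError("activities and counts must be non-negative")

    @classmethod
    def from_csv(cls, path, **kw) -> "PhantomSeries":
        return cls(pd.read_csv(path, comment="#"), **kw)

    @property
    def activities(self) -> np.ndarray:  # (n_tubes, 2)
        return self.data[["A_In_MBq", "A_Lu_MBq"]].to_numpy(float)

    @property
    def counts(self) -> np.ndarray:  # (n_tubes, 2)
        return self.data[["counts_In_window", "counts_Lu_window"]].to_numpy(float)


@dataclass
class UnmixingCalibration:
    """Fitted window x isotope sensitivity matrix (counts per MBq)."""

    M: np.ndarray
    condition_number: float
    residuals: pd.DataFrame
    max_condition_number: float = 1e3

    def __post_init__(self) -> None:
        if np.any(np.diag(self.M) <= 0):
            raise ValueError("calibration diagonal must be positive")

    @property
    def valid(self) -> bool:
        return self.condition_number < self.max_condition_number


def calibrate_unmixing(ph: PhantomSeries,
                       max_condition_number: float = 1e3) -> UnmixingCalibration:
    """Least-squares estimate of M from counts = M @ activities over tubes."""
    A = ph.activities
    C = ph.counts
    if len(A) < 3:
        raise ValueError("need >= 3 tubes to calibrate")
    for j, iso in enumerate(ISOTOPES):
        if not np.any((A[:, j] > 0) & (A[:, 1 - j] == 0)):
            raise ValueError(f"need at least one single-isotope tube for {iso}")
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError(
            "rank-deficient phantom design: all tubes share the same In:Lu ratio")

    # each window row solved independently: C[:, i] = A @ M[i, :]
    M = np.vstack([np.linalg.lstsq(A, C[:, i], rcond=None)[0] for i in range(2)])
    pred = A @ M.T
    resid = pd.DataFrame({
        "tube_id": ph.data.get("tube_id", pd.RangeIndex(len(A))),
        "resid_In_window": C[:, 0] - pred[:, 0],
        "resid_Lu_window": C[:, 1] - pred[:, 1],
    })
    cond = float(np.linalg.cond(M))
    return UnmixingCalibration(M, cond, resid, max_condition_number)


def unmix(counts, cal: UnmixingCalibration) -> dict:
    """Recover (A_In, A_Lu) from window counts.

    Standard errors are propagated from Poisson counting statistics
    (var = counts per window).  Negative estimates are clipped to zero and
    flagged.
    """
    if not cal.valid:
        raise ValueError(
            f"ill-conditioned calibration (cond={cal.condition_number:.3g} "
            f">= {cal.max_condition_number:.3g})")
    c = np.asarray(counts, float)
    squeeze = c.ndim == 1
    c = np.atleast_2d(c)
    Minv = np.linalg.inv(cal.M)
    a = c @ Minv.T
    # cov(a) = Minv diag(c) Minv^T per sample
    se = np.sqrt(np.maximum((Minv ** 2) @ c.T, 0.0)).T
    clipped = a < 0
    a = np.where(clipped, 0.0, a)
    out = {
        "A_In_MBq": a[:, 0], "A_Lu_MBq": a[:, 1],
        "se_In_MBq": se[:, 0], "se_Lu_MBq": se[:, 1],
        "clipped": clipped.any(axis=1),
    }
    if squeeze:
        out = {k: v[0] for k, v in out.items()}
    return out
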
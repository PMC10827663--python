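"""Fisher-z functional connectivity and hemispheric block extraction.

A subject's connectome is the parcel-by-parcel Pearson correlation of
their time series, Fisher z-transformed (z = atanh(r), with |r| clipped
at 1 - 1e-7 so z stays finite). The 360x360 matrix splits into four
180x180 hemispheric blocks: LL (left seeds, left targets), LR, RL, RR.
Rows and columns of every block are reindexed to homolog-pair order so
index i refers to the same pair in all four blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, DimensionError
from .io_core import ParcellationScheme

#: correlation clipping bound before atanh
FISHER_EPS = 1e-7


@dataclass(frozen=True)
class HemiBlocks:
    """The four hemispheric blocks of a Fisher-z connectome, homolog-ordered."""

    LL: np.ndarray
    LR: np.ndarray
    RL: np.ndarray
    RR: np.ndarray

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.LL, self.LR, self.RL, self.RR)}
        if len(shapes) != 1:
            raise DimensionError(f"blocks have inconsistent shapes: {shapes}")

    @property
    def n_pairs(self) -> int:
        return self.LL.shape[0]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"LL": self.LL, "LR": self.LR, "RL": self.RL, "RR": self.RR}


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping at +/-(1 - FISHER_EPS); preserves ordering, bounded output."""
    return np.arctanh(np.clip(r, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS))


def pearson_fc(timeseries: np.ndarray, on_constant: str = "error") -> np.ndarray:
    """Pearson correlation between parcel time series, Fisher z-transformed.

    Parameters
    ----------
    timeseries
        T x P array, one column per parcel.
    on_constant
        'error' raises on a zero-variance parcel; 'nan' leaves its row and
        column as NaN for the caller to flag.

    Returns
    -------
    P x P Fisher-z matrix with zero diagonal.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise DimensionError(f"need a T x P matrix with T >= 3, got shape {ts.shape}")
    sd = ts.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size and on_constant == "error":
        raise DegenerateDataError(f"constant time series at parcel(s) {const.tolist()[:10]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    z = fisher_z(r)
    if const.size:
        z[const, :] = np.nan
        z[:, const] = np.nan
    np.fill_diagonal(z, 0.0)
    return z


def regress_global_signal(timeseries: np.ndarray) -> np.ndarray:
    """Residualize every parcel's series on the spatial-mean (global) signal.

    The fit includes an intercept; residuals are orthogonal to the global
    signal by least squares.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise DimensionError(f"need a T x P matrix with T >= 3, got shape {ts.shape}")
    g = ts.mean(axis=1)
    if g.std() == 0:
        raise DegenerateDataError("global signal has zero variance")
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, ts, rcond=None)
    return ts - X @ beta


def split_blocks(fc: np.ndarray, scheme: ParcellationScheme) -> HemiBlocks:
    """Slice a full connectome into LL/LR/RL/RR blocks in homolog-pair order."""
    fc = np.asarray(fc, dtype=float)
    n = scheme.n_parcels
    if fc.shape != (n, n):
        raise DimensionError(f"fc shape {fc.shape} does not match parcellation size {n}")
    li = scheme.left_indices
    ri = scheme.right_indices
    return HemiBlocks(
        LL=fc[np.ix_(li, li)],
        LR=fc[np.ix_(li, ri)],
        RL=fc[np.ix_(ri, li)],
        RR=fc[np.ix_(ri, ri)],
    )
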
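"""Time-arclength (t-s) field container used by every map in the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = ["TSMap"]


@dataclass
class TSMap:
    """A value field on the (t, s) grid with a validity mask.

    values[i, j] is the field at time t[i] and arc length s[j]; mask[i, j]
    is False where the organ is shorter than s[j] or the estimate is
    undefined, in which case values[i, j] is NaN.
    """

    t: np.ndarray
    s: np.ndarray
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.s = np.asarray(self.s, float)
        self.values = np.asarray(self.values, float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape != (len(self.t), len(self.s)):
            raise ValueError("values must have shape (len(t), len(s))")
        if np.any(np.diff(self.t) <= 0) or np.any(np.diff(self.s) <= 0):
            raise ValueError("grids must be strictly increasing")
        self.values = np.where(self.mask, self.values, np.nan)

    def sample(self, t: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Bilinear interpolation at (t, s) points (NaN outside the mask)."""
        interp = RegularGridInterpolator((self.t, self.s), self.values,
                                         bounds_error=False, fill_value=np.nan)
        return interp(np.column_stack([np.atleast_1d(t), np.atleast_1d(s)]))

    def to_frame(self) -> pd.DataFrame:
        tt, ss = np.meshgrid(self.t, self.s, indexing="ij")
        return pd.DataFrame({
            "t": tt.ravel(), "s": ss.ravel(),
            "value": self.values.ravel(), "valid": self.mask.ravel(),
        })

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "", units: str = "") -> "TSMap":
        t = np.unique(df["t"].to_numpy())
        s = np.unique(df["s"].to_numpy())
        piv = df.pivot(index="t", columns="s", values="value")
        msk = df.pivot(index="t", columns="s", values="valid").to_numpy().astype(bool)
        return cls(t=t, s=s, values=piv.to_numpy(), mask=msk, name=name, units=units)

    @classmethod
    def load_csv(cls, path: str | Path, name: str = "", units: str = "") -> "TSMap":
        return cls.from_frame(pd.read_csv(path), name=name, units=units)
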
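"""In-memory containers for Infinium-style methylation matrices.

All matrices are probe x sample: rows indexed by probe identifier, columns by
sample identifier, held in a :class:`pandas.DataFrame`. ``BetaMatrix`` holds
methylated signal fractions (beta values, bounded in [0, 1]); ``MMatrix``
holds the unbounded logit2-scale values preferred for batch correction;
``SignalMatrices`` pairs raw methylated/unmethylated fluorescence intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "MMatrix",
    "SignalMatrices",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
]


def _as_float_frame(frame: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(frame, pd.DataFrame):
        raise TypeError("expected a pandas DataFrame (probes x samples)")
    return frame.astype(float)


@dataclass
class BetaMatrix:
    """Probe x sample beta values. Non-missing entries must lie in [0, 1]."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = _as_float_frame(self.frame)
        vals = self.frame.to_numpy()
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere((vals < 0.0) | (vals > 1.0))
            i, j = bad[0]
            raise ValueError(
                f"beta value out of [0, 1] at probe {self.frame.index[i]!r}, "
                f"sample {self.frame.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


@dataclass
class MMatrix:
    """Probe x sample M values (log2 methylated/unmethylated ratio)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = _as_float_frame(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


@dataclass
class SignalMatrices:
    """Paired methylated/unmethylated fluorescence intensity matrices.

    Both frames must share probe and sample identifiers; intensities are
    non-negative, NaN marking missing observations.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame

    def __post_init__(self) -> None:
        self.meth = _as_float_frame(self.meth)
        self.unmeth = _as_float_frame(self.unmeth)
        if self.meth.shape != self.unmeth.shape:
            raise ValueError(
                f"meth {self.meth.shape} and unmeth {self.unmeth.shape} differ in shape"
            )
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise ValueError("meth and unmeth must share probe and sample identifiers")
        for name, frame in (("meth", self.meth), ("unmeth", self.unmeth)):
            vals = frame.to_numpy()
            neg = np.argwhere(vals < 0.0)
            if neg.size:
                i, j = neg[0]
                raise ValueError(
                    f"negative {name} signal at probe {frame.index[i]!r}, "
                    f"sample {frame.columns[j]!r}: {vals[i, j]}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth.columns


# --- delimited-text IO -----------------------------------------------------
#
# Dialect: first column probe id, header row of sample ids, tab-separated,
# missing values written as empty fields (also accepted as "NA").


def read_matrix_tsv(path, sep: str = "\t") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    frame.index.name = "probe_id"
    return frame.astype(float)


def write_matrix_tsv(frame: pd.DataFrame, path, sep: str = "\t") -> None:
    out = frame.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=sep, na_rep="")


SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "slide",
    "position_row",
    "position_col",
    "superbatch",
    "gender",
    "treatment",
    "cell_fraction",
)


def read_sample_sheet(path, sep: str = "\t") -> pd.DataFrame:
    sheet = pd.read_csv(path, sep=sep, dtype={"slide": str, "superbatch": str})
    missing = [c for c in ("sample_id", "slide") if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing required columns: {missing}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path, sep: str = "\t") -> None:
    sheet.to_csv(path, sep=sep, index=False)
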
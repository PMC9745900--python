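"""Arcsinh transformation and standardization of phospho-flow readouts.

Flow-cytometry median signals are expressed relative to an isotype control
on the arcsinh scale,

    ratio = asinh(signal / cofactor) - asinh(isotype / cofactor),

so the isotype control itself maps to zero.  The cofactor (default 150,
conventional for fluorescence cytometry) sets where the transform switches
from linear to logarithmic behaviour.  Before regression modelling each
analyte row is standardized to mean 0 / sample SD 1 across cell lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_COFACTOR = 150.0


def arcsinh_ratio(signal, isotype_signal, cofactor: float = DEFAULT_COFACTOR):
    """Arcsinh ratio of a stained signal against its isotype control."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    signal = np.asarray(signal, dtype=float)
    isotype_signal = np.asarray(isotype_signal, dtype=float)
    if np.any(signal < 0) or np.any(isotype_signal < 0):
        raise ValueError("signals must be non-negative")
    out = np.arcsinh(signal / cofactor) - np.arcsinh(isotype_signal / cofactor)
    return float(out) if out.ndim == 0 else out


def ratio_table(
    readouts: pd.DataFrame, cofactor: float = DEFAULT_COFACTOR
) -> pd.DataFrame:
    """Analytes × cell lines arcsinh-ratio matrix from a long-format table.

    Expects columns cell_line, analyte, signal, isotype_signal.
    """
    df = readouts.copy()
    df["arcsinh_ratio"] = arcsinh_ratio(
        df["signal"].to_numpy(), df["isotype_signal"].to_numpy(), cofactor
    )
    mat = df.pivot_table(
        index="analyte", columns="cell_line", values="arcsinh_ratio"
    )
    mat.index.name = "analyte"
    mat.columns.name = "cell_line"
    return mat


def standardize_matrix(
    ratios: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-analyte z-scores (mean 0, sample SD 1) across cell lines.

    Returns (standardized matrix, per-analyte stats with mean, sd and a
    ``zero_variance`` flag).  Constant analytes become rows of zeros.
    """
    if ratios.shape[1] < 2:
        raise ValueError("need >= 2 cell lines to standardize")
    mean = ratios.mean(axis=1)
    sd = ratios.std(axis=1, ddof=1)
    zero_var = sd <= 0
    safe_sd = sd.where(~zero_var, 1.0)
    z = ratios.sub(mean, axis=0).div(safe_sd, axis=0)
    z[zero_var] = 0.0
    stats = pd.DataFrame(
        {"mean": mean, "sd": sd, "zero_variance": zero_var}
    )
    return z, stats
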
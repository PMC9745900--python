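"""Modified drug sensitivity score (DSS) on a 0-100 scale.

The score is a normalized area over the inhibition curve computed inside a
response window running from 100% viability down to a threshold ``t``
(default 10%), and over the log10-concentration window of the tested range.
With ``v(x)`` the fitted viability clipped to [0, 100] at
``x = log10 dose``:

    A   = integral over [x_min, x_max] of (100 - max(v(x), t)) dx
    DSS = 100 * A / ((100 - t) * (x_max - x_min))

Once the curve drops below the threshold the integrand saturates at
(100 - t), which realizes the concentration window "up to the dose where
viability reaches t": doses beyond that point contribute the maximal area
slab rather than being discarded, so a drug that kills everything at the
lowest dose scores 100 rather than 0.  The score carries no extra division
by the logarithm of the upper concentration limit.  High DSS = sensitive.

An alternative ``window="truncate"`` stops the integral at the threshold
crossing (for sensitivity analysis); the default ``"clip"`` semantics are
recommended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseFit


@dataclass(frozen=True)
class DssConfig:
    """Scoring window and integration resolution."""

    t: float = 10.0  # viability threshold, %
    response_upper: float = 100.0
    points_per_decade: int = 1000
    window: str = "clip"  # "clip" (default) or "truncate"

    def __post_init__(self) -> None:
        if not (0.0 < self.t < self.response_upper):
            raise ValueError("threshold t must lie in (0, response_upper)")
        if self.points_per_decade < 2:
            raise ValueError("points_per_decade must be >= 2")
        if self.window not in ("clip", "truncate"):
            raise ValueError("window must be 'clip' or 'truncate'")


@dataclass(frozen=True)
class DssRecord:
    cell_line: str
    drug: str
    dss: float
    x_min: float  # log10 nM
    x_max: float
    x_t: float  # log10 nM where fitted viability first reaches t (or x_max)
    model: str
    low_confidence: bool = False


def _viability_on_grid(fit: DoseResponseFit, x: np.ndarray) -> np.ndarray:
    v = fit.predict(10.0 ** x)
    return np.clip(v, 0.0, 100.0)


def compute_dss(
    fit: DoseResponseFit,
    dose_range_nM: tuple[float, float],
    config: DssConfig = DssConfig(),
    cell_line: str = "",
    drug: str = "",
) -> DssRecord:
    """Score one fitted curve over the tested dose range (nM)."""
    lo, hi = dose_range_nM
    if not (0 < lo < hi):
        raise ValueError("dose range must be positive and ordered")
    x_min, x_max = np.log10(lo), np.log10(hi)
    n = max(int(np.ceil((x_max - x_min) * config.points_per_decade)) + 1, 2)
    x = np.linspace(x_min, x_max, n)
    v = _viability_on_grid(fit, x)

    t = config.t
    below = v <= t
    x_t = float(x[np.argmax(below)]) if below.any() else x_max

    integrand = config.response_upper - np.maximum(v, t)
    if config.window == "truncate":
        integrand = np.where(x <= x_t, integrand, 0.0)
    area = float(np.trapezoid(integrand, x))
    norm = (config.response_upper - t) * (x_max - x_min)
    score = 100.0 * area / norm
    score = float(min(max(score, 0.0), 100.0))
    return DssRecord(
        cell_line=cell_line, drug=drug, dss=score, x_min=float(x_min),
        x_max=float(x_max), x_t=x_t, model=fit.model,
        low_confidence=fit.degenerate,
    )


def build_dss_matrix(records) -> pd.DataFrame:
    """Assemble drugs × cell lines score matrix from DssRecords.

    Duplicated (drug, cell line) pairs raise; combinations missing from the
    record collection appear as NaN.
    """
    records = list(records)
    seen = set()
    for r in records:
        key = (r.drug, r.cell_line)
        if key in seen:
            raise ValueError(f"duplicate record for drug/cell line {key}")
        seen.add(key)
    drugs = sorted({r.drug for r in records})
    lines = sorted({r.cell_line for r in records})
    mat = pd.DataFrame(np.nan, index=drugs, columns=lines)
    for r in records:
        mat.loc[r.drug, r.cell_line] = r.dss
    mat.index.name = "drug"
    mat.columns.name = "cell_line"
    return mat


def summarize_drug(dss_matrix: pd.DataFrame, drug: str) -> tuple[float, float]:
    """Mean and sample SD of one drug's scores across cell lines."""
    row = dss_matrix.loc[drug].dropna()
    if row.empty:
        raise ValueError(f"no scores for drug {drug!r}")
    mean = float(row.mean())
    sd = float(row.std(ddof=1)) if row.size >= 2 else float("nan")
    return mean, sd


def score_screen(
    fits: pd.DataFrame,
    dose_range_nM: tuple[float, float],
    config: DssConfig = DssConfig(),
) -> tuple[pd.DataFrame, list[DssRecord]]:
    """Score a whole table of fits (as produced by ``fit_screen``)."""
    records = []
    for row in fits.itertuples(index=False):
        fit = DoseResponseFit(
            model=row.model, b=row.b, c=row.c, d=row.d, e=row.e,
            converged=row.converged, rss=row.rss, n_points=row.n_points,
            degenerate=bool(getattr(row, "degenerate", False)),
        )
        records.append(
            compute_dss(fit, dose_range_nM, config,
                        cell_line=row.cell_line, drug=row.drug)
        )
    return build_dss_matrix(records), records
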
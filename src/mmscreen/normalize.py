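"""Control-based normalization of raw plate-reader luminescence.

Viability is expressed relative to the plate's own controls:

    viability % = 100 * (signal - pos_mean) / (neg_mean - pos_mean)

where the negative control (vehicle only) defines 100% viability and the
positive control (full kill) defines 0%.  Controls are plate-local; values
outside [0, 100] are retained (curve fitting should see the unclipped
response) and flagged instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "plate", "well", "cell_line", "drug", "concentration_nM", "role",
    "luminescence", "replicate",
)


class NormalizationError(ValueError):
    pass


def normalize_plate(raw: pd.DataFrame, control_stat: str = "mean") -> pd.DataFrame:
    """Normalize raw luminescence to per-plate controls.

    Returns the sample rows with added columns ``viability`` (%) and
    ``out_of_range`` (True when outside [0, 100]).  ``control_stat`` selects
    mean (default) or median aggregation of control wells.
    """
    missing = set(REQUIRED_COLUMNS) - set(raw.columns)
    if missing:
        raise NormalizationError(f"missing columns: {sorted(missing)}")
    if not np.isfinite(raw["luminescence"]).all():
        raise NormalizationError("non-finite luminescence values")
    agg = {"mean": np.mean, "median": np.median}[control_stat]

    out = []
    for plate, grp in raw.groupby("plate", sort=True):
        neg = grp.loc[grp["role"] == "negative", "luminescence"]
        pos = grp.loc[grp["role"] == "positive", "luminescence"]
        if neg.empty or pos.empty:
            raise NormalizationError(f"plate {plate!r}: missing control wells")
        neg_m, pos_m = float(agg(neg)), float(agg(pos))
        if neg_m <= pos_m:
            raise NormalizationError(
                f"plate {plate!r}: inverted controls "
                f"(negative mean {neg_m:.3g} <= positive mean {pos_m:.3g})"
            )
        samples = grp[grp["role"] == "sample"].copy()
        samples["viability"] = (
            100.0 * (samples["luminescence"] - pos_m) / (neg_m - pos_m)
        )
        samples["out_of_range"] = ~samples["viability"].between(0.0, 100.0)
        out.append(samples)
    result = pd.concat(out, ignore_index=True)
    return result.drop(columns=["luminescence"])


def summarize_replicates(profile: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and sample SD per (cell line, drug, concentration).

    SD uses the n-1 denominator; with a single replicate the SD is NaN and
    ``sd_missing`` is flagged.
    """
    grouped = profile.groupby(
        ["cell_line", "drug", "concentration_nM"], sort=True
    )["viability"]
    summary = grouped.agg(viability="mean", sd=lambda v: v.std(ddof=1),
                          n="count").reset_index()
    summary["sd_missing"] = summary["n"] < 2
    return summary
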
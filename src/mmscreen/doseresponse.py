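"""Four-parameter log-logistic dose-response fitting with logistic fallback.

The primary model is the four-parameter log-logistic (LL4),

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e))),

with slope ``b``, lower asymptote ``c`` (% viability), upper asymptote ``d``
and inflection concentration ``e`` (nM).  Where LL4 fails to converge, a
four-parameter logistic (L4) on the log10 concentration axis is fitted
instead:

    f(z) = c + (d - c) / (1 + exp(b * (z - e))),   z = log10 x,

in which ``e`` is a location on the log10 scale.  The fallback choice of
abscissa (log10 rather than raw dose) keeps the two models on comparable
footing across concentration ranges spanning several decades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

# numpy's SIMD exp/log may differ by 1 ulp between the vector body and the
# scalar tail of a loop, so their results depend on buffer alignment, i.e.
# on allocator state.  Ill-conditioned curve fits amplify those ulps into
# visibly different parameters, breaking bit-level reproducibility of
# same-seed runs.  The model functions therefore use the scalar libm
# routines, which are alignment-independent.


def _exp(a: np.ndarray) -> np.ndarray:
    clipped = np.clip(a, -745.0, 709.0)
    flat = clipped.ravel()
    return np.fromiter(
        (math.exp(v) for v in flat), dtype=float, count=flat.size
    ).reshape(clipped.shape)


def _log(a: np.ndarray) -> np.ndarray:
    flat = np.asarray(a, dtype=float).ravel()
    return np.fromiter(
        (math.log(v) if v > 0 else -math.inf for v in flat),
        dtype=float, count=flat.size,
    ).reshape(np.shape(a))


def ll4(x, b, c, d, e):
    """Four-parameter log-logistic response at concentration ``x`` (nM)."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = c + (d - c) / (1.0 + _exp(b * (_log(arr) - math.log(e))))
    return float(out[0]) if np.ndim(x) == 0 else out


def l4(z, b, c, d, e):
    """Four-parameter logistic response at ``z`` = log10 concentration."""
    arr = np.atleast_1d(np.asarray(z, dtype=float))
    out = c + (d - c) / (1.0 + _exp(b * (arr - e)))
    return float(out[0]) if np.ndim(z) == 0 else out


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted curve parameters for one (cell line, drug) profile."""

    model: str  # "LL4" or "L4"
    b: float
    c: float
    d: float
    e: float  # nM for LL4; log10-nM location for L4
    converged: bool
    rss: float
    n_points: int
    degenerate: bool = False
    message: str = ""

    def predict(self, conc_nM):
        """Fitted viability (%) at the given concentrations in nM."""
        conc_nM = np.asarray(conc_nM, dtype=float)
        if self.degenerate:
            return np.full(conc_nM.shape, self.d)
        if self.model == "LL4":
            return ll4(conc_nM, self.b, self.c, self.d, self.e)
        return l4(np.log10(conc_nM), self.b, self.c, self.d, self.e)


class FitError(ValueError):
    """Raised when a dose-response profile cannot be fitted at all."""


def _prepare(conc, resp):
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if conc.shape != resp.shape:
        raise FitError("concentration and response lengths differ")
    ok = np.isfinite(conc) & np.isfinite(resp)
    conc, resp = conc[ok], resp[ok]
    if np.any(conc <= 0):
        raise FitError("concentrations must be positive")
    if np.unique(conc).size < 4:
        raise FitError(
            f"need >= 4 distinct concentrations, got {np.unique(conc).size}"
        )
    return conc, resp


def _initial_guess(conc, resp, log_abscissa: bool):
    d0 = float(np.max(resp))
    c0 = float(np.min(resp))
    half = (c0 + d0) / 2.0
    e0 = float(conc[np.argmin(np.abs(resp - half))])
    if log_abscissa:
        e0 = float(np.log10(e0))
    return 1.0, c0, d0, e0


def _degenerate_fit(model, conc, resp, message):
    mean = float(np.mean(resp))
    e0 = float(np.exp(np.mean(np.log(conc))))
    if model == "L4":
        e0 = float(np.log10(e0))
    rss = float(np.sum((resp - mean) ** 2))
    return DoseResponseFit(
        model=model, b=0.0, c=mean, d=mean, e=e0, converged=True,
        rss=rss, n_points=int(resp.size), degenerate=True, message=message,
    )


def fit_ll4(conc_nM, response, max_nfev: int = 20000) -> DoseResponseFit:
    """Least-squares LL4 fit of % viability against concentration (nM).

    Initialization: d0 = max response, c0 = min response, e0 = the tested
    dose whose response is nearest the half-response, b0 = 1.  The fit is
    declared non-converged when the optimizer fails, any parameter is
    non-finite, or the inflection ``e`` falls outside
    [min dose / 1e4, max dose * 1e4].
    """
    conc, resp = _prepare(conc_nM, response)
    if np.ptp(resp) < 1e-9:
        return _degenerate_fit("LL4", conc, resp, "constant response")

    x0 = _initial_guess(conc, resp, log_abscissa=False)

    def residual(p):
        b, c, d, e = p
        if e <= 0:
            return np.full(resp.shape, 1e6)
        r = ll4(conc, b, c, d, e) - resp
        return np.where(np.isfinite(r), r, 1e6)

    sol = optimize.least_squares(
        residual, x0, method="lm", max_nfev=max_nfev, xtol=1e-12, ftol=1e-12,
        gtol=1e-12,
    )
    b, c, d, e = (float(v) for v in sol.x)
    rss = float(np.sum(residual(sol.x) ** 2))
    lo, hi = conc.min() / 1e4, conc.max() * 1e4
    converged = bool(
        sol.success
        and np.all(np.isfinite(sol.x))
        and lo <= e <= hi
    )
    return DoseResponseFit(
        model="LL4", b=b, c=c, d=d, e=e, converged=converged, rss=rss,
        n_points=int(resp.size), message=str(sol.message),
    )


def fit_l4(conc_nM, response, max_nfev: int = 20000) -> DoseResponseFit:
    """Least-squares L4 fit on the log10-concentration axis.

    As the fallback of last resort this fit multi-starts over a few slope
    and location initializations (steep kills below the tested range leave
    the default start on a flat residual plateau where LM stalls) and keeps
    the converged solution with the lowest RSS.
    """
    conc, resp = _prepare(conc_nM, response)
    if np.ptp(resp) < 1e-9:
        return _degenerate_fit("L4", conc, resp, "constant response")

    z = np.log10(conc)
    _, c0, d0, e0 = _initial_guess(conc, resp, log_abscissa=True)
    z_mid = float((z.min() + z.max()) / 2.0)

    def residual(p):
        b, c, d, e = p
        r = l4(z, b, c, d, e) - resp
        return np.where(np.isfinite(r), r, 1e6)

    best = None
    last = None
    for b0 in (1.0, 3.0, -1.0):
        for e_start in (e0, z_mid, float(z.min())):
            sol = optimize.least_squares(
                residual, (b0, c0, d0, e_start), method="lm",
                max_nfev=max_nfev, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            rss = float(np.sum(residual(sol.x) ** 2))
            ok = bool(sol.success and np.all(np.isfinite(sol.x)))
            last = (sol, rss)
            if ok and (best is None or rss < best[1]):
                best = (sol, rss)
        if best is not None:
            break
    if best is None:
        # profiles that drop before the second dose leave the upper
        # asymptote unidentifiable and send LM down a ridge; a bounded
        # trust-region fit pins the parameters to a sane box
        lo = (-50.0, -50.0, -50.0, float(z.min()) - 4.0)
        hi = (50.0, 150.0, 150.0, float(z.max()) + 4.0)
        for b0 in (3.0, 1.0, -1.0):
            sol = optimize.least_squares(
                residual, (b0, max(c0, -49.0), min(d0, 149.0), z_mid),
                method="trf", bounds=(lo, hi), max_nfev=max_nfev,
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            rss = float(np.sum(residual(sol.x) ** 2))
            ok = bool(sol.success and np.all(np.isfinite(sol.x)))
            last = (sol, rss)
            if ok and (best is None or rss < best[1]):
                best = (sol, rss)
    sol, rss = best if best is not None else last
    b, c, d, e = (float(v) for v in sol.x)
    return DoseResponseFit(
        model="L4", b=b, c=c, d=d, e=e, converged=best is not None, rss=rss,
        n_points=int(resp.size), message=str(sol.message),
    )


def fit_with_fallback(conc_nM, response) -> DoseResponseFit:
    """Fit LL4; if it fails to converge, fall back to L4.

    Raises :class:`FitError` carrying both diagnostics when both fail.
    """
    primary = fit_ll4(conc_nM, response)
    if primary.converged:
        return primary
    fallback = fit_l4(conc_nM, response)
    if fallback.converged:
        return fallback
    raise FitError(
        "both LL4 and L4 fits failed to converge: "
        f"LL4: {primary.message!r}; L4: {fallback.message!r}"
    )


def fit_screen(profiles, max_nfev: int = 20000):
    """Fit every (cell line, drug) profile of a replicate-mean table.

    ``profiles`` is a DataFrame with columns cell_line, drug,
    concentration_nM, viability (replicate means).  Returns a DataFrame of
    fit parameters, one row per (cell line, drug), plus a list of fallback
    events.
    """
    import pandas as pd

    rows = []
    fallbacks = []
    for (cl, dr), grp in profiles.groupby(["cell_line", "drug"], sort=True):
        fit = fit_with_fallback(
            grp["concentration_nM"].to_numpy(), grp["viability"].to_numpy()
        )
        if fit.model == "L4":
            fallbacks.append({"cell_line": cl, "drug": dr})
        rows.append(
            dict(
                cell_line=cl, drug=dr, model=fit.model, b=fit.b, c=fit.c,
                d=fit.d, e=fit.e, converged=fit.converged, rss=fit.rss,
                n_points=fit.n_points, degenerate=fit.degenerate,
            )
        )
    return pd.DataFrame(rows), fallbacks
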
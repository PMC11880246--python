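"""Current-voltage assembly and linear (ohmic) slope-conductance fits.

Unitary currents measured at several holding potentials are fitted with a
straight line i = a V + b.  The slope gives the single-channel conductance
(pS = 1000 x pA/mV) and the x-intercept the reversal potential
E_rev = -b/a, whose standard error follows from the delta method.  Fits go
through statsmodels OLS/WLS so the usual regression diagnostics are
available on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InputError, ReversalUndefinedError

__all__ = ["IVDataset", "IVFitResult", "fit_iv", "build_iv"]


@dataclass(frozen=True)
class IVDataset:
    """Unitary current versus holding potential for one bath condition.

    ``points`` has columns ``holding_mV``, ``current_pA`` and optionally
    ``se_pA`` and ``n_events``.
    """

    points: pd.DataFrame
    bath: str = ""

    def __post_init__(self):
        pts = self.points
        required = {"holding_mV", "current_pA"}
        if not required.issubset(pts.columns):
            raise InputError(f"points must have columns {sorted(required)}")
        if pts["holding_mV"].nunique() < 2:
            raise InputError("need at least 2 distinct holding potentials")
        if not np.all(np.isfinite(pts["current_pA"])):
            raise InputError("currents must be finite")

    @classmethod
    def from_points(
        cls,
        points: list[tuple],
        bath: str = "",
    ) -> "IVDataset":
        """Build from (holding_mV, current_pA[, se_pA]) tuples."""
        cols = ["holding_mV", "current_pA", "se_pA"]
        df = pd.DataFrame([p[:3] for p in points], columns=cols[: len(points[0])])
        return cls(points=df, bath=bath)


@dataclass(frozen=True)
class IVFitResult:
    """Straight-line I-V fit: conductance, reversal potential, uncertainties."""

    conductance_pS: float
    conductance_se_pS: float
    e_rev_mV: float
    e_rev_se_mV: float
    slope_pA_per_mV: float
    intercept_pA: float
    residuals_pA: np.ndarray
    n_points: int
    weighted: bool = False
    bath: str = ""

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals_pA**2))

    def summary(self) -> str:
        return "\n".join(
            [
                f"I-V linear fit ({'weighted' if self.weighted else 'ordinary'} "
                f"least squares, n = {self.n_points})",
                f"  conductance: {self.conductance_pS:.2f} "
                f"+/- {self.conductance_se_pS:.2f} pS",
                f"  reversal potential: {self.e_rev_mV:.2f} "
                f"+/- {self.e_rev_se_mV:.2f} mV",
                f"  RSS: {self.rss:.4g} pA^2",
            ]
        )


def fit_iv(data: IVDataset, weighted: bool = False) -> IVFitResult:
    """Fit i = a V + b by ordinary or inverse-variance-weighted least squares.

    Conductance is 1000 a (pS) and E_rev = -b/a (mV) with its SE from the
    delta method: var(E) = var(b)/a^2 + b^2 var(a)/a^4 - 2 b cov(a,b)/a^3.
    Exact (zero-residual) on collinear points; with only two points the fit
    interpolates and the standard errors are undefined (NaN).
    """
    pts = data.points
    v = pts["holding_mV"].to_numpy(float)
    i = pts["current_pA"].to_numpy(float)
    X = sm.add_constant(v)
    if weighted:
        if "se_pA" not in pts.columns or not np.all(pts["se_pA"].to_numpy() > 0):
            raise InputError("weighted fit requires positive se_pA for all points")
        w = 1.0 / pts["se_pA"].to_numpy(float) ** 2
        model = sm.WLS(i, X, weights=w)
    else:
        model = sm.OLS(i, X)
    res = model.fit()
    b, a = res.params  # intercept, slope
    # slope indistinguishable from zero at floating precision
    v_scale = max(np.max(np.abs(v)), 1.0)
    i_scale = max(np.max(np.abs(i)), 1e-300)
    if a == 0 or abs(a) < 1e-12 * i_scale / v_scale:
        raise ReversalUndefinedError("zero slope: reversal potential undefined")
    if res.df_resid > 0:
        cov = np.asarray(res.cov_params())
    else:  # saturated fit (2 points): uncertainties undefined
        cov = np.full((2, 2), np.nan)
    var_b, var_a = cov[0, 0], cov[1, 1]
    cov_ab = cov[0, 1]
    e_rev = -b / a
    var_e = var_b / a**2 + b**2 * var_a / a**4 - 2 * b * cov_ab / a**3
    e_rev_se = float(np.sqrt(var_e)) if var_e >= 0 else float("nan")
    return IVFitResult(
        conductance_pS=1000.0 * a,
        conductance_se_pS=1000.0 * float(np.sqrt(var_a)),
        e_rev_mV=float(e_rev),
        e_rev_se_mV=e_rev_se,
        slope_pA_per_mV=float(a),
        intercept_pA=float(b),
        residuals_pA=np.asarray(res.resid, float),
        n_points=len(v),
        weighted=weighted,
        bath=data.bath,
    )


def build_iv(analyzed: list[dict], bath: str | None = None) -> IVDataset:
    """Assemble an IVDataset from per-trace analysis records.

    Each record needs ``holding_mV`` and ``amplitude_pA`` and may carry
    ``se_pA`` and ``bath``.  Records at the same voltage are pooled: by
    inverse-variance weighting when every duplicate has a positive SE
    (yielding a smaller pooled SE), by the plain mean otherwise.

    Raises :class:`InputError` on empty input or mixed bath descriptions.
    """
    if not analyzed:
        raise InputError("no analyzed traces given")
    baths = {rec.get("bath", "") for rec in analyzed if rec.get("bath")}
    if bath is None:
        if len(baths) > 1:
            raise InputError(f"mixed bath descriptions: {sorted(baths)}")
        bath = baths.pop() if baths else ""
    by_v: dict[float, list[dict]] = {}
    for rec in analyzed:
        by_v.setdefault(float(rec["holding_mV"]), []).append(rec)
    rows = []
    for v in sorted(by_v):
        recs = by_v[v]
        amps = np.array([r["amplitude_pA"] for r in recs], float)
        ses = np.array([r.get("se_pA", np.nan) for r in recs], float)
        if len(recs) == 1:
            rows.append((v, amps[0], ses[0]))
        elif np.all(np.isfinite(ses)) and np.all(ses > 0):
            w = 1.0 / ses**2
            rows.append((v, float((w * amps).sum() / w.sum()),
                         float(np.sqrt(1.0 / w.sum()))))
        else:
            rows.append((v, float(amps.mean()),
                         float(amps.std(ddof=1) / np.sqrt(len(amps)))
                         if len(amps) > 1 else np.nan))
    df = pd.DataFrame(rows, columns=["holding_mV", "current_pA", "se_pA"])
    return IVDataset(points=df, bath=bath)
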
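"""Dose-response curves over the kinase:phosphatase ratio and Hill analysis.

The dose variable is x = log10(E/F): the kinase total E stays fixed and
the phosphatase total is set to F = E / 10**x at each grid point.  Each
point is an independent steady-state solve; curves are fit to the
logarithmic Hill function

    S(x) = S_min + (S_max - S_min) / (1 + 10**(n * (x50 - x)))

whose parameters are the response floor/ceiling S_min/S_max, the
potency x50 (the log10 kinase:phosphatase ratio giving half-maximal
response) and the Hill number n (sensitivity; n > 1 is switch-like).
An alternative, fit-free sensitivity metric log10(EC90/EC10) is also
provided; for an exact Hill curve it equals log10(81)/n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .constructs import ChainSpec, ConcentrationTotals, RateSet
from .network import generate_network
from .steady_state import (
    SteadyStateError,
    build_rate_system,
    observable,
    solve_steady_state,
)

__all__ = [
    "DoseResponse",
    "HillFit",
    "HillFitError",
    "SensitivityMetrics",
    "hill_function",
    "sweep_ratio",
    "fit_hill",
    "ec_ratio_sensitivity",
    "hill_heatmap",
    "default_grid",
]


class HillFitError(RuntimeError):
    pass


def default_grid(lo: float = -2.0, hi: float = 2.0, n: int = 61) -> np.ndarray:
    return np.linspace(lo, hi, n)


@dataclass
class DoseResponse:
    """Observable vs log10(kinase/phosphatase) for one construct."""

    x: np.ndarray  # strictly increasing log10(E/F)
    y: np.ndarray  # observable, uM
    observable: str
    construct: str = ""
    failures: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size and np.any(np.diff(self.x) <= 0):
            raise ValueError("x grid must be strictly increasing")

    def normalized(self) -> np.ndarray:
        lo, hi = self.y.min(), self.y.max()
        return (self.y - lo) / (hi - lo) if hi > lo else np.zeros_like(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_log10_EF": self.x, self.observable: self.y})


def hill_function(x, s_min, s_max, x50, n):
    """Logarithmic Hill function S(x) = S_min + (S_max-S_min)/(1+10^{n(x50-x)})."""
    return s_min + (s_max - s_min) / (1.0 + 10.0 ** (n * (x50 - np.asarray(x))))


def _plateaus_reached(x: np.ndarray, y: np.ndarray, frac: float = 0.05) -> tuple[bool, bool]:
    """Flat tails: the two outermost 3-point windows on each side agree
    to within ``frac`` of the curve range (medians, robust to noise)."""
    span = y.max() - y.min()
    if span <= 0:
        return True, True
    if y.size < 8:
        return False, False
    left = abs(np.median(y[3:6]) - np.median(y[:3])) <= frac * span
    right = abs(np.median(y[-3:]) - np.median(y[-6:-3])) <= frac * span
    return left, right


def sweep_ratio(
    spec: ChainSpec,
    rates: RateSet | None = None,
    totals: ConcentrationTotals | None = None,
    x_grid: np.ndarray | None = None,
    observable_name: str = "bound_zap",
    tol: float = 1e-8,
    t_max: float = 1e6,
    warm_start: bool = True,
    auto_extend: bool = True,
    max_extensions: int = 3,
    raise_on_failure: bool = True,
) -> DoseResponse:
    """Steady-state dose-response over a log10(E/F) grid.

    E is fixed at ``totals.kinase_total`` and F = E / 10**x.  With
    ``warm_start`` the Newton polish starts from the previous grid
    point's solution (falling back to integration from rest whenever
    the polish fails its contract).  If a plateau is not reached at
    either end, the grid is extended by one decade per side up to
    ``max_extensions`` times.  Failed points are recorded in
    ``failures`` (and raised unless ``raise_on_failure=False``), never
    interpolated.
    """
    rates = rates or RateSet()
    totals = totals or ConcentrationTotals()
    x = default_grid() if x_grid is None else np.asarray(x_grid, dtype=float)
    if x.ndim != 1 or x.size < 2 or np.any(np.diff(x) <= 0):
        raise ValueError("x_grid must be a strictly increasing 1-D grid")
    step = float(np.median(np.diff(x)))

    net = generate_network(spec, rates)
    sys = build_rate_system(net)
    E = totals.kinase_total

    cache: dict[float, float] = {}
    state_cache: dict[float, np.ndarray] = {}

    def solve_point(xi: float, x_prev: float | None) -> float:
        F = E / 10.0**xi
        tot = replace(totals, phosphatase_total=F)
        x0 = state_cache.get(x_prev) if (warm_start and x_prev is not None) else None
        st = solve_steady_state(sys, tot, tol=tol, t_max=t_max, x0=x0)
        state_cache[xi] = st.raw
        return observable(st, net, observable_name)

    failures: list[tuple[float, str]] = []

    def run_grid(xs: np.ndarray) -> None:
        prev = None
        for xi in xs:
            if xi in cache:
                prev = xi
                continue
            try:
                cache[xi] = solve_point(float(xi), prev)
                prev = xi
            except SteadyStateError as exc:
                failures.append((float(xi), str(exc)))
                if raise_on_failure:
                    raise SteadyStateError(
                        f"steady-state solve failed at x={xi:g}: {exc}",
                        residual=exc.residual,
                    ) from exc
                prev = None

    run_grid(x)
    if auto_extend:
        for _ in range(max_extensions):
            xs = np.array(sorted(cache))
            ys = np.array([cache[v] for v in xs])
            left_ok, right_ok = _plateaus_reached(xs, ys)
            if left_ok and right_ok:
                break
            if not left_ok:
                ext = np.arange(xs[0] - 1.0, xs[0], step)
                run_grid(ext[::-1])  # walk outward so warm starts stay adjacent
            if not right_ok:
                ext = np.arange(xs[-1] + step, xs[-1] + 1.0 + step / 2, step)
                run_grid(ext)

    xs = np.array(sorted(cache))
    ys = np.array([cache[v] for v in xs])
    return DoseResponse(
        xs, ys, observable=observable_name, construct=spec.name, failures=failures
    )


@dataclass
class HillFit:
    """Fitted logarithmic Hill parameters with diagnostics."""

    s_min: float
    s_max: float
    x50: float
    n: float
    rmse: float
    monotone: bool = True
    message: str = ""

    def predict(self, x):
        return hill_function(x, self.s_min, self.s_max, self.x50, self.n)

    def as_dict(self) -> dict:
        return {
            "S_min": self.s_min,
            "S_max": self.s_max,
            "x_50": self.x50,
            "n": self.n,
            "rmse": self.rmse,
        }


def _spanning(curve: DoseResponse) -> bool:
    y = curve.y
    if y.max() - y.min() <= 0:
        return False
    left, right = _plateaus_reached(curve.x, y)
    return left and right


def fit_hill(
    curve: DoseResponse,
    n_starts: int = 5,
    seed: int = 0,
    require_span: bool = True,
) -> HillFit:
    """Least-squares fit of the logarithmic Hill function.

    Initial guesses come from the data (plateaus, half-max crossing,
    n = 1); additional multi-starts jitter the guesses with a seeded
    RNG to escape local minima.  A curve that does not approach both
    plateaus raises :class:`HillFitError` advising grid extension; a
    non-monotone curve is fit anyway with ``monotone=False`` and a
    warning.
    """
    x, y = curve.x, curve.y
    if x.size < 8:
        raise HillFitError("need at least 8 points to fit a Hill function")
    if require_span and not _spanning(curve):
        raise HillFitError(
            "curve does not span both plateaus; extend the x grid "
            "(sweep_ratio(auto_extend=True) or a wider x_grid)"
        )
    monotone = bool(np.all(np.diff(y) >= -1e-9 * max(y.max() - y.min(), 1e-30)))
    if not monotone:
        warnings.warn("fitting a non-monotone dose-response curve", stacklevel=2)

    s_min0, s_max0 = float(y.min()), float(y.max())
    half = 0.5 * (s_min0 + s_max0)
    yy = np.maximum.accumulate(y)  # monotone envelope for the crossing guess
    x50_0 = float(np.interp(half, yy, x))

    def residual(params):
        return (
            hill_function(x, params["s_min"], params["s_max"], params["x50"], params["n"]) - y
        )

    rng = np.random.default_rng(seed)
    best = None
    span = max(s_max0 - s_min0, 1e-30)
    for k in range(max(1, n_starts)):
        params = Parameters()
        jit = lambda v, sc: v if k == 0 else v + sc * rng.normal()
        params.add("s_min", value=jit(s_min0, 0.05 * span))
        params.add("delta", value=max(jit(span, 0.1 * span), 1e-12 * span), min=0.0)
        params.add("s_max", expr="s_min + delta")
        params.add("x50", value=jit(x50_0, 0.3), min=x.min() - 2.0, max=x.max() + 2.0)
        params.add("n", value=max(jit(1.0, 0.5), 0.05), min=1e-3, max=100.0)
        try:
            out = minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise HillFitError("all fit attempts failed")
    p = best.params
    rmse = float(np.sqrt(np.mean(residual(p) ** 2)))
    return HillFit(
        s_min=float(p["s_min"]),
        s_max=float(p["s_max"]),
        x50=float(p["x50"]),
        n=float(p["n"]),
        rmse=rmse,
        monotone=monotone,
        message=getattr(best, "message", ""),
    )


@dataclass
class SensitivityMetrics:
    """Hill number plus the fit-free EC90/EC10 steepness metric."""

    hill_n: float
    log_ec_ratio: float  # log10(EC90 / EC10), > 0 for a rising curve


def ec_ratio_sensitivity(curve: DoseResponse, fit: HillFit | None = None) -> SensitivityMetrics:
    """log10(EC90/EC10) by monotone interpolation of the normalized curve.

    Since x is already log10(E/F), the metric is x(EC90) - x(EC10).
    For an exact Hill curve with coefficient n this equals log10(81)/n.
    """
    if fit is None:
        fit = fit_hill(curve)
    if not _spanning(curve):
        raise HillFitError("plateau not reached: cannot locate EC10/EC90")
    y = np.maximum.accumulate(curve.y)  # smooth ties / tiny non-monotonicity
    p_lo, p_hi = float(np.median(y[:3])), float(np.median(y[-3:]))
    if p_hi <= p_lo:
        raise HillFitError("flat curve: EC10/EC90 undefined")
    yn = (y - p_lo) / (p_hi - p_lo)
    keep = np.concatenate([[True], np.diff(yn) > 0])
    yi, xi = yn[keep], curve.x[keep]
    if yi.size >= 3:
        from scipy.interpolate import PchipInterpolator

        inv = PchipInterpolator(yi, xi, extrapolate=False)
        x10, x90 = float(inv(0.1)), float(inv(0.9))
        if np.isnan(x10) or np.isnan(x90):
            raise HillFitError("plateau not reached: cannot locate EC10/EC90")
    else:
        x10 = float(np.interp(0.1, yi, xi))
        x90 = float(np.interp(0.9, yi, xi))
    return SensitivityMetrics(hill_n=fit.n, log_ec_ratio=x90 - x10)


def hill_heatmap(
    base_spec: ChainSpec,
    koff1_grid,
    koff3_grid,
    koff2: float = 1.0,
    rates: RateSet | None = None,
    totals: ConcentrationTotals | None = None,
    x_grid: np.ndarray | None = None,
    metric: str = "hill_n",
) -> pd.DataFrame:
    """Hill numbers over a (koff1, koff3) grid of ZAP-70 unbinding rates.

    ``base_spec`` must be a sequential three-ITAM chain; the middle
    ITAM's unbinding rate is pinned at ``koff2``.  Rows are indexed by
    koff3 (membrane-distal ITAM), columns by koff1 (membrane-proximal);
    a failed cell is recorded as NaN, not fatal.  ``metric`` selects
    ``hill_n``, ``log_ec_ratio`` or ``both`` (a dict of the two maps
    computed from the same sweeps).
    """
    if base_spec.n_itams != 3 or base_spec.scheme != "sequential":
        raise ValueError("heat map requires a sequential three-ITAM chain")
    if metric not in ("hill_n", "log_ec_ratio", "both"):
        raise ValueError(f"unknown metric {metric!r}")
    koff1_grid = np.asarray(koff1_grid, dtype=float)
    koff3_grid = np.asarray(koff3_grid, dtype=float)
    shape = (koff3_grid.size, koff1_grid.size)
    maps = {m: np.full(shape, np.nan) for m in ("hill_n", "log_ec_ratio")}
    it3, it2, it1 = base_spec.itams
    for i, k3 in enumerate(koff3_grid):
        for j, k1 in enumerate(koff1_grid):
            spec = replace(
                base_spec,
                itams=(
                    replace(it3, zap_koff=float(k3)),
                    replace(it2, zap_koff=float(koff2)),
                    replace(it1, zap_koff=float(k1)),
                ),
                name=f"koff1={k1:g},koff3={k3:g}",
            )
            try:
                curve = sweep_ratio(spec, rates, totals, x_grid=x_grid)
                fit = fit_hill(curve)
                maps["hill_n"][i, j] = fit.n
                if metric != "hill_n":
                    maps["log_ec_ratio"][i, j] = ec_ratio_sensitivity(
                        curve, fit
                    ).log_ec_ratio
            except (SteadyStateError, HillFitError):
                pass
    frames = {
        m: pd.DataFrame(v, index=koff3_grid, columns=koff1_grid)
        for m, v in maps.items()
    }
    if metric == "both":
        return frames
    return frames[metric]
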
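"""Additive-term builders: penalised B-splines, natural cubic smoothing
splines, fractional polynomials and plain polynomial bases.

Every fit returns a :class:`SmootherState` carrying the fitted values,
the effective degrees of freedom (trace of the influence operator) and
enough state to evaluate the smooth at new points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import interpolate, linalg

__all__ = [
    "SmootherSpec",
    "SmootherState",
    "bspline_knots",
    "bspline_basis",
    "pspline_fit",
    "pspline_fit_df",
    "cubic_spline_fit",
    "fractional_poly_fit",
    "select_lambda",
]

DEFAULT_FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass
class SmootherSpec:
    """Configuration of one smooth term.

    kind : one of pspline, cubic_spline, fractional_poly, polynomial,
        linear, categorical
    knots : number of interior knots for psplines
    degree : B-spline basis degree
    penalty_order : difference order of the P-spline penalty
    df_target : requested effective degrees of freedom, or "auto" for
        GAIC-based smoothing-parameter selection
    power_set : candidate fractional-polynomial powers
    fp_degree : fractional-polynomial degree (1 or 2)
    """

    kind: str = "pspline"
    knots: int = 20
    degree: int = 3
    penalty_order: int = 2
    df_target: float | str = "auto"
    power_set: Sequence[float] = DEFAULT_FP_POWERS
    fp_degree: int = 1

    def __post_init__(self) -> None:
        if self.kind not in (
            "pspline", "cubic_spline", "fractional_poly",
            "polynomial", "linear", "categorical",
        ):
            raise ValueError(f"unknown smoother kind {self.kind!r}")
        if self.knots < self.penalty_order + 1:
            raise ValueError("knots must be >= penalty_order + 1")
        if self.fp_degree not in (1, 2):
            raise ValueError("fp_degree must be 1 or 2")
        if not isinstance(self.df_target, str) and self.df_target < 1:
            raise ValueError("df_target must be >= 1")


@dataclass
class SmootherState:
    """Fitted state of a smooth term."""

    kind: str
    fitted: np.ndarray
    edf: float
    lam: float = 0.0
    coef: Optional[np.ndarray] = None
    # pspline state
    knot_vector: Optional[np.ndarray] = None
    degree: int = 3
    x_range: Optional[tuple[float, float]] = None
    # cubic spline state: interpolator through fitted values at unique x
    _interp: Optional[Callable] = field(default=None, repr=False)
    # fractional polynomial state
    powers: Optional[tuple[float, ...]] = None
    fp_shift: float = 0.0

    def predict(self, xnew: np.ndarray) -> np.ndarray:
        xnew = np.asarray(xnew, dtype=float)
        if self.kind == "pspline":
            lo, hi = self.x_range
            xc = np.clip(xnew, lo, hi)
            B = _design_matrix(xc, self.knot_vector, self.degree)
            return B @ self.coef
        if self.kind == "cubic_spline":
            lo, hi = self.x_range
            return self._interp(np.clip(xnew, lo, hi))
        if self.kind == "fractional_poly":
            X = _fp_design(xnew + self.fp_shift, self.powers)
            return X @ self.coef
        raise ValueError(f"predict not supported for kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "edf": float(self.edf),
            "lam": float(self.lam),
            "degree": int(self.degree),
        }
        if self.coef is not None:
            d["coef"] = np.asarray(self.coef).tolist()
        if self.knot_vector is not None:
            d["knot_vector"] = np.asarray(self.knot_vector).tolist()
        if self.x_range is not None:
            d["x_range"] = [float(self.x_range[0]), float(self.x_range[1])]
        if self.powers is not None:
            d["powers"] = list(self.powers)
            d["fp_shift"] = float(self.fp_shift)
        if self.kind == "cubic_spline" and self._interp is not None:
            cs = self._interp
            d["cs_x"] = np.asarray(cs.x).tolist()
            d["cs_y"] = np.asarray(cs(cs.x)).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SmootherState":
        st = cls(
            kind=d["kind"],
            fitted=np.empty(0),
            edf=d["edf"],
            lam=d.get("lam", 0.0),
            coef=np.asarray(d["coef"]) if "coef" in d else None,
            knot_vector=(
                np.asarray(d["knot_vector"]) if "knot_vector" in d else None
            ),
            degree=d.get("degree", 3),
            x_range=tuple(d["x_range"]) if "x_range" in d else None,
            powers=tuple(d["powers"]) if "powers" in d else None,
            fp_shift=d.get("fp_shift", 0.0),
        )
        if st.kind == "cubic_spline":
            st._interp = interpolate.CubicSpline(
                np.asarray(d["cs_x"]), np.asarray(d["cs_y"]), bc_type="natural"
            )
        return st


# ---------------------------------------------------------------------------
# B-spline basis
# ---------------------------------------------------------------------------


def bspline_knots(
    lo: float, hi: float, n_interior: int, degree: int
) -> np.ndarray:
    """Equally spaced knot vector with invisible boundary knots.

    ``n_interior`` knots strictly inside (lo, hi) plus the two range ends,
    extended ``degree`` equally spaced knots beyond each side (the classic
    P-spline construction, keeping the basis a partition of unity on the
    whole of [lo, hi]).
    """
    if hi <= lo:
        raise ValueError("empty x range")
    inner = np.linspace(lo, hi, n_interior + 2)
    h = inner[1] - inner[0]
    left = lo - h * np.arange(degree, 0, -1)
    right = hi + h * np.arange(1, degree + 1)
    return np.concatenate([left, inner, right])


def _design_matrix(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo = knots[degree]
    hi = knots[len(knots) - degree - 1]
    # clamp; keep strictly inside the right edge so the last basis function
    # is picked up by the half-open interval convention
    eps = 1e-10 * max(abs(hi - lo), 1.0)
    xc = np.clip(x, lo, hi - eps)
    B = interpolate.BSpline.design_matrix(
        xc, knots, degree, extrapolate=False
    ).toarray()
    return B


def bspline_basis(x: np.ndarray, spec: SmootherSpec,
                  x_range: Optional[tuple[float, float]] = None):
    """Evaluate the P-spline B-spline basis at x.

    Returns ``(B, knot_vector)`` where rows of B sum to one. x values
    outside the knot range are clamped.
    """
    x = np.asarray(x, dtype=float)
    if x_range is None:
        lo, hi = float(np.min(x)), float(np.max(x))
    else:
        lo, hi = x_range
    n_basis = spec.knots + spec.degree + 1
    if np.unique(x).size < min(n_basis, 2):
        raise ValueError("fewer distinct x values than basis requires")
    knots = bspline_knots(lo, hi, spec.knots, spec.degree)
    return _design_matrix(x, knots, spec.degree), knots


def _difference_penalty(n_basis: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def pspline_fit(x, y, weights, spec: SmootherSpec, lam: float,
                x_range=None) -> SmootherState:
    """Penalised B-spline regression at fixed smoothing parameter.

    Solves the penalised weighted least-squares normal equations

        (B' W B + lam * D_d' D_d) a = B' W y

    with D_d the order-``penalty_order`` difference matrix; the effective
    df is the trace of the influence operator. A singular system falls
    back to a logged 1e-8 ridge on the diagonal.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    B, knots = bspline_basis(x, spec, x_range)
    P = _difference_penalty(B.shape[1], spec.penalty_order)
    BtW = B.T * w
    A = BtW @ B + lam * P
    b = BtW @ y
    try:
        cho = linalg.cho_factor(A)
        coef = linalg.cho_solve(cho, b)
        H = linalg.cho_solve(cho, BtW @ B)
    except linalg.LinAlgError:
        # logged ridge fallback, scaled to the problem
        import logging, warnings as _warnings

        logging.getLogger(__name__).info("singular P-spline system; ridge added")
        ridge = max(1e-8, 1e-10 * float(np.mean(np.diag(A)))) * np.eye(A.shape[0])
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", linalg.LinAlgWarning)
            coef = linalg.solve(A + ridge, b, assume_a="sym")
            H = linalg.solve(A + ridge, BtW @ B, assume_a="sym")
    edf = float(np.trace(H))
    lo = knots[spec.degree]
    hi = knots[len(knots) - spec.degree - 1]
    return SmootherState(
        kind="pspline",
        fitted=B @ coef,
        edf=edf,
        lam=float(lam),
        coef=coef,
        knot_vector=knots,
        degree=spec.degree,
        x_range=(float(lo), float(hi)),
    )


def _pspline_edf(BtWB: np.ndarray, P: np.ndarray, lam: float) -> float:
    A = BtWB + lam * P
    try:
        H = linalg.cho_solve(linalg.cho_factor(A), BtWB)
    except linalg.LinAlgError:
        import warnings as _warnings

        ridge = max(1e-8, 1e-10 * float(np.mean(np.diag(A))))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", linalg.LinAlgWarning)
            H = linalg.solve(A + ridge * np.eye(A.shape[0]), BtWB,
                             assume_a="sym")
    return float(np.trace(H))


def pspline_fit_df(x, y, weights, spec: SmootherSpec, df_target: float,
                   x_range=None, tol: float = 0.01) -> SmootherState:
    """P-spline fit with lambda solved so the effective df hits a target."""
    x = np.asarray(x, float)
    B, _ = bspline_basis(x, spec, x_range)
    P = _difference_penalty(B.shape[1], spec.penalty_order)
    w = np.asarray(weights, float)
    BtWB = (B.T * w) @ B
    nullspace = spec.penalty_order
    df_max = _pspline_edf(BtWB, P, 0.0)
    df_target = float(np.clip(df_target, nullspace + 1e-6, df_max))
    # bracket on log10(lambda): edf is monotone decreasing in lambda
    lo, hi = -10.0, 14.0
    f = lambda ll: _pspline_edf(BtWB, P, 10.0 ** ll) - df_target
    flo, fhi = f(lo), f(hi)
    if flo <= 0:
        return pspline_fit(x, y, weights, spec, 10.0 ** lo, x_range)
    if fhi >= 0:
        return pspline_fit(x, y, weights, spec, 10.0 ** hi, x_range)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol:
            break
        if fm > 0:
            lo = mid
        else:
            hi = mid
    return pspline_fit(x, y, weights, spec, 10.0 ** (0.5 * (lo + hi)), x_range)


# ---------------------------------------------------------------------------
# natural cubic smoothing spline
# ---------------------------------------------------------------------------


def _collapse_ties(x, y, w):
    """Collapse duplicate x by weighted averaging (documented convention).

    Values closer than 1e-8 of the data range count as ties, so that
    floating-point residue cannot create near-zero spline intervals.
    """
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]
    tol = 1e-8 * (abs(xs[-1] - xs[0]) + 1.0)
    group = np.concatenate([[0], np.cumsum(np.diff(xs) > tol)])
    wu = np.bincount(group, weights=ws)
    yu = np.bincount(group, weights=ws * ys) / wu
    xu = np.bincount(group, weights=ws * xs) / wu
    return xu, yu, wu


def _ncs_penalty(xu: np.ndarray) -> np.ndarray:
    """Green & Silverman penalty K = Q R^{-1} Q' for a natural cubic spline."""
    m = xu.size
    h = np.diff(xu)
    Q = np.zeros((m, m - 2))
    R = np.zeros((m - 2, m - 2))
    for j in range(1, m - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < m - 2:
            R[j - 1, j] = h[j] / 6.0
            R[j, j - 1] = h[j] / 6.0
    Rinv_Qt = linalg.solve(R, Q.T, assume_a="pos")
    return Q @ Rinv_Qt


def _ncs_solve(K, wu, yu, lam):
    A = lam * K + np.diag(wu)
    try:
        cho = linalg.cho_factor(A)
        f = linalg.cho_solve(cho, wu * yu)
        H = linalg.cho_solve(cho, np.diag(wu))
    except linalg.LinAlgError:
        # K is PSD only up to rounding; jitter scaled to the problem
        import warnings as _warnings

        jitter = max(1e-12, 1e-10 * float(np.mean(np.diag(A))))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", linalg.LinAlgWarning)
            Aj = A + jitter * np.eye(A.shape[0])
            f = linalg.solve(Aj, wu * yu, assume_a="sym")
            H = linalg.solve(Aj, np.diag(wu), assume_a="sym")
    return f, float(np.trace(H))


def cubic_spline_fit(x, y, weights, df_target: float) -> SmootherState:
    """Natural cubic smoothing spline with the smoothing parameter solved
    (monotone 1-D search on log lambda) so the effective df matches
    ``df_target`` within 0.01.

    Ties in x are collapsed by weighted averaging. ``df_target`` must lie
    in [2, number of distinct x]; the boundary values give the straight
    line and the interpolating spline respectively.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    xu, yu, wu = _collapse_ties(x, y, w)
    m = xu.size
    if m < 3:
        raise ValueError("need at least 3 distinct x values")
    if not (2.0 <= df_target <= m):
        raise ValueError(f"df_target must be in [2, {m}]")
    # floor aggregated weights relative to the largest: near-zero weights
    # carry no information but wreck the conditioning of the band solve
    wu = np.maximum(wu, 1e-7 * float(wu.max()))
    K = _ncs_penalty(xu)

    if df_target >= m - 1e-9:
        fu, edf = yu.copy(), float(m)
        lam = 0.0
    elif df_target <= 2.0 + 1e-9:
        # lambda -> inf limit: the weighted least-squares straight line
        X = np.column_stack([np.ones(m), xu])
        beta, *_ = np.linalg.lstsq(X * np.sqrt(wu)[:, None],
                                   yu * np.sqrt(wu), rcond=None)
        fu, edf = X @ beta, 2.0
        lam = np.inf
    else:
        lo, hi = -12.0, 16.0
        scale = float(np.mean(wu)) * (xu[-1] - xu[0]) ** 3
        f_of = lambda ll: _ncs_solve(K, wu, yu, scale * 10.0 ** ll)[1]
        # edf monotone decreasing in lambda
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            edf = f_of(mid)
            if not np.isfinite(edf):
                edf = 0.0
            if abs(edf - df_target) < 0.005:
                break
            if edf > df_target:
                lo = mid
            else:
                hi = mid
        lam = scale * 10.0 ** mid
        fu, edf = _ncs_solve(K, wu, yu, lam)

    interp = interpolate.CubicSpline(xu, fu, bc_type="natural")
    fitted = interp(np.clip(x, xu[0], xu[-1]))
    return SmootherState(
        kind="cubic_spline",
        fitted=fitted,
        edf=edf,
        lam=float(lam),
        x_range=(float(xu[0]), float(xu[-1])),
        _interp=interp,
    )


# ---------------------------------------------------------------------------
# fractional polynomials
# ---------------------------------------------------------------------------


def _fp_design(x: np.ndarray, powers: Sequence[float]) -> np.ndarray:
    """Transformed basis with intercept; repeated powers use the
    log-multiplied convention (x^p, x^p * log x); power 0 means log x."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractional polynomial basis requires x > 0")
    cols = [np.ones_like(x)]
    seen: dict[float, int] = {}
    for p in powers:
        base = np.log(x) if p == 0 else x ** p
        rep = seen.get(p, 0)
        cols.append(base * np.log(x) ** rep)
        seen[p] = rep + 1
    return np.column_stack(cols)


def fractional_poly_fit(x, y, weights, spec: SmootherSpec) -> SmootherState:
    """Best fractional-polynomial fit by residual sum of squares.

    Enumerates every power (degree 1) or unordered power pair (degree 2)
    from ``spec.power_set``; each candidate is a weighted least-squares
    regression on the transformed basis. If x has non-positive values, a
    shift to x + (1 - min x) is applied (and recorded on the state).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    shift = 0.0
    if np.min(x) <= 0:
        shift = 1.0 - float(np.min(x))
    xs = x + shift
    powers = list(spec.power_set)
    if spec.fp_degree == 1:
        candidates = [(p,) for p in powers]
    else:
        candidates = [
            (powers[i], powers[j])
            for i in range(len(powers))
            for j in range(i, len(powers))
        ]
    sw = np.sqrt(w)
    best = None
    for cand in candidates:
        X = _fp_design(xs, cand)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        rss = float(np.sum(w * (y - X @ coef) ** 2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, cand, coef, X @ coef)
    rss, cand, coef, fitted = best
    return SmootherState(
        kind="fractional_poly",
        fitted=fitted,
        edf=float(len(cand) + 1),
        coef=coef,
        powers=tuple(cand),
        fp_shift=shift,
    )


# ---------------------------------------------------------------------------
# smoothing-parameter selection
# ---------------------------------------------------------------------------


def gaic_profile(x, y, weights, spec: SmootherSpec, lambdas,
                 x_range=None, k: float = 2.0):
    """GAIC(k) of the P-spline fit over a grid of lambdas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    B, _ = bspline_basis(x, spec, x_range)
    P = _difference_penalty(B.shape[1], spec.penalty_order)
    BtW = B.T * w
    BtWB = BtW @ B
    b = BtW @ y
    n = y.size
    out = []
    for lam in lambdas:
        A = BtWB + lam * P
        try:
            cho = linalg.cho_factor(A)
            coef = linalg.cho_solve(cho, b)
            edf = float(np.trace(linalg.cho_solve(cho, BtWB)))
        except linalg.LinAlgError:
            import warnings as _warnings

            A = A + max(1e-8, 1e-10 * float(np.mean(np.diag(A)))) * np.eye(
                A.shape[0]
            )
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", linalg.LinAlgWarning)
                coef = linalg.solve(A, b, assume_a="sym")
                edf = float(np.trace(linalg.solve(A, BtWB, assume_a="sym")))
        rss = float(np.sum(w * (y - B @ coef) ** 2))
        dev = n * math.log(max(rss / n, 1e-300))
        out.append((lam, dev + k * edf, edf))
    return out


def select_lambda(x, y, weights, spec: SmootherSpec, x_range=None,
                  k: float = 2.0) -> float:
    """Deterministic GAIC(k) smoothing-parameter selection for psplines:
    a log-spaced grid scan refined by golden-section search."""
    grid = np.logspace(-6, 10, 33)
    prof = gaic_profile(x, y, weights, spec, grid, x_range, k)
    i = int(np.argmin([g for _, g, _ in prof]))
    lo = math.log(prof[max(i - 1, 0)][0])
    hi = math.log(prof[min(i + 1, len(prof) - 1)][0])
    if hi - lo < 1e-12:
        return float(prof[i][0])
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = gaic_profile(x, y, weights, spec, [math.exp(c)], x_range, k)[0][1]
    fd = gaic_profile(x, y, weights, spec, [math.exp(d)], x_range, k)[0][1]
    for _ in range(40):
        if b - a < 1e-4:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = gaic_profile(x, y, weights, spec, [math.exp(c)], x_range, k)[0][1]
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = gaic_profile(x, y, weights, spec, [math.exp(d)], x_range, k)[0][1]
    lam = math.exp(0.5 * (a + b))
    # never worse than the best grid point
    if gaic_profile(x, y, weights, spec, [lam], x_range, k)[0][1] > prof[i][1]:
        return float(prof[i][0])
    return float(lam)
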
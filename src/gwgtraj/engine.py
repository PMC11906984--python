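"""Distributional-regression fitting engine.

Fits models in which every distribution parameter (mu, sigma, nu, tau)
has its own additive predictor — parametric terms plus at most a few
smooth terms — by cyclic backfitting over the parameters:

  for each parameter in turn, form the working response
  ``z = eta + u / w`` and weights ``w = u**2`` (squared score,
  Fisher-style, floored) from the family score functions, fit the
  penalised additive terms by weighted backfitting, and accept the
  update subject to step-halving on the global deviance.

Also provides the linear / cubic-polynomial baseline fits and the
AIC/SBC model-comparison table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import distributions as dist
from .distributions import ParamSet, ShiftedResponse, family_params, param_scores
from . import smoothers as sm
from .smoothers import SmootherSpec, SmootherState

__all__ = [
    "Linear",
    "Poly",
    "Categorical",
    "Smooth",
    "ModelSpec",
    "FitControl",
    "FittedModel",
    "fit_gamlss",
    "fit_baseline",
    "compare_models",
    "default_bct_spec",
]

WEIGHT_FLOOR = 1e-10
MU_FLOOR = 1e-6
SIGMA_FLOOR = 1e-5
SIGMA_CAP = 5.0
NU_BOUND = 5.0  # |nu| beyond this is numerically indistinguishable misfit


# ---------------------------------------------------------------------------
# terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Linear:
    name: str


@dataclass(frozen=True)
class Poly:
    """Raw polynomial columns name^1 ... name^degree."""

    name: str
    degree: int = 3


@dataclass(frozen=True)
class Categorical:
    name: str


@dataclass(frozen=True)
class Smooth:
    name: str
    spec: SmootherSpec = field(default_factory=SmootherSpec)


def _term_to_dict(t) -> dict:
    if isinstance(t, Linear):
        return {"type": "linear", "name": t.name}
    if isinstance(t, Poly):
        return {"type": "poly", "name": t.name, "degree": t.degree}
    if isinstance(t, Categorical):
        return {"type": "categorical", "name": t.name}
    if isinstance(t, Smooth):
        return {"type": "smooth", "name": t.name,
                "spec": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in t.spec.__dict__.items()}}
    raise TypeError(f"unknown term {t!r}")


def _term_from_dict(d: dict):
    if d["type"] == "linear":
        return Linear(d["name"])
    if d["type"] == "poly":
        return Poly(d["name"], d["degree"])
    if d["type"] == "categorical":
        return Categorical(d["name"])
    if d["type"] == "smooth":
        spec = dict(d["spec"])
        if "power_set" in spec:
            spec["power_set"] = tuple(spec["power_set"])
        return Smooth(d["name"], SmootherSpec(**spec))
    raise ValueError(f"unknown term type {d['type']!r}")


@dataclass
class FitControl:
    max_outer: int = 50
    deviance_tol: float = 1e-3
    max_inner: int = 5
    step_halvings: int = 5
    freeze_shape_iters: int = 2  # nu, tau held at init for first outer loops


@dataclass
class ModelSpec:
    """Model formula: per-parameter term lists plus fitting control.

    An intercept is always included in every parameter's predictor; term
    lists add covariate and smooth terms on top of it.
    """

    family: str = "BCT"
    mu: Sequence = ()
    sigma: Sequence = ()
    nu: Sequence = ()
    tau: Sequence = ()
    shift_delta: float = 30.0
    control: FitControl = field(default_factory=FitControl)
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in dist.FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        for pname in ("nu", "tau"):
            if pname not in family_params(self.family) and len(
                getattr(self, pname)
            ):
                raise ValueError(f"{self.family} has no {pname} predictor")

    def terms_for(self, pname: str) -> tuple:
        return tuple(getattr(self, pname))


def default_bct_spec(
    smoother: str = "pspline",
    mu_df: float = 8.0,
    sigma_df: float = 4.0,
    covariates: bool = True,
    shift_delta: float = 30.0,
    label: str = "",
) -> ModelSpec:
    """The workhorse configuration: smooth gestation effects on location
    and scale, covariates on location, intercept-only shape parameters."""
    if smoother == "pspline":
        mu_s = Smooth("gest_age_weeks", SmootherSpec(df_target=mu_df))
        sg_s = Smooth("gest_age_weeks", SmootherSpec(df_target=sigma_df))
    elif smoother == "cubic_spline":
        mu_s = Smooth(
            "gest_age_weeks", SmootherSpec(kind="cubic_spline", df_target=mu_df)
        )
        sg_s = Smooth(
            "gest_age_weeks",
            SmootherSpec(kind="cubic_spline", df_target=sigma_df),
        )
    elif smoother == "fractional_poly":
        mu_s = Smooth(
            "gest_age_weeks", SmootherSpec(kind="fractional_poly", fp_degree=2)
        )
        sg_s = Smooth(
            "gest_age_weeks", SmootherSpec(kind="fractional_poly", fp_degree=1)
        )
    else:
        raise ValueError(f"unknown smoother {smoother!r}")
    mu_terms = [mu_s]
    if covariates:
        mu_terms += [
            Linear("age_years"),
            Linear("bmi"),
            Categorical("ethnicity_region"),
            Categorical("parity_class"),
        ]
    return ModelSpec(
        family="BCT",
        mu=mu_terms,
        sigma=[sg_s],
        shift_delta=shift_delta,
        label=label or f"BCT-{smoother}",
    )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


class _ParamDesign:
    """Parametric design matrix + smooth terms of one parameter."""

    def __init__(self, terms, data: pd.DataFrame):
        self.terms = terms
        self.colnames = ["(Intercept)"]
        self.levels: dict[str, list] = {}
        self.smooths: list[Smooth] = []
        self.smooth_ranges: list[tuple[float, float]] = []
        cols = [np.ones(len(data))]
        for t in terms:
            if isinstance(t, Linear):
                self._require(data, t.name)
                cols.append(data[t.name].to_numpy(dtype=float))
                self.colnames.append(t.name)
            elif isinstance(t, Poly):
                self._require(data, t.name)
                x = data[t.name].to_numpy(dtype=float)
                for d in range(1, t.degree + 1):
                    cols.append(x ** d)
                    self.colnames.append(f"{t.name}^{d}")
            elif isinstance(t, Categorical):
                self._require(data, t.name)
                vals = data[t.name].astype(str)
                levels = sorted(vals.unique())
                self.levels[t.name] = levels
                for lev in levels[1:]:  # first level is the reference
                    cols.append((vals == lev).to_numpy(dtype=float))
                    self.colnames.append(f"{t.name}[{lev}]")
            elif isinstance(t, Smooth):
                self._require(data, t.name)
                x = data[t.name].to_numpy(dtype=float)
                self.smooths.append(t)
                self.smooth_ranges.append((float(x.min()), float(x.max())))
            else:
                raise TypeError(f"unknown term {t!r}")
        self.X = np.column_stack(cols)
        self.n_param_cols = self.X.shape[1]

    @staticmethod
    def _require(data, name):
        if name not in data.columns:
            raise KeyError(f"covariate {name!r} not found in data")

    def matrix_for(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))]
        for t in self.terms:
            if isinstance(t, Linear):
                cols.append(data[t.name].to_numpy(dtype=float))
            elif isinstance(t, Poly):
                x = data[t.name].to_numpy(dtype=float)
                cols.extend(x ** d for d in range(1, t.degree + 1))
            elif isinstance(t, Categorical):
                vals = data[t.name].astype(str)
                levels = self.levels[t.name]
                unseen = set(vals.unique()) - set(levels)
                if unseen:
                    raise ValueError(
                        f"unseen {t.name} categories: {sorted(unseen)}"
                    )
                cols.extend(
                    (vals == lev).to_numpy(dtype=float) for lev in levels[1:]
                )
        return np.column_stack(cols)


def _wls(X: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, res, rank, sv = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient parametric design")
    return beta


def _fit_smooth(term: Smooth, x, z, w, x_range) -> SmootherState:
    spec = term.spec
    if spec.kind == "pspline":
        if spec.df_target == "auto":
            lam = sm.select_lambda(x, z, w, spec, x_range)
            return sm.pspline_fit(x, z, w, spec, lam, x_range)
        return sm.pspline_fit_df(x, z, w, spec, float(spec.df_target), x_range)
    if spec.kind == "cubic_spline":
        df = 8.0 if spec.df_target == "auto" else float(spec.df_target)
        return sm.cubic_spline_fit(x, z, w, df)
    if spec.kind == "fractional_poly":
        return sm.fractional_poly_fit(x, z, w, spec)
    raise ValueError(f"{spec.kind!r} cannot be used as a smooth term")


def _center_state(state: SmootherState, c: float) -> SmootherState:
    """Shift a smooth contribution by -c (absorbed by the intercept)."""
    state.fitted = state.fitted - c
    if state.kind == "pspline":
        state.coef = state.coef - c
    elif state.kind == "cubic_spline":
        from scipy import interpolate as _ip

        xs = state._interp.x
        state._interp = _ip.CubicSpline(
            xs, state._interp(xs) - c, bc_type="natural"
        )
    elif state.kind == "fractional_poly":
        state.coef = state.coef.copy()
        state.coef[0] -= c
    return state


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """State of a fitted distributional regression model."""

    family: str
    spec: ModelSpec
    designs: dict[str, _ParamDesign]
    coefs: dict[str, np.ndarray]
    smooth_states: dict[str, list[SmootherState]]
    fitted_params: dict[str, np.ndarray]
    deviance: float
    edf: float
    n: int
    converged: bool
    iterations: int
    convergence_log: list = field(default_factory=list)
    y_model_scale: np.ndarray = field(default=None, repr=False)
    shift: Optional[ShiftedResponse] = None
    label: str = ""
    _null_deviance: Optional[float] = field(default=None, repr=False)

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.edf

    @property
    def sbc(self) -> float:
        return self.deviance + math.log(self.n) * self.edf

    def predict_eta(self, pname: str, data: pd.DataFrame) -> np.ndarray:
        des = self.designs[pname]
        eta = des.matrix_for(data) @ self.coefs[pname]
        for t, st in zip(des.smooths, self.smooth_states[pname]):
            eta = eta + st.predict(data[t.name].to_numpy(dtype=float))
        return eta

    def predict_params(self, data: pd.DataFrame) -> ParamSet:
        vals = {}
        for pname in family_params(self.family):
            eta = self.predict_eta(pname, data)
            vals[pname] = _theta_from_eta(pname, eta, self.family)
        return ParamSet(**vals)

    def param_set(self) -> ParamSet:
        return ParamSet(
            **{k: v for k, v in self.fitted_params.items()}
        )

    def null_deviance(self) -> float:
        """Deviance of the intercept-only model of the same family on the
        same (model-scale) response; cached."""
        if self._null_deviance is None:
            ydf = pd.DataFrame({"_y": self.y_model_scale})
            nspec = ModelSpec(
                family=self.family,
                shift_delta=self.spec.shift_delta,
                control=replace(self.spec.control, max_outer=100),
                label="null",
            )
            nfit = _fit_core(ydf, self.y_model_scale, nspec)
            self._null_deviance = nfit.deviance
        return self._null_deviance

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "label": self.label,
            "shift_delta": self.spec.shift_delta,
            "deviance": self.deviance,
            "edf": self.edf,
            "n": self.n,
            "converged": self.converged,
            "iterations": self.iterations,
            "params": {},
        }
        for pname in family_params(self.family):
            des = self.designs[pname]
            d["params"][pname] = {
                "terms": [_term_to_dict(t) for t in des.terms],
                "coef": self.coefs[pname].tolist(),
                "colnames": des.colnames,
                "levels": des.levels,
                "smooths": [st.to_dict() for st in self.smooth_states[pname]],
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        family = d["family"]
        spec_kwargs = {"family": family, "shift_delta": d["shift_delta"],
                       "label": d.get("label", "")}
        designs, coefs, sstates = {}, {}, {}
        for pname, pd_ in d["params"].items():
            terms = [_term_from_dict(t) for t in pd_["terms"]]
            spec_kwargs[pname] = [
                t for t in terms if not isinstance(t, Smooth)
            ] + [t for t in terms if isinstance(t, Smooth)]
            des = _ParamDesign.__new__(_ParamDesign)
            des.terms = tuple(terms)
            des.colnames = pd_["colnames"]
            des.levels = {k: list(v) for k, v in pd_["levels"].items()}
            des.smooths = [t for t in terms if isinstance(t, Smooth)]
            des.smooth_ranges = []
            designs[pname] = des
            coefs[pname] = np.asarray(pd_["coef"])
            sstates[pname] = [
                SmootherState.from_dict(s) for s in pd_["smooths"]
            ]
        spec = ModelSpec(**spec_kwargs)
        return cls(
            family=family,
            spec=spec,
            designs=designs,
            coefs=coefs,
            smooth_states=sstates,
            fitted_params={},
            deviance=d["deviance"],
            edf=d["edf"],
            n=d["n"],
            converged=d["converged"],
            iterations=d["iterations"],
            shift=ShiftedResponse(d["shift_delta"])
            if family != "NO"
            else None,
            label=d.get("label", ""),
        )


def _theta_from_eta(pname: str, eta: np.ndarray, family: str) -> np.ndarray:
    if dist.LINKS[pname] == "identity":
        if pname == "mu" and family != "NO":
            return np.maximum(eta, MU_FLOOR)
        if pname == "nu":
            return np.clip(eta, -NU_BOUND, NU_BOUND)
        return eta
    theta = np.exp(np.clip(eta, -50.0, 50.0))
    if pname == "sigma":
        return np.clip(theta, SIGMA_FLOOR, SIGMA_CAP)
    if pname == "tau":
        return np.clip(theta, dist.TAU_FLOOR, dist.TAU_CAP)
    return theta


def _eta_from_theta(pname: str, theta: np.ndarray) -> np.ndarray:
    if dist.LINKS[pname] == "identity":
        return np.asarray(theta, dtype=float)
    return np.log(np.asarray(theta, dtype=float))


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def _binned_curves(t: np.ndarray, y: np.ndarray, n_bins: int = 20):
    """Running median / spread of y against t via quantile bins."""
    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    n = ts.size
    n_bins = int(np.clip(n // 30, 3, n_bins))
    edges = np.quantile(ts, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    centers, med, spread = [], [], []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        mask = (ts >= lo) & (ts <= hi if i == len(edges) - 2 else ts < hi)
        if mask.sum() < 3:
            continue
        centers.append(0.5 * (lo + hi))
        med.append(np.median(ys[mask]))
        spread.append(np.std(ys[mask]))
    centers = np.asarray(centers)
    med = np.asarray(med)
    spread = np.maximum(np.asarray(spread), 1e-3)
    mu0 = np.interp(t, centers, med)
    sd0 = np.interp(t, centers, spread)
    return mu0, sd0


def _initialise(data: pd.DataFrame, y: np.ndarray, spec: ModelSpec):
    family = spec.family
    smooth_vars = [
        t.name
        for pname in family_params(family)
        for t in spec.terms_for(pname)
        if isinstance(t, Smooth)
    ]
    if smooth_vars and smooth_vars[0] in data.columns:
        tvar = data[smooth_vars[0]].to_numpy(dtype=float)
        mu0, sd0 = _binned_curves(tvar, y)
    else:
        mu0 = np.full(y.size, float(np.mean(y)))
        sd0 = np.full(y.size, float(np.std(y)) + 1e-6)
    theta = {"mu": mu0}
    if family == "NO":
        theta["sigma"] = np.maximum(sd0, SIGMA_FLOOR)
    else:
        mu0 = np.maximum(mu0, 10.0 * MU_FLOOR)
        theta["mu"] = mu0
        cv = np.clip(sd0 / mu0, 1e-3, 1.0)
        theta["sigma"] = cv
        theta["nu"] = np.full(y.size, 1.0)
        if "tau" in family_params(family):
            theta["tau"] = np.full(
                y.size, 2.0 if family == "BCPE" else 10.0
            )
    return theta


# ---------------------------------------------------------------------------
# core fitting loop
# ---------------------------------------------------------------------------


def _deviance(family: str, y: np.ndarray, theta: dict) -> float:
    p = ParamSet(**{k: theta.get(k) for k in ("mu", "sigma", "nu", "tau")
                    if k in family_params(family)})
    ll = dist.family_logpdf(family, y, p)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return float(-2.0 * np.sum(ll))


def _paramset_for(family: str, theta: dict) -> ParamSet:
    return ParamSet(
        **{k: theta[k] for k in family_params(family)}
    )


def _backfit_parameter(
    design: _ParamDesign,
    data: pd.DataFrame,
    z: np.ndarray,
    w: np.ndarray,
    beta: np.ndarray,
    states: list,
    control: FitControl,
):
    """Weighted backfit of the additive terms of one parameter.

    Returns (eta, beta, states). Smooth contributions are centered, the
    constant being absorbed by the parametric intercept.
    """
    contribs = [
        st.fitted if st is not None else np.zeros(len(data))
        for st in states
    ]
    new_states: list = list(states)
    for _ in range(max(control.max_inner, 1)):
        prev = beta.copy()
        resid = z - np.sum(contribs, axis=0) if contribs else z
        beta = _wls(design.X, resid, w)
        par = design.X @ beta
        for j, t in enumerate(design.smooths):
            others = par + np.sum(
                [c for i, c in enumerate(contribs) if i != j], axis=0
            ) if len(contribs) > 1 else par
            x = data[t.name].to_numpy(dtype=float)
            st = _fit_smooth(t, x, z - others, w, design.smooth_ranges[j])
            c = float(np.average(st.fitted, weights=w))
            st = _center_state(st, c)
            beta = beta.copy()
            beta[0] += c
            par = design.X @ beta
            new_states[j] = st
            contribs[j] = st.fitted
        if not design.smooths:
            break
        if np.max(np.abs(beta - prev)) < 1e-8 * (1 + np.max(np.abs(beta))):
            break
    eta = design.X @ beta + (
        np.sum(contribs, axis=0) if contribs else 0.0
    )
    return eta, beta, new_states


def fit_gamlss(
    data: pd.DataFrame, spec: ModelSpec, start: Optional[dict] = None
) -> FittedModel:
    """Fit a distributional regression model by cyclic backfitting.

    ``data`` is a preprocessed observation table (gain scores plus
    covariates). For Box-Cox families the response is shifted by
    ``spec.shift_delta`` onto the positive scale before fitting.
    ``start`` optionally warm-starts the per-observation parameter values
    (a mapping name -> array, e.g. a previous fit's ``fitted_params``).
    """
    family = spec.family
    control = spec.control
    shift = None
    y = data["gwg_kg"].to_numpy(dtype=float)
    if family != "NO":
        shift = ShiftedResponse(spec.shift_delta)
        y = shift.to_model_scale(y)
    n = y.size
    pnames = family_params(family)

    designs = {
        pname: _ParamDesign(spec.terms_for(pname), data) for pname in pnames
    }
    total_cols = sum(d.n_param_cols for d in designs.values())
    if n <= total_cols:
        raise ValueError("more requested parameters than observations")

    if start is not None:
        theta = {
            p: np.broadcast_to(
                np.asarray(start[p], dtype=float), y.shape
            ).copy()
            for p in pnames
        }
    else:
        theta = _initialise(data, y, spec)
    eta = {p: _eta_from_theta(p, theta[p]) for p in pnames}
    coefs = {}
    states = {p: [None] * len(designs[p].smooths) for p in pnames}
    for p in pnames:
        # start with intercept-only representation of the initial eta
        beta = np.zeros(designs[p].n_param_cols)
        beta[0] = float(np.mean(eta[p]))
        coefs[p] = beta

    dev = _deviance(family, y, theta)
    if not np.isfinite(dev):
        raise ValueError("non-finite likelihood at initialisation")
    log = [("init", dev)]
    converged = False
    it = 0
    for it in range(1, control.max_outer + 1):
        dev_start = dev
        for p in pnames:
            if p in ("nu", "tau") and it <= control.freeze_shape_iters:
                continue
            scores = param_scores(family, y, _paramset_for(family, theta))
            u = scores[p]
            w = np.maximum(u * u, WEIGHT_FLOOR)
            step = 1.0
            accepted = False
            for _ in range(control.step_halvings + 1):
                z = eta[p] + step * (u / w)
                eta_new, beta_new, st_new = _backfit_parameter(
                    designs[p], data, z, w, coefs[p], states[p], control
                )
                theta_try = dict(theta)
                theta_try[p] = _theta_from_eta(p, eta_new, family)
                dev_try = _deviance(family, y, theta_try)
                if dev_try <= dev + 1e-9:
                    eta[p] = eta_new
                    coefs[p] = beta_new
                    states[p] = st_new
                    theta = theta_try
                    dev = dev_try
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                log.append((f"iter{it}:{p}", "rejected"))
        log.append((f"iter{it}", dev))
        if abs(dev_start - dev) < control.deviance_tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"fit did not converge in {control.max_outer} outer iterations "
            f"(last deviance change "
            f"{abs(dev_start - dev):.3g})",
            RuntimeWarning,
            stacklevel=2,
        )

    edf = 0.0
    for p in pnames:
        edf += designs[p].n_param_cols
        for st in states[p]:
            if st is not None:
                # centered smooth: its constant is already in the intercept
                edf += max(st.edf - 1.0, 0.0)
    return FittedModel(
        family=family,
        spec=spec,
        designs=designs,
        coefs=coefs,
        smooth_states={
            p: [st for st in states[p] if st is not None] for p in pnames
        },
        fitted_params=theta,
        deviance=dev,
        edf=float(edf),
        n=n,
        converged=converged,
        iterations=it,
        convergence_log=log,
        y_model_scale=y,
        shift=shift,
        label=spec.label or family,
    )


def _fit_core(data: pd.DataFrame, y: np.ndarray, spec: ModelSpec):
    """Intercept-only helper used for null deviances."""
    df = data.copy()
    if spec.family != "NO":
        df["gwg_kg"] = y - spec.shift_delta
    else:
        df["gwg_kg"] = y
    return fit_gamlss(df, spec)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def fit_baseline(
    data: pd.DataFrame,
    which: str = "linear",
    covariates: bool = True,
) -> FittedModel:
    """Normal-family baseline fits by exact least squares.

    ``which`` is "linear" (gestation as a single linear term) or
    "cubic_polynomial" (adds squared and cubic gestation terms); other
    covariates enter as linear/categorical terms. Both are returned in
    the same FittedModel shape as the GAMLSS fits so diagnostics and the
    comparison table are uniform.
    """
    if which == "linear":
        gterms = [Linear("gest_age_weeks")]
    elif which == "cubic_polynomial":
        gterms = [Poly("gest_age_weeks", 3)]
    else:
        raise ValueError("which must be 'linear' or 'cubic_polynomial'")
    terms = list(gterms)
    if covariates:
        terms += [
            Linear("age_years"),
            Linear("bmi"),
            Categorical("ethnicity_region"),
            Categorical("parity_class"),
        ]
    spec = ModelSpec(family="NO", mu=terms, label=which)
    design = _ParamDesign(terms, data)
    y = data["gwg_kg"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design.X, y, rcond=None)
    if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient baseline design")
    mu = design.X @ beta
    resid = y - mu
    sigma = float(np.sqrt(np.mean(resid ** 2)))
    sigma = max(sigma, SIGMA_FLOOR)
    sdes = _ParamDesign((), data)
    theta = {"mu": mu, "sigma": np.full(y.size, sigma)}
    dev = _deviance("NO", y, theta)
    edf = design.X.shape[1] + 1
    return FittedModel(
        family="NO",
        spec=spec,
        designs={"mu": design, "sigma": sdes},
        coefs={"mu": beta, "sigma": np.asarray([math.log(sigma)])},
        smooth_states={"mu": [], "sigma": []},
        fitted_params=theta,
        deviance=dev,
        edf=float(edf),
        n=y.size,
        converged=True,
        iterations=1,
        convergence_log=[("ols", dev)],
        y_model_scale=y,
        shift=None,
        label=which,
    )


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


def compare_models(
    fits: Sequence[FittedModel], labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """AIC/SBC/generalised-R2 ranking table, ascending by AIC.

    All fits must be on the identical observation set. Ties on AIC are
    broken by SBC, then label.
    """
    if labels is None:
        labels = [f.label or f.family for f in fits]
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits compare different numbers of observations")
    from .diagnostics import generalized_r2

    rows = []
    for f, lab in zip(fits, labels):
        rows.append(
            {
                "label": lab,
                "deviance": f.deviance,
                "edf": f.edf,
                "AIC": f.aic,
                "SBC": f.sbc,
                "R2": generalized_r2(f),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["AIC", "SBC", "label"], kind="stable"
    ).reset_index(drop=True)
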
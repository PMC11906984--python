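"""Synthetic antenatal cohort generator.

Produces cohorts whose marginal structure matches the published registry
summary (maternal age, 13 country-of-birth regions, parity, delivery
gestation, visit counts) together with a known ground-truth
distributional model for the gain scores, so that every downstream
stage — preprocessing, model fitting, diagnostics, centile charts — is
testable without any external data.

Randomness flows from a single seed through three documented substreams
(cohort -> visits -> weights), so partial regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import ParamSet, _bc_quantile

__all__ = [
    "DEFAULT_ETHNICITY_PROBS",
    "DEFAULT_COVARIATE_OFFSETS",
    "CohortConfig",
    "TruthModel",
    "generate_cohort",
    "generate_visits",
    "generate_weights",
    "simulate_dataset",
    "truth_centiles",
]

#: registry summary counts the generator marginals emulate (also inputs
#: to the acceptance report's percentage recomputations)
REGISTRY_SUMMARY: dict[str, object] = {
    "n_women": 39846,
    "n_measurements": 109339,
    "sensitivity_subset": 5713,
    "ethnicity_counts": {
        "Australian/European": 16503,
        "Polynesian": 611,
        "Mainland Asian": 2945,
        "Maritime Asian": 1595,
        "Northeast Asian": 1953,
        "South central Asian": 9073,
        "African": 1327,
        "Indigenous/Torres Strait Island": 288,
        "South America": 205,
        "Southeast Europe": 2970,
        "Eastern Europe": 1198,
        "North Africa and the Middle East": 509,
        "Other": 669,
    },
}

#: region -> printed cohort percentage, renormalised at use
DEFAULT_ETHNICITY_PROBS: dict[str, float] = {
    "Australian/European": 41.4,
    "Polynesian": 1.5,
    "Mainland Asian": 7.4,
    "Maritime Asian": 4.0,
    "Northeast Asian": 4.9,
    "South central Asian": 22.8,
    "African": 3.3,
    "Indigenous/Torres Strait Island": 0.7,
    "South America": 0.5,
    "Southeast Europe": 7.5,
    "Eastern Europe": 3.0,
    "North Africa and the Middle East": 1.3,
    "Other": 1.7,
}

PARITY_CLASSES = ("0", "1-3", ">3")

#: additive kg effects on the gain median; signs/magnitudes follow the
#: linear-model defaults used as synthetic truth
DEFAULT_COVARIATE_OFFSETS: dict[str, object] = {
    "age_per_year": -0.016,       # centred at the cohort mean age
    "bmi_per_unit": -0.106,       # centred at BMI 24
    "parity": {"0": 0.0, "1-3": -0.717, ">3": -1.532},
    "ethnicity": {
        "Australian/European": 0.0,
        "Polynesian": 0.254,
        "Mainland Asian": -1.11,
        "Maritime Asian": -0.788,
        "Northeast Asian": -0.7,
        "South central Asian": -0.859,
        "African": -1.483,
        "Indigenous/Torres Strait Island": -0.473,
        "South America": -0.336,
        "Southeast Europe": -0.677,
        "Eastern Europe": 0.405,
        "North Africa and the Middle East": -0.211,
        "Other": -0.086,
    },
}

AGE_CENTRE = 28.4
BMI_CENTRE = 24.0
MAX_GESTATION = 43.0
MIN_VISIT_WEEK = 4.0


def _normalise_probs(probs: Mapping[str, float]) -> dict[str, float]:
    vals = np.asarray(list(probs.values()), dtype=float)
    if np.any(vals < 0) or np.any(vals > 100) or vals.sum() <= 0:
        raise ValueError("malformed probability mapping")
    vals = vals / vals.sum()
    return dict(zip(probs.keys(), vals))


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort marginals."""

    n_women: int = 1000
    seed: int = 0
    age_mean: float = 28.4
    age_sd: float = 4.86
    ethnicity_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_PROBS)
    )
    parity_probs: Sequence[float] = (0.403, 0.560, 0.038)
    gestation_mean: float = 38.9
    gestation_sd: float = 1.71
    visits_mean: float = 2.85
    visits_min: int = 1
    visits_max: int = 21
    self_report_error_sd: float = 0.70
    # BMI marginal (log-normal, right-skewed): not printed in the summary
    # table, chosen to give a realistic mean ~24 kg/m^2
    bmi_log_mean: float = field(default=float(np.log(23.5)), repr=False)
    bmi_log_sd: float = 0.18
    height_mean_m: float = 1.62
    height_sd_m: float = 0.07

    def __post_init__(self) -> None:
        if self.n_women <= 0:
            raise ValueError("n_women must be positive")
        if min(self.age_sd, self.gestation_sd, self.self_report_error_sd) <= 0:
            raise ValueError("all SDs must be positive")
        if self.visits_min > self.visits_max or self.visits_min < 1:
            raise ValueError("need 1 <= visits_min <= visits_max")
        p = np.asarray(self.parity_probs, dtype=float)
        if p.size != 3 or np.any(p < 0) or p.sum() <= 0:
            raise ValueError("parity_probs must be 3 non-negative values")
        self.parity_probs = tuple(p / p.sum())
        self.ethnicity_probs = _normalise_probs(self.ethnicity_probs)

    def spawn_rngs(self) -> dict[str, np.random.Generator]:
        """Documented substream order: cohort -> visits -> weights."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "cohort": np.random.default_rng(children[0]),
            "visits": np.random.default_rng(children[1]),
            "weights": np.random.default_rng(children[2]),
        }


def _default_median_curve(t):
    """Median gain in kg at gestation t: ~11 kg at 40 weeks."""
    t = np.asarray(t, dtype=float)
    return 0.0025 * t ** 2 + 0.18 * t


def _default_sigma_curve(t):
    """Coefficient of variation on the shifted scale, increasing in t."""
    t = np.asarray(t, dtype=float)
    return 0.012 + 0.0018 * t


@dataclass
class TruthModel:
    """Ground-truth generating model for gain scores.

    The true gain at gestation t for a woman with covariate offset d is a
    draw from the shifted Box-Cox t law:

        gain = BCT(mu = shift_delta + median_curve(t) + d,
                   sigma = sigma_curve(t), nu, tau) - shift_delta
    """

    median_curve: Callable = _default_median_curve
    sigma_curve: Callable = _default_sigma_curve
    nu_const: float = -1.5
    tau_const: float = 8.0
    covariate_offsets: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_OFFSETS)
    )
    shift_delta: float = 30.0
    family: str = "BCT"

    def __post_init__(self) -> None:
        if self.tau_const <= 0:
            raise ValueError("tau_const must be positive")
        if self.shift_delta <= 0:
            raise ValueError("shift_delta must be positive")
        if abs(float(self.median_curve(0.0))) > 1e-9:
            raise ValueError("median_curve(0) must be 0")
        tt = np.linspace(0.0, MAX_GESTATION, 200)
        if np.any(np.asarray(self.sigma_curve(tt)) <= 0):
            raise ValueError("sigma_curve must be positive on [0, 43]")
        m = np.asarray(self.median_curve(tt))
        if np.any(np.diff(m) < -1e-9):
            raise ValueError("median_curve must be non-decreasing on [0, 43]")

    def offset(self, age, bmi, parity_class, ethnicity_region) -> np.ndarray:
        """Additive kg offset for a covariate profile (vectorised)."""
        off = self.covariate_offsets
        age = np.asarray(age, dtype=float)
        bmi = np.asarray(bmi, dtype=float)
        par = np.asarray(
            [off["parity"][p] for p in np.atleast_1d(parity_class)]
        )
        eth = np.asarray(
            [off["ethnicity"][e] for e in np.atleast_1d(ethnicity_region)]
        )
        return (
            off["age_per_year"] * (age - AGE_CENTRE)
            + off["bmi_per_unit"] * (bmi - BMI_CENTRE)
            + par
            + eth
        )

    def params_at(self, t, offset) -> ParamSet:
        """Truth BCT parameters on the shifted scale at gestation t."""
        t = np.asarray(t, dtype=float)
        mu = self.shift_delta + np.asarray(self.median_curve(t)) + offset
        return ParamSet(
            mu=mu,
            sigma=np.asarray(self.sigma_curve(t)),
            nu=self.nu_const,
            tau=self.tau_const,
        )

    def sample_gains(self, t, offset, rng: np.random.Generator) -> np.ndarray:
        """Draw true gains by inverse transform at gestations t."""
        p = self.params_at(t, offset)
        u = rng.uniform(size=np.asarray(t).shape)
        y = _bc_quantile(self.family, u, p.mu, p.sigma, p.nu, p.tau)
        return y - self.shift_delta


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """One row per woman: demographics and anthropometry.

    Columns: woman_id, age_years, ethnicity_region, parity_class,
    height_m, bmi_true, prepreg_weight_true_kg, prepreg_weight_kg
    (the self-reported value, perturbed in generate_weights),
    delivery_weeks.
    """
    if rng is None:
        rng = config.spawn_rngs()["cohort"]
    n = config.n_women
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 15.0, 55.0)
    regions = list(config.ethnicity_probs.keys())
    probs = np.asarray(list(config.ethnicity_probs.values()))
    eth = rng.choice(regions, size=n, p=probs)
    parity = rng.choice(PARITY_CLASSES, size=n, p=config.parity_probs)
    height = np.clip(
        rng.normal(config.height_mean_m, config.height_sd_m, n), 1.35, 2.05
    )
    bmi = np.exp(rng.normal(config.bmi_log_mean, config.bmi_log_sd, n))
    weight_true = bmi * height ** 2
    delivery = np.minimum(
        rng.normal(config.gestation_mean, config.gestation_sd, n),
        MAX_GESTATION,
    )
    delivery = np.maximum(delivery, MIN_VISIT_WEEK + 1.0)
    return pd.DataFrame(
        {
            "woman_id": np.arange(n, dtype=np.int64),
            "age_years": age,
            "ethnicity_region": eth,
            "parity_class": parity,
            "height_m": height,
            "bmi_true": bmi,
            "prepreg_weight_true_kg": weight_true,
            "delivery_weeks": delivery,
        }
    )


def generate_visits(cohort: pd.DataFrame, config: CohortConfig,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Per-woman antenatal visit schedule.

    Visit counts follow a +1-shifted Poisson truncated to
    [visits_min, visits_max]; visit gestational ages are Beta(2, 1.2)
    draws scaled to (4, delivery] (denser late), rounded to 0.1 weeks and
    made strictly increasing.
    """
    if rng is None:
        rng = config.spawn_rngs()["visits"]
    if np.any(cohort["delivery_weeks"] <= MIN_VISIT_WEEK):
        raise ValueError("delivery gestation at or below the first-visit bound")
    rate = max(config.visits_mean - 1.0, 1e-6)
    n = len(cohort)
    counts = 1 + rng.poisson(rate, size=n)
    counts = np.clip(counts, config.visits_min, config.visits_max)
    rows_id, rows_t = [], []
    delivery = cohort["delivery_weeks"].to_numpy()
    ids = cohort["woman_id"].to_numpy()
    for i in range(n):
        k = counts[i]
        u = np.sort(rng.beta(2.0, 1.2, size=k))
        t = MIN_VISIT_WEEK + u * (delivery[i] - MIN_VISIT_WEEK)
        # 0.1-week recording resolution; keep the support open at week 4
        t = np.maximum(np.round(t, 1), MIN_VISIT_WEEK + 0.1)
        # enforce strictly increasing after rounding
        for j in range(1, k):
            if t[j] <= t[j - 1]:
                t[j] = t[j - 1] + 0.1
        t = np.round(t, 1)  # normalise accumulated fp residue
        t = t[t <= delivery[i]]
        if t.size == 0:
            t = np.asarray(
                [max(np.floor(delivery[i] * 10.0) / 10.0,
                     MIN_VISIT_WEEK + 0.1)]
            )
        rows_id.append(np.full(t.size, ids[i]))
        rows_t.append(t)
    return pd.DataFrame(
        {
            "woman_id": np.concatenate(rows_id),
            "gest_age_weeks": np.concatenate(rows_t),
        }
    )


def generate_weights(
    visits: pd.DataFrame,
    cohort: pd.DataFrame,
    truth: TruthModel,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
    measurement_error: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach measured weights to the visit schedule.

    measured weight = true pre-pregnancy weight + true gain draw
    [+ N(0, self_report_error_sd^2) measurement noise]; the cohort gains a
    ``prepreg_weight_kg`` column holding the self-reported value (true
    weight plus an independent error of the same SD).

    Returns ``(visits_with_weights, cohort_with_selfreport)``.
    """
    if rng is None:
        rng = config.spawn_rngs()["weights"]
    cohort = cohort.copy()
    sd = config.self_report_error_sd
    report_err = rng.normal(0.0, sd, len(cohort)) if measurement_error else 0.0
    cohort["prepreg_weight_kg"] = (
        cohort["prepreg_weight_true_kg"].to_numpy() + report_err
    )
    merged = visits.merge(
        cohort[
            [
                "woman_id", "age_years", "bmi_true", "parity_class",
                "ethnicity_region", "prepreg_weight_true_kg",
            ]
        ],
        on="woman_id",
        how="left",
    )
    offsets = truth.offset(
        merged["age_years"].to_numpy(),
        merged["bmi_true"].to_numpy(),
        merged["parity_class"].to_numpy(),
        merged["ethnicity_region"].to_numpy(),
    )
    gains = truth.sample_gains(
        merged["gest_age_weeks"].to_numpy(), offsets, rng
    )
    noise = (
        rng.normal(0.0, sd, len(merged)) if measurement_error else 0.0
    )
    out = visits.copy()
    out["weight_kg"] = (
        merged["prepreg_weight_true_kg"].to_numpy() + gains + noise
    )
    if np.any(out["weight_kg"] <= 0):
        raise ValueError("generated non-positive weight; check truth model")
    return out, cohort


def simulate_dataset(
    config: CohortConfig, truth: Optional[TruthModel] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: cohort + visit table with weights.

    Returns ``(cohort, visits)`` where cohort carries the self-reported
    pre-pregnancy weight and visits carry measured weights.
    """
    if truth is None:
        truth = TruthModel(shift_delta=30.0)
    rngs = config.spawn_rngs()
    cohort = generate_cohort(config, rngs["cohort"])
    visits = generate_visits(cohort, config, rngs["visits"])
    visits, cohort = generate_weights(
        visits, cohort, truth, config, rngs["weights"]
    )
    return cohort, visits


def truth_centiles(
    truth: TruthModel,
    profile: Mapping[str, object],
    grid: Sequence[float],
    levels: Sequence[float] = (2.3, 16.0, 50.0, 84.0, 97.7),
) -> pd.DataFrame:
    """Exact generating-distribution quantiles on a gestation grid.

    ``profile`` needs age, bmi, parity_class, ethnicity_region. Returns a
    frame indexed by gestation with one column per level (raw kg scale);
    used as ground truth in parameter-recovery tests.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    levels = np.asarray(levels, dtype=float)
    if np.any((levels <= 0) | (levels >= 100)):
        raise ValueError("levels must lie in (0, 100)")
    off = float(
        truth.offset(
            profile["age"], profile["bmi"],
            [profile["parity_class"]], [profile["ethnicity_region"]],
        )[0]
    )
    p = truth.params_at(grid, off)
    out = {}
    for lev in levels:
        q = _bc_quantile(
            truth.family, lev / 100.0, p.mu, p.sigma, p.nu, p.tau
        )
        out[f"P{lev:g}"] = q - truth.shift_delta
    return pd.DataFrame(out, index=pd.Index(grid, name="gest_age_weeks"))
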
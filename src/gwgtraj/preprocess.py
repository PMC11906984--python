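"""Raw visit tables -> modelling-ready gain-score observations.

Covers gain-score computation, the week-0 Gaussian pseudo-observations,
the 4 SD credible-interval exclusion, BMI/ethnicity/parity coding, and
the first-visit re-baselining used in the sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WEEK0_ERROR_SD",
    "BMI_CATEGORIES",
    "BmiScheme",
    "BMI_SCHEMES",
    "scheme_for_region",
    "bmi_category",
    "week0_variance",
    "compute_gwg",
    "draw_week0",
    "exclude_4sd",
    "rebaseline_first_visit",
    "PreprocessReport",
]

#: single-weighing measurement error (kg) used for the week-0 nudge
WEEK0_ERROR_SD = 0.70

MAX_GESTATION = 43.0

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")

OBS_COLUMNS = [
    "woman_id", "gest_age_weeks", "gwg_kg", "is_week0_pseudo",
    "age_years", "bmi", "ethnicity_region", "parity_class",
]


@dataclass(frozen=True)
class BmiScheme:
    """Four exhaustive BMI categories with left-closed boundaries.

    ``cuts`` are the three internal boundaries (kg/m^2); categories are
    [0, c0), [c0, c1), [c1, c2), [c2, inf) — matching the printed
    "<18.5" / ">=30" endpoint conventions.
    """

    label: str
    cuts: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (0 < self.cuts[0] < self.cuts[1] < self.cuts[2]):
            raise ValueError("boundaries must be strictly increasing")

    def category(self, bmi) -> np.ndarray:
        bmi = np.asarray(bmi, dtype=float)
        if np.any(bmi <= 0):
            raise ValueError("bmi must be positive")
        idx = np.searchsorted(np.asarray(self.cuts), bmi, side="right")
        return np.asarray(BMI_CATEGORIES)[idx]

    def midpoints(self) -> tuple[float, float, float, float]:
        """Representative BMI per category, used for batch charts."""
        c0, c1, c2 = self.cuts
        return (c0 - 1.0, (c0 + c1) / 2.0, (c1 + c2) / 2.0, c2 + 2.5)


BMI_SCHEMES: dict[str, BmiScheme] = {
    "WHO": BmiScheme("WHO", (18.5, 25.0, 30.0)),
    "China": BmiScheme("China", (18.5, 24.0, 28.0)),
    "Korea": BmiScheme("Korea", (18.5, 23.0, 25.0)),
}

#: only the mainland-China birth region triggers the Chinese scheme and
#: Korea the Korean one; every other region (incl. Japan/Taiwan) uses WHO
_REGION_SCHEME = {"Mainland Asian": "China", "China": "China", "Korea": "Korea"}


def scheme_for_region(region: str) -> BmiScheme:
    return BMI_SCHEMES[_REGION_SCHEME.get(region, "WHO")]


def bmi_category(bmi, region: str = "WHO"):
    """BMI category under the scheme selected by birth region.

    ``region`` may also be a scheme label (WHO/China/Korea) directly.
    Scalar in, scalar out.
    """
    scheme = BMI_SCHEMES.get(region) or scheme_for_region(region)
    out = scheme.category(bmi)
    return out.item() if np.isscalar(bmi) else out


def week0_variance(error_sd: float = WEEK0_ERROR_SD) -> float:
    """Variance of the week-0 gain score: the difference of two
    independent weighings each with SD ``error_sd`` (kg^2)."""
    if error_sd <= 0:
        raise ValueError("error_sd must be positive")
    return 2.0 * error_sd ** 2


@dataclass
class PreprocessReport:
    """Counts in/out for each preprocessing rule."""

    n_visits_in: int = 0
    n_missing_prepreg: int = 0
    n_missing_covariates: int = 0
    n_observations: int = 0
    n_week0_pseudo: int = 0
    n_excluded_4sd: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _join_covariates(obs: pd.DataFrame, cohort: pd.DataFrame,
                     report: Optional[PreprocessReport]) -> pd.DataFrame:
    cov = cohort.copy()
    if "bmi" not in cov.columns:
        cov["bmi"] = (
            cov["prepreg_weight_kg"] / cov["height_m"] ** 2
        )
    cols = ["woman_id", "age_years", "bmi", "ethnicity_region", "parity_class"]
    out = obs.merge(cov[cols], on="woman_id", how="left")
    missing = out[cols[1:]].isna().any(axis=1)
    if missing.any():
        if report is not None:
            report.n_missing_covariates += int(missing.sum())
        out = out.loc[~missing]
    return out.reset_index(drop=True)


def compute_gwg(
    visits: pd.DataFrame,
    cohort: pd.DataFrame,
    report: Optional[PreprocessReport] = None,
) -> pd.DataFrame:
    """Gain score per visit: measured weight minus pre-pregnancy weight.

    ``cohort`` must provide ``prepreg_weight_kg`` (the self-reported
    baseline) plus the covariate columns; covariates are joined onto every
    observation. Visits from women without a pre-pregnancy weight are
    dropped with a logged count. Negative gains are preserved.
    """
    if report is not None:
        report.n_visits_in += len(visits)
    base = visits.merge(
        cohort[["woman_id", "prepreg_weight_kg"]], on="woman_id", how="left"
    )
    missing = base["prepreg_weight_kg"].isna()
    if missing.any():
        if report is not None:
            report.n_missing_prepreg += int(missing.sum())
        base = base.loc[~missing]
    obs = pd.DataFrame(
        {
            "woman_id": base["woman_id"].to_numpy(),
            "gest_age_weeks": base["gest_age_weeks"].to_numpy(dtype=float),
            "gwg_kg": (
                base["weight_kg"].to_numpy(dtype=float)
                - base["prepreg_weight_kg"].to_numpy(dtype=float)
            ),
            "is_week0_pseudo": False,
        }
    )
    out = _join_covariates(obs, cohort, report)
    if report is not None:
        report.n_observations += len(out)
    return out[OBS_COLUMNS]


def draw_week0(
    cohort: pd.DataFrame,
    error_sd: float = WEEK0_ERROR_SD,
    seed: int = 0,
    report: Optional[PreprocessReport] = None,
) -> pd.DataFrame:
    """Week-0 pseudo-observations: one per woman, N(0, 2 * error_sd^2).

    A zero gain at week 0 would have no variation, so each woman's
    starting gain is drawn from a Gaussian whose variance is the sum of
    two squared single-weighing errors (0.70^2 + 0.70^2 = 0.98 for the
    default). Draws use a dedicated seeded substream so preprocessing is
    reproducible independently of simulation.
    """
    var = week0_variance(error_sd)
    # dedicated substream, keyed so it never collides with the simulation
    # generators even when the same seed integer is reused
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3EE0]))
    obs = pd.DataFrame(
        {
            "woman_id": cohort["woman_id"].to_numpy(),
            "gest_age_weeks": 0.0,
            "gwg_kg": rng.normal(0.0, np.sqrt(var), len(cohort)),
            "is_week0_pseudo": True,
        }
    )
    out = _join_covariates(obs, cohort, report)
    if report is not None:
        report.n_week0_pseudo += len(out)
    return out[OBS_COLUMNS]


def _build_windows(gest_age: np.ndarray, min_count: int = 30):
    """Per-integer-week windows with >= min_count observations.

    Bins are merged left-to-right with their right neighbour until they
    reach the minimum; a final undersized window is merged backwards. If
    the whole sample is below the minimum, one global window is used.
    Returns a list of (lo_week, hi_week) half-open intervals.
    """
    weeks = np.floor(gest_age).astype(int)
    lo_all, hi_all = int(weeks.min()), int(weeks.max())
    if gest_age.size < min_count:
        return [(lo_all, hi_all + 1)]
    counts = np.bincount(weeks - lo_all, minlength=hi_all - lo_all + 1)
    windows = []
    start, acc = lo_all, 0
    for wk, cnt in zip(range(lo_all, hi_all + 1), counts):
        acc += int(cnt)
        if acc >= min_count:
            windows.append((start, wk + 1))
            start, acc = wk + 1, 0
    if acc > 0:
        if windows:
            lo, _ = windows.pop()
            windows.append((lo, hi_all + 1))
        else:
            windows.append((start, hi_all + 1))
    return windows


def _loo_flags(vals: np.ndarray) -> np.ndarray:
    """Points outside 4 leave-one-out SDs of the leave-one-out mean.

    Leaving the candidate point out keeps a single gross outlier from
    inflating its own exclusion threshold; for large windows this is
    indistinguishable from the plain rule.
    """
    n = vals.size
    if n < 3:
        return np.zeros(n, dtype=bool)
    S, Q = vals.sum(), np.sum(vals ** 2)
    loo_mean = (S - vals) / (n - 1)
    loo_var = (Q - vals ** 2 - (n - 1) * loo_mean ** 2) / max(n - 2, 1)
    loo_sd = np.sqrt(np.maximum(loo_var, 0.0))
    flags = np.abs(vals - loo_mean) > 4.0 * loo_sd
    flags &= loo_sd > 0  # degenerate window: no exclusion
    return flags


def exclude_4sd(
    observations: pd.DataFrame,
    windows: Optional[Sequence[tuple]] = None,
    report: Optional[PreprocessReport] = None,
):
    """Remove gain scores outside 4 SD of their gestational window.

    The credible-interval rule is applied within per-week windows (merged
    to hold at least 30 observations) because gain variance grows with
    gestation; a single global SD would exclude almost nothing early and
    too much late. Within each window the 4 SD test uses leave-one-out
    mean/SD, iterated to a fixed point. Week-0 pseudo-observations are
    never excluded, and a window with zero SD excludes nothing.

    Returns ``(kept, n_excluded, windows)`` where each window is
    ``(lo_week, hi_week, mean, sd)`` with the post-exclusion statistics
    frozen in; passing ``windows`` back re-applies the plain 4 SD rule
    with those frozen statistics, which makes the operation idempotent
    on its own output.
    """
    real = ~observations["is_week0_pseudo"].to_numpy()
    if int(real.sum()) < 2:
        raise ValueError("need at least 2 non-pseudo observations")
    gest = observations["gest_age_weeks"].to_numpy(dtype=float)
    gwg = observations["gwg_kg"].to_numpy(dtype=float)
    drop = np.zeros(len(observations), dtype=bool)
    out_windows = []
    if windows is not None and len(windows) and len(windows[0]) == 4:
        for lo, hi, m, sd in windows:
            in_win = real & (gest >= lo) & (gest < hi)
            if sd > 0:
                drop |= in_win & (np.abs(gwg - m) > 4.0 * sd)
        out_windows = list(windows)
    else:
        bounds = (
            [(w[0], w[1]) for w in windows]
            if windows is not None
            else _build_windows(gest[real])
        )
        for lo, hi in bounds:
            in_win = real & (gest >= lo) & (gest < hi)
            idx = np.flatnonzero(in_win)
            keep_idx = idx.copy()
            while keep_idx.size >= 3:
                flags = _loo_flags(gwg[keep_idx])
                if not flags.any():
                    break
                drop[keep_idx[flags]] = True
                keep_idx = keep_idx[~flags]
            if keep_idx.size >= 2:
                m = float(gwg[keep_idx].mean())
                sd = float(gwg[keep_idx].std(ddof=1))
            else:
                m, sd = 0.0, 0.0
            out_windows.append((lo, hi, m, sd))
    n_excluded = int(drop.sum())
    if report is not None:
        report.n_excluded_4sd += n_excluded
    kept = observations.loc[~drop].reset_index(drop=True)
    return kept, n_excluded, out_windows


def rebaseline_first_visit(
    visits: pd.DataFrame,
    cohort: pd.DataFrame,
    report: Optional[PreprocessReport] = None,
    anchor_nudge_sd: Optional[float] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sensitivity-analysis gain scores against the first measured weight.

    The self-reported pre-pregnancy weight is discarded: each woman's
    earliest measured visit becomes her gain-zero anchor, and later gains
    are measured against that weight. Women keep their single zero-gain
    anchor even with only one visit.

    With ``anchor_nudge_sd`` set, each anchor's exact zero is replaced by
    a draw from N(0, 2 * anchor_nudge_sd^2) — the same
    lack-of-variation fix applied to the week-0 pseudo-observations,
    needed because a point mass of exact zeros breaks likelihood fitting
    of continuous families.
    """
    if report is not None:
        report.n_visits_in += len(visits)
    v = visits.sort_values(["woman_id", "gest_age_weeks"], kind="stable")
    first = v.groupby("woman_id", sort=False).first().reset_index()
    base = v.merge(
        first[["woman_id", "weight_kg"]].rename(
            columns={"weight_kg": "baseline_kg"}
        ),
        on="woman_id",
        how="left",
    )
    gwg = (
        base["weight_kg"].to_numpy(dtype=float)
        - base["baseline_kg"].to_numpy(dtype=float)
    )
    if anchor_nudge_sd is not None:
        var = week0_variance(anchor_nudge_sd)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 0xA9C4])
        )
        anchors = np.isclose(gwg, 0.0) & ~base.duplicated("woman_id").to_numpy()
        gwg = gwg.copy()
        gwg[anchors] = rng.normal(0.0, np.sqrt(var), int(anchors.sum()))
    obs = pd.DataFrame(
        {
            "woman_id": base["woman_id"].to_numpy(),
            "gest_age_weeks": base["gest_age_weeks"].to_numpy(dtype=float),
            "gwg_kg": gwg,
            "is_week0_pseudo": False,
        }
    )
    out = _join_covariates(obs, cohort, report)
    if report is not None:
        report.n_observations += len(out)
    return out[OBS_COLUMNS]
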
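"""Relative maturity group (RMG) calibration and classification.

Maturity-group standards with known RMG values are grown alongside the
test cultivars; ordinary least squares of assigned RMG on their VE-R7
day counts gives a calibration line, which then classifies every test
cultivar from its own days to maturity. RMG is a continuous scale where
negative values denote classes earlier than MG 0 (short-season
adaptation); the categorical MG label subdivides it with a leading-zeros
notation (00, 000, 0000 progressively earlier) plus one decimal.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError
from .models import PhenologyRecord, RMGAssignment, RMGModel, SiteEnvironment


def fit_rmg_model(references: Sequence[tuple[float, float]]) -> RMGModel:
    """Fit RMG = slope * ve_r7_days + intercept by OLS.

    Parameters
    ----------
    references
        Pairs of (ve_r7_days, assigned_rmg), one per reference cultivar.
    """
    if len(references) < 2:
        raise InsufficientDataError("need at least 2 reference points")
    days = np.asarray([d for d, _ in references], dtype=float)
    rmgs = np.asarray([r for _, r in references], dtype=float)
    if np.ptp(days) == 0:
        raise DegenerateDesignError("all reference day values identical")
    fit = stats.linregress(days, rmgs)
    resid = rmgs - (fit.slope * days + fit.intercept)
    n = len(days)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return RMGModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=n,
        residual_sd=residual_sd,
    )


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (so -1.25 -> -1.3 at one decimal)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def mg_label(rmg: float) -> str:
    """Map a (one-decimal) RMG value to its categorical MG label.

    Non-negative RMGs keep their decimal form ("0.0", "0.5"). Negative
    RMGs use the leading-zeros notation: each whole unit earlier adds a
    zero, and the decimal counts up from the next-earlier class boundary,
    so -0.1 -> "00.9", -1.0 -> "000.0", -1.1 -> "000.9", -2.2 -> "0000.8".
    """
    tenths = round(round_half_away(rmg, 1) * 10)
    if tenths >= 0:
        return f"{tenths // 10}.{tenths % 10}"
    a = -tenths
    if a % 10 == 0:  # negative whole RMG sits at its class boundary
        return "0" * (2 + a // 10) + ".0"
    return "0" * (2 + a // 10) + f".{10 - a % 10}"


def classify_rmg(model: RMGModel, ve_r7_days: float | None,
                 cultivar_id: str = "") -> RMGAssignment | None:
    """Classify one cultivar from its VE-R7 days; None when the cultivar
    never matured (absent days) and is therefore unclassifiable."""
    if ve_r7_days is None:
        return None
    if model.slope == 0:
        raise DegenerateDesignError("RMG model has zero slope")
    rmg = round_half_away(model.predict(ve_r7_days), 1)
    rmg += 0.0  # normalize -0.0
    return RMGAssignment(cultivar_id=cultivar_id, rmg=rmg, mg_label=mg_label(rmg))


def classify_all(model: RMGModel, records: Iterable[PhenologyRecord],
                 env_ids: set[str] | None = None) -> list[RMGAssignment]:
    """Classify every cultivar from its mean VE-R7 days over the given
    environments (default: all environments present in the records).

    A cultivar contributes the mean of the environments where it matured;
    cultivars that matured nowhere are omitted (unclassifiable).
    """
    days_by_cultivar: dict[str, list[int]] = defaultdict(list)
    for rec in records:
        if env_ids is not None and rec.env_id not in env_ids:
            continue
        if rec.ve_r7_days is not None:
            days_by_cultivar[rec.cultivar_id].append(rec.ve_r7_days)
    out = []
    for cultivar_id in sorted(days_by_cultivar):
        mean_days = float(np.mean(days_by_cultivar[cultivar_id]))
        out.append(classify_rmg(model, mean_days, cultivar_id))
    return out


def interyear_fit(year_a_days: Sequence[float | None],
                  year_b_days: Sequence[float | None],
                  ) -> tuple[float, float, float, int]:
    """Regress year-b VE-R7 days on year-a days over complete pairs.

    Returns (r_squared, f_statistic, p_value, n_excluded) where the
    F-test is the overall regression significance test and n_excluded
    counts cultivars missing either year.
    """
    if len(year_a_days) != len(year_b_days):
        raise ValueError("paired lists must have equal length")
    pairs = [(a, b) for a, b in zip(year_a_days, year_b_days)
             if a is not None and b is not None]
    n_excluded = len(year_a_days) - len(pairs)
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"only {len(pairs)} complete pairs; need at least 3"
        )
    x = np.asarray([a for a, _ in pairs], dtype=float)
    y = np.asarray([b for _, b in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("year-a days have zero variance")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    df = len(pairs) - 2
    if r2 >= 1.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = r2 / (1.0 - r2) * df
        p = float(stats.f.sf(f_stat, 1, df))
    return r2, f_stat, p, n_excluded


def matured_before_frost(records: Iterable[PhenologyRecord],
                         environments: Sequence[SiteEnvironment],
                         ) -> dict[str, set[str]]:
    """Per-environment sets of cultivars that reached R7 on or before the
    first frost date (inclusive boundary). Absent R7 means not matured."""
    frost = {e.env_id: e.first_frost_date for e in environments}
    matured: dict[str, set[str]] = {e.env_id: set() for e in environments}
    for rec in records:
        if rec.env_id not in frost:
            raise ValueError(f"record references unknown env {rec.env_id!r}")
        if rec.r7_date is not None and rec.r7_date <= frost[rec.env_id]:
            matured[rec.env_id].add(rec.cultivar_id)
    return matured


def site_adapted_cultivars(records: Iterable[PhenologyRecord],
                           environments: Sequence[SiteEnvironment],
                           site: str) -> set[str]:
    """Cultivars that matured before first frost at a site in every one of
    that site's environments (e.g. both trial years)."""
    site_envs = [e for e in environments if e.site == site]
    if not site_envs:
        raise ValueError(f"no environments for site {site!r}")
    env_ids = {e.env_id for e in site_envs}
    site_records = [r for r in records if r.env_id in env_ids]
    matured = matured_before_frost(site_records, site_envs)
    sets = [matured[e.env_id] for e in site_envs]
    return set.intersection(*sets)
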
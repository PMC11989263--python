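"""Photothermal sensitivity statistics.

Two relative statistics compare days from emergence to beginning bloom
(DTB) between a baseline site (HH) and two contrast sites:

* temperature sensitivity, using the same-latitude, higher-altitude
  (cooler) site LBDL:  TS% = (DTB_LBDL - DTB_HH) / DTB_LBDL * 100
* photothermal comprehensive response sensitivity, using the
  higher-latitude (longer-day, cooler) site BJC:
  PTCRS% = (DTB_BJC - DTB_HH) / DTB_BJC * 100

Site DTB is the mean over that site's trial years; cultivars lacking a
bloom date at a required site get an absent statistic (no imputation).
Correlations with RMG use pairwise deletion.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, InsufficientDataError
from .models import (
    PhenologyRecord,
    RMGAssignment,
    SensitivityResult,
    SiteEnvironment,
)


def temperature_sensitivity(dtb_lbdl: float, dtb_hh: float) -> float:
    """TS% = (DTB_LBDL - DTB_HH) / DTB_LBDL * 100."""
    if dtb_lbdl <= 0:
        raise AnalysisError(f"DTB at the cool site must be positive, got {dtb_lbdl}")
    return (dtb_lbdl - dtb_hh) / dtb_lbdl * 100.0


def ptcrs(dtb_bjc: float, dtb_hh: float) -> float:
    """PTCRS% = (DTB_BJC - DTB_HH) / DTB_BJC * 100."""
    if dtb_bjc <= 0:
        raise AnalysisError(f"DTB at the long-day site must be positive, got {dtb_bjc}")
    return (dtb_bjc - dtb_hh) / dtb_bjc * 100.0


def site_mean_dtb(records: Iterable[PhenologyRecord],
                  environments: Sequence[SiteEnvironment],
                  ) -> dict[str, dict[str, float]]:
    """Mean DTB (days VE to R1) per cultivar per site, averaged over the
    site's years."""
    env_site = {e.env_id: e.site for e in environments}
    acc: dict[str, dict[str, list[int]]] = defaultdict(lambda: defaultdict(list))
    for rec in records:
        site = env_site.get(rec.env_id)
        if site is None:
            raise ValueError(f"record references unknown env {rec.env_id!r}")
        acc[rec.cultivar_id][site].append(rec.dtb_days)
    return {cultivar: {site: float(np.mean(vals)) for site, vals in by_site.items()}
            for cultivar, by_site in acc.items()}


def compute_sensitivities(records: Iterable[PhenologyRecord],
                          environments: Sequence[SiteEnvironment],
                          baseline_site: str = "HH",
                          temp_site: str = "LBDL",
                          photothermal_site: str = "BJC",
                          ) -> list[SensitivityResult]:
    """TS and PTCRS for every cultivar with the required site DTBs."""
    dtb = site_mean_dtb(records, environments)
    out = []
    for cultivar in sorted(dtb):
        by_site = dtb[cultivar]
        d_hh = by_site.get(baseline_site)
        d_lbdl = by_site.get(temp_site)
        d_bjc = by_site.get(photothermal_site)
        ts_val = (temperature_sensitivity(d_lbdl, d_hh)
                  if d_hh is not None and d_lbdl is not None else None)
        pt_val = (ptcrs(d_bjc, d_hh)
                  if d_hh is not None and d_bjc is not None else None)
        out.append(SensitivityResult(
            cultivar_id=cultivar, dtb_hh=d_hh, dtb_bjc=d_bjc, dtb_lbdl=d_lbdl,
            ts_percent=ts_val, ptcrs_percent=pt_val,
        ))
    return out


def correlate_with_rmg(sensitivities: Sequence[SensitivityResult],
                       assignments: Sequence[RMGAssignment],
                       statistic: str = "ts",
                       ) -> tuple[float, float, int]:
    """Pearson correlation of a sensitivity statistic with RMG.

    Pairs are formed per cultivar with pairwise deletion of absent
    values. Returns (r, two-sided p, n_pairs).
    """
    attr = {"ts": "ts_percent", "ptcrs": "ptcrs_percent"}[statistic]
    rmg_by_cultivar = {a.cultivar_id: a.rmg for a in assignments}
    xs, ys = [], []
    for sens in sensitivities:
        value = getattr(sens, attr)
        rmg = rmg_by_cultivar.get(sens.cultivar_id)
        if value is not None and rmg is not None:
            xs.append(value)
            ys.append(rmg)
    if len(xs) < 3:
        raise InsufficientDataError(f"only {len(xs)} paired observations")
    xs_arr, ys_arr = np.asarray(xs), np.asarray(ys)
    if np.ptp(xs_arr) == 0 or np.ptp(ys_arr) == 0:
        raise AnalysisError("zero variance: correlation undefined")
    res = stats.pearsonr(xs_arr, ys_arr)
    return float(res.statistic), float(res.pvalue), len(xs)


def sensitivity_by_mg(sensitivities: Sequence[SensitivityResult],
                      assignments: Sequence[RMGAssignment],
                      statistic: str = "ts",
                      alpha: float = 0.05):
    """Per-MG-class means with ANOVA and Duncan letters.

    The MG class is the leading-zeros part of the MG label (MG 0, 00,
    000, 0000). Classes with fewer than 2 members are excluded with a
    warning. Returns an AssociationResult-like summary from the
    association module's one-way machinery.
    """
    import logging

    from .association import anova_letters

    attr = {"ts": "ts_percent", "ptcrs": "ptcrs_percent"}[statistic]
    mg_class = {a.cultivar_id: "MG " + a.mg_label.split(".")[0]
                for a in assignments}
    groups: dict[str, list[float]] = defaultdict(list)
    for sens in sensitivities:
        value = getattr(sens, attr)
        cls = mg_class.get(sens.cultivar_id)
        if value is not None and cls is not None:
            groups[cls].append(value)
    for cls in [c for c, vals in groups.items() if len(vals) < 2]:
        logging.getLogger(__name__).warning(
            "MG class %s has <2 members; excluded", cls)
        del groups[cls]
    if len(groups) < 2:
        raise InsufficientDataError("need >=2 MG classes with >=2 members")
    return anova_letters(dict(groups), alpha=alpha)
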
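"""Scat macroscopy: sieve observations to corrected diet profiles.

A thawed scat subsample is washed through 1-mm, 0.5-mm and 0.1-mm sieves;
the 0.1-mm sieve serves identification only and carries no mass, so the
1-mm and 0.5-mm mass fractions (w1, w05) sum to 1. Per-sieve item volumes
come from hundred-checkered plate counts (percent of plate squares).

Pipeline per scat: sieve-weighted raw composition (percent of identified
remains), then multiplicative digestibility correction factors renormalized
to 100, yielding percent dry-matter biomass ingested. Scats are analyzed
separately and averaged per collection site; population summaries are per
season (spring May 15-Jun 14, summer Jun 15-Jul 31, fall Aug 1-Sep 14,
closed bounds) as mean +/- SD over site profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SievedScat",
    "SEASONS",
    "assign_season",
    "scat_raw_composition",
    "apply_correction_factors",
    "site_diet",
    "seasonal_population_summary",
    "filter_rare_items",
    "read_scat_observations",
]

SUM_TOL = 1e-6

# closed date bounds, month/day (year-agnostic)
SEASONS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "spring": ((5, 15), (6, 14)),
    "summer": ((6, 15), (7, 31)),
    "fall": ((8, 1), (9, 14)),
}


class EmptyScatError(ValueError):
    pass


@dataclass
class SievedScat:
    """One scat's sieve mass fractions and per-sieve item percent volumes.

    ``item_volumes`` maps sieve name ('1mm', '0.5mm') to {item: percent};
    per-sieve percents may sum below 100, the remainder being unidentified.
    """

    scat_id: str
    site_id: str
    animal_id: str
    collection_date: date
    w1: float
    w05: float
    item_volumes: dict[str, dict[str, float]]
    is_cub: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.w1 <= 1 and 0 <= self.w05 <= 1):
            raise ValueError("sieve fractions must lie in [0, 1]")
        if abs(self.w1 + self.w05 - 1.0) > SUM_TOL:
            raise ValueError(
                f"sieve fractions must sum to 1 (got {self.w1 + self.w05})"
            )
        for sieve, vols in self.item_volumes.items():
            s = sum(vols.values())
            if any(v < 0 for v in vols.values()):
                raise ValueError(f"negative item volume in sieve {sieve}")
            if s > 100 + SUM_TOL:
                raise ValueError(
                    f"item volumes in sieve {sieve} sum to {s} > 100"
                )


def scat_raw_composition(scat: SievedScat) -> pd.Series:
    """Sieve-weighted raw item composition, renormalized to 100 over
    identified items.

    raw_j = sum_s w_s * v_{s,j}; the unidentified remainder is dropped but
    reported in ``result.attrs['unidentified_pct']``.
    """
    weights = {"1mm": scat.w1, "0.5mm": scat.w05}
    items: dict[str, float] = {}
    for sieve, w in weights.items():
        for item, v in scat.item_volumes.get(sieve, {}).items():
            items[item] = items.get(item, 0.0) + w * v
    raw = pd.Series(items, dtype=float).sort_index()
    total = raw.sum()
    if total <= 0:
        raise EmptyScatError(f"scat {scat.scat_id} has no identified items")
    out = raw / total * 100.0
    out.attrs["unidentified_pct"] = max(0.0, 100.0 - total)
    out.attrs["scat_id"] = scat.scat_id
    return out


def apply_correction_factors(
    raw: pd.Series,
    factors: Mapping[str, float],
    default: float | None = None,
) -> pd.Series:
    """Digestibility correction: corrected_j = 100 * raw_j cf_j / sum raw cf.

    Invariant to a common rescaling of all factors. A missing factor is a
    configuration error unless ``default`` is given (then used with a
    warning recorded in ``attrs``)."""
    missing = [i for i in raw.index if i not in factors]
    if missing and default is None:
        raise KeyError(f"no correction factor for items: {missing}")
    cf = pd.Series(
        {i: float(factors.get(i, default)) for i in raw.index}, dtype=float
    )
    if (cf <= 0).any():
        raise ValueError("correction factors must be strictly positive")
    weighted = raw * cf
    out = weighted / weighted.sum() * 100.0
    out.attrs = dict(raw.attrs)
    if missing:
        out.attrs["defaulted_items"] = missing
    return out


def site_diet(profiles: Sequence[pd.Series], site_id: str | None = None) -> pd.Series:
    """Unweighted component-wise mean of the scat profiles of one site;
    the mean of profiles summing to 100 sums to 100."""
    if len(profiles) == 0:
        raise ValueError("need at least one scat profile")
    ids = {p.attrs.get("site_id") for p in profiles if "site_id" in p.attrs}
    if site_id is not None:
        ids.add(site_id)
    if len(ids) > 1:
        raise ValueError(f"profiles from different sites: {sorted(ids)}")
    df = pd.DataFrame(list(profiles)).fillna(0.0)
    mean = df.mean(axis=0)
    if site_id is not None:
        mean.attrs["site_id"] = site_id
    return mean


def assign_season(d: date) -> str | None:
    """Season of a collection date (closed bounds); None when out of season."""
    md = (d.month, d.day)
    for season, (lo, hi) in SEASONS.items():
        if lo <= md <= hi:
            return season
    return None


def seasonal_population_summary(
    site_profiles: pd.DataFrame, dates: Mapping[str, date]
) -> pd.DataFrame:
    """Per-season, per-item mean and sample SD over site profiles.

    ``site_profiles`` is sites x items (percent dry matter); ``dates`` maps
    site id to collection date. Out-of-season sites are excluded and listed
    in ``result.attrs['out_of_season']``.
    """
    seasons = {}
    out_of_season = []
    for site in site_profiles.index:
        s = assign_season(dates[site])
        if s is None:
            out_of_season.append(site)
        else:
            seasons[site] = s
    rows = []
    for season in SEASONS:
        sites = [s for s, sea in seasons.items() if sea == season]
        if not sites:
            continue
        sub = site_profiles.loc[sites]
        for item in site_profiles.columns:
            rows.append(
                {
                    "season": season,
                    "item": item,
                    "mean": float(sub[item].mean()),
                    "sd": float(sub[item].std(ddof=1)) if len(sites) > 1 else 0.0,
                    "n_sites": len(sites),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["out_of_season"] = out_of_season
    return out


def filter_rare_items(
    site_matrix: pd.DataFrame,
    scat_presence_counts: Mapping[str, int],
    min_feces: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop items present in fewer than ``min_feces`` scats (counts are at
    the scat level, not the site level). Remaining columns are NOT
    renormalized: correspondence analysis works on relative frequencies
    internally, so renormalizing would change nothing and hide the audit
    trail."""
    dropped = [
        c for c in site_matrix.columns if scat_presence_counts.get(c, 0) < min_feces
    ]
    kept = site_matrix.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("rare-item filter removed every item")
    return kept, dropped


def read_scat_observations(
    volumes_csv, sieve_fractions_csv
) -> list[SievedScat]:
    """Assemble SievedScat records from the long-format observation CSV
    (scat_id, site_id, animal_id, date, is_cub, sieve, item, percent_volume)
    and the per-scat sieve-fraction CSV (scat_id, w1, w05)."""
    vols = pd.read_csv(volumes_csv)
    fracs = pd.read_csv(sieve_fractions_csv).set_index("scat_id")
    scats = []
    for scat_id, grp in vols.groupby("scat_id", sort=True):
        first = grp.iloc[0]
        item_volumes: dict[str, dict[str, float]] = {}
        for _, r in grp.iterrows():
            item_volumes.setdefault(str(r["sieve"]), {})[str(r["item"])] = float(
                r["percent_volume"]
            )
        scats.append(
            SievedScat(
                scat_id=str(scat_id),
                site_id=str(first["site_id"]),
                animal_id=str(first["animal_id"]),
                collection_date=pd.Timestamp(first["date"]).date(),
                w1=float(fracs.loc[scat_id, "w1"]),
                w05=float(fracs.loc[scat_id, "w05"]),
                item_volumes=item_volumes,
                is_cub=bool(first.get("is_cub", False)),
            )
        )
    return scats
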
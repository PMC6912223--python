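"""Data model and file IO for camera-trap detection histories and site covariates.

The central objects are :class:`SiteTable` (per-site covariates: study area,
fox-baiting status and ordinal habitat-complexity scores) and
:class:`DetectionDataset` (per site, species and season: a day-indexed vector of
daily detection outcomes, with ``NaN`` marking days a camera was inoperative).

File formats are plain CSV:

* detection histories — wide layout with columns ``site_id, species, season,
  d01..dNN``; cells are ``0`` (surveyed, not detected), ``1`` (detected) or
  blank (camera not operating that day);
* site table — ``site_id, area, baited`` plus the seven habitat attribute
  scores (each 0–3).

A blank cell is *missing*, never zero: conflating the two silently inflates
absences, so the distinction is preserved through every round-trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AREAS = ("BB", "NAD")
SPECIES = ("Isoodon", "Perameles", "Potorous")

#: Habitat attributes scored 0-3 on a 50 m x 20 m plot at each camera site.
SCORE_COLUMNS = (
    "tree_cover",
    "shrub_cover",
    "ground_cover",
    "woody_debris",
    "rocks",
    "leaf_litter",
    "moisture",
)

SITE_COLUMNS = ("site_id", "area", "baited") + SCORE_COLUMNS


class ParseError(ValueError):
    """A cell in an input file could not be interpreted."""


class ValidationError(ValueError):
    """Structurally valid input that violates a dataset invariant."""


@dataclass(frozen=True)
class SiteTable:
    """Per-site covariates: area, baiting status and habitat-complexity scores.

    ``frame`` is indexed by ``site_id`` with columns ``area`` (``"BB"`` or
    ``"NAD"``), ``baited`` (bool) and the seven ordinal scores in
    :data:`SCORE_COLUMNS`, each in {0, 1, 2, 3}.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site_id(s): {dupes}")
        bad_area = set(df["area"].unique()) - set(AREAS)
        if bad_area:
            raise ValidationError(f"unknown area label(s): {sorted(bad_area)}")
        for col in SCORE_COLUMNS:
            vals = df[col].to_numpy()
            if not np.isin(vals, (0, 1, 2, 3)).all():
                raise ValidationError(f"score column {col!r} outside 0-3")
        # Baiting is area-level management; it cannot vary within an area.
        per_area = df.groupby("area", observed=True)["baited"].nunique()
        if (per_area > 1).any():
            raise ValidationError("baited must be constant within an area")

    @property
    def site_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.frame.index

    def area_of(self, site_id: str) -> str:
        return self.frame.at[site_id, "area"]

    def covariates(self, site_id: str) -> pd.Series:
        return self.frame.loc[site_id]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteTable":
        missing = set(SITE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"site table missing column(s): {sorted(missing)}")
        out = df.loc[:, list(SITE_COLUMNS)].copy()
        out["site_id"] = out["site_id"].astype(str)
        out["baited"] = out["baited"].astype(bool)
        for col in SCORE_COLUMNS:
            out[col] = out[col].astype(int)
        return cls(out.set_index("site_id"))

    @classmethod
    def read_csv(cls, path: str | Path) -> "SiteTable":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.reset_index().to_csv(path, index=False)


@dataclass(frozen=True)
class DetectionDataset:
    """Daily detection outcomes per (species, site, season).

    ``histories`` maps ``(species, site_id, season)`` to a float vector whose
    entries are 0.0, 1.0 or ``NaN`` (missing day). Day indexing is 1-based and
    season-relative: element ``k`` of the vector is day ``k + 1`` of that
    deployment, aligned at day 1. A (site, season) pair absent from the mapping
    is a lost deployment (camera theft/malfunction for the whole season).
    """

    seasons: tuple[str, ...]
    histories: dict[tuple[str, str, str], np.ndarray]

    def __post_init__(self) -> None:
        for key, h in self.histories.items():
            vals = h[~np.isnan(h)]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValidationError(f"outcomes for {key} not in {{0, 1, missing}}")
            if key[2] not in self.seasons:
                raise ValidationError(f"record {key} references unknown season")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({k[0] for k in self.histories}))

    @property
    def max_days(self) -> int:
        return max((len(h) for h in self.histories.values()), default=0)

    def __len__(self) -> int:
        return len(self.histories)

    def subset(
        self,
        species: str | None = None,
        seasons: Sequence[str] | None = None,
    ) -> "DetectionDataset":
        """Restrict to one species and/or a subset of seasons."""
        keep_seasons = tuple(seasons) if seasons is not None else self.seasons
        hist = {
            k: v
            for k, v in self.histories.items()
            if (species is None or k[0] == species) and k[2] in keep_seasons
        }
        return DetectionDataset(keep_seasons, hist)

    def n_detections(self) -> int:
        return int(sum(np.nansum(h) for h in self.histories.values()))

    def active_trap_days(self) -> int:
        return int(sum((~np.isnan(h)).sum() for h in self.histories.values()))

    # ------------------------------------------------------------------ IO

    def to_frame(self) -> pd.DataFrame:
        width = self.max_days
        rows = []
        for (sp, site, season), h in sorted(self.histories.items()):
            padded = np.full(width, np.nan)
            padded[: len(h)] = h
            rows.append([site, sp, season, *padded])
        cols = ["site_id", "species", "season"] + [
            f"d{i:02d}" for i in range(1, width + 1)
        ]
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        day_cols = [c for c in df.columns if c.startswith("d")]
        # write 0/1 without a trailing ".0", blanks for missing days
        for c in day_cols:
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
        df.to_csv(path, index=False)


def _parse_day_cell(raw: object, row: int, col: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text == "":
        return np.nan
    if text in ("0", "1"):
        return float(text)
    try:
        val = float(text)
    except ValueError:
        raise ParseError(f"row {row}, column {col}: cell {raw!r} is not 0/1/blank")
    if val in (0.0, 1.0):
        return val
    raise ParseError(f"row {row}, column {col}: cell {raw!r} is not 0/1/blank")


def load_detection_data(
    history_path: str | Path, sites_path: str | Path
) -> tuple[DetectionDataset, SiteTable]:
    """Read a detection-history CSV and its companion site table.

    Every history row must name a site present in the site table; duplicate
    (species, site, season) rows are rejected. Records with no surveyed days at
    all carry no information and are dropped with a warning.
    """
    sites = SiteTable.read_csv(sites_path)
    raw = pd.read_csv(history_path, dtype=str, keep_default_na=False)
    needed = {"site_id", "species", "season"}
    if not needed <= set(raw.columns):
        raise ParseError(f"history file missing column(s): {sorted(needed - set(raw.columns))}")
    day_cols = [c for c in raw.columns if c not in needed]

    histories: dict[tuple[str, str, str], np.ndarray] = {}
    seasons: list[str] = []
    for i, row in raw.iterrows():
        site = str(row["site_id"])
        if site not in sites:
            raise ValidationError(f"row {i}: unknown site_id {site!r}")
        key = (str(row["species"]), site, str(row["season"]))
        if key in histories:
            raise ValidationError(f"duplicate record for {key}")
        outcomes = np.array(
            [_parse_day_cell(row[c], i, c) for c in day_cols], dtype=float
        )
        if np.isnan(outcomes).all():
            logger.warning("record %s has no surveyed days; dropped", key)
            continue
        histories[key] = outcomes
        if key[2] not in seasons:
            seasons.append(key[2])
    return DetectionDataset(tuple(sorted(seasons)), histories), sites


def truncate_histories(data: DetectionDataset, max_days: int) -> DetectionDataset:
    """Keep only days 1..max_days of every deployment.

    The study protocol left cameras out 30-40 days; analyses compare a 30-day
    and a 40-day survey window, so truncation is the switch between the two.
    """
    if max_days < 1:
        raise ValueError(f"max_days must be >= 1, got {max_days}")
    return DetectionDataset(
        data.seasons,
        {k: h[:max_days].copy() for k, h in data.histories.items()},
    )


def detection_frequency_summary(
    data: DetectionDataset,
    sites: SiteTable,
    by_area: bool = True,
    with_totals: bool = True,
) -> pd.DataFrame:
    """Detection counts, active trap days and per-1000-day rates.

    One row per (species, season[, area]); when ``with_totals`` each species
    additionally gets a ``Total`` row whose counts are the column sums of its
    season rows. ``rate_per_1000`` is ``1000 * n_detections /
    active_trap_days`` and NaN for strata with no active days.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    rows = []
    for (sp, site, season), h in data.histories.items():
        rows.append(
            {
                "species": sp,
                "season": season,
                "area": sites.area_of(site),
                "n_detections": int(np.nansum(h)),
                "active_trap_days": int((~np.isnan(h)).sum()),
            }
        )
    long = pd.DataFrame(rows)
    keys = ["species", "season"] + (["area"] if by_area else [])
    table = long.groupby(keys, as_index=False)[["n_detections", "active_trap_days"]].sum()
    if with_totals:
        total_keys = ["species"] + (["area"] if by_area else [])
        totals = table.groupby(total_keys, as_index=False)[
            ["n_detections", "active_trap_days"]
        ].sum()
        totals["season"] = "Total"
        table = pd.concat([table, totals], ignore_index=True)[table.columns]
    with np.errstate(divide="ignore", invalid="ignore"):
        table["rate_per_1000"] = np.where(
            table["active_trap_days"] > 0,
            1000.0 * table["n_detections"] / table["active_trap_days"],
            np.nan,
        )
    return table.sort_values(keys).reset_index(drop=True)
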
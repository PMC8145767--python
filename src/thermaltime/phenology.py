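"""Phenological stage records, maturation index and harvest calling.

Three anchor stages are tracked per season on the BBCH scale: bud break
(stage 09), full bloom (stage 65) and harvest/ripening (stage 89).  Ripeness
is judged from weekly berry samples through the maturation index, the ratio
of total soluble solids (deg Brix) to titratable acidity (g/L tartaric
acid); harvest is called on the first sampling date whose index exceeds the
threshold (18 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Literal, Sequence

import pandas as pd

__all__ = [
    "StageError",
    "SeasonPhenology",
    "MaturationSample",
    "maturation_index",
    "call_harvest",
    "season_length",
    "read_phenology_csv",
    "write_phenology_csv",
    "read_maturation_csv",
]

STAGES = ("bud_break", "full_bloom", "harvest")
MI_HARVEST_THRESHOLD = 18.0


class StageError(ValueError):
    """A required stage date is missing or out of order."""


@dataclass(frozen=True)
class SeasonPhenology:
    """Anchor stage dates of one season and site.

    ``harvest=None`` encodes a pending harvest (season still running).
    Ties between stages are allowed (degenerate zero-requirement seasons);
    ordering must be non-decreasing.
    """

    season: str
    site: Literal["open_field", "greenhouse"]
    bud_break: date
    full_bloom: date | None = None
    harvest: date | None = None

    def __post_init__(self) -> None:
        if self.site not in ("open_field", "greenhouse"):
            raise ValueError(f"unknown site {self.site!r}")
        chain = [d for d in (self.bud_break, self.full_bloom, self.harvest) if d is not None]
        if any(a > b for a, b in zip(chain, chain[1:])):
            raise StageError(
                f"season {self.season}: stage dates out of order "
                f"({self.bud_break}, {self.full_bloom}, {self.harvest})"
            )

    def stage_date(self, stage: str) -> date | None:
        if stage not in STAGES:
            raise StageError(f"unknown stage {stage!r}; expected one of {STAGES}")
        return getattr(self, stage)


@dataclass(frozen=True)
class MaturationSample:
    """One weekly berry sample: soluble solids, acidity, derived index."""

    date: date
    tss: float  # total soluble solids, deg Brix
    ta: float  # titratable acidity, g/L tartaric acid

    def __post_init__(self) -> None:
        if self.tss <= 0 or self.ta <= 0:
            raise ValueError(f"{self.date}: tss and ta must be positive ({self.tss}, {self.ta})")

    @property
    def mi(self) -> float:
        return self.tss / self.ta


def maturation_index(tss: float, ta: float) -> float:
    """Maturation index: deg Brix over g/L tartaric acid, dimensionless."""
    if tss <= 0 or ta <= 0:
        raise ValueError(f"tss and ta must be positive, got ({tss}, {ta})")
    return tss / ta


def call_harvest(
    samples: Sequence[MaturationSample],
    threshold: float = MI_HARVEST_THRESHOLD,
    strict: bool = True,
) -> date | None:
    """Date of the first sample whose maturation index crosses the threshold.

    ``strict=True`` requires MI > threshold (the default harvest rule);
    ``strict=False`` accepts MI >= threshold.  Returns None when no sample
    crosses ("not reached").  Samples must be strictly increasing in date.
    """
    if not samples:
        raise ValueError("no maturation samples")
    dates = [s.date for s in samples]
    if any(a >= b for a, b in zip(dates, dates[1:])):
        raise ValueError("samples must be strictly increasing in date")
    for s in samples:
        if (s.mi > threshold) if strict else (s.mi >= threshold):
            return s.date
    return None


def season_length(phen: SeasonPhenology) -> int:
    """Days from bud break to harvest (date difference)."""
    if phen.harvest is None:
        raise StageError(f"season {phen.season}: harvest pending")
    return (phen.harvest - phen.bud_break).days


def read_phenology_csv(path) -> dict[str, SeasonPhenology]:
    """Read ``season,site,bud_break,full_bloom,harvest`` rows keyed by season id."""
    raw = pd.read_csv(path, dtype=str)
    out: dict[str, SeasonPhenology] = {}
    for _, row in raw.iterrows():
        def _d(v):
            return None if pd.isna(v) or v in ("", "pending") else date.fromisoformat(v)

        phen = SeasonPhenology(
            season=str(row["season"]),
            site=row["site"],
            bud_break=date.fromisoformat(row["bud_break"]),
            full_bloom=_d(row.get("full_bloom")),
            harvest=_d(row.get("harvest")),
        )
        out[phen.season] = phen
    return out


def write_phenology_csv(phens: Sequence[SeasonPhenology], path) -> None:
    rows = [
        {
            "season": p.season,
            "site": p.site,
            "bud_break": p.bud_break.isoformat(),
            "full_bloom": "" if p.full_bloom is None else p.full_bloom.isoformat(),
            "harvest": "pending" if p.harvest is None else p.harvest.isoformat(),
        }
        for p in phens
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_maturation_csv(path) -> dict[str, list[MaturationSample]]:
    """Read ``season,date,tss_brix,ta_g_per_l`` rows grouped by season id."""
    raw = pd.read_csv(path, dtype=str)
    out: dict[str, list[MaturationSample]] = {}
    for _, row in raw.iterrows():
        out.setdefault(str(row["season"]), []).append(
            MaturationSample(
                date=date.fromisoformat(row["date"]),
                tss=float(row["tss_brix"]),
                ta=float(row["ta_g_per_l"]),
            )
        )
    for samples in out.values():
        samples.sort(key=lambda s: s.date)
    return out
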
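"""Planned-vs-measured dose agreement statistics for TLD verification.

Each record pairs a treatment-planning-system (TPS) dose with a TLD-measured
dose at one scalp location; agreement is the absolute percent difference with
the planned (TPS) dose as denominator.  The summary reports the mean, sample
(n−1) standard deviation, and maximum of the absolute percent differences,
plus the fraction of locations within a tolerance (5% by default, the usual
in-vivo action level).

Input is delimited text with either (location, planned, measured) columns or
a precomputed (location, abs_percent_diff) pair; the phantom-study reference
table of 20 scalp locations ships as a packaged fixture.  Multi-fraction
in-vivo measurements are summarized per fraction and then averaged, with the
per-location across-fraction (interfraction) SD reported separately.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import io
import os
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DosimetryError


def abs_percent_difference(planned: float, measured: float) -> float:
    """100 * |measured - planned| / planned."""
    if planned <= 0:
        raise DosimetryError(f"planned dose must be positive, got {planned}")
    return 100.0 * abs(measured - planned) / planned


@dataclasses.dataclass(frozen=True)
class TLDRecord:
    """One TLD location: planned and measured dose in cGy, or a precomputed
    absolute percent difference."""

    location_id: str
    planned_dose: float | None = None
    measured_dose: float | None = None
    abs_percent_diff: float | None = None

    def __post_init__(self) -> None:
        has_doses = self.planned_dose is not None and self.measured_dose is not None
        if not has_doses and self.abs_percent_diff is None:
            raise DosimetryError(
                f"record {self.location_id}: need both doses or abs_percent_diff"
            )
        for d in (self.planned_dose, self.measured_dose):
            if d is not None and d <= 0:
                raise DosimetryError(f"record {self.location_id}: doses must be > 0")
        if self.abs_percent_diff is not None and self.abs_percent_diff < 0:
            raise DosimetryError(f"record {self.location_id}: percent diff must be >= 0")

    @property
    def percent_diff(self) -> float:
        if self.planned_dose is not None and self.measured_dose is not None:
            return abs_percent_difference(self.planned_dose, self.measured_dose)
        return float(self.abs_percent_diff)


@dataclasses.dataclass(frozen=True)
class DoseComparisonSummary:
    """Agreement statistics over a set of TLD locations."""

    n: int
    mean_abs_pct: float
    sd_abs_pct: float  # sample SD (n-1); 0 with single_record flag when n == 1
    max_abs_pct: float
    tolerance_pct: float
    fraction_within_tolerance: float
    single_record: bool = False
    _diffs: np.ndarray = dataclasses.field(default=None, repr=False, compare=False)

    def fraction_within(self, tol_pct: float) -> float:
        """Proportion of locations with |percent difference| <= tol_pct."""
        return float(np.mean(self._diffs <= tol_pct))


def summarize(
    records: Sequence[TLDRecord], tolerance_pct: float = 5.0
) -> DoseComparisonSummary:
    """Summarize absolute percent differences over TLD locations."""
    if len(records) == 0:
        raise DosimetryError("no TLD records to summarize")
    diffs = np.array([r.percent_diff for r in records], dtype=float)
    n = len(diffs)
    return DoseComparisonSummary(
        n=n,
        mean_abs_pct=float(diffs.mean()),
        sd_abs_pct=float(diffs.std(ddof=1)) if n > 1 else 0.0,
        max_abs_pct=float(diffs.max()),
        tolerance_pct=float(tolerance_pct),
        fraction_within_tolerance=float(np.mean(diffs <= tolerance_pct)),
        single_record=(n == 1),
        _diffs=diffs,
    )


@dataclasses.dataclass(frozen=True)
class MultiFractionSummary:
    """Per-fraction summaries plus interfraction reproducibility."""

    per_fraction: dict
    mean_abs_pct: float  # average of per-fraction means
    max_abs_pct: float
    interfraction_sd_mean: float  # per-location SD across fractions, averaged


def summarize_fractions(
    fractions: Mapping[object, Sequence[TLDRecord]], tolerance_pct: float = 5.0
) -> MultiFractionSummary:
    """Summarize each measured fraction, then average across fractions.

    Interfraction reproducibility is the sample SD of each location's percent
    difference across fractions, averaged over the locations present in every
    fraction.
    """
    if not fractions:
        raise DosimetryError("no fractions to summarize")
    per = {k: summarize(v, tolerance_pct) for k, v in fractions.items()}

    by_location: dict[str, list[float]] = {}
    for recs in fractions.values():
        for r in recs:
            by_location.setdefault(r.location_id, []).append(r.percent_diff)
    n_frac = len(fractions)
    sds = [np.std(v, ddof=1) for v in by_location.values() if len(v) == n_frac and n_frac > 1]
    return MultiFractionSummary(
        per_fraction=per,
        mean_abs_pct=float(np.mean([s.mean_abs_pct for s in per.values()])),
        max_abs_pct=float(max(s.max_abs_pct for s in per.values())),
        interfraction_sd_mean=float(np.mean(sds)) if sds else 0.0,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O and the packaged phantom reference table
# ---------------------------------------------------------------------------

def load_tld_table(path: str | os.PathLike | io.IOBase) -> list[TLDRecord]:
    """Read TLD records from delimited text.

    Accepts (location, planned, measured) or (location, abs_percent_diff)
    layouts, by column count or by name.
    """
    table = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    cols = [str(c).strip().lower() for c in table.columns]
    table.columns = cols
    if {"planned", "measured"}.issubset(cols) or table.shape[1] >= 3:
        loc = table.columns[0] if "location" not in cols else "location"
        planned = "planned" if "planned" in cols else table.columns[1]
        measured = "measured" if "measured" in cols else table.columns[2]
        return [
            TLDRecord(
                location_id=str(row[loc]),
                planned_dose=float(row[planned]),
                measured_dose=float(row[measured]),
            )
            for _, row in table.iterrows()
        ]
    if table.shape[1] == 2:
        return [
            TLDRecord(location_id=str(row.iloc[0]), abs_percent_diff=float(row.iloc[1]))
            for _, row in table.iterrows()
        ]
    raise DosimetryError("TLD table needs 2 or 3 columns")


def phantom_reference_table() -> list[TLDRecord]:
    """The packaged phantom-study table: absolute percent difference between
    TPS-calculated and TLD-measured dose at 20 scalp locations."""
    ref = importlib.resources.files("boluscap.data") / "tld_phantom_table.tsv"
    with ref.open("rb") as fh:
        return load_tld_table(fh)
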
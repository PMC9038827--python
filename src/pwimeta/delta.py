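"""Quintile (Vincentile) binning, delta profiles and delta-segment slopes.

The delta-plot procedure characterises how a between-condition effect
evolves over the reaction-time distribution: per unit (participant or
item) and condition, RTs are rank-ordered and cut into *k* equal-count
bins (quintiles for *k* = 5), the mean of each bin is taken, and the
per-bin difference between conditions — the *delta* — is examined as a
function of overall speed.

The slope of a delta segment between quintiles *a* and *b* is

    slope(a, b) = (delta(b) - delta(a)) / (mean(b) - mean(a))

where ``mean(q)`` is the across-condition average of the two condition
quintile means. The slope of the *slowest* segment (quintiles 4-5) has
been used as an index of selective inhibition; the *fastest* segment is
quintiles 1-2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pwimeta.core_data import CONDITIONS, TrialTable
from pwimeta.errors import DegenerateProfileError, InsufficientDataError

logger = logging.getLogger(__name__)

#: quintile index pairs (0-based) of the two named delta segments
SEGMENTS = {"fastest": (0, 1), "slowest": (3, 4)}


@dataclass(frozen=True)
class QuintileMeans:
    """Per-bin means of the sorted RTs of one unit in one condition."""

    means: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class DeltaProfile:
    """Quintile-level summary of one unit (participant or item).

    ``deltas[q] = related[q] - unrelated[q]`` and ``combined[q]`` is the
    across-condition average of the two condition quintile means.
    ``mean_effect`` is the unit's raw mean RT difference (related minus
    unrelated) over all of its trials.
    """

    unit_id: str
    unit_kind: str
    related: QuintileMeans
    unrelated: QuintileMeans
    mean_effect: float
    n_related: int
    n_unrelated: int

    @property
    def k(self) -> int:
        return self.related.k

    @property
    def deltas(self) -> tuple[float, ...]:
        return tuple(r - u for r, u in zip(self.related.means, self.unrelated.means))

    @property
    def combined(self) -> tuple[float, ...]:
        return tuple((r + u) / 2.0 for r, u in zip(self.related.means, self.unrelated.means))


@dataclass(frozen=True)
class SegmentSlope:
    """Delta-segment slope; dimensionless (ms change in delta per ms)."""

    segment: str
    value: float


def bin_assignments(n: int, k: int) -> np.ndarray:
    """Bin index for each rank ``j`` of ``n`` sorted values: ``floor(j*k/n)``.

    Deterministic; every bin is non-empty whenever ``n >= k``.
    """
    return (np.arange(n) * k) // n


def vincentize(rts: Sequence[float], k: int = 5) -> QuintileMeans:
    """Sort RTs ascending (stable) and return the mean of each of ``k``
    equal-count bins.

    Raises :class:`InsufficientDataError` when fewer than ``k`` values are
    supplied and :class:`ValueError` on non-finite or non-positive input.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = np.asarray(rts, dtype=float)
    if x.size < k:
        raise InsufficientDataError(f"need at least {k} RTs to form {k} bins, got {x.size}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("RTs must be finite and positive")
    x = np.sort(x, kind="stable")
    bins = bin_assignments(x.size, k)
    sums = np.bincount(bins, weights=x, minlength=k)
    counts = np.bincount(bins, minlength=k)
    return QuintileMeans(means=tuple(sums / counts))


def delta_profile(
    trials: TrialTable | pd.DataFrame,
    unit_id: str = "",
    unit_kind: str = "participant",
    k: int = 5,
) -> DeltaProfile:
    """Delta profile for the trials of a single unit.

    Each condition is vincentized independently; ``mean_effect`` is the
    raw mean difference (related minus unrelated) over the unit's trials.
    """
    frame = trials.data if isinstance(trials, TrialTable) else trials
    rel = frame.loc[frame["condition"] == "related", "rt"].to_numpy()
    unrel = frame.loc[frame["condition"] == "unrelated", "rt"].to_numpy()
    if rel.size == 0 or unrel.size == 0:
        raise InsufficientDataError(
            f"unit {unit_id!r} lacks trials in one condition "
            f"(related={rel.size}, unrelated={unrel.size})"
        )
    return DeltaProfile(
        unit_id=str(unit_id),
        unit_kind=unit_kind,
        related=vincentize(rel, k),
        unrelated=vincentize(unrel, k),
        mean_effect=float(rel.mean() - unrel.mean()),
        n_related=int(rel.size),
        n_unrelated=int(unrel.size),
    )


def segment_slope(profile: DeltaProfile, segment: str = "slowest") -> SegmentSlope:
    """Slope of the named delta segment.

    ``fastest`` uses quintiles (1, 2); ``slowest`` uses (4, 5). Raises
    :class:`DegenerateProfileError` when the combined quintile means of
    the segment coincide (zero denominator).
    """
    try:
        a, b = SEGMENTS[segment]
    except KeyError:
        raise ValueError(f"segment must be one of {sorted(SEGMENTS)}, got {segment!r}") from None
    deltas, combined = profile.deltas, profile.combined
    denom = combined[b] - combined[a]
    if denom == 0.0:
        raise DegenerateProfileError(
            f"unit {profile.unit_id!r}: combined quintile means equal across segment {segment!r}"
        )
    return SegmentSlope(segment=segment, value=(deltas[b] - deltas[a]) / denom)


def unit_profiles(
    trials: TrialTable,
    unit_kind: str = "participant",
    k: int = 5,
) -> list[DeltaProfile]:
    """One :class:`DeltaProfile` per unit, in first-appearance order.

    Units missing a condition (possible when the table was not
    sparsity-excluded for this ``unit_kind``) are skipped with a logged
    exclusion rather than an error.
    """
    if unit_kind not in ("participant", "item"):
        raise ValueError(f"unit_kind must be 'participant' or 'item', got {unit_kind!r}")
    if len(trials) == 0:
        logger.warning("unit_profiles: empty trial table")
        return []
    profiles = []
    for unit_id, group in trials.data.groupby(unit_kind, sort=False):
        try:
            profiles.append(delta_profile(group, unit_id=str(unit_id), unit_kind=unit_kind, k=k))
        except InsufficientDataError as exc:
            logger.warning("unit_profiles: excluding %s %r: %s", unit_kind, unit_id, exc)
    return profiles


def profiles_frame(profiles: Iterable[DeltaProfile]) -> pd.DataFrame:
    """Tabulate profiles for export: quintile means per condition, deltas,
    mean effect and the two segment slopes (NaN for degenerate units)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"unit_kind": p.unit_kind, "unit_id": p.unit_id}
        for q in range(p.k):
            row[f"related_q{q + 1}"] = p.related.means[q]
            row[f"unrelated_q{q + 1}"] = p.unrelated.means[q]
        for q, d in enumerate(p.deltas):
            row[f"delta{q + 1}"] = d
        row["mean_effect"] = p.mean_effect
        for seg in ("fastest", "slowest"):
            try:
                row[f"slope_{seg}"] = segment_slope(p, seg).value
            except DegenerateProfileError:
                row[f"slope_{seg}"] = np.nan
        row["n_related"] = p.n_related
        row["n_unrelated"] = p.n_unrelated
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(profiles: Iterable[DeltaProfile], path: str | Path, sep: str = ",") -> None:
    profiles_frame(profiles).to_csv(path, sep=sep, index=False)
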
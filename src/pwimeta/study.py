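"""Per-study summaries feeding the meta-analysis.

Two kinds of study-level effect are extracted from trial data:

* the semantic interference effect (ms) in each quintile, summarised
  across participants (mean of per-participant quintile deltas, with
  standard error sd/sqrt(n));
* the Pearson correlation, across units, between a unit's delta-segment
  slope and its mean interference effect, carried into the meta-analysis
  on the Fisher-z scale with SE = 1/sqrt(n - 3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pwimeta.core_data import TrialTable
from pwimeta.delta import DeltaProfile, DegenerateProfileError, segment_slope, unit_profiles
from pwimeta.errors import InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyEffect:
    """One study's observed effect and its standard error.

    ``quantity`` identifies what ``y`` measures: ``quintile_effect_q<j>``
    (ms) or ``correlation_slowest`` / ``correlation_fastest`` (Fisher-z
    units).
    """

    study_id: str
    quantity: str
    y: float
    se: float
    n_units: int


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its Fisher-z transform."""

    r: float
    n: int
    z: float

    @property
    def se_z(self) -> float:
        return fisher_z_se(self.n)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform, z = atanh(r) =
    0.5*ln((1+r)/(1-r)); requires \\|r\\| < 1."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"fisher_z requires |r| < 1, got {r}")
    return math.atanh(r)


def fisher_z_inverse(z: float) -> float:
    """Inverse transform r = tanh(z)."""
    return math.tanh(z)


def fisher_z_se(n: int) -> float:
    """Large-sample standard error of a Fisher-z score, 1/sqrt(n - 3)."""
    if n < 4:
        raise InsufficientDataError(f"Fisher-z SE needs n >= 4 units, got {n}")
    return 1.0 / math.sqrt(n - 3)


def quintile_effects(
    trials: TrialTable,
    study_id: str | None = None,
    k: int = 5,
) -> list[StudyEffect]:
    """Per-quintile interference effects of one study.

    For each quintile q, ``y`` is the mean over participants of the
    participant's delta at q and ``se`` is the across-participant
    sd/sqrt(n). Requires at least two retained participants (the SE is
    undefined for one).
    """
    profiles = unit_profiles(trials, unit_kind="participant", k=k)
    if len(profiles) < 2:
        raise InsufficientDataError(
            f"quintile effects need >= 2 participants, got {len(profiles)}"
        )
    if study_id is None:
        study_id = str(trials.data["study"].iloc[0]) if len(trials) else ""
    deltas = np.array([p.deltas for p in profiles])  # (n_participants, k)
    n = deltas.shape[0]
    y = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        logger.warning("quintile_effects: zero between-participant variance in some quintile")
    se = sd / math.sqrt(n)
    return [
        StudyEffect(study_id=study_id, quantity=f"quintile_effect_q{q + 1}",
                    y=float(y[q]), se=float(se[q]), n_units=n)
        for q in range(k)
    ]


def slope_effect_correlation(
    profiles: Sequence[DeltaProfile],
    segment: str = "slowest",
) -> CorrelationResult:
    """Pearson correlation, across units, between the named delta-segment
    slope and the mean interference effect.

    Units with a degenerate (zero-denominator) slope are dropped
    pairwise; ``n`` reflects the drop. Raises on fewer than 4 usable
    units or zero variance in either variable; a perfect \\|r\\| = 1 is
    returned with an infinite-z warning (such studies cannot enter the
    meta-analysis).
    """
    slopes, effects = [], []
    for p in profiles:
        try:
            slopes.append(segment_slope(p, segment).value)
            effects.append(p.mean_effect)
        except DegenerateProfileError as exc:
            logger.warning("slope_effect_correlation: %s", exc)
    n = len(slopes)
    if n < 4:
        raise InsufficientDataError(f"correlation needs >= 4 units with finite slopes, got {n}")
    s = np.asarray(slopes)
    e = np.asarray(effects)
    if s.std() == 0.0 or e.std() == 0.0:
        raise InsufficientDataError("correlation undefined: zero variance in slopes or effects")
    r = float(np.corrcoef(s, e)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # perfectly collinear up to rounding
        r = math.copysign(1.0, r)
        logger.warning("slope_effect_correlation: |r| = 1, Fisher z infinite")
        return CorrelationResult(r=r, n=n, z=math.copysign(math.inf, r))
    return CorrelationResult(r=r, n=n, z=fisher_z(r))


def correlation_effect(
    result: CorrelationResult,
    study_id: str,
    segment: str,
) -> StudyEffect:
    """Package a correlation as a meta-analysis input row (Fisher-z scale)."""
    if not math.isfinite(result.z):
        raise ValueError(f"study {study_id!r}: infinite Fisher z cannot enter the meta-analysis")
    return StudyEffect(
        study_id=study_id,
        quantity=f"correlation_{segment}",
        y=result.z,
        se=result.se_z,
        n_units=result.n,
    )


def effects_frame(effects: Iterable[StudyEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"study_id": e.study_id, "quantity": e.quantity, "y": e.y, "se": e.se, "n_units": e.n_units}
            for e in effects
        ]
    )


def write_effects(effects: Iterable[StudyEffect], path: str | Path, sep: str = ",") -> None:
    """Write the StudyEffect table — the meta-analysis input contract."""
    effects_frame(effects).to_csv(path, sep=sep, index=False)


def read_effects(path: str | Path, sep: str = ",") -> list[StudyEffect]:
    frame = pd.read_csv(path, sep=sep)
    required = {"study_id", "quantity", "y", "se", "n_units"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"effects table missing column(s): {sorted(missing)}")
    return [
        StudyEffect(
            study_id=str(row.study_id),
            quantity=str(row.quantity),
            y=float(row.y),
            se=float(row.se),
            n_units=int(row.n_units),
        )
        for row in frame.itertuples()
    ]
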
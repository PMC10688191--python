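"""Residue-level summary metrics and state-conditioned property analysis.

ANSR (angle switch ratio) is the fraction of a residue's enumerable
angles that are switches; ATSC (atom switch contribution) counts, for
each selected atom, how many switch angles contain it (vertex and end
atoms alike), so the ATSC values of a residue always sum to three times
its switch-angle count.  A state-conditioned property summary relates a
binary angular-state trace to any per-frame global property (RMSD,
activation level, helix-helix distance, ...) through per-state means and
the point-biserial correlation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import AtomTriplet
from .stability import StateTrace

__all__ = [
    "Ansr",
    "StatePropertySummary",
    "ResidueReport",
    "ansr",
    "atsc",
    "state_property_summary",
    "report",
]

_GRADE_ORDER = {"SS": 0, "US": 1, "nonswitch": 2}


@dataclass(frozen=True)
class Ansr:
    """Angle switch ratio as an explicit fraction (e.g. 2/10)."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator or self.denominator < 1:
            raise ValueError(f"invalid ANSR fraction {self.numerator}/{self.denominator}")

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def ansr(switch_flags: Iterable[int] | Mapping[str, int]) -> Ansr:
    """ANSR from per-triplet switch flags (all triplets of one residue)."""
    flags = list(switch_flags.values()) if isinstance(switch_flags, Mapping) else list(switch_flags)
    if not flags:
        raise ValueError("ANSR requires at least one classified triplet")
    return Ansr(sum(int(bool(f)) for f in flags), len(flags))


def atsc(switch_triplets: Sequence[AtomTriplet | tuple[str, str, str] | str]) -> dict[str, int]:
    """Per-atom switch contributions, ordered by count descending then name.

    Accepts :class:`AtomTriplet` objects, (a, vertex, b) tuples, or
    "A-V-B" labels.  Every atom of a switch triplet contributes 1.
    """
    counts: Counter[str] = Counter()
    for t in switch_triplets:
        if isinstance(t, AtomTriplet):
            names = t.atoms
        elif isinstance(t, str):
            names = tuple(t.split("-"))
        else:
            names = tuple(t)
        if len(names) != 3 or len(set(names)) != 3:
            raise ValueError(f"switch triplet must name three distinct atoms, got {t!r}")
        counts.update(names)
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


@dataclass(frozen=True)
class StatePropertySummary:
    """Per-angular-state summary of a global per-frame property."""

    mean_state0: float
    mean_state1: float
    count_state0: int
    count_state1: int
    mean_difference: float   # mean_state1 - mean_state0
    correlation: float       # point-biserial between state and property


def state_property_summary(
    trace: StateTrace | np.ndarray, values: Sequence[float]
) -> StatePropertySummary:
    """Relate a binary state trace to a frame-aligned property series.

    The correlation is point-biserial (Pearson correlation of the binary
    state with the property); it is defined as 0 when either series is
    constant.
    """
    states = trace.states if isinstance(trace, StateTrace) else np.asarray(trace, dtype=int)
    vals = np.asarray(values, dtype=float)
    if states.size != vals.size:
        raise ValueError(
            f"state trace has {states.size} frames but property series has {vals.size}"
        )
    m0 = states == 0
    m1 = states == 1
    mean0 = float(vals[m0].mean()) if m0.any() else float("nan")
    mean1 = float(vals[m1].mean()) if m1.any() else float("nan")
    if m0.any() and m1.any() and np.ptp(vals) > 0:
        corr = float(stats.pointbiserialr(states, vals).statistic)
        if not np.isfinite(corr):
            corr = 0.0
    else:
        corr = 0.0
    diff = (mean1 - mean0) if (m0.any() and m1.any()) else 0.0
    return StatePropertySummary(
        mean_state0=mean0 if m0.any() else 0.0,
        mean_state1=mean1 if m1.any() else 0.0,
        count_state0=int(m0.sum()),
        count_state1=int(m1.sum()),
        mean_difference=float(diff),
        correlation=corr,
    )


@dataclass
class ResidueReport:
    """Full switch summary for one residue."""

    residue_index: int
    residue_name: str
    is_switch: bool
    grade: str  # SS | US | nonswitch
    ansr: Ansr
    atsc: dict[str, int] = field(default_factory=dict)
    switch_triplets: list[str] = field(default_factory=list)
    selection_atoms: tuple[str, ...] = ()
    property_summary: StatePropertySummary | None = None

    def __post_init__(self) -> None:
        if self.grade not in _GRADE_ORDER:
            raise ValueError(f"grade must be SS, US, or nonswitch, got {self.grade!r}")
        if sum(self.atsc.values()) != 3 * self.ansr.numerator:
            raise ValueError(
                "ATSC conservation violated: counts must sum to 3 x switch-angle count"
            )
        if self.selection_atoms and not set(self.atsc) <= set(self.selection_atoms):
            raise ValueError("ATSC names atoms outside the residue selection")

    @property
    def atsc_label(self) -> str:
        return ", ".join(f"{a}:{c}" for a, c in self.atsc.items())


def report(residues: Sequence[ResidueReport]) -> pd.DataFrame:
    """Ranked switch-residue table: SS first, then by ANSR descending,
    ties by residue index.  Nonswitch residues are omitted.
    """
    ids = [r.residue_index for r in residues]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate residue identifiers in report input")
    switches = [r for r in residues if r.is_switch]
    switches.sort(key=lambda r: (_GRADE_ORDER[r.grade], -r.ansr.value, r.residue_index))
    return pd.DataFrame(
        {
            "residue_index": [r.residue_index for r in switches],
            "residue_name": [r.residue_name for r in switches],
            "grade": [r.grade for r in switches],
            "ansr": [str(r.ansr) for r in switches],
            "ansr_value": [r.ansr.value for r in switches],
            "atsc": [r.atsc_label for r in switches],
            "switch_triplets": [";".join(r.switch_triplets) for r in switches],
        }
    )
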
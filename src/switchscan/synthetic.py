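"""Ground-truth generators for angle dynamics, labeled corpora, and toy trajectories.

The generators emulate the four qualitative classes of residue-angle
dynamics seen in MD data: unimodal (nonswitch), stable switch (one
scheduled jump between two angular states), unstable switch (constant
two-state oscillation, modeled as a symmetric first-order Markov chain),
and bimodal-with-intermediate (a populated third state between the two
main modes, which disqualifies the angle as a switch).  Angular noise is
truncated-Gaussian around the active mode center, confined to [0, pi].

Defaults mirror typical switch geometry in receptor trajectories:
mode centers near 1.6 and 2.5 rad (separation ~0.9 rad) with spreads of
~0.08 rad.  Everything is reproducible bit-for-bit from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .classifier import LabeledFeatureSet
from .dos import FEATURE_NAMES, build_dos, extract_features
from .geometry import AngleSeries, AtomTriplet

__all__ = [
    "AngleDynamicsSpec",
    "SyntheticSeries",
    "ToySystem",
    "gen_angle_series",
    "gen_labeled_corpus",
    "gen_toy_trajectory",
]

MODES = ("unimodal", "ss", "us", "multimodal_with_intermediate")

DEFAULT_CENTERS = (1.6, 2.5)     # rad
DEFAULT_SPREAD = 0.08            # rad
DEFAULT_US_SWITCH_RATE = 0.1     # per-frame switching probability


@dataclass(frozen=True)
class AngleDynamicsSpec:
    """Declarative description of one synthetic angle's dynamics."""

    mode: str
    centers: tuple[float, ...] = DEFAULT_CENTERS
    spreads: tuple[float, ...] = (DEFAULT_SPREAD, DEFAULT_SPREAD)
    weights: tuple[float, ...] | None = None       # multimodal only
    schedule: tuple[int, ...] | None = None        # ss only: transition frames
    switch_rate: float | None = None               # us only
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if len(self.centers) != len(self.spreads):
            raise ValueError("need one spread per mode center")
        if len(set(self.centers)) != len(self.centers):
            raise ValueError("mode centers must be pairwise distinct")
        for c in self.centers:
            if not 0.0 < c < math.pi:
                raise ValueError(f"mode center {c} outside (0, pi)")
        for s in self.spreads:
            if not s > 0:
                raise ValueError("mode spreads must be positive")
        if self.mode == "unimodal" and len(self.centers) < 1:
            raise ValueError("unimodal dynamics need one center")
        if self.mode in ("ss", "us") and len(self.centers) < 2:
            raise ValueError("switch dynamics need two centers")
        if self.mode == "multimodal_with_intermediate":
            if len(self.centers) < 3:
                raise ValueError("intermediate-state dynamics need >= 3 centers")
            w = self.weights
            if w is None or len(w) != len(self.centers):
                raise ValueError("need one mixture weight per center")
            if any(x <= 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("mixture weights must be positive and sum to 1")
        if self.schedule is not None:
            sched = self.schedule
            if list(sched) != sorted(set(sched)):
                raise ValueError("transition schedule must be strictly increasing")
            if sched and (sched[0] < 1 or sched[-1] >= self.n_frames):
                raise ValueError("transition frames must lie in [1, n_frames)")
        if self.switch_rate is not None and not 0.0 <= self.switch_rate <= 1.0:
            raise ValueError("switch rate must be a probability")


@dataclass
class SyntheticSeries:
    """A generated angle series plus its ground truth."""

    series: AngleSeries
    states: np.ndarray               # generating mode index per frame
    switch_label: int                # 1 for clean bimodal (ss/us)
    stability_label: str | None      # 'SS' | 'US' | None
    spec: AngleDynamicsSpec = field(repr=False, default=None)

    @property
    def true_transitions(self) -> int:
        return int(np.count_nonzero(np.diff(self.states)))


def _state_schedule(spec: AngleDynamicsSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_frames
    if spec.mode == "unimodal":
        return np.zeros(n, dtype=int)
    if spec.mode == "ss":
        sched = spec.schedule if spec.schedule is not None else (n // 2,)
        states = np.zeros(n, dtype=int)
        cur = 0
        prev = 0
        for t in sched:
            states[prev:t] = cur
            cur ^= 1
            prev = t
        states[prev:] = cur
        return states
    if spec.mode == "us":
        rate = spec.switch_rate if spec.switch_rate is not None else DEFAULT_US_SWITCH_RATE
        flips = rng.random(n - 1) < rate
        return np.r_[0, np.cumsum(flips)] % 2
    # multimodal_with_intermediate: i.i.d. categorical occupancy
    return rng.choice(len(spec.centers), size=n, p=spec.weights)


def gen_angle_series(
    spec: AngleDynamicsSpec,
    triplet: AtomTriplet | None = None,
    noiseless: bool = False,
) -> SyntheticSeries:
    """Generate one angle series from a dynamics spec, with ground truth.

    Per-frame values are truncated-Gaussian around the active mode center,
    confined to [0, pi]; ``noiseless=True`` emits the bare center schedule.
    """
    rng = np.random.default_rng(spec.seed)
    states = _state_schedule(spec, rng)
    centers = np.asarray(spec.centers)
    if noiseless:
        values = centers[states].astype(float)
    else:
        values = np.empty(spec.n_frames)
        for k in range(len(spec.centers)):
            idx = states == k
            if not idx.any():
                continue
            loc, scale = spec.centers[k], spec.spreads[k]
            a, b = (0.0 - loc) / scale, (math.pi - loc) / scale
            values[idx] = truncnorm.rvs(
                a, b, loc=loc, scale=scale, size=int(idx.sum()), random_state=rng
            )
    trip = triplet or AtomTriplet(0, "N", "CA", "O")
    series = AngleSeries(trip, values)
    switch = 1 if spec.mode in ("ss", "us") else 0
    stab = {"ss": "SS", "us": "US"}.get(spec.mode)
    return SyntheticSeries(series, states, switch, stab, spec)


# ---------------------------------------------------------------------------
# Labeled feature corpus
# ---------------------------------------------------------------------------

def _draw_corpus_spec(
    class_name: str, rng: np.random.Generator, n_frames: int
) -> AngleDynamicsSpec:
    """Randomize mode geometry within clear-margin ranges for one corpus item."""
    seed = int(rng.integers(0, 2**31 - 1))
    if class_name == "unimodal":
        c = float(rng.uniform(1.0, 2.2))
        s = float(rng.uniform(0.05, 0.15))
        return AngleDynamicsSpec("unimodal", (c,), (s,), n_frames=n_frames, seed=seed)
    c0 = float(rng.uniform(1.3, 1.7))
    sep = float(rng.uniform(0.7, 1.0))
    s0 = float(rng.uniform(0.05, 0.09))
    s1 = float(rng.uniform(0.05, 0.09))
    if class_name == "bimodal":
        mode = "ss" if rng.random() < 0.5 else "us"
        if mode == "ss":
            t = int(rng.integers(n_frames // 4, 3 * n_frames // 4))
            return AngleDynamicsSpec(
                mode, (c0, c0 + sep), (s0, s1), schedule=(t,), n_frames=n_frames, seed=seed
            )
        rate = float(rng.uniform(0.08, 0.25))
        return AngleDynamicsSpec(
            mode, (c0, c0 + sep), (s0, s1), switch_rate=rate, n_frames=n_frames, seed=seed
        )
    if class_name == "intermediate":
        mid = c0 + sep * float(rng.uniform(0.4, 0.6))
        w_mid = float(rng.uniform(0.15, 0.35))
        w0 = float(rng.uniform(0.4, 0.6)) * (1.0 - w_mid)
        sm = float(rng.uniform(0.05, 0.08))
        return AngleDynamicsSpec(
            "multimodal_with_intermediate",
            (c0, mid, c0 + sep),
            (s0, sm, s1),
            weights=(w0, w_mid, 1.0 - w_mid - w0),
            n_frames=n_frames,
            seed=seed,
        )
    raise ValueError(f"unknown corpus class {class_name!r}")


def gen_labeled_corpus(
    n_per_class: int = 200,
    seed: int = 0,
    n_frames: int = 2000,
    n_bins: int = 90,
    classes: Sequence[str] = ("unimodal", "bimodal", "intermediate"),
) -> tuple[LabeledFeatureSet, pd.DataFrame]:
    """Balanced labeled corpus of DoS feature vectors with ground truth.

    Only the clean-bimodal class carries switch label 1.  Returns the
    feature set and a truth table (identifier, class, label, stability).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: list[int] = []
    truth_rows: list[dict] = []
    for class_name in classes:
        for i in range(n_per_class):
            spec = _draw_corpus_spec(class_name, rng, n_frames)
            item = gen_angle_series(spec)
            fv = extract_features(build_dos(item.series, n_bins))
            ident = f"{class_name}_{i:04d}"
            ids.append(ident)
            rows.append(fv.to_array())
            labels.append(item.switch_label)
            truth_rows.append(
                {
                    "identifier": ident,
                    "class": class_name,
                    "label": item.switch_label,
                    "stability_label": item.stability_label or "",
                    "seed": spec.seed,
                }
            )
    dataset = LabeledFeatureSet(ids, np.vstack(rows), np.array(labels))
    return dataset, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Toy 3-D trajectories
# ---------------------------------------------------------------------------

#: static local geometry of one toy ALA residue, nm, relative to CA at origin.
#: O is the moving atom: it orbits CA in the xy-plane at _ARM_O so that the
#: N-CA-O angle realizes the prescribed schedule exactly (N lies on +x).
_ARM_N = 0.15
_ARM_O = 0.24
_STATIC_OFFSETS = {
    "N": (_ARM_N, 0.0, 0.0),
    "CB": (-0.10, -0.12, 0.05),
    "C": (-0.05, 0.10, -0.06),
}
_STATIC_O_ANGLE = 1.9  # rad, for residues without dynamics


@dataclass
class ToySystem:
    """A generated toy topology/trajectory pair with per-residue ground truth."""

    pdb_path: Path
    trajectory_paths: list[Path]
    truth: dict[int, SyntheticSeries]   # residue_index -> designated-angle truth
    designated_triplet: tuple[str, str, str] = ("N", "CA", "O")


def gen_toy_trajectory(
    residue_specs: Sequence[AngleDynamicsSpec | None],
    out_dir: str | Path,
    stem: str = "toy",
    n_trajectories: int = 1,
) -> ToySystem:
    """Build a PDB + DCD toy system realizing prescribed angle schedules.

    Each entry of ``residue_specs`` creates one ALA residue; ``None`` gives
    a static (nonswitch) residue.  In each dynamic residue the O atom
    rotates in-plane around the CA vertex so that the designated N-CA-O
    angle equals the generated schedule exactly; all other atoms are
    static.  The trajectory can be split into ``n_trajectories`` DCD files
    of equal length to exercise multi-trajectory pooling.
    """
    import mdtraj as md

    if not residue_specs:
        raise ValueError("at least one residue spec (or None) is required")
    n_frames_set = {s.n_frames for s in residue_specs if s is not None}
    if len(n_frames_set) > 1:
        raise ValueError("all residue specs must share n_frames")
    n_frames = n_frames_set.pop() if n_frames_set else 100
    if n_trajectories < 1 or n_frames % n_trajectories != 0:
        raise ValueError("n_trajectories must divide n_frames")

    top = md.Topology()
    chain = top.add_chain()
    atom_order = ("N", "CA", "CB", "C", "O")
    elements = {
        "N": md.element.nitrogen,
        "CA": md.element.carbon,
        "CB": md.element.carbon,
        "C": md.element.carbon,
        "O": md.element.oxygen,
    }
    truth: dict[int, SyntheticSeries] = {}
    coords = np.zeros((n_frames, 5 * len(residue_specs), 3))
    for r, spec in enumerate(residue_specs):
        res_seq = r + 1
        res = top.add_residue("ALA", chain, resSeq=res_seq)
        for name in atom_order:
            top.add_atom(name, elements[name], res)
        base = np.array([0.0, 0.0, 0.6 * r])  # keep coords small: DCD is float32
        offset = 5 * r
        for name, rel in _STATIC_OFFSETS.items():
            coords[:, offset + atom_order.index(name)] = base + np.asarray(rel)
        coords[:, offset + atom_order.index("CA")] = base
        if spec is None:
            theta = np.full(n_frames, _STATIC_O_ANGLE)
        else:
            item = gen_angle_series(spec)
            truth[res_seq] = item
            theta = item.series.values
        io = offset + atom_order.index("O")
        coords[:, io, 0] = base[0] + _ARM_O * np.cos(theta)
        coords[:, io, 1] = base[1] + _ARM_O * np.sin(theta)
        coords[:, io, 2] = base[2]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj = md.Trajectory(coords.astype(np.float32), top)
    pdb_path = out_dir / f"{stem}.pdb"
    traj[0].save_pdb(str(pdb_path))
    traj_paths: list[Path] = []
    chunk = n_frames // n_trajectories
    for t in range(n_trajectories):
        p = out_dir / (f"{stem}.dcd" if n_trajectories == 1 else f"{stem}_{t:02d}.dcd")
        traj[t * chunk : (t + 1) * chunk].save_dcd(str(p))
        traj_paths.append(p)
    return ToySystem(pdb_path, traj_paths, truth)
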
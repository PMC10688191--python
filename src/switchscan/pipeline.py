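"""End-to-end scan: geometry -> DoS -> switch calls -> stability -> report.

``run_scan`` executes the full chain on a topology/trajectory set and
writes features, per-angle calls, a stability table, the ranked residue
report (CSV + JSON), and a provenance record.  With fixed seeds and
config the outputs are byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classifier import SwitchModel, predict, residue_rollup, train, load_model
from .dos import build_dos, extract_features, heuristic_label
from .geometry import (
    STANDARD_RESIDUES,
    TrajectorySet,
    angle_series,
    enumerate_triplets,
    load_selection_table,
)
from .io import PipelineConfig, read_property_csv, write_features_csv
from .metrics import Ansr, ResidueReport, ansr, atsc, report, state_property_summary
from .stability import (
    StabilityModel,
    assign_states,
    classify_stability,
    instability_ratio,
    train_stability_classifier,
)
from .synthetic import gen_labeled_corpus

__all__ = ["ScanResult", "run_scan", "default_stability_model"]

logger = logging.getLogger("switchscan")

# synthetic instability-ratio corpus for the default logistic SS/US model:
# SS examples drawn below 1%, US examples above 6% (the unambiguous regimes)
_SS_RATIO_RANGE = (0.05, 0.95)   # percent
_US_RATIO_RANGE = (6.5, 30.0)    # percent
_N_RATIO_EXAMPLES = 100          # per class


def default_stability_model(seed: int = 0) -> StabilityModel:
    """Logistic SS/US model trained on synthetic clear-regime ratios."""
    rng = np.random.default_rng(seed)
    ss = rng.uniform(*_SS_RATIO_RANGE, _N_RATIO_EXAMPLES)
    us = rng.uniform(*_US_RATIO_RANGE, _N_RATIO_EXAMPLES)
    ratios = np.r_[ss, us]
    labels = ["SS"] * _N_RATIO_EXAMPLES + ["US"] * _N_RATIO_EXAMPLES
    return train_stability_classifier(ratios, labels, seed=seed)


@dataclass
class ScanResult:
    residues: list[ResidueReport]
    report_table: "object"            # pandas DataFrame
    feature_rows: list[dict]
    stability_rows: list[dict]
    switch_model: SwitchModel | None
    stability_model: StabilityModel
    output_dir: Path | None = None
    provenance: dict = field(default_factory=dict)


def _resolve_switch_model(config: PipelineConfig) -> SwitchModel | None:
    if config.classifier_kind == "heuristic":
        return None
    if config.classifier_model:
        logger.info("loading switch model from %s", config.classifier_model)
        return load_model(config.classifier_model)
    logger.info(
        "training %s switch model on synthetic corpus (%d per class, seed %d)",
        config.classifier_kind,
        config.corpus_per_class,
        config.seed,
    )
    corpus, _ = gen_labeled_corpus(
        n_per_class=config.corpus_per_class,
        seed=config.seed,
        n_frames=config.corpus_n_frames,
        n_bins=config.n_bins,
    )
    return train(corpus, config.classifier_kind, seed=config.seed)


def run_scan(
    config: PipelineConfig,
    trajectories: TrajectorySet | None = None,
    write_outputs: bool = True,
) -> ScanResult:
    """Run the full switch-residue scan described by ``config``.

    ``trajectories`` may be passed directly (e.g. a synthetic system held
    in memory); otherwise topology/trajectory paths from the config are
    loaded.  Stage errors propagate with the stage, residue, and triplet
    named in the message.
    """
    if trajectories is None:
        if not config.topology or not config.trajectories:
            raise ValueError("config must name a topology and >= 1 trajectory")
        trajectories = TrajectorySet.from_files(config.topology, config.trajectories)
    logger.info(
        "geometry stage: %d frames from %d trajectories",
        trajectories.n_frames,
        len(trajectories.segments),
    )

    table = load_selection_table(config.selection_table)
    switch_model = _resolve_switch_model(config)
    stability_model = default_stability_model(config.seed)
    property_values = (
        read_property_csv(config.property_series) if config.property_series else None
    )

    feature_rows: list[dict] = []
    stability_rows: list[dict] = []
    residues: list[ResidueReport] = []
    n_angles = 0

    for res in trajectories.topology.residues:
        if res.name not in STANDARD_RESIDUES or res.name not in table:
            logger.info("skipping residue %s%d: no selection", res.name, res.resSeq)
            continue
        selection = table[res.name]
        present = {a.name for a in res.atoms}
        if not set(selection.atoms) <= present:
            missing = sorted(set(selection.atoms) - present)
            logger.info(
                "skipping residue %s%d: selection atoms %s absent",
                res.name,
                res.resSeq,
                missing,
            )
            continue
        triplets = enumerate_triplets(selection, residue_index=res.resSeq)
        per_angle: dict[str, int] = {}
        per_angle_series = {}
        for trip in triplets:
            try:
                s = angle_series(trajectories, res.resSeq, trip)
                d = build_dos(s, config.n_bins)
                fv = extract_features(
                    d, config.smooth_window, config.min_prominence, config.min_separation_bins
                )
            except Exception as exc:
                raise RuntimeError(
                    f"dos stage failed for residue {res.name}{res.resSeq} "
                    f"triplet {trip.label}: {exc}"
                ) from exc
            if switch_model is None:
                call = heuristic_label(
                    d,
                    smooth_window=config.smooth_window,
                    min_prominence=config.min_prominence,
                    min_separation_bins=config.min_separation_bins,
                ).value
            else:
                call = int(predict(switch_model, fv.to_array())[0])
            per_angle[trip.label] = call
            per_angle_series[trip.label] = s
            feature_rows.append(
                {
                    "residue_index": res.resSeq,
                    "residue_name": res.name,
                    "triplet": trip.label,
                    **fv.to_dict(),
                    "switch_call": call,
                }
            )
            n_angles += 1

        is_switch, switch_trips = residue_rollup(per_angle)
        grade = "nonswitch"
        prop_summary = None
        if is_switch:
            grades = []
            for lab in switch_trips:
                s = per_angle_series[lab]
                try:
                    trace = assign_states(s, seed=config.seed)
                except ValueError:
                    continue  # constant series cannot be a real switch
                rec = instability_ratio(trace)
                g = classify_stability(stability_model, rec)
                grades.append(g)
                stability_rows.append(
                    {
                        "residue_index": res.resSeq,
                        "residue_name": res.name,
                        "triplet": lab,
                        "transitions": rec.transitions,
                        "n_frames": rec.n_frames,
                        "ratio_percent": rec.ratio_percent,
                        "grade": g,
                    }
                )
                if property_values is not None and prop_summary is None and g == "SS":
                    prop_summary = state_property_summary(trace, property_values)
            # a residue is SS if any of its switch angles is stable
            grade = "SS" if "SS" in grades else ("US" if grades else "nonswitch")
            if not grades:
                is_switch, switch_trips = False, []
        residues.append(
            ResidueReport(
                residue_index=res.resSeq,
                residue_name=res.name,
                is_switch=is_switch,
                grade=grade,
                ansr=ansr(per_angle),
                atsc=atsc(switch_trips),
                switch_triplets=switch_trips,
                selection_atoms=selection.atoms,
                property_summary=prop_summary,
            )
        )

    logger.info(
        "classified %d angles over %d residues; %d switch residues",
        n_angles,
        len(residues),
        sum(r.is_switch for r in residues),
    )
    report_table = report(residues)
    provenance = {
        "config": dict(config.__dict__),
        "config_digest": config.digest(),
        "seed": config.seed,
        "switchscan_version": __version__,
        "n_frames": trajectories.n_frames,
        "n_trajectories": len(trajectories.segments),
        "n_residues": len(residues),
        "n_angles": n_angles,
    }

    out_dir = None
    if write_outputs:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_features_csv(feature_rows, out_dir / "features.csv")
        write_features_csv(stability_rows or [{}], out_dir / "stability.csv")
        report_table.to_csv(out_dir / "report.csv", index=False, float_format="%.12g")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report_table.to_dict(orient="records"), fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return ScanResult(
        residues,
        report_table,
        feature_rows,
        stability_rows,
        switch_model,
        stability_model,
        out_dir,
        provenance,
    )
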
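"""Shared configuration and the end-to-end pipeline run.

One YAML config wires every stage: input paths, the sample-to-role
mapping, detection thresholds, prediction limits, and an optional moiety
database file overriding the shipped default. Unknown keys are rejected so
a typo cannot silently disable a filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import annotate_record, annotation_coverage
from .chem import MoietyDatabase, default_database
from .cooccur import build_fragment_matrix, fragment_correlations, organ_correlation
from .detect import DetectionConfig, detect, detections_to_frame
from .io import read_alignment, read_mgf
from .predict import (
    PredictionConfig,
    candidates_to_frame,
    enumerate_candidates,
    score_candidates,
)

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "mgf", "areas", "sample_roles", "database", "detection", "prediction",
    "tolerance", "top_n_fragments",
}
_DETECTION_KEYS = {"blank_ratio_min", "area_min", "relative_intensity_min",
                   "fragment_match_tolerance", "keep_linked"}
_PREDICTION_KEYS = {"max_acyls", "acyl_pool", "precursor_tolerance", "min_sugars",
                    "max_sugars", "allow_water_loss", "adducts", "ring_states",
                    "hydroxyacyl_pool", "candidate_cap"}


@dataclass
class PipelineConfig:
    mgf: Path
    areas: Path
    sample_roles: dict[str, str]
    database: Path | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    tolerance: float = 0.01
    top_n_fragments: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for sub, allowed in (("detection", _DETECTION_KEYS),
                             ("prediction", _PREDICTION_KEYS)):
            bad = set(doc.get(sub, {})) - allowed
            if bad:
                raise ValueError(f"unknown {sub} config keys: {sorted(bad)}")
        det = DetectionConfig(**doc.get("detection", {}))
        pred_kwargs = dict(doc.get("prediction", {}))
        for key in ("acyl_pool", "adducts", "ring_states", "hydroxyacyl_pool"):
            if key in pred_kwargs and pred_kwargs[key] is not None:
                pred_kwargs[key] = tuple(pred_kwargs[key])
        pred = PredictionConfig(**pred_kwargs)
        return cls(
            mgf=Path(doc["mgf"]),
            areas=Path(doc["areas"]),
            sample_roles=dict(doc["sample_roles"]),
            database=Path(doc["database"]) if doc.get("database") else None,
            detection=det,
            prediction=pred,
            tolerance=float(doc.get("tolerance", 0.01)),
            top_n_fragments=int(doc.get("top_n_fragments", 20)),
        )

    def load_database(self) -> MoietyDatabase:
        if self.database is not None:
            return MoietyDatabase.from_yaml(self.database)
        return default_database()


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run detect -> annotate -> predict -> correlate and write one output
    file per stage plus a summary JSON. Deterministic for fixed inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = config.load_database()

    records = read_mgf(config.mgf)
    table = read_alignment(config.areas, config.sample_roles)
    spectra = {r.feature_id: r for r in records}

    detections, attrition = detect(records, table, db, config.detection)
    detections_to_frame(detections).to_csv(out / "detected.tsv", sep="\t", index=False)
    logger.info("detection attrition: %s", attrition)

    annotations = {}
    ann_json = {}
    for det_rg in detections:
        ann = annotate_record(spectra[det_rg.feature_id], db, config.tolerance,
                              config.top_n_fragments)
        annotations[det_rg.feature_id] = ann
        ann_json[det_rg.feature_id] = {
            "precursor_mz": ann.precursor_mz,
            "annotated_fraction": ann.annotated_fraction,
            "max_annotated_mz": ann.max_annotated_mz,
            "residual": ann.residual,
            "assignments": [
                {"mz": a.mz, "intensity": a.intensity,
                 "matches": [{"name": n, "theoretical_mz": t} for n, t in a.matches]}
                for a in ann.assignments
            ],
            "loss_edges": [
                {"higher_mz": e.higher_mz, "lower_mz": e.lower_mz, "loss": e.loss,
                 "candidates": list(e.candidates),
                 "from_precursor": e.from_precursor}
                for e in ann.loss_edges
            ],
        }
    (out / "annotations.json").write_text(json.dumps(
        {"version": __version__, "features": ann_json}, indent=1))

    frames = []
    n_predicted = 0
    for det_rg in detections:
        cands = enumerate_candidates(det_rg.precursor_mz, db, config.prediction)
        cands = score_candidates(cands, annotations[det_rg.feature_id], db,
                                 config.tolerance)
        if cands:
            n_predicted += 1
        frames.append(candidates_to_frame(det_rg.feature_id, cands))
    import pandas as pd
    pred_frame = (pd.concat(frames, ignore_index=True) if frames
                  else candidates_to_frame("", []))
    pred_frame.to_csv(out / "predictions.tsv", sep="\t", index=False)

    coverage = (annotation_coverage(list(annotations.values()))
                if annotations else 0.0)
    if len(detections) >= 2:
        matrix = build_fragment_matrix(detections, spectra)
        fragment_correlations(matrix).to_csv(out / "fragment_correlations.tsv",
                                             sep="\t", index=False)
    organ = organ_correlation(table, detections)

    summary = {
        "version": __version__,
        "n_input_features": len(records),
        "attrition": attrition,
        "n_detected": len(detections),
        "annotation_coverage": coverage,
        "n_with_prediction": n_predicted,
        "fraction_with_prediction": (n_predicted / len(detections)
                                     if detections else 0.0),
        "organ_pcc": organ.pcc,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
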
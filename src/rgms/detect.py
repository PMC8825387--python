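"""Separate likely true resin-glycoside peaks from noise.

Four filters are applied per species dataset, in order:

(i)   blank/area filter -- the MS1 peak area in leaf or root must exceed
      1000 and be more than 10x the blank area;
(iv)  linked-peak resolution -- of two linked features only one (by default
      the higher-mass one) is kept; adduct-labelled features are always
      retained;
(ii)  signature-pair filter -- the spectrum must contain at least one of
      the 30 hydroxyacyl / hydroxyacyl+sugar fragment pairs;
(iii) relative-intensity filter -- both members of a matching pair must
      exceed 10% of the base-peak intensity.

Features passing all filters get an organ call from the unnormalized leaf
and root areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem import MoietyDatabase, SignaturePair, signature_pair_table
from .io import AlignmentTable, SpectrumRecord

__all__ = ["DetectionConfig", "DetectedRG", "detect", "assign_organ",
           "filter_blank_area", "filter_signature_pairs", "resolve_linked_peaks"]


@dataclass
class DetectionConfig:
    blank_ratio_min: float = 10.0
    area_min: float = 1000.0
    relative_intensity_min: float = 0.10
    fragment_match_tolerance: float = 0.01  # Da; absorbs instrument drift
    keep_linked: str = "higher"  # higher | lower | both

    def __post_init__(self) -> None:
        if min(self.blank_ratio_min, self.area_min,
               self.relative_intensity_min, self.fragment_match_tolerance) <= 0:
            raise ValueError("all detection thresholds must be > 0")
        if self.keep_linked not in ("higher", "lower", "both"):
            raise ValueError(f"keep_linked must be higher/lower/both, got "
                             f"{self.keep_linked!r}")


@dataclass
class DetectedRG:
    feature_id: str
    precursor_mz: float
    retention_time: float
    matched_pairs: list[SignaturePair]
    organ_call: str
    leaf_area: float
    root_area: float
    blank_area: float
    provenance: dict[str, str] = field(default_factory=dict)


def filter_blank_area(
    record: SpectrumRecord, table: AlignmentTable, cfg: DetectionConfig
) -> tuple[bool, str]:
    """Filter (i): max(leaf, root) area must exceed area_min and the
    blank-ratio threshold. A blank area of 0 passes the ratio clause."""
    if record.feature_id not in table:
        raise KeyError(f"feature {record.feature_id!r} absent from alignment table")
    leaf, root = table.leaf_area(record.feature_id), table.root_area(record.feature_id)
    blank = table.blank_area(record.feature_id)
    best = max(leaf, root)
    if best <= cfg.area_min:
        return False, f"area {best:g} <= {cfg.area_min:g}"
    if blank > 0 and best <= cfg.blank_ratio_min * blank:
        return False, (f"area {best:g} <= {cfg.blank_ratio_min:g} x blank {blank:g}")
    return True, "pass"


def filter_signature_pairs(
    record: SpectrumRecord, pairs: list[SignaturePair], cfg: DetectionConfig
) -> list[SignaturePair]:
    """Filters (ii)+(iii): return signature pairs whose two fragments are
    both present within tolerance and both above the relative-intensity
    floor; empty means reject."""
    tol = cfg.fragment_match_tolerance
    matched = []
    for pair in pairs:
        if (record.relative_intensity(pair.acyl_mz, tol) > cfg.relative_intensity_min
                and record.relative_intensity(pair.combined_mz, tol)
                > cfg.relative_intensity_min):
            matched.append(pair)
    return matched


def resolve_linked_peaks(
    records: list[SpectrumRecord], cfg: DetectionConfig
) -> tuple[list[SpectrumRecord], list[str]]:
    """Filter (iv): for each feature linked to a higher-mass feature keep
    only one of the two (default the higher-mass one). Adduct-labelled
    features are always retained. Returns (kept, dropped ids)."""
    if cfg.keep_linked == "both":
        return list(records), []
    by_id = {r.feature_id: r for r in records}
    dropped: set[str] = set()
    for rec in records:
        if not rec.linked_to:
            continue
        partner = by_id.get(rec.linked_to)
        if partner is None:
            # dangling link: keep both, the export was inconsistent
            continue
        lower, higher = sorted((rec, partner), key=lambda r: r.precursor_mz)
        victim = lower if cfg.keep_linked == "higher" else higher
        if not victim.adduct_label:
            dropped.add(victim.feature_id)
    kept = [r for r in records if r.feature_id not in dropped]
    return kept, sorted(dropped)


def assign_organ(leaf_area: float, root_area: float,
                 area_min: float = 1000.0) -> str:
    """Organ call from unnormalized areas: >area_min in one organ and 0 in
    the other gives a single-organ call, >area_min in both gives ``both``,
    anything else is ``ambiguous``."""
    if leaf_area < 0 or root_area < 0:
        raise ValueError("areas must be non-negative")
    leaf_hi, root_hi = leaf_area > area_min, root_area > area_min
    if leaf_hi and root_area == 0:
        return "leaf_only"
    if root_hi and leaf_area == 0:
        return "root_only"
    if leaf_hi and root_hi:
        return "both"
    return "ambiguous"


def detect(
    records: list[SpectrumRecord],
    table: AlignmentTable,
    db: MoietyDatabase,
    cfg: DetectionConfig | None = None,
) -> tuple[list[DetectedRG], dict[str, int]]:
    """Run the full filter cascade; returns detections plus an attrition
    report counting rejects per filter. The result is independent of the
    input record order."""
    cfg = cfg or DetectionConfig()
    pairs = signature_pair_table(db)
    ordered = sorted(records, key=lambda r: r.feature_id)

    attrition = {"input": len(ordered), "blank_area": 0, "linked": 0,
                 "signature_pair": 0, "detected": 0}
    survivors: list[tuple[SpectrumRecord, str]] = []
    for rec in ordered:
        ok, reason = filter_blank_area(rec, table, cfg)
        if ok:
            survivors.append((rec, reason))
        else:
            attrition["blank_area"] += 1

    kept, dropped = resolve_linked_peaks([r for r, _ in survivors], cfg)
    attrition["linked"] = len(dropped)
    kept_ids = {r.feature_id for r in kept}

    detections: list[DetectedRG] = []
    for rec, blank_reason in survivors:
        if rec.feature_id not in kept_ids:
            continue
        matched = filter_signature_pairs(rec, pairs, cfg)
        if not matched:
            attrition["signature_pair"] += 1
            continue
        leaf = table.leaf_area(rec.feature_id)
        root = table.root_area(rec.feature_id)
        detections.append(
            DetectedRG(
                feature_id=rec.feature_id,
                precursor_mz=rec.precursor_mz,
                retention_time=rec.retention_time,
                matched_pairs=matched,
                organ_call=assign_organ(leaf, root, cfg.area_min),
                leaf_area=leaf,
                root_area=root,
                blank_area=table.blank_area(rec.feature_id),
                provenance={
                    "blank_area": blank_reason,
                    "linked": "kept",
                    "signature_pair": f"{len(matched)} pair(s)",
                },
            )
        )
    attrition["detected"] = len(detections)
    return detections, attrition


def detections_to_frame(detections: list[DetectedRG]) -> pd.DataFrame:
    """Tabular view of detections for TSV export."""
    rows = []
    for d in detections:
        rows.append({
            "feature_id": d.feature_id,
            "precursor_mz": round(d.precursor_mz, 6),
            "retention_time": round(d.retention_time, 4),
            "matched_pairs": ";".join(
                f"{p.hydroxyacyl}+{p.sugar_class}" for p in d.matched_pairs),
            "organ_call": d.organ_call,
            "leaf_area": d.leaf_area,
            "root_area": d.root_area,
            "blank_area": d.blank_area,
        })
    return pd.DataFrame(
        rows,
        columns=["feature_id", "precursor_mz", "retention_time", "matched_pairs",
                 "organ_call", "leaf_area", "root_area", "blank_area"],
    )
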
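"""Knowledge-based per-spectrum fragment annotation.

For each detected RG peak the top-20 most intense MS/MS fragments are
matched against a fragment database derived from the moiety database
(hydroxyacyl anions, hydroxyacyl plus one or two sugars, acyl fragment
ions, short sugar-chain ions). All pairwise fragment differences -- with
the precursor included as a pseudo-fragment node -- are then compared to a
neutral-loss database (sugar residues, acyl residues, water, CO2, formic
acid). A fragment counts as annotated when it carries at least one direct
assignment or participates in at least one recognized loss edge. The
residual between the highest annotated fragment and the precursor feeds
the combinatorial composition prediction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .chem import (
    CO2,
    FORMIC_ACID,
    SUGAR_CLASSES,
    WATER,
    MoietyDatabase,
)
from .detect import DetectedRG
from .io import SpectrumRecord

__all__ = [
    "FragmentAssignment",
    "NeutralLossEdge",
    "AnnotationResult",
    "top_fragments",
    "build_fragment_db",
    "build_loss_db",
    "match_fragments",
    "infer_neutral_losses",
    "annotate_record",
    "annotation_coverage",
    "scan_components",
]

PRECURSOR_NODE = "precursor"


@dataclass(frozen=True)
class FragmentAssignment:
    mz: float
    intensity: float
    matches: tuple[tuple[str, float], ...]  # (name, theoretical mz)

    @property
    def unmatched(self) -> bool:
        return not self.matches


@dataclass(frozen=True)
class NeutralLossEdge:
    higher_mz: float
    lower_mz: float
    loss: float
    candidates: tuple[str, ...]
    from_precursor: bool = False

    def __post_init__(self) -> None:
        if self.loss <= 0:
            raise ValueError("loss must be positive")


@dataclass
class AnnotationResult:
    feature_id: str
    precursor_mz: float
    assignments: list[FragmentAssignment]
    loss_edges: list[NeutralLossEdge]
    annotated_fraction: float
    n_annotated: int
    max_annotated_mz: float | None
    residual: float | None

    @property
    def n_fragments(self) -> int:
        return len(self.assignments)


def top_fragments(record: SpectrumRecord, n: int = 20) -> list[tuple[float, float]]:
    """The n most intense fragments; intensity ties broken by lower m/z."""
    if not record.fragments:
        return []
    ranked = sorted(record.fragments, key=lambda p: (-p[1], p[0]))
    return sorted(ranked[:n])


def build_fragment_db(db: MoietyDatabase, max_chain: int = 2) -> list[tuple[str, float]]:
    """Theoretical fragment masses derived from the moiety database.

    Entries: hydroxyacyl [M-H]-; hydroxyacyl plus 1..max_chain sugar
    residues; acyl fragment ions; deprotonated sugar chains of 1..3
    residues (B/C-type oligosaccharide ions are mass-degenerate at this
    resolution with the chain anion).
    """
    entries: list[tuple[str, float]] = []
    sugar_mass = {c: db.sugar_residue_mass(c) for c in SUGAR_CLASSES}
    for ha in db.hydroxyacyls.values():
        entries.append((ha.name, ha.fragment_mz))
        for k in range(1, max_chain + 1):
            for combo in itertools.combinations_with_replacement(SUGAR_CLASSES, k):
                mz = ha.fragment_mz + sum(sugar_mass[c] for c in combo)
                entries.append((f"{ha.name}+{'+'.join(combo)}", mz))
    for acyl in db.acyls.values():
        entries.append((acyl.name, acyl.fragment_mz))
    water_minus_proton = WATER - 1.007276  # deprotonated chain terminus
    for k in range(1, 4):
        for combo in itertools.combinations_with_replacement(SUGAR_CLASSES, k):
            mz = sum(sugar_mass[c] for c in combo) + water_minus_proton
            entries.append((f"sugar-chain:{'+'.join(combo)}", mz))
    return entries


def build_loss_db(db: MoietyDatabase) -> list[tuple[str, float]]:
    """Neutral-loss masses: sugar residues, acyl residues, water, CO2 and
    formic acid."""
    losses = [("water", WATER), ("CO2", CO2), ("formic_acid", FORMIC_ACID)]
    for c in SUGAR_CLASSES:
        losses.append((c, db.sugar_residue_mass(c)))
    for acyl in db.acyls.values():
        losses.append((acyl.name, acyl.residue_mass))
    return losses


def match_fragments(
    fragments: list[tuple[float, float]],
    fragment_db: list[tuple[str, float]],
    tol: float = 0.01,
) -> list[FragmentAssignment]:
    out = []
    for mz, inten in fragments:
        matches = tuple(
            (name, theo) for name, theo in fragment_db if abs(mz - theo) <= tol
        )
        out.append(FragmentAssignment(mz=mz, intensity=inten, matches=matches))
    return out


def infer_neutral_losses(
    fragments: list[tuple[float, float]],
    precursor_mz: float,
    loss_db: list[tuple[str, float]],
    tol: float = 0.01,
) -> list[NeutralLossEdge]:
    """Pairwise mass differences between fragments (and the precursor as an
    extra node) compared to the loss database. Each recognized difference
    yields one directed higher->lower edge."""
    nodes = [(mz, False) for mz, _ in fragments] + [(precursor_mz, True)]
    edges = []
    for (a, a_prec), (b, b_prec) in itertools.combinations(nodes, 2):
        hi, lo = (a, b) if a > b else (b, a)
        hi_prec = a_prec if a > b else b_prec
        diff = hi - lo
        names = tuple(name for name, mass in loss_db if abs(diff - mass) <= tol)
        if names:
            edges.append(NeutralLossEdge(hi, lo, diff, names, from_precursor=hi_prec))
    return edges


def annotate_record(
    record: SpectrumRecord,
    db: MoietyDatabase,
    tol: float = 0.01,
    top_n: int = 20,
    fragment_db: list[tuple[str, float]] | None = None,
    loss_db: list[tuple[str, float]] | None = None,
) -> AnnotationResult:
    """Full annotation of one spectrum: top-n selection, database matching,
    neutral-loss inference, coverage and residual mass."""
    frag_db = fragment_db if fragment_db is not None else build_fragment_db(db)
    losses = loss_db if loss_db is not None else build_loss_db(db)
    frags = top_fragments(record, top_n)
    assignments = match_fragments(frags, frag_db, tol)
    edges = infer_neutral_losses(frags, record.precursor_mz, losses, tol)
    edge_members = set()
    for e in edges:
        edge_members.add(round(e.higher_mz, 6))
        edge_members.add(round(e.lower_mz, 6))
    annotated = [
        a for a in assignments
        if a.matches or round(a.mz, 6) in edge_members
    ]
    fraction = len(annotated) / len(assignments) if assignments else 0.0
    direct = [a.mz for a in assignments if a.matches]
    max_annotated = max(direct) if direct else None
    residual = record.precursor_mz - max_annotated if max_annotated is not None else None
    return AnnotationResult(
        feature_id=record.feature_id,
        precursor_mz=record.precursor_mz,
        assignments=assignments,
        loss_edges=edges,
        annotated_fraction=fraction,
        n_annotated=len(annotated),
        max_annotated_mz=max_annotated,
        residual=residual,
    )


def annotation_coverage(results: list[AnnotationResult]) -> float:
    """Fraction of all considered fragments (pooled across spectra) that
    carry an assignment or participate in a loss edge."""
    if not results:
        raise ValueError("no annotation results")
    total = sum(r.n_fragments for r in results)
    if total == 0:
        return 0.0
    annotated = sum(r.n_annotated for r in results)
    return annotated / total


# -- Component occurrence scans (hydroxyacyl / sugar / acyl usage) --------

@dataclass
class ComponentScan:
    """Occurrence tables across a set of detected RGs."""

    hydroxyacyl_counts: pd.Series
    sugar_pair_counts: pd.Series
    acyl_counts: pd.Series
    acyl_percent: pd.Series
    n_rgs: int
    n_with_acyl: int


def _acetic_loss_observed(record: SpectrumRecord, edges: list[NeutralLossEdge],
                          acetic_residue: float, acetic_acid: float,
                          tol: float) -> bool:
    """Acetic acid is too small to yield a reliable fragment ion; it is
    inferred from neutral loss only -- either an edge matching the acetate
    residue (ketene-type, 42.0106) or a direct pairwise difference matching
    the full acid (60.0211)."""
    for e in edges:
        if abs(e.loss - acetic_residue) <= tol:
            return True
    mzs = [mz for mz, _ in record.fragments] + [record.precursor_mz]
    for a, b in itertools.combinations(mzs, 2):
        if abs(abs(a - b) - acetic_acid) <= tol:
            return True
    return False


def scan_components(
    detections: list[DetectedRG],
    spectra: dict[str, SpectrumRecord],
    db: MoietyDatabase,
    tol: float = 0.01,
) -> ComponentScan:
    """Count, across detected RGs, occurrences of each hydroxyacyl fragment,
    each sugar-paired fragment class, and the percentage of RGs (among those
    with any acyl evidence) containing each acyl fragment. Acetic acid is
    counted via neutral loss, all other acyls via their fragment ion."""
    ha_counts = {name: 0 for name in db.hydroxyacyls}
    sugar_counts = {c: 0 for c in SUGAR_CLASSES}
    acyl_counts = {name: 0 for name in db.acyls}
    loss_db = build_loss_db(db)
    n_with_acyl = 0
    acetic = db.acyls.get("acetic")
    for det in detections:
        rec = spectra[det.feature_id]
        for name, ha in db.hydroxyacyls.items():
            if rec.has_fragment(ha.fragment_mz, tol):
                ha_counts[name] += 1
        for c in SUGAR_CLASSES:
            residue = db.sugar_residue_mass(c)
            if any(rec.has_fragment(ha.fragment_mz + residue, tol)
                   for ha in db.hydroxyacyls.values()):
                sugar_counts[c] += 1
        edges = infer_neutral_losses(rec.fragments, rec.precursor_mz, loss_db, tol)
        hit_any = False
        for name, acyl in db.acyls.items():
            if name == "acetic" and acetic is not None:
                hit = _acetic_loss_observed(
                    rec, edges, acetic.residue_mass, acetic.acid_mass, tol)
            else:
                hit = rec.has_fragment(acyl.fragment_mz, tol)
            if hit:
                acyl_counts[name] += 1
                hit_any = True
        if hit_any:
            n_with_acyl += 1
    denom = n_with_acyl if n_with_acyl else 1
    acyl_percent = pd.Series(acyl_counts, dtype=float) / denom * 100.0
    return ComponentScan(
        hydroxyacyl_counts=pd.Series(ha_counts, dtype=int),
        sugar_pair_counts=pd.Series(sugar_counts, dtype=int),
        acyl_counts=pd.Series(acyl_counts, dtype=int),
        acyl_percent=acyl_percent,
        n_rgs=len(detections),
        n_with_acyl=n_with_acyl,
    )
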
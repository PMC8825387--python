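"""Combinatorial resin-glycoside component prediction.

Given a precursor m/z, enumerate every composition -- an oligosaccharide
core of 2-7 sugars over three classes, one hydroxyacyl, a multiset of up
to ``max_acyls`` decorating acyls drawn from the frequent pool, an open or
closed macrolactone, and a deprotonated or formate adduct, optionally with
an in-source water loss -- whose theoretical pseudo-molecular ion mass
falls within tolerance of the observed precursor. Candidates are then
re-ranked by the observed-fragment evidence for their components.

Default mode mirrors the conservative search (hepta-saccharide cores, at
most three frequent acyls); extended mode allows five acyls and adds
decanoic acid to the pool, which is what recovers the known five-acyl and
decanoate-bearing RGs that the default search cannot express.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import AnnotationResult, scan_components
from .chem import (
    FORMIC_ACID,
    SUGAR_CLASSES,
    WATER,
    MoietyDatabase,
    RGComposition,
    adduct_mz,
    composition_mass,
)
from .detect import DetectedRG
from .io import SpectrumRecord

__all__ = [
    "PredictionConfig",
    "Candidate",
    "CandidateSet",
    "enumerate_candidates",
    "score_candidates",
    "derive_frequent_acyls",
    "evaluate_recall",
]


@dataclass
class PredictionConfig:
    """Search-space limits for composition enumeration.

    ``acyl_pool`` of None means the database's frequent set (plus decanoic
    acid when ``extended``). ``allow_water_loss`` admits candidates whose
    ion lost one water in source.
    """

    max_acyls: int = 3
    acyl_pool: tuple[str, ...] | None = None
    precursor_tolerance: float = 0.01
    min_sugars: int = 2
    max_sugars: int = 7
    allow_water_loss: bool = True
    adducts: tuple[str, ...] = ("deprotonated", "formate")
    ring_states: tuple[str, ...] = ("closed", "open")
    hydroxyacyl_pool: tuple[str, ...] | None = None
    candidate_cap: int = 10_000

    def __post_init__(self) -> None:
        if self.max_acyls < 0 or self.min_sugars < 1 or self.max_sugars < self.min_sugars:
            raise ValueError("invalid prediction limits")
        if self.precursor_tolerance <= 0:
            raise ValueError("precursor tolerance must be > 0")

    @classmethod
    def extended(cls, **kwargs) -> "PredictionConfig":
        """Five acyl chains and decanoic acid added to the pool."""
        cfg = cls(max_acyls=5, **kwargs)
        cfg._extended = True
        return cfg

    def resolve_acyl_pool(self, db: MoietyDatabase) -> tuple[str, ...]:
        if self.acyl_pool is not None:
            pool = tuple(self.acyl_pool)
        else:
            pool = tuple(db.frequent_acyls)
            if getattr(self, "_extended", False) and "decanoic" in db.acyls:
                pool = pool + ("decanoic",)
        if not pool:
            raise ValueError("acyl pool is empty")
        return pool

    def resolve_hydroxyacyl_pool(self, db: MoietyDatabase) -> tuple[str, ...]:
        pool = (tuple(self.hydroxyacyl_pool) if self.hydroxyacyl_pool is not None
                else tuple(db.hydroxyacyls))
        if not pool:
            raise ValueError("hydroxyacyl pool is empty")
        return pool


@dataclass
class Candidate:
    composition: RGComposition
    theoretical_mz: float  # as observed, i.e. including any water loss
    delta: float  # theoretical - observed precursor
    water_loss: bool = False
    score: float = 0.0
    supporting: tuple[str, ...] = ()
    contradicting: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.composition.total_sugars + 1 + len(self.composition.acyls)


CandidateSet = list[Candidate]


def _sugar_multisets(cfg: PredictionConfig, db: MoietyDatabase):
    out = []
    for n in range(cfg.min_sugars, cfg.max_sugars + 1):
        for combo in itertools.combinations_with_replacement(SUGAR_CLASSES, n):
            counts: dict[str, int] = {}
            for c in combo:
                counts[c] = counts.get(c, 0) + 1
            mass = sum(db.sugar_residue_mass(c) * k for c, k in counts.items())
            out.append((counts, mass))
    return out


def _acyl_multisets(pool: tuple[str, ...], max_acyls: int, db: MoietyDatabase):
    out = []
    for n in range(0, max_acyls + 1):
        for combo in itertools.combinations_with_replacement(sorted(pool), n):
            mass = sum(db.acyls[a].residue_mass for a in combo)
            out.append((combo, mass))
    return out


def enumerate_candidates(
    precursor_mz: float,
    db: MoietyDatabase,
    cfg: PredictionConfig | None = None,
) -> CandidateSet:
    """Exhaustive generate-and-test over the configured component space.

    Returns every candidate whose theoretical ion m/z (adduct applied,
    optional water loss) lies within ``precursor_tolerance`` of the
    precursor, sorted by |delta| then composition key. Raises if the set
    would exceed ``candidate_cap``.
    """
    if precursor_mz <= 0:
        raise ValueError("precursor m/z must be positive")
    cfg = cfg or PredictionConfig()
    acyl_pool = cfg.resolve_acyl_pool(db)
    ha_pool = cfg.resolve_hydroxyacyl_pool(db)

    sugars = _sugar_multisets(cfg, db)
    has = [(name, db.hydroxyacyls[name].residue_mass) for name in sorted(ha_pool)]
    acyls = _acyl_multisets(acyl_pool, cfg.max_acyls, db)

    s_mass = np.array([m for _, m in sugars])
    h_mass = np.array([m for _, m in has])
    a_mass = np.array([m for _, m in acyls])
    # neutral open-chain mass with terminal water; ring/adduct applied below
    base = WATER + s_mass[:, None, None] + h_mass[None, :, None] + a_mass[None, None, :]

    water_states = [False, True] if cfg.allow_water_loss else [False]
    candidates: CandidateSet = []
    for ring in cfg.ring_states:
        ring_off = -WATER if ring == "closed" else 0.0
        for adduct in cfg.adducts:
            ion = adduct_mz(1.0, adduct) - 1.0  # additive adduct offset
            for lost_water in water_states:
                offset = ring_off + ion + (-WATER if lost_water else 0.0)
                theo = base + offset
                hit = np.nonzero(np.abs(theo - precursor_mz) <= cfg.precursor_tolerance)
                for si, hi, ai in zip(*hit):
                    comp = RGComposition.make(
                        sugars[si][0], has[hi][0], acyls[ai][0], ring, adduct
                    )
                    t = float(theo[si, hi, ai])
                    candidates.append(
                        Candidate(
                            composition=comp,
                            theoretical_mz=t,
                            delta=t - precursor_mz,
                            water_loss=lost_water,
                        )
                    )
                    if len(candidates) > cfg.candidate_cap:
                        raise OverflowError(
                            f"candidate set exceeds cap {cfg.candidate_cap}; "
                            "narrow the precursor tolerance"
                        )
    candidates.sort(key=lambda c: (abs(c.delta), c.composition.key(), c.water_loss))
    return candidates


def score_candidates(
    candidates: CandidateSet,
    annotation: AnnotationResult | None,
    db: MoietyDatabase,
    tol: float = 0.01,
) -> CandidateSet:
    """Re-rank candidates by observed-fragment evidence.

    Each component with a supporting observed fragment or loss edge adds
    one point: the hydroxyacyl via its anion or sugar-paired fragment, a
    sugar class via a matching residue-loss edge or paired fragment, an
    acyl via its fragment ion (acetic via an acetate-residue loss edge). A
    formate-adduct candidate lacking a formic-acid loss from the precursor
    is penalized one point. Ties break by |delta|, then fewer components,
    then composition key -- fully deterministic.
    """
    if annotation is None:
        return sorted(candidates,
                      key=lambda c: (abs(c.delta), c.n_components, c.composition.key()))
    frag_mzs = [a.mz for a in annotation.assignments]

    def observed(mz: float) -> bool:
        return any(abs(f - mz) <= tol for f in frag_mzs)

    def loss_edge(mass: float, from_precursor: bool = False) -> bool:
        return any(
            abs(e.loss - mass) <= tol and (e.from_precursor or not from_precursor)
            for e in annotation.loss_edges
        )

    rescored: CandidateSet = []
    for cand in candidates:
        support: list[str] = []
        contra: list[str] = []
        comp = cand.composition
        ha = db.hydroxyacyls[comp.hydroxyacyl]
        ha_hit = observed(ha.fragment_mz) or any(
            observed(ha.fragment_mz + db.sugar_residue_mass(c))
            for c, _ in comp.sugars
        )
        if ha_hit:
            support.append(comp.hydroxyacyl)
        for c, _n in comp.sugars:
            residue = db.sugar_residue_mass(c)
            if loss_edge(residue) or observed(ha.fragment_mz + residue):
                support.append(c)
        for acyl_name in set(comp.acyls):
            acyl = db.acyls[acyl_name]
            if acyl_name == "acetic":
                if loss_edge(acyl.residue_mass):
                    support.append(acyl_name)
            elif observed(acyl.fragment_mz) or loss_edge(acyl.residue_mass):
                support.append(acyl_name)
        if comp.adduct == "formate":
            if loss_edge(FORMIC_ACID, from_precursor=True):
                support.append("formate")
            else:
                contra.append("formate")
        score = float(len(support) - len(contra))
        rescored.append(replace(cand, score=score,
                                supporting=tuple(support),
                                contradicting=tuple(contra)))
    rescored.sort(key=lambda c: (-c.score, abs(c.delta), c.n_components,
                                 c.composition.key()))
    return rescored


def derive_frequent_acyls(
    detections: list[DetectedRG],
    spectra: dict[str, SpectrumRecord],
    db: MoietyDatabase,
    threshold: float = 0.05,
    tol: float = 0.01,
) -> list[str]:
    """Acyls whose fragment (or, for acetic, neutral-loss) occurrence across
    detected RGs strictly exceeds ``threshold`` -- the empirical "frequent"
    set that bounds the default prediction pool."""
    if not detections:
        raise ValueError("no detected RGs to derive frequencies from")
    scan = scan_components(detections, spectra, db, tol)
    frac = scan.acyl_counts / len(detections)
    return sorted(frac.index[frac > threshold])


@dataclass
class RecallReport:
    recall: float
    verdicts: pd.DataFrame = field(repr=False)


def evaluate_recall(
    known: list[tuple[str, RGComposition, float]],
    db: MoietyDatabase,
    cfg: PredictionConfig | None = None,
) -> RecallReport:
    """Fraction of known RGs whose true composition appears anywhere in the
    candidate set enumerated at their precursor m/z."""
    if not known:
        raise ValueError("known RG list is empty")
    cfg = cfg or PredictionConfig()
    rows = []
    hits = 0
    for name, comp, precursor in known:
        candidates = enumerate_candidates(precursor, db, cfg)
        found = any(c.composition == comp for c in candidates)
        hits += found
        rows.append({
            "name": name,
            "precursor_mz": precursor,
            "true_composition": comp.key(),
            "n_candidates": len(candidates),
            "recovered": found,
        })
    return RecallReport(recall=hits / len(known), verdicts=pd.DataFrame(rows))


def candidates_to_frame(feature_id: str, candidates: CandidateSet) -> pd.DataFrame:
    rows = []
    for rank, c in enumerate(candidates, start=1):
        rows.append({
            "feature_id": feature_id,
            "rank": rank,
            "composition": c.composition.key(),
            "theoretical_mz": round(c.theoretical_mz, 6),
            "delta_mz": round(c.delta, 6),
            "water_loss": c.water_loss,
            "score": c.score,
            "supporting": ";".join(c.supporting),
            "contradicting": ";".join(c.contradicting),
        })
    return pd.DataFrame(
        rows,
        columns=["feature_id", "rank", "composition", "theoretical_mz", "delta_mz",
                 "water_loss", "score", "supporting", "contradicting"],
    )
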
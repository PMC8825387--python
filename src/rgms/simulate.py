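"""Synthetic RG spectra and MS-DIAL-style fixture generation.

Builds in-silico negative-mode MS/MS spectra for planted RG compositions
-- the hydroxyacyl-anchored glycosidic ladder with water-loss satellites,
acyl fragment ions, and precursor-side water/formate/CO2 losses -- plus
decoy features engineered to violate specific detection filters, and the
matching MGF + peak-area alignment table + truth table so every pipeline
stage is testable without any instrument data.

The emulated world: a Q-Exactive-style run with precursor scan range
500-2000 m/z, clean-preset m/z jitter of 0.001 Da (well under the 0.01 Da
match tolerance), base-peak intensity 1e6 with informative ions log-uniform
between 10.5 and 100% of base so the 10% relative-intensity filter is
exercised from both sides by dedicated decoys, and blank signal absent
except in blank-dominated decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import (
    CO2,
    FORMIC_ACID,
    WATER,
    MoietyDatabase,
    RGComposition,
    composition_mass,
    composition_mz,
    default_database,
)
from .io import AlignmentTable, SpectrumRecord, write_alignment, write_mgf

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "fragment_composition",
    "simulate_dataset",
    "build_filter_fixture",
    "known_rg_panel",
    "DEFAULT_ROLES",
]

DEFAULT_ROLES = {"leaf_1": "leaf", "root_1": "root", "blank_1": "blank"}

ACETIC_ACID_LOSS = 60.021130  # CH3COOH; pairs with the -18 ion via the 42.0106 residue


@dataclass
class SimulationConfig:
    seed: int = 0
    n_rgs: int = 20
    n_blank_dominated: int = 2
    n_low_area: int = 2
    n_pairless: int = 3
    include_hard_cases: bool = False
    mz_jitter_sd: float = 0.001
    base_intensity: float = 1.0e6
    scan_range: tuple[float, float] = (500.0, 2000.0)
    sugar_class_weights: dict[str, float] = field(
        default_factory=lambda: {"deoxyhexose": 0.5, "hexose": 0.3, "pentose": 0.2}
    )
    hydroxyacyl_weights: dict[str, float] = field(
        default_factory=lambda: {"C16-OH": 0.55, "C15-OH": 0.15, "C17-OH": 0.10,
                                 "C16-OHOH": 0.10, "C18-OH": 0.10}
    )

    def __post_init__(self) -> None:
        if self.n_rgs < 0 or self.mz_jitter_sd < 0:
            raise ValueError("invalid simulation config")


@dataclass
class SimulatedDataset:
    records: list[SpectrumRecord]
    table: AlignmentTable
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mgf(self.records, out / "spectra.mgf")
        write_alignment(self.table, out / "areas.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _ladder_sequence(comp: RGComposition) -> list[str]:
    """Deterministic expansion of the sugar multiset into a linear chain
    (class order: deoxyhexose, hexose, pentose)."""
    order = ("deoxyhexose", "hexose", "pentose")
    counts = comp.sugar_counts
    seq: list[str] = []
    for cls_ in order:
        seq.extend([cls_] * counts.get(cls_, 0))
    return seq


def fragment_composition(
    comp: RGComposition,
    db: MoietyDatabase,
    rng: np.random.Generator | None = None,
    base_intensity: float = 1.0e6,
) -> list[tuple[float, float]]:
    """Theoretical fragment list for a composition.

    Emits: the hydroxyacyl anion (base peak); the glycosidic ladder
    (hydroxyacyl plus 1..k sugars); water-loss satellites for the first two
    ladder ions; for open-chain compositions a +water variant of the top
    ladder ion (ring water retained); one fragment ion per decorating acyl
    (acetic instead appears as a neutral acetic-acid loss from the
    precursor); precursor water loss; and formate-adduct -46.0055/-43.9898
    losses. Informative ions draw log-uniform 10.5-100% of base intensity,
    keeping signature pairs above the 10% relative-intensity filter.
    """

    def inten() -> float:
        if rng is None:
            return 0.5 * base_intensity
        return base_intensity * 10 ** rng.uniform(np.log10(0.105), 0.0)

    ha = db.hydroxyacyls[comp.hydroxyacyl]
    precursor = composition_mz(comp, db)
    frags: list[tuple[float, float]] = [(ha.fragment_mz, base_intensity)]
    ladder = [ha.fragment_mz]
    mz = ha.fragment_mz
    for cls_ in _ladder_sequence(comp):
        mz += db.sugar_residue_mass(cls_)
        ladder.append(mz)
        frags.append((mz, inten()))
    for ion in ladder[1:3]:
        frags.append((ion - WATER, inten()))
    if comp.macrolactone == "open" and len(ladder) > 1:
        frags.append((ladder[-1] + WATER, inten()))
    emitted_acyls = set()
    for acyl_name in comp.acyls:
        if acyl_name == "acetic" or acyl_name in emitted_acyls:
            continue
        frags.append((db.acyls[acyl_name].fragment_mz, inten()))
        emitted_acyls.add(acyl_name)
    frags.append((precursor - WATER, inten()))
    if "acetic" in comp.acyls:
        frags.append((precursor - ACETIC_ACID_LOSS, inten()))
    if comp.adduct == "formate":
        frags.append((precursor - FORMIC_ACID, inten()))
        frags.append((precursor - CO2, inten()))
    # merge mass-degenerate ions; drop anything above the precursor
    merged: dict[float, float] = {}
    for fmz, fi in frags:
        if fmz > precursor + 1e-6:
            continue
        key = round(fmz, 6)
        merged[key] = merged.get(key, 0.0) + fi
    return sorted(merged.items())


def _sample_composition(
    rng: np.random.Generator, db: MoietyDatabase, cfg: SimulationConfig
) -> RGComposition:
    sugar_names = list(cfg.sugar_class_weights)
    sugar_p = np.array([cfg.sugar_class_weights[s] for s in sugar_names])
    sugar_p = sugar_p / sugar_p.sum()
    ha_names = list(cfg.hydroxyacyl_weights)
    ha_p = np.array([cfg.hydroxyacyl_weights[h] for h in ha_names])
    ha_p = ha_p / ha_p.sum()
    frequent = sorted(db.frequent_acyls)
    lo, hi = cfg.scan_range
    for _ in range(200):
        n_sugars = int(rng.integers(2, 8))
        counts: dict[str, int] = {}
        for cls_ in rng.choice(sugar_names, size=n_sugars, p=sugar_p):
            counts[cls_] = counts.get(cls_, 0) + 1
        ha = str(rng.choice(ha_names, p=ha_p))
        n_acyls = int(rng.integers(0, 4))
        acyls = (tuple(str(a) for a in rng.choice(frequent, size=n_acyls))
                 if n_acyls else ())
        ring = "closed" if rng.random() < 0.7 else "open"
        adduct = "formate" if rng.random() < 0.5 else "deprotonated"
        comp = RGComposition.make(counts, ha, acyls, ring, adduct)
        if lo <= composition_mz(comp, db) <= hi:
            return comp
    raise RuntimeError("could not sample a composition inside the scan range")


def _organ_areas(rng: np.random.Generator) -> tuple[float, float, str]:
    scenario = rng.choice(["leaf_only", "root_only", "both"], p=[0.2, 0.4, 0.4])
    area = lambda: float(10 ** rng.uniform(4, 6))  # noqa: E731
    if scenario == "leaf_only":
        return area(), 0.0, "leaf_only"
    if scenario == "root_only":
        return 0.0, area(), "root_only"
    return area(), area(), "both"


def _decoy_fragments(rng: np.random.Generator, base: float,
                     n: int = 6) -> list[tuple[float, float]]:
    """Fragments away from any database mass (offset by ~0.35 Da from
    integer grid) so they match nothing."""
    mzs = rng.uniform(120, 900, size=n)
    mzs = np.round(mzs) + 0.351 + rng.uniform(0, 0.05, size=n)
    return sorted((float(m), float(base * rng.uniform(0.15, 1.0))) for m in mzs)


def simulate_dataset(
    cfg: SimulationConfig, db: MoietyDatabase | None = None
) -> SimulatedDataset:
    """Generate planted RGs plus filter-violating decoys.

    Decoy presets: ``blank_dominated`` (fails the blank-ratio clause),
    ``low_area`` (fails the 1000-area clause), ``pairless`` (no signature
    pair). With ``include_hard_cases`` two extra true RGs are planted that
    defeat default prediction limits: a five-acyl open-chain RG and a
    decanoate-bearing RG (recoverable only in extended mode). Output is
    byte-identical for a fixed seed.
    """
    db = db or default_database()
    rng = np.random.default_rng(cfg.seed)
    records: list[SpectrumRecord] = []
    areas: dict[str, dict[str, float]] = {}
    truth_rows: list[dict] = []

    def jitter(frags: list[tuple[float, float]]) -> list[tuple[float, float]]:
        if cfg.mz_jitter_sd == 0:
            return frags
        return [(mz + float(rng.normal(0, cfg.mz_jitter_sd)), i) for mz, i in frags]

    def add_feature(fid: str, precursor: float, frags, leaf: float, root: float,
                    blank: float, kind: str, comp: RGComposition | None,
                    organ: str, rt: float) -> None:
        records.append(SpectrumRecord(
            feature_id=fid,
            precursor_mz=precursor + float(rng.normal(0, cfg.mz_jitter_sd / 2)),
            retention_time=rt,
            fragments=jitter(frags),
        ))
        areas[fid] = {"leaf_1": leaf, "root_1": root, "blank_1": blank}
        truth_rows.append({
            "feature_id": fid, "kind": kind,
            "composition": comp.key() if comp else "",
            "theoretical_mz": round(precursor, 6) if precursor else np.nan,
            "organ": organ,
        })

    for i in range(cfg.n_rgs):
        comp = _sample_composition(rng, db, cfg)
        precursor = composition_mz(comp, db)
        frags = fragment_composition(comp, db, rng, cfg.base_intensity)
        leaf, root, organ = _organ_areas(rng)
        add_feature(f"RG_{i + 1:03d}", precursor, frags, leaf, root, 0.0,
                    "rg", comp, organ, rt=float(rng.uniform(2, 28)))

    if cfg.include_hard_cases:
        five_acyl = RGComposition.make(
            {"deoxyhexose": 2, "hexose": 2}, "C16-OH",
            ("acetic", "acetic", "C5", "C5", "tiglic"), "open", "deprotonated")
        decanoate = RGComposition.make(
            {"deoxyhexose": 3, "hexose": 1}, "C16-OH",
            ("decanoic", "C5"), "closed", "formate")
        for j, (comp, kind) in enumerate(
                [(five_acyl, "rg_hard_five_acyl"), (decanoate, "rg_hard_decanoic")]):
            precursor = composition_mz(comp, db)
            frags = fragment_composition(comp, db, rng, cfg.base_intensity)
            leaf, root, organ = _organ_areas(rng)
            add_feature(f"RG_HARD_{j + 1:02d}", precursor, frags, leaf, root, 0.0,
                        kind, comp, organ, rt=float(rng.uniform(2, 28)))

    for i in range(cfg.n_blank_dominated):
        comp = _sample_composition(rng, db, cfg)
        frags = fragment_composition(comp, db, rng, cfg.base_intensity)
        add_feature(f"DECOY_BLANK_{i + 1:02d}", composition_mz(comp, db), frags,
                    leaf=5.0e4, root=0.0, blank=2.0e4, kind="decoy_blank_dominated",
                    comp=comp, organ="", rt=float(rng.uniform(2, 28)))
    for i in range(cfg.n_low_area):
        comp = _sample_composition(rng, db, cfg)
        frags = fragment_composition(comp, db, rng, cfg.base_intensity)
        add_feature(f"DECOY_LOWAREA_{i + 1:02d}", composition_mz(comp, db), frags,
                    leaf=600.0, root=0.0, blank=0.0, kind="decoy_low_area",
                    comp=comp, organ="", rt=float(rng.uniform(2, 28)))
    for i in range(cfg.n_pairless):
        precursor = float(rng.uniform(*cfg.scan_range))
        frags = _decoy_fragments(rng, cfg.base_intensity)
        leaf, root, organ = _organ_areas(rng)
        add_feature(f"DECOY_PAIRLESS_{i + 1:02d}", precursor, frags, leaf, root, 0.0,
                    "decoy_pairless", None, "", rt=float(rng.uniform(2, 28)))

    table = AlignmentTable(
        areas=pd.DataFrame.from_dict(areas, orient="index")[list(DEFAULT_ROLES)],
        roles=dict(DEFAULT_ROLES),
    )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(records=records, table=table, truth=truth)


def known_rg_panel(db: MoietyDatabase | None = None) -> list[
        tuple[str, RGComposition, float]]:
    """A 13-member panel of known-RG compositions with their exact
    precursor m/z, mirroring the published validation set's failure modes:
    11 lie within the default search limits, one carries five acyl chains
    (Dichondrin-D-like) and one carries decanoic acid (Merremin-D-like),
    so default-mode recall is 11/13 and extended-mode recall 13/13.
    """
    db = db or default_database()
    mk = RGComposition.make
    panel = [
        ("tricolorin_like", mk({"deoxyhexose": 3, "hexose": 1}, "C16-OH",
                               ("C5", "C5"), "closed", "formate")),
        ("rg_02", mk({"deoxyhexose": 2}, "C16-OH", ("tiglic",), "closed",
                     "deprotonated")),
        ("rg_03", mk({"deoxyhexose": 4}, "C16-OH", ("C5", "tiglic", "HMBA"),
                     "closed", "deprotonated")),
        ("rg_04", mk({"pentose": 1, "deoxyhexose": 2}, "C15-OH", ("C5",),
                     "closed", "formate")),
        ("rg_05", mk({"hexose": 2, "deoxyhexose": 1}, "C16-OHOH", (),
                     "open", "deprotonated")),
        ("rg_06", mk({"deoxyhexose": 5}, "C16-OH", ("cinnamic",), "closed",
                     "deprotonated")),
        ("rg_07", mk({"deoxyhexose": 3, "pentose": 1}, "C17-OH", ("butyric", "C5"),
                     "closed", "formate")),
        ("rg_08", mk({"hexose": 3}, "C18-OH", ("acetic",), "open", "deprotonated")),
        ("rg_09", mk({"deoxyhexose": 4, "hexose": 2}, "C16-OH",
                     ("C5", "C5", "tiglic"), "closed", "deprotonated")),
        ("rg_10", mk({"deoxyhexose": 2, "hexose": 1}, "C16-OH", ("HMBA",),
                     "closed", "formate")),
        ("rg_11", mk({"deoxyhexose": 6}, "C16-OH", ("C5",), "closed",
                     "deprotonated")),
        ("dichondrin_like", mk({"deoxyhexose": 2, "hexose": 2}, "C16-OH",
                               ("acetic", "acetic", "C5", "C5", "tiglic"),
                               "open", "deprotonated")),
        ("merremin_like", mk({"deoxyhexose": 3, "hexose": 1}, "C16-OH",
                             ("decanoic", "C5"), "closed", "formate")),
    ]
    return [(name, comp, composition_mz(comp, db)) for name, comp in panel]


def build_filter_fixture(
    db: MoietyDatabase | None = None,
) -> tuple[list[SpectrumRecord], AlignmentTable, pd.DataFrame]:
    """A deterministic 30-feature fixture with planted pass/fail cases for
    every detection filter and organ rule.

    Includes the two published edge cases: a signature pair whose
    hydroxyacyl member sits at 4% relative intensity (rejected by the 10%
    rule) and a peak linked to a higher-mass feature (dropped by the
    linked-peak filter). The truth table gives the expected verdict and
    organ call per feature.
    """
    db = db or default_database()
    base = 1.0e6
    c16 = db.hydroxyacyls["C16-OH"].fragment_mz          # 271.2279
    c15 = db.hydroxyacyls["C15-OH"].fragment_mz          # 257.2122
    deoxy = db.sugar_residue_mass("deoxyhexose")
    hexo = db.sugar_residue_mass("hexose")

    def pair_frags(rel_low: float = 0.5) -> list[tuple[float, float]]:
        return [(c16, base), (c16 + deoxy, base * rel_low)]

    records: list[SpectrumRecord] = []
    areas: dict[str, dict[str, float]] = {}
    rows: list[dict] = []

    def add(fid, frags, leaf, root, blank, expect_detected, expect_organ,
            expect_stage, precursor=900.0, linked=None, adduct=None):
        records.append(SpectrumRecord(
            feature_id=fid, precursor_mz=precursor, retention_time=10.0,
            fragments=frags, linked_to=linked, adduct_label=adduct))
        areas[fid] = {"leaf_1": leaf, "root_1": root, "blank_1": blank}
        rows.append({"feature_id": fid, "detected": expect_detected,
                     "organ": expect_organ, "reject_stage": expect_stage})

    # clean passes covering the organ rules (8)
    add("P01_leaf", pair_frags(), 5000, 0, 0, True, "leaf_only", "")
    add("P02_leaf", pair_frags(0.9), 2.0e5, 0, 100, True, "leaf_only", "")
    add("P03_root", pair_frags(), 0, 5000, 0, True, "root_only", "")
    add("P04_root", pair_frags(0.11), 0, 8.0e4, 0, True, "root_only", "")
    add("P05_both", pair_frags(), 1500, 1200, 0, True, "both", "")
    add("P06_both", pair_frags(), 9.0e4, 7.0e4, 500, True, "both", "")
    add("P07_ambig", pair_frags(), 5000, 300, 0, True, "ambiguous", "")
    add("P08_ambig", pair_frags(), 800, 4000, 0, True, "ambiguous", "")
    # filter (i) failures (4)
    add("F01_low_area", pair_frags(), 600, 0, 50, False, "", "blank_area")
    add("F02_low_area", pair_frags(), 0, 1000, 0, False, "", "blank_area")
    add("F03_blank_ratio", pair_frags(), 20000, 0, 5000, False, "", "blank_area")
    add("F04_blank_ratio", pair_frags(), 0, 30000, 3000, False, "", "blank_area")
    # filter (ii) failures: no complete pair (4)
    add("F05_pairless", [(500.351, base), (623.417, 0.5 * base)],
        9000, 0, 0, False, "", "signature_pair")
    add("F06_half_pair", [(c16, base)], 9000, 0, 0, False, "", "signature_pair")
    add("F07_half_pair", [(c16 + deoxy, base), (880.351, 0.4 * base)],
        9000, 0, 0, False, "", "signature_pair")
    add("F08_pairless", [(101.0608, base)], 0, 9000, 0, False, "",
        "signature_pair")
    # filter (iii): pair member below 10% relative intensity (3)
    add("F09_lowrel", [(c15, 0.04 * base), (c15 + hexo, 0.6 * base),
                       (1079.4929, base)],
        0, 9000, 0, False, "", "signature_pair", precursor=1079.4929)
    add("F10_lowrel", [(c16, base), (c16 + deoxy, 0.05 * base)],
        9000, 0, 0, False, "", "signature_pair")
    add("F11_at_threshold", [(c16, base), (c16 + deoxy, 0.10 * base)],
        9000, 0, 0, False, "", "signature_pair")
    # filter (iv): linked peaks (4)
    add("L01_linked_low", pair_frags(), 0, 9000, 0, False, "", "linked",
        precursor=1279.6692, linked="L02_linked_high")
    add("L02_linked_high", pair_frags(), 0, 9000, 0, True, "root_only", "",
        precursor=1364.642)
    add("L03_adduct", pair_frags(), 7000, 0, 0, True, "leaf_only", "",
        precursor=950.0, linked="L04_partner", adduct="[M+FA-H]-")
    add("L04_partner", pair_frags(), 7000, 0, 0, True, "leaf_only", "",
        precursor=996.0)
    # dangling link: kept with a warning (1)
    add("L05_dangling", pair_frags(), 6000, 0, 0, True, "leaf_only", "",
        linked="NOT_A_FEATURE")
    # more clean passes with varied pairs (6)
    for k, (ha_name, sugar) in enumerate([
        ("C15-OH", "hexose"), ("C16-OHOH", "deoxyhexose"), ("C17-OH", "pentose"),
        ("C18-OH", "deoxyhexose"), ("C14-OH", "hexose"), ("C16-OH", "pentose"),
    ]):
        ha_mz = db.hydroxyacyls[ha_name].fragment_mz
        frags = [(ha_mz, base), (ha_mz + db.sugar_residue_mass(sugar), 0.4 * base)]
        add(f"P{9 + k:02d}_pair", frags, 0, 6000 + 100 * k, 0, True, "root_only", "")
    assert len(records) == 30
    table = AlignmentTable(
        areas=pd.DataFrame.from_dict(areas, orient="index")[list(DEFAULT_ROLES)],
        roles=dict(DEFAULT_ROLES),
    )
    return records, table, pd.DataFrame(rows)
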
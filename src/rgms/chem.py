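"""Elemental-mass arithmetic and the curated resin-glycoside moiety database.

Resin glycosides (RGs) are Convolvulaceae acylsugars built from an
oligosaccharide core (2-7 pentose/deoxyhexose/hexose residues), one
14-18-carbon hydroxy or dihydroxy fatty acid that may close into a
macrolactone ring, and short aliphatic/aromatic acyl ester decorations.
Every theoretical m/z the pipeline matches against -- signature fragment
pairs, acyl fragment ions, neutral losses, precursor masses of candidate
compositions -- is derived here from elemental formulas and monoisotopic
atomic masses, never hard-coded downstream.

Conventions
-----------
* Residue mass: mass of a sugar or acyl unit after loss of one water on
  glycosidic/ester bond formation (e.g. deoxyhexose residue C6H10O4,
  146.0579 Da).
* [M-H]- is computed as M minus the proton mass (1.007276 Da), i.e. the
  electron stays with the anion.
* Formate adducts [M+HCOO]- add the formate anion mass (44.998200 Da).
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ATOMIC_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "WATER",
    "CO2",
    "FORMIC_ACID",
    "FORMATE_ANION",
    "Formula",
    "Moiety",
    "MoietyDatabase",
    "SignaturePair",
    "RGComposition",
    "monoisotopic_mass",
    "deprotonated_mz",
    "composition_mass",
    "composition_mz",
    "adduct_mz",
    "signature_pair_table",
    "default_database",
]

# Monoisotopic atomic masses (Da), CODATA/IUPAC values at the precision the
# instrument-facing arithmetic needs.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "O": 15.9949146,
    "N": 14.0030740,
    "S": 31.9720707,
    "P": 30.9737615,
}

PROTON_MASS = 1.007276
ELECTRON_MASS = 0.000549
WATER = 18.010565
CO2 = 43.989830
FORMIC_ACID = 46.005480
FORMATE_ANION = 44.998200

SUGAR_CLASSES = ("pentose", "deoxyhexose", "hexose")
MOIETY_CLASSES = SUGAR_CLASSES + ("hydroxyacyl", "acyl", "adduct")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formula operations."""


@dataclass(frozen=True)
class Formula:
    """An elemental formula as non-negative integer element counts.

    Construct from a Hill-notation string (``Formula.parse("C16H32O3")``)
    or a mapping. Supports addition and subtraction; subtraction raises
    rather than produce a negative count.
    """

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def parse(cls, text: str) -> "Formula":
        text = text.strip()
        if not text:
            raise FormulaError("empty formula")
        counts: Counter[str] = Counter()
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            symbol, digits = match.groups()
            if symbol not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
            counts[symbol] += int(digits) if digits else 1
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls.from_counts(counts)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "Formula":
        clean = {}
        for symbol, n in counts.items():
            if symbol not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element symbol {symbol!r}")
            if n < 0:
                raise FormulaError(f"negative count for {symbol}: {n}")
            if n:
                clean[symbol] = int(n)
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        # Hill order: C, H, then alphabetical.
        order = sorted(clean, key=lambda s: (s != "C", s != "H", s))
        return cls(tuple((s, clean[s]) for s in order))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = Counter(self.as_dict())
        merged.update(other.as_dict())
        return Formula.from_counts(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = Counter(self.as_dict())
        merged.subtract(other.as_dict())
        if any(v < 0 for v in merged.values()):
            raise FormulaError(
                f"subtraction {self} - {other} yields a negative element count"
            )
        return Formula.from_counts(merged)

    @property
    def mass(self) -> float:
        return sum(ATOMIC_MASSES[s] * n for s, n in self.counts)

    def __str__(self) -> str:
        return "".join(f"{s}{n if n != 1 else ''}" for s, n in self.counts)


WATER_FORMULA = Formula.parse("H2O")


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic mass (Da) of a formula; accepts Hill-notation strings."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return formula.mass


def deprotonated_mz(formula: Formula | str) -> float:
    """[M-H]- m/z of a neutral molecule: M minus the proton mass.

    The electron is retained by the anion, reproducing e.g. 271.2279 for
    jalapinolic acid (C16H32O3) to four decimals.
    """
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    if formula.as_dict().get("H", 0) < 1:
        raise FormulaError(f"{formula} has no hydrogen to remove")
    return formula.mass - PROTON_MASS


@dataclass(frozen=True)
class Moiety:
    """A named RG building block in residue form.

    ``formula`` is the residue (free molecule minus one water for sugar and
    acyl residues); ``residue_mass`` must equal its monoisotopic mass.
    For acyls and hydroxyacyls the free-acid [M-H]- fragment m/z is exposed
    via :attr:`fragment_mz`.
    """

    name: str
    moiety_class: str
    formula: Formula
    frequent: bool = False

    def __post_init__(self) -> None:
        if self.moiety_class not in MOIETY_CLASSES:
            raise ValueError(f"unknown moiety class {self.moiety_class!r}")

    @property
    def residue_mass(self) -> float:
        return self.formula.mass

    @property
    def acid_formula(self) -> Formula:
        """Free-acid (or free-sugar) formula: residue plus one water."""
        return self.formula + WATER_FORMULA

    @property
    def acid_mass(self) -> float:
        return self.acid_formula.mass

    @property
    def fragment_mz(self) -> float:
        """Deprotonated free acid/molecule, the fragment ion observed in MS/MS."""
        return deprotonated_mz(self.acid_formula)


@dataclass(frozen=True)
class SignaturePair:
    """The RG detection criterion: a hydroxyacyl anion plus the same
    hydroxyacyl glycosidically bound to one sugar."""

    hydroxyacyl: str
    sugar_class: str
    acyl_mz: float
    combined_mz: float


# Default hydroxyacyl set: mono- and dihydroxy C14-C18 fatty acids (10
# entries). C16-OH (jalapinolic acid) dominates observed RGs; C15-OH,
# C16-OHOH, C17-OH and C18-OH recur in the more diverse species.
_DEFAULT_HYDROXYACYLS = [
    ("C14-OH", "C14H28O3"),
    ("C15-OH", "C15H30O3"),
    ("C16-OH", "C16H32O3"),
    ("C17-OH", "C17H34O3"),
    ("C18-OH", "C18H36O3"),
    ("C14-OHOH", "C14H28O4"),
    ("C15-OHOH", "C15H30O4"),
    ("C16-OHOH", "C16H32O4"),
    ("C17-OHOH", "C17H34O4"),
    ("C18-OHOH", "C18H36O4"),
]

# Default acyl database: 22 free-acid formulas spanning the short branched
# and aromatic acids seen as RG ester decorations plus longer fatty acids
# in the 50-200 Da acyl-CoA mass window. ``frequent`` marks the decorations
# recurring in >5% of RG peaks (the default prediction pool); the empirical
# re-derivation of that set from data lives in rgms.predict.
_DEFAULT_ACYLS = [
    ("acetic", "C2H4O2", True),
    ("propionic", "C3H6O2", False),
    ("acrylic", "C3H4O2", False),
    ("butyric", "C4H8O2", True),
    ("crotonic", "C4H6O2", False),
    ("C5", "C5H10O2", True),  # methylbutyric / isovaleric / pentanoic
    ("tiglic", "C5H8O2", True),
    ("acetoacetic", "C4H6O3", False),
    ("HMBA", "C5H10O3", True),  # hydroxymethylbutyric
    ("hexanoic", "C6H12O2", False),
    ("octanoic", "C8H16O2", False),
    ("decanoic", "C10H20O2", False),
    ("dodecanoic", "C12H24O2", False),
    ("tetradecanoic", "C14H28O2", False),
    ("hexadecanoic", "C16H32O2", False),
    ("octadecanoic", "C18H36O2", False),
    ("octadecenoic", "C18H34O2", False),
    ("benzoic", "C7H6O2", False),
    ("cinnamic", "C9H8O2", True),
    ("coumaric", "C9H8O3", False),
    ("caffeic", "C9H8O4", False),
    ("ferulic", "C10H10O3", False),
]

# Sugar residues (free sugar minus water). Identity within a class
# (rhamnose vs fucose vs quinovose) is mass-degenerate and out of scope.
_DEFAULT_SUGARS = [
    ("pentose", "pentose", "C5H8O4"),
    ("deoxyhexose", "deoxyhexose", "C6H10O4"),
    ("hexose", "hexose", "C6H10O5"),
]


def _residue_from_acid(acid: str) -> Formula:
    return Formula.parse(acid) - WATER_FORMULA


@dataclass
class MoietyDatabase:
    """The curated moiety database all signature masses derive from.

    Holds exactly three sugar-class residues, the hydroxyacyl set (default
    10) and the acyl set (default 22 fragment masses). Sugars are stored in
    residue form; hydroxyacyls and acyls are stored as residues of their
    free acids (acid minus water).
    """

    sugars: dict[str, Moiety] = field(default_factory=dict)
    hydroxyacyls: dict[str, Moiety] = field(default_factory=dict)
    acyls: dict[str, Moiety] = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.sugars) != set(SUGAR_CLASSES):
            raise ValueError(
                f"database must define exactly the sugar classes {SUGAR_CLASSES}"
            )
        seen: set[str] = set()
        for m in self.all_moieties():
            if m.name in seen:
                raise ValueError(f"duplicate moiety name {m.name!r}")
            seen.add(m.name)
        if not self.hydroxyacyls:
            raise ValueError("database has no hydroxyacyls")
        if not self.acyls:
            raise ValueError("database has no acyls")

    def all_moieties(self) -> Iterable[Moiety]:
        yield from self.sugars.values()
        yield from self.hydroxyacyls.values()
        yield from self.acyls.values()

    @property
    def frequent_acyls(self) -> list[str]:
        return [m.name for m in self.acyls.values() if m.frequent]

    def sugar_residue_mass(self, sugar_class: str) -> float:
        return self.sugars[sugar_class].residue_mass

    # -- serialization --------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "moieties": [
                {
                    "name": m.name,
                    "class": m.moiety_class,
                    "formula": str(m.formula),
                    "frequent": m.frequent,
                }
                for m in self.all_moieties()
            ]
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MoietyDatabase":
        doc = yaml.safe_load(Path(path).read_text())
        db = cls()
        for entry in doc["moieties"]:
            m = Moiety(
                name=entry["name"],
                moiety_class=entry["class"],
                formula=Formula.parse(entry["formula"]),
                frequent=bool(entry.get("frequent", False)),
            )
            if m.moiety_class in SUGAR_CLASSES:
                db.sugars[m.moiety_class] = m
            elif m.moiety_class == "hydroxyacyl":
                db.hydroxyacyls[m.name] = m
            elif m.moiety_class == "acyl":
                db.acyls[m.name] = m
        db.validate()
        return db


def default_database() -> MoietyDatabase:
    """Build the shipped default moiety database (3 sugar classes, 10
    hydroxyacyls, 22 acyls)."""
    db = MoietyDatabase()
    for name, cls_, residue in _DEFAULT_SUGARS:
        db.sugars[cls_] = Moiety(name, cls_, Formula.parse(residue))
    for name, acid in _DEFAULT_HYDROXYACYLS:
        db.hydroxyacyls[name] = Moiety(
            name, "hydroxyacyl", _residue_from_acid(acid), frequent=True
        )
    for name, acid, freq in _DEFAULT_ACYLS:
        db.acyls[name] = Moiety(name, "acyl", _residue_from_acid(acid), frequent=freq)
    db.validate()
    return db


def signature_pair_table(db: MoietyDatabase) -> list[SignaturePair]:
    """Cartesian product of hydroxyacyl [M-H]- masses and sugar residue
    masses; 30 pairs with the default database (10 x 3)."""
    pairs = []
    for ha, sugar_class in itertools.product(db.hydroxyacyls.values(), SUGAR_CLASSES):
        acyl_mz = ha.fragment_mz
        pairs.append(
            SignaturePair(
                hydroxyacyl=ha.name,
                sugar_class=sugar_class,
                acyl_mz=acyl_mz,
                combined_mz=acyl_mz + db.sugar_residue_mass(sugar_class),
            )
        )
    return pairs


@dataclass(frozen=True)
class RGComposition:
    """Counts of each structural component of one resin glycoside.

    ``sugars`` maps sugar class to count (2-7 total in default prediction
    mode); exactly one hydroxyacyl; ``acyls`` is a multiset of acyl names
    stored sorted; ``macrolactone`` is ``"closed"`` (ring, minus one water)
    or ``"open"``; ``adduct`` is ``"deprotonated"`` or ``"formate"``.
    """

    sugars: tuple[tuple[str, int], ...]
    hydroxyacyl: str
    acyls: tuple[str, ...]
    macrolactone: str = "closed"
    adduct: str = "deprotonated"

    @classmethod
    def make(
        cls,
        sugars: Mapping[str, int],
        hydroxyacyl: str,
        acyls: Iterable[str] = (),
        macrolactone: str = "closed",
        adduct: str = "deprotonated",
    ) -> "RGComposition":
        if macrolactone not in ("open", "closed"):
            raise ValueError(f"macrolactone must be open/closed, got {macrolactone!r}")
        if adduct not in ("deprotonated", "formate"):
            raise ValueError(f"unknown adduct {adduct!r}")
        clean = tuple(
            (cls_, int(n))
            for cls_, n in sorted(sugars.items())
            if n
        )
        for cls_, n in clean:
            if cls_ not in SUGAR_CLASSES:
                raise ValueError(f"unknown sugar class {cls_!r}")
            if n < 0:
                raise ValueError("negative sugar count")
        return cls(clean, hydroxyacyl, tuple(sorted(acyls)), macrolactone, adduct)

    @property
    def total_sugars(self) -> int:
        return sum(n for _, n in self.sugars)

    @property
    def sugar_counts(self) -> dict[str, int]:
        return dict(self.sugars)

    def key(self) -> str:
        """Stable one-line serialization (truth tables, TSV outputs)."""
        sug = "+".join(f"{n}x{cls_}" for cls_, n in self.sugars)
        acy = "+".join(self.acyls) if self.acyls else "none"
        return f"{sug}|{self.hydroxyacyl}|{acy}|{self.macrolactone}|{self.adduct}"

    @classmethod
    def from_key(cls, key: str) -> "RGComposition":
        sug_s, ha, acy_s, ring, adduct = key.split("|")
        sugars: dict[str, int] = {}
        for part in sug_s.split("+"):
            n, cls_ = part.split("x", 1)
            sugars[cls_] = int(n)
        acyls = () if acy_s == "none" else tuple(acy_s.split("+"))
        return cls.make(sugars, ha, acyls, ring, adduct)


def composition_mass(comp: RGComposition, db: MoietyDatabase) -> float:
    """Neutral monoisotopic mass of a composition.

    Each glycosidic or ester bond removes one water; residues already carry
    that loss, so M = water (terminal/reducing end) + sum of sugar residues
    + hydroxy-acid residue + acyl residues, minus one more water if the
    macrolactone ring is closed.
    """
    if comp.total_sugars < 1:
        raise ValueError("composition needs at least one sugar")
    if comp.hydroxyacyl not in db.hydroxyacyls:
        raise ValueError(f"unknown hydroxyacyl {comp.hydroxyacyl!r}")
    mass = WATER
    for cls_, n in comp.sugars:
        mass += n * db.sugar_residue_mass(cls_)
    mass += db.hydroxyacyls[comp.hydroxyacyl].residue_mass
    for acyl in comp.acyls:
        mass += db.acyls[acyl].residue_mass
    if comp.macrolactone == "closed":
        mass -= WATER
    return mass


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Observed pseudo-molecular ion m/z for a neutral mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if adduct == "deprotonated":
        return neutral_mass - PROTON_MASS
    if adduct == "formate":
        return neutral_mass + FORMATE_ANION
    raise ValueError(f"unknown adduct {adduct!r}")


def composition_mz(comp: RGComposition, db: MoietyDatabase) -> float:
    """Theoretical precursor m/z of a composition under its own adduct."""
    return adduct_mz(composition_mass(comp, db), comp.adduct)
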
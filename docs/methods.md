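# Methods

## The measurement model

The pipeline consumes aligned negative-mode LC–MS/MS features: each
feature has a precursor m/z (pseudo-molecular ion, [M−H]⁻ or formate
adduct [M+HCOO]⁻), a centroided MS/MS fragment list, and per-sample peak
areas for leaf, root and extraction-blank injections. Resin glycosides
(RGs) fragment predictably along their glycosidic and ester bonds, which
makes three ion families diagnostic:

* the free hydroxy-acid anion of the 14–18-carbon chain (jalapinolic
  acid C16H32O3 → 271.2279);
* the same chain glycosidically bound to 1..k sugars (a ladder in steps
  of 132.0423 / 146.0579 / 162.0528 Da for pentose / deoxyhexose /
  hexose residues), with −18.0106 water-loss satellites;
* acyl fragment ions of the ester decorations (e.g. C5 acids → 101.0608)
  and precursor-side neutral losses (−18 water, −44 CO₂, −46 formic
  acid from formate adducts).

All theoretical masses are computed, never tabulated: residue masses are
free-unit formulas minus one water, deprotonation subtracts the proton
mass 1.007276 Da (the electron stays with the anion — this convention,
rather than subtracting a hydrogen atom, reproduces the four-decimal
reference value 271.2279), and a neutral composition mass is

    M = H2O + Σ sugar residues + hydroxyacyl residue + Σ acyl residues
        − H2O (if the macrolactone is closed)

## Moiety database

The shipped database holds 3 sugar-class residues, 10 hydroxyacyls
(mono- and dihydroxy C14–C18 acids; the mono/di × C14–C18 grid is a
symmetric reconstruction around the chains confirmed in real RG data)
and 22 acyl acids spanning short branched-chain, straight-chain (C2–C18,
including unsaturated C18:1) and aromatic (benzoic through ferulic)
acids in the 50–200 Da acyl mass window. Six acyls (acetic, butyric, C5,
tiglic, HMBA, cinnamic) carry a `frequent` flag and form the default
prediction pool; the flag can also be re-derived empirically from any
detected RG set as "occurs in strictly more than 5% of RG peaks". The
database is YAML-serializable and fully swappable; the shipped counts
(10 × 3 = 30 signature pairs, 22 acyls) apply to the default only.

Sugar identity within a class (rhamnose/fucose/quinovose), acylation
position and stereochemistry are mass-degenerate and out of scope.

## Detection filters

Applied per species dataset, in order:

1. **Blank/area** — max(leaf, root) area must strictly exceed 1000 and
   exceed 10× the blank area. A blank area of zero passes the ratio
   clause (nothing to normalize against). The low absolute threshold
   keeps genuine low-abundance RGs.
2. **Linked peaks** — alignment exports mark features linked to
   higher-mass features; only one of each linked pair is kept
   (configurable: higher [default], lower, or both). Adduct-labelled
   features are always retained. A dangling link keeps both members.
3. **Signature pairs + relative intensity** — at least one of the 30
   (hydroxyacyl anion, anion + sugar residue) pairs must be present
   within the fragment tolerance with *both* members strictly above 10%
   of the base-peak intensity. The 10% rule is applied to pair members
   only, not to every fragment; this reading matches the documented
   false-negative where a 4%-intensity hydroxyacyl member invalidates
   the pair.
4. **Organ call** — area > 1000 in one organ and exactly 0 in the other
   gives a single-organ call; > 1000 in both gives `both`; anything else
   is `ambiguous`.

Fragment match tolerance defaults to ±0.01 Da absolute
(Orbitrap-appropriate; it also absorbs the ~0.5 mDa spread between
computed values and instrument-observed prints such as 299.2592 vs
299.2586). Raising any threshold can only shrink the detected set, and
the cascade is independent of input record order (records are processed
in feature-id order).

## Annotation

Per spectrum the 20 most intense fragments are considered (intensity
ties broken toward lower m/z). Direct matches come from a database of
hydroxyacyl anions, hydroxyacyl + 1–2 sugar residues, acyl anions and
short sugar-chain ions; neutral-loss edges come from all pairwise
differences — the precursor is included as a pseudo-node so losses from
the molecular ion are captured — against sugar residues, acyl residues,
water, CO₂ and formic acid. A fragment is "annotated" if it has a direct
match or touches at least one loss edge; coverage is the pooled fraction
of annotated fragments across spectra. Acetic acid is a special case
throughout: its anion (59 Da) is below the usable mass range, so it is
inferred only from neutral losses (the 42.0106 acetate-residue edge, or
a direct 60.0211 acetic-acid difference).

## Composition prediction

Candidate enumeration is a complete generate-and-test over the
configured space: sugar multisets of 2–7 residues over 3 classes (116
cores), × hydroxyacyls (10), × acyl multisets of size 0–3 from the
frequent pool, × {open, closed} ring, × {deprotonated, formate} adduct,
× optional in-source water loss. Component masses are precomputed and
combined by array broadcasting, so a full default-mode enumeration is a
~1M-element mass comparison and runs in milliseconds; an explicit
candidate cap (10 000) guards against absurd tolerances. Because the
full space is this cheap, the residual mass (precursor − highest
annotated fragment) is *not* used to prune the search — pruning is the
paper-and-pencil shortcut for a manual workflow, and skipping it removes
a place where annotation errors could propagate; every candidate is
verified against the full precursor mass. Completeness is tested against
an independent brute-force oracle on reduced pools.

Evidence scoring adds one point per candidate component with a
supporting observed fragment or loss edge (hydroxyacyl anion or paired
fragment; sugar residue loss; acyl anion, acetic via loss) and subtracts
one point from formate-adduct candidates lacking a −46.0055 loss from
the precursor. Ties break by |Δmass|, then fewer components, then the
lexicographic composition key — fully deterministic.

Known degeneracies: deoxyhexose + hydroxymethylbutyrate and hexose + a
C5 acid both sum to C11H18O6, so candidate sets of decorated RGs
necessarily contain isobaric swaps (high recall, low precision — all
candidates are reported for manual review). Similarly an open-chain
composition observed with an in-source water loss is isobaric with its
closed-ring form; both are reported, distinguished by the `water_loss`
flag.

Default mode cannot, by construction, express compositions with more
than three acyls or with non-frequent acyls; the extended mode
(`PredictionConfig.extended()`: 5 acyls, + decanoic) exists precisely
for those, at a ~10× larger search space.

## Synthetic data

The generator emulates MS-DIAL-style exports of a Q-Exactive-type run:
precursors confined to the 500–2000 m/z scan window, base peak 10⁶
(arbitrary units), informative ions log-uniform between 10.5% and 100%
of base (keeping signature pairs above the 10% filter in clean presets),
Gaussian m/z jitter with SD 0.001 Da (≈ one third of the match
tolerance), leaf/root areas log-uniform between 10⁴ and 10⁶ with blank
zero. Sampling weights favor deoxyhexose cores and jalapinolic acid,
matching the dominant chemotypes. Decoy presets violate exactly one
filter each (blank-dominated, sub-1000 area, pairless spectra); hard-case
presets plant a five-acyl open-chain RG and a decanoate-bearing RG that
defeat default prediction but not extended mode. Everything is driven by
one seed and is byte-identical across reruns.

What the generator does **not** emulate: collision-energy-dependent
intensities, isotope envelopes, chimeric spectra, co-eluting isomers, or
realistic noise floors. A green round-trip test therefore establishes
the internal consistency of the mass logic and filter semantics — not
instrument-level performance on real extracts, where annotation coverage
and detection recall will be lower.

## Numerical choices

* Atomic masses: C 12 (exact), H 1.00782503, O 15.9949146, N 14.0030740;
  proton 1.007276, water 18.010565, CO₂ 43.989830, formic acid
  46.005480, formate anion 44.998200 Da.
* All tolerances are absolute Da (MS/MS fragments ±0.01, precursor
  ±0.01 by default); percentages and ratio thresholds are strict
  inequalities (">10%", ">1000", ">10×", ">5%").
* Signature-pair theoretical masses use the computed values; observed
  prints that differ by < 1 mDa (417.2854, 299.2586) are treated as
  instrument-observed and absorbed by the tolerance.
* Pearson correlations use scipy; a zero-variance column yields a
  missing value, never 0. Fragment-pair correlations require ≥3 jointly
  nonzero observations (the statistic is meaningless below that).
* Organ correlation uses per-organ relative areas (each organ normalized
  to its total over the detected set) by default, with a raw-area option.

## Limitations

* The shipped hydroxyacyl and acyl sets are curated reconstructions;
  laboratory-specific moiety lists should be supplied via the YAML
  database.
* Detection presumes the hydroxyacyl-anchored fragmentation habit; RG
  classes that fragment differently (e.g. intermolecular condensates)
  are invisible to the signature-pair criterion.
* Prediction output is intentionally low-precision: the tool narrows a
  structural neighborhood, it does not identify compounds
  (class-level, not compound-level annotation).
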
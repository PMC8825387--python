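# rgms — resin glycoside discovery and component annotation from LC–MS/MS

Resin glycosides (RGs) are acylsugars of the morning glory family
(Convolvulaceae): an oligosaccharide core of 2–7 pentose / deoxyhexose /
hexose residues, one 14–18-carbon hydroxy or dihydroxy fatty acid (often
closed into a macrolactone ring), and short aliphatic or aromatic acyl
ester decorations. In negative-mode LC–MS/MS they fragment in a highly
characteristic way: the free hydroxy-acid anion (e.g. jalapinolic acid,
[M−H]⁻ 271.2279) co-occurs with the same chain bound to one sugar
(271.2279 + 146.0579 = 417.2858 for a deoxyhexose), extending into a
glycosidic ladder with water-loss satellites and acyl fragment ions.

`rgms` turns that fragmentation knowledge into a desk-scale pipeline for
untargeted metabolomics feature exports (MS-DIAL-style MGF + peak-area
alignment tables). It is aimed at natural-product and plant-metabolism
groups who need to triage thousands of unidentified features into
high-confidence RG candidates and narrow their structural neighborhood
without NMR.

## What it does

1. **Detection** (`rgms.detect`) — four filters separate likely RGs from
   noise: (i) leaf/root peak area > 1000 and > 10× the blank area;
   (ii) at least one of 30 signature fragment pairs (10 hydroxyacyls ×
   3 sugar classes); (iii) both pair members > 10% of the base peak;
   (iv) of two linked features only the higher-mass one is kept. Organ
   localization (leaf/root/both/ambiguous) is called from unnormalized
   areas.
2. **Annotation** (`rgms.annotate`) — the top-20 fragments are matched to
   a moiety-derived database; all pairwise differences (precursor
   included) are compared to a neutral-loss database (sugar residues,
   acyl residues, water 18.0106, CO₂ 43.9898, formic acid 46.0055); the
   residual between the highest annotated fragment and the precursor is
   computed.
3. **Prediction** (`rgms.predict`) — exhaustive enumeration of every
   composition (sugar multiset, hydroxyacyl, acyl multiset, ring state,
   adduct, optional in-source water loss) whose theoretical ion mass
   matches the precursor within tolerance, re-ranked by observed-fragment
   evidence. Default mode searches up to hepta-saccharide cores with ≤3
   frequent acyls; extended mode allows 5 acyls and decanoic acid.
4. **Co-occurrence** (`rgms.cooccur`) — pairwise Pearson correlation of
   nominal-mass fragment intensities (water-loss Δ18 pairs flagged) and
   the leaf-vs-root relative peak-area correlation.
5. **Simulation** (`rgms.simulate`) — a seeded generator of synthetic
   MGF/alignment fixtures with planted compositions, filter-violating
   decoys and hard prediction cases, so the entire pipeline is testable
   without instrument data.

All masses derive from one place (`rgms.chem`): monoisotopic elemental
arithmetic over Hill-notation formulas, residue masses (free unit minus
one water per glycosidic/ester bond), [M−H]⁻ = M − 1.007276 Da and
[M+HCOO]⁻ = M + 44.998200 Da.

## Worked example

```python
from rgms import (SimulationConfig, simulate_dataset, default_database,
                  enumerate_candidates, score_candidates, PredictionConfig)
from rgms.detect import detect
from rgms.annotate import annotate_record

db = default_database()
ds = simulate_dataset(SimulationConfig(seed=7, n_rgs=10), db)
detections, attrition = detect(ds.records, ds.table, db)
print("attrition:", attrition)

spectra = {r.feature_id: r for r in ds.records}
d = detections[0]
ann = annotate_record(spectra[d.feature_id], db)
cands = score_candidates(
    enumerate_candidates(d.precursor_mz, db, PredictionConfig()), ann, db)
print(d.feature_id, d.organ_call, ann.annotated_fraction, len(cands))
```

prints

```
attrition: {'input': 17, 'blank_area': 4, 'linked': 0, 'signature_pair': 3, 'detected': 10}
RG_001 root_only 1.0 1063
```

All 10 planted RGs survive the filters while the 7 decoys are rejected at
the stage they were built to fail (4 at the blank/area filter, 3 at the
signature-pair filter). The first detection is annotated completely
(fraction 1.0) and receives 1063 mass-compatible candidate compositions —
deliberately low precision, as isobaric residue combinations (e.g.
deoxyhexose + hydroxymethylbutyrate vs hexose + a C5 acid, both summing
to C11H18O6) cannot be distinguished by precursor mass alone; the
evidence score and the Δ-mass ranking then push fragment-supported
candidates to the top, and the planted truth is always contained in the
set on clean data.

A CLI mirrors the library: `rgms simulate|detect|annotate|predict|
correlate|run-all` (see `rgms --help`).

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference m/z values
from scratch — deprotonated hydroxy/acyl acid anions from their elemental
formulas, the C16-OH + deoxyhexose signature fragment from the pair
table, and the assembled tricolorin-type and dichondrin-type
pseudo-molecular ions from their component compositions — and writes them
as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
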
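"""Composition enumeration: completeness, soundness, scoring, recall."""

import itertools

import pytest

from rgms.annotate import annotate_record
from rgms.chem import (
    SUGAR_CLASSES,
    WATER,
    RGComposition,
    adduct_mz,
    composition_mass,
    composition_mz,
)
from rgms.io import SpectrumRecord
from rgms.predict import (
    PredictionConfig,
    derive_frequent_acyls,
    enumerate_candidates,
    evaluate_recall,
    score_candidates,
)
from rgms.simulate import fragment_composition, known_rg_panel


def brute_force_candidates(precursor_mz, db, cfg):
    """Independent generate-and-test oracle: nested loops over the whole
    component space, no shared code with the enumerator's index math."""
    hits = set()
    acyl_pool = sorted(cfg.resolve_acyl_pool(db))
    ha_pool = sorted(cfg.resolve_hydroxyacyl_pool(db))
    water_states = [False, True] if cfg.allow_water_loss else [False]
    for n_sug in range(cfg.min_sugars, cfg.max_sugars + 1):
        for sugar_seq in itertools.combinations_with_replacement(SUGAR_CLASSES, n_sug):
            counts = {c: sugar_seq.count(c) for c in set(sugar_seq)}
            for ha in ha_pool:
                for n_acyl in range(cfg.max_acyls + 1):
                    for acyls in itertools.combinations_with_replacement(
                            acyl_pool, n_acyl):
                        for ring in cfg.ring_states:
                            for adduct in cfg.adducts:
                                comp = RGComposition.make(counts, ha, acyls,
                                                          ring, adduct)
                                mz = adduct_mz(composition_mass(comp, db), adduct)
                                for lost in water_states:
                                    theo = mz - (WATER if lost else 0.0)
                                    if abs(theo - precursor_mz) <= \
                                            cfg.precursor_tolerance:
                                        hits.add((comp, lost))
    return hits


REDUCED = dict(max_sugars=4, hydroxyacyl_pool=("C16-OH", "C15-OH"),
               acyl_pool=("C5", "tiglic", "HMBA"))


class TestEnumerationCompleteness:
    @pytest.mark.parametrize("precursor", [
        1067.5644,   # tricolorin-like formate adduct
        835.4433, 1021.5589, 655.3704,
    ])
    def test_matches_brute_force_oracle(self, db, precursor):
        cfg = PredictionConfig(**REDUCED)
        got = {(c.composition, c.water_loss)
               for c in enumerate_candidates(precursor, db, cfg)}
        assert got == brute_force_candidates(precursor, db, cfg)

    def test_planted_compositions_present(self, db):
        cfg = PredictionConfig(**REDUCED)
        comp = RGComposition.make({"deoxyhexose": 2, "pentose": 1}, "C15-OH",
                                  ("tiglic",), "closed", "formate")
        candidates = enumerate_candidates(composition_mz(comp, db), db, cfg)
        assert any(c.composition == comp for c in candidates)


class TestEnumerationProperties:
    def test_soundness(self, db):
        for cand in enumerate_candidates(1067.5644, db, PredictionConfig()):
            recomputed = composition_mz(cand.composition, db)
            if cand.water_loss:
                recomputed -= WATER
            assert recomputed == pytest.approx(cand.theoretical_mz, abs=1e-9)
            assert abs(cand.delta) <= PredictionConfig().precursor_tolerance

    def test_monotone_in_tolerance(self, db):
        counts = [len(enumerate_candidates(1067.5644, db,
                                           PredictionConfig(precursor_tolerance=t)))
                  for t in (0.002, 0.005, 0.01, 0.02)]
        assert counts == sorted(counts)

    def test_monotone_in_pool_and_acyl_limit(self, db):
        small = PredictionConfig(**REDUCED)
        more_acyls = PredictionConfig(**{**REDUCED,
                                         "acyl_pool": ("C5", "tiglic", "HMBA",
                                                       "acetic", "butyric")})
        deeper = PredictionConfig(**REDUCED, max_acyls=5)
        n_small = len(enumerate_candidates(1067.5644, db, small))
        assert len(enumerate_candidates(1067.5644, db, more_acyls)) >= n_small
        assert len(enumerate_candidates(1067.5644, db, deeper)) >= n_small

    def test_deterministic_order(self, db):
        a = enumerate_candidates(1067.5644, db, PredictionConfig())
        b = enumerate_candidates(1067.5644, db, PredictionConfig())
        assert [(c.composition, c.water_loss) for c in a] == \
               [(c.composition, c.water_loss) for c in b]

    def test_candidate_cap_overflow(self, db):
        cfg = PredictionConfig(precursor_tolerance=5.0, candidate_cap=100)
        with pytest.raises(OverflowError, match="narrow"):
            enumerate_candidates(1067.5644, db, cfg)

    def test_isobaric_swap_present(self, db):
        """deoxyhexose+HMBA and hexose+C5 are exactly isobaric; both
        variants must appear for the tricolorin-like precursor."""
        candidates = enumerate_candidates(1067.5644, db, PredictionConfig())
        comps = {c.composition for c in candidates}
        a = RGComposition.make({"deoxyhexose": 3, "hexose": 1}, "C16-OH",
                               ("C5", "C5"), "closed", "formate")
        b = RGComposition.make({"deoxyhexose": 4}, "C16-OH",
                               ("C5", "HMBA"), "closed", "formate")
        assert a in comps and b in comps


class TestScoring:
    def _annotation(self, db, comp):
        frags = fragment_composition(comp, db)
        rec = SpectrumRecord("f", composition_mz(comp, db), 10.0, frags)
        return annotate_record(rec, db)

    def test_supported_candidate_outranks_isobar(self, db):
        comp = RGComposition.make({"deoxyhexose": 3, "hexose": 1}, "C16-OH",
                                  ("C5", "C5"), "closed", "formate")
        ann = self._annotation(db, comp)
        candidates = enumerate_candidates(1067.5644, db, PredictionConfig())
        ranked = score_candidates(candidates, ann, db)
        ranks = {c.composition: i for i, c in enumerate(ranked)}
        isobar = RGComposition.make({"deoxyhexose": 4}, "C16-OH",
                                    ("C5", "HMBA"), "closed", "formate")
        assert ranks[comp] < ranks[isobar]

    def test_formate_candidates_need_formate_loss(self, db):
        # no -46 loss edge observed: formate candidates are penalized
        rec = SpectrumRecord("f", 1067.5644, 10.0,
                             [(271.2279, 1.0e6), (417.2858, 5e5)])
        ann = annotate_record(rec, db)
        ranked = score_candidates(
            enumerate_candidates(1067.5644, db, PredictionConfig()), ann, db)
        for cand in ranked:
            if cand.composition.adduct == "formate":
                assert "formate" in cand.contradicting

    def test_empty_annotation_orders_by_mass_closeness(self, db):
        candidates = enumerate_candidates(1067.5644, db, PredictionConfig())
        ranked = score_candidates(candidates, None, db)
        deltas = [abs(c.delta) for c in ranked]
        assert deltas == sorted(deltas)


class TestFrequentAcyls:
    def _detections(self, db, with_c5):
        from rgms.detect import DetectedRG
        spectra, detections = {}, []
        for i in range(100):
            frags = [(271.2279, 1.0e6), (417.2858, 5e5)]
            if i < with_c5:
                frags.append((101.0608, 3e5))
            fid = f"f{i}"
            spectra[fid] = SpectrumRecord(fid, 900.0, 10.0, frags)
            detections.append(DetectedRG(fid, 900.0, 10.0, [], "both",
                                         1e4, 1e4, 0.0))
        return detections, spectra

    def test_strictly_greater_than_threshold(self, db):
        detections, spectra = self._detections(db, with_c5=6)
        assert "C5" in derive_frequent_acyls(detections, spectra, db)
        detections, spectra = self._detections(db, with_c5=5)
        assert "C5" not in derive_frequent_acyls(detections, spectra, db)

    def test_no_detections_rejected(self, db):
        with pytest.raises(ValueError):
            derive_frequent_acyls([], {}, db)


class TestRecall:
    def test_panel_recall_default_vs_extended(self, db):
        panel = known_rg_panel(db)
        default = evaluate_recall(panel, db, PredictionConfig())
        assert default.recall == pytest.approx(11 / 13)
        missed = set(default.verdicts.query("~recovered")["name"])
        assert missed == {"dichondrin_like", "merremin_like"}
        extended = evaluate_recall(panel, db, PredictionConfig.extended())
        assert extended.recall == 1.0

    def test_empty_known_list_rejected(self, db):
        with pytest.raises(ValueError):
            evaluate_recall([], db)
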
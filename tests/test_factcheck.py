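import random

import numpy as np
import pytest

from domfact import synthetic
from domfact.content import DomainHit
from domfact.events import AD, MD, OrthologPair, detect_events
from domfact.factcheck import (
    ANN_ORTHO,
    ANN_REF,
    GENE_PRED,
    ISOFORM,
    SWITCHING,
    TRUE_AD,
    TRUE_MD,
    UNDET_GENOME,
    CheckResources,
    ResourceError,
    check_gene_prediction,
    check_genome_Ns,
    check_isoforms,
    classify_final,
    fact_check_all,
    fact_check_one,
    find_n_runs,
    reconcile_annotation,
)
from domfact.formats import AnnotationSet, GenomicRegion


def _hit(fam, start=1, end=60, evalue=1e-10, pid=None):
    return DomainHit(family=fam, start=start, end=end, evalue=evalue,
                     protein_id=pid, source="hmm_scan")


def _md_event(ref_fams=("PF00001", "PF00002"), ortho_fams=("PF00001",),
              ref_seq="", ortho_seq=""):
    def ann(pid, fams, sp):
        hits, pos = [], 1
        for f in fams:
            hits.append(DomainHit(family=f, start=pos, end=pos + 59))
            pos += 80
        return AnnotationSet(pid, species=sp, hits=hits)

    pair = OrthologPair(ref_ann=ann("R1", ref_fams, "reference"),
                        ortho_ann=ann("O1", ortho_fams, "sp1"),
                        species="sp1", ref_seq=ref_seq, ortho_seq=ortho_seq)
    events = detect_events(pair)
    return next(e for e in events if e.direction == MD)


def _resources(ref_hits=(), ortho_hits=(), **kw):
    return CheckResources(
        scan_hits={"R1": list(ref_hits), "O1": list(ortho_hits)}, **kw)


class TestReconcileAnnotation:
    def test_md_found_in_ortholog_scan(self):
        ev = _md_event()
        res = _resources(ref_hits=[_hit("PF00002")],
                         ortho_hits=[_hit("PF00002", evalue=1.6e-8)])
        v = reconcile_annotation(ev, res)
        assert v.klass == ANN_ORTHO
        assert v.evidence["evalue"] == pytest.approx(1.6e-8)

    def test_md_reference_annotation_unsupported(self):
        ev = _md_event()
        # no scan hit for PF00002 on either side
        res = _resources(ref_hits=[_hit("PF00001")], ortho_hits=[])
        assert reconcile_annotation(ev, res).klass == ANN_REF

    def test_md_passes_when_ref_supported_and_ortho_above_threshold(self):
        ev = _md_event()
        res = _resources(ref_hits=[_hit("PF00002", evalue=1e-20)],
                         ortho_hits=[_hit("PF00002", evalue=0.5)])
        assert reconcile_annotation(ev, res) is None

    def test_ad_mirrored(self):
        ref = AnnotationSet("R1", hits=[DomainHit(family="PF00001", start=1, end=60)])
        ortho = AnnotationSet("O1", hits=[
            DomainHit(family="PF00001", start=1, end=60),
            DomainHit(family="PF00003", start=80, end=140)])
        pair = OrthologPair(ref_ann=ref, ortho_ann=ortho, species="sp1")
        (ad,) = detect_events(pair)
        assert ad.direction == AD
        # gained domain unsupported on the ortholog -> ortho-side inconsistency
        res = _resources(ref_hits=[], ortho_hits=[_hit("PF00003", evalue=0.3)])
        assert reconcile_annotation(ad, res).klass == ANN_ORTHO
        # confirmed on ortholog but also present in the reference per re-scan
        res = _resources(ref_hits=[_hit("PF00003", evalue=3.2e-8)],
                         ortho_hits=[_hit("PF00003", evalue=2e-10)])
        assert reconcile_annotation(ad, res).klass == ANN_REF
        # confirmed on ortholog, absent from reference -> undecided here
        res = _resources(ref_hits=[], ortho_hits=[_hit("PF00003", evalue=2e-10)])
        assert reconcile_annotation(ad, res) is None

    def test_missing_scan_results_is_config_error(self):
        ev = _md_event()
        res = CheckResources(scan_hits={"R1": []})
        with pytest.raises(ResourceError, match="O1"):
            reconcile_annotation(ev, res)


class TestGenePrediction:
    def _setup(self, plant=True, scramble=False, intron=0):
        rng = np.random.default_rng(5)
        dom = synthetic._random_protein(60, rng)
        linker = synthetic._random_protein(20, rng)
        ref_seq = linker + dom + linker + synthetic._random_protein(60, rng) + linker
        ref = AnnotationSet("R1", hits=[
            DomainHit(family="PF00002", start=21, end=80),
            DomainHit(family="PF00008", start=101, end=160)])
        ortho_seq = linker + linker + synthetic._random_protein(60, rng) + linker
        ortho = AnnotationSet("O1", hits=[DomainHit(family="PF00008", start=41, end=100)])
        pair = OrthologPair(ref_ann=ref, ortho_ann=ortho, species="sp1",
                            ref_seq=ref_seq, ortho_seq=ortho_seq)
        ev = next(e for e in detect_events(pair) if str(e.unit) == "PF00002")
        cds = synthetic.back_translate(ortho_seq, rng)
        if plant:
            cds = synthetic.plant_gene_error(cds, dom, len(cds), rng, intron_len=intron)
        if scramble:
            cds = "".join(rng.permutation(list(cds)))
        region = GenomicRegion("O1", "sp1",
                               synthetic._random_dna(300, rng) + cds +
                               synthetic._random_dna(300, rng), 300)
        res = CheckResources(scan_hits={"R1": [_hit("PF00002", 21, 80)], "O1": []},
                             regions={"O1": region})
        return ev, res

    def test_planted_exon_found(self):
        ev, res = self._setup(plant=True)
        v = check_gene_prediction(ev, res)
        assert v is not None and v.klass == GENE_PRED
        assert v.evidence["identity"] > 0.9

    def test_scrambled_region_no_verdict(self):
        ev, res = self._setup(plant=False, scramble=True)
        assert check_gene_prediction(ev, res) is None

    def test_intron_split_exon_still_found(self):
        ev, res = self._setup(plant=True, intron=200)
        v = check_gene_prediction(ev, res)
        assert v is not None and v.evidence["coverage"] >= 0.4

    def test_missing_region_skips_stage(self):
        ev, res = self._setup()
        res = CheckResources(scan_hits=res.scan_hits, regions={})
        assert check_gene_prediction(ev, res) is None

    def test_corrected_protein_hook_takes_precedence(self):
        ev, res = self._setup(plant=False)
        res = CheckResources(
            scan_hits=res.scan_hits, regions=res.regions,
            corrected_scan_hits={"O1": [_hit("PF00002", evalue=1e-6)]})
        v = check_gene_prediction(ev, res)
        assert v.klass == GENE_PRED and "corrected_protein_hit" in v.evidence


class TestGenomeNs:
    def test_run_coordinates(self):
        assert find_n_runs("ACGTNNNNNNACGT") == [(5, 10)]
        assert find_n_runs("NNACGTN") == [(1, 2), (7, 7)]

    def test_threshold(self):
        assert find_n_runs("ACGTNNNNNACGT", min_run=10) == []
        assert find_n_runs("ACGT" + "N" * 10 + "ACGT", min_run=10) == [(5, 14)]

    def test_verdict(self):
        ev = _md_event()
        region = GenomicRegion("O1", "sp1", "ACGT" * 10 + "N" * 6 + "ACGT" * 10, 0)
        res = CheckResources(scan_hits={"R1": [], "O1": []}, regions={"O1": region})
        v = check_genome_Ns(ev, res)
        assert v.klass == UNDET_GENOME and v.evidence["n_runs"] == [[41, 46]]

    def test_n_free_region(self):
        ev = _md_event()
        res = CheckResources(scan_hits={"R1": [], "O1": []},
                             regions={"O1": GenomicRegion("O1", "sp1", "ACGT" * 20, 0)})
        assert check_genome_Ns(ev, res) is None


class TestIsoforms:
    def _ad_event(self):
        ref = AnnotationSet("R1", hits=[DomainHit(family="PF00001", start=1, end=60)])
        ortho = AnnotationSet("O1", hits=[
            DomainHit(family="PF00001", start=1, end=60),
            DomainHit(family="PF00003", start=80, end=140)])
        pair = OrthologPair(ref_ann=ref, ortho_ann=ortho, species="sp1")
        (ev,) = detect_events(pair)
        return ev

    def test_isoform_with_unit(self):
        ev = self._ad_event()
        iso = AnnotationSet("R1-iso2", hits=[
            DomainHit(family="PF00001", start=1, end=60),
            DomainHit(family="PF00003", start=80, end=140)])
        res = CheckResources(scan_hits={}, ref_isoforms={"R1": [iso]})
        v = check_isoforms(ev, res)
        assert v.klass == ISOFORM and v.evidence["isoform_id"] == "R1-iso2"

    def test_no_isoforms(self):
        res = CheckResources(scan_hits={})
        assert check_isoforms(self._ad_event(), res) is None

    def test_same_clan_different_family_isoform_does_not_match(self):
        """Family-level matching here; clan relatives are switching territory."""
        ev = self._ad_event()
        iso = AnnotationSet("R1-iso2", hits=[DomainHit(family="PF00004", start=1, end=60)])
        res = CheckResources(scan_hits={}, ref_isoforms={"R1": [iso]},
                             clans={"PF00003": "CL0009", "PF00004": "CL0009"})
        assert check_isoforms(ev, res) is None


class TestClassifyFinal:
    clans = {"PF00002": "CL0007", "PF00009": "CL0007"}

    def test_clan_mate_means_switching(self):
        ev = _md_event(("PF00001", "PF00002"), ("PF00001", "PF00009"))
        res = CheckResources(scan_hits={}, clans=self.clans)
        v = classify_final(ev, res)
        assert v.klass == SWITCHING and v.evidence["clan"] == "CL0007"

    def test_no_clan_relative_true_md(self):
        ev = _md_event()
        res = CheckResources(scan_hits={}, clans=self.clans)
        assert classify_final(ev, res).klass == TRUE_MD

    def test_unmapped_family_true_ad(self):
        ref = AnnotationSet("R1", hits=[DomainHit(family="PF00001", start=1, end=60)])
        ortho = AnnotationSet("O1", hits=[
            DomainHit(family="PF00001", start=1, end=60),
            DomainHit(family="PF00042", start=80, end=140)])
        pair = OrthologPair(ref_ann=ref, ortho_ann=ortho, species="sp1")
        (ev,) = detect_events(pair)
        res = CheckResources(scan_hits={}, clans=self.clans)
        assert classify_final(ev, res).klass == TRUE_AD

    def test_reciprocal_mode_requires_unmatched_clan_mate(self):
        # ortholog has the clan mate AND the reference has it too -> matched,
        # so reciprocal mode falls through to a true event
        ev = _md_event(("PF00001", "PF00002", "PF00009"), ("PF00001", "PF00009"))
        res_p = CheckResources(scan_hits={}, clans=self.clans, switch_mode="presence")
        res_r = CheckResources(scan_hits={}, clans=self.clans, switch_mode="reciprocal")
        assert classify_final(ev, res_p).klass == SWITCHING
        assert classify_final(ev, res_r).klass == TRUE_MD


class TestPipelineOrder:
    def test_short_circuit_records_one_stage(self):
        ev = _md_event()
        res = _resources(ref_hits=[_hit("PF00002")],
                         ortho_hits=[_hit("PF00002", evalue=1e-9)])
        v = fact_check_one(ev, res)
        assert v.klass == ANN_ORTHO and v.stages_run == ["annotation"]

    def test_exon_beats_n_run_and_flags_dual_evidence(self, recovery_dataset):
        ds = recovery_dataset
        gp = next(t for t in ds.truth if t.planted_class == "gene_pred")
        region = ds.regions[gp.ortho_id]
        # graft an N-run onto the gene-prediction pair's region
        seq = region.sequence
        noisy = seq[:50] + "N" * 40 + seq[50:]
        regions = dict(ds.regions)
        regions[gp.ortho_id] = GenomicRegion(region.gene_id, region.species,
                                             noisy, region.flank_nt)
        res = ds.check_resources(regions=regions)
        pair = next(p for p in ds.build_pairs() if p.ortho_id == gp.ortho_id)
        ev = next(e for e in detect_events(pair, ds.clans) if e.direction == MD)
        v = fact_check_one(ev, res)
        assert v.klass == GENE_PRED
        assert v.evidence.get("also_has_n_runs") is True
        assert v.stages_run == ["annotation", "gene_prediction"]

    def test_event_order_never_changes_verdicts(self, small_dataset):
        ds = small_dataset
        events = [e for p in ds.build_pairs() for e in detect_events(p, ds.clans)]
        res = ds.check_resources()
        base = {(v.event.key): v.klass for v in fact_check_all(events, res)}
        rnd = random.Random(3)
        for _ in range(3):
            shuffled = list(events)
            rnd.shuffle(shuffled)
            got = {(v.event.key): v.klass for v in fact_check_all(shuffled, res)}
            assert got == base

    def test_evalue_monotonicity(self, small_dataset):
        """Raising evalue_max only moves MD events into the ortho-annotation
        class, never out of it."""
        ds = small_dataset
        events = [e for p in ds.build_pairs() for e in detect_events(p, ds.clans)]
        lo = fact_check_all(events, ds.check_resources(evalue_max=0.01))
        hi = fact_check_all(events, ds.check_resources(evalue_max=10.0))
        lo_by = {v.event.key: v.klass for v in lo}
        hi_by = {v.event.key: v.klass for v in hi}
        for key, klass in lo_by.items():
            if klass == ANN_ORTHO and key[2] == MD:
                assert hi_by[key] == ANN_ORTHO


class TestPlantedRecovery:
    def test_every_planted_class_recovered_exactly(self, recovery_dataset):
        ds = recovery_dataset
        events = [e for p in ds.build_pairs() for e in detect_events(p, ds.clans)]
        verdicts = fact_check_all(events, ds.check_resources())
        expected = {}
        for t in ds.truth:
            klass = dict(synthetic.PLANT_TRUTH[t.planted_class])[t.direction]
            expected[(t.species, t.ref_id, t.direction, t.unit)] = klass
        got = {v.event.key: v.klass for v in verdicts}
        assert got == expected
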
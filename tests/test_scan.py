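"""Genome scanning: exact p-value DP vs enumeration, BH correction,
plant-and-recover scans, strand consistency, and site annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tfdissect.pwm import PositionWeightMatrix, revcomp
from tfdissect.scan import (MotifHit, ScoreDistribution, annotate_hits,
                            benjamini_hochberg, exact_pvalue,
                            proximal_filter, scan_genome,
                            tss_relative_location)
from tfdissect.simulate import SyntheticGenomeSpec, build_synthetic_genome
from tfdissect.datasets import genome_sites
from .conftest import pwm_from_consensus, random_pwm


def brute_force_pvalue(pwm, threshold, granularity=1e-3):
    """Independent oracle: enumerate all 4^w sequences, sum the
    background probability of those whose quantized score clears the
    quantized threshold (the quantization is part of the statistic's
    definition)."""
    q = np.rint(pwm.log_odds / granularity).astype(np.int64)
    qt = int(np.rint(threshold / granularity))
    bg = pwm.background
    total = 0.0
    for seq in itertools.product(range(4), repeat=pwm.width):
        if sum(q[j, b] for j, b in enumerate(seq)) >= qt:
            p = 1.0
            for b in seq:
                p *= bg[b]
            total += p
    return total


class TestExactPvalue:
    def test_minimum_score_gives_p_one(self, consensus_pwm):
        assert exact_pvalue(
            consensus_pwm, consensus_pwm.min_score()) == pytest.approx(1.0)

    def test_width4_strict_maximum(self):
        # strict per-column maximum under uniform background: only the
        # consensus itself achieves the max, p = (1/4)^4
        pwm = pwm_from_consensus("ACGT")
        assert exact_pvalue(pwm, pwm.max_score()) == pytest.approx(
            0.25 ** 4)

    @pytest.mark.parametrize("width", [3, 5, 6, 8])
    def test_matches_enumeration(self, width, rng):
        """DP vs 4^w enumeration over 25 random PWMs at |dp| <= 1e-9."""
        n_pwms = {3: 10, 5: 6, 6: 6, 8: 3}[width]
        for _ in range(n_pwms):
            pwm = random_pwm(rng, width)
            lo, hi = pwm.min_score(), pwm.max_score()
            for thr in rng.uniform(lo, hi, 8):
                assert exact_pvalue(pwm, float(thr)) == pytest.approx(
                    brute_force_pvalue(pwm, float(thr)), abs=1e-9)

    def test_quantization_error_bounded(self, rng):
        # a coarser grid changes any achievable score by at most w*g/2
        pwm = random_pwm(rng, 6)
        fine = ScoreDistribution(pwm, granularity=1e-4)
        coarse = ScoreDistribution(pwm, granularity=1e-2)
        for thr in rng.uniform(pwm.min_score(), pwm.max_score(), 5):
            pf = float(fine.pvalue(thr))
            shift = 6 * 1e-2
            assert float(coarse.pvalue(thr + shift)) - 1e-12 <= pf \
                <= float(coarse.pvalue(thr - shift)) + 1e-12


class TestBenjaminiHochberg:
    def test_hand_checked_cases(self):
        assert benjamini_hochberg([0.5]) == pytest.approx([0.5])
        np.testing.assert_allclose(
            benjamini_hochberg([0.02, 0.02, 0.02]), [0.02, 0.02, 0.02])
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        q = benjamini_hochberg(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(benjamini_hochberg(p[perm]), q[perm])

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(1e-6, 1, 200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(p), q_ref)

    def test_empty_and_domain(self):
        assert benjamini_hochberg([]).size == 0
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0, 0.5])


class TestScanGenome:
    def test_plant_and_recover(self, consensus_pwm, consensus):
        genome, _, _ = build_synthetic_genome(SyntheticGenomeSpec(
            length=5000, planted_sites=((consensus, 1001, "+"),), seed=3))
        hits = scan_genome(consensus_pwm, genome, p_threshold=1e-4)
        top = hits[0]
        assert (top.start, top.end) == (1001, 1016)
        assert top.end - top.start + 1 == consensus_pwm.width
        assert top.matched_sequence == consensus

    def test_palindromic_hits_reported_once(self, consensus_pwm,
                                            consensus):
        from tfdissect.pwm import palindromize
        pal = palindromize(consensus_pwm)
        genome, _, _ = build_synthetic_genome(SyntheticGenomeSpec(
            length=3000, planted_sites=((consensus, 501, "+"),), seed=7))
        hits = scan_genome(pal, genome, p_threshold=1e-4)
        loci = [(h.start, h.end) for h in hits]
        assert len(loci) == len(set(loci))
        assert all(h.strand == "+" for h in hits
                   if (h.start, h.end) == (501, 516))

    def test_strand_consistency(self, rng):
        """Scanning the reverse-complemented genome mirrors the hit set."""
        pwm = pwm_from_consensus("TGTGGTCCAGGCTACC", weight=8)
        genome, _, _ = build_synthetic_genome(SyntheticGenomeSpec(
            length=2000,
            planted_sites=(("TGTGGTCCAGGCTACC", 301, "+"),), seed=9))
        hits_f = scan_genome(pwm, genome, p_threshold=1e-3)
        hits_r = scan_genome(pwm, revcomp(genome), p_threshold=1e-3)
        L = len(genome)
        mirrored = {(L - h.end + 1, L - h.start + 1,
                     "-" if h.strand == "+" else "+") for h in hits_r}
        assert {(h.start, h.end, h.strand) for h in hits_f} == mirrored

    def test_span_matches_width_and_qvalues_in_range(self, consensus_pwm):
        genome, _, _ = build_synthetic_genome(SyntheticGenomeSpec(
            length=4000,
            planted_sites=((consensus_pwm.consensus(), 101, "+"),
                           (consensus_pwm.consensus(), 2001, "-")),
            seed=5))
        hits = scan_genome(consensus_pwm, genome, p_threshold=1e-3)
        for h in hits:
            assert h.end - h.start + 1 == consensus_pwm.width
            assert 0 < h.p_value <= 1
            assert 0 < h.q_value <= 1

    def test_short_genome_warns_empty(self, consensus_pwm):
        with pytest.warns(UserWarning):
            assert scan_genome(consensus_pwm, "ACGT") == []


def _hit(start, end, strand="+"):
    return MotifHit(start, end, strand, "N" * (end - start + 1),
                    10.0, 1e-6, 1e-3)


class TestAnnotation:
    def test_spanning_hit_overlapping_core(self):
        genes = pd.DataFrame([
            {"gene_id": "gA", "strand": "+", "tss": 1000,
             "operon_id": "op1", "operon_pos": "1/2"}])
        elements = pd.DataFrame([
            {"gene_id": "gA", "element_type": "plus1",
             "start": 1000, "end": 1000},
            {"gene_id": "gA", "element_type": "minus10",
             "start": 988, "end": 993}])
        annos = annotate_hits([_hit(990, 1005)], genes, elements)
        (a,) = annos
        assert a.gene_id == "gA"
        assert a.loc <= 0
        assert a.promoter_class == "overlapping_core"
        assert a.proximal and a.candidate_regulated

    def test_upstream_and_downstream_classes(self):
        genes = pd.DataFrame([
            {"gene_id": "gA", "strand": "+", "tss": 1000,
             "operon_id": "op1", "operon_pos": "S"}])
        elements = pd.DataFrame([
            {"gene_id": "gA", "element_type": "minus35",
             "start": 960, "end": 965},
            {"gene_id": "gA", "element_type": "minus10",
             "start": 985, "end": 990}])
        up = annotate_hits([_hit(930, 945)], genes, elements)[0]
        assert up.promoter_class == "upstream_of_minus35"
        down = annotate_hits([_hit(992, 999)], genes, elements)[0]
        assert down.promoter_class == "downstream_of_minus10"

    def test_far_hit_annotated_as_orphan(self):
        genes = pd.DataFrame([
            {"gene_id": "gA", "strand": "+", "tss": 10_000,
             "operon_id": "op1", "operon_pos": "S"}])
        (a,) = annotate_hits([_hit(4990, 5005)], genes)
        assert a.gene_id is None and not a.proximal

    def test_bidirectional_site_annotated_per_gene(self):
        # a site between divergent genes yields one annotation per
        # flanking gene, with reading-direction-signed locations
        genes = pd.DataFrame([
            {"gene_id": "fwd", "strand": "+", "tss": 1060,
             "operon_id": "a", "operon_pos": "1/3"},
            {"gene_id": "rev", "strand": "-", "tss": 960,
             "operon_id": "b", "operon_pos": "S"}])
        annos = annotate_hits([_hit(1000, 1015)], genes)
        by_gene = {a.gene_id: a for a in annos}
        assert set(by_gene) == {"fwd", "rev"}
        assert by_gene["fwd"].loc == 1015 - 1060      # upstream, negative
        assert by_gene["rev"].loc == 960 - 1000       # upstream, negative

    def test_minus_strand_loc_signs(self):
        genes = pd.DataFrame([
            {"gene_id": "rev", "strand": "-", "tss": 500,
             "operon_id": "a", "operon_pos": "S"}])
        assert annotate_hits([_hit(520, 535)], genes)[0].loc == -20
        assert annotate_hits([_hit(460, 475)], genes)[0].loc == 25

    def test_tss_relative_location_plus_one(self):
        # a site starting 1 bp downstream of the TSS reports +1
        assert tss_relative_location(81408, 81423, 81407, "+") == 1


class TestProximalWindow:
    def test_reference_site_table_filter(self):
        """Of the 25 genome-mapped site annotations, exactly 16 fall in
        the activator-typical −200..+20 window, and each of those lies
        upstream of a first-of-operon or single-unit gene."""
        sites = genome_sites()
        kept = sites[sites["loc"].apply(
            lambda x: -200 <= x <= 20)]
        assert len(kept) == 16
        assert len(proximal_filter(sites["loc"].tolist())) == 16
        from tfdissect.scan import is_first_or_single
        assert all(is_first_or_single(op) for op in kept["operon_pos"])

    def test_paired_bidirectional_rows_are_revcomps(self):
        # one genomic locus serves two divergent genes: the two listed
        # site sequences are reverse complements of each other
        sites = genome_sites()
        dup = sites[sites.duplicated("start", keep=False)]
        for _, grp in dup.groupby("start"):
            a, b = grp["sequence"].tolist()
            assert revcomp(a) == b
            spans = (grp["end"] - grp["start"] + 1).unique()
            assert list(spans) == [16]
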
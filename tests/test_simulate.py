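"""Synthetic-data generators: selection dynamics, sensorgram closed
forms, genome construction, expression matrices."""

import numpy as np
import pandas as pd
import pytest

from tfdissect.pwm import revcomp
from tfdissect.simulate import (ExpressionSimSpec, RepsaRoundConfig,
                                SelectionLibraryConfig,
                                SyntheticGenomeSpec,
                                build_synthetic_genome,
                                simulate_expression, simulate_selection,
                                simulate_sensorgram)
from .conftest import pwm_from_consensus

# a short palindromic motif: desk-scale random pools (thousands of
# molecules, not billions) must contain genuine sites for selection
# dynamics to act on, which a 16-mer cannot provide at this pool size
MOTIF = pwm_from_consensus("TGTACA", weight=8)


def small_lib(seed=0, n=2000):
    return SelectionLibraryConfig(pool_size=n, seed=seed)


class TestSelection:
    def test_no_cleavage_no_selection_pressure(self):
        cfg = RepsaRoundConfig(cleavage_efficiency={"A": 0.0, "B": 0.0},
                               rounds=("A", "B", "A"))
        res = simulate_selection(small_lib(), cfg, MOTIF)
        f = res.motif_bearing_fraction
        # survival probability is 1 for everyone: only resampling noise
        assert max(f) - min(f) < 0.02

    def test_no_protein_full_cleavage_extinction(self):
        cfg = RepsaRoundConfig(protein_concentration=0.0,
                               cleavage_efficiency={"A": 1.0, "B": 1.0},
                               resistant_fraction=0.0, rounds=("A",))
        with pytest.raises(RuntimeError, match="round 1"):
            simulate_selection(small_lib(), cfg, MOTIF)

    def test_enrichment_monotone_over_seeds(self):
        """With protein and cleavage pressure and no resistant
        contaminants, the expected motif-bearing fraction is
        non-decreasing per round (averaged over 5 seeds)."""
        cfg = RepsaRoundConfig(rounds=("A",) * 5)
        trajs = []
        for seed in range(5):
            res = simulate_selection(small_lib(seed, 3000), cfg, MOTIF)
            trajs.append(res.motif_bearing_fraction)
        mean = np.mean(trajs, axis=0)
        assert np.all(np.diff(mean) >= -0.005)
        assert mean[-1] > mean[0]

    def test_enzyme_switch_purges_resistant_contaminants(self):
        """Cleavage-resistant molecules sweep the pool under enzyme A
        and collapse once rounds switch to enzyme B; motif enrichment
        then proceeds (the pattern that motivates switching enzymes)."""
        cfg = RepsaRoundConfig(resistant_fraction=0.001,
                               cleavage_efficiency={"A": 0.95, "B": 0.8},
                               rounds=("A", "A", "A", "A", "B", "B", "B"))
        res = simulate_selection(small_lib(1, 4000), cfg, MOTIF)
        rf = res.resistant_fraction
        assert rf[4] > 20 * rf[0]         # contaminant expands under A
        assert rf[7] < 0.1 * rf[4]        # collapses after switch to B
        f = res.motif_bearing_fraction
        assert f[-1] > f[0]

    def test_deterministic_under_seed(self):
        cfg = RepsaRoundConfig(rounds=("A", "B"))
        a = simulate_selection(small_lib(3), cfg, MOTIF)
        b = simulate_selection(small_lib(3), cfg, MOTIF)
        assert a.motif_bearing_fraction == b.motif_bearing_fraction
        assert a.reads[-1] == b.reads[-1]

    def test_motif_wider_than_cassette_rejected(self):
        wide = pwm_from_consensus("A" * 30)
        with pytest.raises(ValueError, match="cassette"):
            simulate_selection(small_lib(), RepsaRoundConfig(), wide)


class TestSensorgram:
    KON, KOFF = 131308.0, 2.907e-4

    def test_half_saturation_plateau(self):
        kd = self.KOFF / self.KON
        frames = simulate_sensorgram(self.KON, self.KOFF, rmax=2.0,
                                     concentrations=[kd],
                                     t_assoc=2e5, noise_sd=0.0)
        assoc = frames[0][frames[0]["phase"] == "association"]
        assert assoc["response"].iloc[-1] == pytest.approx(
            1.0, rel=1e-6)   # Rmax/2 at C = KD

    def test_closed_form_association_and_dissociation(self):
        frames = simulate_sensorgram(self.KON, self.KOFF, 1.0,
                                     [450e-9], t_assoc=300, t_dissoc=200,
                                     dt=1.0, noise_sd=0.0)
        df = frames[0]
        kobs = self.KON * 450e-9 + self.KOFF
        assert kobs == pytest.approx(5.938e-2, rel=1e-3)
        kd = self.KOFF / self.KON
        r_eq = 450e-9 / (450e-9 + kd)
        assoc = df[df["phase"] == "association"]
        expected = r_eq * (1 - np.exp(-kobs * assoc["time_s"]))
        np.testing.assert_allclose(assoc["response"], expected,
                                   atol=1e-10)
        dis = df[df["phase"] == "dissociation"]
        r_end = r_eq * (1 - np.exp(-kobs * 300.0))
        np.testing.assert_allclose(
            dis["response"],
            r_end * np.exp(-self.KOFF * (dis["time_s"] - 300.0)),
            atol=1e-10)

    def test_seeded_noise_bit_identical(self):
        a = simulate_sensorgram(self.KON, self.KOFF, 1.0, [50e-9],
                                noise_sd=0.05, seed=9)
        b = simulate_sensorgram(self.KON, self.KOFF, 1.0, [50e-9],
                                noise_sd=0.05, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_sensorgram(1e5, 1e-3, 1.0, [1e-9], dt=0.0)
        with pytest.raises(ValueError):
            simulate_sensorgram(1e5, 1e-3, 1.0, [1e-9, 1e-9])


class TestGenome:
    def test_planted_site_written_at_coordinate(self):
        site = "TGTATTCTAGAATACA"
        genome, _, _ = build_synthetic_genome(SyntheticGenomeSpec(
            length=2000, planted_sites=((site, 1001, "+"),), seed=0))
        assert genome[1000:1016] == site

    def test_minus_strand_palindrome_identical_forward_text(self):
        site = "TGTATTCTAGAATACA"
        assert revcomp(site) == site
        genome, _, _ = build_synthetic_genome(SyntheticGenomeSpec(
            length=2000, planted_sites=((site, 501, "-"),), seed=0))
        assert genome[500:516] == site

    def test_collision_and_bounds_errors(self):
        with pytest.raises(ValueError, match="overlapping"):
            build_synthetic_genome(SyntheticGenomeSpec(
                length=100, planted_sites=(("ACGTACGT", 10, "+"),
                                           ("ACGTACGT", 12, "+"))))
        with pytest.raises(ValueError, match="fit"):
            SyntheticGenomeSpec(length=10,
                                planted_sites=(("ACGTACGT", 8, "+"),))

    def test_annotation_tables_roundtrip_loc_labels(self, consensus):
        """Planting sites at stated TSS offsets and annotating the scan
        output reproduces the planted location labels."""
        from tfdissect.scan import annotate_hits, scan_genome
        pwm = pwm_from_consensus(consensus)
        offsets = [-150, -48, -26, 13]
        planted, genes = [], []
        pos = 3000
        for i, off in enumerate(offsets):
            tss = pos - off + (16 - 1 if off <= 0 else 0)
            # for + strand gene: loc = end - tss if upstream else start - tss
            start = tss + off - 15 if off <= 0 else tss + off
            planted.append((consensus, start, "+"))
            genes.append((f"g{i}", "+", tss, f"op{i}", "S"))
            pos += 3000
        genome, gene_df, _ = build_synthetic_genome(SyntheticGenomeSpec(
            length=16000, planted_sites=tuple(planted),
            gene_models=tuple(genes), seed=2))
        hits = scan_genome(pwm, genome, p_threshold=1e-5)
        annos = annotate_hits(hits, gene_df)
        got = sorted((a.gene_id, a.loc) for a in annos
                     if a.gene_id is not None)
        want = sorted((f"g{i}", off) for i, off in enumerate(offsets))
        assert got == want


class TestExpression:
    def test_null_logfc_centred_on_zero(self):
        est = []
        for seed in range(10):
            m = simulate_expression(ExpressionSimSpec(
                n_genes=50, noise_sd=0.3, seed=seed))
            groups = m.columns.get_level_values("group")
            est.append((m.loc[:, groups == "test"].mean(axis=1)
                        - m.loc[:, groups == "control"].mean(axis=1))
                       .mean())
        assert abs(np.mean(est)) < 0.05

    def test_planted_effect_recovered(self):
        m = simulate_expression(ExpressionSimSpec(
            n_genes=20, planted_logfc={"gene0003": 2.62},
            noise_sd=0.2, seed=5))
        groups = m.columns.get_level_values("group")
        lfc = (m.loc["gene0003", groups == "test"].mean()
               - m.loc["gene0003", groups == "control"].mean())
        se = 0.2 * np.sqrt(2 / 3)
        assert abs(lfc - 2.62) < 3 * se

    def test_seeded_reproducible_and_validation(self):
        a = simulate_expression(ExpressionSimSpec(seed=1))
        b = simulate_expression(ExpressionSimSpec(seed=1))
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            ExpressionSimSpec(samples_per_group=1)
        with pytest.raises(ValueError):
            ExpressionSimSpec(noise_sd=0.0)
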
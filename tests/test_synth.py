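import json

import numpy as np
import pytest

import germdiv as gd
from germdiv.synth import PANEL_LOCI, PANEL_POPULATIONS, QualTrait, QuantTrait


class TestGenPhenotypes:
    def test_stem_height_moments_match_target(self):
        cfg = gd.SynthesisConfig(
            n_accessions=1582,
            quant_traits=[QuantTrait("SH", 129.57, 26.03, "cm")],
            seed=1,
        )
        tm = gd.gen_phenotypes(cfg)
        (s,) = gd.trait_summaries(tm)
        assert s.mean == pytest.approx(129.57, abs=2.0)
        assert s.cv_percent == pytest.approx(100 * 26.03 / 129.57, abs=1.5)
        assert s.cv_percent == pytest.approx(20.09, abs=1.5)

    def test_qualitative_frequencies_within_binomial_bound(self):
        cfg = gd.SynthesisConfig(
            n_accessions=1582,
            qual_traits=[QualTrait("IC", (0.965, 0.035))],
            seed=3,
        )
        tm = gd.gen_phenotypes(cfg)
        freq = (tm.values[:, 0] == 1).mean()
        assert freq == pytest.approx(0.035, abs=0.02)

    def test_uncorrelated_traits_stay_uncorrelated(self):
        cfg = gd.SynthesisConfig(
            n_accessions=1582,
            quant_traits=[QuantTrait("x", 10, 2), QuantTrait("y", 5, 1)],
            correlation=np.eye(2),
            seed=5,
        )
        tm = gd.gen_phenotypes(cfg)
        r = np.corrcoef(tm.values[:, 0], tm.values[:, 1])[0, 1]
        assert abs(r) < 2.58 / np.sqrt(1582)

    def test_target_correlations_realized(self):
        cfg = gd.default_config(seed=2)
        tm = gd.gen_phenotypes(cfg)
        names = [t.name for t in cfg.quant_traits]
        X = tm.values[:, : len(names)]
        r = np.corrcoef(X.T)
        i, j = names.index("PWP"), names.index("GWP")
        assert r[i, j] == pytest.approx(0.91, abs=0.05)

    def test_nonneg_flag_clips_at_zero(self):
        cfg = gd.SynthesisConfig(
            n_accessions=500,
            quant_traits=[QuantTrait("w", 1.0, 5.0, nonneg=True)],
            seed=0,
        )
        tm = gd.gen_phenotypes(cfg)
        assert tm.values.min() >= 0.0

    def test_non_psd_correlation_rejected(self):
        C = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            gd.SynthesisConfig(
                quant_traits=[QuantTrait("a", 1, 1)] * 3, correlation=C
            )


class TestBaldingNichols:
    def test_draw_moments(self):
        # population frequencies have mean p and variance F p (1-p)
        rng = np.random.default_rng(77)
        p, F, n = 0.6, 0.15, 10_000
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        draws = rng.beta(a, b, size=n)
        se_mean = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - p) < 3 * se_mean
        target_var = F * p * (1 - p)
        # sd of the sample variance ~ var * sqrt(2/(n-1)) for near-normal
        assert abs(draws.var(ddof=1) - target_var) < 5 * target_var * np.sqrt(2 / n)

    def test_no_divergence_limit(self):
        # with F_div -> 0 the true population frequencies coincide, so the
        # between-population Nei distance of the generating truth vanishes
        cfg = gd.default_config(seed=4)
        cfg.f_div = 1e-4
        gm, _, P = gd.gen_structured_genotypes(cfg)
        loci = gm.locus_names
        pops = gm.population_names
        dmax = 0.0
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                fx = {l: np.array([P[m, i], 1 - P[m, i]]) for m, l in enumerate(loci)}
                fy = {l: np.array([P[m, j], 1 - P[m, j]]) for m, l in enumerate(loci)}
                _, d = gd.nei_identity_distance(fx, fy)
                dmax = max(dmax, d)
        assert dmax < 0.005

    def test_full_inbreeding_removes_heterozygotes(self):
        cfg = gd.default_config(seed=6)
        cfg.f_is = 1.0
        gm, _, _ = gd.gen_structured_genotypes(cfg)
        assert (gm.calls == "AB").sum() == 0

    def test_distance_grows_with_divergence(self):
        means = []
        for f_div in (0.01, 0.05, 0.15, 0.3):
            vals = []
            for seed in (0, 1, 2):
                cfg = gd.default_config(seed=seed)
                cfg.f_div = f_div
                gm, _, _ = gd.gen_structured_genotypes(cfg)
                _, _, dist = gd.nei_identity_matrix(gm)
                vals.append(dist[np.triu_indices(6, 1)].mean())
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestStructuredGenotypes:
    def test_panel_shape_and_populations(self, panel_genotypes):
        assert panel_genotypes.n_accessions == 147
        assert panel_genotypes.locus_names == PANEL_LOCI
        sizes = {
            p: sum(1 for a in panel_genotypes.accession_ids
                   if panel_genotypes.populations[a] == p)
            for p in panel_genotypes.population_names
        }
        assert sizes == PANEL_POPULATIONS

    def test_locus_diversities_span_published_range(self, panel_genotypes):
        df = gd.locus_table(panel_genotypes)
        nei = df[~df.Primer.isin(["Mean", "St.Dev"])]["Nei"].astype(float)
        assert nei.min() <= 0.05
        assert nei.max() >= 0.45

    def test_truth_matrices_are_consistent(self, panel_genotypes):
        gm, Q, P = gd.gen_structured_genotypes(gd.default_config(seed=7))
        assert Q.shape == (147, 6)
        np.testing.assert_allclose(Q.sum(axis=1), 1.0)
        assert P.shape == (15, 6)
        assert (P > 0).all() and (P < 1).all()

    def test_admixture_recovery_closed_loop(self):
        # one-hot ancestry, strong divergence: EM at the true K recovers
        # the generating populations after label matching
        cfg = gd.SynthesisConfig(
            n_loci=50,
            locus_names=[f"L{j}" for j in range(50)],
            population_sizes={"A": 40, "B": 40},
            f_div=0.3,
            f_is=0.0,
            seed=10,
        )
        gm, Q_true, _ = gd.gen_structured_genotypes(cfg)
        fit = gd.em_admixture(gm, k=2, seed=1)
        matched = gd.match_columns(Q_true, fit.q)
        agree = (matched.argmax(axis=1) == Q_true.argmax(axis=1)).mean()
        assert agree > 0.95


class TestFixtureSuite:
    def test_same_seed_is_byte_identical(self, tmp_path):
        m1 = gd.gen_fixture_suite(3, tmp_path / "a")
        m2 = gd.gen_fixture_suite(3, tmp_path / "b")
        assert m1 == m2
        for name in m1:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert manifest == m1

    def test_different_seeds_differ(self, tmp_path):
        assert gd.gen_fixture_suite(3, tmp_path / "a") != gd.gen_fixture_suite(
            4, tmp_path / "b"
        )

    def test_bundle_loads_through_io_without_warnings(self, tmp_path, recwarn):
        gd.gen_fixture_suite(5, tmp_path)
        import pandas as pd

        schema_df = pd.read_csv(tmp_path / "schema.csv")
        schema = dict(zip(schema_df.trait, schema_df.kind))
        tm = gd.read_trait_matrix(tmp_path / "traits.csv", schema)
        assert tm.n_accessions == 1582 and len(tm.trait_names) == 22
        pops_df = pd.read_csv(tmp_path / "populations.csv")
        pops = dict(zip(pops_df.accession, pops_df.population))
        gm = gd.read_genotype_matrix(tmp_path / "genotypes.csv", pops)
        assert gm.n_accessions == 147
        bm = gd.read_band_matrix(tmp_path / "bands.csv")
        assert bm.n_accessions == 147 and len(bm.primer_names) == 15
        screen = gd.read_trait_matrix(tmp_path / "screening_panel.csv", schema)
        assert screen.n_accessions == 20
        assert len(recwarn) == 0

    def test_fingerprints_mostly_distinct_under_generic_diversity(self):
        # with ancestral frequencies ~ U(0.1, 0.9) the 12-primer codes are
        # nearly unique; the published-diversity calibration (11 of 15 loci
        # close to fixation) necessarily produces many multilocus
        # collisions under independent sampling, so distinctness is
        # asserted for the generic configuration
        cfg = gd.SynthesisConfig(seed=0)
        gm, _, _ = gd.gen_structured_genotypes(cfg)
        codes = {c.code for c in gd.encode_fingerprint(gd.genotype_to_band(gm))}
        assert len(codes) >= 0.95 * gm.n_accessions

    def test_default_fixture_codes_are_valid_and_deterministic(self, tmp_path):
        gd.gen_fixture_suite(8, tmp_path / "a")
        gd.gen_fixture_suite(8, tmp_path / "b")
        c1 = [c.code for c in gd.encode_fingerprint(gd.read_band_matrix(tmp_path / "a" / "bands.csv"))]
        c2 = [c.code for c in gd.encode_fingerprint(gd.read_band_matrix(tmp_path / "b" / "bands.csv"))]
        assert c1 == c2
        assert all(len(c) == 24 and set(c) <= {"0", "1"} for c in c1)
        assert len(set(c1)) > 1
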
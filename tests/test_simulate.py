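"""Tetrasomic meiosis, founder LD, trait generation, dataset round-trips."""

import numpy as np
import pytest
from scipy import stats

from tetrapanel import io as tio
from tetrapanel import ldprune as lp
from tetrapanel import phenotypes as ph
from tetrapanel.simulate import (
    GeneticMap,
    PhasedTetraploid,
    SimConfig,
    _recombinant_chromatid,
    make_genetic_map,
    meiosis_gamete,
    simulate_dataset,
    simulate_family,
    simulate_founders,
    simulate_population,
    simulate_traits,
    write_dataset,
    read_config,
)


def _single_chrom_map(n_loci=100, morgans=1.0):
    cfg = SimConfig(n_chrom=1, unanchored_groups=(), loci_per_chrom=n_loci,
                    map_length_morgans=morgans)
    return cfg, make_genetic_map(cfg, np.random.default_rng(0))


def _uniform_parent(gmap, value):
    homologs = {c: np.full((4, len(gmap.genetic_pos[c])), value,
                           dtype=np.int8)
                for c in gmap.chrom_order}
    return PhasedTetraploid(homologs)


class TestFounders:
    def test_zero_alt_freq_gives_zero_dosage(self):
        cfg = SimConfig(n_chrom=2, unanchored_groups=(), loci_per_chrom=50,
                        founder_alt_freq=(0.0, 0.0))
        gmap = make_genetic_map(cfg, np.random.default_rng(1))
        founders = simulate_founders(cfg, gmap, np.random.default_rng(1), 3)
        for f in founders:
            assert f.dosages(gmap.chrom_order).sum() == 0

    def test_mean_dosage_matches_alt_freq(self):
        cfg = SimConfig(n_chrom=1, unanchored_groups=(),
                        loci_per_chrom=10_000,
                        founder_alt_freq=(0.5, 0.5),
                        founder_switch_prob=1.0)   # iid loci
        gmap = make_genetic_map(cfg, np.random.default_rng(2))
        f = simulate_founders(cfg, gmap, np.random.default_rng(2), 1)[0]
        assert f.dosages(gmap.chrom_order).mean() == pytest.approx(2.0,
                                                                   abs=0.05)

    def test_seed_determinism(self):
        cfg = SimConfig(seed=99, loci_per_chrom=30, offspring_per_family=3)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        np.testing.assert_array_equal(a.genotypes.dosages,
                                      b.genotypes.dosages)
        assert a.phenotypes.equals(b.phenotypes)


class TestMeiosis:
    def test_homozygous_parent_transmits_identically(self):
        _, gmap = _single_chrom_map()
        parent = _uniform_parent(gmap, 1)
        gam = meiosis_gamete(parent, gmap, np.random.default_rng(3))
        chrom = gmap.chrom_order[0]
        np.testing.assert_array_equal(gam[chrom],
                                      np.ones_like(gam[chrom]))

    def test_zero_map_length_means_no_recombination(self):
        cfg, gmap = _single_chrom_map(morgans=0.0)
        rng = np.random.default_rng(4)
        parent = simulate_founders(cfg, gmap, rng, 1)[0]
        chrom = gmap.chrom_order[0]
        homolog_set = {h.tobytes() for h in parent.homologs[chrom]}
        for _ in range(10):
            gam = meiosis_gamete(parent, gmap, rng)
            for chromatid in gam[chrom]:
                assert chromatid.tobytes() in homolog_set

    def test_recombinant_fraction_follows_haldane(self):
        # loci 0.5 Morgans apart on a 1-Morgan chromosome: expected
        # recombinant fraction r = (1 - e^-1)/2 ~ 0.316
        rng = np.random.default_rng(5)
        gpos = np.array([0.25, 0.75])
        ha = np.array([0, 0], dtype=np.int8)
        hb = np.array([1, 1], dtype=np.int8)
        n = 10_000
        rec = 0
        for _ in range(n):
            c = _recombinant_chromatid(ha, hb, gpos, rng)
            rec += c[0] != c[1]
        expected = 0.5 * (1 - np.exp(-2 * 0.5))
        assert rec / n == pytest.approx(expected, abs=0.02)

    def test_quadruplex_by_nulliplex_gives_all_duplex(self):
        _, gmap = _single_chrom_map(n_loci=50)
        p1 = _uniform_parent(gmap, 1)   # AAAA at every locus (dosage 4)
        p2 = _uniform_parent(gmap, 0)   # aaaa (dosage 0)
        rng = np.random.default_rng(6)
        kids = simulate_family(p1, p2, 30, gmap, rng)
        for kid in kids:
            assert (kid.dosages(gmap.chrom_order) == 2.0).all()

    def test_offspring_mean_near_midparent(self):
        cfg, gmap = _single_chrom_map(n_loci=60)
        rng = np.random.default_rng(7)
        p1, p2 = simulate_founders(cfg, gmap, rng, 2)
        kids = simulate_family(p1, p2, 2000, gmap, rng)
        chrom = gmap.chrom_order[0]
        mid = (p1.homologs[chrom].sum(0) + p2.homologs[chrom].sum(0)) / 2
        mean_dos = np.mean([k.dosages(gmap.chrom_order) for k in kids],
                           axis=0)
        assert np.abs(mean_dos - mid).max() < 0.15
        all_dos = np.concatenate(
            [k.dosages(gmap.chrom_order) for k in kids])
        assert all_dos.min() >= 0 and all_dos.max() <= 4

    def test_simplex_by_nulliplex_segregates_one_to_one(self):
        # a single simplex (Aaaa) locus crossed to nulliplex gives
        # offspring dosages {0, 1} in a 1:1 ratio under bivalent pairing
        _, gmap = _single_chrom_map(n_loci=1, morgans=0.0)
        chrom = gmap.chrom_order[0]
        p1 = PhasedTetraploid({chrom: np.array([[1], [0], [0], [0]],
                                               dtype=np.int8)})
        p2 = _uniform_parent(gmap, 0)
        rng = np.random.default_rng(8)
        kids = simulate_family(p1, p2, 2000, gmap, rng)
        dosages = np.array([k.dosages(gmap.chrom_order)[0] for k in kids])
        assert set(np.unique(dosages)) <= {0.0, 1.0}
        n1 = (dosages == 1).sum()
        p = stats.binomtest(int(n1), 2000, 0.5).pvalue
        assert p > 0.001


class TestLdStructure:
    def test_ld_decays_with_genetic_distance(self, study_sim):
        g = study_sim.genotypes
        mm = study_sim.marker_map
        chrom1 = mm[mm["chrom"] == "1"]["marker"].tolist()
        sub = g.subset_markers(chrom1)
        dip = tio.diploidize(sub)
        R = lp.r2_matrix(dip.dosages)
        pos = mm.set_index("marker").loc[chrom1, "pos_bp"].to_numpy()
        cfg = study_sim.config
        cm = pos / cfg.chrom_length_bp * cfg.map_length_morgans * 100
        dist = np.abs(cm[:, None] - cm[None, :])
        iu = np.triu_indices(len(chrom1), k=1)
        bins = [(0, 5), (5, 20), (20, np.inf)]
        means = []
        for lo, hi in bins:
            sel = (dist[iu] >= lo) & (dist[iu] < hi)
            means.append(R[iu][sel].mean())
        assert means[0] > means[1] > means[2]


class TestTraits:
    @pytest.fixture(scope="class")
    def field_scale(self):
        """Study-scale field population: ~1880 offspring for trait checks."""
        cfg = SimConfig(seed=21, offspring_per_family=235,
                        loci_per_chrom=40, loci_per_unanchored=8,
                        missing_rate=0.0, frac_high_missing=0.0)
        genotypes, gmap, metadata, _ = simulate_population(cfg)
        phenos, truth = simulate_traits(genotypes, metadata, cfg)
        return cfg, phenos, truth

    def test_negative_yield_resistance_correlation(self, field_scale):
        cfg, phenos, _ = field_scale
        r, p = ph.trait_correlation(phenos["audpc"],
                                    phenos["tuber_number"])
        assert r == pytest.approx(cfg.trait_correlation, abs=0.1)
        assert p < 0.001

    def test_audpc_from_progress_curves(self, field_scale):
        _, phenos, truth = field_scale
        sev = truth["severity_curves"]
        dates = truth["score_dates"]
        recomputed = np.array([ph.audpc(dates, sev[i])
                               for i in range(sev.shape[0])])
        np.testing.assert_allclose(phenos["audpc"], recomputed, atol=0.01)

    def test_high_heritability_tracks_genetic_value(self):
        cfg = SimConfig(seed=22, offspring_per_family=60,
                        loci_per_chrom=40, loci_per_unanchored=8,
                        family_variance_share=0.0, missing_rate=0.0,
                        frac_high_missing=0.0)
        cfg.h2["tuber_weight_avg"] = 0.99
        genotypes, gmap, metadata, _ = simulate_population(cfg)
        phenos, truth = simulate_traits(genotypes, metadata, cfg)
        r = np.corrcoef(phenos["tuber_weight_avg"],
                        truth["true_gebv"]["tuber_weight_avg"])[0, 1]
        assert r > 0.95

    def test_zero_qtl_effects_icc_equals_family_share(self):
        cfg = SimConfig(seed=23, offspring_per_family=100,
                        loci_per_chrom=30, loci_per_unanchored=5,
                        qtl_effect_scale=0.0, missing_rate=0.0,
                        frac_high_missing=0.0)
        genotypes, gmap, metadata, _ = simulate_population(cfg)
        phenos, _ = simulate_traits(genotypes, metadata, cfg)
        offspring = phenos["family"] != "ancestor"
        got = ph.icc(phenos.loc[offspring, "tuber_weight_avg"],
                     phenos.loc[offspring, "family"])
        assert got == pytest.approx(cfg.family_variance_share, abs=0.12)


class TestDataset:
    def test_write_read_roundtrip(self, small_sim, tmp_path):
        paths = write_dataset(small_sim, tmp_path / "data")
        g = tio.read_genotypes(paths["genotypes"])
        np.testing.assert_array_equal(g.dosages, small_sim.genotypes.dosages)
        assert g.sample_ids == small_sim.genotypes.sample_ids
        mm = tio.read_marker_map(paths["marker_map"])
        assert mm.equals(small_sim.marker_map)
        ident = tio.read_identity_table(paths["identity"])
        assert len(ident) == len(small_sim.identity)
        cfg = read_config(paths["config"])
        assert cfg == small_sim.config

    def test_truth_qtl_count_matches_config(self, small_sim):
        qtl = small_sim.truth["qtl"]
        n = small_sim.config.n_qtl
        assert (qtl["trait"] == "susceptibility").sum() == n
        # tuber number carries its own QTL plus the shared opposite-signed
        # susceptibility QTL
        assert (qtl["trait"] == "tuber_number").sum() == 2 * n

    def test_same_seed_identical_files(self, tmp_path):
        cfg = SimConfig(seed=31, offspring_per_family=3, loci_per_chrom=20,
                        loci_per_unanchored=4)
        p1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
        p2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
        for key in p1:
            with open(p1[key]) as f1, open(p2[key]) as f2:
                assert f1.read() == f2.read(), key

    def test_unreasonable_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(h2={"tuber_number": 1.5})
        with pytest.raises(NotImplementedError):
            SimConfig(double_reduction_rate=0.1)

    def test_unanchored_groups_present(self, study_sim):
        chroms = set(study_sim.marker_map["chrom"])
        assert {"00", "UN"} <= chroms
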
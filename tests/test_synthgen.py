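"""Landscape generation, sampling design and genotype simulation."""

import numpy as np
import pytest
from scipy.ndimage import label

from ibrscape.genotypes import MISSING, read_vcf
from ibrscape.raster import read_ascii_grid
from ibrscape.resistance import categorical_surface, commute_distance
from ibrscape.synthgen import (CLASS_CODES, make_landscape, sample_locations,
                               simulate_genotypes, write_fixtures)

SCHED = {1979: 0, 2011: 120, 2014: 200, 2016: 300}


def hudson_fst(X, labels):
    """Independent Hudson-style two-population F_ST estimator."""
    nums, dens = [], []
    for i in range(X.shape[1]):
        x1 = X[labels == 0, i]
        x2 = X[labels == 1, i]
        x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
        n1, n2 = 2 * len(x1), 2 * len(x2)
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = x1.sum() / n1, x2.sum() / n2
        nums.append((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
                    - p2 * (1 - p2) / (n2 - 1))
        dens.append(p1 * (1 - p2) + p2 * (1 - p1))
    return float(np.sum(nums) / np.sum(dens))


def mantel_pvalue(A, D, n_perm=499, seed=0):
    """Permutation Mantel test of the Spearman matrix correlation."""
    from scipy.stats import spearmanr
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    obs = spearmanr(A[iu], D[iu]).statistic
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = spearmanr(A[np.ix_(perm, perm)][iu], D[iu]).statistic
    p = (1 + np.sum(null <= obs)) / (n_perm + 1)  # one-sided: negative corr
    return obs, p


class TestLandscape:
    def test_mine_counts_match_schedule(self):
        truth = make_landscape(grid_size=60, mine_growth_schedule=SCHED, seed=3)
        assert truth.mine_counts() == SCHED

    def test_premining_year_has_no_mine(self, landscape):
        pre = landscape.class_maps[min(landscape.years)]
        assert (pre.data == CLASS_CODES["mine"]).sum() == 0

    def test_deterministic(self):
        a = make_landscape(grid_size=40, mine_growth_schedule=SCHED, seed=9)
        b = make_landscape(grid_size=40, mine_growth_schedule=SCHED, seed=9)
        for y in a.years:
            assert np.array_equal(a.class_maps[y].data, b.class_maps[y].data)
        for nm in a.climate_fields:
            assert np.array_equal(a.climate_fields[nm].data,
                                  b.climate_fields[nm].data)

    def test_three_classes_partition_grid(self, landscape):
        for grid in landscape.class_maps.values():
            assert set(np.unique(grid.data)) <= set(CLASS_CODES.values())

    def test_mine_is_nondecreasing_and_never_fragments(self, landscape):
        counts = [landscape.mine_counts()[y] for y in landscape.years]
        assert counts == sorted(counts)
        for grid in landscape.class_maps.values():
            _, ncomp = label(grid.data == CLASS_CODES["canga"])
            assert ncomp == 1

    def test_excessive_growth_target_names_year(self):
        with pytest.raises(ValueError, match="2016"):
            make_landscape(grid_size=20,
                           mine_growth_schedule={1979: 0, 2016: 10_000})

    def test_climate_fields_distinct(self, landscape):
        fields = list(landscape.climate_fields.values())
        for i in range(len(fields)):
            for j in range(i + 1, len(fields)):
                r = np.corrcoef(fields[i].data.ravel(),
                                fields[j].data.ravel())[0, 1]
                assert abs(r) < 0.8


class TestSampling:
    def test_contract(self, landscape, samples):
        assert samples.n == 30
        d = np.sqrt(((samples.coords[:, None] - samples.coords[None]) ** 2
                     ).sum(-1))
        iu = np.triu_indices(30, 1)
        assert d[iu].min() >= 2.0
        latest = landscape.latest_map
        for x, y in samples.coords:
            r, c = latest.index_of(x, y)
            assert latest.data[r, c] == CLASS_CODES["canga"]

    def test_infeasible_raises(self, landscape):
        with pytest.raises(ValueError):
            sample_locations(landscape, n=10_000, min_dist=0.0, seed=0)

    def test_seed_reproducible(self, landscape):
        a = sample_locations(landscape, n=10, min_dist=2.0, seed=4)
        b = sample_locations(landscape, n=10, min_dist=2.0, seed=4)
        assert np.array_equal(a.coords, b.coords)


class TestGenotypes:
    def test_target_fst_realized(self, samples):
        truth = make_landscape(grid_size=40, mine_growth_schedule=SCHED,
                               seed=5, cluster_params={"K": 2, "fst": 0.10},
                               gp_params={"sigma2": 0.0})
        geno, record = simulate_genotypes(truth, samples, n_loci=2000, seed=11)
        fst = hudson_fst(geno.dosages_float(), record["ancestry"].argmax(1))
        assert fst == pytest.approx(0.10, rel=0.20)

    def test_fst_monotone_in_target(self, samples):
        realized = []
        for target in (0.02, 0.1, 0.3):
            truth = make_landscape(grid_size=40, mine_growth_schedule=SCHED,
                                   seed=5,
                                   cluster_params={"K": 2, "fst": target},
                                   gp_params={"sigma2": 0.0})
            geno, record = simulate_genotypes(truth, samples, n_loci=2000,
                                              seed=13)
            realized.append(hudson_fst(geno.dosages_float(),
                                       record["ancestry"].argmax(1)))
        assert realized == sorted(realized)

    def test_panmictic_relatedness_at_centering_expectation(self,
                                                            unstructured_geno):
        # sample-estimated allele frequencies force the mean off-diagonal to
        # -1/(n-1) exactly in expectation; no relatedness beyond that
        from ibrscape.relatedness import yang_relatedness
        geno, _ = unstructured_geno
        rel = yang_relatedness(geno)
        off = rel.offdiag()
        n = rel.n
        se = off.std() / np.sqrt(len(off))
        assert abs(off.mean() - (-1.0 / (n - 1))) < 3 * max(se, 1e-3)

    def test_relatedness_decays_with_commute_distance(self, samples):
        # exponential decay range = quarter of the distance span
        truth = make_landscape(grid_size=40, mine_growth_schedule=SCHED,
                               seed=5, cluster_params={"K": 1},
                               gp_params={"sigma2": 1.0, "phi_frac": 0.25,
                                          "kernel": "exponential"})
        geno, record = simulate_genotypes(truth, samples, n_loci=800, seed=21)
        from ibrscape.relatedness import yang_relatedness
        rel = yang_relatedness(geno)
        rho, p = mantel_pvalue(rel.values, record["commute_distance"])
        assert rho < 0 and p < 0.01

    def test_determinism(self, landscape, samples):
        a, _ = simulate_genotypes(landscape, samples, n_loci=150, seed=8)
        b, _ = simulate_genotypes(landscape, samples, n_loci=150, seed=8)
        assert np.array_equal(a.dosages, b.dosages)

    def test_artifact_bookkeeping_matches_independent_check(self, samples):
        flat = make_landscape(grid_size=40, mine_growth_schedule=SCHED,
                              seed=5, cluster_params={"K": 1},
                              gp_params={"sigma2": 0.0})
        spec = {"missing": 6, "low_qual": 4, "bad_depth": 4, "rare": 4,
                "all_het": 2, "hwe": 3, "ld_dup": 3}
        geno, record = simulate_genotypes(flat, samples, n_loci=120,
                                          artifact_spec=spec, seed=17)
        planted = record["planted"]
        # independently recheck each planted rule
        miss = set(np.flatnonzero(geno.missing_rate() > 0.30))
        assert miss == set(planted["missing"])
        qual = set(np.flatnonzero(geno.loci["qual"].to_numpy() <= 50))
        assert qual == set(planted["low_qual"])
        d = geno.loci["mean_depth"].to_numpy()
        assert set(np.flatnonzero((d < 30) | (d > 240))) == set(planted["bad_depth"])
        p = geno.allele_freq()
        assert set(np.flatnonzero(np.minimum(p, 1 - p) < 0.03)) == set(planted["rare"])

    def test_artifact_overflow_rejected(self, landscape, samples):
        with pytest.raises(ValueError):
            simulate_genotypes(landscape, samples, n_loci=100,
                               artifact_spec={"missing": 200}, seed=0)


class TestFixtures:
    def test_round_trip(self, tmp_path, landscape, samples):
        geno, _ = simulate_genotypes(landscape, samples, n_loci=120, seed=8)
        manifest = write_fixtures(geno, samples, landscape, tmp_path)
        back = read_vcf(manifest["vcf"])
        assert np.array_equal(back.dosages, geno.dosages)
        assert back.sample_ids == list(geno.sample_ids)
        assert np.allclose(back.loci["qual"], geno.loci["qual"], rtol=1e-5)
        assert np.allclose(back.loci["mean_depth"], geno.loci["mean_depth"],
                           rtol=1e-5)
        assert (back.dosages == MISSING).sum() == (geno.dosages == MISSING).sum()

    def test_raster_round_trip(self, tmp_path, landscape, samples):
        geno, _ = simulate_genotypes(landscape, samples, n_loci=120, seed=8)
        manifest = write_fixtures(geno, samples, landscape, tmp_path)
        assert set(manifest["landcover"]) == {str(y) for y in landscape.years}
        for y in landscape.years:
            grid = read_ascii_grid(manifest["landcover"][str(y)])
            orig = landscape.class_maps[y]
            assert grid.shape == orig.shape
            assert grid.cell_size == orig.cell_size
            assert grid.xll == orig.xll and grid.yll == orig.yll
            assert np.array_equal(grid.data, orig.data)

    def test_simulation_distance_shares_resistance_module(self, landscape,
                                                          samples):
        # the recovery target is the optimizer, not a distance-code mismatch
        _, record = simulate_genotypes(landscape, samples, n_loci=120, seed=8)
        codes = {CLASS_CODES[k]: v for k, v in landscape.true_resistance.items()}
        surf = categorical_surface(landscape.latest_map, codes)
        d = commute_distance(surf, samples.coords)
        assert np.allclose(d.matrix, record["commute_distance"])
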
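"""Variant filtering, HWE exact test, LD pruning and IBS-MDS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betameth.genotype import (
    GenotypeMatrix,
    classical_mds,
    filter_variants,
    hwe_exact_test,
    ibs_distance,
    ibs_mds,
    ld_prune,
    read_vcf,
    write_vcf,
)
from betameth.synthetic import simulate_two_population_genotypes

from oracles import hwe_exact_oracle


def _gmat(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    m, n = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom or ["1"] * m,
            "pos": pos or list(range(1, m + 1)),
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"v{i + 1}" for i in range(m)], name="variant"),
    )
    return GenotypeMatrix(variants, dosages, [f"s{j + 1}" for j in range(n)])


# ---------------------------------------------------------------------- HWE


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(17, 0, 0) == 1.0

    def test_two_sample_case_is_one_third(self):
        # 2 ref + 2 alt alleles in 2 individuals: het in {0, 2} with
        # conditional probabilities 1/3 and 2/3; observing het=0 gives 1/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize(
        "counts",
        [(20, 10, 20), (5, 20, 5), (50, 21, 3), (0, 3, 7), (88, 10, 2), (33, 40, 27)],
    )
    def test_matches_rational_enumeration(self, counts):
        expected = float(hwe_exact_oracle(*counts))
        assert hwe_exact_test(*counts) == pytest.approx(expected, rel=1e-10)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(0, 70), st.integers(0, 60), st.integers(0, 70)
    )
    def test_symmetric_and_matches_oracle(self, a, h, b):
        if a + h + b == 0:
            with pytest.raises(ValueError):
                hwe_exact_test(a, h, b)
            return
        p = hwe_exact_test(a, h, b)
        assert p == pytest.approx(hwe_exact_test(b, h, a), rel=1e-12)
        assert p == pytest.approx(float(hwe_exact_oracle(a, h, b)), rel=1e-9)

    def test_counts_must_be_consistent(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


# ------------------------------------------------------------------ filters


class TestFilterVariants:
    def test_monomorphic_and_low_callrate_removed(self):
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.4, 100).astype(float)
        mono = np.zeros(100)
        missing = good.copy()
        missing[:3] = np.nan  # callrate 0.97 < 0.98
        g = _gmat([good, mono, missing])
        out, report = filter_variants(g)
        assert list(out.variants.index) == ["v1"]
        assert report.loc["v2", "fail_maf"]
        assert report.loc["v3", "fail_callrate"]

    def test_hwe_filter_follows_exact_test(self):
        # (20,10,20): strong heterozygote deficit
        d = np.r_[np.zeros(20), np.ones(10), np.full(20, 2.0)]
        g = _gmat([d])
        p = hwe_exact_test(20, 10, 20)
        _, report = filter_variants(g, callrate_min=0, maf_min=0)
        assert report.loc["v1", "fail_hwe"] == (not p > 1e-6)

    def test_empty_result_warns_not_raises(self):
        g = _gmat([np.zeros(10)])
        out, _ = filter_variants(g)
        assert out.n_variants == 0


# ----------------------------------------------------------------- pruning


def _brute_prune(dosages, mafs, window, step, r2_max):
    """Literal application of the stated sliding-window removal rule."""
    keep = list(range(len(dosages)))

    def r2(i, j):
        r = np.corrcoef(dosages[i], dosages[j])[0, 1]
        return r * r

    start = 0
    while True:
        win = [i for i in range(start, min(start + window, len(dosages)))]
        removed = True
        while removed:
            removed = False
            active = [i for i in win if i in keep]
            for ai in range(len(active)):
                for bi in range(ai + 1, len(active)):
                    i, j = active[ai], active[bi]
                    if r2(i, j) > r2_max:
                        keep.remove(i if mafs[i] < mafs[j] else j)
                        removed = True
                        break
                if removed:
                    break
        if start + window >= len(dosages):
            break
        start += step
    return keep


class TestLdPrune:
    def test_identical_columns_one_removed(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, 50).astype(float)
        g = _gmat([d, d.copy()])
        kept = ld_prune(g)
        assert len(kept) == 1

    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.5, (5, 400)).astype(float)
        g = _gmat(list(d))
        assert len(ld_prune(g)) == 5

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.4, 80).astype(float)
        noisy = base.copy()
        noisy[rng.choice(80, 10, replace=False)] = rng.integers(0, 3, 10)
        other = rng.binomial(2, 0.2, 80).astype(float)
        dosages = [base, noisy, other]
        g = _gmat(dosages)
        mafs = g.maf()
        expected = _brute_prune(dosages, mafs, window=3, step=1, r2_max=0.2)
        kept = ld_prune(g, window=3, step=1, r2_max=0.2)
        assert kept == [f"v{i + 1}" for i in expected]

    def test_unsorted_input_rejected(self):
        g = _gmat([np.zeros(4), np.ones(4)], pos=[10, 5])
        with pytest.raises(ValueError, match="sorted"):
            ld_prune(g)


# --------------------------------------------------------------------- MDS


class TestIbsMds:
    def test_identical_samples_coincide(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, (30, 3)).astype(float)
        d[:, 1] = d[:, 0]
        g = _gmat(list(d))
        res = ibs_mds(g, k=2)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-8)

    def test_three_sample_toy_matches_eigendecomposition(self):
        # Euclidean configuration so classical MDS is exact
        pts = np.array([[0.0], [1.0], [3.0]])
        dist = np.abs(pts - pts.T)
        coords, evals = classical_mds(dist, k=2)
        # oracle: independent double-centering + eigh
        n = 3
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dist**2) @ j
        w, v = np.linalg.eigh(b)
        lead = v[:, np.argmax(w)] * np.sqrt(w.max())
        got = coords[:, 0]
        assert np.allclose(np.abs(got), np.abs(lead), atol=1e-10)
        # distances reconstructed from the full positive spectrum
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, dist, atol=1e-8)

    def test_distance_reconstruction_from_ibs(self):
        rng = np.random.default_rng(5)
        g = _gmat(list(rng.binomial(2, 0.4, (40, 8)).astype(float)))
        dist = ibs_distance(g)
        coords, _ = classical_mds(dist, k=7)
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        # IBS distances are near-Euclidean on dosage data; allow loose slack
        assert np.allclose(rec, dist, atol=1e-6)

    def test_two_population_cohort_separates_on_axis_one(self):
        g, pop = simulate_two_population_genotypes(n_per_pop=40, n_snps=300,
                                                  divergence=0.3, seed=11)
        res = ibs_mds(g, k=2)
        r = np.corrcoef(res.coordinates[:, 0], pop)[0, 1]
        assert abs(r) > 0.9

    def test_k_too_large_rejected(self):
        g = _gmat(list(np.random.default_rng(0).binomial(2, 0.5, (10, 4)).astype(float)))
        with pytest.raises(ValueError):
            ibs_mds(g, k=4)


# ---------------------------------------------------------------------- IO


def test_vcf_round_trip(tmp_path, small_bundle):
    path = tmp_path / "g.vcf"
    write_vcf(small_bundle.genotypes, str(path))
    back = read_vcf(str(path))
    assert back.samples == small_bundle.genotypes.samples
    assert list(back.variants.index) == list(small_bundle.genotypes.variants.index)
    a, b = back.dosages, small_bundle.genotypes.dosages
    assert np.array_equal(np.isnan(a), np.isnan(b))
    assert np.array_equal(a[~np.isnan(a)], b[~np.isnan(b)])
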
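import numpy as np
import pytest
from scipy import stats

from oracles import oracle_log_cpm

from dimerqc.expression import (
    CountMatrix,
    dimer_batch_effect_test,
    leading_logfc_mds,
    log_cpm,
)
from dimerqc.simulate import SimConfig, simulate_cohort


def matrix(counts, allow_zero=False):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"f{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
        allow_zero_samples=allow_zero,
    )


class TestLogCpm:
    def test_closed_form_single_sample(self):
        got = log_cpm(matrix([[1], [1]]), prior=0.5)
        assert np.allclose(got, np.log2(5e5))

    def test_random_matrix_matches_elementwise_oracle(self, rng):
        counts = rng.integers(0, 500, size=(40, 6))
        counts[0] += 1  # keep every library non-empty
        got = log_cpm(matrix(counts), prior=2.0)
        assert np.max(np.abs(got - oracle_log_cpm(counts, 2.0))) < 1e-12

    def test_near_scale_invariance(self, rng):
        counts = rng.integers(1, 500, size=(50, 3))
        a = log_cpm(matrix(counts), prior=2.0)
        b = log_cpm(matrix(counts * 2), prior=2.0)
        # doubling all counts only moves values through the prior term
        assert np.max(np.abs(a - b)) < np.log2(1 + 2.0)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            log_cpm(matrix([[1, 0], [2, 0]], allow_zero=True))


class TestCountMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="duplicate"):
            CountMatrix(["f", "f"], ["s"], np.ones((2, 1)))
        with pytest.raises(ValueError, match="zero library"):
            matrix([[0], [0]])
        with pytest.raises(ValueError, match="non-negative"):
            matrix([[-1], [2]])

    def test_tsv_round_trip(self, tmp_path, rng):
        m = matrix(rng.integers(1, 9, size=(5, 3)))
        m.to_tsv(tmp_path / "c.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv")
        assert back.features == m.features and back.samples == m.samples
        assert (back.counts == m.counts).all()


class TestMds:
    def test_identical_samples_have_zero_distance(self):
        lcpm = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = leading_logfc_mds(lcpm, top_n=10, k=2)
        assert np.allclose(res.distance_matrix, 0.0)

    def test_euclidean_configuration_recovered_exactly(self):
        """For a Euclidean-embeddable distance matrix, classical MDS
        reproduces every pairwise distance to 1e-9."""
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0], [3.0, 4.0]])
        # two 'features' holding the coordinates: leading-logFC distance
        # over all features = Euclidean distance / sqrt(2)
        lcpm = pts.T
        with pytest.warns(UserWarning):
            res = leading_logfc_mds(lcpm, top_n=500, k=3)
        emb = res.coordinates
        D_emb = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
        assert np.max(np.abs(D_emb - res.distance_matrix)) < 1e-9
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # descending

    def test_agreement_with_pcoa_reference(self, rng):
        """Cross-check against scikit-bio's principal coordinate analysis on
        the same distance matrix (coordinates agree up to axis sign)."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa

        lcpm = rng.normal(8, 2, size=(60, 5))
        res = leading_logfc_mds(lcpm, top_n=30, k=3)
        ref = pcoa(DistanceMatrix(res.distance_matrix), number_of_dimensions=3)
        ref_coords = ref.samples.to_numpy()
        for axis in range(3):
            a, b = res.coordinates[:, axis], ref_coords[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_sample_permutation_equivariance(self, rng):
        lcpm = rng.normal(8, 2, size=(40, 6))
        perm = rng.permutation(6)
        a = leading_logfc_mds(lcpm, top_n=40, k=2).coordinates
        b = leading_logfc_mds(lcpm[:, perm], top_n=40, k=2).coordinates
        for axis in range(2):
            assert (
                min(
                    np.abs(b[:, axis] - a[perm, axis]).max(),
                    np.abs(b[:, axis] + a[perm, axis]).max(),
                )
                < 1e-9
            )

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            leading_logfc_mds(np.ones((5, 2)), k=1)


class TestBatchEffectTest:
    def _mds(self, coords):
        from dimerqc.expression import MDSResult

        coords = np.asarray(coords, dtype=float)
        return MDSResult(
            coordinates=coords,
            eigenvalues=np.zeros(coords.shape[1]),
            distance_matrix=np.zeros((len(coords), len(coords))),
            samples=[f"s{i}" for i in range(len(coords))],
        )

    def test_perfect_association(self):
        # 12 samples: the chance of a random permutation reproducing
        # |rho| = 1 is 2/12!, so the p-value sits at its floor
        pct = np.array([5.0, 8, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90])
        res = dimer_batch_effect_test(self._mds(pct[:, None]), pct, n_perm=1000, seed=1)
        assert res[0].spearman_rho == pytest.approx(1.0)
        assert res[0].p_perm == pytest.approx(1 / 1001)

    def test_sign_flip_symmetry(self, rng):
        pct = rng.uniform(0, 80, 8)
        coords = rng.normal(size=(8, 1))
        a = dimer_batch_effect_test(self._mds(coords), pct, n_perm=500, seed=2)[0]
        b = dimer_batch_effect_test(self._mds(coords), -pct, n_perm=500, seed=2)[0]
        assert b.spearman_rho == pytest.approx(-a.spearman_rho)
        assert b.p_perm == a.p_perm

    def test_seeded_reproducibility(self, rng):
        pct = rng.uniform(0, 80, 10)
        coords = rng.normal(size=(10, 2))
        a = dimer_batch_effect_test(self._mds(coords), pct, n_perm=400, seed=9)
        b = dimer_batch_effect_test(self._mds(coords), pct, n_perm=400, seed=9)
        assert [(r.spearman_rho, r.p_perm) for r in a] == [
            (r.spearman_rho, r.p_perm) for r in b
        ]

    def test_constant_dimer_fraction_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dimer_batch_effect_test(
                self._mds(np.zeros((6, 1))), np.full(6, 30.0), n_perm=200, seed=0
            )

    def test_null_pvalues_uniform(self):
        """Under a dimer-independent null (equal expected contamination,
        no coupling) permutation p-values are uniform (KS at reduced reps)."""
        pvals = []
        for rep in range(80):
            base = SimConfig(
                n_reads=8000, dimer_fraction=0.3, short_fraction=0.1,
                dimer_bias_coupling=0.0, seed=3000 + rep,
            )
            sim = simulate_cohort(10, [0.3] * 10, base, make_reads=False)
            pct = np.array([100 * t.fractions["dimer"] for t in sim.truths])
            mds = leading_logfc_mds(log_cpm(sim.counts), top_n=200, k=1)
            res = dimer_batch_effect_test(mds, pct, n_perm=400, seed=rep)
            pvals.append(res[0].p_perm)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_with_injected_coupling(self):
        """With a dimer-coupled composition tilt across contamination levels
        0.05-0.8 the test rejects at the 5% level in most cohorts."""
        hits = 0
        fr = list(np.linspace(0.05, 0.8, 12))
        for rep in range(40):
            base = SimConfig(
                n_reads=10_000, short_fraction=0.1,
                dimer_bias_coupling=1.5, seed=7000 + rep,
            )
            sim = simulate_cohort(12, fr, base, make_reads=False)
            mds = leading_logfc_mds(log_cpm(sim.counts), top_n=200, k=1)
            res = dimer_batch_effect_test(
                mds, 100 * np.array(fr), n_perm=500, seed=rep
            )
            hits += res[0].p_perm <= 0.05
        assert hits / 40 >= 0.8
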
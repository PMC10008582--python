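"""Transfer deconvolution stages: signatures, HVG selection, NMF + batch
alignment, the SVR ensemble, and the assembled pipeline."""

import numpy as np
import pytest

import celldeconv as cd
from celldeconv.transfer import (
    ReferenceSignature,
    SelectParams,
    build_signature,
    factorize_align,
    run_select,
    select_hvg,
    svr_deconvolve,
)
from celldeconv.types import ConfigError, InputError


def _labeled_ds(counts, types, normalized=True):
    counts = np.asarray(counts, dtype=float)
    ds = cd.SingleCellDataset(
        counts=counts,
        gene_symbols=[f"G{j}" for j in range(counts.shape[1])],
        cell_types=types,
        cell_ids=[f"c{i}" for i in range(counts.shape[0])],
        normalized=normalized,
    )
    return ds


class TestSignature:
    def test_mean_rows_label_sorted(self):
        ds = _labeled_ds([[1, 3], [3, 1], [5, 5]], ["B", "B", "A"])
        sig = build_signature(ds)
        assert sig.type_names == ["A", "B"]
        np.testing.assert_allclose(sig.matrix, [[5, 5], [2, 2]])

    def test_cell_order_invariant(self):
        a = _labeled_ds([[1, 3], [3, 1], [5, 5]], ["B", "B", "A"])
        b = _labeled_ds([[5, 5], [3, 1], [1, 3]], ["A", "B", "B"])
        np.testing.assert_allclose(build_signature(a).matrix,
                                   build_signature(b).matrix)

    def test_single_label_rejected(self):
        with pytest.raises(InputError):
            build_signature(_labeled_ds([[1, 2], [3, 4]], ["A", "A"]))


class TestHVG:
    def _sig(self, M):
        M = np.asarray(M, dtype=float)
        return ReferenceSignature(
            ["A", "B"], M, [f"G{j}" for j in range(M.shape[1])]
        )

    def test_identity_when_n_equals_genes(self):
        sig = self._sig([[1, 2, 3], [4, 5, 6]])
        np.testing.assert_array_equal(select_hvg(sig, 3), [0, 1, 2])

    def test_constant_gene_excluded(self):
        sig = self._sig([[1, 7, 3], [5, 7, 4]])  # G1 constant across types
        assert 1 not in select_hvg(sig, 2)

    def test_markers_rank_top_on_planted_corpus(self, norm_corpus):
        cfg = cd.CorpusConfig(seed=0)
        sig = build_signature(norm_corpus)
        chosen = set(select_hvg(sig, cfg.markers_per_type * cfg.n_types))
        planted = set(
            j for t in range(cfg.n_types) for j in cfg.marker_block(t)
        )
        assert len(chosen & planted) / len(planted) >= 0.9


class TestFactorizeAlign:
    def test_batch_means_agree_after_alignment(self):
        rng = np.random.default_rng(0)
        ref = rng.random((6, 40))
        mix = rng.random((30, 40)) + 0.5  # deliberate batch shift
        r, m = factorize_align(ref, mix, k=4, seed=0)
        np.testing.assert_allclose(r.mean(axis=0), m.mean(axis=0), atol=1e-6)

    def test_exact_rank_k_block_reconstructed(self):
        rng = np.random.default_rng(1)
        W = rng.random((8, 3))
        H = rng.random((3, 25))
        block = W @ H
        from sklearn.decomposition import NMF

        nmf = NMF(n_components=3, init="nndsvda", solver="cd",
                  max_iter=5000, random_state=0, tol=1e-10)
        W2 = nmf.fit_transform(block)
        err = np.linalg.norm(block - W2 @ nmf.components_) / np.linalg.norm(block)
        assert err <= 1e-3  # numerically rank-3, near-exact factorization

    def test_identical_rows_project_identically(self):
        rng = np.random.default_rng(2)
        ref = rng.random((5, 20))
        mix = np.vstack([ref[2], ref[2]])
        r, m = factorize_align(ref, mix, k=3, seed=0)
        np.testing.assert_allclose(m[0], m[1], atol=1e-12)

    def test_infeasible_rank_rejected(self):
        with pytest.raises(ConfigError):
            factorize_align(np.ones((3, 4)), np.ones((2, 4)), k=5)

    def test_eb_combat_route_runs(self):
        rng = np.random.default_rng(3)
        ref = rng.random((10, 30))
        mix = rng.random((40, 30)) + 0.3
        r, m = factorize_align(ref, mix, k=4, seed=0, shrink_combat=True)
        # EB shrinkage brings batch means together without exact equality
        before = np.abs(ref.mean() - mix.mean())
        after = np.abs(r.mean(axis=0) - m.mean(axis=0)).max()
        assert np.isfinite(r).all() and np.isfinite(m).all()
        assert after < before


class TestSVRDeconvolve:
    def test_noiseless_two_signature_mixture(self):
        rng = np.random.default_rng(0)
        ref = np.array([[1.0, 0, 0, 0.5, 0, 0], [0, 1.0, 0, 0, 0.5, 0]])
        mix = (0.3 * ref[0] + 0.7 * ref[1])[None, :]
        fr = svr_deconvolve(mix, ref, SelectParams(n_bags=16, seed=0), rng=rng)
        np.testing.assert_allclose(fr[0], [0.3, 0.7], atol=0.05)

    def test_pure_signature_recovered(self):
        rng = np.random.default_rng(1)
        ref = np.array([[1.0, 0, 0.2, 0.7, 0, 0], [0, 1.0, 0, 0.1, 0.8, 0.3]])
        fr = svr_deconvolve(ref[0][None, :], ref, SelectParams(n_bags=16, seed=0),
                            rng=rng)
        assert fr[0, 0] >= 0.95

    def test_simplex_contract_on_random_inputs(self):
        rng = np.random.default_rng(2)
        ref = rng.random((4, 12))
        mix = rng.standard_normal((10, 12))
        fr = svr_deconvolve(mix, ref, SelectParams(n_bags=8, seed=0), rng=rng)
        assert (fr >= 0).all()
        np.testing.assert_allclose(fr.sum(axis=1), 1.0, atol=1e-9)


class TestRunSelect:
    @pytest.mark.parametrize("mode", ["genes", "embeddings", "both"])
    def test_all_ablation_modes_valid(self, trained_model, reference_and_mixtures,
                                      mode):
        ref, mixtures = reference_and_mixtures
        res = run_select(trained_model, mixtures.X[:40], ref,
                         SelectParams(use_blocks=mode, seed=0))
        assert res.catalog.type_names == sorted(set(ref.cell_types))
        assert (res.fractions >= 0).all()
        np.testing.assert_allclose(res.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_pure_spots_assigned_to_their_type(self, trained_model, norm_corpus):
        """Pure type-0 spots inside a compositionally varied spot set are
        assigned >= 0.9 to their type with a two-type reference. (The batch
        alignment assumes a varied mixture batch, so the spot set mixes pure
        and blended compositions, as any real capture array does.)"""
        labels = np.asarray(norm_corpus.cell_types)
        keep = np.isin(labels, ["type_0", "type_1"])
        two = norm_corpus.subset_cells(np.flatnonzero(keep))
        rng = np.random.default_rng(0)
        perm = rng.permutation(two.n_cells)
        ref = two.subset_cells(perm[: two.n_cells // 2])
        src = two.subset_cells(perm[two.n_cells // 2:])
        V = src.dense_counts()
        lab = np.asarray(src.cell_types)
        a = np.flatnonzero(lab == "type_0")
        b = np.flatnonzero(lab == "type_1")

        def spot(frac_a, n=30):
            na = int(round(frac_a * n))
            idx = np.concatenate([rng.choice(a, na, replace=False),
                                  rng.choice(b, n - na, replace=False)])
            return V[idx].mean(axis=0)

        fracs = [1.0] * 10 + [0.0] * 10 + [0.5] * 10
        spots = np.vstack([spot(f) for f in fracs])
        res = run_select(trained_model, spots, ref, SelectParams(seed=0))
        a_col = res.catalog.index["type_0"]
        assert (res.fractions[:10, a_col] >= 0.9).all()
        assert (res.fractions[10:20, a_col] <= 0.1).all()

    def test_deterministic_under_seed(self, trained_model, reference_and_mixtures):
        ref, mixtures = reference_and_mixtures
        a = run_select(trained_model, mixtures.X[:10], ref, SelectParams(seed=4))
        b = run_select(trained_model, mixtures.X[:10], ref, SelectParams(seed=4))
        np.testing.assert_array_equal(a.fractions, b.fractions)
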
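import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from histodti.phantoms import (
    AstroPhantomSpec, CohortSpec, FiberPhantomSpec, NisslPhantomSpec,
    ResponseSpec, calibrate_noise_sd, generate_astrocytes, generate_cohort,
    generate_fibers, generate_nissl,
)


class TestNissl:
    def test_empty_spec_gives_blank_image(self):
        img, truth = generate_nissl(NisslPhantomSpec(n_cells=0, seed=1))
        assert truth.count == 0
        assert np.all(img.pixels == 200)

    def test_component_count_matches_truth(self):
        spec = NisslPhantomSpec(n_cells=50, noise_sd=0.0, seed=2)
        img, truth = generate_nissl(spec)
        n = ndi.label(truth.ideal_mask)[1]
        assert truth.count == 50 == n  # non-overlapping disks stay separate

    def test_seed_contract(self):
        spec_a = NisslPhantomSpec(seed=1)
        spec_b = NisslPhantomSpec(seed=2)
        _, ta = generate_nissl(spec_a)
        _, tb = generate_nissl(spec_b)
        assert ta.count == tb.count
        assert not np.array_equal(ta.centers, tb.centers)

    def test_reproducible(self):
        a, _ = generate_nissl(NisslPhantomSpec(seed=3, noise_sd=5.0))
        b, _ = generate_nissl(NisslPhantomSpec(seed=3, noise_sd=5.0))
        assert np.array_equal(a.pixels, b.pixels)

    def test_overcrowded_spec_errors(self):
        spec = NisslPhantomSpec(image_size=(128, 128), n_cells=500, seed=0)
        with pytest.raises(RuntimeError, match="overcrowded"):
            generate_nissl(spec)

    def test_invalid_intensities_rejected(self):
        with pytest.raises(ValueError):
            NisslPhantomSpec(cell_intensity=220, background_intensity=200)


class TestFibers:
    def test_kappa_cap_gives_parallel_fibers(self):
        _, truth = generate_fibers(FiberPhantomSpec(dispersion_kappa=1e12, seed=0))
        assert np.allclose(truth.orientations, truth.orientations[0])
        assert truth.circular_variance == pytest.approx(0.0, abs=1e-12)

    def test_uniform_orientations_at_kappa_zero(self):
        _, truth = generate_fibers(FiberPhantomSpec(
            dispersion_kappa=0.0, n_fibers=4000, seed=0, image_size=(64, 64)))
        # axial circular variance of uniform orientations approaches 1
        assert truth.circular_variance > 0.95

    def test_no_fibers_gives_uniform_background(self):
        img, truth = generate_fibers(FiberPhantomSpec(n_fibers=0, seed=0))
        assert np.all(img.pixels == 210)
        assert np.isnan(truth.circular_variance)

    def test_reproducible(self):
        a, _ = generate_fibers(FiberPhantomSpec(seed=5, noise_sd=4.0))
        b, _ = generate_fibers(FiberPhantomSpec(seed=5, noise_sd=4.0))
        assert np.array_equal(a.pixels, b.pixels)


class TestAstrocytes:
    def test_ground_truth_additive_over_trees(self, astro_phantom):
        _, _, truth = astro_phantom
        assert truth.branches == sum(t["branches"] for t in truth.per_tree)
        assert truth.endpoints == sum(t["endpoints"] for t in truth.per_tree)
        assert truth.junctions == sum(
            t["triple_points"] + t["quadruple_points"] for t in truth.per_tree)
        assert truth.total_length_um == pytest.approx(
            sum(t["total_length_um"] for t in truth.per_tree))

    def test_endpoint_and_junction_bookkeeping(self, astro_phantom):
        """Binary-splitting trees: leaves double per level, junction degrees 3/4."""
        _, _, truth = astro_phantom
        for t in truth.per_tree:
            n_primary = 3 if t["quadruple_points"] == 0 else 4
            depth_levels = int(np.log2(t["endpoints"] / n_primary)) + 1
            assert t["branches"] == n_primary * (2 ** depth_levels - 1)
            assert t["triple_points"] + t["quadruple_points"] == t["branches"] - t["endpoints"] + 1

    def test_trees_are_disjoint_components(self, astro_phantom):
        spec, img, truth = astro_phantom
        n_comp = ndi.label(truth.ideal_mask, structure=np.ones((3, 3)))[1]
        assert n_comp == spec.n_somata + truth.n_fragments

    def test_reproducible(self):
        spec = AstroPhantomSpec(seed=11, n_somata=2)
        a, _ = generate_astrocytes(spec)
        b, _ = generate_astrocytes(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_unplaceable_spec_errors(self):
        with pytest.raises(RuntimeError):
            generate_astrocytes(AstroPhantomSpec(image_size=(64, 64), n_somata=4, seed=0))


class TestCohort:
    def test_default_design_is_17_by_4(self):
        table = generate_cohort(CohortSpec(seed=0))
        assert len(table) == 68
        assert table["animal_id"].nunique() == 17
        assert table["region"].nunique() == 4
        assert (table["group"] == "C").sum() == 4 * 4  # 4 control animals

    def test_noiseless_response_is_exact_linear_function(self):
        b = (0.8, -300.0, 150.0, 0.5, -0.4)
        spec = CohortSpec(seed=1, responses={"y": ResponseSpec(b=b, c=0.3, noise_sd=0.0)})
        table = generate_cohort(spec)
        x = table[["FA", "RD", "MD", "CP", "CS"]].to_numpy()
        assert np.allclose(table["y"], x @ np.array(b) + 0.3, atol=1e-12)

    def test_eigenvalues_sorted_positive(self):
        table = generate_cohort(CohortSpec(seed=2))
        lam = table[["lambda1", "lambda2", "lambda3"]].to_numpy()
        assert np.all(lam[:, 0] >= lam[:, 1]) and np.all(lam[:, 1] >= lam[:, 2])
        assert np.all(lam[:, 2] > 0)

    def test_null_coefficients_give_null_correlations(self):
        """With b = 0 the response is pure noise: sample R with each predictor
        stays within the null sampling band at large n."""
        spec = CohortSpec(
            K=100, J=4, group_labels=("C",) * 20 + ("SE",) * 80, seed=3,
            responses={"y": ResponseSpec(b=(0,) * 5, c=1.0, noise_sd=1.0)})
        table = generate_cohort(spec)
        for pred in ("FA", "RD", "MD", "CP", "CS"):
            r = np.corrcoef(table[pred], table["y"])[0, 1]
            assert abs(r) < 4 / np.sqrt(len(table))

    def test_marginal_convergence_of_eigenvalue_draws(self):
        spec = CohortSpec(K=400, J=4, group_labels=("C",) * 100 + ("SE",) * 300, seed=4)
        table = generate_cohort(spec)
        sub = table[(table.group == "C") & (table.region == "cc")]
        means, sds = spec.eigenvalue_distributions[("C", "cc")]
        for i, col in enumerate(["lambda1", "lambda2", "lambda3"]):
            se = sds[i] / np.sqrt(len(sub))
            assert abs(sub[col].mean() - means[i]) < 3 * se

    def test_true_coefficients_recorded(self):
        table = generate_cohort(CohortSpec(seed=5))
        truth = table.attrs["true_coefficients"]["AI_myelin"]
        assert set(truth["b"]) == {"FA", "RD", "MD", "CP", "CS"}

    def test_noise_calibration_hits_target_r2(self):
        from histodti.model import fit_multivariate

        spec = CohortSpec(seed=0)
        ns = calibrate_noise_sd(spec, "AI_myelin", 0.8)
        r2 = []
        for seed in range(40):
            s = CohortSpec(seed=seed, responses={
                "y": ResponseSpec(b=spec.responses["AI_myelin"].b, c=0.3, noise_sd=ns)})
            r2.append(fit_multivariate(generate_cohort(s), "y", ci=False).R2)
        assert np.mean(r2) == pytest.approx(0.8, abs=0.05)

    def test_label_length_validated(self):
        with pytest.raises(ValueError, match="group labels"):
            CohortSpec(K=5, group_labels=("C", "SE"))
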
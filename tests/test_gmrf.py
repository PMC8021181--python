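import warnings

import numpy as np
import pytest

import gmrftex as g
from gmrftex.core import LABELS, ImageGrid, LabelField, build_neighborhood
from gmrftex.gmrf import (
    DEFAULT_GAMMA,
    N_ITERATIONS,
    TissueParams,
    bg_params,
    conditional_density,
    default_model,
    drop_label_renormalize,
    estimate_params,
    gibbs_sweep,
    proposal_probabilities,
    temperature,
)


def simple_model(beta_wm=None, beta00=0.0025, nbh=None):
    nbh = nbh or build_neighborhood(20)
    beta = np.zeros(nbh.n_slots)
    if beta_wm:
        for slot, v in beta_wm.items():
            beta[slot] = v
    params = {
        "WM": TissueParams(0.3, beta00, beta),
        "GM": TissueParams(0.6, beta00, np.zeros(nbh.n_slots)),
        "PV": TissueParams(0.45, beta00, np.zeros(nbh.n_slots)),
        "CB": TissueParams(0.8, beta00, np.zeros(nbh.n_slots)),
    }
    return default_model(params, neighborhood=nbh)


class TestTemperature:
    def test_schedule_endpoints(self):
        assert temperature(1) == pytest.approx(1.0)
        assert temperature(253) == 0.25
        assert temperature(255) == 0.0
        assert temperature(258) == 0.0

    def test_non_increasing(self):
        ts = [temperature(n) for n in range(1, N_ITERATIONS + 1)]
        assert all(a >= b for a, b in zip(ts, ts[1:]))

    @pytest.mark.parametrize("n", [0, 259])
    def test_out_of_range_errors(self, n):
        with pytest.raises(ValueError):
            temperature(n)


def assemble_precision(labels, model):
    """Joint precision matrix of the conditional-autoregression model.

    Independent oracle: Q_ii = 1/beta00(l_i) and for neighbours
    Q_ij = -(beta_{l_i,s}/beta00_{l_i} + beta_{l_j,s}/beta00_{l_j})/2,
    symmetrized across the pair.
    """
    h, w = labels.shape
    n = h * w
    nbh = model.neighborhood
    names = labels.label_set
    Q = np.zeros((n, n))
    for i in range(h):
        for j in range(w):
            a = i * w + j
            pa = model.params[names[labels.labels[i, j]]]
            Q[a, a] = 1.0 / pa.beta00
            for (dy, dx), slot in zip(nbh.offsets, nbh.pair_slot):
                ii, jj = i + dy, j + dx
                if not (0 <= ii < h and 0 <= jj < w):
                    continue
                b = ii * w + jj
                pb = model.params[names[labels.labels[ii, jj]]]
                Q[a, b] = -0.5 * (
                    pa.beta[slot] / pa.beta00 + pb.beta[slot] / pb.beta00
                )
    return Q


class TestConditionalDensity:
    def test_mode_value_without_neighbours(self):
        model = simple_model()
        nan = np.full(20, np.nan)
        d = conditional_density(0.3, nan, nan, "WM", model)
        assert d == pytest.approx(1.0 / np.sqrt(2 * np.pi * 0.0025))

    def test_neighbour_shift_hand_computed(self):
        # one horizontal pair with weight 0.4, both neighbour deviations +0.1:
        # conditional mean = mu + 0.4*(0.1+0.1) = mu + 0.08
        model = simple_model(beta_wm={0: 0.4})
        nv = np.full(20, np.nan)
        nm = np.full(20, np.nan)
        nbh = model.neighborhood
        for k, (dy, dx) in enumerate(nbh.offsets):
            if nbh.pair_slot[k] == 0:
                nv[k], nm[k] = 0.4, 0.3  # deviation +0.1
        x = 0.3 + 0.08
        d = conditional_density(x, nv, nm, "WM", model)
        assert d == pytest.approx(1.0 / np.sqrt(2 * np.pi * 0.0025))

    def test_density_integrates_to_one(self):
        model = simple_model(beta_wm={0: 0.2, 3: -0.1})
        nv = np.random.default_rng(0).normal(0.3, 0.05, 20)
        nm = np.full(20, 0.3)
        sd = np.sqrt(0.0025)
        xs = np.linspace(0.3 - 10 * sd, 0.3 + 10 * sd, 20001)
        ys = [conditional_density(x, nv, nm, "WM", model) for x in xs]
        assert np.trapezoid(ys, xs) == pytest.approx(1.0, abs=1e-6)

    def test_bg_label_rejected(self):
        model = simple_model()
        with pytest.raises(ValueError, match="BG"):
            conditional_density(0.0, np.full(20, np.nan), np.full(20, np.nan), "BG", model)

    @pytest.mark.parametrize("shape", [(3, 3), (4, 5), (5, 5)])
    def test_agrees_with_joint_gaussian_conditional(self, shape):
        """The per-pixel conditional matches analytic conditioning of the
        explicitly assembled joint Gaussian on single-label lattices."""
        rng = np.random.default_rng(0)
        nbh = build_neighborhood(20)
        model = simple_model(beta_wm={0: 0.15, 1: -0.05, 4: 0.08}, nbh=nbh)
        labels = LabelField(
            np.full(shape, LABELS.index("WM")), LABELS
        )
        Q = assemble_precision(labels, model)
        x = rng.normal(0.3, 0.05, shape)
        mu = np.full(shape, 0.3)
        h, w = shape
        for i in range(h):
            for j in range(w):
                a = i * w + j
                # analytic conditional of N(mu, Q^-1) at site a
                var_joint = 1.0 / Q[a, a]
                others = np.delete(np.arange(h * w), a)
                mean_joint = mu[i, j] - var_joint * (
                    Q[a, others] @ (x.ravel()[others] - mu.ravel()[others])
                )
                nv = np.full(20, np.nan)
                nm = np.full(20, np.nan)
                for k, (dy, dx) in enumerate(nbh.offsets):
                    ii, jj = i + dy, j + dx
                    if 0 <= ii < h and 0 <= jj < w:
                        nv[k], nm[k] = x[ii, jj], mu[ii, jj]
                p = model.params["WM"]
                slots = np.array(nbh.pair_slot)
                dev = np.where(np.isfinite(nv), nv - nm, 0.0)
                mean_cond = p.mu + p.beta @ np.bincount(slots, weights=dev, minlength=10)
                assert var_joint == pytest.approx(p.beta00, abs=1e-8)
                assert mean_cond == pytest.approx(mean_joint, abs=1e-8)


class TestProposalProbabilities:
    def _setup(self):
        model = simple_model()
        vals = np.full((5, 5), 0.45)
        grid = ImageGrid(vals, np.ones((5, 5), bool))
        labels = LabelField(np.full((5, 5), LABELS.index("PV")), LABELS)
        return model, grid, labels

    def test_prior_only_case(self):
        # two labels with identical conditional densities: probabilities
        # reduce to the prior ratio
        nbh = build_neighborhood(20)
        z = np.zeros(10)
        params = {
            "WM": TissueParams(0.5, 0.01, z),
            "GM": TissueParams(0.5, 0.01, z),
            "CB": TissueParams(0.5, 0.01, z),
        }
        model = default_model(
            params, gamma=np.array([0.25, 0.74, 0.005, 0.005]),
            neighborhood=nbh, label_set=("WM", "GM", "CB", "BG"),
        )
        grid = ImageGrid(np.full((5, 5), 0.5), np.ones((5, 5), bool))
        labels = LabelField(np.zeros((5, 5), dtype=int), ("WM", "GM", "CB", "BG"))
        p = proposal_probabilities((2, 2), labels, grid, model, t=1.0)
        assert p[0] / p[1] == pytest.approx(0.25 / 0.74, rel=1e-9)

    def test_sums_to_one_for_positive_t(self):
        model, grid, labels = self._setup()
        for t in (0.25, 0.5, 1.0, 3.0):
            p = proposal_probabilities((2, 2), labels, grid, model, t)
            assert p.sum() == pytest.approx(1.0)

    def test_small_t_converges_to_argmax_oracle(self):
        """As t -> 0+ the proposal approaches the one-hot argmax vector."""
        rng = np.random.default_rng(12)
        model = simple_model(beta_wm={0: 0.1})
        for _ in range(100):
            vals = np.clip(rng.normal(0.5, 0.2, (5, 5)), 0, 1)
            grid = ImageGrid(vals, np.ones((5, 5), bool))
            labels = LabelField(
                rng.integers(0, 4, (5, 5)), LABELS
            )
            cold = proposal_probabilities((2, 2), labels, grid, model, 1e-3)
            hard = proposal_probabilities((2, 2), labels, grid, model, 0.0)
            assert np.argmax(cold) == np.argmax(hard)
            assert hard[np.argmax(hard)] == 1.0

    def test_negative_temperature_rejected(self):
        model, grid, labels = self._setup()
        with pytest.raises(ValueError):
            proposal_probabilities((2, 2), labels, grid, model, -0.1)


class TestGibbsSweep:
    def test_empty_mask_leaves_labels_unchanged(self):
        model = simple_model()
        grid = ImageGrid(np.zeros((6, 6)), np.zeros((6, 6), bool))
        labels = LabelField(np.full((6, 6), LABELS.index("BG")), LABELS)
        out = gibbs_sweep(labels, grid, model, 1.0, rng=0)
        assert np.array_equal(out.labels, labels.labels)

    def test_same_seed_same_output(self):
        rng = np.random.default_rng(4)
        model = simple_model()
        vals = np.clip(rng.normal(0.5, 0.15, (16, 16)), 0, 1)
        grid = ImageGrid(vals, np.ones((16, 16), bool))
        labels = LabelField(rng.integers(0, 4, (16, 16)), LABELS)
        a = gibbs_sweep(labels, grid, model, 0.8, rng=77)
        b = gibbs_sweep(labels, grid, model, 0.8, rng=77)
        assert np.array_equal(a.labels, b.labels)

    def test_icm_sweep_reduces_argmax_mismatch(self):
        """At t=0 a sweep never increases the number of pixels whose label
        differs from their local conditional argmax."""
        rng = np.random.default_rng(21)
        model = simple_model()

        def mismatch(labels, grid):
            n = 0
            for i in range(labels.shape[0]):
                for j in range(labels.shape[1]):
                    p = proposal_probabilities((i, j), labels, grid, model, 0.0)
                    n += int(labels.labels[i, j] != np.argmax(p))
            return n

        for _ in range(3):
            vals = np.clip(rng.normal(0.5, 0.2, (9, 9)), 0, 1)
            grid = ImageGrid(vals, np.ones((9, 9), bool))
            labels = LabelField(rng.integers(0, 4, (9, 9)), LABELS)
            before = mismatch(labels, grid)
            after = mismatch(gibbs_sweep(labels, grid, model, 0.0, rng=0), grid)
            assert after <= before


class TestEstimateParams:
    def test_iid_field_recovery(self, single_label_field):
        rng = np.random.default_rng(31)
        vals = 0.5 + 0.05 * rng.standard_normal((64, 64))
        grid = ImageGrid(np.clip(vals, 0, 1), np.ones((64, 64), bool))
        est = estimate_params(single_label_field, grid)
        p = est["WM"]
        assert p.mu == pytest.approx(0.5, rel=0.05)
        assert p.beta00 == pytest.approx(0.0025, rel=0.10)
        assert np.all(np.abs(p.beta) < 0.05)

    def test_horizontal_weight_recovery(self, single_label_field):
        """Round-trip: fields simulated with beta01=0.2 yield estimates
        within +-0.05, averaged over chains."""
        model = simple_model(beta_wm={0: 0.2})
        grids = np.ones((64, 64), bool)
        b01 = []
        for seed in range(10):
            sim = g.simulate_field(single_label_field, model, 200, seed=seed)
            est = estimate_params(
                single_label_field, ImageGrid(sim.values, grids)
            )
            b01.append(est["WM"].beta[0])
        assert np.mean(b01) == pytest.approx(0.2, abs=0.05)

    def test_tiny_label_falls_back_with_warning(self):
        labels = np.full((20, 20), LABELS.index("WM"))
        labels[0, 0] = LABELS.index("CB")  # single-pixel label
        field = LabelField(labels, LABELS)
        rng = np.random.default_rng(1)
        grid = ImageGrid(rng.random((20, 20)), np.ones((20, 20), bool))
        with pytest.warns(UserWarning, match="CB"):
            est = estimate_params(field, grid)
        assert np.all(est["CB"].beta == 0)

    def test_bg_fixed(self, phantom):
        est = estimate_params(phantom.labels, phantom.mri)
        assert est["BG"].mu == 0.0
        assert est["BG"].beta00 == 1e-30
        assert np.all(est["BG"].beta == 0)


class TestSegmentAndDrop:
    def test_all_bg_init_unchanged(self):
        grid = ImageGrid(np.zeros((12, 12)), np.zeros((12, 12), bool))
        init = LabelField(np.full((12, 12), LABELS.index("BG")), LABELS)
        model = simple_model()
        labels, _ = g.segment(grid, init, model, seed=0)
        assert (labels.labels == LABELS.index("BG")).all()

    def test_gamma_simplex_after_drop(self, phantom, segmented):
        _, labels, model = segmented
        out_labels, out_model = drop_label_renormalize(
            labels, phantom.mri, model, "PV"
        )
        assert out_model.gamma.sum() == pytest.approx(1.0)
        assert "PV" not in out_labels.label_set
        assert out_model.gamma.min() > 0

    def test_drop_without_pv_pixels_changes_only_gamma(self):
        model = simple_model()
        labels = LabelField(np.full((8, 8), LABELS.index("WM")), LABELS)
        grid = ImageGrid(np.full((8, 8), 0.3), np.ones((8, 8), bool))
        out_labels, out_model = drop_label_renormalize(labels, grid, model, "PV")
        assert out_labels.of("WM").all()
        assert out_model.gamma.sum() == pytest.approx(1.0)

    def test_reassignment_matches_bruteforce_argmax(self):
        """A dropped pixel goes to the remaining label with the highest
        density-times-prior, per exhaustive evaluation."""
        rng = np.random.default_rng(8)
        model = simple_model(beta_wm={0: 0.1})
        vals = np.clip(rng.normal(0.5, 0.15, (9, 9)), 0, 1)
        grid = ImageGrid(vals, np.ones((9, 9), bool))
        arr = rng.integers(0, 4, (9, 9))
        arr[4, 4] = LABELS.index("PV")
        labels = LabelField(arr, LABELS)
        expected = {}
        for name in ("CB", "GM", "WM"):
            gam = model.gamma[LABELS.index(name)]
            # renormalized over remaining labels; constant factor,
            # irrelevant for the argmax
            d = conditional_density(
                vals[4, 4],
                *_neighbour_arrays(labels, grid, model, (4, 4)),
                name,
                model,
                log=True,
            )
            expected[name] = d + np.log(gam)
        best = max(expected, key=expected.get)
        out_labels, _ = drop_label_renormalize(labels, grid, model, "PV")
        assert out_labels.label_set[out_labels.labels[4, 4]] == best

    def test_drop_below_three_tissues_errors(self):
        nbh = build_neighborhood(20)
        z = np.zeros(10)
        params = {
            "WM": TissueParams(0.3, 0.01, z),
            "GM": TissueParams(0.6, 0.01, z),
            "CB": TissueParams(0.8, 0.01, z),
            "BG": bg_params(),
        }
        model = default_model(
            params, gamma=np.array([0.1, 0.1, 0.1, 0.7]),
            neighborhood=nbh, label_set=("WM", "GM", "CB", "BG"),
        )
        labels = LabelField(np.zeros((8, 8), dtype=int), ("WM", "GM", "CB", "BG"))
        grid = ImageGrid(np.full((8, 8), 0.3), np.ones((8, 8), bool))
        with pytest.raises(ValueError, match="3 tissue"):
            drop_label_renormalize(labels, grid, model, "CB")

    def test_default_gamma_is_simplex(self):
        assert DEFAULT_GAMMA.sum() == pytest.approx(1.0)


def _neighbour_arrays(labels, grid, model, pixel):
    """Gather neighbour values/means for conditional_density at a pixel."""
    nbh = model.neighborhood
    i, j = pixel
    h, w = grid.shape
    nv = np.full(len(nbh.offsets), np.nan)
    nm = np.full(len(nbh.offsets), np.nan)
    bg = labels.bg_index
    for k, (dy, dx) in enumerate(nbh.offsets):
        ii, jj = i + dy, j + dx
        if 0 <= ii < h and 0 <= jj < w and grid.mask[ii, jj]:
            if labels.labels[ii, jj] != bg:
                nv[k] = grid.values[ii, jj]
                nm[k] = model.params[
                    labels.label_set[labels.labels[ii, jj]]
                ].mu
    return nv, nm
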
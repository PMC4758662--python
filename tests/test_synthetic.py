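"""Synthetic ring-measurement generator: determinism and noise statistics."""

import numpy as np
import pytest
from scipy import stats

from pelletgrowth import (
    DimensionalScales,
    ModelParameters,
    RadialGrid,
    SolverConfig,
    bin_profile,
    days_to_model_time,
    generate,
    initial_state,
    read_dataset,
    run_to,
    write_dataset,
)

# coarse-but-adequate simulation settings keep the statistical tests fast
COARSE_GRID = RadialGrid(80)
COARSE_CFG = SolverConfig(dt=1e-2)


@pytest.fixture(scope="module")
def fitted_point():
    return ModelParameters(kappa=0.3, sigma0=6.0), DimensionalScales()


@pytest.fixture(scope="module")
def noiseless(fitted_point):
    params, scales = fitted_point
    return generate(params, scales, noise_sd=0.0, seed=7, grid=COARSE_GRID, config=COARSE_CFG)


class TestStructure:
    def test_noiseless_sections_equal_model_rings(self, fitted_point, noiseless):
        params, scales = fitted_point
        # independent forward run + binning with the same settings
        cps = [days_to_model_time(d, scales) for d in (7, 14, 21, 28)]
        states = run_to(
            initial_state(params, COARSE_GRID, COARSE_CFG),
            cps[-1], params, COARSE_GRID, COARSE_CFG, checkpoints=cps,
        )
        for day, st in zip((7, 14, 21, 28), states):
            expected = bin_profile(st.p, COARSE_GRID, n_rings=6).values
            sub = noiseless.data[noiseless.data["day"] == day]
            for _, section in sub.groupby(["replicate_id", "section_id"]):
                assert np.allclose(
                    section.sort_values("ring_index")["proteoglycan_fraction"], expected
                )

    def test_rows_and_ranges(self, noiseless):
        df = noiseless.data
        assert len(df) == 4 * 3 * 8 * 6  # days x replicates x sections x rings
        assert set(df["day"]) == {7, 14, 21, 28}
        assert df["proteoglycan_fraction"].between(0, 1).all()
        assert df["pellet_radius_um"].min() > 84.0  # grows beyond S0

    def test_seed_determinism(self, fitted_point):
        params, scales = fitted_point
        kw = dict(noise_sd=0.05, grid=COARSE_GRID, config=COARSE_CFG)
        a = generate(params, scales, seed=11, **kw)
        b = generate(params, scales, seed=11, **kw)
        c = generate(params, scales, seed=12, **kw)
        assert a.data.equals(b.data)
        assert not a.data.equals(c.data)

    def test_invalid_arguments(self, fitted_point):
        params, scales = fitted_point
        with pytest.raises(ValueError):
            generate(params, scales, noise_sd=-0.1, seed=0)
        with pytest.raises(ValueError):
            generate(params, scales, sections_per_replicate=3, seed=0)
        with pytest.raises(ValueError):
            generate(params, scales, sections_per_replicate=15, seed=0)
        with pytest.raises(ValueError):
            generate(params, scales, noise="lognormal", seed=0)


class TestNoiseStatistics:
    def test_section_scatter_matches_nominal_sd(self, fitted_point):
        params, scales = fitted_point
        ds = generate(
            params, scales, noise_sd=0.05, sections_per_replicate=14, seed=5,
            grid=COARSE_GRID, config=COARSE_CFG,
        )
        model = generate(
            params, scales, noise_sd=0.0, seed=5, grid=COARSE_GRID, config=COARSE_CFG
        )
        for day in (14, 21, 28):
            means = model.ring_means(day)
            sub = ds.data[ds.data["day"] == day]
            sds = sub.groupby("ring_index")["proteoglycan_fraction"].std().to_numpy()
            inner = (means > 0.2) & (means < 0.8)
            if inner.any():
                assert np.all((sds[inner] > 0.03) & (sds[inner] < 0.07))

    def test_ring_means_recover_model_values(self, fitted_point):
        # 3 x 14 sections: sample means within 3*sd/sqrt(42) almost always
        params, scales = fitted_point
        model = generate(params, scales, noise_sd=0.0, seed=0,
                         grid=COARSE_GRID, config=COARSE_CFG)
        bound = 3 * 0.05 / np.sqrt(42)
        hits, total = 0, 0
        for seed in range(6):
            ds = generate(
                params, scales, noise_sd=0.05, sections_per_replicate=14, seed=seed,
                grid=COARSE_GRID, config=COARSE_CFG,
            )
            for day in (7, 14, 21, 28):
                m, truth = ds.ring_means(day), model.ring_means(day)
                interior = (truth > 0.1) & (truth < 0.9)  # no truncation bias
                hits += int(np.sum(np.abs(m - truth)[interior] < bound))
                total += int(interior.sum())
        assert hits / total >= 0.95

    def test_truncation_bias_negligible_in_interior(self):
        # property of the noise model itself, via the scipy oracle
        for m in np.linspace(0.2, 0.8, 7):
            a, b = (0 - m) / 0.05, (1 - m) / 0.05
            assert abs(stats.truncnorm.mean(a, b, loc=m, scale=0.05) - m) < 0.005

    def test_beta_noise_bounded_and_centred(self, fitted_point):
        params, scales = fitted_point
        ds = generate(
            params, scales, noise_sd=0.05, noise="beta", seed=2,
            grid=COARSE_GRID, config=COARSE_CFG,
        )
        vals = ds.data["proteoglycan_fraction"]
        assert vals.between(0, 1).all()
        model = generate(params, scales, noise_sd=0.0, seed=2,
                         grid=COARSE_GRID, config=COARSE_CFG)
        m28 = ds.ring_means(28)
        assert np.max(np.abs(m28 - model.ring_means(28))) < 0.05


class TestEarlyRegimeOption:
    def test_shift_only_touches_early_days(self, fitted_point, noiseless):
        params, scales = fitted_point
        shifted = generate(
            params, scales, noise_sd=0.0, seed=7, grid=COARSE_GRID, config=COARSE_CFG,
            early_centre_shift=0.2,
        )
        for day in (21, 28):
            assert np.allclose(shifted.ring_means(day), noiseless.ring_means(day))
        assert not np.allclose(shifted.ring_means(7), noiseless.ring_means(7))
        # the distortion is centre-weighted
        delta = shifted.ring_means(7) - noiseless.ring_means(7)
        assert delta[0] > delta[-1]


def test_csv_roundtrip_with_sidecar(tmp_path, fitted_point):
    params, scales = fitted_point
    ds = generate(params, scales, noise_sd=0.02, seed=9,
                  grid=COARSE_GRID, config=COARSE_CFG)
    path = tmp_path / "study.csv"
    write_dataset(ds, path)
    assert (tmp_path / "study.provenance.json").exists()
    loaded = read_dataset(path)
    assert loaded.provenance["seed"] == 9
    assert np.allclose(
        loaded.data["proteoglycan_fraction"], ds.data["proteoglycan_fraction"]
    )
    bad = tmp_path / "bad.csv"
    bad.write_text("day,replicate_id\n7,1\n")
    with pytest.raises(ValueError, match="missing"):
        read_dataset(bad)
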
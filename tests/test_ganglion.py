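import numpy as np
import pytest

from drgstereo import (
    Ganglion,
    GanglionConfig,
    InjuryScenario,
    LabellingSpec,
    SubpopulationSpec,
    apply_injury,
    apply_labels,
    calibrate_survival_ratio,
    generate_ganglion,
    nuclear_spot_table,
)
from drgstereo.ganglion import ConfigurationError, lognormal_params


def test_lognormal_moment_match():
    mu, sigma = lognormal_params(361.0, 138.0)
    mean = np.exp(mu + sigma**2 / 2)
    var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
    assert mean == pytest.approx(361.0, rel=1e-12)
    assert np.sqrt(var) == pytest.approx(138.0, rel=1e-12)


def test_generate_deterministic(small_config):
    a = generate_ganglion(small_config, seed=3)
    b = generate_ganglion(small_config, seed=3)
    c = generate_ganglion(small_config, seed=4)
    assert np.array_equal(a.centers, b.centers)
    assert np.array_equal(a.soma_radius, b.soma_radius)
    assert list(a.subpop) == list(b.subpop)
    assert not np.array_equal(a.centers, c.centers)


def test_positions_inside_ellipsoid(small_ganglion):
    ax, ay, az = small_ganglion.semi_axes
    c = small_ganglion.centers
    r2 = (c[:, 0] / ax) ** 2 + (c[:, 1] / ay) ** 2 + (c[:, 2] / az) ** 2
    assert (r2 <= 1.0 + 1e-12).all()


def test_positions_roughly_uniform(full_config):
    g = generate_ganglion(full_config, seed=0)
    # mean near centre; each coordinate has variance a^2/5 for a uniform ball
    for k, a in enumerate(g.semi_axes):
        assert abs(g.centers[:, k].mean()) < 0.1 * a
        assert g.centers[:, k].var() == pytest.approx(a**2 / 5, rel=0.1)


def test_subpop_and_soma_area_fidelity(full_config):
    g = generate_ganglion(full_config, seed=1)
    fracs = {s.name: s.fraction for s in full_config.subpopulations}
    for name, frac in fracs.items():
        obs = float((g.subpop == name).mean())
        assert obs == pytest.approx(frac, abs=0.03)
    mrg = g.soma_area[g.subpop == "mrgprd"]
    assert mrg.mean() == pytest.approx(361.0, abs=15.0)
    assert np.allclose(g.nucleus_radius, 0.45 * g.soma_radius)


def test_config_validation(subpops):
    with pytest.raises(ConfigurationError):
        GanglionConfig(n=10, subpopulations=subpops[:2])  # fractions don't sum to 1
    with pytest.raises(ConfigurationError):
        GanglionConfig(n=-1, subpopulations=subpops)
    with pytest.raises(ConfigurationError):
        SubpopulationSpec("x", 0.5, -1.0, 10.0)
    with pytest.raises(ConfigurationError):
        SubpopulationSpec("x", 0.5, 100.0, 10.0, nucleus_ratio=1.5)


def _injury(schedule):
    return InjuryScenario(
        scenario_id="test",
        axotomized_territories=("tibial", "peroneal"),
        survival_schedule=schedule,
    )


def test_survival_schedule_validation():
    with pytest.raises(ConfigurationError):
        _injury({"mrgprd": {7: 0.5, 14: 0.8}})  # increasing
    with pytest.raises(ConfigurationError):
        _injury({"mrgprd": {7: 1.2}})
    with pytest.raises(ConfigurationError):
        InjuryScenario("t", ("volar",), {})


def test_survival_interpolation():
    inj = _injury({"a": {10: 0.8, 30: 0.4}})
    assert inj.survival_at("a", 0) == 1.0
    assert inj.survival_at("a", 10) == 0.8
    assert inj.survival_at("a", 20) == pytest.approx(0.6)
    assert inj.survival_at("a", 100) == 0.4
    with pytest.raises(ConfigurationError):
        inj.survival_at("unknown", 10)


def test_injury_nested_and_spares_intact(small_ganglion):
    sched = {
        name: {7: 1.0, 14: 0.6, 56: 0.3}
        for name in ("mrgprd", "cgrp", "trpm8", "thy1", "other")
    }
    inj = _injury(sched)
    days = [7, 14, 28, 56]
    alive = [apply_injury(small_ganglion, inj, day=d, seed=9).alive for d in days]
    for earlier, later in zip(alive, alive[1:]):
        assert not (later & ~earlier).any()  # nobody comes back to life
    g56 = apply_injury(small_ganglion, inj, day=56, seed=9)
    intact = ~g56.axotomized
    assert g56.alive[intact].all()
    assert (g56.axotomized == np.isin(small_ganglion.territory, ["tibial", "peroneal"])).all()
    # same seed, same day -> identical outcome
    again = apply_injury(small_ganglion, inj, day=56, seed=9)
    assert np.array_equal(g56.alive, again.alive)


def test_injury_survival_fraction(full_config):
    g = generate_ganglion(full_config, seed=2)
    sched = {name: {28: 0.4} for name in np.unique(g.subpop)}
    g28 = apply_injury(g, _injury(sched), day=28, seed=5)
    axo = g28.axotomized
    assert g28.alive[axo].mean() == pytest.approx(0.4, abs=0.03)


def test_labels_deterministic_membership(small_ganglion):
    specs = [
        LabellingSpec("mrgprd", sensitivity=1.0, false_positive=0.0, target="marker"),
        LabellingSpec("FB", sensitivity=1.0, false_positive=0.0, target="territory",
                      territory_restriction="tibial"),
    ]
    gl = apply_labels(small_ganglion, specs, seed=0)
    assert np.array_equal(gl.labels["mrgprd"], small_ganglion.subpop == "mrgprd")
    assert np.array_equal(gl.labels["FB"], small_ganglion.territory == "tibial")


def test_injury_target_label(small_ganglion):
    sched = {name: {28: 1.0} for name in np.unique(small_ganglion.subpop)}
    gi = apply_injury(small_ganglion, _injury(sched), day=28, seed=1)
    gl = apply_labels(gi, [LabellingSpec("GFP", 1.0, 0.0, target="injury")], seed=2)
    assert np.array_equal(gl.labels["GFP"], gi.axotomized)


def test_label_rates(full_config):
    g = generate_ganglion(full_config, seed=3)
    gl = apply_labels(g, [LabellingSpec("GFP", 0.9, 0.05, target="injury")], seed=4)
    # nothing axotomized: labelling is pure false positives
    assert gl.labels["GFP"].mean() == pytest.approx(0.05, abs=0.01)


def test_label_spec_validation():
    with pytest.raises(ConfigurationError):
        LabellingSpec("x", sensitivity=1.5)
    with pytest.raises(ConfigurationError):
        LabellingSpec("x", 0.9, target="nonsense")
    with pytest.raises(ConfigurationError):
        LabellingSpec("x", 0.9, target="territory", territory_restriction="volar")


def test_calibrate_survival_ratio_frozen():
    assert calibrate_survival_ratio(0.15, 0.017) == pytest.approx(0.0980, abs=1e-4)
    assert calibrate_survival_ratio(0.156, 0.233) == pytest.approx(1.6435, abs=1e-3)
    assert calibrate_survival_ratio(0.3, 0.3) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        calibrate_survival_ratio(0.0, 0.1)
    with pytest.raises(ValueError):
        calibrate_survival_ratio(0.5, 1.0)


def test_calibrate_survival_ratio_closure():
    # applying survival s*rho to marker+ and s to marker- recovers p_ipsi
    p, p_ipsi, s = 0.15, 0.017, 0.5
    rho = calibrate_survival_ratio(p, p_ipsi)
    recovered = p * s * rho / (p * s * rho + (1 - p) * s)
    assert recovered == pytest.approx(p_ipsi, rel=1e-12)


def test_nuclear_spot_table(small_ganglion):
    g = small_ganglion.copy()
    g.alive[:100] = False
    tab = nuclear_spot_table(g, drg_id="d1", side="ipsi")
    assert len(tab) == int(g.alive.sum())
    expect = 4 / 3 * np.pi * g.nucleus_radius[g.alive] ** 3
    assert np.allclose(tab["volume"].to_numpy(), expect)
    assert (tab["side"] == "ipsi").all()


def test_csv_roundtrip(tmp_path, small_ganglion):
    gl = apply_labels(
        small_ganglion,
        [LabellingSpec("mrgprd", 1.0, 0.0), LabellingSpec("thy1", 1.0, 0.0)],
        seed=0,
    )
    p = tmp_path / "g.csv"
    side = tmp_path / "g.json"
    gl.to_csv(p, sidecar_path=side)
    back = Ganglion.from_csv(p, sidecar_path=side)
    assert back.n == gl.n
    assert np.allclose(back.centers, gl.centers)
    assert np.allclose(back.soma_radius, gl.soma_radius)
    for name in gl.labels:
        assert np.array_equal(back.labels[name], gl.labels[name])
    assert tuple(back.semi_axes) == tuple(gl.semi_axes)
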
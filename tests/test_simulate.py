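import numpy as np
import pytest
from scipy import stats

from evsort.simulate import (BindingCurve, ParameterError, SimConfig,
                             generate_binding_curve, generate_count_experiment,
                             generate_droplets, generate_intensity_table,
                             generate_sequences, hill_response)


def test_dimensions_and_determinism():
    cfg = SimConfig(n_mirna=50, n_exported=5, seed=3)
    cm, truth = generate_count_experiment(cfg)
    assert cm.counts.shape == (50, 4 * cfg.n_replicates)
    cm2, _ = generate_count_experiment(cfg)
    assert (cm.counts.to_numpy() == cm2.counts.to_numpy()).all()
    seqs = generate_sequences(cfg, truth)
    cfg2 = SimConfig(n_mirna=50, n_exported=5, seed=3)
    _, truth2 = generate_count_experiment(cfg2)
    seqs2 = generate_sequences(cfg2, truth2)
    assert seqs.sequences == seqs2.sequences
    assert (truth.table == truth2.table).all().all()


def test_zero_exported_and_config_validation():
    cfg = SimConfig(n_mirna=30, n_exported=0, seed=1)
    _, truth = generate_count_experiment(cfg)
    assert truth.table["is_exported"].sum() == 0
    seqs = generate_sequences(cfg, truth)
    assert truth.table["motif_planted"].sum() == 0
    assert len(seqs) == 30

    with pytest.raises(ParameterError, match="n_exported"):
        generate_count_experiment(SimConfig(n_mirna=5, n_exported=6))
    with pytest.raises(ParameterError, match="dispersion"):
        generate_count_experiment(SimConfig(dispersion=-1))
    with pytest.raises(ParameterError, match="background_freqs"):
        generate_count_experiment(SimConfig(background_freqs=(0.5, 0.5, 0.2, 0.2)))


def test_motif_longer_than_min_length_rejected():
    cfg = SimConfig(motif_consensus="A" * 30)
    with pytest.raises(ParameterError, match="consensus"):
        cfg.validate()


def test_forced_planting_yields_exact_consensus_everywhere():
    cfg = SimConfig(n_mirna=40, n_exported=15, motif_consensus="AUUGCA",
                    motif_plant_prob=1.0, seed=5)
    _, truth = generate_count_experiment(cfg)
    seqs = generate_sequences(cfg, truth)
    exported = truth.exported_ids()
    assert truth.table["motif_planted"].sum() == 15  # non-degenerate, prob 1
    for sid in exported:
        pos = int(truth.table.at[sid, "planted_position"])
        assert seqs[sid][pos:pos + 6] == "AUUGCA"
    assert sum("AUUGCA" in seqs[s] for s in exported) == 15


def test_background_frequencies_within_exact_binomial_interval():
    cfg = SimConfig(n_mirna=500, n_exported=0, seq_length_range=(20, 20), seed=9)
    _, truth = generate_count_experiment(cfg)
    seqs = generate_sequences(cfg, truth)
    pooled = "".join(seqs.sequences.values())
    n = len(pooled)
    assert n == 10000
    for base in "ACGU":
        k = pooled.count(base)
        lo = stats.binom.ppf(0.005, n, 0.25)
        hi = stats.binom.ppf(0.995, n, 0.25)
        assert lo <= k <= hi


def test_export_effect_direction_depletes_cavin1_evs():
    """Exported miRNAs must be higher in CONT EVs than CAVIN1 EVs (CAVIN1
    suppresses export), and unchanged in cells."""
    cfg = SimConfig(n_mirna=200, n_exported=40, export_effect=-2.0,
                    dispersion=0.01, size_factor_range=(1.0, 1.0), seed=2)
    cm, truth = generate_count_experiment(cfg)
    exp = truth.table["is_exported"].to_numpy()
    meta = cm.sample_meta
    ev_cont = cm.counts.loc[:, (meta.compartment == "EV") & (meta.condition == "CONT")]
    ev_cav = cm.counts.loc[:, (meta.compartment == "EV") & (meta.condition == "CAVIN1")]
    ratio = np.log2(ev_cav.mean(axis=1) + 1) - np.log2(ev_cont.mean(axis=1) + 1)
    assert np.median(ratio[exp]) == pytest.approx(-2.0, abs=0.3)
    assert np.median(ratio[~exp]) == pytest.approx(0.0, abs=0.3)


def test_intensity_generator_null_and_power():
    # type-I: with no planted signal the false-positive fraction sits near alpha
    from evsort.proteomics import ttest_volcano
    fp, n = 0, 0
    for seed in range(10):
        tab, _ = generate_intensity_table(200, 8, 0, 0.0, 0.2, seed)
        res = ttest_volcano(tab)
        fp += int(res["significant"].sum())
        n += len(res)
    assert 0.03 <= fp / n <= 0.07
    # power: planted log2 effect 3 at noise 0.2 is essentially always found
    hits = []
    for seed in range(20):
        tab, truth = generate_intensity_table(100, 8, 10, 3.0, 0.2, 1000 + seed)
        res = ttest_volcano(tab)
        hits.append(res.loc[truth, "significant"].mean())
    assert np.mean(hits) >= 0.9


def test_intensity_generator_validation():
    with pytest.raises(ParameterError, match="n_per_group"):
        generate_intensity_table(10, 0, 0, 1.0, 0.1, 0)
    with pytest.raises(ParameterError, match="n_signal"):
        generate_intensity_table(10, 4, 11, 1.0, 0.1, 0)


def test_binding_curve_hill_identity_and_seeds():
    conc = np.geomspace(1e-8, 1.5e-4, 12)
    kd = 5e-6
    curve = generate_binding_curve(kd, 1.0, 1.0, 0.0, conc, 0.0, 0)
    # response at x = kd is exactly the half-range point
    assert hill_response(kd, kd, 1.0, 1.0, 0.0) == pytest.approx(0.5, abs=1e-12)
    c1 = generate_binding_curve(kd, 1.0, 1.0, 0.0, conc, 0.05, 1)
    c2 = generate_binding_curve(kd, 1.0, 1.0, 0.0, conc, 0.05, 2)
    assert not np.allclose(c1.responses, c2.responses)
    assert np.allclose(c1.responses - (c1.responses - curve.responses),
                       curve.responses)
    with pytest.raises(ParameterError, match="kd"):
        generate_binding_curve(-1.0, 1.0, 1.0, 0.0, conc, 0.0, 0)
    with pytest.raises(ParameterError):
        BindingCurve(np.array([1e-6, 2e-6]), np.array([0.1, 0.2]))


def test_droplet_generator_matches_poisson_occupancy():
    k, n = generate_droplets(0.5, 20000, 3)
    expected = 1 - np.exp(-0.5)
    assert abs(k / n - expected) < 0.01
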
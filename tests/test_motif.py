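import numpy as np
import pytest

from evsort.io import SequenceSet
from evsort.motif import (MotifModel, ZoopsConfig, best_overlap_agreement,
                          build_background, consensus_agreement,
                          consensus_from_pwm, discover, model_from_text,
                          model_to_text, motif_evalue, zoops_em)

FAST = ZoopsConfig(max_substring_starts=150, n_restarts=5, seed=0)


def test_build_background_counts():
    assert np.allclose(build_background(SequenceSet({"a": "AAAA"})), [1, 0, 0, 0])
    assert np.allclose(build_background(SequenceSet({"a": "ACGU"})),
                       [0.25] * 4)
    rng = np.random.default_rng(0)
    seqs = {f"s{i}": "".join(rng.choice(list("ACGU"), 30)) for i in range(10)}
    bg = build_background(SequenceSet(seqs))
    pooled = "".join(seqs.values())
    expect = np.array([pooled.count(b) for b in "ACGU"]) / len(pooled)
    assert np.allclose(bg, expect)
    with pytest.raises(ValueError):
        build_background(SequenceSet({}))


def test_planted_hexamer_recovery_and_site_localization(planted_30):
    _, truth, seqs = planted_30
    model = zoops_em(seqs, 6, config=FAST)
    assert consensus_agreement(model.consensus, "AUUGCA") >= 5
    planted = truth.table[truth.table.motif_planted]
    correct = 0
    for sid, row in planted.iterrows():
        if model.best_sites()[sid] == int(row["planted_position"]):
            correct += 1
    assert correct >= 16


def test_em_objective_monotone_and_model_invariants(planted_30):
    _, _, seqs = planted_30
    model = zoops_em(seqs, 6, config=FAST)
    trace = np.array(model.objective_trace)
    assert (np.diff(trace) >= -1e-9).all()
    assert np.allclose(model.pwm.sum(axis=1), 1.0, atol=1e-9)
    assert (model.pwm > 0).all()
    assert 0 <= model.lam <= 1
    for sid, z in model.site_posteriors.items():
        assert z.sum() + model.no_site_mass[sid] == pytest.approx(1.0, abs=1e-9)


def test_identical_sequences_give_point_mass_columns():
    seqs = SequenceSet({f"s{i}": "ACGUACGUAC" for i in range(8)})
    model = zoops_em(seqs, 4, config=FAST)
    assert model.pwm.max(axis=1).min() >= 0.95


def test_too_short_sequence_named_in_error():
    seqs = SequenceSet({"longer": "ACGUACGU", "tiny": "ACG"})
    with pytest.raises(ValueError, match="tiny"):
        zoops_em(seqs, 6, config=FAST)


def test_determinism_and_order_exchangeability(planted_30):
    _, _, seqs = planted_30
    m1 = zoops_em(seqs, 6, config=FAST)
    m2 = zoops_em(seqs, 6, config=FAST)
    assert np.array_equal(m1.pwm, m2.pwm) and m1.lam == m2.lam
    reordered = SequenceSet(dict(reversed(list(seqs.items()))))
    m3 = zoops_em(reordered, 6, config=FAST)
    assert m3.consensus == m1.consensus
    assert m3.lam == pytest.approx(m1.lam, rel=1e-6)


def test_discover_width_scan_recovers_planted(planted_30):
    _, _, seqs = planted_30
    cfg = ZoopsConfig(w_min=4, w_max=10, max_substring_starts=120,
                      n_restarts=5, n_shuffles=25,
                      shuffle_substring_starts=40, shuffle_restarts=3, seed=0)
    model = discover(seqs, cfg)
    assert model.width in (5, 6, 7)
    assert best_overlap_agreement(model.consensus, "AUUGCA") >= 5
    again = discover(seqs, cfg)
    assert np.array_equal(model.pwm, again.pwm)
    assert model.e_value == again.e_value


def test_evalue_floor_under_strong_signal_and_width_scaling(planted_30):
    cfg, truth, seqs = planted_30
    model = zoops_em(seqs, 6, config=FAST)
    e1 = motif_evalue(model, seqs, n_shuffles=25, seed=1, config=FAST)
    assert e1 == pytest.approx(1 / 26)  # reporting floor: signal saturates
    e7 = motif_evalue(model, seqs, n_shuffles=25, seed=1, config=FAST,
                      n_widths=7)
    assert e7 == pytest.approx(7 * e1)


def test_evalue_null_calibration_background_only():
    """On pure i.i.d. background input the shuffle E-value should rarely
    reach significance (<= 0.05 in at most 10% of seeds)."""
    from evsort.simulate import SimConfig, generate_count_experiment, \
        generate_sequences
    cfg_em = ZoopsConfig(max_substring_starts=80, n_restarts=3,
                         shuffle_substring_starts=40, shuffle_restarts=3)
    n_sig = 0
    evals = []
    for seed in range(20):
        sc = SimConfig(n_mirna=15, n_exported=0, seq_length_range=(20, 24),
                       seed=3000 + seed)
        _, truth = generate_count_experiment(sc)
        seqs = generate_sequences(sc, truth)
        model = zoops_em(seqs, 6, config=cfg_em)
        e = motif_evalue(model, seqs, n_shuffles=39, seed=seed, config=cfg_em)
        evals.append(e)
        n_sig += e <= 0.05
    assert n_sig <= 2
    assert float(np.median(evals)) > 0.05


def test_consensus_rules():
    assert consensus_from_pwm(np.array([[0.9, 0.03, 0.04, 0.03]])) == "A"
    assert consensus_from_pwm(np.array([[0.05, 0.45, 0.45, 0.05]])) == "s"
    assert consensus_from_pwm(np.array([[0.25, 0.25, 0.25, 0.25]])) == "n"
    assert consensus_from_pwm(np.array([[0.45, 0.05, 0.45, 0.05]])) == "r"
    # dominant but not 2x runner-up falls through to the two-base rule
    assert consensus_from_pwm(np.array([[0.5, 0.4, 0.05, 0.05]])) == "m"


def test_consensus_agreement_uses_iupac_sets():
    assert consensus_agreement("ASUGNA", "ACUGUA") == 6
    assert consensus_agreement("ACGU", "UGCA") == 0
    assert best_overlap_agreement("nnAUUGCA", "AUUGCA") == 6


def test_model_text_roundtrip(planted_30):
    _, _, seqs = planted_30
    model = zoops_em(seqs, 6, config=FAST)
    model.e_value = 0.025
    back = model_from_text(model_to_text(model))
    assert back.width == model.width
    assert np.allclose(back.pwm, model.pwm, atol=1e-6)
    assert back.e_value == pytest.approx(0.025)
    assert back.consensus == model.consensus
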
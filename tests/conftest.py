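"""Shared fixtures.

The expensive fixtures (fine-tuned desk-scale models, the uncrowding
protocol runs, the simulated behavioral cohort) are session-scoped so the
trend tests and the acceptance tests share one computation.
"""

import numpy as np
import pandas as pd
import pytest

from gaborpath import model_zoo, probe, psychophysics as psy, stimuli, uncrowding

# desk-scale trend configuration: 128-px displays on an 8x8 grid, straight
# contours, toy twins fine-tuned from the flattened relu5 point
TREND_SEEDS = (0, 1, 2)
TREND_TRAIN_PAIRS = 200
TREND_TEST_PAIRS = 50
TREND_CFG = dict(layer="relu5", mode="finetune", epochs=15,
                 learning_rate=1e-3, optimizer="adamw")

UNCROWD_SEEDS = (0, 1, 2, 3, 4)
UNCROWD_CFG = uncrowding.UncrowdingConfig(
    canvas_size=96, counts=(1,), offset=4, n_train=600,
    n_test_per_condition=100, seed=0)


@pytest.fixture(scope="session")
def desk_train_ds():
    return probe.make_contour_dataset([0], TREND_TRAIN_PAIRS, seed=11)


@pytest.fixture(scope="session")
def desk_test_ds():
    return probe.make_contour_dataset([0], TREND_TEST_PAIRS, seed=99)


@pytest.fixture(scope="session")
def desk_test_jittered():
    return {j: probe.make_contour_dataset([0], TREND_TEST_PAIRS, seed=99,
                                          jitter=j)
            for j in (0, 4, 8)}


@pytest.fixture(scope="session")
def trend_models(desk_train_ds, desk_test_ds):
    """Fine-tuned full-RF and pinhole toy twins for each trend seed;
    returns {kind: {seed: (model, head, test_accuracy)}}."""
    out = {}
    for kind in ("full", "pinhole"):
        out[kind] = {}
        for seed in TREND_SEEDS:
            model, _ = model_zoo.make_toy_net(kind, seed=seed)
            cfg = probe.ProbeConfig(seed=seed, **TREND_CFG)
            head = probe.train_readout(model, desk_train_ds, cfg)
            rep = probe.evaluate(head, model, cfg.layer, desk_test_ds,
                                 train_pair_ids=desk_train_ds.pair_ids)
            out[kind][seed] = (model, head, rep.accuracy)
    return out


@pytest.fixture(scope="session")
def uncrowding_runs():
    """Per-seed accuracy tables from the desk uncrowding protocol."""
    runs = {}
    for seed in UNCROWD_SEEDS:
        model, _ = model_zoo.make_vernier_net(
            input_size=UNCROWD_CFG.canvas_size, seed=seed)
        pcfg = probe.ProbeConfig(layer="pool4", mode="finetune", epochs=12,
                                 learning_rate=1e-3, optimizer="adamw",
                                 batch_size=8, seed=seed)
        runs[seed] = uncrowding.run_protocol(model, "pool4", UNCROWD_CFG,
                                             pcfg).set_index("condition")
    return runs


@pytest.fixture(scope="session")
def behavioral_set():
    return stimuli.build_behavioral_set(seed=5)


@pytest.fixture(scope="session")
def cohort(behavioral_set):
    """Simulated 2-IFC cohort: 50 observers spread over the 5 behavioral
    splits, Weibull threshold 45 deg / slope 2 / lapse 0.02, shared
    per-pair difficulty offsets of SD 0.5 logit units."""
    beh = behavioral_set
    rng = np.random.default_rng(7)
    splits = {s: beh[beh["split"] == s] for s in range(5)}
    sessions, splits_of, params = {}, {}, []
    for pid in range(50):
        s = pid % 5
        sessions[pid] = psy.build_session(splits[s], seed=1000 + pid)
        splits_of[pid] = s
        params.append(psy.ObserverParams(weibull_threshold=45.0,
                                         weibull_slope=2.0, lapse_rate=0.02,
                                         trial_difficulty_sd=0.5,
                                         seed=2000 + pid))
    difficulties = psy.make_trial_difficulties(beh["pair_id"], 0.5, rng)
    responses = psy.simulate_observers(params, sessions, difficulties,
                                       splits_of)
    return {"responses": responses, "difficulties": difficulties,
            "sessions": sessions, "params": params, "behavioral": beh}
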
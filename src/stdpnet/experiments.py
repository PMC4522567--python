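"""End-to-end experiment drivers on the synthetic fixture.

These functions wire the full pipeline — synthetic data, encoding, training,
labeling, rate-vote evaluation — into single calls used by the test suite,
the acceptance script, and the CLI.  Problem sizes default to a scaled-down
regime (5 classes, 25 excitatory neurons, hundreds of presentations) that
exercises every mechanism of the full-scale digit setup while remaining
desk-runnable.
"""

from __future__ import annotations

import numpy as np

from . import evaluation as ev
from .config import preset
from .data_io import SyntheticSpec, generate_synthetic
from .network import build_network, train_network

__all__ = [
    "build_synthetic_network",
    "run_synthetic_experiment",
    "run_stability_experiment",
]


def _spawn(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def build_synthetic_network(rule_id: str, n_exc: int, seed: int, **overrides):
    cfg = preset(n_exc, rule_id, **overrides)
    return build_network(
        cfg.network,
        seed=seed,
        exc_params=cfg.exc_neuron,
        inh_params=cfg.inh_neuron,
        homeo=cfg.homeostasis,
        rule=cfg.rule,
    )


def run_synthetic_experiment(
    rule_id: str = "powerlaw",
    n_exc: int = 25,
    n_train: int = 600,
    n_assign: int = 250,
    n_test: int = 150,
    n_classes: int = 5,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
    **config_overrides,
) -> dict:
    """Train on the synthetic fixture and evaluate by rate vote.

    Returns a dict with the trained network, the labeled assignment, the
    test accuracy/confusion matrix, receptive-field template matches, and
    the spike-sparsity report.
    """
    seeds = _spawn(seed, 5)
    data_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    if spec is None:
        spec = SyntheticSpec(n_classes=n_classes, seed=data_seed)
    n_per_train = -(-n_train // spec.n_classes)
    train_imgs, train_labels = generate_synthetic(spec, n_per_train)
    train_imgs, train_labels = train_imgs[:n_train], train_labels[:n_train]

    eval_spec = SyntheticSpec(
        n_classes=spec.n_classes,
        image_side=spec.image_side,
        stroke_templates=spec.stroke_templates,
        intensity_high=spec.intensity_high,
        jitter_px=spec.jitter_px,
        noise_flip_prob=spec.noise_flip_prob,
        seed=(data_seed + 1) % (2**31),
    )
    n_per_eval = -(-(n_assign + n_test) // spec.n_classes)
    eval_imgs, eval_labels = generate_synthetic(eval_spec, n_per_eval)
    assign_imgs, assign_labels = eval_imgs[:n_assign], eval_labels[:n_assign]
    test_imgs, test_labels = (
        eval_imgs[n_assign : n_assign + n_test],
        eval_labels[n_assign : n_assign + n_test],
    )

    net_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    net = build_synthetic_network(rule_id, n_exc, net_seed, **config_overrides)

    train_records = train_network(net, train_imgs, rng=np.random.default_rng(seeds[2]))
    assign_records = ev.collect_records(net, assign_imgs, rng=np.random.default_rng(seeds[3]))
    assignment = ev.assign_labels(assign_records, assign_labels, spec.n_classes)
    test_records = ev.collect_records(net, test_imgs, rng=np.random.default_rng(seeds[4]))
    predictions = ev.predict_batch(test_records, assignment)
    cm, accuracy = ev.confusion_and_accuracy(predictions, test_labels, spec.n_classes)
    sparsity = ev.spike_sparsity_report(test_records, predictions, test_labels, assignment)
    template_match = ev.best_template_match(
        net.w, spec.stroke_templates.astype(float), max_shift=spec.jitter_px
    )
    return {
        "net": net,
        "spec": spec,
        "assignment": assignment,
        "accuracy": accuracy,
        "confusion": cm,
        "predictions": predictions,
        "test_labels": test_labels,
        "train_records": train_records,
        "train_labels": train_labels,
        "sparsity": sparsity,
        "template_match": template_match,
    }


def run_stability_experiment(
    rule_id: str = "prepost",
    n_exc: int = 25,
    n_train: int = 3000,
    block_size: int = 300,
    n_classes: int = 5,
    seed: int = 0,
    **config_overrides,
) -> dict:
    """Prolonged training with a trailing-block training-accuracy curve.

    Each block of training responses is classified using neuron labels
    assigned from the preceding block, tracing learning stability over the
    stream without separate evaluation passes.
    """
    seeds = _spawn(seed, 3)
    data_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    spec = SyntheticSpec(n_classes=n_classes, seed=data_seed)
    n_per = -(-n_train // n_classes)
    imgs, labels = generate_synthetic(spec, n_per)
    imgs, labels = imgs[:n_train], labels[:n_train]

    net_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    net = build_synthetic_network(rule_id, n_exc, net_seed, **config_overrides)
    records = train_network(net, imgs, rng=np.random.default_rng(seeds[2]))
    curve = ev.trailing_block_accuracy(records, labels, block_size, n_classes)
    return {"net": net, "curve": curve, "records": records, "labels": labels}
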
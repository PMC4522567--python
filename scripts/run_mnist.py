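"""Full-scale digit benchmark run (100 excitatory neurons).

NOT part of the test suite: it needs the external handwritten-digit dataset
(IDX files) on disk and several hours of CPU time.  Download the four files
of the standard 60k/10k digit benchmark, gunzip them, and point this script
at the directory:

    python scripts/run_mnist.py --data-dir mnist/ --out runs/mnist100 \
        --presentations 40000 --n-exc 100 --seed 0

Expected files in --data-dir:
    train-images-idx3-ubyte   train-labels-idx1-ubyte
    t10k-images-idx3-ubyte    t10k-labels-idx1-ubyte

With 100 excitatory neurons, the power-law rule and 40 000 training
presentations, a rate-vote accuracy in the low-to-mid 80 % range on the
10 000-image test set is the expected outcome of this configuration.
"""

from __future__ import annotations

import argparse
import json
import pathlib

import numpy as np


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=pathlib.Path, required=True)
    parser.add_argument("--out", type=pathlib.Path, default=pathlib.Path("runs/mnist100"))
    parser.add_argument("--n-exc", type=int, default=100)
    parser.add_argument("--rule", default="powerlaw",
                        choices=("powerlaw", "expdep", "prepost", "triplet"))
    parser.add_argument("--presentations", type=int, default=40000)
    parser.add_argument("--n-test", type=int, default=10000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    from stdpnet import evaluation as ev
    from stdpnet.config import preset
    from stdpnet.data_io import read_idx, save_weights
    from stdpnet.network import build_network, train_network

    train_images, train_labels = read_idx(
        args.data_dir / "train-images-idx3-ubyte",
        args.data_dir / "train-labels-idx1-ubyte",
        n_classes=10,
    )
    test_images, test_labels = read_idx(
        args.data_dir / "t10k-images-idx3-ubyte",
        args.data_dir / "t10k-labels-idx1-ubyte",
        n_classes=10,
    )

    cfg = preset(args.n_exc, args.rule)
    net = build_network(cfg.network, seed=args.seed, exc_params=cfg.exc_neuron,
                        inh_params=cfg.inh_neuron, homeo=cfg.homeostasis,
                        rule=cfg.rule)
    args.out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed + 1)

    # unsupervised training over (repeats of) the training set
    order = np.resize(np.arange(len(train_images)), args.presentations)
    train_network(net, train_images[order], rng=rng,
                  log_path=args.out / "train.log",
                  epoch_summary_path=args.out / "train_summary.json")
    save_weights(args.out / "weights.npz", net.w, net.exc.theta,
                 rule_id=args.rule, seed=args.seed,
                 n_presentations=net.n_presentations)

    # labeled assignment pass over one presentation of the training set,
    # then rate-vote evaluation on the test set
    assign_records = ev.collect_records(net, train_images, rng)
    assignment = ev.assign_labels(assign_records, train_labels, 10)
    test_records = ev.collect_records(net, test_images[: args.n_test], rng)
    preds = ev.predict_batch(test_records, assignment)
    cm, acc = ev.confusion_and_accuracy(preds, test_labels[: args.n_test], 10)

    report = {
        "accuracy": acc,
        "confusion": cm.counts.tolist(),
        "sparsity": ev.spike_sparsity_report(
            test_records, preds, test_labels[: args.n_test], assignment
        ),
    }
    (args.out / "evaluation.json").write_text(json.dumps(report, indent=2))
    ev.receptive_field_grid(net.w, args.out / "receptive_fields.png")
    print(f"test accuracy: {acc:.4f}")


if __name__ == "__main__":
    main()
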
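"""Post-hoc neuron labeling, rate-vote classification, and analysis.

The network never sees labels during synaptic learning.  Afterwards, each
excitatory neuron is assigned the class to which it responded most strongly
(on average) over a labeled assignment pass with learning off and the
adaptive threshold frozen.  A test presentation is then classified by
averaging the spike counts of the neurons assigned to each class and taking
the class with the highest average — a pure rate vote, with no trained
readout on top of the spiking network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .encoding import present_with_retry

__all__ = [
    "LabeledAssignment",
    "ConfusionMatrix",
    "assign_labels",
    "predict",
    "predict_batch",
    "confusion_and_accuracy",
    "receptive_fields",
    "receptive_field_grid",
    "best_template_match",
    "spike_sparsity_report",
    "collect_records",
    "trailing_block_accuracy",
]


@dataclass
class LabeledAssignment:
    """Neuron -> class map plus the mean response of each neuron per class."""

    label_of_neuron: np.ndarray        # (n_neurons,) int
    class_response_matrix: np.ndarray  # (n_neurons, n_classes) mean spike counts

    @property
    def n_classes(self) -> int:
        return self.class_response_matrix.shape[1]


@dataclass
class ConfusionMatrix:
    """Counts per (true class, predicted class)."""

    counts: np.ndarray

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")


def _counts_matrix(records) -> np.ndarray:
    return np.stack([np.asarray(r.counts) for r in records])


def assign_labels(records, true_labels, n_classes: int | None = None) -> LabeledAssignment:
    """Label each neuron by its highest mean response over the labeled set.

    Ties are broken toward the lowest class index; a neuron that never
    spiked is assigned class 0 with a warning.
    """
    true_labels = np.asarray(true_labels)
    counts = _counts_matrix(records)
    if counts.shape[0] != true_labels.shape[0]:
        raise ValueError("records and true_labels must have equal length")
    if n_classes is None:
        n_classes = int(true_labels.max()) + 1
    response = np.zeros((counts.shape[1], n_classes))
    for c in range(n_classes):
        mask = true_labels == c
        if mask.any():
            response[:, c] = counts[mask].mean(axis=0)
    silent = ~response.any(axis=1)
    if silent.any():
        warnings.warn(
            f"{int(silent.sum())} neuron(s) never spiked on the assignment set; "
            "assigned class 0",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = response.argmax(axis=1)  # argmax returns the lowest index on ties
    return LabeledAssignment(label_of_neuron=labels, class_response_matrix=response)


def _class_scores(counts: np.ndarray, a: LabeledAssignment) -> np.ndarray:
    scores = np.zeros(a.n_classes)
    for c in range(a.n_classes):
        members = a.label_of_neuron == c
        if members.any():
            scores[c] = counts[members].mean()
    return scores


def predict(record, a: LabeledAssignment) -> int:
    """Rate vote: the class whose assigned neurons fired most on average.

    Ties (including the all-silent record) resolve to the lowest class
    index; classes with no assigned neurons score zero.
    """
    return int(np.argmax(_class_scores(np.asarray(record.counts), a)))


def predict_batch(records, a: LabeledAssignment) -> np.ndarray:
    return np.array([predict(r, a) for r in records])


def confusion_and_accuracy(predictions, truths, n_classes: int | None = None):
    """Tally the confusion matrix and overall accuracy."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    if n_classes is None:
        n_classes = int(max(predictions.max(), truths.max())) + 1
    if predictions.max(initial=0) >= n_classes or truths.max(initial=0) >= n_classes:
        raise ValueError("label outside the class set")
    counts = _sk_confusion(truths, predictions, labels=np.arange(n_classes))
    cm = ConfusionMatrix(counts=counts)
    return cm, cm.accuracy


def receptive_fields(w: np.ndarray, side: int | None = None) -> np.ndarray:
    """Reshape each neuron's incoming weight vector into a square image.

    Column j of the (n_input, n_exc) matrix becomes image j, row-major —
    the inverse of flattening the input image, so a neuron whose weights
    copy a stimulus template displays that template.
    """
    n_input, n_exc = w.shape
    if side is None:
        side = int(round(n_input ** 0.5))
    if side * side != n_input:
        raise ValueError(f"n_input={n_input} is not a square image")
    return w.T.reshape(n_exc, side, side)


def receptive_field_grid(w: np.ndarray, path, side: int | None = None) -> None:
    """Tile all receptive fields into one PNG figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fields = receptive_fields(w, side)
    n = fields.shape[0]
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(1.2 * ncols, 1.2 * nrows))
    for k, ax in enumerate(np.atleast_1d(axes).ravel()):
        ax.axis("off")
        if k < n:
            ax.imshow(fields[k], cmap="hot_r", interpolation="nearest")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def best_template_match(
    w: np.ndarray, templates: np.ndarray, max_shift: int = 0
) -> np.ndarray:
    """Cosine similarity between each template and its best-matching field.

    Returns one value per template: the maximum over neurons (and, when
    ``max_shift`` > 0, over integer translations up to ``max_shift`` pixels
    per axis) of the cosine between the template and a receptive field.
    When the stimuli were jittered translations of the templates, prototypes
    are only identifiable up to that translation group, so recovery is
    scored against the best-aligned copy of each template.
    """
    templates = np.asarray(templates, dtype=np.float64)
    flat_w = w.T.astype(np.float64)  # (n_exc, n_input)
    wn = np.linalg.norm(flat_w, axis=1)
    wn[wn == 0] = np.inf
    shifts = range(-max_shift, max_shift + 1)
    best = np.zeros(templates.shape[0])
    for k, tmpl in enumerate(templates):
        for dr in shifts:
            for dc in shifts:
                shifted = np.zeros_like(tmpl)
                side = tmpl.shape[0]
                r0, r1 = max(dr, 0), side + min(dr, 0)
                c0, c1 = max(dc, 0), side + min(dc, 0)
                shifted[r0:r1, c0:c1] = tmpl[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
                flat_t = shifted.ravel()
                norm = np.linalg.norm(flat_t)
                if norm == 0:
                    continue
                cos = flat_w @ flat_t / (wn * norm)
                best[k] = max(best[k], float(cos.max()))
    return best


def collect_records(net, images, rng, retry: bool = True):
    """Evaluation pass: learning off, theta frozen, one record per image.

    The minimum-response retry boost stays active by default (configurable),
    so weak test stimuli are re-presented at higher rates just as during
    training.
    """
    net.set_evaluation_mode(True)
    records = []
    try:
        for img in images:
            if retry:
                record, _ = present_with_retry(net, img, learning=False, rng=rng)
            else:
                from .encoding import intensity_to_rate, sample_poisson_raster

                rate_map = intensity_to_rate(img, net.cfg.intensity_divisor)
                raster = sample_poisson_raster(
                    rate_map, net.cfg.presentation_ms, net.cfg.dt, rng
                )
                record = net.run_presentation(raster, learning=False)
            net.run_rest()
            records.append(record)
    finally:
        net.set_evaluation_mode(False)
    return records


def trailing_block_accuracy(records, labels, block_size: int, n_classes: int | None = None):
    """Training-accuracy curve: each block is classified with neuron labels
    assigned from the immediately preceding block of training responses.

    Returns a list of ``(end_presentation_index, accuracy)`` starting at the
    second block.  Mirrors monitoring learning stability on a running stream
    without a separate evaluation pass.
    """
    labels = np.asarray(labels)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    out = []
    n = len(records)
    for end in range(2 * block_size, n + 1, block_size):
        assign_slice = slice(end - 2 * block_size, end - block_size)
        eval_slice = slice(end - block_size, end)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = assign_labels(records[assign_slice], labels[assign_slice], n_classes)
        preds = predict_batch(records[eval_slice], a)
        _, acc = confusion_and_accuracy(preds, labels[eval_slice], n_classes)
        out.append((end, acc))
    return out


def spike_sparsity_report(records, predictions, truths, a: LabeledAssignment) -> dict:
    """Spike-economy statistics of the classifier's responses.

    Reports the mean total spikes per presentation and, separately for
    correctly and incorrectly classified presentations, the mean number of
    spikes from neurons assigned to the true class versus other classes.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    counts = _counts_matrix(records)
    same = np.array(
        [counts[i][a.label_of_neuron == truths[i]].sum() for i in range(len(truths))]
    )
    other = counts.sum(axis=1) - same
    correct = predictions == truths

    def _mean(x, mask):
        return float(x[mask].mean()) if mask.any() else float("nan")

    return {
        "mean_spikes_per_presentation": float(counts.sum(axis=1).mean()),
        "correct": {
            "mean_same_class_spikes": _mean(same, correct),
            "mean_other_class_spikes": _mean(other, correct),
        },
        "incorrect": {
            "mean_same_class_spikes": _mean(same, ~correct),
            "mean_other_class_spikes": _mean(other, ~correct),
        },
        "n_correct": int(correct.sum()),
        "n_total": int(len(truths)),
    }
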
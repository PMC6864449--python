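"""A sequential network with categorical cross-entropy training."""

from __future__ import annotations

import numpy as np

from .layers import Layer, softmax
from .optim import clip_gradients, make_optimizer

__all__ = ["SequentialNet", "cross_entropy"]


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of softmax outputs against integer
    labels."""
    eps = 1e-12
    n = len(labels)
    return float(-np.mean(np.log(probs[np.arange(n), labels] + eps)))


class SequentialNet:
    """Layers applied in order, ending in a linear (logit) output; softmax
    and the cross-entropy loss are applied here rather than as a layer so
    the backward pass can use the combined ``p - y`` gradient."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.history: list[dict[str, float]] = []

    # -- inference ---------------------------------------------------------
    def logits(self, x: np.ndarray, *, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-class probability rows (each sums to 1); deterministic —
        dropout is inactive outside training."""
        return softmax(self.logits(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax labels; np.argmax breaks ties toward the lowest index."""
        return np.argmax(self.predict_proba(x), axis=1)

    # -- training ----------------------------------------------------------
    def snapshot(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()}
                for layer in self.layers]

    def restore(self, snapshot: list[dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self.layers, snapshot):
            layer.params = {k: v.copy() for k, v in params.items()}

    def fit(
        self,
        x: np.ndarray,
        labels: np.ndarray,
        *,
        epochs: int = 50,
        batch_size: int = 32,
        optimizer: str = "adam",
        learning_rate: float = 1e-3,
        lr_decay: float = 1.0,
        clip_norm: float = 5.0,
        seed: int = 0,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        restore_best: bool = False,
        swa_start: int | None = None,
        augment=None,
        verbose: bool = False,
    ) -> "SequentialNet":
        """Mini-batch training with cross-entropy loss.

        ``lr_decay`` multiplies the learning rate once per epoch (1.0 =
        constant).  With ``restore_best`` and a validation set, the
        parameters giving the best validation accuracy (ties broken by
        loss) are restored after the final epoch — long recurrent runs
        can destabilise late, and the snapshot guards against handing
        back a collapsed model.

        ``augment`` is an optional callable ``(batch, rng) -> batch``
        applied to each training mini-batch (never to validation or
        inference inputs).

        With ``swa_start`` set, parameters are additionally averaged over
        every epoch from that index on (stochastic weight averaging); the
        averaged weights are kept if they validate at least as well as the
        best single epoch.
        """
        labels = np.asarray(labels, dtype=np.int64)
        if len(np.unique(labels)) < 2:
            raise ValueError("training set must contain at least two classes")
        n = len(labels)
        n_classes = self.layers[-1].params["W"].shape[1]
        opt = make_optimizer(optimizer, learning_rate)
        rng = np.random.default_rng(seed)
        best = (-1.0, np.inf, None)  # (val acc, val loss, snapshot)
        swa_sum: list[dict[str, np.ndarray]] | None = None
        swa_count = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            epoch_correct = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], labels[idx]
                if augment is not None:
                    xb = augment(xb, rng)
                logits = self.logits(xb, train=True, rng=rng)
                probs = softmax(logits)
                loss = cross_entropy(probs, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"loss became non-finite at epoch {epoch + 1}; "
                        "lower the learning rate or tighten clip_norm"
                    )
                onehot = np.zeros((len(yb), n_classes), dtype=np.float32)
                onehot[np.arange(len(yb)), yb] = 1.0
                dlogits = (probs.astype(np.float32) - onehot) / len(yb)
                dout = dlogits
                for layer in reversed(self.layers):
                    dout = layer.backward(dout)
                clip_gradients(self.layers, clip_norm)
                opt.step(self.layers)
                epoch_loss += loss * len(yb)
                epoch_correct += int(np.sum(np.argmax(probs, axis=1) == yb))
            entry = {
                "epoch": epoch + 1,
                "loss": epoch_loss / n,
                "accuracy": epoch_correct / n,
            }
            if validation is not None:
                xv, yv = validation
                pv = self.predict_proba(xv)
                entry["val_loss"] = cross_entropy(pv, yv)
                entry["val_accuracy"] = float(np.mean(np.argmax(pv, 1) == yv))
                if restore_best and (
                    entry["val_accuracy"] > best[0]
                    or (entry["val_accuracy"] == best[0]
                        and entry["val_loss"] < best[1])
                ):
                    best = (entry["val_accuracy"], entry["val_loss"],
                            self.snapshot())
            self.history.append(entry)
            opt.lr *= lr_decay
            if swa_start is not None and epoch >= swa_start:
                if swa_sum is None:
                    swa_sum = self.snapshot()
                else:
                    for layer, acc in zip(self.layers, swa_sum):
                        for k in acc:
                            acc[k] += layer.params[k]
                swa_count += 1
            if verbose:
                print(
                    "  epoch {epoch:3d}  loss {loss:.4f}  acc {accuracy:.3f}".format(
                        **entry
                    )
                    + (
                        "  val_acc {val_accuracy:.3f}".format(**entry)
                        if validation is not None
                        else ""
                    )
                )
        if swa_sum is not None and swa_count > 1:
            swa_params = [
                {k: v / swa_count for k, v in acc.items()} for acc in swa_sum
            ]
            if validation is not None:
                final = self.snapshot()
                self.restore(swa_params)
                xv, yv = validation
                pv = self.predict_proba(xv)
                swa_acc = float(np.mean(np.argmax(pv, 1) == yv))
                swa_loss = cross_entropy(pv, yv)
                candidate_best = (
                    best if restore_best
                    else (self.history[-1].get("val_accuracy", -1.0),
                          self.history[-1].get("val_loss", np.inf), final)
                )
                if (swa_acc, -swa_loss) < (candidate_best[0], -candidate_best[1]):
                    self.restore(candidate_best[2] or final)
                return self
            self.restore(swa_params)
            return self
        if restore_best and best[2] is not None:
            self.restore(best[2])
        return self
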
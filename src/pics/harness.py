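"""Shared training harness: epoch loop, early stopping, best-snapshot rule.

All three trainable stages follow the same discipline, differing only in the
monitored quantity and its direction:

* translation — fixed epoch budget (optionally patience on validation loss),
  keep the weights with the *lowest* validation loss;
* detection — stop when validation mAP has not *increased* for ``patience``
  consecutive epochs, keep the weights with the highest validation mAP;
* segmentation — stop when validation loss has not *decreased* for
  ``patience`` consecutive epochs, keep the weights with the lowest loss.

Improvement is strict; the counter resets on every improvement.  The
returned snapshot is always the one recorded at the best epoch, never the
last one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

__all__ = ["EpochRecord", "FitResult", "fit_loop"]


@dataclass
class EpochRecord:
    epoch: int  # 1-based
    train_metric: float
    val_metric: float


@dataclass
class FitResult:
    best_state: object
    best_epoch: int
    best_val: float
    log: list[EpochRecord] = field(default_factory=list)
    stopped_early: bool = False


def fit_loop(
    train_epoch: Callable[[int], float],
    evaluate: Callable[[int], float],
    snapshot: Callable[[], object],
    max_epochs: int,
    patience: int | None = None,
    mode: str = "min",
) -> FitResult:
    """Run the epoch loop with strict-improvement early stopping.

    ``train_epoch(epoch)`` performs one pass and returns the training metric;
    ``evaluate(epoch)`` returns the validation metric; ``snapshot()`` captures
    the current weights (called only when the metric improves).  ``mode`` is
    ``"min"`` (loss) or ``"max"`` (mAP).  With ``patience`` None the loop
    always runs ``max_epochs`` epochs.
    """
    if mode not in ("min", "max"):
        raise ValueError(f"mode must be 'min' or 'max', got {mode!r}")
    if patience is not None and patience < 1:
        raise ValueError("patience must be >= 1")
    better = (lambda a, b: a < b) if mode == "min" else (lambda a, b: a > b)

    log: list[EpochRecord] = []
    best_val = None
    best_state = None
    best_epoch = 0
    wait = 0
    stopped = False
    for epoch in range(1, max_epochs + 1):
        train_metric = train_epoch(epoch)
        val_metric = evaluate(epoch)
        log.append(EpochRecord(epoch, float(train_metric), float(val_metric)))
        if best_val is None or better(val_metric, best_val):
            best_val = float(val_metric)
            best_state = snapshot()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if patience is not None and wait >= patience:
                stopped = True
                break
    if best_epoch == 0:
        raise RuntimeError("no epochs were run")
    return FitResult(
        best_state=best_state,
        best_epoch=best_epoch,
        best_val=best_val,
        log=log,
        stopped_early=stopped,
    )
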
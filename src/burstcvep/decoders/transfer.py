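"""Cross-participant pretrain / fine-tune procedure.

A classifier is first fit on one source participant's full training data,
then adapted on the target's two calibration runs.  For the gradient-trained
models this continues optimization with a budget matching within-participant
training; for TS-LDA (closed form, no gradients) the tangent reference and
the discriminant are refit on the pooled data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pretrain_finetune"]


def pretrain_finetune(
    model,
    X_source: np.ndarray,
    y_source: np.ndarray,
    X_calib: np.ndarray,
    y_calib: np.ndarray,
    finetune_epochs: int | None = None,
):
    """Fit ``model`` on source data, then fine-tune on target calibration.

    ``model`` must implement ``fit`` and ``finetune``.  ``finetune_epochs``
    caps the adaptation budget for gradient-trained models (None uses the
    model's own training budget; 0 returns the pretrained model unchanged).
    """
    if not hasattr(model, "finetune"):
        raise TypeError(f"{type(model).__name__} does not support fine-tuning")
    model.fit(np.asarray(X_source), np.asarray(y_source))
    from .tslda import TSLDAClassifier

    if isinstance(model, TSLDAClassifier):
        if finetune_epochs == 0:
            return model
        return model.finetune(X_calib, y_calib, X_extra=X_source, y_extra=y_source)
    return model.finetune(X_calib, y_calib, n_epochs=finetune_epochs)
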
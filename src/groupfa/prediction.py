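"""Multi-output and missing-data prediction from a fitted model.

An unobserved group of new samples is predicted through the approximate
predictive expectation: the latent posterior for each test sample is
formed from the observed groups using the training-posterior loading and
noise moments, and the target group's expectation is ``<W> mu_z``. The
same machinery fills missing cells of the training data, conditioning on
the *other* groups' observed cells. Masked cells of the conditioning
groups are simply dropped from the sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import GroupedDataset
from .gfa import GFA, GFAPosterior, latent_posterior

__all__ = ["PredictionResult", "predict_group", "predict_missing", "chance_level"]


@dataclass
class PredictionResult:
    """Predicted matrix for one group plus per-variable error summaries."""

    predicted: np.ndarray          # (Dm, N*)
    target: int
    mse: np.ndarray = None         # per-variable, vs observed truth if available
    chance_mse: np.ndarray = None


def _posterior_of(model) -> GFAPosterior:
    if isinstance(model, GFA):
        return model.posterior_
    if isinstance(model, GFAPosterior):
        return model
    raise TypeError("model must be a fitted GFA or a GFAPosterior")


def predict_group(model, observed: GroupedDataset, target: int,
                  truth: np.ndarray | None = None) -> PredictionResult:
    """Predict group ``target`` of new samples from the other groups.

    ``observed`` carries all groups (the target's values/mask are ignored).
    If ``truth`` is given, per-variable MSE against it is reported.
    """
    post = _posterior_of(model)
    if not 0 <= target < post.n_groups:
        raise IndexError(f"target group {target} out of range")
    if post.n_groups < 2:
        raise ValueError("prediction needs at least one observed group")
    z_mean, _ = latent_posterior(post, observed, exclude_groups=[target])
    pred = post.W_mean[target] @ z_mean
    mse = None
    if truth is not None:
        truth = np.asarray(truth, dtype=float)
        mse = np.mean((truth - pred) ** 2, axis=1)
    return PredictionResult(predicted=pred, target=target, mse=mse)


def predict_missing(model, data: GroupedDataset) -> GroupedDataset:
    """Fill the masked cells of ``data`` with model expectations.

    For each group with missing cells, the latent posterior of every
    sample is computed from the observed cells of the *other* groups, and
    the masked cells are replaced with ``<W> mu_z``; observed cells are
    untouched. Fully observed data is returned unchanged.
    """
    post = _posterior_of(model)
    out = data.copy()
    for m in range(data.n_groups):
        missing = ~data.masks[m]
        if not missing.any():
            continue
        z_mean, _ = latent_posterior(post, data, exclude_groups=[m])
        recon = post.W_mean[m] @ z_mean
        out.groups[m][missing] = recon[missing]
        out.masks[m] = np.ones_like(data.masks[m])
    return out


def chance_level(train: GroupedDataset, test: GroupedDataset, target: int,
                 metric: str = "mse") -> np.ndarray:
    """Error of the train-mean predictor on the test set, per variable.

    ``metric='mse'`` is the plain mean squared error; ``'rmse'`` is the
    relative MSE (error energy over true-signal energy).
    """
    if not np.array_equal(train.variable_ids[target], test.variable_ids[target]):
        raise ValueError("train and test must share the target's variable ids")
    tr_x, tr_mask = train.groups[target], train.masks[target]
    means = np.array(
        [tr_x[j, tr_mask[j]].mean() for j in range(tr_x.shape[0])]
    )
    te_x, te_mask = test.groups[target], test.masks[target]
    out = np.empty(te_x.shape[0])
    for j in range(te_x.shape[0]):
        truth = te_x[j, te_mask[j]]
        err = np.mean((truth - means[j]) ** 2)
        if metric == "mse":
            out[j] = err
        elif metric == "rmse":
            denom = np.mean(truth ** 2)
            if denom == 0:
                raise ValueError(f"variable {test.variable_ids[target][j]} has zero energy")
            out[j] = err / denom
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out
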
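"""Factor relevance, classification, matching and error metrics.

Two complementary relevance measures rank fitted factors:

* ``rvar`` — relative variance explained by factor k within group m,
  ``w_k^T w_k / Tr(W W^T)``, which sums to 100% over factors per group;
* ``var`` — variance explained including the noise floor,
  ``w_k^T w_k / Tr(W W^T + T^-1)``, whose group-2/group-1 ratio ``r_k``
  labels a factor shared (ratio within bounds) or group-specific
  (ratio beyond either bound).

Matching of inferred factors to a reference (e.g. the generating latent
time-courses) is by maximum absolute Pearson correlation with sign
flipping, so the permutation/sign non-identifiability of factor models
does not obscure recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gfa import GFA, GFAPosterior

__all__ = [
    "FactorReport",
    "relative_variance",
    "explained_variance_ratio",
    "classify_factors",
    "match_factors",
    "FactorMatch",
    "multi_output_error",
]

DEFAULT_RVAR_THRESHOLD = 7.5          # percent, within any one group
DEFAULT_RATIO_BOUNDS = (0.001, 300.0)  # shared iff lower <= r_k <= upper


def _posterior_of(model) -> GFAPosterior:
    if isinstance(model, GFA):
        return model.posterior_
    if isinstance(model, GFAPosterior):
        return model
    raise TypeError("model must be a fitted GFA or a GFAPosterior")


@dataclass
class FactorReport:
    """Per-factor relevance statistics and labels for a fitted model."""

    rvar: np.ndarray               # (M, K) percent, sums to 100 per group
    var: np.ndarray                # (M, K) percent of total incl. noise
    ratio: np.ndarray              # (K,) var group2 / var group1
    most_relevant: np.ndarray = None   # (K,) bool
    labels: list = field(default_factory=list)  # 'shared' | 'specific:g<m>'


def relative_variance(model, group: int) -> np.ndarray:
    """Percentage of loading energy carried by each factor within a group."""
    post = _posterior_of(model)
    w = post.W_mean[group]
    col = np.sum(w ** 2, axis=0)
    total = col.sum()
    if total == 0:
        raise ValueError(f"group {group}: zero total loading energy")
    return 100.0 * col / total


def _var_with_noise(post: GFAPosterior, group: int) -> np.ndarray:
    w = post.W_mean[group]
    col = np.sum(w ** 2, axis=0)
    total = col.sum() + np.sum(1.0 / post.tau_mean(group))
    if total == 0:
        raise ValueError(f"group {group}: zero total variance")
    return 100.0 * col / total


def explained_variance_ratio(model, factor: int | None = None):
    """Ratio of variance explained in group 2 over group 1 (M=2 only).

    Zero loadings in group 1 yield ``inf`` (a group-2-specific factor).
    """
    post = _posterior_of(model)
    if post.n_groups != 2:
        raise ValueError("the variance ratio is defined for exactly two groups")
    v1 = _var_with_noise(post, 0)
    v2 = _var_with_noise(post, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(v1 > 0, v2 / v1, np.inf)
    r = np.where((v1 == 0) & (v2 == 0), np.nan, r)
    return r if factor is None else float(r[factor])


def classify_factors(model, rvar_threshold: float = DEFAULT_RVAR_THRESHOLD,
                     ratio_bounds=DEFAULT_RATIO_BOUNDS) -> FactorReport:
    """Build a :class:`FactorReport` with relevance flags and labels.

    A factor is *most relevant* if its rvar exceeds ``rvar_threshold``
    in any group; it is *shared* if the variance ratio lies inside
    ``ratio_bounds``, otherwise specific to the group it loads on.
    """
    post = _posterior_of(model)
    rvar = np.stack([relative_variance(post, m) for m in range(post.n_groups)])
    var = np.stack([_var_with_noise(post, m) for m in range(post.n_groups)])
    ratio = explained_variance_ratio(post)
    lo, hi = ratio_bounds
    most = (rvar > rvar_threshold).any(axis=0)
    labels = []
    for k in range(post.n_factors):
        r = ratio[k]
        if np.isnan(r):
            labels.append("pruned")
        elif lo <= r <= hi:
            labels.append("shared")
        elif r > hi:
            labels.append("specific:g1")   # loads (almost) only on group 2
        else:
            labels.append("specific:g0")   # loads (almost) only on group 1
    return FactorReport(rvar=rvar, var=var, ratio=ratio,
                        most_relevant=most, labels=labels)


@dataclass
class FactorMatch:
    """Pairing of inferred to reference factors with sign corrections."""

    pairs: list                    # (reference_index, inferred_index)
    correlations: np.ndarray       # signed rho per pair, after flipping
    signs: np.ndarray              # +-1 applied to each inferred factor
    matched: np.ndarray            # bool, |rho| > report_threshold
    aligned: np.ndarray            # inferred factors, reordered and flipped


def match_factors(reference: np.ndarray, inferred: np.ndarray,
                  report_threshold: float = 0.70,
                  method: str = "greedy") -> FactorMatch:
    """Match inferred to reference factors by maximum |Pearson correlation|.

    Greedy assignment by descending |rho| without replacement (the
    ``'optimal'`` method solves the exact assignment problem instead;
    both agree on well-separated designs). Negative correlations flip
    the inferred factor's sign. Rows are factors, columns samples.
    """
    ref = np.asarray(reference, dtype=float)
    inf_ = np.asarray(inferred, dtype=float)
    if ref.shape[1] != inf_.shape[1]:
        raise ValueError("reference and inferred must share the sample count")
    kr, ki = ref.shape[0], inf_.shape[0]
    c = np.corrcoef(np.vstack([ref, inf_]))[:kr, kr:]
    c = np.nan_to_num(c)
    if method == "greedy":
        pairs = []
        used_r, used_i = set(), set()
        order = np.dstack(np.unravel_index(np.argsort(-np.abs(c), axis=None),
                                           c.shape))[0]
        for r, i in order:
            if r in used_r or i in used_i:
                continue
            pairs.append((int(r), int(i)))
            used_r.add(r)
            used_i.add(i)
            if len(pairs) == min(kr, ki):
                break
    elif method == "optimal":
        rows, cols = linear_sum_assignment(-np.abs(c))
        pairs = list(zip(rows.tolist(), cols.tolist()))
    else:
        raise ValueError(f"unknown method {method!r}")
    pairs.sort()
    signs = np.array([1.0 if c[r, i] >= 0 else -1.0 for r, i in pairs])
    rhos = np.array([abs(c[r, i]) for r, i in pairs])
    aligned = np.full((kr, ref.shape[1]), np.nan)
    for (r, i), s in zip(pairs, signs):
        aligned[r] = s * inf_[i]
    return FactorMatch(pairs=pairs, correlations=rhos, signs=signs,
                       matched=rhos > report_threshold, aligned=aligned)


def multi_output_error(true: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Relative MSE per variable: error energy over true-signal energy.

    ``rMSE_j = mean_n (x_jn - xhat_jn)^2 / mean_n x_jn^2``. A perfect
    prediction scores 0; predicting zero scores 1 on zero-mean variables.
    """
    true = np.asarray(true, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if true.shape != predicted.shape:
        raise ValueError("true and predicted must be aligned")
    denom = np.mean(true ** 2, axis=1)
    if np.any(denom == 0):
        raise ValueError("variable(s) with zero energy cannot be scored")
    return np.mean((true - predicted) ** 2, axis=1) / denom
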
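"""Inverse-covariance combination of module scores.

Module responses are pooled as ``r = (1' S^-1 R) / (1' S^-1 1)`` where ``S``
is the covariance matrix of response residuals (score minus binary truth) —
a weighted mean whose weights sum to one and reduce to classical
inverse-variance weights when the residuals are uncorrelated.  The
covariance is estimated leave-one-out so reported combined responses for
training children are not overfit.  A dual threshold band on the combined
response yields the three-way verdict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Outcome, ValidationError

__all__ = [
    "CombinationModel",
    "combine_responses",
    "fit_combination",
    "banded_outcome",
    "tune_band",
]


@dataclass
class CombinationModel:
    module_ids: list[str]
    sigma: np.ndarray
    lower_threshold: float = 0.5
    upper_threshold: float = 0.5
    ridge: float = 1e-6
    #: per-child leave-one-out combined responses, set by fit_combination
    loo_responses: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        m = len(self.module_ids)
        if self.sigma.shape != (m, m):
            raise ValidationError("sigma shape must match module count")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-9):
            raise ValidationError("sigma must be symmetric")
        if self.ridge < 0:
            raise ValidationError("ridge must be >= 0")
        if self.lower_threshold > self.upper_threshold:
            raise ValidationError("lower_threshold must be <= upper_threshold")

    def weights(self) -> np.ndarray:
        """Combination weights; sum to exactly 1."""
        return _weights(self.sigma, self.ridge)

    def to_json(self, path) -> None:
        payload = {
            "module_ids": self.module_ids,
            "sigma": self.sigma.tolist(),
            "lower_threshold": self.lower_threshold,
            "upper_threshold": self.upper_threshold,
            "ridge": self.ridge,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CombinationModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            module_ids=payload["module_ids"],
            sigma=np.asarray(payload["sigma"]),
            lower_threshold=payload["lower_threshold"],
            upper_threshold=payload["upper_threshold"],
            ridge=payload["ridge"],
        )


def _weights(sigma: np.ndarray, ridge: float) -> np.ndarray:
    m = sigma.shape[0]
    eff = sigma + ridge * np.eye(m)
    ones = np.ones(m)
    try:
        solved = np.linalg.solve(eff, ones)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "effective covariance is singular; increase the ridge parameter"
        ) from None
    denom = ones @ solved
    if abs(denom) < 1e-300:
        raise ValidationError("degenerate covariance; increase the ridge parameter")
    w = solved / denom
    return w


def combine_responses(model: CombinationModel, R) -> float:
    """Pooled response for one child's module-score vector.

    When some modules are missing (NaN entries), the combination is computed
    over the submatrix of available modules.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (len(model.module_ids),):
        raise ValidationError("response vector length must match module count")
    avail = ~np.isnan(R)
    if not avail.any():
        raise ValidationError("no module responses available")
    sigma = model.sigma[np.ix_(avail, avail)]
    w = _weights(sigma, model.ridge)
    return float(w @ R[avail])


def fit_combination(
    responses: pd.DataFrame, labels: pd.Series, ridge: float = 1e-6
) -> CombinationModel:
    """Estimate the residual covariance from aligned per-module score tables.

    ``responses`` is indexed by child_id with one column per module;
    ``labels`` is the binary truth on the same index.  The fitted model
    carries per-child leave-one-out combined responses: for child *i* the
    covariance is re-estimated from all other children before pooling *i*'s
    scores, so the stored responses are honest out-of-sample values.
    """
    if not responses.index.equals(labels.index):
        raise ValidationError("responses and labels must share the same child index")
    n, m = responses.shape
    if n < 3:
        raise ValidationError("need at least 3 children to estimate covariance")
    resid = responses.to_numpy(dtype=float) - labels.to_numpy(dtype=float)[:, None]
    if np.isnan(resid).any():
        raise ValidationError("fit_combination requires complete response tables")
    sigma = np.cov(resid, rowvar=False, ddof=1).reshape(m, m)
    model = CombinationModel(module_ids=list(responses.columns), sigma=sigma, ridge=ridge)

    # leave-one-out via downdated sufficient statistics
    R = responses.to_numpy(dtype=float)
    total = resid.sum(axis=0)
    outer = resid.T @ resid
    loo = np.empty(n)
    for i in range(n):
        r_i = resid[i]
        mean_i = (total - r_i) / (n - 1)
        outer_i = outer - np.outer(r_i, r_i)
        cov_i = (outer_i - (n - 1) * np.outer(mean_i, mean_i)) / (n - 2)
        w = _weights(cov_i.reshape(m, m), ridge)
        loo[i] = w @ R[i]
    model.loo_responses = pd.Series(loo, index=responses.index, name="r_comb")
    return model


def banded_outcome(model: CombinationModel, r: float, child_id: str = "") -> Outcome:
    """Dual-threshold verdict: below the band negative, inside inconclusive,
    above positive."""
    if r < model.lower_threshold:
        verdict = "negative"
    elif r > model.upper_threshold:
        verdict = "positive"
    else:
        verdict = "inconclusive"
    score = None if verdict == "inconclusive" else float(r)
    return Outcome(child_id=child_id, verdict=verdict, score=score)


def _band_metrics(r: np.ndarray, y: np.ndarray, lower: float, upper: float):
    """(inconclusive fraction, conclusive sensitivity, conclusive specificity)."""
    inc = (r >= lower) & (r <= upper)
    pos = r > upper
    neg = r < lower
    n_pos = ((y == 1) & ~inc).sum()
    n_neg = ((y == 0) & ~inc).sum()
    sens = (pos & (y == 1)).sum() / n_pos if n_pos else np.nan
    spec = (neg & (y == 0)).sum() / n_neg if n_neg else np.nan
    return inc.mean(), sens, spec


def tune_band(
    model: CombinationModel,
    responses: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
    target_sensitivity: float = 0.9,
    max_inconclusive: float = 0.3,
) -> CombinationModel:
    """Grid-search the (lower, upper) band on leave-one-out combined responses.

    Among bands with inconclusive fraction within allowance and conclusive
    sensitivity at target, picks maximal conclusive specificity; ties prefer
    the narrower band.  Raises with the best achievable frontier if no band
    is feasible.
    """
    if model.loo_responses is None:
        raise ValidationError("tune_band needs a fitted model with LOO responses")
    if labels is None:
        raise ValidationError("labels are required")
    r = model.loo_responses.to_numpy(dtype=float)
    y = labels.loc[model.loo_responses.index].to_numpy(dtype=int)

    # candidate thresholds between adjacent observed responses, plus extremes
    uniq = np.unique(r)
    edges = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]])
    best = None  # (spec, -width, lower, upper)
    best_frontier = None
    for li, lower in enumerate(edges):
        for upper in edges[li:]:
            inc_frac, sens, spec = _band_metrics(r, y, lower, upper)
            if inc_frac > max_inconclusive or np.isnan(sens) or np.isnan(spec):
                continue
            if sens < target_sensitivity:
                if best_frontier is None or sens > best_frontier[0]:
                    best_frontier = (sens, spec, inc_frac)
                continue
            key = (spec, -(upper - lower), lower)
            if best is None or key > best[:3]:
                best = (spec, -(upper - lower), lower, upper)
    if best is None:
        raise ValidationError(
            "no feasible band; best achievable (sensitivity, specificity, "
            f"inconclusive) frontier: {best_frontier}"
        )
    return replace(
        model, lower_threshold=float(best[2]), upper_threshold=float(best[3])
    )
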
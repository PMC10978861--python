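"""Consensus of repeated segmentations: majority vote and STAPLE.

When the same volume is segmented several times (by one operator repeating
the task, or by several raters), a single representative mask is needed
before comparisons.  Majority voting is the simple route; STAPLE
(simultaneous truth and performance level estimation) treats the hidden
true segmentation and each rater's sensitivity p_j / specificity q_j as
unknowns of a binary mixture model and estimates both by
expectation-maximization:

* E-step: per-voxel posterior probability W_i that the voxel is truly
  foreground, given the rater decisions and current (p_j, q_j) and a
  global foreground prior;
* M-step: re-estimate each rater's p_j and q_j from the posterior weights.

The observed-data log-likelihood is non-decreasing across iterations (a
standard EM guarantee, asserted in the tests).  The representative mask
thresholds the converged posterior at 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import BinaryMask

__all__ = ["RaterSet", "StapleResult", "majority_vote", "staple"]


@dataclass
class RaterSet:
    """>= 2 binary segmentations of one volume on a single grid."""

    masks: list[BinaryMask]
    rater_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.masks) < 2:
            raise ValueError(f"need at least 2 raters, got {len(self.masks)}")
        ref = self.masks[0]
        for m in self.masks[1:]:
            ref.require_same_grid(m, "rater mask")
        if not self.rater_ids:
            self.rater_ids = [f"rater{i}" for i in range(len(self.masks))]
        if len(self.rater_ids) != len(self.masks):
            raise ValueError("rater_ids length disagrees with masks")

    def stacked(self) -> np.ndarray:
        """(n_raters, n_voxels) boolean decision matrix."""
        return np.stack([m.data.ravel() for m in self.masks])


def majority_vote(raters: RaterSet, tie_rule: str = "background") -> BinaryMask:
    """Foreground iff strictly more than half of the raters mark it.

    Exact ties (even rater counts only) are resolved by ``tie_rule``.
    """
    if tie_rule not in ("foreground", "background"):
        raise ValueError(f"tie_rule must be foreground/background, got {tie_rule!r}")
    d = raters.stacked()
    votes = d.sum(axis=0)
    n = d.shape[0]
    out = votes * 2 > n
    if tie_rule == "foreground":
        out |= votes * 2 == n
    ref = raters.masks[0]
    return BinaryMask.like(ref, out.reshape(ref.shape))


@dataclass
class StapleResult:
    posterior: np.ndarray            # per-voxel P(truth = foreground)
    sensitivity: np.ndarray          # p_j per rater
    specificity: np.ndarray          # q_j per rater
    mask: BinaryMask                 # posterior thresholded
    n_iter: int
    log_likelihood: list[float]      # trajectory, one entry per iteration
    converged: bool


def staple(raters: RaterSet,
           tol: float = 1e-6,
           max_iter: int = 100,
           prior: float | None = None,
           threshold: float = 0.5,
           eps: float = 1e-6) -> StapleResult:
    """EM estimate of the consensus segmentation and rater performances.

    Parameters
    ----------
    tol:
        Convergence threshold on the max per-voxel posterior change.
    prior:
        Global foreground prior probability; defaults to the mean rater
        foreground fraction.
    eps:
        Clamp for p_j, q_j in (eps, 1 - eps), guarding the degenerate
        empty/full-mask raters.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    d = raters.stacked().astype(np.float64)   # (J, N)
    nj, nv = d.shape
    if prior is None:
        prior = float(d.mean())
    prior = min(max(prior, eps), 1.0 - eps)

    p = np.full(nj, 0.9)
    q = np.full(nj, 0.9)
    w = np.full(nv, prior)
    lls: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space: log P(d_i | truth=fg) and | truth=bg)
        log_a = (d.T @ np.log(p) + (1 - d).T @ np.log1p(-p)) + np.log(prior)
        log_b = ((1 - d).T @ np.log(q) + d.T @ np.log1p(-q)) + np.log1p(-prior)
        m = np.maximum(log_a, log_b)
        ea = np.exp(log_a - m)
        eb = np.exp(log_b - m)
        w_new = ea / (ea + eb)
        lls.append(float(np.sum(m + np.log(ea + eb))))
        delta = float(np.abs(w_new - w).max())
        w = w_new
        # M-step
        sw = w.sum()
        swc = nv - sw
        p = np.clip((d @ w) / max(sw, eps), eps, 1 - eps)
        q = np.clip(((1 - d) @ (1 - w)) / max(swc, eps), eps, 1 - eps)
        if delta < tol:
            converged = True
            break

    ref = raters.masks[0]
    mask = BinaryMask.like(ref, (w >= threshold).reshape(ref.shape))
    return StapleResult(
        posterior=w.reshape(ref.shape),
        sensitivity=p,
        specificity=q,
        mask=mask,
        n_iter=it,
        log_likelihood=lls,
        converged=converged,
    )
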
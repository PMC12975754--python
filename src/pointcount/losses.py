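"""Composite point-supervision objective.

L_total = L_cls + lambda_reg * L_reg + lambda_near * L_near + lambda_overlap * L_overlap

The base terms (binary cross-entropy over proposal confidences and Smooth-L1
over matched offsets, after one-to-one Hungarian matching) supervise what to
predict; the two spatial-distribution penalties regularise *where*:

* L_near  = (1/N_p^2) * sum_{i != j} max(0, d_min - ||p_i - p_j||)
  over ordered pairs of predicted points — pushes near-duplicate predictions
  apart (strict trigger d_ij < d_min; zero when N_p <= 1).
* L_overlap = (1/N_g) * sum_i max(0, n_i - 1), with
  n_i = #{p : ||p - g_i|| < r_o} — penalises surplus predictions crowded
  inside radius r_o of a single ground-truth point (zero when N_g = 0).

Penalties act on the decoded prediction set (scores >= score_threshold);
a soft, score-weighted variant is available for differentiability through
the selection itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .point_core import MatchResult, as_points, hungarian_match, pairwise_distances


@dataclass
class LossConfig:
    lambda_reg: float = 0.5
    lambda_near: float = 0.1
    lambda_overlap: float = 0.1
    d_min: float = 6.5  # px; ~half the expected seed diameter
    r_o: float = 6.5  # px; ~expected seed radius
    score_threshold: float = 0.5
    match_score_weight: float = 1.0  # confidence bonus in the matching cost
    soft_selection: bool = False  # score-weighted penalties instead of hard decode
    soft_temp: float = 2.0  # px; width of the soft overlap count

    def __post_init__(self):
        if self.d_min <= 0 or self.r_o <= 0:
            raise ValueError("d_min and r_o must be positive")
        if min(self.lambda_reg, self.lambda_near, self.lambda_overlap) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossBreakdown:
    L_cls: float
    L_reg: float
    L_near: float
    L_overlap: float
    L_total: float
    tensor: object = None  # autodiff Tensor of L_total when inputs carry a graph

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("L_cls", "L_reg", "L_near", "L_overlap", "L_total")}


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_proposals(proposals, gt, score_weight: float = 1.0) -> MatchResult:
    """Hungarian one-to-one assignment of predicted points to ground truth.

    Cost(i, j) = ||p_i - g_j|| + score_weight * (1 - s_i): distance plus a
    confidence bonus (an equivalent, nonnegative form of distance minus a
    score reward).  ``proposals`` may be a ProposalSet or an (N, 2) array
    (then scores default to 1).
    """
    if hasattr(proposals, "predicted_points"):
        pred = proposals.predicted_points
        scores = np.asarray(proposals.scores, dtype=float)
    else:
        pred = as_points(proposals)
        scores = np.ones(len(pred))
    gt = as_points(gt)
    if len(pred) == 0 or len(gt) == 0:
        return MatchResult([], list(range(len(pred))), list(range(len(gt))), 0.0)
    cost = pairwise_distances(pred, gt) + score_weight * (1.0 - scores)[:, None]
    return hungarian_match(cost)


# ---------------------------------------------------------------------------
# Base terms
# ---------------------------------------------------------------------------

def classification_loss(scores, match: MatchResult, logits=None):
    """Mean binary cross-entropy; matched proposals are foreground.

    When ``logits`` is given the numerically stable log-sigmoid form is used
    (training path); otherwise probabilities are clipped at 1e-12.
    """
    n = len(_data(scores))
    labels = np.zeros(n)
    for pi, _ in match.pairs:
        labels[pi] = 1.0
    y = labels
    if logits is not None:
        z = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits, dtype=float))
        # softplus(z) - y*z = -log sigmoid(z) + (1-y)*z, stable both tails
        absz = ad.maximum(z, -z)
        softplus = ad.relu(z) + ad.log(ad.exp(-absz) + 1.0)
        return ad.tmean(softplus - Tensor(y) * z)
    if isinstance(scores, Tensor):
        s = scores
        eps = 1e-12
        one_m = (1.0 - s) + eps
        return -ad.tmean(Tensor(y) * ad.log(s + eps) + Tensor(1.0 - y) * ad.log(one_m))
    s = np.clip(_data(scores), 1e-12, 1 - 1e-12)
    return float(-(y * np.log(s) + (1 - y) * np.log(1 - s)).mean())


def _smooth_l1(r):
    """Huber with transition at 1, elementwise, on Tensor or ndarray."""
    if isinstance(r, Tensor):
        a = ad.maximum(r, -r)
        quad_mask = (a.data < 1.0).astype(r.data.dtype)
        return Tensor(quad_mask) * (0.5 * r * r) + Tensor(1.0 - quad_mask) * (a - 0.5)
    a = np.abs(r)
    return np.where(a < 1.0, 0.5 * r * r, a - 0.5)


def regression_loss(proposals, match: MatchResult, gt):
    """Smooth-L1 of matched coordinate residuals, mean over pairs and axes."""
    if not match.pairs:
        if isinstance(proposals, Tensor):
            return Tensor(0.0)
        return 0.0
    pidx = np.array([p for p, _ in match.pairs])
    gidx = np.array([g for _, g in match.pairs])
    gt = as_points(gt)
    if isinstance(proposals, Tensor):
        r = proposals[pidx] - Tensor(gt[gidx])
        return ad.tmean(_smooth_l1(r))
    pred = as_points(proposals)
    return float(_smooth_l1(pred[pidx] - gt[gidx]).mean())


# ---------------------------------------------------------------------------
# Spatial-distribution penalties
# ---------------------------------------------------------------------------

def near_penalty(pred, d_min: float, weights=None):
    """(1/N_p^2) * sum over ordered pairs i != j of max(0, d_min - d_ij).

    ``pred``: (N, 2) array / PointSet (exact float64 path) or Tensor (autodiff
    path).  Optional per-point ``weights`` (Tensor) give the soft, score-
    weighted variant: each pair's hinge is scaled by w_i * w_j.
    """
    if isinstance(pred, Tensor):
        n = pred.shape[0]
        if n <= 1:
            return Tensor(0.0)
        A = ad.reshape(pred, (n, 1, 2))
        B = ad.reshape(pred, (1, n, 2))
        diff = A - B
        d = ad.sqrt(ad.tsum(diff * diff, axis=2), eps=1e-12)
        hinge = ad.relu(d_min - d)
        off = 1.0 - np.eye(n)
        hinge = hinge * Tensor(off)
        if weights is not None:
            w = weights if isinstance(weights, Tensor) else Tensor(np.asarray(weights, dtype=float))
            hinge = hinge * ad.matmul(ad.reshape(w, (n, 1)), ad.reshape(w, (1, n)))
        return ad.tsum(hinge) * (1.0 / float(n * n))
    pts = as_points(pred)
    n = len(pts)
    if n <= 1:
        return 0.0
    d = pairwise_distances(pts, pts)
    hinge = np.maximum(0.0, d_min - d)
    np.fill_diagonal(hinge, 0.0)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        hinge = hinge * np.outer(w, w)
    return float(hinge.sum() / (n * n))


def overlap_penalty(pred, gt, r_o: float, soft_temp: float | None = None, weights=None):
    """(1/N_g) * sum_i max(0, n_i - 1) with n_i = #{p : ||p - g_i|| < r_o}.

    The exact count is piecewise constant; when ``soft_temp`` is given the
    indicator is smoothed to sigmoid((r_o - d)/temp) so the term carries a
    gradient (Tensor path)."""
    gt = as_points(gt)
    ng = len(gt)
    if ng == 0:
        return Tensor(0.0) if isinstance(pred, Tensor) else 0.0
    if isinstance(pred, Tensor):
        n = pred.shape[0]
        if n == 0:
            return Tensor(0.0)
        temp = soft_temp if soft_temp is not None else 1.0
        A = ad.reshape(pred, (n, 1, 2))
        diff = A - Tensor(gt[None, :, :])
        d = ad.sqrt(ad.tsum(diff * diff, axis=2), eps=1e-12)  # (n, ng)
        ind = ad.sigmoid((r_o - d) * (1.0 / temp))
        if weights is not None:
            w = weights if isinstance(weights, Tensor) else Tensor(np.asarray(weights, dtype=float))
            ind = ind * ad.reshape(w, (n, 1))
        counts = ad.tsum(ind, axis=0)  # (ng,)
        return ad.tmean(ad.relu(counts - 1.0))
    pts = as_points(pred)
    if len(pts) == 0:
        return 0.0
    d = pairwise_distances(pts, gt)
    counts = (d < r_o).sum(axis=0)
    return float(np.maximum(0, counts - 1).mean())


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def total_loss(scores, proposals, gt, cfg: LossConfig | None = None,
               logits=None, match: MatchResult | None = None) -> LossBreakdown:
    """Compose the four terms on one image.

    ``scores``: (P,) confidences; ``proposals``: (P, 2) predicted point
    coordinates (Tensor during training); ``gt``: ground-truth points.
    Passing ``logits`` switches L_cls to the stable log-sigmoid form.
    """
    cfg = cfg or LossConfig()
    scores_np = _data(scores)
    pred_np = _data(proposals).reshape(-1, 2)
    if not np.isfinite(scores_np).all():
        raise FloatingPointError("L_cls input (scores) is not finite")
    if not np.isfinite(pred_np).all():
        raise FloatingPointError("L_reg input (proposal coordinates) is not finite")
    if match is None:
        match = match_proposals(
            type("P", (), {"predicted_points": pred_np, "scores": scores_np})(),
            gt, cfg.match_score_weight,
        )
    lcls = classification_loss(scores, match, logits=logits)
    lreg = regression_loss(proposals, match, gt)

    keep = scores_np >= cfg.score_threshold
    idx = np.nonzero(keep)[0]
    if isinstance(proposals, Tensor):
        selected = proposals[idx] if len(idx) else Tensor(np.zeros((0, 2)))
    else:
        selected = pred_np[idx]
    if cfg.soft_selection:
        w = scores[idx] if isinstance(scores, Tensor) else scores_np[idx]
        lnear = near_penalty(selected, cfg.d_min, weights=w)
        lover = overlap_penalty(selected, gt, cfg.r_o, soft_temp=cfg.soft_temp, weights=w)
    else:
        lnear = near_penalty(selected, cfg.d_min)
        # exact piecewise-constant count: contributes its value, no gradient
        lover = overlap_penalty(pred_np[idx], as_points(gt), cfg.r_o)

    def val(t):
        return float(t.data) if isinstance(t, Tensor) else float(t)

    terms = {"L_cls": val(lcls), "L_reg": val(lreg), "L_near": val(lnear),
             "L_overlap": val(lover)}
    for name, v in terms.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"{name} is not finite ({v})")

    total = terms["L_cls"] + cfg.lambda_reg * terms["L_reg"] \
        + cfg.lambda_near * terms["L_near"] + cfg.lambda_overlap * terms["L_overlap"]
    tensor = None
    if any(isinstance(t, Tensor) for t in (lcls, lreg, lnear, lover)):
        def as_t(t):
            return t if isinstance(t, Tensor) else Tensor(float(t))
        tensor = as_t(lcls) + cfg.lambda_reg * as_t(lreg) \
            + cfg.lambda_near * as_t(lnear) + cfg.lambda_overlap * as_t(lover)
    return LossBreakdown(terms["L_cls"], terms["L_reg"], terms["L_near"],
                         terms["L_overlap"], float(total), tensor=tensor)
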
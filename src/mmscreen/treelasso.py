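"""Tree-guided group lasso for multi-response drug-sensitivity prediction.

All drug responses are modelled jointly: for features X (samples × p) and
response scores Y (samples × q drugs) the model minimizes

    (1/2) ||Y - X B||_F^2  +  Lambda * Omega_tree(B)

where the structured penalty groups each feature's coefficients across
drugs according to a hierarchical clustering tree of the drug response
profiles.  Each internal tree node v carries a mixing value s_v in [0, 1]
(here: the node's normalized merge height, clamped at ``h_cut``) that
interpolates between selecting the node's subtrees separately (s_v -> 1)
and selecting the whole node group jointly (s_v -> 0).  The penalty is the
recursion, per feature row beta:

    W(v) = s_v * sum_children W(c) + (1 - s_v) * ||beta_{G_v}||_2,
    W(leaf j) = |beta_j|,

which expands to a weighted sum of group L2 norms with

    weight(internal v) = (1 - s_v) * prod_{a in ancestors(v)} s_a,
    weight(leaf j)     =            prod_{a in ancestors(j)} s_a,

so the weights along each root-to-leaf path telescope to exactly 1 (the
penalty is path-normalized by construction).  s == 1 everywhere recovers
the plain lasso; s == 0 recovers a single all-drug L2 group per feature.

Optimization uses the smoothing proximal gradient (SPG) scheme: the
internal-node group norms are Nesterov-smoothed with parameter mu, the
leaf-level L1 part is handled exactly by soft-thresholding, and a monotone
accelerated proximal-gradient iteration drives the objective down.  The
step size comes from a backtracking estimate of the local curvature,
capped by the analytic Lipschitz bound of the smoothed gradient

    L = sigma_max(X^T X) + Lambda^2 * max_j sum_{v : j in G_v} w_v^2 / mu

(the global bound is safe but far too conservative away from zero, where
the smoothed group norms are nearly linear).  Exact zeros in B come from
the proximal step; momentum restarts on any non-monotone step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DEFAULT_H_CUT = 0.7
DEFAULT_MU = 1e-4
DEFAULT_MAX_ITER = 20_000
DEFAULT_TOL = 1e-8


# ---------------------------------------------------------------------------
# Drug tree


@dataclass(frozen=True)
class DrugTree:
    """Binary merge tree over drugs with normalized, clamped node heights.

    ``merges`` is a scipy linkage matrix; ``heights`` are merge heights
    normalized so the root sits at 1 and leaves at 0; ``mixing`` holds the
    per-internal-node s values actually used by the penalty (by default the
    heights clamped at ``h_cut``).
    """

    labels: tuple[str, ...]
    merges: np.ndarray
    heights: np.ndarray
    h_cut: float = DEFAULT_H_CUT
    mixing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mixing is None:
            object.__setattr__(
                self, "mixing", np.minimum(self.heights, self.h_cut)
            )

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, node: int) -> np.ndarray:
        """Leaf indices under a node (leaves are 0..n-1, internal n..2n-2)."""
        n = self.n_leaves
        if node < n:
            return np.array([node])
        left, right = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
        return np.concatenate([self.members(left), self.members(right)])

    def with_mixing(self, s) -> "DrugTree":
        """Copy of the tree with explicit per-internal-node mixing values."""
        s = np.broadcast_to(np.asarray(s, dtype=float), self.heights.shape)
        return replace(self, mixing=s.copy())


def build_drug_tree(
    dss_matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "complete",
    h_cut: float = DEFAULT_H_CUT,
) -> DrugTree:
    """Hierarchical tree over drug rows of a drugs × cell lines DSS matrix.

    Default distance is 1 - Pearson correlation between drug response
    profiles (so strongly co-varying drugs merge low in the tree), with
    complete linkage.  Merge heights are normalized to put the root at 1
    and the leaves at 0; a degenerate tree whose merges are all at height 0
    (identical profiles throughout) keeps all heights at 0.
    """
    if dss_matrix.shape[0] < 2 or dss_matrix.shape[1] < 2:
        raise ValueError("need >= 2 drugs and >= 2 cell lines")
    values = dss_matrix.to_numpy(dtype=float)
    if distance == "correlation":
        sd = values.std(axis=1)
        if np.any(sd == 0):
            bad = list(dss_matrix.index[sd == 0])
            raise ValueError(
                f"constant response profile under correlation distance: {bad}"
            )
        dist = squareform(1.0 - np.corrcoef(values), checks=False)
        dist = np.maximum(dist, 0.0)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        dist = pdist(values)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    z = hierarchy.linkage(dist, method=linkage)
    heights = z[:, 2].copy()
    root = heights[-1]
    heights = heights / root if root > 0 else np.zeros_like(heights)
    return DrugTree(
        labels=tuple(dss_matrix.index), merges=z, heights=heights, h_cut=h_cut
    )


def clamp_heights(tree: DrugTree, h_cut: float, mode: str = "clamp") -> DrugTree:
    """Apply the height cutoff; topology unchanged.

    ``mode="clamp"`` (default) caps every node's mixing value at ``h_cut``,
    keeping the joint penalty of high nodes (including the root) active at
    reduced strength.  ``mode="prune"`` instead removes the joint penalty
    of nodes above the cutoff entirely (their subtrees are selected
    separately), which discards the root-level group.
    """
    if not (0.0 < h_cut <= 1.0):
        raise ValueError("h_cut must be in (0, 1]")
    if mode == "clamp":
        mixing = np.minimum(tree.heights, h_cut)
    elif mode == "prune":
        mixing = np.where(tree.heights > h_cut, 1.0, tree.heights)
    else:
        raise ValueError(f"unknown cutoff mode {mode!r}")
    return replace(tree, h_cut=h_cut, mixing=mixing)


# ---------------------------------------------------------------------------
# Penalty weights


@dataclass(frozen=True)
class PenaltyWeights:
    """Expanded group weights over drug coefficients, per feature row.

    ``leaf`` has one L1 weight per drug; ``groups`` is a list of
    (drug-index array, weight) pairs for internal-node L2 groups with
    nonzero weight.
    """

    leaf: np.ndarray
    groups: tuple[tuple[np.ndarray, float], ...]

    @property
    def n_drugs(self) -> int:
        return self.leaf.size

    def value(self, B: np.ndarray) -> float:
        """Exact (unsmoothed, un-scaled) penalty Omega(B)."""
        B = np.atleast_2d(B)
        total = float(np.sum(np.abs(B) * self.leaf))
        for idx, w in self.groups:
            total += w * float(
                np.sum(np.sqrt(np.sum(B[:, idx] ** 2, axis=1)))
            )
        return total


def lasso_weights(n_drugs: int) -> PenaltyWeights:
    """Flat (tree-less) weights: plain per-coefficient lasso."""
    return PenaltyWeights(leaf=np.ones(n_drugs), groups=())


def node_weights(tree: DrugTree, drop_tol: float = 1e-12) -> PenaltyWeights:
    """Expand the recursive tree penalty into per-group weights.

    Walks the tree from the root, carrying the product of ancestor mixing
    values; internal node v gets (1 - s_v) times that product, each leaf
    the full product.  Groups with weight below ``drop_tol`` are dropped.
    """
    n = tree.n_leaves
    prod = np.ones(2 * n - 1)
    leaf = np.ones(n)
    groups: list[tuple[np.ndarray, float]] = []
    # internal node ids are n..2n-2; children always have smaller ids
    for v in range(2 * n - 2, n - 1, -1):
        s = float(tree.mixing[v - n])
        w = (1.0 - s) * prod[v]
        if w > drop_tol:
            groups.append((tree.members(v), w))
        left, right = int(tree.merges[v - n, 0]), int(tree.merges[v - n, 1])
        prod[left] = prod[right] = prod[v] * s
    leaf = prod[:n].copy()
    leaf[leaf <= drop_tol] = 0.0
    return PenaltyWeights(leaf=leaf, groups=tuple(groups))


# ---------------------------------------------------------------------------
# SPG optimizer


@dataclass
class TreeLassoModel:
    """Fitted multi-response model with structured sparsity."""

    B: np.ndarray  # features × drugs
    intercept: np.ndarray  # per drug
    x_mean: np.ndarray  # per feature (training means)
    lam: float
    mu: float
    converged: bool
    n_iter: int
    objective_trace: np.ndarray
    feature_names: tuple[str, ...] | None = None
    drug_names: tuple[str, ...] | None = None

    def predict(self, X) -> np.ndarray:
        # intercept = y_mean - x_mean @ B, so plain X @ B + intercept
        # reproduces the centered fit on the original scale
        X = np.asarray(X, dtype=float)
        return X @ self.B + self.intercept

    def coefficients(self) -> pd.DataFrame:
        idx = self.feature_names or range(self.B.shape[0])
        cols = self.drug_names or range(self.B.shape[1])
        return pd.DataFrame(self.B, index=idx, columns=cols)


class _SmoothedPenalty:
    """Vectorized Nesterov smoothing of the internal-node group norms."""

    def __init__(self, weights: PenaltyWeights, n_drugs: int):
        self.leaf = weights.leaf
        if weights.groups:
            idx = np.concatenate([g for g, _ in weights.groups])
            sizes = np.array([g.size for g, _ in weights.groups])
            self.starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
            self.w = np.array([w for _, w in weights.groups])
            self.w_expanded = np.repeat(self.w, sizes)
            self.idx = idx
            # scatter matrix: (sum group sizes) × drugs
            scatter = np.zeros((idx.size, n_drugs))
            scatter[np.arange(idx.size), idx] = 1.0
            self.scatter = scatter
            # per-drug sum of squared group weights, for the Lipschitz bound
            self.wsq_per_drug = scatter.T @ (self.w_expanded**2)
        else:
            self.idx = None
            self.wsq_per_drug = np.zeros(n_drugs)

    def max_wsq(self) -> float:
        return float(self.wsq_per_drug.max()) if self.idx is not None else 0.0

    def value_and_grad(self, B: np.ndarray, lam: float, mu: float):
        """Smoothed penalty value and gradient (both already scaled by lam)."""
        if self.idx is None or lam == 0.0:
            return 0.0, np.zeros_like(B)
        U = B[:, self.idx] * (lam * self.w_expanded)  # u = lam * w * beta_G
        norms = np.sqrt(
            np.add.reduceat(U * U, self.starts, axis=1)
        )  # features × groups
        # alpha* = u / max(mu, ||u||); value = ||u||^2/2mu or ||u|| - mu/2
        denom = np.maximum(norms, mu)
        value = float(
            np.sum(np.where(norms <= mu, norms**2 / (2 * mu), norms - mu / 2))
        )
        sizes = np.diff(np.concatenate([self.starts, [self.idx.size]]))
        alpha = U / np.repeat(denom, sizes, axis=1)
        grad = (alpha * (lam * self.w_expanded)) @ self.scatter
        return value, grad


def _soft_threshold(B: np.ndarray, thresh: np.ndarray) -> np.ndarray:
    return np.sign(B) * np.maximum(np.abs(B) - thresh, 0.0)


class _ProxPenalty:
    """Vectorized exact prox of the tree penalty (laminar group family).

    The proximal operator of a sum of nested group L2 norms is the
    composition of per-group soft-thresholdings applied children-first.
    Groups at equal nesting depth are disjoint, so each depth level is
    applied in one vectorized pass.
    """

    def __init__(self, weights: PenaltyWeights):
        self.leaf = weights.leaf
        groups = weights.groups
        if groups:
            sets = [frozenset(idx.tolist()) for idx, _ in groups]
            depth = [
                sum(1 for other in sets if s < other) for s in sets
            ]
            levels = []
            for d in sorted(set(depth), reverse=True):  # deepest first
                members = [groups[i] for i in range(len(groups))
                           if depth[i] == d]
                idx = np.concatenate([g for g, _ in members])
                sizes = np.array([g.size for g, _ in members])
                starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
                w = np.array([wv for _, wv in members])
                levels.append((idx, starts, sizes, w))
            self.levels = levels
            self.idx_all = np.concatenate([g for g, _ in groups])
            sizes_all = np.array([g.size for g, _ in groups])
            self.starts_all = np.concatenate([[0], np.cumsum(sizes_all)[:-1]])
            self.w_all = np.array([wv for _, wv in groups])
        else:
            self.levels = []
            self.idx_all = None

    def prox(self, V: np.ndarray, step_lam: float) -> np.ndarray:
        B = _soft_threshold(V, step_lam * self.leaf)
        for idx, starts, sizes, w in self.levels:
            sub = B[:, idx]
            norms = np.sqrt(np.add.reduceat(sub * sub, starts, axis=1))
            shrink = np.maximum(
                0.0, 1.0 - step_lam * w / np.maximum(norms, 1e-300)
            )
            B[:, idx] = sub * np.repeat(shrink, sizes, axis=1)
        return B

    def group_value(self, B: np.ndarray) -> float:
        """Sum of weighted internal-group L2 norms (un-scaled by lam)."""
        if self.idx_all is None:
            return 0.0
        sub = B[:, self.idx_all]
        norms = np.sqrt(np.add.reduceat(sub * sub, self.starts_all, axis=1))
        return float(np.sum(norms * self.w_all))


def spg_fit(
    X,
    Y,
    tree: DrugTree | None = None,
    lam: float = 1.0,
    mu: float = DEFAULT_MU,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    B0: np.ndarray | None = None,
    weights: PenaltyWeights | None = None,
    method: str = "spg",
) -> TreeLassoModel:
    """Fit the tree-lasso by monotone accelerated proximal gradient.

    ``X`` is samples × features, ``Y`` samples × drugs (DataFrames keep
    their labels).  Both are column-centered internally; the per-drug means
    are restored as intercepts at prediction time.  ``tree=None`` (and no
    explicit ``weights``) fits a plain multi-response lasso.

    ``method='spg'`` (the default) Nesterov-smooths the internal-node group
    norms with parameter ``mu`` and handles the leaf L1 part by proximal
    soft-thresholding.  ``method='prox'`` solves the exact (unsmoothed)
    objective instead: because the groups are tree-structured, the proximal
    operator of the whole penalty is the bottom-up composition of per-group
    soft-thresholdings, allowing full 1/sigma_max steps — it is much faster
    on cross-validation paths, and agrees with SPG up to the smoothing gap
    (at most lam * mu * n_groups / 2 in objective).
    """
    feature_names = tuple(X.columns) if isinstance(X, pd.DataFrame) else None
    drug_names = tuple(Y.columns) if isinstance(Y, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("X and Y must be finite")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n, p = X.shape
    q = Y.shape[1]

    if weights is None:
        weights = node_weights(tree) if tree is not None else lasso_weights(q)
    if weights.n_drugs != q:
        raise ValueError("penalty weights do not match the number of drugs")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    XtX = Xc.T @ Xc
    XtY = Xc.T @ Yc

    if method not in ("spg", "prox"):
        raise ValueError(f"unknown method {method!r}")
    smoothed = _SmoothedPenalty(weights, q)
    proxop = _ProxPenalty(weights)
    sigma_max = float(np.linalg.eigvalsh(XtX)[-1]) if p else 0.0
    # analytic Lipschitz bound of the smoothed gradient; the line search
    # below estimates the (much smaller) local curvature and is capped here
    if method == "spg":
        L_bound = max(sigma_max + lam**2 * smoothed.max_wsq() / mu, 1e-12)
    else:
        # exact prox: the smooth part is the quadratic alone
        L_bound = max(sigma_max, 1e-12)
    L = max(sigma_max, L_bound * 1e-8, 1e-12)

    yty = float(np.sum(Yc * Yc))

    def quad_ls(B, GB):
        # (1/2)||Xc B - Yc||^2 via cached Gram products
        return 0.5 * (float(np.sum(B * GB)) - 2.0 * float(np.sum(B * XtY))
                      + yty)

    def prox(V, step_lam):
        if method == "prox":
            return proxop.prox(V, step_lam)
        return _soft_threshold(V, step_lam * weights.leaf)

    def f_and_obj(B, GB):
        """(smooth part, full objective) at B given GB = XtX @ B."""
        f = quad_ls(B, GB)
        if method == "spg":
            pen, _ = smoothed.value_and_grad(B, lam, mu)
            f += pen
            nonsm = lam * float(np.sum(np.abs(B) * weights.leaf))
        else:
            nonsm = lam * (float(np.sum(np.abs(B) * weights.leaf))
                           + proxop.group_value(B))
        return f, f + nonsm

    B = np.zeros((p, q)) if B0 is None else np.array(B0, dtype=float)
    Z = B.copy()
    t = 1.0
    _, F_best = f_and_obj(B, XtX @ B)
    trace = [F_best]
    converged = False
    quiet = 0  # consecutive accepted iterations with tiny improvement
    it = 0
    for it in range(1, max_iter + 1):
        GZ = XtX @ Z
        grad = GZ - XtY
        f_z = quad_ls(Z, GZ)
        if method == "spg":
            fz_pen, gpen = smoothed.value_and_grad(Z, lam, mu)
            grad += gpen
            f_z += fz_pen
        while True:
            cand = prox(Z - grad / L, lam / L)
            f_cand, F_cand = f_and_obj(cand, XtX @ cand)
            if L >= L_bound:
                break  # analytic bound always satisfies the inequality
            step = cand - Z
            quad = f_z + float(np.sum(grad * step)) + 0.5 * L * float(
                np.sum(step**2)
            )
            if f_cand <= quad + 1e-12 * max(1.0, abs(quad)):
                break
            L = min(L * 2.0, L_bound)
        # monotone acceleration: keep the best iterate seen so far; on a
        # rejected step restart the momentum from the best iterate, after
        # which the next (plain proximal) step is guaranteed to descend
        if F_cand <= F_best:
            rel_change = (F_best - F_cand) / max(1.0, abs(F_best))
            quiet = quiet + 1 if rel_change < tol else 0
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            Z = cand + ((t - 1.0) / t_new) * (cand - B)
            B, F_best, t = cand, F_cand, t_new
        else:
            # rejected step: restart momentum; a rejection by less than the
            # tolerance still counts as a stalled (converged) iteration
            gap = (F_cand - F_best) / max(1.0, abs(F_best))
            quiet = quiet + 1 if gap <= tol else 0
            Z = B
            t = 1.0
        L = max(L * 0.9, sigma_max, 1e-12)  # let the step size re-grow
        trace.append(F_best)
        if quiet >= 5:
            converged = True
            break

    return TreeLassoModel(
        B=B,
        intercept=y_mean - x_mean @ B,
        x_mean=x_mean,
        lam=lam,
        mu=mu,
        converged=converged,
        n_iter=it,
        objective_trace=np.asarray(trace),
        feature_names=feature_names,
        drug_names=drug_names,
    )


def tree_lasso_objective(
    B, X, Y, lam: float, weights: PenaltyWeights
) -> float:
    """Exact (unsmoothed) objective at B, on column-centered data."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    B = np.atleast_2d(np.asarray(B, dtype=float))
    resid = Xc @ B - Yc
    return 0.5 * float(np.sum(resid**2)) + lam * weights.value(B)


# ---------------------------------------------------------------------------
# Cross-validation and reporting


@dataclass(frozen=True)
class CvResult:
    lam_grid: np.ndarray
    mse: np.ndarray
    selected_lam: float
    selected_index: int
    rule: str
    n_folds: int = 0


def lambda_grid(
    X, Y, n_points: int = 30, span: float = 1e3
) -> np.ndarray:
    """Log-spaced grid below the pure-lasso null bound.

    The largest value is the smallest Lambda at which a plain lasso zeroes
    every coefficient (max |Xc^T Yc|); the grid spans three decades below
    it by default.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    lam_max = float(np.max(np.abs(Xc.T @ Yc)))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max / span, lam_max, n_points)


def loo_cv(
    X,
    Y,
    tree: DrugTree | None = None,
    lam_grid_values: Sequence[float] | None = None,
    mu: float = DEFAULT_MU,
    flat_tol: float = 0.02,
    tol: float = 1e-6,
    max_iter: int = 3000,
    weights: PenaltyWeights | None = None,
    method: str = "prox",
) -> CvResult:
    """Leave-one-out CV of the per-entry mean squared error over a grid.

    One sample (cell line) is held out per fold; held-out squared errors
    are pooled over every (sample, drug) entry.  The selected Lambda is the
    smallest grid value whose MSE is within ``flat_tol`` (relative) of the
    minimum MSE over that value and all larger ones — the point where the
    CV curve becomes essentially flat.

    Fold fits default to the exact proximal engine (``method='prox'``),
    which reaches the same minimizers as SPG up to the smoothing gap at a
    fraction of the cost; pass ``method='spg'`` to cross-validate with the
    smoothed objective itself.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < 3:
        raise ValueError("need >= 3 samples for leave-one-out CV")
    if lam_grid_values is None:
        grid = lambda_grid(X, Y)
    else:
        grid = np.asarray(list(lam_grid_values), dtype=float)
        if grid.size == 0:
            raise ValueError("lambda grid is empty")
        uniq = np.unique(grid)
        if uniq.size < grid.size:
            import warnings

            warnings.warn("duplicate lambda values removed from grid")
        grid = np.sort(uniq)
    if weights is None:
        weights = node_weights(tree) if tree is not None else lasso_weights(
            Y.shape[1]
        )

    sq_err = np.zeros(grid.size)
    for holdout in range(n):
        mask = np.ones(n, dtype=bool)
        mask[holdout] = False
        Xtr, Ytr = X[mask], Y[mask]
        B0 = None
        # fit the path from the most to the least penalized, warm-starting
        for gi in range(grid.size - 1, -1, -1):
            model = spg_fit(
                Xtr, Ytr, lam=float(grid[gi]), mu=mu, tol=tol,
                max_iter=max_iter, B0=B0, weights=weights, method=method,
            )
            B0 = model.B
            pred = model.predict(X[holdout][None, :])
            sq_err[gi] += float(np.sum((pred - Y[holdout]) ** 2))
    mse = sq_err / (n * Y.shape[1])

    selected_index = grid.size - 1
    for i in range(grid.size):
        tail_min = float(np.min(mse[i:]))
        if mse[i] <= (1.0 + flat_tol) * tail_min:
            selected_index = i
            break
    rule = (
        f"smallest lambda with MSE within {flat_tol:.0%} of the minimum over "
        "itself and all larger lambdas"
    )
    return CvResult(
        lam_grid=grid, mse=mse, selected_lam=float(grid[selected_index]),
        selected_index=int(selected_index), rule=rule, n_folds=n,
    )


def fit_cv(
    X,
    Y,
    tree: DrugTree | None = None,
    lam_grid_values: Sequence[float] | None = None,
    mu: float = DEFAULT_MU,
    flat_tol: float = 0.02,
    cv_tol: float = 1e-6,
    cv_max_iter: int = 3000,
    weights: PenaltyWeights | None = None,
) -> tuple[TreeLassoModel, CvResult]:
    """LOO-CV Lambda selection followed by a full-data fit at the optimum."""
    cv = loo_cv(
        X, Y, tree=tree, lam_grid_values=lam_grid_values, mu=mu,
        flat_tol=flat_tol, tol=cv_tol, max_iter=cv_max_iter, weights=weights,
    )
    model = spg_fit(X, Y, tree=tree, lam=cv.selected_lam, mu=mu,
                    weights=weights)
    return model, cv


def r_squared(model: TreeLassoModel, X, Y) -> float:
    """R^2 = 1 - RSS/TSS, pooled over every (sample, drug) entry.

    TSS is taken around per-drug means, so an intercept-only model scores 0.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    pred = model.predict(X)
    rss = float(np.sum((Y - pred) ** 2))
    tss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    if tss == 0:
        raise ValueError("total sum of squares is zero")
    return 1.0 - rss / tss


def filter_coefficients_for_display(
    B: pd.DataFrame, fraction: float = 0.05
) -> pd.DataFrame:
    """Drop negligible feature rows from a coefficient matrix.

    A row is dropped when its coefficients are exactly zero for all drugs,
    or when for *every* drug its absolute coefficient is strictly below
    ``fraction`` of that drug's total absolute coefficient mass.
    """
    absB = B.abs()
    col_mass = absB.sum(axis=0)
    nonzero = (absB.sum(axis=1) > 0)
    # strict <: a row exactly at the threshold for some drug is retained
    visible = (absB >= fraction * col_mass).any(axis=1)
    return B.loc[nonzero & visible]
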
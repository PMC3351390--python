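"""Phylogenetic signal in species traits: Blomberg's K and Pagel's lambda.

Both statistics ask whether closely related species resemble each other more
than expected by chance, against the Brownian-motion (BM) expectation encoded
in the among-species covariance matrix ``V`` of a rooted tree with branch
lengths (``V[i, j]`` = shared root-to-tip path length of tips i and j).

* Blomberg's K compares the observed ratio of the mean squared error around
  the phylogenetic mean to its GLS counterpart with the ratio expected under
  BM on the given tree; K = 1 matches BM, K near 0 means no signal.
* Pagel's lambda rescales the off-diagonal entries of ``V`` by a factor in
  [0, 1] and picks the value maximizing the multivariate-normal likelihood of
  the trait; lambda = 0 is a star phylogeny (no signal), lambda = 1 the
  untransformed tree.

Values close to zero for a trait suggest no phylogenetic pseudo-replication,
in which case species values can be analyzed as independent observations; the
decision is exposed as an advisory, never applied silently.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "Phylogeny",
    "SignalResult",
    "TreeError",
    "read_newick",
    "vcv",
    "lambda_transform",
    "blomberg_k",
    "pagel_lambda",
    "signal_table",
    "correction_advised",
]


class TreeError(ValueError):
    """Malformed tree input or a tree/trait-table mismatch."""


@dataclass(frozen=True)
class Phylogeny:
    """A rooted tree with branch lengths, wrapping a dendropy tree."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tree.taxon_namespace)

    @property
    def n_tips(self) -> int:
        return len(self.tree.taxon_namespace)

    def write_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(source: str) -> Phylogeny:
    """Parse a Newick string (or path contents) into a validated Phylogeny.

    Every non-root edge must carry a branch length; unifurcations are
    collapsed so internal nodes have at least two children.
    """
    try:
        tree = dendropy.Tree.get(
            data=source,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    tree.suppress_unifurcations()
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate tip labels")
    if len(labels) < 2:
        raise TreeError("tree needs at least two tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeError(
                f"missing branch length above node "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
        if not np.isfinite(edge.length) or edge.length < 0:
            raise TreeError("branch lengths must be finite and nonnegative")
    return Phylogeny(tree)


def vcv(phylo: Phylogeny, order: tuple[str, ...] | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Among-species covariance matrix of a tree under Brownian motion.

    ``V[i, j]`` is the shared root-to-tip path length of tips i and j
    (computed as ``(d_i + d_j - patristic(i, j)) / 2``); the diagonal holds
    root-to-tip distances.  Returns ``(V, labels)`` in the requested species
    order (default: taxon-namespace order).
    """
    tree = phylo.tree
    tips = {t.label: t for t in tree.taxon_namespace}
    labels = tuple(order) if order is not None else phylo.tip_labels
    missing = [lab for lab in labels if lab not in tips]
    if missing:
        raise TreeError(f"species absent from tree: {missing}")
    tree.calc_node_root_distances(
        return_leaf_distances_only=False
    )
    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[leaf.taxon.label] = leaf.root_distance
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        V[i, i] = depth[a]
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(tips[a], tips[b])
            V[i, j] = V[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return V, labels


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal entries of V by ``lam``, leaving the diagonal
    unchanged: identity at ``lam = 1``, star phylogeny at ``lam = 0``."""
    Vl = lam * np.asarray(V, float)
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _safe_cholesky(V: np.ndarray) -> np.ndarray:
    """Cholesky with a documented ridge fallback for singular V (e.g. zero
    terminal branch lengths)."""
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * float(np.mean(np.diag(V)))
        warnings.warn(
            f"tree covariance singular; adding ridge {ridge:g} to the diagonal"
        )
        return np.linalg.cholesky(V + ridge * np.eye(V.shape[0]))


def _gls_mean_and_quadratics(y: np.ndarray, V: np.ndarray):
    """GLS phylogenetic mean and the quadratic forms used by K and lambda."""
    L = _safe_cholesky(V)
    ones = np.ones(len(y))
    Li_y = np.linalg.solve(L, y)
    Li_1 = np.linalg.solve(L, ones)
    denom = Li_1 @ Li_1  # 1' V^-1 1
    a_hat = (Li_1 @ Li_y) / denom
    resid_white = Li_y - a_hat * Li_1
    mse = resid_white @ resid_white  # (y - a)' V^-1 (y - a)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return a_hat, denom, mse, logdet


def blomberg_k(y: np.ndarray, V: np.ndarray) -> float:
    """Blomberg's K for a trait vector against a tree covariance matrix.

    K = [MSE0 / MSE]_observed / [(tr(V) - n / (1' V^-1 1)) / (n - 1)],
    with the phylogenetic GLS mean a_hat = (1'V^-1 1)^-1 1'V^-1 y,
    MSE0 = (y - a_hat)'(y - a_hat) / (n - 1) and
    MSE = (y - a_hat)'V^-1(y - a_hat) / (n - 1).

    K is scale- and shift-invariant in y; a constant trait has no defined K.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant; K undefined")
    a_hat, denom, mse, _ = _gls_mean_and_quadratics(y, np.asarray(V, float))
    mse0 = float((y - a_hat) @ (y - a_hat))
    expected = (np.trace(V) - n / denom) / (n - 1)
    observed = mse0 / mse
    return float(observed / expected)


def _lambda_neg_loglik(lam: float, y: np.ndarray, V: np.ndarray) -> float:
    n = len(y)
    Vl = lambda_transform(V, lam)
    try:
        _, _, mse, logdet = _gls_mean_and_quadratics(y, Vl)
    except np.linalg.LinAlgError:
        return np.inf
    sigma2 = mse / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return np.inf
    return 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda(y: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Pagel's lambda on [0, 1] and its log-likelihood.

    The likelihood is the multivariate normal of ``y`` with mean ``a 1`` and
    covariance ``sigma^2 V(lambda)``, profiled analytically over ``a`` and
    ``sigma^2`` and maximized over lambda by bounded scalar search (tolerance
    1e-6), with the boundary values checked explicitly.
    """
    y = np.asarray(y, float)
    V = np.asarray(V, float)
    if len(y) < 3:
        raise ValueError("need at least 3 species")
    res = optimize.minimize_scalar(
        _lambda_neg_loglik,
        bounds=(0.0, 1.0),
        args=(y, V),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(float(res.x), float(res.fun))]
    for lam in (0.0, 1.0):
        candidates.append((lam, float(_lambda_neg_loglik(lam, y, V))))
    lam_hat, nll = min(candidates, key=lambda t: t[1])
    return lam_hat, -nll


@dataclass(frozen=True)
class SignalResult:
    """Phylogenetic signal estimates for one trait."""

    trait: str
    K: float
    lam: float
    logL_lambda: float
    n_tips: int


def signal_table(table, phylo: Phylogeny, columns=None) -> list[SignalResult]:
    """Blomberg's K and Pagel's lambda for every trait column, with species
    matched to tree tips by label (row order is irrelevant).

    ``table`` is a :class:`~endopath.sem.TraitTable`; species sets must match
    the tree's tips exactly.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    species = set(table.species)
    tips = set(phylo.tip_labels)
    if species != tips:
        raise TreeError(
            f"species/tree mismatch: only in table {sorted(species - tips)}, "
            f"only in tree {sorted(tips - species)}"
        )
    order = tuple(sorted(species))
    V, _ = vcv(phylo, order)
    df = table.data.loc[list(order)]
    out = []
    for c in cols:
        y = df[c].to_numpy(float)
        lam, logl = pagel_lambda(y, V)
        out.append(
            SignalResult(
                trait=c,
                K=blomberg_k(y, V),
                lam=lam,
                logL_lambda=logl,
                n_tips=len(order),
            )
        )
    return out


def signal_frame(results: list[SignalResult]) -> pd.DataFrame:
    """CSV-ready frame with columns variable, K, lambda, logL."""
    return pd.DataFrame(
        [
            {"variable": r.trait, "K": r.K, "lambda": r.lam, "logL": r.logL_lambda}
            for r in results
        ]
    )


def correction_advised(
    results: list[SignalResult],
    k_threshold: float = 0.5,
    lambda_threshold: float = 0.5,
) -> bool:
    """Advisory: does any trait show enough signal (K or lambda above its
    threshold) to warrant phylogenetically corrected analysis?

    The thresholds are user policy — "close to zero" has no canonical cutoff —
    and the advisory is informational only; no correction is ever applied
    automatically.
    """
    return any(
        r.K > k_threshold or r.lam > lambda_threshold for r in results
    )
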
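"""Phylogenetic signal and ancestral reconstruction of temperature preference.

Genus-level thermal preference (mean Bio1/Bio6 over a genus's band records)
is treated as a continuous trait evolving by Brownian motion (BM) on the
chronogram.  Two quantities are computed:

* **Pagel's λ** — a multiplier on the off-diagonal (shared-history) entries
  of the BM tip covariance; λ̂ maximizes the multivariate-normal likelihood,
  profiling out the root state (GLS mean) and the BM rate σ², over λ∈[0,1].
  λ = 1 is pure BM, λ = 0 phylogenetic independence; the LR test against
  λ = 0 uses χ² with 1 df.
* **ML ancestral states** — for each internal node, the BM maximum-likelihood
  estimate equals the GLS root estimate of the tree re-rooted at that node.
  It is computed here in linear time with a two-pass (tip-to-root then
  root-to-tip) message-passing scheme; the variance is σ̂² times the pooled
  message variance, and the 95% CI is the ±1.96·sd normal interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .phylo import Chronogram

__all__ = [
    "LambdaFit",
    "ASRResult",
    "genus_temp_pref",
    "bm_covariance",
    "lambda_transform",
    "pagel_lambda",
    "asr_bm",
]


def genus_temp_pref(
    records: pd.DataFrame,
    stats: pd.DataFrame,
    variable: str = "bio1",
) -> tuple[pd.Series, list[str]]:
    """Per-genus thermal preference: mean band climate over the genus records.

    Every occurrence record contributes the climate value attached to its
    (gradient, band); the unweighted mean is pooled across gradients.
    Genera whose records carry no climate value are excluded and returned in
    the dropped list.
    """
    variable = variable.lower()
    if variable not in stats.columns:
        raise KeyError(f"band statistics carry no column {variable!r}")
    merged = records.merge(
        stats[["gradient_id", "elevation_m", variable]],
        on=["gradient_id", "elevation_m"],
        how="left",
    )
    merged = merged.rename(columns={variable: "value"})
    pref = merged.dropna(subset=["value"]).groupby("genus")["value"].mean()
    dropped = sorted(set(records["genus"]) - set(pref.index))
    return pref.sort_index(), dropped


def bm_covariance(tree: Chronogram, taxa: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """BM tip covariance: C[i, j] = shared path length from the root (Myr).

    Diagonals are root-to-tip distances (the crown age on an ultrametric
    tree).  Computed by one preorder sweep assigning each internal node's
    root distance to the tip pairs whose most recent common ancestor it is.
    """
    labels = taxa if taxa is not None else tree.tip_labels
    index = {tree.resolve_tip(l): i for i, l in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    root = tree.tree.seed_node
    root_dist = {root: 0.0}
    # leaf sets per node restricted to requested taxa
    leafset: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            leafset[node] = [index[lab]] if lab in index else []
        else:
            leafset[node] = [i for ch in node.child_nodes() for i in leafset[ch]]
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is not None:
            root_dist[node] = root_dist[node.parent_node] + node.edge.length
        if node.is_leaf():
            i = leafset[node][0] if leafset[node] else None
            if i is not None:
                C[i, i] = root_dist[node]
        else:
            children = node.child_nodes()
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in leafset[children[a]]:
                        for j in leafset[children[b]]:
                            C[i, j] = C[j, i] = root_dist[node]
    return C, list(labels)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariance entries by λ, keeping the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


@dataclass
class LambdaFit:
    lam: float
    loglik: float
    loglik_zero: float
    loglik_one: float
    lr_stat: float
    p: float
    sigma2: float
    root_state: float
    n: int


def _profile_loglik(C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(logL, σ̂², μ̂) of a BM model with covariance σ²·C, profiling μ and σ²."""
    n = len(y)
    try:
        cf = sla.cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular trait covariance (zero-length structure in the tree?)"
        ) from exc
    one = np.ones(n)
    Ci1 = sla.cho_solve(cf, one)
    Ciy = sla.cho_solve(cf, y)
    mu = float(one @ Ciy / (one @ Ci1))
    r = y - mu
    q = float(r @ sla.cho_solve(cf, r))
    sigma2 = q / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, sigma2, mu


def pagel_lambda(tree: Chronogram, trait: pd.Series, xatol: float = 1e-6) -> LambdaFit:
    """ML estimate of Pagel's λ for a tip trait, bounded to [0, 1].

    The 1-D profile likelihood over λ is maximized by bounded Brent search;
    both endpoints are evaluated explicitly so λ̂ = 0 and λ̂ = 1 are exact
    when they are the optimum.  The p value is the LR test of λ̂ against
    λ = 0 on χ²₁.
    """
    trait = trait.dropna()
    if len(trait) < 4:
        raise ValueError("need trait values for at least 4 tips")
    taxa = [t for t in trait.index if tree.has_tip(t)]
    if len(taxa) < 4:
        raise ValueError("fewer than 4 trait genera are tips of the tree")
    y = trait.loc[taxa].to_numpy(dtype=float)
    C, _ = bm_covariance(tree, taxa)

    def nll(lam: float) -> float:
        return -_profile_loglik(lambda_transform(C, lam), y)[0]

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": xatol})
    candidates = [(0.0, -nll(0.0)), (1.0, -nll(1.0)), (float(res.x), -float(res.fun))]
    lam_hat, ll_hat = max(candidates, key=lambda c: c[1])
    ll0 = candidates[0][1]
    ll1 = candidates[1][1]
    _, sigma2, mu = _profile_loglik(lambda_transform(C, lam_hat), y)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    return LambdaFit(
        lam=lam_hat, loglik=ll_hat, loglik_zero=ll0, loglik_one=ll1,
        lr_stat=lr, p=float(chi2.sf(lr, 1)), sigma2=sigma2, root_state=mu,
        n=len(y),
    )


@dataclass
class ASRResult:
    estimates: pd.DataFrame   # node_id, estimate, variance, ci_low, ci_high
    sigma2: float
    root_state: float

    def annotated_newick(self, tree: Chronogram) -> str:
        """Newick with internal-node comments carrying the estimates."""
        est = dict(zip(self.estimates["node_id"], self.estimates["estimate"]))
        t = tree.tree.extract_tree()
        for node, nid in zip(
            (n for n in t.preorder_node_iter() if not n.is_leaf()),
            (r for r in self.estimates["node_id"]),
        ):
            node.label = f"{est[nid]:.4f}"
        return t.as_string(schema="newick", suppress_rooting=True,
                           unquoted_underscores=True).strip() + "\n"


def asr_bm(tree: Chronogram, trait: pd.Series, lam: float | None = None) -> ASRResult:
    """ML (GLS) ancestral states under Brownian motion.

    Internal-node estimates come from two message-passing sweeps (each node's
    estimate pools the information arriving from every adjacent subtree,
    i.e. the GLS root estimate of the tree re-rooted there).  By default the
    tree is used untransformed; ``lam`` reconstructs on a λ-scaled tree
    (terminal shares of root-to-tip paths stretched to keep the diagonal).

    Every tip of the tree must carry a trait value.
    """
    missing = [t for t in tree.tip_labels if t not in trait.index or pd.isna(trait.get(t))]
    if missing:
        raise ValueError(f"tips without trait values: {missing[:5]}")
    y = trait
    C, taxa = bm_covariance(tree)
    Cw = C if lam is None else lambda_transform(C, lam)
    _, sigma2, mu = _profile_loglik(Cw, y.loc[taxa].to_numpy(dtype=float))

    # branch lengths, λ-scaled if requested: internal edges ×λ, terminal
    # edges stretched so tip depth (diagonal) is preserved
    dtree = tree.tree

    def edge_len(node) -> float:
        L = node.edge.length
        if lam is None:
            return L
        if node.is_leaf():
            root_to_tip = tree.root_depth - 0.0  # ultrametric diagonal
            # tip variance kept: lam * (path - L) + L' = path  =>  L' = path - lam*(path - L)
            path = _root_distance(tree, node)
            return path - lam * (path - L)
        return lam * L

    down: dict = {}   # node -> (x, v): estimate and scaled variance from below
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            down[node] = (float(y[node.taxon.label]), 0.0)
        else:
            w = x = 0.0
            for ch in node.child_nodes():
                xc, vc = down[ch]
                wc = 1.0 / (vc + edge_len(ch))
                w += wc
                x += wc * xc
            down[node] = (x / w, 1.0 / w)

    up: dict = {}     # node -> (x, v) message from the rest of the tree
    root = dtree.seed_node
    up[root] = None
    rows = []
    node_counter = 0
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            continue
        # combine down message with up message (if any)
        xd, vd = down[node]
        if up[node] is None:
            est, var = xd, sigma2 * vd
        else:
            xu, vu = up[node]
            w1, w2 = 1.0 / vd if vd > 0 else np.inf, 1.0 / vu
            if np.isinf(w1):
                est, var = xd, 0.0
            else:
                est = (w1 * xd + w2 * xu) / (w1 + w2)
                var = sigma2 / (w1 + w2)
        node_counter += 1
        nid = f"nd{node_counter}"
        sd = np.sqrt(var)
        rows.append((nid, est, var, est - 1.96 * sd, est + 1.96 * sd))
        # messages to children: pool up[node] with the other children
        for ch in node.child_nodes():
            parts = []
            if up[node] is not None:
                parts.append(up[node])
            for sib in node.child_nodes():
                if sib is not ch:
                    xs, vs = down[sib]
                    parts.append((xs, vs + edge_len(sib)))
            w = sum(1.0 / v if v > 0 else np.inf for _, v in parts)
            if np.isinf(w):
                x0 = next(x for x, v in parts if v == 0)
                up[ch] = (x0, edge_len(ch))
            else:
                x0 = sum(x / v for x, v in parts) / w
                up[ch] = (x0, 1.0 / w + edge_len(ch))

    est_df = pd.DataFrame(rows, columns=["node_id", "estimate", "variance",
                                         "ci_low", "ci_high"])
    return ASRResult(estimates=est_df, sigma2=sigma2, root_state=mu)


def _root_distance(tree: Chronogram, node) -> float:
    d = 0.0
    while node.parent_node is not None:
        d += node.edge.length
        node = node.parent_node
    return d
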
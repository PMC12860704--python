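"""Lipid correlation networks: marginal and debiased sparse partial.

Two network kinds are built per experimental group and compared:

* **pearson** — all pairwise Pearson correlations; p-values from the
  Fisher Z-transformation (z = atanh r, SE = 1/sqrt(n-3), two-tailed
  normal), BH-adjusted across all pairs; an edge is reported significant
  when the adjusted p < 0.05 AND |r| > 0.7.
* **dspc** — debiased sparse partial correlations for the p >~ n regime:
  node-wise lasso regressions estimate a sparse precision matrix, a
  de-biasing correction restores an asymptotically normal estimator per
  entry, and edges with p < alpha (default 0.1) are flagged.

Group differences are assessed with Fisher's exact test on a 2x2 table of
significant vs non-significant edges incident to a chosen node stratum
(e.g. unsaturated free fatty acids), over the identical edge universe in
both groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV

from .core import AbundanceMatrix, ContractError
from .differential import benjamini_hochberg


@dataclass
class LipidNetwork:
    """Node set plus scored edges for one group's correlation structure.

    ``edges`` columns: u, v (u < v lexicographically), estimate (r or
    partial r), p, q (BH), significant.
    """

    nodes: list[str]
    edges: pd.DataFrame
    kind: str  # pearson | dspc
    group_label: str
    n_samples: int
    node_annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("pearson", "dspc"):
            raise ContractError(f"unknown network kind {self.kind!r}")
        if len(self.edges):
            if (self.edges["u"] == self.edges["v"]).any():
                raise ContractError("self-edges are not allowed")
            pairs = list(zip(self.edges["u"], self.edges["v"]))
            if len(set(map(frozenset, pairs))) != len(pairs):
                raise ContractError("duplicate edges for an unordered pair")

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]


def _pair_frame(names: list[str], est: np.ndarray, p: np.ndarray) -> pd.DataFrame:
    iu, ju = np.triu_indices(len(names), k=1)
    return pd.DataFrame(
        {
            "u": [names[i] for i in iu],
            "v": [names[j] for j in ju],
            "estimate": est[iu, ju],
            "p": p[iu, ju],
        }
    )


def fisher_z_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p for H0: rho=0 via Fisher Z (atanh r, SE 1/sqrt(n-3))."""
    if n <= 3:
        raise ContractError("Fisher Z undefined for n <= 3")
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r) * np.sqrt(n - 3)
    # floor at the smallest positive float: downstream BH requires p in (0, 1]
    return np.maximum(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1))


def pearson_network(
    m: AbundanceMatrix,
    group: str,
    q_threshold: float = 0.05,
    r_min: float = 0.7,
) -> LipidNetwork:
    """All-pairs Pearson network for one group's samples.

    Edge significance is conjunctive: BH-adjusted p < ``q_threshold`` and
    |r| > ``r_min``.
    """
    m.require_stage("zscore")
    cols = m.group_columns(group)
    n = len(cols)
    if n <= 3:
        raise ContractError("Fisher Z undefined: need n > 3 samples")
    x = m.data[cols].to_numpy()
    keep = x.std(axis=1, ddof=1) > 0
    if not keep.all():
        warnings.warn(
            f"pearson_network: excluding {int((~keep).sum())} constant feature(s)",
            stacklevel=2,
        )
    names = [f for f, k in zip(m.feature_names, keep) if k]
    x = x[keep]
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    p = fisher_z_pvalue(r, n)
    edges = _pair_frame(names, r, p)
    edges["q"] = benjamini_hochberg(np.clip(edges["p"], np.nextafter(0, 1), 1.0))
    edges["significant"] = (edges["q"] < q_threshold) & (edges["estimate"].abs() > r_min)
    return LipidNetwork(
        nodes=names, edges=edges, kind="pearson", group_label=group, n_samples=n
    )


# -- class-stratum profiles ------------------------------------------------

def stratum_means(m: AbundanceMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Mean z-score per class stratum (class x saturated/unsaturated) per sample."""
    ann = annotation.reindex(m.feature_names)
    sat = np.where(ann["double_bonds"] == 0, "saturated", "unsaturated")
    label = pd.Series(sat, index=ann.index) + " " + ann["class"].astype(str)
    return m.data.groupby(label, sort=False).mean()


def ffa_correlation_profile(
    m: AbundanceMatrix,
    annotation: pd.DataFrame,
    group: str,
    ffa_saturation: str = "unsaturated",
    q_threshold: float = 0.05,
    r_min: float = 0.7,
) -> pd.DataFrame:
    """Correlate one FFA saturation stratum with every other class stratum.

    Operates on per-stratum mean z-scores within the given group's
    samples.  Returns a frame (stratum, r, p, q, significant) with the
    conjunctive significance rule of the pearson kind.
    """
    if ffa_saturation not in ("saturated", "unsaturated"):
        raise ContractError("ffa_saturation must be 'saturated' or 'unsaturated'")
    m.require_stage("zscore")
    cols = m.group_columns(group)
    n = len(cols)
    if n <= 3:
        raise ContractError("Fisher Z undefined: need n > 3 samples")
    means = stratum_means(m, annotation)[cols]
    target = f"{ffa_saturation} FFA"
    if target not in means.index:
        raise ContractError(f"stratum {target!r} absent from the panel")
    ref = means.loc[target].to_numpy()
    rows = []
    for stratum, vals in means.iterrows():
        if stratum == target:
            continue
        v = vals.to_numpy()
        if np.std(v, ddof=1) == 0 or np.std(ref, ddof=1) == 0:
            continue
        r = float(np.corrcoef(ref, v)[0, 1])
        rows.append({"stratum": stratum, "r": r, "p": float(fisher_z_pvalue(np.array(r), n))})
    out = pd.DataFrame(rows).set_index("stratum")
    out["q"] = benjamini_hochberg(np.clip(out["p"], np.nextafter(0, 1), 1.0))
    out["significant"] = (out["q"] < q_threshold) & (out["r"].abs() > r_min)
    return out


# -- debiased sparse partial correlation ----------------------------------

def _nodewise_lasso(x: np.ndarray, cv: int, seed: int | None) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise lasso coefficients and residual scales.

    For each column j, lasso-regress x_j on the remaining columns with the
    penalty chosen by ``cv``-fold cross-validation.  Returns (B, tau2)
    where B[j] holds the coefficients (0 at position j) and
    tau2[j] = RSS_j/n + lambda_j * ||beta_j||_1, the scale that makes the
    node-wise precision estimate consistent.
    """
    n, p = x.shape
    B = np.zeros((p, p))
    tau2 = np.zeros(p)
    for j in range(p):
        others = np.delete(np.arange(p), j)
        y = x[:, j]
        X = x[:, others]
        model = LassoCV(
            cv=cv,
            alphas=50,
            random_state=seed,
            max_iter=5000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        beta = model.coef_
        resid = y - X @ beta
        lam = model.alpha_
        tau2[j] = resid @ resid / n + lam * np.abs(beta).sum()
        B[j, others] = beta
    return B, tau2


def debiased_partial_correlations(
    x: np.ndarray, cv: int = 10, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Debiased precision-based partial correlations with normal p-values.

    ``x`` is n x p (samples x features), internally standardized.  The
    sparse node-wise estimate Theta is de-biased as
    T = Theta + Theta' - Theta' Sigma Theta, which is asymptotically
    normal entrywise with variance (Theta_jj Theta_kk + Theta_jk^2)/n.
    Returns (partial correlation matrix, symmetric p-value matrix).
    """
    n, p = x.shape
    if n < 6:
        raise ContractError("dspc requires n >= 6 samples")
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    sigma = x.T @ x / n
    B, tau2 = _nodewise_lasso(x, cv=min(cv, n), seed=seed)
    theta = -B / tau2[:, None]
    np.fill_diagonal(theta, 1.0 / tau2)
    # de-bias: removes the lasso shrinkage bias, restoring sqrt(n)-normality
    T = theta + theta.T - theta.T @ sigma @ theta
    d = np.sqrt(np.abs(np.diag(T)))
    pc = -T / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    pc = np.clip((pc + pc.T) / 2, -1.0, 1.0)
    var = np.outer(np.diag(T), np.diag(T)) + T**2
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.sqrt(n) * T / np.sqrt(np.maximum(var, 1e-300))
    pmat = 2 * stats.norm.sf(np.abs(z))
    pmat = (pmat + pmat.T) / 2
    return pc, pmat


def dspc_network(
    m: AbundanceMatrix,
    group: str,
    alpha: float = 0.1,
    cv: int = 10,
    seed: int | None = 0,
) -> LipidNetwork:
    """Debiased sparse partial correlation network for one group.

    Works in the high-dimensional regime (features may exceed samples).
    Edges with p < ``alpha`` are flagged significant; BH-adjusted values
    are reported alongside but do not enter the flag (the network
    definition thresholds the raw edge p-value).
    """
    m.require_stage("zscore")
    cols = m.group_columns(group)
    n = len(cols)
    if n < 6:
        raise ContractError("dspc requires n >= 6 samples")
    x = m.data[cols].to_numpy().T  # samples x features
    keep = x.std(axis=0, ddof=1) > 0
    if not keep.all():
        warnings.warn(
            f"dspc_network: excluding {int((~keep).sum())} constant feature(s)",
            stacklevel=2,
        )
    names = [f for f, k in zip(m.feature_names, keep) if k]
    pc, pmat = debiased_partial_correlations(x[:, keep], cv=cv, seed=seed)
    edges = _pair_frame(names, pc, pmat)
    edges["q"] = benjamini_hochberg(np.clip(edges["p"], np.nextafter(0, 1), 1.0))
    edges["significant"] = edges["p"] < alpha
    return LipidNetwork(
        nodes=names, edges=edges, kind="dspc", group_label=group, n_samples=n
    )


# -- network comparison ----------------------------------------------------

@dataclass(frozen=True)
class EdgeContingency:
    """2x2 table: significant / non-significant edges x network A / B."""

    a: int  # significant in A
    b: int  # non-significant in A
    c: int  # significant in B
    d: int  # non-significant in B

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractError("contingency counts must be nonnegative")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_test(table: EdgeContingency | np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact p and conditional-MLE odds ratio for a 2x2 table."""
    t = table.table if isinstance(table, EdgeContingency) else np.asarray(table)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    orr = stats.contingency.odds_ratio(t, kind="conditional")
    return float(orr.statistic), float(p)


def edge_contingency_compare(
    netA: LipidNetwork,
    netB: LipidNetwork,
    node_filter: list[str] | set[str],
) -> tuple[EdgeContingency, float, float]:
    """Compare two networks' significant-edge rates around a node stratum.

    The edge universe is every unordered candidate pair incident to at
    least one node in ``node_filter`` and present in both networks, so the
    two denominators are identical.  Returns (table, odds ratio, p).
    """
    if netA.kind != netB.kind:
        raise ContractError("cannot compare networks of different kinds")
    stratum = set(node_filter)
    common = set(netA.nodes) & set(netB.nodes)

    def filtered(net: LipidNetwork) -> pd.DataFrame:
        e = net.edges
        mask = (
            (e["u"].isin(stratum) | e["v"].isin(stratum))
            & e["u"].isin(common)
            & e["v"].isin(common)
        )
        sub = e[mask].copy()
        sub["pair"] = [frozenset(t) for t in zip(sub["u"], sub["v"])]
        return sub.set_index("pair")

    ea, eb = filtered(netA), filtered(netB)
    universe = ea.index.intersection(eb.index)
    if len(universe) == 0:
        raise ContractError("empty edge universe after node filtering")
    sa = ea.loc[universe, "significant"].astype(bool)
    sb = eb.loc[universe, "significant"].astype(bool)
    table = EdgeContingency(
        a=int(sa.sum()),
        b=int((~sa).sum()),
        c=int(sb.sum()),
        d=int((~sb).sum()),
    )
    orr, p = fisher_exact_test(table)
    return table, orr, p


# -- export ----------------------------------------------------------------

def to_networkx(net: LipidNetwork, significant_only: bool = False) -> nx.Graph:
    g = nx.Graph(kind=net.kind, group=net.group_label, n_samples=net.n_samples)
    g.add_nodes_from(net.nodes)
    edges = net.significant_edges() if significant_only else net.edges
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.u,
            row.v,
            estimate=float(row.estimate),
            p=float(row.p),
            q=float(row.q),
            significant=bool(row.significant),
        )
    return g


def export_network(net: LipidNetwork, path, format: str = "edge-CSV") -> None:
    """Write a network to SIF, GraphML, or tidy edge-CSV.

    edge-CSV is lossless (re-import reproduces the network); SIF and
    GraphML carry estimate/p/q/significant as attributes.
    """
    path = Path(path)
    if format == "edge-CSV":
        meta = f"# kind={net.kind} group={net.group_label} n_samples={net.n_samples}\n"
        with open(path, "w") as fh:
            fh.write(meta)
            net.edges.to_csv(fh, index=False)
    elif format == "SIF":
        with open(path, "w") as fh:
            for row in net.edges.itertuples(index=False):
                rel = "pos" if row.estimate >= 0 else "neg"
                fh.write(f"{row.u}\t{rel}\t{row.v}\n")
    elif format == "GraphML":
        nx.write_graphml(to_networkx(net), path)
    else:
        raise ContractError(f"unknown export format {format!r}")


def import_edge_csv(path) -> LipidNetwork:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(tok.split("=") for tok in header.split())
        edges = pd.read_csv(fh)
    if len(edges):
        edges["significant"] = edges["significant"].astype(bool)
    nodes = sorted(set(edges["u"]) | set(edges["v"])) if len(edges) else []
    return LipidNetwork(
        nodes=nodes,
        edges=edges,
        kind=meta["kind"],
        group_label=meta["group"],
        n_samples=int(meta["n_samples"]),
    )
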
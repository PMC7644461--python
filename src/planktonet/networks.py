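"""Spearman correlation networks with Monte-Carlo permutation p-values.

For every unordered pair of taxa in a period-sliced abundance matrix the
Spearman rank correlation is computed and its two-sided significance
estimated by Monte-Carlo permutation (9999 iterations by default, add-one
estimator so p is never zero).  Pairs with p below the significance level
(0.05 by default, uncorrected) become edges; three networks are produced per
period: negative-only, positive-only, and the combined network that merges
both edge sets.  Node sets contain only non-isolated taxa, which is why the
combined network can have more nodes than either signed network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["taxon_a", "taxon_b", "rho", "p", "sign"]


@dataclass
class CorrelationNetwork:
    """A signed, weighted, p-valued correlation network for one period."""

    period_label: str
    sign_mode: str  # "negative" | "positive" | "combined"
    edges: pd.DataFrame  # columns: taxon_a, taxon_b, rho, p, sign
    alpha: float
    n_permutations: int
    dropped_taxa: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sign_mode not in ("negative", "positive", "combined"):
            raise ValueError(f"unknown sign_mode {self.sign_mode!r}")
        e = self.edges
        if list(e.columns) != EDGE_COLUMNS:
            raise ValueError(f"edge table must have columns {EDGE_COLUMNS}")
        if len(e):
            if (e["taxon_a"] >= e["taxon_b"]).any():
                raise ValueError("edges must satisfy taxon_a < taxon_b")
            if (e["p"] >= self.alpha).any():
                raise ValueError("edge with p >= alpha")
            if self.sign_mode == "negative" and (e["rho"] >= 0).any():
                raise ValueError("positive rho in negative network")
            if self.sign_mode == "positive" and (e["rho"] <= 0).any():
                raise ValueError("negative rho in positive network")

    @property
    def nodes(self) -> list[int]:
        """Non-isolated taxa: exactly the endpoints of the edges."""
        if not len(self.edges):
            return []
        return sorted(
            set(self.edges["taxon_a"].astype(int)) | set(self.edges["taxon_b"].astype(int))
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[int, int]:
        deg: dict[int, int] = {t: 0 for t in self.nodes}
        for a, b in zip(self.edges["taxon_a"], self.edges["taxon_b"]):
            deg[int(a)] += 1
            deg[int(b)] += 1
        return deg


@dataclass
class NetworkDescriptors:
    """Table-style structural descriptors of one network."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    pct_negative: int | None
    degree_by_node: dict[int, int]
    hubs: list[tuple[int, int]]  # (taxon_id, degree), degree descending


def _validated_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant series")
    return x, y


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x, y = _validated_pair(x, y)
    return float(stats.spearmanr(x, y).statistic)


def _rank_center(v: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v)
    return r - r.mean()


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_iter: int = 9999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Two-sided Monte-Carlo permutation test of the Spearman correlation.

    The second series is shuffled by independent uniform permutations and the
    p-value uses the add-one estimator
    ``p = (1 + #{|rho_b| >= |rho_obs|}) / (n_iter + 1)``, so ``p`` lies in
    ``(0, 1]`` and is deterministic for a fixed seed.
    """
    x, y = _validated_pair(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rx = _rank_center(x)
    ry = _rank_center(y)
    n = len(x)
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    rho_obs = float(rx @ ry / denom)
    # permutation matrix: argsort of uniforms gives uniform random permutations
    perms = rng.random((n_iter, n)).argsort(axis=1)
    rho_b = (ry[perms] @ rx) / denom
    n_extreme = int(np.sum(np.abs(rho_b) >= abs(rho_obs) - 1e-12))
    p = (1 + n_extreme) / (n_iter + 1)
    return rho_obs, p


def _pair_rng(master_seed: int, a: int, b: int) -> np.random.Generator:
    # child stream keyed by the ordered taxon-ID pair: edge p-values do not
    # depend on the order pairs are evaluated in
    return np.random.default_rng([master_seed, int(a), int(b)])


def build_networks(
    m: pd.DataFrame,
    alpha: float = 0.05,
    n_iter: int = 9999,
    seed: int = 0,
    period_label: str = "",
) -> dict[str, CorrelationNetwork]:
    """Build negative, positive and combined networks from an abundance matrix.

    Columns constant within the period (taxa absent or unvarying) are dropped
    with a log message.  Every remaining unordered column pair is tested; the
    combined network is the disjoint union of the signed edge sets.
    """
    if len(m) < 4:
        raise ValueError("need at least 4 samples to build networks")
    values = m.to_numpy(dtype=float)
    cols = [int(c) for c in m.columns]
    keep = [i for i in range(len(cols)) if np.ptp(values[:, i]) > 0]
    dropped = [cols[i] for i in range(len(cols)) if i not in set(keep)]
    if dropped:
        logger.info("dropping %d constant-in-period taxa: %s", len(dropped), dropped)
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant taxa in period")
    ranks = {cols[i]: _rank_center(values[:, i]) for i in keep}
    ids = sorted(ranks)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            rng = _pair_rng(seed, a, b)
            rho, p = permutation_pvalue(ranks[a], ranks[b], n_iter=n_iter, seed=rng)
            if p < alpha:
                rows.append((a, b, rho, p, "+" if rho > 0 else "-"))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    neg = edges[edges["rho"] < 0].reset_index(drop=True)
    pos = edges[edges["rho"] > 0].reset_index(drop=True)
    common = dict(alpha=alpha, n_permutations=n_iter, dropped_taxa=dropped)
    return {
        "negative": CorrelationNetwork(period_label, "negative", neg, **common),
        "positive": CorrelationNetwork(period_label, "positive", pos, **common),
        "combined": CorrelationNetwork(period_label, "combined", edges, **common),
    }


def summarize_counts(
    n_nodes: int, n_edges: int, n_negative: int | None = None
) -> tuple[float, int | None]:
    """Mean degree and percent-negative from raw node/edge counts.

    Mean degree is ``2E/N`` rounded to 2 decimals; percent negative is
    ``100 * E_neg / E`` rounded to the nearest integer.
    """
    mean_degree = round(2 * n_edges / n_nodes, 2) if n_nodes else 0.0
    pct = None
    if n_negative is not None and n_edges:
        pct = int(round(100 * n_negative / n_edges))
    return mean_degree, pct


def descriptors(
    net: CorrelationNetwork, e_neg: int | None = None, k_hubs: int = 3
) -> NetworkDescriptors:
    """Structural descriptors: N, E, mean degree, % negative, degrees, hubs."""
    n, e = net.n_nodes, net.n_edges
    if e_neg is None and net.sign_mode == "combined" and e:
        e_neg = int((net.edges["rho"] < 0).sum())
    mean_degree, pct = summarize_counts(n, e, e_neg)
    deg = net.degrees()
    return NetworkDescriptors(
        n_nodes=n,
        n_edges=e,
        mean_degree=mean_degree,
        pct_negative=pct,
        degree_by_node=deg,
        hubs=hubs(net, k=k_hubs),
    )


def hubs(net: CorrelationNetwork, k: int = 3) -> list[tuple[int, int]]:
    """Top-k taxa by degree (ties broken by ascending taxon ID)."""
    deg = net.degrees()
    if not deg:
        return []
    ranked = sorted(deg.items(), key=lambda t: (-t[1], t[0]))
    return ranked[:k]


def autocorrelation_report(m: pd.DataFrame, max_lag: int = 5) -> pd.DataFrame:
    """Per-taxon autocorrelation diagnostics at lags 1..max_lag.

    Lags whose sample ACF falls outside ``+-1.96/sqrt(n)`` are flagged.  This
    is purely diagnostic; no series is removed.  Constant columns yield
    missing ACF values.
    """
    from statsmodels.tsa.stattools import acf

    if len(m) < 8:
        raise ValueError("need at least 8 samples for autocorrelation diagnostics")
    n = len(m)
    bound = 1.96 / np.sqrt(n)
    rows = []
    for col in m.columns:
        v = m[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            for lag in range(1, max_lag + 1):
                rows.append((int(col), lag, np.nan, False))
            continue
        r = acf(v, nlags=max_lag, fft=False)
        for lag in range(1, max_lag + 1):
            rows.append((int(col), lag, float(r[lag]), bool(abs(r[lag]) > bound)))
    return pd.DataFrame(rows, columns=["taxon_id", "lag", "acf", "significant"])
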
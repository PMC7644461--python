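"""Synthetic plankton community generator.

Emulates a weekly coastal-lagoon monitoring campaign: a taxon catalogue
spanning the six microbial food-web compartments (viruses, bacteria,
phytoplankton, heterotrophic nanoflagellates, naked ciliates, tintinnids),
a daily chlorophyll-a fluorescence record with planted bloom windows, and a
weekly abundance matrix whose rank-correlation structure is planted through
a latent Gaussian copula.  Because Spearman correlation is invariant under
the monotone lognormal marginal transform, the planted latent correlations
are directly the rank correlations the downstream network inference should
recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Compartments in catalogue order (node IDs ascend in this order).
GROUP_ORDER = (
    "virus",
    "bacteria",
    "phytoplankton",
    "HF",
    "naked_ciliate",
    "tintinnid",
)

#: Default community partition: 110 taxa.
DEFAULT_GROUP_COUNTS = {
    "virus": 1,
    "bacteria": 2,
    "phytoplankton": 46,
    "HF": 4,
    "naked_ciliate": 28,
    "tintinnid": 29,
}

#: Equivalent spherical diameter ranges (um) per compartment.  Chosen so each
#: compartment spans realistic cell sizes: viruses well below a micron,
#: bacteria ~0.5 um, phytoplankton from picoeukaryotes to large diatoms,
#: nanoflagellates 2-15 um, ciliates tens of um, tintinnids the largest.
DEFAULT_ESD_RANGES = {
    "virus": (0.05, 0.2),
    "bacteria": (0.4, 1.0),
    "phytoplankton": (1.0, 50.0),
    "HF": (2.0, 15.0),
    "naked_ciliate": (12.0, 90.0),
    "tintinnid": (30.0, 130.0),
}

#: Abundance scale (geometric mean, organisms per mL) per compartment.
DEFAULT_ABUNDANCE_SCALE = {
    "virus": 1e7,
    "bacteria": 1e6,
    "phytoplankton": 1e3,
    "HF": 1e3,
    "naked_ciliate": 10.0,
    "tintinnid": 5.0,
}


def generate_taxa(
    group_counts: dict[str, int] | None = None,
    esd_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a taxon catalogue.

    Taxon IDs are contiguous from 1 and assigned in fixed compartment order
    (viruses first, tintinnids last).  ESDs are drawn uniformly within each
    compartment's range.

    Returns a DataFrame with columns ``taxon_id, name, group, esd_um``.
    """
    counts = dict(DEFAULT_GROUP_COUNTS if group_counts is None else group_counts)
    ranges = dict(DEFAULT_ESD_RANGES)
    if esd_ranges is not None:
        ranges.update(esd_ranges)
    unknown = set(counts) - set(GROUP_ORDER)
    if unknown:
        raise ValueError(f"unknown groups: {sorted(unknown)}")
    for g, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for group {g!r}")
    if sum(counts.values()) == 0:
        raise ValueError("no taxa: all group counts are zero")
    rng = np.random.default_rng(seed)
    rows = []
    tid = 1
    for g in GROUP_ORDER:
        c = counts.get(g, 0)
        lo, hi = ranges[g]
        if not lo < hi:
            raise ValueError(f"invalid ESD range for group {g!r}: ({lo}, {hi})")
        esds = rng.uniform(lo, hi, size=c)
        for k in range(c):
            rows.append(
                {
                    "taxon_id": tid,
                    "name": f"{g} sp. {k + 1}",
                    "group": g,
                    "esd_um": float(esds[k]),
                }
            )
            tid += 1
    return pd.DataFrame(rows, columns=["taxon_id", "name", "group", "esd_um"])


def generate_fluorescence(
    n_days: int,
    bloom_windows: list[tuple[int, int]] | None = None,
    base_level: float = 1.0,
    bloom_amplitude: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    start_date: str = "2015-01-01",
    decay_days: int = 7,
) -> pd.Series:
    """Generate a daily fluorescence series with planted bloom windows.

    A window ``(s, e)`` (1-based day indices, inclusive) is the growth phase:
    the log-level ramps linearly from the baseline on day ``s-1`` up to
    ``log(1 + bloom_amplitude)`` above baseline on day ``e``, then relaxes
    back over ``decay_days`` days.  Daily log growth rates are therefore
    strictly positive on ``s..e`` and strictly negative on the following
    ``decay_days`` days, so a noise-free series is exactly recoverable by the
    bloom-detection rules.  Multiplicative lognormal noise with log-scale
    ``noise_sd`` is applied last.
    """
    if n_days < 2:
        raise ValueError("need at least 2 days")
    if base_level <= 0:
        raise ValueError("base_level must be positive")
    if bloom_amplitude < 0:
        raise ValueError("bloom_amplitude must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    windows = sorted(bloom_windows or [])
    prev_end = 0
    for s, e in windows:
        if not (1 <= s <= e <= n_days):
            raise ValueError(f"window ({s}, {e}) outside [1, {n_days}]")
        if s <= prev_end:
            raise ValueError(f"overlapping bloom windows at ({s}, {e})")
        prev_end = e

    amp = np.log1p(bloom_amplitude)
    bump = np.zeros(n_days)
    days = np.arange(1, n_days + 1)
    for s, e in windows:
        rise = (days >= s) & (days <= e)
        bump[rise] = np.maximum(bump[rise], amp * (days[rise] - (s - 1)) / (e - (s - 1)))
        fall = (days > e) & (days <= e + decay_days)
        bump[fall] = np.maximum(bump[fall], amp * (1.0 - (days[fall] - e) / decay_days))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=n_days) if noise_sd > 0 else np.zeros(n_days)
    values = base_level * np.exp(bump + noise)
    index = pd.date_range(start_date, periods=n_days, freq="D")
    return pd.Series(values, index=index, name="fluorescence")


@dataclass
class InteractionPlan:
    """Planted rank-correlation structure for the abundance generator.

    ``planted_edges`` holds ``(taxon_id_a, taxon_id_b, rho)`` triples with
    the sign carried by ``rho``; each unordered pair may appear once and
    ``|rho| < 1``.  ``noise_sd`` attenuates all planted correlations by
    mixing independent Gaussian noise into the latent field (attenuation
    factor ``1 / (1 + noise_sd**2)``); the default of zero plants the
    correlations exactly.
    """

    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sd: float = 0.0
    abundance_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCE_SCALE)
    )

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        seen: set[tuple[int, int]] = set()
        for a, b, rho in self.planted_edges:
            if a == b:
                raise ValueError(f"self pair ({a}, {b}) not allowed")
            if not abs(rho) < 1:
                raise ValueError(f"|rho| must be < 1, got {rho} for ({a}, {b})")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"pair {key} planted more than once")
            seen.add(key)


def default_interaction_plan(
    taxa: pd.DataFrame,
    n_positive: int = 15,
    n_negative: int = 15,
    rho: float = 0.9,
    seed: int = 0,
) -> InteractionPlan:
    """Build an ecologically flavoured default plan.

    Positive blocks mimic mutualism/commensalism (bacteria-phytoplankton and
    within-phytoplankton co-response); negative blocks mimic grazing
    (ciliates and tintinnids against phytoplankton and bacteria).  Pairs are
    node-disjoint so the planted correlation matrix is block diagonal and
    positive definite by construction; selection is deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    by_group = {g: taxa.loc[taxa["group"] == g, "taxon_id"].to_numpy() for g in GROUP_ORDER}
    producers = list(
        rng.permutation(np.concatenate([by_group["bacteria"], by_group["phytoplankton"]]))
    )
    grazers = list(rng.permutation(np.concatenate([by_group["naked_ciliate"], by_group["tintinnid"]])))
    edges: list[tuple[int, int, float]] = []
    for _ in range(n_positive):
        if len(producers) < 2:
            break
        a, b = int(producers.pop()), int(producers.pop())
        edges.append((min(a, b), max(a, b), rho))
    for _ in range(n_negative):
        if not grazers or not producers:
            break
        a, b = int(grazers.pop()), int(producers.pop())
        edges.append((min(a, b), max(a, b), -rho))
    return InteractionPlan(planted_edges=edges)


def _nearest_positive_definite(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues to make a correlation matrix positive definite."""
    w, v = np.linalg.eigh(corr)
    if w.min() > eps:
        return corr
    w_clipped = np.clip(w, eps, None)
    repaired = (v * w_clipped) @ v.T
    # restore unit diagonal
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    logger.warning(
        "planted correlation matrix repaired to positive definite "
        "(min eigenvalue %.3g clipped)",
        w.min(),
    )
    return repaired


def generate_abundances(
    taxa: pd.DataFrame,
    n_weeks: int,
    plan: InteractionPlan | None = None,
    seed: int = 0,
    start_date: str = "2015-01-08",
    log_sd: float = 1.0,
) -> pd.DataFrame:
    """Generate a weekly abundance matrix with planted rank correlations.

    A latent multivariate Gaussian with the plan's correlation entries is
    drawn, then each column is pushed through a per-taxon lognormal marginal
    scaled by the compartment's abundance scale.  The transform is strictly
    increasing, so the sample Spearman correlation of a planted pair
    converges to its planted value as ``n_weeks`` grows.

    Returns a DataFrame indexed by weekly sampling dates with one column per
    ``taxon_id``.
    """
    if n_weeks < 4:
        raise ValueError("need at least 4 weekly samples")
    plan = plan if plan is not None else InteractionPlan()
    ids = taxa["taxon_id"].to_numpy()
    k = len(ids)
    pos = {int(t): i for i, t in enumerate(ids)}
    corr = np.eye(k)
    bad = [(a, b) for a, b, _ in plan.planted_edges if a not in pos or b not in pos]
    if bad:
        raise ValueError(f"planted pairs reference unknown taxa: {bad}")
    atten = 1.0 / (1.0 + plan.noise_sd**2)
    for a, b, rho in plan.planted_edges:
        corr[pos[a], pos[b]] = corr[pos[b], pos[a]] = rho * atten
    corr = _nearest_positive_definite(corr)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - repair should prevent this
        raise ValueError(f"planted correlation matrix is not repairable: {exc}") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_weeks, k)) @ chol.T
    scale = np.array(
        [plan.abundance_scale.get(g, 1.0) for g in taxa["group"]], dtype=float
    )
    values = np.exp(np.log(scale) + log_sd * z)
    index = pd.date_range(start_date, periods=n_weeks, freq="7D")
    return pd.DataFrame(values, index=index, columns=[int(t) for t in ids])
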
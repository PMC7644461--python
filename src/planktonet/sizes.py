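"""ESD size classes by PELT changepoint detection, biovolumes, dominance.

Taxa within a compartment are ordered by mean equivalent spherical diameter
(ESD) and the Pruned Exact Linear Time (PELT) dynamic program locates
changepoints in that ordered sequence under a Gaussian change-in-mean cost;
the segments become size classes labelled "<b1", "b1-b2", ..., ">bk" with
boundaries at the (rounded) midpoints between the ESDs flanking each
changepoint.  Cell biovolume is the volume of the ESD-equivalent sphere,
``(pi/6) * ESD^3``; multiplied by mean abundance it gives the biovolume per
mL used to pick the biomass-dominant taxa (the minimal prefix reaching 90%
of a compartment's total biovolume).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Compartments whose taxa are split into ESD classes; the single-taxon or
#: pooled compartments (virus, bacteria, HF) pass through whole.
SIZE_CLASSED_GROUPS = ("phytoplankton", "naked_ciliate", "tintinnid")


@dataclass
class ChangepointResult:
    """Segmentation of an ordered value sequence."""

    sorted_values: np.ndarray
    changepoint_indices: list[int]  # k means a boundary between values[k-1] and values[k]
    class_boundaries: list[float]  # midpoint ESD at each changepoint
    penalty: float
    cost_name: str = "gaussian_mean"

    @property
    def n_classes(self) -> int:
        return len(self.changepoint_indices) + 1


def _segment_cost_factory(values: np.ndarray, scale: float | None):
    """Gaussian change-in-mean cost: within-segment SSE / variance scale.

    The scale defaults to the Rice difference-based noise estimator
    ``mean(diff(v)^2) / 2``, which tolerates the mean shifts the search is
    looking for; it also keeps the segmentation invariant under rescaling
    the ESD axis.  If it degenerates (constant series) the overall variance
    is used, then 1 (all costs are zero for a constant series anyway).
    """
    v = np.asarray(values, dtype=float)
    if scale is None:
        d = np.diff(v)
        scale = float(np.mean(d * d) / 2.0) if len(d) else 0.0
        if scale == 0:
            scale = float(np.var(v)) or 1.0
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cs2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def cost(s: int, t: int) -> float:
        # SSE of v[s:t] around its mean
        n_ = t - s
        su = cs[t] - cs[s]
        return ((cs2[t] - cs2[s]) - su * su / n_) / scale

    return cost


def pelt_changepoints(
    values: np.ndarray,
    penalty: float | None = None,
    min_segment: int = 2,
    scale: float | None = None,
) -> ChangepointResult:
    """Exact penalized changepoint detection by the PELT dynamic program.

    Minimizes ``sum of segment costs + penalty * (#changepoints)`` under the
    Gaussian change-in-mean cost.  Pruning uses the standard inequality for
    subadditive costs (K = 0 for SSE), so the segmentation is identical to
    exhaustive optimal partitioning.  ``values`` must be sorted ascending by
    the caller; ``penalty`` defaults to ``2 * log(n)`` (BIC-like).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2 * min_segment:
        raise ValueError(f"need at least {2 * min_segment} values")
    if np.any(np.diff(v) < 0):
        raise ValueError("values must be sorted ascending")
    beta = 2.0 * math.log(n) if penalty is None else float(penalty)
    cost = _segment_cost_factory(v, scale)

    f = np.full(n + 1, np.inf)
    f[0] = -beta
    prev = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(min_segment, n + 1):
        best_val = np.inf
        best_s = 0
        vals = {}
        for s in candidates:
            if t - s < min_segment:
                continue
            val = f[s] + cost(s, t) + beta
            vals[s] = val
            if val < best_val:
                best_val = val
                best_s = s
        f[t] = best_val
        prev[t] = best_s
        # prune only evaluated candidates; keep those too recent to evaluate
        candidates = [
            s
            for s in candidates
            if s not in vals or vals[s] - beta <= f[t]
        ]
        candidates.append(t)

    cps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(int(s))
        t = s
    cps.reverse()
    boundaries = [float((v[k - 1] + v[k]) / 2) for k in cps]
    return ChangepointResult(
        sorted_values=v, changepoint_indices=cps, class_boundaries=boundaries, penalty=beta
    )


def _class_labels(boundaries: list[float], precision: int = 0) -> list[str]:
    def fmt(b: float) -> str:
        r = round(b, precision)
        return str(int(r)) if precision == 0 else str(r)

    if not boundaries:
        return ["all"]
    labels = [f"<{fmt(boundaries[0])}"]
    for lo, hi in zip(boundaries, boundaries[1:]):
        labels.append(f"{fmt(lo)}-{fmt(hi)}")
    labels.append(f">{fmt(boundaries[-1])}")
    return labels


def size_classes(
    taxa: pd.DataFrame,
    group: str,
    penalty: float | None = None,
    precision: int = 0,
    log_esd: bool = False,
) -> pd.DataFrame:
    """Assign PELT-derived ESD class labels to one compartment's taxa.

    Returns a copy of ``taxa`` where the compartment's rows carry a
    ``size_class`` column with labels like ``"<6"``, ``"6-12"``, ``">25"``.
    Set ``log_esd`` to run the changepoint search on log-transformed ESDs.
    """
    sub = taxa[taxa["group"] == group]
    if sub.empty:
        raise ValueError(f"no taxa in group {group!r}")
    if len(sub) < 4:
        raise ValueError(f"need at least 4 taxa in group {group!r} for size classes")
    order = sub.sort_values(["esd_um", "taxon_id"])
    esd = order["esd_um"].to_numpy(dtype=float)
    series = np.log(esd) if log_esd else esd
    res = pelt_changepoints(series, penalty=penalty)
    boundaries = [
        float((esd[k - 1] + esd[k]) / 2) for k in res.changepoint_indices
    ]
    labels = _class_labels(boundaries, precision=precision)
    out = taxa.copy()
    if "size_class" not in out.columns:
        out["size_class"] = pd.NA
    bounds = [round(b, precision) for b in boundaries]
    for tid, e in zip(order["taxon_id"], esd):
        k = int(np.searchsorted(bounds, e, side="right"))
        out.loc[out["taxon_id"] == tid, "size_class"] = labels[min(k, len(labels) - 1)]
    return out


def assign_size_classes(
    taxa: pd.DataFrame,
    groups: tuple[str, ...] = SIZE_CLASSED_GROUPS,
    penalty: float | None = None,
    precision: int = 0,
    log_esd: bool = False,
) -> pd.DataFrame:
    """Size-class the listed compartments; the rest keep their group name.

    Class labels are prefixed with the group so that "phytoplankton <6" and
    "naked_ciliate <6" remain distinct labels in null-model groupings.
    """
    out = taxa.copy()
    out["size_class"] = out["group"]
    for g in groups:
        labelled = size_classes(taxa, g, penalty=penalty, precision=precision, log_esd=log_esd)
        mask = out["group"] == g
        out.loc[mask, "size_class"] = g + " " + labelled.loc[mask, "size_class"].astype(str)
    return out


def biovolume(esd_um: float | np.ndarray) -> float | np.ndarray:
    """Spherical biovolume (um^3) from ESD (um): ``(pi/6) * esd^3``."""
    esd = np.asarray(esd_um, dtype=float)
    if np.any(esd <= 0):
        raise ValueError("ESD must be positive")
    vol = (math.pi / 6.0) * esd**3
    return float(vol) if np.isscalar(esd_um) else vol


def biovolume_table(m: pd.DataFrame, taxa: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon mean biovolume per mL and within-group share for one period."""
    mean_ab = m.mean(axis=0)
    rows = []
    for _, t in taxa.iterrows():
        tid = int(t["taxon_id"])
        if tid not in m.columns:
            continue
        vol = biovolume(float(t["esd_um"]))
        bio = float(mean_ab[tid]) * vol
        rows.append((tid, t["group"], float(t["esd_um"]), float(mean_ab[tid]), vol, bio))
    out = pd.DataFrame(
        rows,
        columns=[
            "taxon_id",
            "group",
            "esd_um",
            "mean_abundance",
            "biovolume_um3",
            "mean_biovolume_per_ml",
        ],
    )
    totals = out.groupby("group")["mean_biovolume_per_ml"].transform("sum")
    out["share"] = np.where(totals > 0, out["mean_biovolume_per_ml"] / totals, 0.0)
    return out


def dominant_taxa(
    m: pd.DataFrame,
    taxa: pd.DataFrame,
    share_threshold: float = 0.90,
    selection_groups: tuple[str, ...] = SIZE_CLASSED_GROUPS,
) -> pd.DataFrame:
    """Biomass-dominant taxa: the minimal prefix reaching the biovolume share.

    Within each compartment in ``selection_groups``, taxa are sorted by mean
    biovolume per mL (descending) and the shortest prefix whose cumulative
    within-group share reaches ``share_threshold`` is selected; taxa tied in
    mean biovolume with the last selected one are included too.  Compartments
    outside ``selection_groups`` pass through whole.  All-zero compartments
    yield an empty (logged) selection.
    """
    if not 0 < share_threshold <= 1:
        raise ValueError("share_threshold must be in (0, 1]")
    table = biovolume_table(m, taxa)
    selected = np.zeros(len(table), dtype=bool)
    for g, idx in table.groupby("group").groups.items():
        block = table.loc[idx]
        if g not in selection_groups:
            selected[table.index.get_indexer(idx)] = True
            continue
        if block["mean_biovolume_per_ml"].sum() == 0:
            logger.info("group %s has zero total biovolume; nothing selected", g)
            continue
        order = block.sort_values(
            ["mean_biovolume_per_ml", "taxon_id"], ascending=[False, True]
        )
        cum = order["share"].cumsum()
        n_take = int(np.searchsorted(cum.to_numpy(), share_threshold - 1e-12) + 1)
        n_take = min(n_take, len(order))
        cut_value = order["mean_biovolume_per_ml"].iloc[n_take - 1]
        take = order.index[
            (np.arange(len(order)) < n_take)
            | (order["mean_biovolume_per_ml"] == cut_value).to_numpy()
        ]
        selected[table.index.get_indexer(take)] = True
    out = table.copy()
    out["selected"] = selected
    return out
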
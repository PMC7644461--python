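"""Inter-annual comparison by ISO-week pairing and paired Wilcoxon tests.

Sampling dates from two campaigns are matched by ISO-8601 week number (so
e.g. 2015-01-08 and 2016-01-12 pair up as week 2 of their respective years)
and each group or size-class abundance series is compared week-by-week with
the paired Wilcoxon signed-rank test.  Zero differences are discarded
(Wilcoxon's original treatment); the exact null distribution is used for
small tie-free samples and the normal approximation with continuity and tie
correction otherwise.  No correction across the multiple group tests is
applied; p-values are reported per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Largest sample size for which the exact signed-rank distribution is used.
EXACT_N_MAX = 25


def iso_week_pairing(
    dates_a,
    values_a,
    dates_b,
    values_b,
    truncate_to_common: bool = True,
) -> pd.DataFrame:
    """Pair two campaigns' values by ISO-8601 week number.

    Returns a DataFrame with columns ``iso_week, value_a, value_b`` for the
    weeks present in both campaigns.  With ``truncate_to_common`` (default)
    unmatched weeks are silently dropped — this reproduces trimming a longer
    campaign's trailing dates down to the shorter one; otherwise unmatched
    weeks raise an error.
    """

    def week_map(dates, values, which: str) -> dict[int, float]:
        idx = pd.DatetimeIndex(pd.to_datetime(list(dates)))
        if len(idx) != len(list(values)):
            raise ValueError(f"dates and values of campaign {which} differ in length")
        weeks = idx.isocalendar().week.to_numpy()
        out: dict[int, float] = {}
        for w, v in zip(weeks, values):
            w = int(w)
            if w in out:
                raise ValueError(f"duplicate ISO week {w} in campaign {which}")
            out[w] = float(v)
        return out

    wa = week_map(dates_a, values_a, "a")
    wb = week_map(dates_b, values_b, "b")
    common = sorted(set(wa) & set(wb))
    if not truncate_to_common:
        unmatched = sorted(set(wa) ^ set(wb))
        if unmatched:
            raise ValueError(f"unmatched ISO weeks: {unmatched}")
    return pd.DataFrame(
        {
            "iso_week": common,
            "value_a": [wa[w] for w in common],
            "value_b": [wb[w] for w in common],
        }
    )


@dataclass
class WilcoxonResult:
    statistic: float  # W: the smaller of the two signed-rank sums
    pvalue: float
    n_effective: int  # pairs remaining after discarding zero differences
    direction: str  # "b_greater" | "a_greater" | "none"
    degenerate: bool = False  # all differences were zero


def paired_wilcoxon(pairs: pd.DataFrame) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on an ISO-week pairing.

    ``pairs`` must carry ``value_a`` and ``value_b`` columns.  Differences
    ``value_b - value_a`` equal to zero are discarded; if none remain the
    result is flagged degenerate with p = 1.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    d = pairs["value_b"].to_numpy(dtype=float) - pairs["value_a"].to_numpy(dtype=float)
    nz = d[d != 0]
    if len(nz) == 0:
        return WilcoxonResult(0.0, 1.0, 0, "none", degenerate=True)
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= EXACT_N_MAX and not ties) else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    med = float(np.median(nz))
    direction = "b_greater" if med > 0 else ("a_greater" if med < 0 else "none")
    return WilcoxonResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        n_effective=int(len(nz)),
        direction=direction,
    )


def compare_years(
    m_a: pd.DataFrame,
    m_b: pd.DataFrame,
    taxa: pd.DataFrame,
    by: str = "size_class",
    truncate_to_common: bool = True,
) -> pd.DataFrame:
    """Paired Wilcoxon comparison of per-group abundances between campaigns.

    Abundances are summed over the taxa of each label in ``taxa[by]`` per
    sampling date, the two campaigns are ISO-week paired, and each label is
    tested.  Returns a tidy table: label, n_pairs, W, p, direction.
    """
    if by not in taxa.columns:
        raise ValueError(f"taxa table has no column {by!r}")
    rows = []
    for label, block in taxa.groupby(by, sort=True):
        ids = [int(t) for t in block["taxon_id"] if int(t) in m_a.columns and int(t) in m_b.columns]
        if not ids:
            continue
        sa = m_a[ids].sum(axis=1)
        sb = m_b[ids].sum(axis=1)
        paired = iso_week_pairing(
            sa.index, sa.to_numpy(), sb.index, sb.to_numpy(),
            truncate_to_common=truncate_to_common,
        )
        if paired.empty:
            continue
        res = paired_wilcoxon(paired)
        rows.append(
            (label, res.n_effective, res.statistic, res.pvalue, res.direction)
        )
    return pd.DataFrame(rows, columns=["label", "n_pairs", "W", "p", "direction"])
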
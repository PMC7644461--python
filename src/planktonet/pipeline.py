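"""End-to-end pipeline: periods -> networks -> descriptors -> null model ->
dominant-species networks -> inter-annual comparisons.

For each analysis period (pooled blooms and sufficiently sampled non-bloom
periods) the pipeline emits the negative, positive and combined correlation
networks, a descriptor table row per network, null-model classifications for
both the functional-group and the ESD-class labellings, the biomass-dominant
taxa and their sub-networks, plus autocorrelation diagnostics and a run log
recording the seed and every parameter in effect.  Outputs are byte-stable
for a fixed seed.
"""

from __future__ import annotations

import contextlib
import logging
from pathlib import Path

import pandas as pd

import planktonet
from planktonet.blooms import detect_blooms, growth_rates, pool_blooms, slice_abundance
from planktonet.compare import compare_years
from planktonet.config import PipelineConfig
from planktonet.networks import CorrelationNetwork, build_networks, descriptors, autocorrelation_report
from planktonet.nullmodel import classify_pairs, summary_network
from planktonet.sizes import assign_size_classes, dominant_taxa
from planktonet import io

logger = logging.getLogger(__name__)

SIGN_MODES = ("negative", "positive", "combined")


@contextlib.contextmanager
def _stage(name: str):
    try:
        logger.info("stage %s", name)
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def subnetwork(net: CorrelationNetwork, taxon_ids: set[int]) -> CorrelationNetwork:
    """Restrict a network to edges whose endpoints are both in ``taxon_ids``."""
    e = net.edges
    mask = e["taxon_a"].isin(taxon_ids) & e["taxon_b"].isin(taxon_ids)
    return CorrelationNetwork(
        period_label=net.period_label,
        sign_mode=net.sign_mode,
        edges=e[mask].reset_index(drop=True),
        alpha=net.alpha,
        n_permutations=net.n_permutations,
        dropped_taxa=list(net.dropped_taxa),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a report bundle of in-memory results."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "periods": {}, "descriptors": None}

    with _stage("read_inputs"):
        taxa = io.read_taxa_csv(config.taxa)
        abundance = io.read_abundance_csv(config.abundance, taxa=taxa)
        fluo = io.read_fluorescence_csv(config.fluorescence)

    with _stage("size_classes"):
        taxa = assign_size_classes(
            taxa, penalty=config.pelt_penalty, precision=config.boundary_precision
        )
        io.write_taxa_csv(taxa, out / "taxa_with_size_classes.csv")

    with _stage("bloom_periods"):
        rates = growth_rates(fluo)
        raw = detect_blooms(
            rates,
            min_pos_start=config.min_pos_start,
            min_window=config.min_window,
            end_neg_run=config.end_neg_run,
        )
        periods = pool_blooms(raw, max_gap_weeks=config.max_gap_weeks)
        io.write_periods_csv(periods, out / "periods.csv")
        (out / "periods_log.txt").write_text(periods.provenance + "\n")
        report["period_set"] = periods

    group_labels = {int(t): str(g) for t, g in zip(taxa["taxon_id"], taxa["group"])}
    class_labels = {int(t): str(c) for t, c in zip(taxa["taxon_id"], taxa["size_class"])}

    # analysis periods: pooled blooms and non-blooms with enough samples
    analysis: list[tuple[str, pd.DataFrame]] = []
    counters = {"bloom": 0, "non_bloom": 0}
    for per in periods.periods:
        rows = abundance[(abundance.index >= per.start) & (abundance.index <= per.end)]
        if len(rows) < config.min_period_samples:
            logger.info(
                "skipping %s %s..%s: %d samples < %d",
                per.label, per.start.date(), per.end.date(), len(rows),
                config.min_period_samples,
            )
            continue
        counters[per.label] += 1
        analysis.append((f"{per.label}_{counters[per.label]}", rows))
    if not analysis:
        raise RuntimeError("no analysis period has enough abundance samples")

    desc_rows = []
    for p_idx, (label, rows) in enumerate(analysis):
        pdir = out / label
        pdir.mkdir(exist_ok=True)
        period_report: dict = {}

        with _stage(f"autocorrelation[{label}]"):
            if len(rows) >= 8:
                acf_table = autocorrelation_report(rows)
                acf_table.to_csv(pdir / "acf_diagnostics.tsv", sep="\t", index=False)
                period_report["acf"] = acf_table

        with _stage(f"networks[{label}]"):
            nets = build_networks(
                rows,
                alpha=config.alpha,
                n_iter=config.n_permutations,
                seed=config.seed,
                period_label=label,
            )
            for mode in SIGN_MODES:
                io.write_network(nets[mode], taxa, pdir / f"network_{mode}.tsv")
                io.write_network(nets[mode], taxa, pdir / f"network_{mode}.graphml", format="graphml")
                d = descriptors(nets[mode], k_hubs=config.hub_k)
                desc_rows.append(
                    {
                        "period": label,
                        "sign_mode": mode,
                        "n_nodes": d.n_nodes,
                        "n_edges": d.n_edges,
                        "pct_negative": d.pct_negative if mode == "combined" else None,
                        "mean_degree": d.mean_degree,
                        "hubs": "; ".join(f"{t}:{k}" for t, k in d.hubs),
                    }
                )
            period_report["networks"] = nets

        with _stage(f"null_model[{label}]"):
            classifications = {}
            for grouping, labels in (
                ("functional_group", group_labels),
                ("esd_class", class_labels),
            ):
                per_mode = {}
                for mode in ("negative", "positive"):
                    cls = classify_pairs(
                        nets[mode],
                        labels,
                        n_random=config.n_random_networks,
                        seed=config.seed + 1000 + p_idx,
                        grouping=grouping,
                    )
                    io.write_classification_tsv(
                        cls, pdir / f"dominance_{grouping}_{mode}.tsv"
                    )
                    per_mode[mode] = cls
                import networkx as nx

                nx.write_graphml(summary_network(per_mode), pdir / f"summary_{grouping}.graphml")
                classifications[grouping] = per_mode
            period_report["classifications"] = classifications

        with _stage(f"dominant_taxa[{label}]"):
            dom = dominant_taxa(rows, taxa, share_threshold=config.dominance_threshold)
            dom.to_csv(pdir / "dominant_taxa.tsv", sep="\t", index=False, float_format="%.10g")
            dom_ids = set(dom.loc[dom["selected"], "taxon_id"].astype(int))
            for mode in ("negative", "positive"):
                sub = subnetwork(nets[mode], dom_ids)
                io.write_network(sub, taxa, pdir / f"dominant_network_{mode}.tsv")
            period_report["dominant_taxa"] = dom

        report["periods"][label] = period_report

    desc = pd.DataFrame(desc_rows)
    desc.to_csv(out / "descriptors.tsv", sep="\t", index=False)
    io.write_json(
        [
            {k: (v if v is None or isinstance(v, (int, str)) else float(v)) for k, v in r.items()}
            for r in desc_rows
        ],
        out / "descriptors.json",
    )
    report["descriptors"] = desc

    if config.abundance_b:
        with _stage("inter_annual_comparison"):
            m_b = io.read_abundance_csv(config.abundance_b, taxa=taxa)
            for by in ("group", "size_class"):
                table = compare_years(abundance, m_b, taxa, by=by)
                table.to_csv(out / f"comparison_{by}.tsv", sep="\t", index=False, float_format="%.10g")
                report[f"comparison_{by}"] = table

    io.write_json(
        {
            "package": "planktonet",
            "version": planktonet.__version__,
            "seed": config.seed,
            "parameters": config.to_dict(),
            "analysis_periods": [label for label, _ in analysis],
            "n_networks": 3 * len(analysis),
        },
        out / "run_log.json",
    )
    return report
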
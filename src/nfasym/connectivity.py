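"""Blockwise ROI functional connectivity and differential-network extraction.

Zero-lag Pearson correlation per unordered ROI pair, per block segment; the
first two Upregulation volumes of each block are dropped to discount View
carry-over.  Correlations are Fisher z-transformed before averaging and
testing.  The edge statistics pair Upregulation against View per run-block,
compare the pairing between groups, and BH-FDR both families; an edge
survives only when significant in both (conjunction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .paradigm import ANALYSIS_LABELS, UPREGULATION, VIEW, ExperimentSchedule
from .stats import bh_fdr, two_sample_t
from .synth import ROITimeSeriesSet

__all__ = [
    "blockwise_correlations",
    "cohort_block_correlations",
    "edge_condition_tests",
    "DifferentialNetwork",
    "differential_network",
    "connectivity_distributions",
]


def blockwise_correlations(
    roi_series: ROITimeSeriesSet,
    schedule: ExperimentSchedule,
    trim_up_vols: int = 2,
) -> pd.DataFrame:
    """Pearson r (and Fisher z) per ROI pair, per run, per analysis block.

    Columns: run, block, roi_i, roi_j, r, z, valid.  Segments with zero
    variance in either ROI yield ``valid=False`` and NaN r.
    """
    data = roi_series.frame.to_numpy(dtype=float)
    names = roi_series.roi_names
    n_roi = len(names)
    iu, ju = np.triu_indices(n_roi, k=1)
    rows = []
    for run, lab, sl in roi_series_slices(schedule, trim_up_vols):
        seg = data[sl]
        if seg.shape[0] < 3:
            raise ValueError(
                f"block segment run={run} {lab} has {seg.shape[0]} volumes (< 3)"
            )
        sd = seg.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(seg.T)
        for i, j in zip(iu, ju):
            valid = sd[i] > 0 and sd[j] > 0 and np.isfinite(corr[i, j])
            r = float(corr[i, j]) if valid else np.nan
            z = float(np.arctanh(np.clip(r, -0.999999, 0.999999))) if valid else np.nan
            rows.append(
                {
                    "run": run,
                    "block": lab,
                    "roi_i": names[i],
                    "roi_j": names[j],
                    "r": r,
                    "z": z,
                    "valid": valid,
                }
            )
    return pd.DataFrame(rows)


def cohort_block_correlations(
    subjects, schedule: ExperimentSchedule, trim_up_vols: int = 2
) -> pd.DataFrame:
    """Stack :func:`blockwise_correlations` over ``(subject, group, series)``."""
    frames = []
    for subject, group, series in subjects:
        frame = blockwise_correlations(series, schedule, trim_up_vols)
        frame.insert(0, "subject", subject)
        frame.insert(1, "group", group)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def roi_series_slices(schedule: ExperimentSchedule, trim_up_vols: int = 2):
    """Volume slices per run and analysis block, trimming Upregulation."""
    for run, lab, sl in schedule.volume_slices():
        if lab not in ANALYSIS_LABELS:
            continue
        if lab == UPREGULATION:
            sl = slice(sl.start + trim_up_vols, sl.stop)
        yield run, lab, sl


def edge_condition_tests(block_corr: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Per-edge condition and group statistics with BH-FDR per family.

    ``block_corr`` must carry subject and group columns in addition to the
    output of :func:`blockwise_correlations`.  Per edge: paired t on
    z(Up) - z(View) over experimental run-blocks (df = n - 1, 179 with the
    default 18 x 10 design); two-sample pooled t on those differences
    between groups (df = n1 + n2 - 2, 318 with defaults); edges surviving
    BOTH families at ``q`` are marked ``survives``.  Run-blocks where either
    segment is invalid are excluded, not imputed.
    """
    required = {"subject", "group", "run", "block", "roi_i", "roi_j", "z", "valid"}
    missing = required - set(block_corr.columns)
    if missing:
        raise ValueError(f"block_corr missing columns {missing}")
    frame = block_corr[block_corr["valid"]]
    frame = frame[frame["block"].isin([UPREGULATION, VIEW])]
    wide = frame.pivot_table(
        index=["roi_i", "roi_j", "subject", "group", "run"],
        columns="block",
        values="z",
    ).reset_index()
    wide = wide.dropna(subset=[UPREGULATION, VIEW])
    wide["dz"] = wide[UPREGULATION] - wide[VIEW]

    rows = []
    for (roi_i, roi_j), sub in wide.groupby(["roi_i", "roi_j"], sort=True):
        exp = sub.loc[sub["group"] == "experimental", "dz"].to_numpy()
        ctl = sub.loc[sub["group"] == "control", "dz"].to_numpy()
        if exp.size < 2:
            continue
        sd = exp.std(ddof=1)
        if sd == 0:
            continue
        t_cond = exp.mean() / (sd / np.sqrt(exp.size))
        df_cond = exp.size - 1
        p_cond = 2.0 * sps.t.sf(abs(t_cond), df_cond)
        row = {
            "roi_i": roi_i,
            "roi_j": roi_j,
            "n_runblocks": exp.size,
            "mean_dz_experimental": exp.mean(),
            "t_condition": t_cond,
            "df_condition": df_cond,
            "p_condition": p_cond,
        }
        if ctl.size >= 2:
            res = two_sample_t(exp, ctl)
            row.update(
                {
                    "t_group": res.statistic,
                    "df_group": res.df,
                    "p_group": res.p,
                    "weight": exp.mean() - ctl.mean(),
                }
            )
        else:
            row.update(
                {"t_group": np.nan, "df_group": np.nan, "p_group": np.nan,
                 "weight": exp.mean()}
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    rej_c, q_c = bh_fdr(table["p_condition"].to_numpy(), q=q)
    table["q_condition"] = q_c
    table["sig_condition"] = rej_c
    has_group = table["p_group"].notna().to_numpy()
    table["q_group"] = np.nan
    table["sig_group"] = False
    if has_group.any():
        rej_g, q_g = bh_fdr(table.loc[has_group, "p_group"].to_numpy(), q=q)
        table.loc[has_group, "q_group"] = q_g
        table.loc[has_group, "sig_group"] = rej_g
    table["survives"] = table["sig_condition"] & table["sig_group"]
    return table


@dataclass(frozen=True)
class DifferentialNetwork:
    nodes: tuple[str, ...]
    edges: pd.DataFrame  # roi_i, roi_j, weight
    q: float

    def to_json(self, path) -> None:
        payload = {
            "nodes": list(self.nodes),
            "q": self.q,
            "edges": self.edges.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DifferentialNetwork":
        with open(path) as fh:
            payload = json.load(fh)
        edges = pd.DataFrame(payload["edges"], columns=["roi_i", "roi_j", "weight"])
        return cls(nodes=tuple(payload["nodes"]), edges=edges, q=payload["q"])

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["roi_i"], row["roi_j"], weight=row["weight"])
        return g


def differential_network(
    edge_stats: pd.DataFrame, q: float = 0.05, nodes=None
) -> DifferentialNetwork:
    """Surviving edges with group-contrast weights, deterministically ordered.

    An empty network is a valid result (no surviving edges).
    """
    if edge_stats.empty:
        return DifferentialNetwork(
            nodes=tuple(nodes or ()), edges=pd.DataFrame(columns=["roi_i", "roi_j", "weight"]), q=q
        )
    if nodes is None:
        nodes = sorted(set(edge_stats["roi_i"]) | set(edge_stats["roi_j"]))
    surv = edge_stats[edge_stats["survives"]]
    edges = (
        surv[["roi_i", "roi_j", "weight"]]
        .sort_values(["roi_i", "roi_j"])
        .reset_index(drop=True)
    )
    return DifferentialNetwork(nodes=tuple(nodes), edges=edges, q=q)


def connectivity_distributions(
    block_corr: pd.DataFrame, edges: pd.DataFrame
) -> dict:
    """Pooled r distributions over the surviving edges + location-shift test.

    Restricted to the experimental group when a group column is present.
    Returns per-condition summaries (mean, quartiles) and a pooled
    two-sample t on the Fisher-z values.
    """
    if edges.empty:
        raise ValueError("need at least one surviving edge")
    frame = block_corr[block_corr["valid"]]
    if "group" in frame.columns:
        frame = frame[frame["group"] == "experimental"]
    key = set(map(tuple, edges[["roi_i", "roi_j"]].to_numpy()))
    sel = frame[[tuple(p) in key for p in frame[["roi_i", "roi_j"]].to_numpy()]]
    out: dict = {"edges": sorted(key)}
    samples = {}
    for lab in (UPREGULATION, VIEW):
        vals = sel.loc[sel["block"] == lab, "r"].to_numpy()
        zvals = sel.loc[sel["block"] == lab, "z"].to_numpy()
        samples[lab] = zvals
        out[lab] = {
            "n": int(vals.size),
            "mean_r": float(vals.mean()) if vals.size else np.nan,
            "quartiles": [float(x) for x in np.percentile(vals, [25, 50, 75])]
            if vals.size
            else [np.nan] * 3,
        }
    if samples[UPREGULATION].size >= 2 and samples[VIEW].size >= 2:
        try:
            res = two_sample_t(samples[UPREGULATION], samples[VIEW])
            out["shift_test"] = {"t": res.statistic, "df": res.df, "p": res.p}
        except Exception:
            out["shift_test"] = None
    else:
        out["shift_test"] = None
    return out
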
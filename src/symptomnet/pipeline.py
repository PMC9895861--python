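"""End-to-end orchestration: read/simulate -> score -> networks -> centrality.

File conventions: UTF-8 comma-separated CSV with a header row and "." decimal
separator.  Floating-point cells are written with 17 significant digits so a
write/read round trip reproduces matrices exactly.  Every CSV the pipeline
writes starts with a provenance comment line (``# symptomnet ... seed=...
config_sha256=...``); readers skip ``#`` comments.  Results go to stdout/files,
logging (stage timers) to stderr.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .centrality import NetworkCentrality
from .errors import ResponseValidationError, SchemaError
from .instrument import InstrumentConfig, default_instrument
from .layout import fruchterman_reingold
from .network import SpearmanNetwork, build_cluster_nodes, top_edges
from .scoring import exclude_incomplete, summary_table
from .synthetic import CopulaSpec, calibrated_spec, generate_responses

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "read_responses",
    "write_responses",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_graphml",
    "read_graphml",
    "run_pipeline",
    "plot_network",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_responses(
    path: str | Path, instrument: InstrumentConfig | None = None
) -> pd.DataFrame:
    """Parse a responses CSV, preserving missingness.

    Cells must be integers in {0, 1, 2, 3} or empty (missing).  When an
    instrument is given the header must contain exactly its item ids.
    """
    df = pd.read_csv(path, comment="#")
    if instrument is not None:
        got, want = set(df.columns), set(instrument.item_ids)
        if got != want:
            unknown = sorted(got - want)
            absent = sorted(want - got)
            raise SchemaError(
                f"response columns do not match the instrument "
                f"(unknown: {unknown}, missing: {absent})"
            )
        df = df[list(instrument.item_ids)]
    values = df.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | (np.isin(values, (0.0, 1.0, 2.0, 3.0))))
    if bad.any():
        row, col = map(int, np.argwhere(bad)[0])
        raise ResponseValidationError(
            f"invalid score {values[row, col]!r} in row {row}, "
            f"column {df.columns[col]!r}: scores must be 0-3 or empty"
        )
    logger.info("read %d records x %d items from %s", *df.shape, path)
    return df


def _provenance_header(provenance: Mapping | None) -> str:
    if not provenance:
        return ""
    fields = " ".join(f"{k}={v}" for k, v in provenance.items())
    return f"# symptomnet {fields}\n"


def write_responses(
    df: pd.DataFrame, path: str | Path, provenance: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        df.to_csv(fh, index=False)


def write_matrix_csv(
    matrix: pd.DataFrame, path: str | Path, provenance: Mapping | None = None
) -> None:
    """Write a node x node matrix (or any frame) with exact float round-trip."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        matrix.to_csv(fh, float_format=_FLOAT_FMT)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0, float_precision="round_trip")


def write_edges_csv(
    edges: pd.DataFrame, path: str | Path, provenance: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        edges.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_edges_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_graphml(net: SpearmanNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_graph(), path)


def read_graphml(path: str | Path) -> pd.DataFrame:
    """Weight matrix recovered from a GraphML export (absent edges -> 0)."""
    G = nx.read_graphml(path)
    nodes = list(G.nodes)
    W = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    np.fill_diagonal(W, 1.0)
    return pd.DataFrame(W, index=nodes, columns=nodes)


def edges_to_matrix(edges: pd.DataFrame) -> pd.DataFrame:
    """Symmetric weight matrix (unit diagonal) from a node_a/node_b/r edge list."""
    nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
    W = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for a, b, r in edges.itertuples(index=False):
        W.loc[a, b] = r
        W.loc[b, a] = r
    np.fill_diagonal(W.values, 1.0)
    return W


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis end to end."""

    responses: str | None = None  # CSV path; None -> simulate
    instrument: str | None = None  # YAML/JSON path; None -> default instrument
    copula_spec: str | None = None  # YAML/JSON path; None -> calibrated default
    n_participants: int = 503
    seed: int = 0
    mode: str = "theoretical-max"
    display_threshold: float = 0.0
    top_k_edges: int = 3
    layout_iterations: int = 500
    outdir: str | None = None
    make_figures: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """In-memory results of one pipeline run (everything recomputable)."""

    summary: pd.DataFrame
    networks: dict[str, SpearmanNetwork]
    centralities: dict[str, NetworkCentrality]
    strongest_edges: dict[str, pd.DataFrame]
    layouts: dict[str, pd.DataFrame]
    n_raw: int
    n_excluded: int
    pct_excluded: float
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "exclusion": {
                "n_raw": self.n_raw,
                "n_excluded": self.n_excluded,
                "pct_excluded": self.pct_excluded,
            },
            "strongest_edges": {
                k: v.to_dict(orient="records")
                for k, v in self.strongest_edges.items()
            },
            "centrality": {
                k: c.report_.reset_index().to_dict(orient="records")
                for k, c in self.centralities.items()
            },
        }


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis and (optionally) write all artifacts."""
    t0 = time.perf_counter()
    instrument = (
        InstrumentConfig.from_file(config.instrument)
        if config.instrument
        else default_instrument()
    )

    if config.responses:
        raw = read_responses(config.responses, instrument)
    else:
        spec = (
            CopulaSpec.from_file(config.copula_spec)
            if config.copula_spec
            else calibrated_spec(
                n_participants=config.n_participants,
                seed=config.seed,
                instrument=instrument,
            )
        )
        raw = generate_responses(spec)
    logger.info("input stage done in %.2fs", time.perf_counter() - t0)

    complete, n_excluded, pct_excluded = exclude_incomplete(raw)
    complete = complete[list(instrument.item_ids)]
    summary = summary_table(complete, instrument)

    networks = {
        "symptom": SpearmanNetwork().fit(complete),
        "cluster": SpearmanNetwork().fit(build_cluster_nodes(complete, instrument)),
    }
    centralities = {
        k: NetworkCentrality(mode=config.mode).fit(net)
        for k, net in networks.items()
    }
    strongest = {k: net.top_edges(config.top_k_edges) for k, net in networks.items()}
    layouts = {
        k: fruchterman_reingold(
            net, seed=config.seed, iterations=config.layout_iterations
        ).coordinates
        for k, net in networks.items()
    }
    logger.info("analysis done in %.2fs", time.perf_counter() - t0)

    provenance = {
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "symptomnet_version": __version__,
    }
    report = AnalysisReport(
        summary=summary,
        networks=networks,
        centralities=centralities,
        strongest_edges=strongest,
        layouts=layouts,
        n_raw=len(raw),
        n_excluded=n_excluded,
        pct_excluded=pct_excluded,
        provenance=provenance,
    )
    if config.outdir:
        _write_artifacts(report, config, instrument)
    return report


def _write_artifacts(
    report: AnalysisReport, config: PipelineConfig, instrument: InstrumentConfig
) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = report.provenance
    with open(out / "summary.csv", "w") as fh:
        fh.write(_provenance_header(prov))
        report.summary.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    for level, net in report.networks.items():
        write_matrix_csv(net.correlation_, out / f"{level}_matrix.csv", prov)
        write_edges_csv(net.edge_list(), out / f"{level}_edges.csv", prov)
        write_graphml(net, out / f"{level}_network.graphml")
        write_matrix_csv(
            report.centralities[level].report_, out / f"{level}_centrality.csv", prov
        )
        write_matrix_csv(report.layouts[level], out / f"{level}_layout.csv", prov)
        if config.make_figures:
            plot_network(
                net.correlation_,
                report.layouts[level],
                r_s=report.centralities[level].r_s_,
                display_threshold=config.display_threshold,
                path=out / f"{level}_network.png",
            )
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    logger.info("artifacts written to %s", out)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def plot_network(
    weights: pd.DataFrame,
    coordinates: pd.DataFrame,
    r_s: pd.Series | None = None,
    display_threshold: float = 0.0,
    path: str | Path | None = None,
):
    """Figure-style rendering: node size ~ r_S, edge width ~ |r|.

    ``display_threshold`` suppresses weak edges from the drawing only; the
    underlying network is unchanged.  Returns the matplotlib Figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    nodes = list(weights.columns)
    W = weights.to_numpy()
    xy = coordinates.loc[nodes, ["x", "y"]].to_numpy()
    fig, ax = plt.subplots(figsize=(8, 8))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            w = W[i, j]
            if abs(w) >= max(display_threshold, 1e-12):
                ax.plot(
                    xy[[i, j], 0],
                    xy[[i, j], 1],
                    color="seagreen" if w > 0 else "indianred",
                    linewidth=3.0 * abs(w),
                    alpha=min(1.0, 0.15 + 0.85 * abs(w)),
                    zorder=1,
                )
    sizes = (
        100 + 900 * r_s.loc[nodes].to_numpy()
        if r_s is not None
        else np.full(len(nodes), 300.0)
    )
    ax.scatter(xy[:, 0], xy[:, 1], s=sizes, c="lightsteelblue",
               edgecolors="navy", zorder=2)
    for label, (x, y) in zip(nodes, xy):
        ax.annotate(label, (x, y), fontsize=6, ha="center", va="center", zorder=3)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
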
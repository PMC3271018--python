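"""File I/O: tab-delimited time series, BIDS-style event tables, cohort
manifests, and graph serialization.

Formats
-------
- Time series: one TSV per subject, header row = region names, one row
  per TR sample.
- Events: TSV with columns onset, duration, trial_type (seconds).
- Behavior / structural connectivity: TSV keyed by subject_id.
- Cohort manifest: YAML mapping subjects to files and groups, carrying TR
  and file-relative paths.
- Causal graphs: edge-list TSV (source, target, strength, p, q,
  significant) plus a JSON document with the full matrices; matrix
  orientation is row = target throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (ROITimeSeries, validate_behavior_table,
                        validate_structural_table)
from .design import EventDesign
from .inference import CausalGraph
from .simulate import Cohort

__all__ = ["write_timeseries", "read_timeseries", "write_events",
           "read_events", "write_cohort", "load_cohort", "write_graph",
           "read_graph"]

_FLOAT_FMT = "%.10g"


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    ts.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path: str | Path, tr: float, subject_id: str = "",
                    group_label: str = "") -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(df.to_numpy(float), tuple(df.columns), tr,
                         subject_id or Path(path).stem, group_label)


def write_events(design: EventDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False,
                             float_format=_FLOAT_FMT)


def read_events(path: str | Path, run_length: float, tr: float) -> EventDesign:
    return EventDesign.from_frame(pd.read_csv(path, sep="\t"), run_length, tr)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Serialize a cohort: per-subject TSVs, events, behavior, structure,
    ground truth, and a YAML manifest tying them together."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects = []
    for ts in cohort.timeseries:
        fname = f"{ts.subject_id}_timeseries.tsv"
        write_timeseries(ts, outdir / fname)
        subjects.append({"subject_id": ts.subject_id, "file": fname,
                         "group": ts.group_label})
    write_events(cohort.design, outdir / "events.tsv")
    cohort.behavior.to_csv(outdir / "behavior.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
    cohort.structure.to_csv(outdir / "structure.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FMT)
    truth = {sid: mat.tolist() for sid, mat in cohort.ground_truth.items()}
    (outdir / "ground_truth.json").write_text(json.dumps(
        {"orientation": "row=target", "connections": truth}, indent=1))
    manifest = {
        "tr": float(cohort.timeseries[0].tr),
        "region_names": list(cohort.timeseries[0].region_names),
        "run_length": float(cohort.design.run_length),
        "events": "events.tsv",
        "behavior": "behavior.tsv",
        "structure": "structure.tsv",
        "subjects": subjects,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir / "manifest.yaml"


def load_cohort(manifest_path: str | Path):
    """Load a serialized cohort from its manifest.

    Returns (timeseries list, design, behavior table, structure table).
    Subjects whose columns are ordered differently but share the region
    set are reordered to the manifest's canonical order.
    """
    manifest_path = Path(manifest_path)
    man = yaml.safe_load(manifest_path.read_text())
    root = manifest_path.parent
    tr = float(man["tr"])
    regions = tuple(man["region_names"])
    timeseries = []
    for sub in man["subjects"]:
        ts = read_timeseries(root / sub["file"], tr, sub["subject_id"],
                             sub.get("group", ""))
        if ts.region_names != regions:
            ts = ts.reorder(regions)
        timeseries.append(ts)
    design = read_events(root / man["events"], float(man["run_length"]), tr)
    behavior = structure = None
    if man.get("behavior"):
        behavior = validate_behavior_table(
            pd.read_csv(root / man["behavior"], sep="\t"))
    if man.get("structure"):
        structure = validate_structural_table(
            pd.read_csv(root / man["structure"], sep="\t"))
    return timeseries, design, behavior, structure


def write_graph(graph: CausalGraph, path: str | Path,
                provenance: dict | None = None) -> None:
    """Edge-list TSV with provenance header comments, plus a JSON sidecar."""
    path = Path(path)
    header = [f"# method: {graph.method}", f"# alpha: {graph.alpha}",
              "# orientation: matrix row = target; edge list is explicit"]
    for k, v in (provenance or {}).items():
        header.append(f"# {k}: {v}")
    body = graph.to_edge_list().to_csv(sep="\t", index=False,
                                       float_format=_FLOAT_FMT)
    path.write_text("\n".join(header) + "\n" + body)
    side = {
        "region_names": list(graph.region_names),
        "alpha": graph.alpha,
        "method": graph.method,
        "strength": graph.strength.tolist(),
        "p": graph.p.tolist(),
        "q": graph.q.tolist(),
        "significant": graph.significant.astype(bool).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def read_graph(path: str | Path) -> CausalGraph:
    path = Path(path)
    if path.suffix == ".json":
        d = json.loads(path.read_text())
        return CausalGraph(tuple(d["region_names"]),
                           np.asarray(d["strength"], float),
                           np.asarray(d["p"], float),
                           np.asarray(d["q"], float),
                           np.asarray(d["significant"], bool),
                           alpha=d.get("alpha", 0.01),
                           method=d.get("method", ""))
    df = pd.read_csv(path, sep="\t", comment="#")
    return CausalGraph.from_edge_list(df)
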
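"""End-to-end analysis pipeline.

Runs the full sequence - simulate (or load) a cohort, preprocess, MDS and
Granger causal graphs with surrogate nulls and group comparison, onset
latencies, graph metrics with hub tests, functional connectivity and
structure-function coupling, and sparse behavior regression - from one
YAML config, writing every stage's outputs plus a JSON run report.

Determinism: one master seed; each stage derives its own seed from it
(counter-based spawn keys), so stages can be rerun independently and two
runs with the same config+seed produce byte-identical numeric outputs.
Stages communicate only through serialized files and the returned report.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import compare_model_fit, sparse_regression
from .connectivity import (compare_fc_groups, compare_structural,
                           functional_connectivity,
                           structure_function_correlation)
from .granger import (compare_groups_doi, doi_matrix, influence_terms,
                      group_causal_graph, surrogate_null_granger)
from .graphmetrics import hub_test, node_metrics
from .inference import difference_null
from .io import load_cohort, write_cohort, write_graph
from .latency import EventResponseModel, compare_latencies, subject_onsets
from .mds import (compare_groups_mds, fit_mds, significant_edges,
                  surrogate_null_mds)
from .preprocess import preprocess_timeseries
from .simulate import default_cohort_spec, generate_cohort

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int = 0
    manifest: Path | None = None        # load an existing cohort ...
    simulate: dict = field(default_factory=dict)   # ... or generate one
    mds: dict = field(default_factory=dict)
    granger: dict = field(default_factory=dict)
    latency: dict = field(default_factory=dict)
    graph: dict = field(default_factory=dict)
    fc: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in d:
            raise ValueError("config must set 'outdir'")
        d["outdir"] = Path(d["outdir"])
        if d.get("manifest"):
            d["manifest"] = Path(d["manifest"])
        return cls(**d)


def validate_inputs(cfg: RunConfig) -> list[str]:
    """Collect every config/manifest violation; empty list means valid."""
    violations: list[str] = []
    if cfg.manifest is None and not isinstance(cfg.simulate, dict):
        violations.append("either 'manifest' or 'simulate' must be given")
    if cfg.manifest is not None:
        if not Path(cfg.manifest).exists():
            violations.append(f"manifest not found: {cfg.manifest}")
            return violations
        man = yaml.safe_load(Path(cfg.manifest).read_text())
        root = Path(cfg.manifest).parent
        regions = set(man.get("region_names", []))
        behavior_ids = set()
        if man.get("behavior"):
            bpath = root / man["behavior"]
            if not bpath.exists():
                violations.append(f"behavior table not found: {bpath}")
            else:
                behavior_ids = set(
                    pd.read_csv(bpath, sep="\t")["subject_id"])
        for sub in man.get("subjects", []):
            sid = sub.get("subject_id", "?")
            f = root / sub.get("file", "")
            if not f.exists():
                violations.append(f"subject {sid}: time-series file missing ({f})")
                continue
            cols = set(pd.read_csv(f, sep="\t", nrows=0).columns)
            if regions and cols != regions:
                violations.append(
                    f"subject {sid}: region set {sorted(cols)} does not match "
                    f"manifest {sorted(regions)}")
            if behavior_ids and sid not in behavior_ids:
                violations.append(f"subject {sid}: no behavior row")
        if man.get("events") and not (root / man["events"]).exists():
            violations.append(f"events table not found: {man['events']}")
    return violations


def _stage_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(index,))
               .generate_state(1)[0] % (2 ** 31))


def _write_table(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    header = "".join(f"# {k}: {v}\n" for k, v in provenance.items())
    path.write_text(header + df.to_csv(sep="\t", index=False,
                                       float_format=_FLOAT_FMT))


def _pair_features(regions: tuple[str, ...], doi: np.ndarray
                   ) -> tuple[list[str], np.ndarray]:
    """Net strengths of the M(M-1)/2 unordered region pairs from a doi
    matrix (sign: positive means earlier-listed region drives the later)."""
    names, vals = [], []
    M = len(regions)
    for i in range(M):
        for j in range(i + 1, M):
            names.append(f"{regions[i]}->{regions[j]}")
            vals.append(doi[j, i])  # doi[target, source] > 0: i drives j
    return names, np.asarray(vals)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run report."""
    violations = validate_inputs(cfg)
    if violations:
        raise ValueError("invalid inputs:\n- " + "\n- ".join(violations))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {},
                    "config": {k: str(v) if isinstance(v, Path) else v
                               for k, v in vars(cfg).items()}}

    def record(stage, status, **extra):
        report["stages"][stage] = {"status": status, **extra}

    # ----- stage 0: cohort -------------------------------------------------
    if cfg.manifest is not None:
        timeseries, design, behavior_tab, structure_tab = load_cohort(cfg.manifest)
        record("cohort", "loaded", manifest=str(cfg.manifest))
    else:
        sim = dict(cfg.simulate)
        n_sub = sim.pop("n_subjects", {"adult": 8, "child": 8})
        spec = default_cohort_spec(seed=_stage_seed(cfg.seed, 0), **sim)
        for g, n in n_sub.items():
            spec.groups[g].n_subjects = int(n)
        cohort = generate_cohort(spec)
        write_cohort(cohort, out / "cohort")
        timeseries, design = cohort.timeseries, cohort.design
        behavior_tab, structure_tab = cohort.behavior, cohort.structure
        record("cohort", "simulated", path=str(out / "cohort"))

    groups = list(dict.fromkeys(ts.group_label for ts in timeseries))
    regions = timeseries[0].region_names
    pre = {g: [preprocess_timeseries(ts) for ts in timeseries
               if ts.group_label == g] for g in groups}

    # ----- stage 1: Granger ------------------------------------------------
    per_subject_doi: dict[str, np.ndarray] = {}
    try:
        gcfg = {"order": 1, "n_surrogates": 199, "alpha": 0.01,
                "method": "phase", **cfg.granger}
        seed = _stage_seed(cfg.seed, 1)
        nulls, graphs = {}, {}
        for k, g in enumerate(groups):
            nulls[g] = surrogate_null_granger(
                pre[g], order=gcfg["order"], n_surrogates=gcfg["n_surrogates"],
                method=gcfg["method"], seed=seed + k)
            graphs[g] = group_causal_graph(pre[g], gcfg["order"], nulls[g],
                                           alpha=gcfg["alpha"])
            write_graph(graphs[g], out / f"granger_{g}.tsv",
                        {"group": g, "order": gcfg["order"], "seed": seed + k})
        for ts_list in pre.values():
            for ts in ts_list:
                per_subject_doi[ts.subject_id] = doi_matrix(
                    influence_terms(ts, gcfg["order"]))
        if len(groups) == 2:
            dn = difference_null(nulls[groups[0]], nulls[groups[1]])
            diff = compare_groups_doi(pre[groups[0]], pre[groups[1]],
                                      gcfg["order"], dn, alpha=gcfg["alpha"])
            write_graph(diff, out / "granger_groupdiff.tsv",
                        {"contrast": f"{groups[0]} - {groups[1]}"})
        record("granger", "ok", files=[f"granger_{g}.tsv" for g in groups])
    except Exception:
        record("granger", "failed", error=traceback.format_exc(limit=3))
        graphs = {}

    # ----- stage 2: MDS ----------------------------------------------------
    try:
        mcfg = {"max_iter": 60, "n_surrogates": 100, "surrogate_max_iter": 12,
                "alpha": 0.01, "method": "phase", **cfg.mds}
        seed = _stage_seed(cfg.seed, 2)
        mds_fits, mds_nulls, mds_graphs = {}, {}, {}
        for k, g in enumerate(groups):
            mds_fits[g] = fit_mds(pre[g], design, max_iter=mcfg["max_iter"])
            mds_nulls[g] = surrogate_null_mds(
                pre[g], design, n_surrogates=mcfg["n_surrogates"],
                method=mcfg["method"], seed=seed + k,
                surrogate_max_iter=mcfg["surrogate_max_iter"])
            mds_graphs[g] = significant_edges(mds_fits[g], mds_nulls[g],
                                              alpha=mcfg["alpha"])
            write_graph(mds_graphs[g], out / f"mds_{g}.tsv",
                        {"group": g, "seed": seed + k})
        if len(groups) == 2:
            diff = compare_groups_mds(mds_fits[groups[0]], mds_fits[groups[1]],
                                      mds_nulls[groups[0]], mds_nulls[groups[1]],
                                      alpha=mcfg["alpha"])
            write_graph(diff, out / "mds_groupdiff.tsv",
                        {"contrast": f"{groups[0]} - {groups[1]}"})
        record("mds", "ok", files=[f"mds_{g}.tsv" for g in groups],
               converged={g: bool(mds_fits[g].converged) for g in groups})
    except Exception:
        record("mds", "failed", error=traceback.format_exc(limit=3))

    # ----- stage 3: latency ------------------------------------------------
    try:
        lcfg = {"threshold_frac": 0.10, "alpha": 0.01, **cfg.latency}
        onsets = {}
        for g in groups:
            resp = EventResponseModel().fit(pre[g], design).responses_
            onsets[g] = subject_onsets(resp, lcfg["threshold_frac"])
        tests = compare_latencies(onsets, alpha=lcfg["alpha"])
        summary = pd.concat([df.assign(group=g) for g, df in onsets.items()])
        mean_onsets = (summary.groupby(["group", "region"])["onset"]
                       .agg(["mean", "sem"]).reset_index())
        _write_table(mean_onsets, out / "latency.tsv",
                     {"threshold_frac": lcfg["threshold_frac"]})
        _write_table(tests["within_group"], out / "latency_within.tsv", {})
        _write_table(tests["between_group"], out / "latency_between.tsv", {})
        record("latency", "ok", files=["latency.tsv"])
    except Exception:
        record("latency", "failed", error=traceback.format_exc(limit=3))

    # ----- stage 4: graph metrics -----------------------------------------
    try:
        gmcfg = {"alpha": 0.05, **cfg.graph}
        frames = []
        for g in groups:
            if g in graphs:
                gm = node_metrics(graphs[g]).assign(group=g, level="group")
                frames.append(gm)
            rows = []
            for i, ts in enumerate(pre[g]):
                adj = (per_subject_doi[ts.subject_id] > 0).astype(int).T
                sm = node_metrics(adj)
                sm["region"] = list(regions)
                sm["subject"] = i
                rows.append(sm)
            per_sub = pd.concat(rows, ignore_index=True)
            hubs_net = hub_test(per_sub, "net_outflow", alpha=gmcfg["alpha"])
            hubs_pl = hub_test(per_sub, "path_length", alpha=gmcfg["alpha"])
            _write_table(hubs_net, out / f"hub_net_outflow_{g}.tsv", {"group": g})
            _write_table(hubs_pl, out / f"hub_path_length_{g}.tsv", {"group": g})
        if frames:
            _write_table(pd.concat(frames, ignore_index=True),
                         out / "node_metrics.tsv", {})
        record("graph", "ok", files=["node_metrics.tsv"])
    except Exception:
        record("graph", "failed", error=traceback.format_exc(limit=3))

    # ----- stage 5: FC + structure ----------------------------------------
    try:
        fcfg = {"alpha": 0.01, "edge": ["rAI", "rPPC"], **cfg.fc}
        fc = {g: np.stack([functional_connectivity(ts) for ts in pre[g]])
              for g in groups}
        if len(groups) == 2:
            fc_cmp = compare_fc_groups(fc[groups[0]], fc[groups[1]], regions,
                                       alpha=fcfg["alpha"])
            _write_table(fc_cmp, out / "fc_comparison.tsv",
                         {"contrast": f"{groups[0]} - {groups[1]}"})
        sf_rows = []
        if structure_tab is not None:
            edge = tuple(fcfg["edge"])
            ia, ib = regions.index(edge[0]), regions.index(edge[1])
            for g in groups:
                ids = [ts.subject_id for ts in pre[g]]
                if len(ids) < 5:  # correlation undefined below 5 subjects
                    continue
                fc_edge = pd.Series(fc[g][:, ia, ib], index=ids)
                r, p = structure_function_correlation(
                    fc_edge, structure_tab, edge)
                sf_rows.append({"group": g, "measure": "fc_r", "r": r, "p": p})
                causal = pd.Series(
                    [per_subject_doi[i][ib, ia] for i in ids], index=ids)
                r2, p2 = structure_function_correlation(
                    causal, structure_tab, edge)
                sf_rows.append({"group": g, "measure": "causal_doi",
                                "r": r2, "p": p2})
            _write_table(pd.DataFrame(sf_rows),
                         out / "structure_function.tsv", {"edge": fcfg["edge"]})
            if len(groups) == 2:
                sc_cmp = compare_structural(structure_tab, edge,
                                            groups=(groups[0], groups[1]))
                _write_table(sc_cmp, out / "structural_comparison.tsv",
                             {"edge": fcfg["edge"]})
        record("fc", "ok", files=["fc_comparison.tsv"])
    except Exception:
        record("fc", "failed", error=traceback.format_exc(limit=3))

    # ----- stage 6: behavior ----------------------------------------------
    try:
        bcfg = {"folds": 5, "targets": ["reaction_time", "accuracy"],
                **cfg.behavior}
        seed = _stage_seed(cfg.seed, 6)
        if behavior_tab is None:
            raise ValueError("no behavior table available")
        results = []
        for target in bcfg["targets"]:
            fits = {}
            for g in groups:
                ids = [ts.subject_id for ts in pre[g]]
                names, _ = _pair_features(regions, per_subject_doi[ids[0]])
                X = np.stack([_pair_features(regions, per_subject_doi[i])[1]
                              for i in ids])
                yv = (behavior_tab.set_index("subject_id")
                      .loc[ids, target].to_numpy(float))
                fits[g] = sparse_regression(X, yv, feature_names=names,
                                            cv_folds=min(bcfg["folds"], len(ids)),
                                            seed=seed)
            if len(groups) == 2:
                cmp = compare_model_fit(fits[groups[0]], fits[groups[1]],
                                        labels=(groups[0], groups[1]))
                cmp.insert(0, "target", target)
                results.append(cmp)
            (out / f"behavior_{target}.json").write_text(json.dumps(
                {g: fits[g].report() for g in groups}, indent=1))
        if results:
            _write_table(pd.concat(results, ignore_index=True),
                         out / "behavior_comparison.tsv", {})
        record("behavior", "ok", files=["behavior_comparison.tsv"])
    except Exception:
        record("behavior", "failed", error=traceback.format_exc(limit=3))

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
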
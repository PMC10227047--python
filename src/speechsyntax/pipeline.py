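"""End-to-end pipeline: simulate/ingest -> metrics -> compare -> classify
-> cluster -> network.

A :class:`PipelineConfig` (usually loaded from YAML) names the input source
(a simulation block or transcript + covariate files), the stages to run,
per-stage parameter overrides, the master seed and the output directory.
Every stage writes plain CSV/TSV tables with a fixed float format, and the
resolved configuration is echoed to ``manifest.json`` — re-running with the
manifest reproduces every output byte for byte.  All randomness flows from
the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as ssio
from .classify import permutation_pvalue
from .cluster import characterize_clusters, interaction_effect_test, select_clusters_bic
from .groupstats import compare_measures_table, confounder_correlations
from .metrics import HEADLINE_MEASURES, compute_syntax_profile
from .network import DEFAULT_NODES, bootstrap_edges, centralities, estimate_ggm, fr_layout
from .simulate import COVARIATE_NAMES, CohortConfig, cohort_frame, sample_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "metrics", "compare", "classify", "cluster", "network")

_COMPARE_MEASURES = [
    "total_words", "total_sentences", "mlu", "total_different_words", "ttr",
    "rate_simple", "rate_coordinated",
] + HEADLINE_MEASURES


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/run"
    stages: Tuple[str, ...] = ALL_STAGES
    simulate: Optional[Mapping] = field(default_factory=dict)   # CohortConfig dict
    transcripts_path: Optional[str] = None
    covariates_path: Optional[str] = None
    classify: Mapping = field(default_factory=dict)
    cluster: Mapping = field(default_factory=dict)
    network: Mapping = field(default_factory=dict)

    @staticmethod
    def from_dict(d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = PipelineConfig(**{k: v for k, v in d.items()})
        cfg = dataclasses.replace(cfg, stages=tuple(cfg.stages))
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {ALL_STAGES}")
        return cfg

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def validate_config(config: PipelineConfig) -> List[str]:
    """Dry-run validation: returns a list of problems (empty when runnable)."""
    problems = []
    needs_data = [s for s in config.stages if s != "simulate"]
    if "simulate" not in config.stages:
        if needs_data and not config.transcripts_path:
            problems.append("stages need transcripts but no simulate stage or transcripts_path")
        elif config.transcripts_path and not Path(config.transcripts_path).exists():
            problems.append(f"transcripts_path {config.transcripts_path!r} does not exist")
        if any(s in config.stages for s in ("classify", "cluster", "network")) and (
            config.covariates_path and not Path(config.covariates_path).exists()
        ):
            problems.append(f"covariates_path {config.covariates_path!r} does not exist")
    return problems


def _load_cohort(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Cohort table (profiles recomputed from transcripts + covariates)."""
    if "simulate" in config.stages:
        cohort_cfg = CohortConfig.from_dict(config.simulate or {})
        records = sample_cohort(cohort_cfg, seed=config.seed)
        ssio.write_transcripts([r.transcript for r in records], outdir / "transcripts.tsv")
        frame = cohort_frame(records)
        ssio.write_table(frame, outdir / "cohort.csv")
        return frame
    transcripts = ssio.read_transcripts(config.transcripts_path)
    profiles = {t.participant_id: compute_syntax_profile(t) for t in transcripts}
    frame = ssio.profiles_to_frame(profiles)
    if config.covariates_path:
        cov = pd.read_csv(config.covariates_path)
        frame = frame.merge(cov, on="participant_id", how="left")
    if "group" not in frame.columns:
        frame["group"] = "ALL"
    return frame


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the enabled stages in order; returns a manifest dict."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("speechsyntax")
    root.addHandler(handler)
    outputs: List[str] = []
    try:
        cohort = _load_cohort(config, outdir)
        if "simulate" in config.stages:
            outputs += ["transcripts.tsv", "cohort.csv"]

        if "metrics" in config.stages:
            keep = ["participant_id", "group"] + [
                c for c in cohort.columns if c not in ("participant_id", "group")
            ]
            ssio.write_table(cohort[keep], outdir / "profiles.csv")
            outputs.append("profiles.csv")

        if "compare" in config.stages:
            measures = [m for m in _COMPARE_MEASURES if m in cohort.columns]
            table, _ = compare_measures_table(cohort, measures)
            ssio.write_table(table, outdir / "group_comparison.csv")
            outputs.append("group_comparison.csv")
            conf_cols = [c for c in ("age", "sex", "education") if c in cohort.columns]
            if conf_cols:
                grid = confounder_correlations(cohort[HEADLINE_MEASURES], cohort[conf_cols])
                ssio.write_table(grid, outdir / "confounder_correlations.csv")
                outputs.append("confounder_correlations.csv")

        if "classify" in config.stages:
            params = dict(config.classify)
            pairs = params.pop("pairs", None)
            if pairs is None:
                labels = sorted(set(cohort["group"]))
                pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
            rows = []
            for k, (a, b) in enumerate(pairs):
                sub = cohort[cohort["group"].isin([a, b])]
                res = permutation_pvalue(
                    sub[HEADLINE_MEASURES].to_numpy(),
                    sub["group"].to_numpy(),
                    n_reps=int(params.get("n_reps", 200)),
                    n_perm=int(params.get("n_perm", 1000)),
                    null_reps=int(params.get("null_reps", 20)),
                    seed=int(np.random.SeedSequence((config.seed, 100 + k)).generate_state(1)[0] % 2**31),
                    pair_label=f"{a}_vs_{b}",
                )
                rows.append({"pair": res.pair_label, "mean_accuracy": res.mean_accuracy,
                             "p_value": res.p_value, "n_dropped": res.n_dropped})
            ssio.write_table(pd.DataFrame(rows), outdir / "classification.csv")
            outputs.append("classification.csv")

        assignments = None
        if "cluster" in config.stages:
            params = dict(config.cluster)
            k_range = range(int(params.get("k_min", 1)), int(params.get("k_max", 8)) + 1)
            feats = cohort.dropna(subset=HEADLINE_MEASURES)
            result = select_clusters_bic(
                feats[["participant_id"] + HEADLINE_MEASURES],
                k_range=k_range,
                seed=config.seed,
                diagnosis=dict(zip(feats["participant_id"], feats["group"])),
            )
            assignments = result.assignments
            ssio.write_table(
                pd.DataFrame(
                    {"participant_id": list(result.assignments),
                     "cluster": list(result.assignments.values())}
                ),
                outdir / "cluster_assignments.csv",
            )
            ssio.write_table(
                pd.DataFrame({"k": list(result.bic_by_k), "bic": list(result.bic_by_k.values())}),
                outdir / "bic_by_k.csv",
            )
            outputs += ["cluster_assignments.csv", "bic_by_k.csv"]
            if result.k_selected > 1 and cohort["group"].nunique() > 1:
                inter_rows = []
                merged = feats.assign(cluster=feats["participant_id"].map(assignments))
                for m in HEADLINE_MEASURES:
                    F, p = interaction_effect_test(merged[m], merged["group"], merged["cluster"])
                    inter_rows.append({"measure": m, "F": F, "p": p})
                ssio.write_table(pd.DataFrame(inter_rows), outdir / "interaction_tests.csv")
                outputs.append("interaction_tests.csv")
                covs = [c for c in COVARIATE_NAMES if c in cohort.columns]
                table, composition, _ = characterize_clusters(
                    merged, assignments, HEADLINE_MEASURES + covs
                )
                ssio.write_table(table, outdir / "cluster_characterization.csv")
                ssio.write_table(composition.reset_index(), outdir / "cluster_composition.csv")
                outputs += ["cluster_characterization.csv", "cluster_composition.csv"]

        if "network" in config.stages:
            params = dict(config.network)
            nodes = [c for c in DEFAULT_NODES if c in cohort.columns]
            data = cohort.dropna(subset=nodes)[nodes]
            model = estimate_ggm(data, gamma=float(params.get("gamma", 0.25)))
            ssio.write_table(model.edge_list(), outdir / "network_edges.tsv")
            ssio.write_table(model.edge_list(threshold=0.1), outdir / "network_edges_display.tsv")
            ssio.write_table(centralities(model), outdir / "centralities.csv")
            ssio.write_table(fr_layout(model, seed=config.seed), outdir / "layout.csv")
            outputs += ["network_edges.tsv", "network_edges_display.tsv",
                        "centralities.csv", "layout.csv"]
            B = int(params.get("bootstrap", 0))
            if B:
                boot = bootstrap_edges(data, B=B, gamma=float(params.get("gamma", 0.25)),
                                       seed=config.seed)
                ssio.write_table(boot, outdir / "edge_stability.csv")
                outputs.append("edge_stability.csv")

        manifest = {
            "config": {
                "seed": config.seed,
                "outdir": str(config.outdir),
                "stages": list(config.stages),
                "simulate": dict(config.simulate or {}),
                "transcripts_path": config.transcripts_path,
                "covariates_path": config.covariates_path,
                "classify": dict(config.classify),
                "cluster": dict(config.cluster),
                "network": dict(config.network),
            },
            "outputs": outputs,
            "n_participants": int(len(cohort)),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
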
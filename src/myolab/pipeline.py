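"""Stage orchestration over a run configuration.

``run_pipeline`` executes any subset of {simulate, preprocess, de, network,
meta, sensitivity} in dependency order over a shared output directory,
carrying intermediate results in memory and on disk (TSV/GraphML/JSON) so a
later invocation can resume from files.  Defaults reproduce the conventional
parameterization of the two-group bead-array workflow: detection floor 100,
|fold change| ≥ 1.2, PFP ≤ 0.05, sample-graph r > 0.85 with MCL inflation
3.0, probe-graph r > 0.80 with inflation 2.2.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import meta as meta_mod
from . import network as net
from .containers import ExpressionMatrix, check_metadata
from .diffexp import RankProductConfig, run_diffexp
from .preprocess import preprocess
from .simulate import (
    MixtureParams,
    StudyDesign,
    SyntheticStudy,
    default_catalog,
    generate_multistudy,
    generate_study,
)
from .validation import subgroup_sensitivity

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "de", "network", "meta", "sensitivity")
_STAGE_DEPS = {
    "preprocess": "simulate",
    "de": "preprocess",
    "network": "de",
    "sensitivity": "preprocess",
}


class DependencyError(RuntimeError):
    """A requested stage is missing the outputs of an earlier stage."""


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; every field has the conventional default."""

    outdir: str = "results/run"
    seed: int = 0
    # simulate
    n_labour: int = 22
    n_nonlabour: int = 26
    induced_fraction: float = 0.5
    # preprocess
    floor: float | None = None  # None -> negative-control median
    # differential expression
    fc_threshold: float = 1.2
    pfp_alpha: float = 0.05
    n_permutations: int = 100
    max_pairs: int = 100
    scale: str = "raw"
    # network
    sample_r: float = 0.85
    probe_r: float = 0.80
    inflation_sample: float = 3.0
    inflation_probe: float = 2.2
    graph_top_n: int = 100  # top probes per direction (by rank product)
    # meta
    effects_model: str = "both"  # fixed | random | both
    collapse_rule: str = "max_mean"
    meta_n_studies: int = 3
    shared_gene_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"invalid config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _de_cfg(config: RunConfig) -> RankProductConfig:
    return RankProductConfig(
        n_permutations=config.n_permutations,
        max_pairs=config.max_pairs,
        seed=config.seed,
        scale=config.scale,
        fc_threshold=config.fc_threshold,
        pfp_alpha=config.pfp_alpha,
    )


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order and return the run report."""
    stages = list(stages) if stages else list(STAGES)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": stages, "warnings": []}
    state: dict = {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in stages:
            dep = _STAGE_DEPS.get(stage)
            if dep is not None and not _stage_available(dep, state, outdir):
                raise DependencyError(
                    f"stage {stage!r} requires outputs of stage {dep!r}; run it first"
                )
            _STAGE_FUNCS[stage](config, state, outdir, report)
        report["warnings"] = sorted({str(w.message) for w in caught})

    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _stage_available(stage: str, state: dict, outdir: Path) -> bool:
    if stage in state.get("done", set()):
        return True
    marker = {
        "simulate": outdir / "study_expression.tsv",
        "preprocess": outdir / "processed_expression.tsv",
        "de": outdir / "de_table.tsv",
    }.get(stage)
    return marker is not None and marker.exists()


def _load_study(state: dict, outdir: Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    if "study" in state:
        study: SyntheticStudy = state["study"]
        return study.expression, study.metadata
    expr = ExpressionMatrix.from_tsv(
        outdir / "study_expression.tsv", outdir / "study_controls.tsv"
    )
    md = check_metadata(pd.read_csv(outdir / "study_metadata.tsv", sep="\t"))
    return expr, md


def _stage_simulate(config: RunConfig, state: dict, outdir: Path, report: dict) -> None:
    catalog = default_catalog(seed=config.seed)
    design = StudyDesign(
        n_labour=config.n_labour,
        n_nonlabour=config.n_nonlabour,
        induced_fraction=config.induced_fraction,
        seed=config.seed,
        label="sim",
    )
    study = generate_study(catalog, MixtureParams(), design)
    study.write(outdir, prefix="study")
    state["study"] = study
    state.setdefault("done", set()).add("simulate")
    report["simulate"] = {
        "n_samples": study.expression.n_samples,
        "n_probes": study.expression.n_probes,
        "n_control_probes": int(study.expression.is_control.sum()),
    }


def _stage_preprocess(config: RunConfig, state: dict, outdir: Path, report: dict) -> None:
    expr, md = _load_study(state, outdir)
    processed, pre_report = preprocess(expr, md, floor=config.floor)
    processed.to_tsv(outdir / "processed_expression.tsv")
    state["processed"] = processed
    state["metadata"] = md
    state.setdefault("done", set()).add("preprocess")
    pre_report = dict(pre_report)
    pre_report.pop("normexp_params", None)  # bulky; parameters recoverable from inputs
    report["preprocess"] = pre_report


def _load_processed(state: dict, outdir: Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    if "processed" in state:
        return state["processed"], state["metadata"]
    expr, md = _load_study(state, outdir)
    annotation = expr.annotation
    processed = ExpressionMatrix.from_tsv(outdir / "processed_expression.tsv")
    if annotation is not None:
        processed = ExpressionMatrix(
            values=processed.values,
            is_control=processed.is_control,
            annotation=annotation.reindex(processed.values.index),
        )
    return processed, md


def _stage_de(config: RunConfig, state: dict, outdir: Path, report: dict) -> None:
    processed, md = _load_processed(state, outdir)
    table = run_diffexp(processed, md, _de_cfg(config))
    table.rename_axis("probe_id").reset_index().to_csv(
        outdir / "de_table.tsv", sep="\t", index=False
    )
    state["de"] = table
    state.setdefault("done", set()).add("de")
    report["de"] = {
        "n_probes_tested": len(table),
        "n_up": int((table["call"] == "up").sum()),
        "n_down": int((table["call"] == "down").sum()),
        "fc_threshold": config.fc_threshold,
        "pfp_alpha": config.pfp_alpha,
    }


def _stage_network(config: RunConfig, state: dict, outdir: Path, report: dict) -> None:
    processed, md = _load_processed(state, outdir)
    de = state.get("de")
    if de is None:
        de = pd.read_csv(outdir / "de_table.tsv", sep="\t").set_index("probe_id")
    # graph input: top up- and down-regulated probes by rank product; the
    # significance-gated set can be one-sided on small studies, which starves
    # the sample graph of intensity diversity
    top_n = min(config.graph_top_n, len(de))
    selected = de["rp_up"].nsmallest(top_n).index.union(
        de["rp_down"].nsmallest(top_n).index
    )
    if len(selected) < 3:
        raise DependencyError("network stage needs >= 3 selected probes")
    sub = processed.subset_probes(selected)
    # log2 intensities: sample-sample similarity rides on the shared intensity
    # profile, which per-probe standardization would erase
    logged = np.log2(sub.values)

    sample_graph = net.correlation_graph(logged, net.MODE_SAMPLE, config.sample_r)
    sample_clusters = net.mcl_cluster(
        sample_graph, net.MCLConfig(inflation=config.inflation_sample)
    )
    assoc = net.cluster_trait_association(sample_clusters, md, md["group"])
    net.export_graphml(
        sample_graph, outdir / "sample_graph.graphml",
        node_attributes=md, assignment=sample_clusters,
    )
    sample_clusters.labels.rename("cluster").rename_axis("node_id").reset_index().to_csv(
        outdir / "sample_clusters.tsv", sep="\t", index=False
    )

    probe_graph = net.correlation_graph(logged, net.MODE_PROBE, config.probe_r)
    probe_clusters = net.mcl_cluster(
        probe_graph, net.MCLConfig(inflation=config.inflation_probe)
    )
    profiles = net.cluster_profiles(sub, probe_clusters)
    net.export_graphml(probe_graph, outdir / "probe_graph.graphml", assignment=probe_clusters)
    probe_clusters.labels.rename("cluster").rename_axis("node_id").reset_index().to_csv(
        outdir / "probe_clusters.tsv", sep="\t", index=False
    )
    prof_long = pd.concat(
        {cid: p for cid, p in profiles.items()}, names=["cluster", "sample_id"]
    )
    prof_long.reset_index().to_csv(outdir / "cluster_profiles.tsv", sep="\t", index=False)

    state.setdefault("done", set()).add("network")
    report["network"] = {
        "n_selected_probes": int(len(selected)),
        "sample_clusters": sample_clusters.n_clusters,
        "probe_clusters": probe_clusters.n_clusters,
        "labour_association_test": assoc["test"],
        "labour_association_p": assoc["pvalue"],
    }


def _stage_meta(config: RunConfig, state: dict, outdir: Path, report: dict) -> None:
    designs = [
        StudyDesign(n_labour=config.n_labour, n_nonlabour=config.n_nonlabour, label="sharp"),
        StudyDesign(n_labour=6, n_nonlabour=6, label="weiner"),
        StudyDesign(n_labour=7, n_nonlabour=6, label="bukowski"),
    ][: max(2, config.meta_n_studies)]
    studies = generate_multistudy(
        designs,
        shared_gene_fraction=config.shared_gene_fraction,
        attenuation=[1.0] * len(designs),
        seed=config.seed + 17,
    )
    processed = []
    for s in studies:
        p, _ = preprocess(s.expression, s.metadata)
        processed.append(p)
    harmonized = meta_mod.harmonize_genes(processed, rule=config.collapse_rule)
    smds = []
    de_tables = {}
    cfg = _de_cfg(config)
    for s, gene_matrix in zip(studies, harmonized):
        summary = meta_mod.study_summary(gene_matrix, s.metadata, s.label)
        smds.append(meta_mod.smd_table(summary))
        expr = ExpressionMatrix(
            values=gene_matrix,
            is_control=pd.Series(False, index=gene_matrix.index),
            annotation=pd.DataFrame({"gene_symbol": gene_matrix.index}, index=gene_matrix.index),
        )
        de_tables[s.label] = run_diffexp(expr, s.metadata, cfg)
    smd_long = pd.concat(smds, ignore_index=True)
    pooled = meta_mod.pool_all(smd_long)
    pooled.reset_index().to_csv(outdir / "meta_pooled.tsv", sep="\t", index=False)
    smd_long.to_csv(outdir / "meta_smd_long.tsv", sep="\t", index=False)

    shared_genes = set(harmonized[0].index)
    conc_rows = []
    labels = [s.label for s in studies]
    for i in range(len(labels)):
        for j in range(len(labels)):
            if i == j:
                continue
            rep = meta_mod.de_concordance(de_tables[labels[i]], de_tables[labels[j]], shared_genes)
            rep["study_A"], rep["study_B"] = labels[i], labels[j]
            conc_rows.append(rep)
    conc = pd.DataFrame(conc_rows)
    conc.to_csv(outdir / "meta_concordance.tsv", sep="\t", index=False)

    state.setdefault("done", set()).add("meta")
    report["meta"] = {
        "n_studies": len(studies),
        "n_shared_genes": len(shared_genes),
        "mean_tau2": float(pooled["tau2"].mean()),
        "frac_low_heterogeneity": float((pooled["p_Q"] > 0.05).mean()),
    }


def _stage_sensitivity(config: RunConfig, state: dict, outdir: Path, report: dict) -> None:
    processed, md = _load_processed(state, outdir)
    sens = subgroup_sensitivity(processed, md, "induction", _de_cfg(config))
    report["sensitivity"] = {
        "n_probes": sens.n_probes,
        "median_abs_diff": sens.median_abs_diff,
        "iqr_signed_diff": list(sens.iqr_signed_diff),
        "pearson_r": sens.pearson_r,
        "pct_same_direction": sens.pct_same_direction,
    }
    pd.DataFrame([report["sensitivity"]]).to_csv(
        outdir / "sensitivity_report.tsv", sep="\t", index=False
    )
    state.setdefault("done", set()).add("sensitivity")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "de": _stage_de,
    "network": _stage_network,
    "meta": _stage_meta,
    "sensitivity": _stage_sensitivity,
}
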
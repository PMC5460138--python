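"""End-to-end orchestration over resources and cancer types.

A run is described by one declarative YAML file (paths to the edge lists,
expression matrices, mutation lists, GAF and bioactivity table, plus all
stage parameters and a single seed). Every stage writes its tables under
``<output_dir>/<resource>/<cancer>/`` and a consolidated summary table ties
the run together. Identical (config, seed) pairs produce identical numeric
outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .classify import (
    CLASS_LABELS,
    classification_table,
    classify,
    consensus_influencers,
    first_neighbour_split,
    with_influencers,
)
from .construct import build_tissue_network, call_differential_expression, discretize
from .errors import ConfigError, DataError, PipelineError
from .functional_drug import added_bp_binomial_test, added_bps, count_by_class, filter_drugs
from .topology import (
    compare_classes,
    comparisons_frame,
    compute_topology,
    giant_component_test,
    randomization_analysis,
)

logger = logging.getLogger(__name__)


@dataclass
class StageParams:
    """Stage parameters; defaults mirror the analysis' reference settings."""

    n_perm: int = 1000
    randomizations: int = 100
    potency_cutoff_nM: float = 500.0
    phase_cutoff: int = 4
    consensus_k: int = 3
    summary: str = "mean"
    sd: str = "sample"
    pooling: str = "combined"
    uncovered: str = "absent"
    edge_rule: str = "union"
    control: str = "whole_network"
    restrict_influencers_to_de_fn: bool = True
    plots: bool = True


@dataclass
class CancerInputs:
    expression: Path
    normal_samples: list[str]
    cancer_samples: list[str]
    mutations: Path


@dataclass
class RunConfig:
    resources: dict[str, Path]
    cancers: dict[str, CancerInputs]
    output_dir: Path
    gaf: Path | None = None
    bioactivity: Path | None = None
    params: StageParams = field(default_factory=StageParams)
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.resources:
            raise ConfigError("at least one network resource is required")
        if not self.cancers:
            raise ConfigError("at least one cancer type is required")
        for name, path in self.resources.items():
            if not Path(path).exists():
                raise ConfigError(f"resource {name!r}: missing file {path}")
        for cancer, inputs in self.cancers.items():
            for p in (inputs.expression, inputs.mutations):
                if not Path(p).exists():
                    raise ConfigError(f"cancer {cancer!r}: missing file {p}")
        for p in (self.gaf, self.bioactivity):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"missing file {p}")
        if self.params.consensus_k < 1:
            raise ConfigError("consensus_k must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a mapping")
    base = path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    try:
        resources = {k: _resolve(v) for k, v in raw["resources"].items()}
        cancers = {}
        for cancer, spec in raw["cancers"].items():
            cancers[cancer] = CancerInputs(
                expression=_resolve(spec["expression"]),
                normal_samples=list(spec["normal_samples"]),
                cancer_samples=list(spec["cancer_samples"]),
                mutations=_resolve(spec["mutations"]),
            )
    except (KeyError, TypeError, AttributeError) as exc:
        raise ConfigError(f"{path}: malformed run configuration ({exc!r})") from exc
    params = StageParams(**raw.get("params", {}))
    config = RunConfig(
        resources=resources,
        cancers=cancers,
        output_dir=_resolve(str(raw.get("output_dir", "neighbornet_out"))),
        gaf=_resolve(raw["gaf"]) if raw.get("gaf") else None,
        bioactivity=_resolve(raw["bioactivity"]) if raw.get("bioactivity") else None,
        params=params,
        rng_seed=int(raw.get("seed", 0)),
    )
    config.validate()
    return config


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def _class_boxplot(topology: pd.DataFrame, classification, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, metric in zip(axes, ("degree", "betweenness", "clustering")):
        data = [
            topology.loc[sorted(classification.members(label)), metric]
            for label in CLASS_LABELS
        ]
        ax.boxplot(data, tick_labels=["CR", "FN", "UA"], showfliers=False)
        ax.set_title(metric)
        if metric != "clustering":
            ax.set_yscale("symlog")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every (resource, cancer) pair.

    Returns the summary as a dict and writes the full report bundle under
    ``config.output_dir``. A stage failure leaves a ``FAILED`` marker file
    naming the stage and re-raises as :class:`PipelineError`; outputs
    written before the failure are retained.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    stage = "setup"
    summary_rows: list[dict] = []
    influencers_by_cancer: dict[str, dict[str, frozenset]] = {}
    dropped_log: list[str] = []
    try:
        stage = "load_annotations"
        annotations = nio.read_gaf(config.gaf) if config.gaf else None
        bioactivity = nio.read_bioactivity(config.bioactivity) if config.bioactivity else None

        for resource, edge_path in config.resources.items():
            stage = f"load_network[{resource}]"
            interactome = nio.read_edge_list(edge_path, resource_name=resource)
            dropped_log.append(
                f"{resource}: self_loops_dropped={interactome.n_self_loops_dropped} "
                f"duplicates_collapsed={interactome.n_duplicates_collapsed}"
            )
            for cancer, inputs in config.cancers.items():
                rundir = outdir / resource / cancer
                stage = f"expression[{resource}/{cancer}]"
                profile = nio.read_expression_matrix(
                    inputs.expression, inputs.normal_samples, inputs.cancer_samples
                )
                mutated = nio.read_gene_list(inputs.mutations)

                stage = f"discretize[{resource}/{cancer}]"
                disc = discretize(
                    profile, interactome.nodes,
                    summary=params.summary, sd=params.sd, pooling=params.pooling,
                )
                de = call_differential_expression(disc)
                network = build_tissue_network(
                    interactome, disc, uncovered=params.uncovered, rule=params.edge_rule
                )
                unexpressed_mutated = (mutated & interactome.nodes) - network.nodes
                dropped_log.append(
                    f"{resource}/{cancer}: mutated_not_in_tissue_network={len(unexpressed_mutated)}"
                )

                stage = f"classify[{resource}/{cancer}]"
                classification = classify(network, mutated, de)
                classification = with_influencers(
                    network, classification, params.restrict_influencers_to_de_fn
                )
                assert classification.n_nodes == network.n_nodes()
                influencers_by_cancer.setdefault(cancer, {})[resource] = classification.influencers
                _write_tsv(pd.DataFrame(classification_table(classification)),
                           rundir / "classes.tsv", index=False)
                presence = pd.DataFrame(
                    sorted(network.presence.items()), columns=["node", "presence"]
                )
                _write_tsv(presence, rundir / "presence.tsv", index=False)

                stage = f"topology[{resource}/{cancer}]"
                topology = compute_topology(network)
                _write_tsv(topology, rundir / "topology.tsv")
                comparisons = compare_classes(topology, classification, control=params.control)
                comparisons += compare_classes(topology, classification, control="unaffected")
                _write_tsv(comparisons_frame(comparisons), rundir / "comparisons.tsv", index=False)
                if params.plots:
                    _class_boxplot(topology, classification, rundir / "class_metrics.png")

                stage = f"giant_component[{resource}/{cancer}]"
                gc_rows = []
                gc_by_class = {}
                for i, label in enumerate(CLASS_LABELS):
                    members = classification.members(label)
                    if not members:
                        continue
                    res = giant_component_test(
                        network, members, n_perm=params.n_perm,
                        seed=np.random.default_rng([config.rng_seed, zlib.crc32(resource.encode()) % 2**16, i]),
                        label=label,
                    )
                    gc_by_class[label] = res
                    gc_rows.append(
                        {
                            "class": label, "size": res.class_size, "r_obs": res.r_obs,
                            "mean_null": res.mean_null, "sd_null": res.sd_null,
                            "z": res.z, "p_normal": res.p_normal,
                            "p_empirical": res.p_empirical, "n_perm": res.n_perm,
                        }
                    )
                _write_tsv(pd.DataFrame(gc_rows), rundir / "giant_component.tsv", index=False)

                stage = f"randomization[{resource}/{cancer}]"
                rand = randomization_analysis(
                    network, classification, R=params.randomizations,
                    seed=np.random.default_rng([config.rng_seed, zlib.crc32(resource.encode()) % 2**16, 99]),
                )
                occ = pd.DataFrame(
                    sorted(rand.occurrence.items()), columns=["node", "fn_occurrence"]
                )
                _write_tsv(occ, rundir / "randomization.tsv", index=False)

                stage = f"go[{resource}/{cancer}]"
                go_row: dict = {}
                if annotations:
                    bp = added_bps(annotations, classification)
                    bp_test = added_bp_binomial_test(bp, classification, network)
                    go_row = {
                        "bp_cr": len(bp.bp_cr), "bp_added": bp.k,
                        "bp_n": bp.n, "bp_p_expected": bp_test.p_expected,
                        "bp_p": bp_test.p_value,
                    }
                    _write_tsv(pd.DataFrame([go_row]), rundir / "go_added_bp.tsv", index=False)

                stage = f"drugs[{resource}/{cancer}]"
                drug_row: dict = {}
                if bioactivity is not None:
                    drug_records, compound_records = filter_drugs(
                        bioactivity, params.potency_cutoff_nM, params.phase_cutoff
                    )
                    counts = count_by_class(
                        drug_records, compound_records, classification, network
                    )
                    drug_row = {
                        "drugs_fn": counts.drug_count("first_neighbour"),
                        "drugs_cr": counts.drug_count("cancer_related"),
                        "compounds_fn": counts.compound_count("first_neighbour"),
                        "compounds_cr": counts.compound_count("cancer_related"),
                        "drug_chi2_p": counts.chi2.p_value if counts.chi2 else float("nan"),
                        "drug_binomial_p": counts.binomial.p_value if counts.binomial else float("nan"),
                    }
                    _write_tsv(pd.DataFrame([drug_row]), rundir / "drug_counts.tsv", index=False)

                stage = f"summary[{resource}/{cancer}]"
                fn_mut, fn_de = first_neighbour_split(classification, network)
                row = {
                    "resource": resource, "cancer": cancer,
                    "n_nodes": network.n_nodes(), "n_edges": network.n_edges(),
                    "n_cr": len(classification.cancer_related),
                    "n_mutated": len(classification.mutated),
                    "n_de": len(classification.de),
                    "n_fn": len(classification.first_neighbour),
                    "n_fn_of_mutated": len(fn_mut), "n_fn_of_de": len(fn_de),
                    "n_ua": len(classification.unaffected),
                    "n_influencers": len(classification.influencers),
                    "mu": disc.mu, "sigma": disc.sigma, "tau": disc.tau,
                }
                assert row["n_cr"] + row["n_fn"] + row["n_ua"] == row["n_nodes"]
                for label, res in gc_by_class.items():
                    short = {"cancer_related": "cr", "first_neighbour": "fn",
                             "unaffected": "ua"}[label]
                    row[f"gc_ratio_{short}"] = res.r_obs
                    row[f"gc_z_{short}"] = res.z
                    row[f"gc_p_{short}"] = res.p_empirical
                for c in comparisons:
                    if c.class_b == "whole_network":
                        row[f"{c.class_a}_{c.metric}_p"] = c.wilcoxon.p_value
                row.update({f"go_{k}": v for k, v in go_row.items()})
                row.update(drug_row)
                summary_rows.append(row)

        stage = "consensus"
        consensus_rows = []
        for cancer, per_resource in influencers_by_cancer.items():
            if len(per_resource) < 2:
                logger.info("cancer %s: single resource, consensus section omitted", cancer)
                continue
            k = min(params.consensus_k, len(per_resource))
            consensus = consensus_influencers(list(per_resource.values()), k)
            consensus_rows.append(
                {"cancer": cancer, "k": k, "n_resources": len(per_resource),
                 "n_consensus_influencers": len(consensus),
                 "proteins": ";".join(sorted(consensus))}
            )
        if consensus_rows:
            _write_tsv(pd.DataFrame(consensus_rows), outdir / "consensus_influencers.tsv",
                       index=False)

        stage = "report"
        summary = pd.DataFrame(summary_rows)
        _write_tsv(summary, outdir / "summary.tsv", index=False)
        (outdir / "run.log").write_text(
            "\n".join(
                [f"seed={config.rng_seed}", f"params={json.dumps(asdict(params))}"]
                + dropped_log
            ) + "\n",
            encoding="utf-8",
        )
        return {
            "summary": summary_rows,
            "consensus": consensus_rows,
            "output_dir": str(outdir),
        }
    except Exception as exc:
        marker = outdir / "FAILED"
        marker.write_text(f"stage={stage}\nerror={exc}\n", encoding="utf-8")
        if isinstance(exc, (ConfigError, DataError)):
            raise
        raise PipelineError(stage, exc) from exc
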
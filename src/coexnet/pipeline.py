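"""End-to-end orchestration of the two-condition seed-coexpression study.

One :func:`run_pipeline` call either simulates or reads a pair of
expression matrices, builds both thresholded networks, scores every gene
against the seed set, calls friends and seed self-connectivity per
condition, partitions the friend sets, optionally runs over-representation
analysis on the partition lists, and writes a machine-readable manifest.
Re-running with the same configuration and inputs reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .compare import (
    compare_friend_sets,
    compare_seed_self_connectivity,
    pvalue_change_table,
    write_comparison,
)
from .enrichment import enrich, read_gmt, write_enrichment
from .errors import ConfigurationError, CoexnetError
from .expression import (
    collapse_probes,
    filter_uninformative,
    read_expression_matrix,
    read_probe_map,
    write_expression_matrix,
)
from .friends import (
    SeedSet,
    call_friends,
    read_seed_list,
    seed_self_connectivity,
    test_all_genes,
    write_friend_table,
)
from .network import build_network, write_edge_list
from .simulate import SimulationConfig, generate_paired_dataset, write_truth

__all__ = ["PipelineConfig", "load_pipeline_config", "run_pipeline"]

logger = logging.getLogger("coexnet")


@dataclass
class PipelineConfig:
    """Configuration of one full study run.

    Exactly one of {matrix_a + matrix_b, simulation} must be active.  All
    paths are resolved relative to the current working directory (or to the
    config file's directory when loaded from YAML).
    """

    output_dir: str | Path = "coexnet_run"
    matrix_a: str | Path | None = None
    matrix_b: str | Path | None = None
    probe_map: str | Path | None = None
    seed_list: str | Path | None = None
    gmt: str | Path | None = None
    label_a: str = "normal"
    label_b: str = "treated"
    threshold: float = 0.3
    method: str = "spearman"
    edge_rule: str = "signed"
    alpha: float = 1e-8
    ease: bool = True
    min_count: int = 2
    simulation: SimulationConfig | None = None
    rng_seed: int = 0

    def validate(self) -> "PipelineConfig":
        have_matrices = self.matrix_a is not None and self.matrix_b is not None
        have_sim = self.simulation is not None
        if have_matrices == have_sim:
            raise ConfigurationError(
                "exactly one of {matrix_a + matrix_b, simulation} must be provided"
            )
        if have_matrices and self.seed_list is None:
            raise ConfigurationError("seed_list is required when reading matrices")
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must be in (0, 1], got {self.threshold}")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.simulation is not None:
            self.simulation.validate()
        return self


def load_pipeline_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file.

    Top-level keys map onto :class:`PipelineConfig` fields; an optional
    nested ``simulation`` block maps onto :class:`SimulationConfig`.
    Relative paths are resolved against the config file's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys: {sorted(unknown)}")
    sim = raw.pop("simulation", None)
    if sim is not None:
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim) - sim_known
        if bad:
            raise ConfigurationError(f"{path}: unknown simulation keys: {sorted(bad)}")
        raw["simulation"] = SimulationConfig(**sim)
    cfg = PipelineConfig(**raw)
    base = path.parent
    for name in ("output_dir", "matrix_a", "matrix_b", "probe_map", "seed_list", "gmt"):
        value = getattr(cfg, name)
        if value is not None:
            setattr(cfg, name, str((base / value)))
    return cfg.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key, value in d.items():
        if isinstance(value, Path):
            d[key] = str(value)
    return d


class _Stage:
    """Context manager tagging any error with the failing stage's name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, CoexnetError):
            exc.args = (f"stage {self.name}: {exc}",)
        elif exc is None:
            logger.info("stage %s: done", self.name)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study; returns the manifest dictionary.

    Outputs written to ``config.output_dir``: per condition an edge list,
    node list, friend table and seed self-connectivity list; the friend-set
    comparison, seed self-connectivity comparison and p-value change table;
    enrichment reports for the in_both / only_a / only_b lists when a GMT
    file is supplied; ``manifest.json`` and ``run.log``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(min(logger.level or logging.INFO, logging.INFO))

    manifest: dict = {
        "config": _config_dict(config),
        "rng_seed": config.simulation.rng_seed if config.simulation else config.rng_seed,
        "inputs": {},
        "counts": {},
        "versions": _versions(),
    }
    try:
        la, lb = config.label_a, config.label_b

        with _Stage("input"):
            if config.simulation is not None:
                normal, treated, truth = generate_paired_dataset(config.simulation)
                write_expression_matrix(normal, out / f"{la}_expression.tsv")
                write_expression_matrix(treated, out / f"{lb}_expression.tsv")
                write_truth(truth, out / "truth.tsv")
                matrices = {la: normal, lb: treated}
                seed = SeedSet(truth.seed_genes, name="simulated_seed")
                manifest["counts"]["truth"] = {
                    "seed": len(truth.seed_genes),
                    "friend": len(truth.true_friends),
                    "background": len(truth.background_genes),
                    "disrupted": len(truth.disrupted_genes),
                }
            else:
                matrices = {}
                for label, p in ((la, config.matrix_a), (lb, config.matrix_b)):
                    m = read_expression_matrix(p)
                    if config.probe_map is not None:
                        m = collapse_probes(m, read_probe_map(config.probe_map))
                    matrices[label] = m
                    manifest["inputs"][str(p)] = _sha256(Path(p))
                seed = read_seed_list(config.seed_list)
                manifest["inputs"][str(config.seed_list)] = _sha256(Path(config.seed_list))
            manifest["counts"]["genes"] = {k: int(len(v)) for k, v in matrices.items()}
            manifest["counts"]["samples"] = {k: int(v.shape[1]) for k, v in matrices.items()}

        networks, results, friend_sets, self_conn = {}, {}, {}, {}
        for label in (la, lb):
            with _Stage(f"network[{label}]"):
                filtered = filter_uninformative(matrices[label])
                net = build_network(
                    filtered,
                    threshold=config.threshold,
                    method=config.method,
                    edge_rule=config.edge_rule,
                )
                write_edge_list(net, out / f"{label}_edges.tsv", out / f"{label}_nodes.txt")
                networks[label] = net
            with _Stage(f"friends[{label}]"):
                res = test_all_genes(net, seed)
                results[label] = res
                write_friend_table(res, out / f"{label}_friends.tsv")
                friend_sets[label] = call_friends(
                    res, seed=seed, alpha=config.alpha, condition_label=label
                )
                self_conn[label] = seed_self_connectivity(res, seed, alpha=config.alpha)
                with open(out / f"{label}_seed_self.txt", "w", encoding="utf-8") as fh:
                    for gene in sorted(self_conn[label]):
                        fh.write(f"{gene}\n")
                manifest["counts"].setdefault("edges", {})[label] = net.n_edges
                manifest["counts"].setdefault("friends", {})[label] = len(
                    friend_sets[label].members
                )
                manifest["counts"].setdefault("seed_self_connected", {})[label] = len(
                    self_conn[label]
                )

        with _Stage("compare"):
            comparison = compare_friend_sets(
                friend_sets[la], friend_sets[lb],
                universe_a=networks[la].universe,
                universe_b=networks[lb].universe,
            )
            write_comparison(comparison, out / "comparison.tsv")
            seed_cmp = compare_seed_self_connectivity(
                self_conn[la], self_conn[lb], seed, label_a=la, label_b=lb
            )
            write_comparison(seed_cmp, out / "seed_self_comparison.tsv")
            pvalue_change_table(results[la], results[lb]).to_csv(
                out / "pvalue_changes.tsv", sep="\t", index=False
            )
            manifest["counts"]["comparison"] = comparison.counts()
            manifest["counts"]["seed_self_comparison"] = seed_cmp.counts()

        if config.gmt is not None:
            with _Stage("enrichment"):
                annotations = read_gmt(config.gmt)
                manifest["inputs"][str(config.gmt)] = _sha256(Path(config.gmt))
                population = networks[la].universe | networks[lb].universe
                for name, genes in (
                    ("in_both", comparison.in_both),
                    (f"only_{la}", comparison.only_a),
                    (f"only_{lb}", comparison.only_b),
                ):
                    rows = enrich(
                        genes & population, population, annotations,
                        ease=config.ease, min_count=config.min_count,
                    ) if genes else []
                    write_enrichment(rows, out / f"enrichment_{name}.tsv")
                    manifest["counts"].setdefault("enriched_terms", {})[name] = len(rows)

        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _versions() -> dict:
    import networkx
    import numpy
    import pandas
    import scipy

    return {
        "coexnet": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
        "python": sys.version.split()[0],
    }
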
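"""Paired synthetic expression data with a planted, disruptable seed module.

The generator emulates the study design the pipeline is built for: a
"normal" condition (many tissues) in which a block of seed genes and their
friend genes is jointly driven by one latent factor, and a "treated"
condition (many chemical exposures) in which a configurable fraction of
those module genes has been decoupled from the factor.

Generative model, per sample: one latent factor f ~ N(0, 1); each gene g
has expression a_g * f + eps with eps ~ N(0, noise_sd^2) i.i.d.  The
loading a_g is ``loading_seed`` for seed genes, ``loading_friend`` for
friend genes, 0 for background genes, and 0 for disrupted genes in the
treated condition.  The pairwise Pearson correlation between module genes
is then available in closed form,

    corr(g, h) = a_g * a_h / sqrt((a_g^2 + s^2)(a_h^2 + s^2)),

which anchors the test suite.  Disrupted genes are the first
ceil(disruption_fraction * |module|) module genes under sorted gene-id
order (ids are assigned seeds first, then friends, then background), so the
ground truth is fully reproducible from the configuration alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataFormatError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_paired_dataset",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-condition factor-model simulation.

    Defaults mirror the scale of the motivating study: 65 normal-condition
    samples (one per tissue), 130 treated-condition samples (one per
    chemical exposure), a 56-gene seed set, 200 true friend genes, and a
    2000-gene universe that keeps all-pairs correlation cheap while leaving
    a realistic background.
    """

    n_genes: int = 2000
    n_samples_normal: int = 65
    n_samples_treated: int = 130
    seed_size: int = 56
    n_true_friends: int = 200
    loading_seed: float = 0.9
    loading_friend: float = 0.8
    noise_sd: float = 1.0
    disruption_fraction: float = 0.5
    rng_seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name in ("n_genes", "n_samples_normal", "n_samples_treated"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.seed_size < 1:
            raise ConfigurationError(f"seed_size must be >= 1, got {self.seed_size}")
        if self.n_true_friends < 0:
            raise ConfigurationError(f"n_true_friends must be >= 0, got {self.n_true_friends}")
        if self.seed_size + self.n_true_friends > self.n_genes:
            raise ConfigurationError(
                f"seed_size + n_true_friends must be <= n_genes, got"
                f" {self.seed_size} + {self.n_true_friends} > {self.n_genes}"
            )
        for name in ("loading_seed", "loading_friend"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not self.noise_sd > 0.0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.disruption_fraction <= 1.0:
            raise ConfigurationError(
                f"disruption_fraction must be in [0, 1], got {self.disruption_fraction}"
            )
        return self

    def expected_module_correlation(self, a: float, b: float) -> float:
        """Closed-form Pearson correlation between two intact module genes
        with loadings ``a`` and ``b``."""
        s2 = self.noise_sd**2
        return a * b / math.sqrt((a**2 + s2) * (b**2 + s2))


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth gene roles of a simulated pair of conditions."""

    seed_genes: frozenset
    true_friends: frozenset
    disrupted_genes: frozenset
    background_genes: frozenset

    def __post_init__(self):
        module = self.seed_genes | self.true_friends
        if self.background_genes & module:
            raise ConfigurationError("background genes overlap the seed/friend module")
        if not self.disrupted_genes <= module:
            raise ConfigurationError("disrupted genes must lie inside the module")

    @property
    def disrupted_seeds(self) -> frozenset:
        return self.disrupted_genes & self.seed_genes

    @property
    def intact_seeds(self) -> frozenset:
        return self.seed_genes - self.disrupted_genes


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_paired_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (normal_matrix, treated_matrix, truth).

    Both matrices share the same gene ids; identical configuration (which
    includes ``rng_seed``) yields bitwise-identical output.
    """
    config.validate()
    genes = _gene_ids(config.n_genes)
    seed_genes = genes[: config.seed_size]
    friend_genes = genes[config.seed_size : config.seed_size + config.n_true_friends]
    background = genes[config.seed_size + config.n_true_friends :]

    module = sorted(seed_genes + friend_genes)
    n_disrupted = math.ceil(config.disruption_fraction * len(module))
    disrupted = set(module[:n_disrupted])

    loading = {g: config.loading_seed for g in seed_genes}
    loading.update({g: config.loading_friend for g in friend_genes})
    loading.update({g: 0.0 for g in background})

    rng = np.random.default_rng(config.rng_seed)

    def draw(n_samples: int, zeroed: set) -> np.ndarray:
        a = np.array([0.0 if g in zeroed else loading[g] for g in genes])
        f = rng.standard_normal(n_samples)
        eps = rng.standard_normal((config.n_genes, n_samples)) * config.noise_sd
        return a[:, None] * f[None, :] + eps

    normal = pd.DataFrame(
        draw(config.n_samples_normal, set()),
        index=pd.Index(genes, name="gene_id"),
        columns=[f"N{i + 1:03d}" for i in range(config.n_samples_normal)],
    )
    treated = pd.DataFrame(
        draw(config.n_samples_treated, disrupted),
        index=pd.Index(genes, name="gene_id"),
        columns=[f"T{i + 1:03d}" for i in range(config.n_samples_treated)],
    )
    truth = SimulationTruth(
        seed_genes=frozenset(seed_genes),
        true_friends=frozenset(friend_genes),
        disrupted_genes=frozenset(disrupted),
        background_genes=frozenset(background),
    )
    return normal, treated, truth


def write_truth(truth: SimulationTruth, path) -> None:
    """Three-column TSV role table: gene_id, role, disrupted flag."""
    rows = (
        [(g, "seed") for g in sorted(truth.seed_genes)]
        + [(g, "friend") for g in sorted(truth.true_friends)]
        + [(g, "background") for g in sorted(truth.background_genes)]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\trole\tdisrupted\n")
        for gene, role in rows:
            fh.write(f"{gene}\t{role}\t{int(gene in truth.disrupted_genes)}\n")


def read_truth(path) -> SimulationTruth:
    """Inverse of :func:`write_truth`."""
    buckets = {"seed": set(), "friend": set(), "background": set()}
    disrupted = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "role", "disrupted"]:
            raise DataFormatError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[1] not in buckets or parts[2] not in ("0", "1"):
                raise DataFormatError(f"{path}: line {lineno}: malformed role row")
            buckets[parts[1]].add(parts[0])
            if parts[2] == "1":
                disrupted.add(parts[0])
    return SimulationTruth(
        seed_genes=frozenset(buckets["seed"]),
        true_friends=frozenset(buckets["friend"]),
        disrupted_genes=frozenset(disrupted),
        background_genes=frozenset(buckets["background"]),
    )
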
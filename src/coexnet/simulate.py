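"""Synthetic RNA-seq count matrices with planted co-expression modules.

The generator emulates the statistical structure the pipeline assumes in
real shoot/inflorescence transcriptomes: a genes × samples matrix of
overdispersed (negative-binomial) counts in which a handful of small gene
modules share a latent expression factor, background genes carry no shared
structure, samples fall into two treatment groups, and optionally one or
more samples are aberrant outliers.

Model
-----
Each background gene g has a base mean ``mu_g`` drawn log-uniformly over
``base_mean_log_range``; module genes draw from the upper half of that range,
because the co-expression modules of interest sit among robustly expressed
genes (planting them at the expression-filter boundary would conflate the
cpm filter with network recovery).  For module m and sample s a latent
log-expression factor ``f_ms = latent_sd * z_ms + o_ms`` is drawn with
``z_ms ~ N(0,1)`` and ``o_ms`` a group offset (± latent_sd * group_effect/2,
sign alternating across modules so both groups contain up- and
down-regulated modules).  A gene in module m has expected count::

    mu_gs = mu_g * exp(strength_m * f_ms)

so at the default ``latent_sd = 0.6`` a coupling strength of 2 produces
roughly e^{±2.4}-fold expression swings and within-module Spearman around 0.93
— the correlation scale the hard-threshold refinement grid presumes —
while keeping module genes inside the expressed regime.  Background genes
have constant ``mu_g``.  Counts are negative-binomial with size (shape)
parameter ``dispersion`` — variance ``mu + mu²/size``.  Outlier samples
additionally multiply every gene's mean by an independent log-normal factor
of log-scale ``outlier_shift``.

Everything is bit-reproducible from ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import CountMatrix
from .network import Network

__all__ = [
    "ModuleSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_modular_counts",
    "inject_outlier",
    "generate_benchmark_graph",
]


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expressed module: ``size`` genes sharing one latent
    factor with coupling ``strength`` (0 = no shared structure)."""

    size: int
    strength: float = 2.0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if self.strength < 0:
            raise ValueError("module strength must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: ~12k expressed genes over 12 shoot + 5
    inflorescence samples, four modules at the vicinity-network scale
    (10–36 genes), moderately overdispersed counts."""

    n_genes: int = 12000
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"shoot": 12, "inflorescence": 5}
    )
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(36), ModuleSpec(12), ModuleSpec(10), ModuleSpec(34)
    )
    dispersion: float = 10.0  # negative-binomial size (shape); var = mu + mu^2/size
    base_mean_log_range: tuple[float, float] = (3.0, 6.0)  # ln of base mean counts
    latent_sd: float = 0.6  # log-sd of the per-module latent factor
    group_effect: float = 2.0  # group offset between groups, in latent-sd units
    outlier_samples: int = 0
    outlier_shift: float = 2.0  # log-normal sigma of the aberrant-sample factors
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.n_samples_per_group:
            raise ValueError("need at least one sample group")
        if any(n < 1 for n in self.n_samples_per_group.values()):
            raise ValueError("each group needs >= 1 sample")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB size) must be > 0")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be > 0")
        lo, hi = self.base_mean_log_range
        if hi < lo:
            raise ValueError("base_mean_log_range must be (low, high)")
        if self.outlier_samples < 0:
            raise ValueError("outlier_samples must be >= 0")
        n_samples = sum(self.n_samples_per_group.values())
        if self.outlier_samples > n_samples:
            raise ValueError("more outlier samples than samples")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for recovery testing: which gene sits in which module,
    the sample groups, and which samples were made aberrant."""

    module_assignment: Mapping[str, int | None]  # gene -> module index or None
    sample_groups: Mapping[str, str]
    outlier_ids: tuple[str, ...]
    config: SyntheticConfig

    def module_members(self, module: int) -> list[str]:
        return [g for g, m in self.module_assignment.items() if m == module]

    def background_genes(self) -> list[str]:
        return [g for g, m in self.module_assignment.items() if m is None]

    def to_json(self) -> str:
        cfg = asdict(self.config)
        cfg["n_samples_per_group"] = dict(self.config.n_samples_per_group)
        cfg["modules"] = [asdict(m) for m in self.config.modules]
        return json.dumps(
            {
                "module_assignment": {g: m for g, m in self.module_assignment.items()},
                "sample_groups": dict(self.sample_groups),
                "outlier_ids": list(self.outlier_ids),
                "config": cfg,
            },
            indent=2,
            sort_keys=True,
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draw parameterised by mean and size (shape)."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_modular_counts(
    cfg: SyntheticConfig | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix with planted modules; returns (matrix, truth)."""
    if cfg is None:
        cfg = SyntheticConfig()
    rng = np.random.default_rng(cfg.rng_seed)

    n_digits = max(4, len(str(cfg.n_genes)))
    gene_ids = [f"g{i + 1:0{n_digits}d}" for i in range(cfg.n_genes)]
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for grp in sorted(cfg.n_samples_per_group):
        for r in range(cfg.n_samples_per_group[grp]):
            sid = f"{grp.capitalize()}_{r + 1}"
            sample_ids.append(sid)
            groups[sid] = grp
    n_samples = len(sample_ids)
    group_labels = sorted(set(groups.values()))
    group_sign = {grp: (1.0 if i == 0 else -1.0)
                  for i, grp in enumerate(group_labels)}

    lo, hi = cfg.base_mean_log_range
    mu = np.exp(rng.uniform(lo, hi, size=cfg.n_genes))

    # scatter module genes over the universe (seeded, disjoint); module genes
    # redraw their base mean from the upper half of the range so planted
    # structure stays inside the expressed (post-filter) regime
    module_gene_idx: list[np.ndarray] = []
    pool = rng.permutation(cfg.n_genes)
    offset = 0
    for mod in cfg.modules:
        idx = np.sort(pool[offset:offset + mod.size])
        module_gene_idx.append(idx)
        mu[idx] = np.exp(rng.uniform((lo + hi) / 2.0, hi, size=mod.size))
        offset += mod.size

    mean_matrix = np.tile(mu[:, None], (1, n_samples))
    for m_idx, (mod, idx) in enumerate(zip(cfg.modules, module_gene_idx)):
        z = rng.normal(size=n_samples)
        # group offset alternates sign across modules so either group holds
        # both up- and down-shifted modules
        mod_sign = 1.0 if m_idx % 2 == 0 else -1.0
        offsets = np.array([
            mod_sign * group_sign[groups[s]] * cfg.group_effect / 2.0
            for s in sample_ids
        ])
        f = cfg.latent_sd * (z + offsets)
        mean_matrix[idx, :] *= np.exp(mod.strength * f)[None, :]

    outlier_ids: tuple[str, ...] = ()
    if cfg.outlier_samples:
        chosen = rng.choice(n_samples, size=cfg.outlier_samples, replace=False)
        outlier_ids = tuple(sample_ids[i] for i in sorted(chosen))
        for i in sorted(chosen):
            factors = np.exp(cfg.outlier_shift * rng.normal(size=cfg.n_genes))
            mean_matrix[:, i] *= factors

    counts = _nb_draw(rng, mean_matrix, cfg.dispersion)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        groups,
    )
    assignment: dict[str, int | None] = {g: None for g in gene_ids}
    for m_idx, idx in enumerate(module_gene_idx):
        for i in idx:
            assignment[gene_ids[i]] = m_idx
    truth = SyntheticTruth(assignment, groups, outlier_ids, cfg)
    return cm, truth


def inject_outlier(
    cm: CountMatrix,
    sample: str,
    shift: float,
    rng_seed: int,
) -> CountMatrix:
    """Make one sample aberrant by perturbing its gene means.

    The sample's observed counts are taken as plug-in means, multiplied by
    independent gene-wise log-normal factors of log-scale ``shift``, and
    counts are re-drawn (Poisson around the shifted means).  ``shift = 0``
    leaves the distribution unchanged up to resampling noise.
    """
    if sample not in cm.sample_ids:
        raise KeyError(f"unknown sample: {sample!r}")
    if shift < 0:
        raise ValueError("shift must be >= 0")
    rng = np.random.default_rng(rng_seed)
    counts = cm.counts.copy()
    factors = np.exp(shift * rng.normal(size=counts.shape[0]))
    shifted = counts[sample].to_numpy(dtype=float) * factors
    new_col = rng.poisson(shifted)
    if new_col.sum() == 0:  # keep the column-sum invariant intact
        new_col[int(np.argmax(shifted))] = 1
    counts[sample] = new_col
    return CountMatrix(counts, dict(cm.groups))


def generate_benchmark_graph(
    kind: str,
    params: Mapping[str, int | float] | None = None,
    rng_seed: int = 0,
) -> Network:
    """Benchmark graphs for topology-metric tests.

    ``kind`` is one of ``preferential_attachment`` (params ``n``, ``m``),
    ``erdos_renyi`` (``n`` plus ``m`` edges or ``p``), ``star`` (``n_leaves``),
    ``clique``/``path``/``cycle`` (``n``).  Random kinds are deterministic
    given ``rng_seed``; the deterministic fixtures carry closed-form metric
    values (e.g. the clique K_n has meanCC = meanPath = density = 1).
    """
    params = dict(params or {})
    if kind == "preferential_attachment":
        g = nx.barabasi_albert_graph(int(params["n"]), int(params.get("m", 2)),
                                     seed=int(rng_seed))
    elif kind == "erdos_renyi":
        n = int(params["n"])
        if "m" in params:
            g = nx.gnm_random_graph(n, int(params["m"]), seed=int(rng_seed))
        else:
            g = nx.gnp_random_graph(n, float(params["p"]), seed=int(rng_seed))
    elif kind == "star":
        g = nx.star_graph(int(params.get("n_leaves", params.get("n", 9))))
    elif kind == "clique":
        g = nx.complete_graph(int(params["n"]))
    elif kind == "path":
        g = nx.path_graph(int(params["n"]))
    elif kind == "cycle":
        g = nx.cycle_graph(int(params["n"]))
    else:
        raise ValueError(f"unknown benchmark graph kind: {kind!r}")
    g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
    universe = tuple(sorted(g.nodes, key=lambda s: int(s[1:])))
    return Network(g, universe, threshold=None)
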
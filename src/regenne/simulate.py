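"""Synthetic pathway-structured expression data.

The generator emulates the three features of real pathway/expression data
the model exploits: blocks of within-pathway correlated genes (one latent
factor per pathway), genes shared between pathway pairs (chain topology by
default: consecutive pathways share a fixed fraction of genes, which makes
their factors' footprints overlap), and a binary outcome driven by a small
set of causal pathways through a logistic model on their mean expression.

Gene values are built as
    x = sqrt(w) * (sum of owning pathways' factors) / sqrt(#owners)
        + sqrt(1 - w) * idiosyncratic noise
with standard-normal factors and noise, so every gene is marginally
standard normal and two genes of one pathway correlate ~ w (the
``within_corr`` target).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from .containers import ExpressionMatrix, PathwayCollection, PhenotypeTable
from .io import write_expression, write_gmt, write_phenotype


@dataclass
class SimConfig:
    n_samples: int = 200
    n_pathways: int = 8
    genes_per_pathway: int = 10
    overlap_frac: float = 0.3
    within_corr: float = 0.5
    causal_pathways: tuple[int, ...] = (0,)
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    random_overlap: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in [0, 1)")
        if not 0 <= self.within_corr < 1:
            raise ValueError("within_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        bad = [i for i in self.causal_pathways if not 0 <= i < self.n_pathways]
        if bad:
            raise ValueError(f"causal pathway indices out of range: {bad}")


def simulate_pathway_collection(cfg: SimConfig) -> PathwayCollection:
    """Gene sets with chain-structured overlap: consecutive pathways share
    ceil(overlap_frac * genes_per_pathway) genes."""
    rng = np.random.default_rng(cfg.seed)
    n_shared = int(np.ceil(cfg.overlap_frac * cfg.genes_per_pathway))
    coll = PathwayCollection()
    counter = 0

    def fresh(k: int) -> list[str]:
        nonlocal counter
        out = [f"G{counter + i:05d}" for i in range(k)]
        counter += k
        return out

    prev: list[str] = []
    for p in range(cfg.n_pathways):
        if p == 0 or n_shared == 0:
            genes = fresh(cfg.genes_per_pathway)
        else:
            if cfg.random_overlap:
                shared = list(rng.choice(prev, size=n_shared, replace=False))
            else:
                shared = prev[-n_shared:]
            genes = shared + fresh(cfg.genes_per_pathway - n_shared)
        coll.add(f"PW{p:03d}", f"synthetic pathway {p}", genes)
        prev = genes
    return coll


def simulate_expression(collection: PathwayCollection, cfg: SimConfig) -> ExpressionMatrix:
    """Latent-factor expression for every gene in the collection; shared
    genes load on all of their owning pathways' factors (normalized)."""
    rng = np.random.default_rng(cfg.seed + 1)
    names = collection.names
    genes = collection.all_genes()
    owners: dict[str, list[int]] = {g: [] for g in genes}
    for p, name in enumerate(names):
        for g in collection.genes(name):
            owners[g].append(p)
    factors = rng.standard_normal((cfg.n_samples, len(names)))
    noise = rng.standard_normal((cfg.n_samples, len(genes)))
    w = cfg.within_corr
    values = np.empty((cfg.n_samples, len(genes)))
    for j, g in enumerate(genes):
        own = owners[g]
        signal = factors[:, own].sum(axis=1) / np.sqrt(len(own))
        values[:, j] = np.sqrt(w) * signal + np.sqrt(1.0 - w) * noise[:, j]
    sample_ids = [f"S{i:05d}" for i in range(cfg.n_samples)]
    return ExpressionMatrix(sample_ids, genes, values)


def simulate_outcome(
    expr: ExpressionMatrix, collection: PathwayCollection, cfg: SimConfig
) -> PhenotypeTable:
    """Binary labels from a logistic model on the causal pathways' mean
    expression: lp = effect_size * sum_c mean(expr[pathway c]) + noise,
    y ~ Bernoulli(expit(lp))."""
    gene_idx = expr.gene_index()
    names = collection.names
    lp = np.zeros(expr.n_samples)
    for c in cfg.causal_pathways:
        cols = [gene_idx[g] for g in collection.genes(names[c])]
        lp += expr.values[:, cols].mean(axis=1)
    lp *= cfg.effect_size
    rng = np.random.default_rng(cfg.seed + 2)
    for attempt in range(10):
        noisy = lp + cfg.noise_sd * rng.standard_normal(expr.n_samples)
        y = (rng.random(expr.n_samples) < expit(noisy)).astype(int)
        if 0 < y.sum() < len(y):
            if attempt:
                warnings.warn(
                    f"single-class outcome draw; redrew {attempt} time(s)",
                    RuntimeWarning,
                )
            return PhenotypeTable(dict(zip(expr.sample_ids, (int(v) for v in y))))
    raise RuntimeError("could not draw a two-class outcome in 10 attempts")


def true_linear_predictor(
    expr: ExpressionMatrix, collection: PathwayCollection, cfg: SimConfig
) -> np.ndarray:
    """The noiseless oracle predictor the labels were generated from."""
    gene_idx = expr.gene_index()
    names = collection.names
    lp = np.zeros(expr.n_samples)
    for c in cfg.causal_pathways:
        cols = [gene_idx[g] for g in collection.genes(names[c])]
        lp += expr.values[:, cols].mean(axis=1)
    return cfg.effect_size * lp


PRESETS: dict[str, SimConfig] = {
    "small": SimConfig(
        n_samples=200,
        n_pathways=8,
        genes_per_pathway=10,
        overlap_frac=0.5,
        within_corr=0.5,
        causal_pathways=(0,),
        effect_size=3.0,
        noise_sd=1.0,
    ),
    "medium": SimConfig(
        n_samples=500,
        n_pathways=20,
        genes_per_pathway=15,
        overlap_frac=1.0 / 3.0,
        within_corr=0.5,
        causal_pathways=(0, 7, 14),
        effect_size=3.0,
        noise_sd=1.0,
    ),
}


def preset_config(name: str, seed: int = 0) -> SimConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return SimConfig(**{**asdict(cfg), "seed": seed,
                        "causal_pathways": tuple(cfg.causal_pathways)})


@dataclass
class SimBundle:
    expression: ExpressionMatrix
    pathways: PathwayCollection
    phenotype: PhenotypeTable
    config: SimConfig
    causal_names: list[str] = field(default_factory=list)


def simulate_bundle(cfg: SimConfig) -> SimBundle:
    coll = simulate_pathway_collection(cfg)
    expr = simulate_expression(coll, cfg)
    pheno = simulate_outcome(expr, coll, cfg)
    names = coll.names
    return SimBundle(
        expression=expr,
        pathways=coll,
        phenotype=pheno,
        config=cfg,
        causal_names=[names[c] for c in cfg.causal_pathways],
    )


def make_fixture(name: str, seed: int, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a named preset bundle (expression TSV, GMT, phenotype TSV and
    a truth JSON listing the causal pathways) and return the paths.
    Deterministic: the same name and seed reproduce byte-identical files."""
    bundle = simulate_bundle(preset_config(name, seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "gmt": str(out / "pathways.gmt"),
        "phenotype": str(out / "phenotype.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_expression(bundle.expression, paths["expression"])
    write_gmt(bundle.pathways, paths["gmt"])
    write_phenotype(bundle.phenotype, paths["phenotype"])
    cfg_dict = asdict(bundle.config)
    cfg_dict["causal_pathways"] = list(cfg_dict["causal_pathways"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"preset": name, "causal_pathways": bundle.causal_names, "config": cfg_dict},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
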
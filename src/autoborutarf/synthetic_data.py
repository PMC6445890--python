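"""Seeded generator of drug-response datasets with planted signal.

The generator emulates the structure of cell-line pharmacogenomic panels:
a few hundred cell lines, real-valued expression and copy-number matrices,
a binary mutation matrix, and a per-drug IC50 response driven by a small
planted subset of features.  Expression/CNA features come in tight
correlated blocks (so the correlation-pruning step has real work) on top of
independent Gaussian noise columns; mutations are Bernoulli with moderate
prevalence.  Missing values appear completely at random in IC50, CNA and
SNV — never in expression.  Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import FeatureMatrix, ResponseTable
from .labeling import LabelVector
from .core_io import NON_SENSITIVE, SENSITIVE


@dataclass
class SyntheticConfig:
    n_cells: int = 200
    n_expression: int = 300
    n_cna: int = 300
    n_snv: int = 100
    n_informative: int = 5  # per kind
    effect_size: float = 1.0  # per informative feature, units of noise sd
    noise_sd: float = 1.0
    block_size: int = 3  # 1 disables correlated blocks
    block_corr: float = 0.98
    n_noise_blocks: int = 3  # extra correlated blocks without signal, per kind
    snv_prevalence: tuple = (0.05, 0.4)
    missing_rate_ic50: float = 0.1
    missing_rate_cna: float = 0.1
    missing_rate_snv: float = 0.1
    drug: str = "drug_0"
    seed: int = 1

    def __post_init__(self) -> None:
        for kind, n in (("expression", self.n_expression), ("cna", self.n_cna),
                        ("snv", self.n_snv)):
            if n > 0 and self.n_informative > n:
                raise ValueError(f"n_informative exceeds n_{kind}")
        for r in (self.missing_rate_ic50, self.missing_rate_cna,
                  self.missing_rate_snv):
            if not 0 <= r < 1:
                raise ValueError("missing rates must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.n_expression <= 0:
            raise ValueError("expression features are required (distances)")
        if not 0 <= self.block_corr < 1:
            raise ValueError("block_corr must be in [0, 1)")


@dataclass
class GroundTruth:
    informative: dict  # kind -> list of feature ids
    coefficients: dict  # feature id -> generating coefficient
    seed: int

    @property
    def all_informative(self) -> list[str]:
        return [f for ids in self.informative.values() for f in ids]


@dataclass
class SyntheticDataset:
    features: dict  # kind -> FeatureMatrix
    response: ResponseTable
    truth: GroundTruth
    config: SyntheticConfig


def boruta_benchmark_config(seed: int = 1) -> SyntheticConfig:
    """One complete 50-feature kind (5 informative + 45 independent noise),
    200 cells, no missingness: the canonical selection benchmark."""
    return SyntheticConfig(n_cells=200, n_expression=50, n_cna=0, n_snv=0,
                           n_informative=5, block_size=1, n_noise_blocks=0,
                           missing_rate_ic50=0.0, missing_rate_cna=0.0,
                           missing_rate_snv=0.0, seed=seed)


def _real_kind(rng: np.random.Generator, n: int, p: int, n_informative: int,
               block_size: int, block_corr: float, n_noise_blocks: int,
               prefix: str):
    """Block-correlated Gaussian features; informative ones head the blocks."""
    X = rng.standard_normal((n, p))
    if block_size > 1:
        # informative features head correlated blocks while space allows;
        # any overflow informative features stay unblocked
        info_blocks = min(n_informative,
                          max(0, (p - n_informative) // (block_size - 1)))
        extra_info = n_informative - info_blocks
        used = info_blocks * block_size + extra_info
        noise_blocks = min(n_noise_blocks, max(0, (p - used) // block_size))
        a = np.sqrt(block_corr)
        b = np.sqrt(1.0 - block_corr)
        starts = [blk * block_size for blk in range(info_blocks)]
        starts += [info_blocks * block_size + extra_info + blk * block_size
                   for blk in range(noise_blocks)]
        for s in starts:
            factor = rng.standard_normal(n)
            for j in range(s, s + block_size):
                X[:, j] = a * factor + b * rng.standard_normal(n)
        informative_idx = [blk * block_size for blk in range(info_blocks)]
        informative_idx += list(range(info_blocks * block_size,
                                      info_blocks * block_size + extra_info))
    else:
        informative_idx = list(range(n_informative))
    ids = [f"{prefix}{j}" for j in range(p)]
    return X, ids, [ids[j] for j in informative_idx]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; the returned ground truth lists the planted signal."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    cells = [f"cell_{i}" for i in range(n)]

    blocks = {}
    informative: dict[str, list[str]] = {}
    signal_cols: list[np.ndarray] = []
    coefficients: dict[str, float] = {}

    for kind, p, prefix in (("expression", config.n_expression, "EXPR_"),
                            ("cna", config.n_cna, "CNA_")):
        if p == 0:
            informative[kind] = []
            continue
        X, ids, info_ids = _real_kind(
            rng, n, p, config.n_informative, config.block_size,
            config.block_corr, config.n_noise_blocks, prefix)
        blocks[kind] = pd.DataFrame(X, index=cells, columns=ids)
        informative[kind] = info_ids
        for f in info_ids:
            col = blocks[kind][f].to_numpy()
            signal_cols.append((col - col.mean()) / col.std())
            coefficients[f] = config.effect_size

    if config.n_snv > 0:
        prev = rng.uniform(*config.snv_prevalence, size=config.n_snv)
        S = (rng.random((n, config.n_snv)) < prev).astype(float)
        ids = [f"SNV_{j}" for j in range(config.n_snv)]
        blocks["snv"] = pd.DataFrame(S, index=cells, columns=ids)
        informative["snv"] = ids[: config.n_informative]
        for f in informative["snv"]:
            col = blocks["snv"][f].to_numpy()
            sd = col.std()
            if sd == 0:  # fully absent mutation carries no signal
                continue
            signal_cols.append((col - col.mean()) / sd)
            coefficients[f] = config.effect_size
    else:
        informative["snv"] = []

    latent = np.zeros(n)
    for col in signal_cols:
        latent += config.effect_size * col
    ic50 = latent + rng.normal(0.0, config.noise_sd, size=n)

    # inject MCAR missingness (never in expression)
    if "cna" in blocks and config.missing_rate_cna > 0:
        mask = rng.random(blocks["cna"].shape) < config.missing_rate_cna
        blocks["cna"] = blocks["cna"].mask(mask)
    if "snv" in blocks and config.missing_rate_snv > 0:
        mask = rng.random(blocks["snv"].shape) < config.missing_rate_snv
        blocks["snv"] = blocks["snv"].mask(mask)
    ic50_obs = ic50.copy()
    if config.missing_rate_ic50 > 0:
        mask = rng.random(n) < config.missing_rate_ic50
        ic50_obs[mask] = np.nan

    features = {kind: FeatureMatrix(df, kind) for kind, df in blocks.items()}
    response = ResponseTable(
        pd.DataFrame([ic50_obs], index=[config.drug], columns=cells))
    truth = GroundTruth(informative=informative, coefficients=coefficients,
                        seed=config.seed)
    return SyntheticDataset(features=features, response=response, truth=truth,
                            config=config)


def labels_at_threshold(response: ResponseTable, drug: str,
                        threshold: float) -> LabelVector:
    """Labels from a fixed external IC50 cutoff instead of the median."""
    ic50 = response.drug_vector(drug)
    if ic50.isna().any():
        raise ValueError("IC50 vector must be complete")
    labels = [SENSITIVE if v < threshold else NON_SENSITIVE
              for v in ic50.to_numpy()]
    return LabelVector(drug=drug, cell_line_ids=list(ic50.index),
                       labels=labels, threshold=threshold)


def make_imbalanced(dataset: SyntheticDataset,
                    target_fraction: float) -> SyntheticDataset:
    """Shift the IC50 offset so ~``target_fraction`` of cells are
    non-sensitive against the fixed external threshold 0.

    Only sensible for majority non-sensitive scenarios, so the target must
    exceed 1/2.  Labels for the shifted dataset come from
    ``labels_at_threshold(..., threshold=0.0)``.
    """
    if not 0.5 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0.5, 1)")
    ic50 = dataset.response.ic50.copy()
    vals = ic50.to_numpy()
    obs = vals[~np.isnan(vals)]
    if len(obs) < 2:
        raise ValueError("not enough observed IC50 values")
    n_non = int(round(target_fraction * len(obs)))
    if n_non in (0, len(obs)):
        raise ValueError("target fraction unattainable at this sample size")
    # place cutoff between order statistics so exactly n_non cells sit at or
    # above the external threshold 0 after shifting
    srt = np.sort(obs)
    shift = (srt[-n_non] + srt[-n_non - 1]) / 2 if n_non < len(obs) else srt[0]
    shifted = ResponseTable(ic50 - shift)
    return SyntheticDataset(features=dataset.features, response=shifted,
                            truth=dataset.truth, config=dataset.config)
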
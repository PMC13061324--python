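"""Synthetic matched RNA-seq count / copy-number datasets with ground truth.

The generator emulates a tumor-vs-normal bulk RNA-seq experiment over genes
belonging to four dosage classes.  Per gene, a baseline mean mu0 is drawn
from a log-normal, a dispersion from the trend a0 + a1/mu0 with log-normal
jitter, and the tumor mean is shaped by the class mechanism:

    nonDEG  tumor mean mu0, tumor CN 2
    DIG     tumor mean mu0 * 2^beta (beta ~ +-Uniform(lfc_range)), CN 2
    DSG     tumor mean mu0 * CN/2 per sample (pure dosage), beta = 0
    DCG     tumor CN altered but expression buffered: tumor mean
            mu0 * (CN/2)^(1-buffering); full buffering keeps the mean at mu0,
            so the CN-aware model sees a regulation of -log2(CN/2)

Counts are NB draws around the class mean times a log-normal library-depth
factor; normal samples are diploid (CN = 2) throughout.  The CN-noise
injector perturbs a fixed fraction of CN entries with weighted discrete
additive noise, mimicking CN-calling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import DesignSpec

CLASS_ORDER = ("DSG", "DIG", "DCG", "nonDEG")

#: additive CN error values and their weights (moderate errors dominate)
CN_NOISE_VALUES = np.array([-2, -1, 0, 1, 2], dtype=float)
CN_NOISE_WEIGHTS = np.array([0.05, 0.30, 0.30, 0.30, 0.05])


@dataclass
class SimConfig:
    """Study conditions of the simulation benchmark."""

    n_genes: int = 5000
    n_per_condition: int = 10
    class_proportions: dict = field(
        default_factory=lambda: {"DSG": 0.10, "DIG": 0.40, "DCG": 0.0, "nonDEG": 0.50}
    )
    cn_signal: str = "strong"          # 'strong' (CN 4-5 / 1) or 'weak' (CN 3-4 / 1)
    lfc_range: tuple = (1.2, 3.0)      # |log2FC| of DIG regulation
    mean_log_mu: float = 5.0           # log-normal baseline mean (natural log)
    sd_log_mu: float = 1.5
    disp_a0: float = 0.05              # dispersion trend asymptote
    disp_a1: float = 5.0               # dispersion trend 1/mu coefficient
    disp_jitter_sd: float = 0.3        # log-normal jitter around the trend
    gain_fraction: float = 0.8         # gains vs losses among CN-altered genes
    weak_altered_fraction: float = 1.0 # tumor samples carrying the weak CN event
    buffering: float = 1.0             # DCG buffering (1 = full compensation)
    depth_sd: float = 0.15             # log-normal library-size spread
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASS_ORDER)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.n_genes <= 0 or self.n_per_condition < 2:
            raise ValueError("need n_genes > 0 and n_per_condition >= 2")
        if self.cn_signal not in ("strong", "weak"):
            raise ValueError("cn_signal must be 'strong' or 'weak'")


@dataclass
class SimulatedDataset:
    """Counts + CN + design + per-gene ground truth."""

    counts: pd.DataFrame
    cn: pd.DataFrame
    design: DesignSpec
    truth: pd.DataFrame   # columns: class, true_lfc, tumor_cn_mean

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer class counts matching proportions exactly (largest remainder)."""
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _tumor_cn_profiles(
    n_genes: int, n_tumor: int, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Tumor CN matrix for CN-altered genes under the configured signal."""
    gains = rng.random(n_genes) < cfg.gain_fraction
    if cfg.cn_signal == "strong":
        value = np.where(gains, rng.choice([4.0, 5.0], size=n_genes), 1.0)
    else:
        # weak signal: smaller-magnitude gains whose dosage effect straddles
        # the |log2FC| > 1 calling threshold
        value = np.where(gains, rng.choice([3.0, 4.0], size=n_genes), 1.0)
    if cfg.weak_altered_fraction >= 1.0 or cfg.cn_signal == "strong":
        return np.repeat(value[:, None], n_tumor, axis=1)
    carrier = rng.random((n_genes, n_tumor)) < cfg.weak_altered_fraction
    return np.where(carrier, value[:, None], 2.0)


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Draw one matched counts/CN/design dataset with ground-truth labels."""
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    G, n = cfg.n_genes, cfg.n_per_condition

    props = np.array([cfg.class_proportions.get(c, 0.0) for c in CLASS_ORDER])
    counts_per_class = _largest_remainder(props, G)
    labels = np.repeat(np.array(CLASS_ORDER, dtype=object), counts_per_class)
    labels = labels[rng.permutation(G)]

    mu0 = rng.lognormal(cfg.mean_log_mu, cfg.sd_log_mu, size=G)
    alpha = (cfg.disp_a0 + cfg.disp_a1 / mu0) * rng.lognormal(
        0.0, cfg.disp_jitter_sd, size=G
    )

    tumor_cn = np.full((G, n), 2.0)
    altered = (labels == "DSG") | (labels == "DCG")
    if altered.any():
        tumor_cn[altered] = _tumor_cn_profiles(int(altered.sum()), n, cfg, rng)

    beta = np.zeros(G)
    dig = labels == "DIG"
    lo, hi = cfg.lfc_range
    beta[dig] = rng.uniform(lo, hi, size=int(dig.sum())) * rng.choice(
        [-1.0, 1.0], size=int(dig.sum())
    )

    dosage_exponent = np.zeros(G)
    dosage_exponent[labels == "DSG"] = 1.0
    dosage_exponent[labels == "DCG"] = 1.0 - cfg.buffering

    normal_mean = np.repeat(mu0[:, None], n, axis=1)
    tumor_mean = (
        mu0[:, None] * (tumor_cn / 2.0) ** dosage_exponent[:, None]
        * 2.0 ** beta[:, None]
    )

    depth = rng.lognormal(0.0, cfg.depth_sd, size=2 * n)
    mean = np.concatenate([normal_mean, tumor_mean], axis=1) * depth[None, :]

    r = 1.0 / alpha[:, None]
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(np.int64)

    sample_ids = [f"normal_{i + 1:03d}" for i in range(n)] + [
        f"tumor_{i + 1:03d}" for i in range(n)
    ]
    gene_ids = [f"gene_{i + 1:05d}" for i in range(G)]

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    cn_full = np.concatenate([np.full((G, n), 2.0), tumor_cn], axis=1)
    cn_df = pd.DataFrame(cn_full, index=gene_ids, columns=sample_ids)
    design = DesignSpec(
        pd.DataFrame(
            {"condition": [0] * n + [1] * n},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # biological (regulatory) effect: what the CN-aware model should recover
    true_lfc = beta.copy()
    dcg = labels == "DCG"
    true_lfc[dcg] = -cfg.buffering * np.log2(tumor_cn[dcg] / 2.0).mean(axis=1)
    truth = pd.DataFrame(
        {
            "class": labels,
            "true_lfc": true_lfc,
            "tumor_cn_mean": tumor_cn.mean(axis=1),
            "baseline_mean": mu0,
            "dispersion": alpha,
        },
        index=gene_ids,
    )
    return SimulatedDataset(counts=counts_df, cn=cn_df, design=design, truth=truth)


def inject_cn_noise(
    cn: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Perturb round(fraction * size) CN entries with weighted discrete noise.

    Entries are chosen uniformly without replacement; each receives an
    additive value from {-2, -1, 0, 1, 2} with weights 5/30/30/30/5 percent,
    and the result is floored at 0.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = cn.to_numpy(dtype=float).copy()
    n_entries = int(round(fraction * values.size))
    if n_entries == 0:
        return cn.copy()
    flat = rng.choice(values.size, size=n_entries, replace=False)
    noise = rng.choice(CN_NOISE_VALUES, size=n_entries, p=CN_NOISE_WEIGHTS)
    values.flat[flat] = np.maximum(values.flat[flat] + noise, 0.0)
    return pd.DataFrame(values, index=cn.index, columns=cn.columns)


def replicate_grid(
    config: SimConfig,
    sample_sizes: list[int],
    n_replicates: int,
    master_seed: int = 0,
):
    """Lazily yield (sample_size, replicate, dataset) over a simulation grid.

    Replicate streams are derived from the master seed via SeedSequence
    spawning, so they are deterministic and pairwise independent.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(sample_sizes) * n_replicates)
    k = 0
    for n in sample_sizes:
        for rep in range(n_replicates):
            rng = np.random.default_rng(children[k])
            k += 1
            yield n, rep, simulate_dataset(
                replace(config, n_per_condition=n), rng=rng
            )
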
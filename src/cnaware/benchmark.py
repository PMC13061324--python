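"""Benchmark harness: confusion metrics, effect-size accuracy, robustness.

DE detection is scored against the simulator's ground truth with DIGs as
true positives and DSGs / non-DEGs as true negatives (DCGs, which are true
positives only for a CN-aware analysis, are scored in a separate
classification task).  Metrics are the standard confusion summaries

    precision = TP/(TP+FP)          recall = TP/(TP+FN)
    F1 = 2 PR / (P + R)             MCC = (TP*TN - FP*FN) / sqrt(prod margins)

plus MSE / squared Pearson correlation of estimated vs true log2FC, and the
Jaccard index |A&B| / |A|B| for class-membership stability under CN noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .glm import GLMConfig
from .pipeline import AnalysisResult, analyze
from .simulate import SimConfig, inject_cn_noise, replicate_grid

DEFAULT_SAMPLE_SIZES = (10, 20, 40, 60)
DEFAULT_NOISE_GRID = (0.05, 0.10, 0.15, 0.20)

#: class mix used when the DCG classification task is benchmarked
CLASSIFICATION_PROPORTIONS = {"DSG": 0.15, "DIG": 0.25, "DCG": 0.15, "nonDEG": 0.45}


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_truth(
    truth,
    predicted,
    scheme: str = "de_detection",
    positive: str = "DCG",
    negative: str = "DSG",
) -> ConfusionCounts:
    """Confusion counts against ground-truth classes.

    ``de_detection``: ``predicted`` are DE bits; true positives are DIGs,
    true negatives DSGs and non-DEGs; DCGs are excluded.  ``class_vs_class``:
    ``predicted`` are class labels; the count is restricted to genes whose
    truth is ``positive`` or ``negative`` and a prediction counts as positive
    when it equals the ``positive`` class.
    """
    truth = np.asarray(truth, dtype=object)
    known = {"DSG", "DIG", "DCG", "nonDEG"}
    bad = set(np.unique(truth)) - known
    if bad:
        raise ValueError(f"unknown truth label(s): {sorted(bad)}")
    if scheme == "de_detection":
        pred = np.asarray(predicted).astype(bool)
        mask = np.isin(truth, ["DIG", "DSG", "nonDEG"])
        pos = truth == "DIG"
    elif scheme == "class_vs_class":
        labels = np.asarray(predicted, dtype=object)
        mask = np.isin(truth, [positive, negative])
        pred = labels == positive
        pos = truth == positive
    else:
        raise ValueError("scheme must be 'de_detection' or 'class_vs_class'")
    pred, pos = pred[mask], pos[mask]
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def metrics(counts: ConfusionCounts) -> dict:
    """Precision, recall, F1 and MCC; undefined ratios are NaN."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = tp / (tp + fp) if tp + fp else np.nan
    recall = tp / (tp + fn) if tp + fn else np.nan
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = np.nan
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    denom = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else np.nan
    return {"precision": precision, "recall": recall, "f1": f1, "mcc": mcc}


def lfc_accuracy(true_lfc, estimated_lfc) -> dict:
    """MSE, Pearson r and squared Pearson correlation of log2FC estimates."""
    t = np.asarray(true_lfc, dtype=float)
    e = np.asarray(estimated_lfc, dtype=float)
    ok = np.isfinite(t) & np.isfinite(e)
    t, e = t[ok], e[ok]
    if t.size < 3:
        raise ValueError("need at least 3 paired log2FC values")
    mse = float(np.mean((e - t) ** 2))
    if np.std(t) == 0 or np.std(e) == 0:
        return {"mse": mse, "pearson_r": np.nan, "pearson_r2": np.nan}
    r = float(pearsonr(t, e).statistic)
    return {"mse": mse, "pearson_r": r, "pearson_r2": r * r}


def jaccard(set_a, set_b) -> float:
    """|A & B| / |A | B|; two empty sets are identical (1.0)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# benchmark drivers

def _evaluate_dataset(result: AnalysisResult, truth: pd.DataFrame) -> list[dict]:
    """Per-method DE detection and effect-size metrics for one dataset."""
    truth = truth.loc[result.table.index]
    rows = []
    for method, bits, lfc in (
        ("aware", result.table["de_aware"], result.table["lfc_aware"]),
        ("naive", result.table["de_naive"], result.table["lfc_naive"]),
    ):
        m = metrics(confusion_from_truth(truth["class"], bits, "de_detection"))
        m.update(lfc_accuracy(truth["true_lfc"], lfc))
        # the naive model is not expected to recover regulatory effects of
        # CN-altered genes; its accuracy is still scored on the same truth
        rows.append({"method": method, **m})
    return rows


def de_benchmark(
    base_config: SimConfig | None = None,
    sample_sizes=DEFAULT_SAMPLE_SIZES,
    n_replicates: int = 5,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    mt_mode: str = "stagewise",
    master_seed: int = 0,
    glm_config: GLMConfig | None = None,
) -> pd.DataFrame:
    """DE detection benchmark over the sample-size grid (tidy per-replicate)."""
    cfg = base_config or SimConfig()
    rows = []
    for n, rep, ds in replicate_grid(cfg, list(sample_sizes), n_replicates, master_seed):
        res = analyze(
            ds.counts, ds.cn, ds.design, alpha=alpha,
            lfc_threshold=lfc_threshold, mt_mode=mt_mode,
            glm_config=glm_config, align=False,
        )
        for row in _evaluate_dataset(res, ds.truth):
            rows.append({"sample_size": n, "replicate": rep, **row})
    return pd.DataFrame(rows)


def summarize(report: pd.DataFrame, by=("method", "sample_size")) -> pd.DataFrame:
    """Mean and sd of every metric per grid cell."""
    value_cols = [
        c for c in report.columns
        if c not in (*by, "replicate") and report[c].dtype.kind == "f"
    ]
    g = report.groupby(list(by))[value_cols]
    mean = g.mean().add_suffix("_mean")
    sd = g.std().add_suffix("_sd")
    return mean.join(sd).reset_index()


def classification_benchmark(
    base_config: SimConfig | None = None,
    sample_sizes=DEFAULT_SAMPLE_SIZES,
    n_replicates: int = 5,
    signals=("strong",),
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    master_seed: int = 1,
    glm_config: GLMConfig | None = None,
) -> pd.DataFrame:
    """DCG-vs-DSG / DCG-vs-DIG discrimination plus one-vs-rest class metrics."""
    cfg = base_config or SimConfig(class_proportions=dict(CLASSIFICATION_PROPORTIONS))
    if cfg.class_proportions.get("DCG", 0.0) <= 0:
        raise ValueError("classification benchmark needs a non-zero DCG fraction")
    rows = []
    for signal in signals:
        sig_cfg = replace(cfg, cn_signal=signal)
        for n, rep, ds in replicate_grid(
            sig_cfg, list(sample_sizes), n_replicates, master_seed
        ):
            res = analyze(
                ds.counts, ds.cn, ds.design, alpha=alpha,
                lfc_threshold=lfc_threshold, glm_config=glm_config, align=False,
            )
            truth = ds.truth.loc[res.table.index]
            predicted = res.table["dosage_class"]
            for pos, neg in (("DCG", "DSG"), ("DCG", "DIG")):
                m = metrics(
                    confusion_from_truth(
                        truth["class"], predicted, "class_vs_class",
                        positive=pos, negative=neg,
                    )
                )
                rows.append(
                    {
                        "signal": signal, "sample_size": n, "replicate": rep,
                        "task": f"{pos}_vs_{neg}", **m,
                    }
                )
            for cls in ("DSG", "DIG", "DCG"):
                tp = int(((predicted == cls) & (truth["class"] == cls)).sum())
                fp = int(((predicted == cls) & (truth["class"] != cls)).sum())
                fn = int(((predicted != cls) & (truth["class"] == cls)).sum())
                tn = len(predicted) - tp - fp - fn
                m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
                rows.append(
                    {
                        "signal": signal, "sample_size": n, "replicate": rep,
                        "task": f"{cls}_vs_rest", **m,
                    }
                )
    return pd.DataFrame(rows)


def robustness_suite(
    base_config: SimConfig | None = None,
    sample_sizes=DEFAULT_SAMPLE_SIZES,
    noise_fractions=DEFAULT_NOISE_GRID,
    n_replicates: int = 3,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    master_seed: int = 2,
    glm_config: GLMConfig | None = None,
) -> pd.DataFrame:
    """Stability of classes, log2FC and FDR rankings under CN-matrix noise.

    For each dataset the clean pipeline is compared with pipelines rerun on a
    noise-injected CN matrix (the CN-naive arm is unaffected by construction).
    Emits per (sample size, replicate, noise fraction, class): the Jaccard
    index of class membership, squared Pearson correlation of clean-vs-noisy
    aware log2FC, and squared Spearman correlation of adjusted-p rankings.
    """
    cfg = base_config or SimConfig(
        n_genes=2000, class_proportions=dict(CLASSIFICATION_PROPORTIONS)
    )
    rows = []
    ss = np.random.SeedSequence(master_seed + 10_000)
    noise_children = iter(ss.spawn(len(sample_sizes) * n_replicates * len(noise_fractions)))
    for n, rep, ds in replicate_grid(cfg, list(sample_sizes), n_replicates, master_seed):
        clean = analyze(
            ds.counts, ds.cn, ds.design, alpha=alpha,
            lfc_threshold=lfc_threshold, glm_config=glm_config, align=False,
        )
        for frac in noise_fractions:
            rng = np.random.default_rng(next(noise_children))
            noisy_cn = inject_cn_noise(ds.cn, frac, rng)
            noisy = analyze(
                ds.counts, noisy_cn, ds.design, alpha=alpha,
                lfc_threshold=lfc_threshold, glm_config=glm_config, align=False,
            )
            genes = clean.table.index.intersection(noisy.table.index)
            ct, nt = clean.table.loc[genes], noisy.table.loc[genes]
            usable = ct["p_aware"].notna() & nt["p_aware"].notna()
            ct, nt = ct[usable], nt[usable]
            for cls in ("DSG", "DIG", "DCG", "nonDEG"):
                in_clean = ct.index[ct["dosage_class"] == cls]
                in_noisy = nt.index[nt["dosage_class"] == cls]
                members = in_clean.union(in_noisy)
                row = {
                    "sample_size": n, "replicate": rep, "noise": frac,
                    "class": cls,
                    "jaccard": jaccard(in_clean, in_noisy),
                    "lfc_r2": np.nan, "fdr_spearman_r2": np.nan,
                }
                if len(members) >= 3:
                    a = ct.loc[members, "lfc_aware"]
                    b = nt.loc[members, "lfc_aware"]
                    if a.std() > 0 and b.std() > 0:
                        r = float(pearsonr(a, b).statistic)
                        row["lfc_r2"] = r * r
                    fa = ct.loc[members, "padj_screen"].fillna(1.0)
                    fb = nt.loc[members, "padj_screen"].fillna(1.0)
                    if fa.nunique() > 1 and fb.nunique() > 1:
                        rho = float(spearmanr(fa, fb).statistic)
                        row["fdr_spearman_r2"] = rho * rho
                rows.append(row)
    return pd.DataFrame(rows)
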
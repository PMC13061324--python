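"""Stage-wise multiple testing across the CN-naive and CN-aware models.

For each gene the two component null hypotheses (not DE under the naive
model, not DE under the aware model) are combined into a gene-level global
null.  Screening tests the global null with the two-hypothesis Simes p-value

    p_S = min(2 * min(p_N, p_A), max(p_N, p_A))

followed by a single Benjamini-Hochberg pass over all genes at level alpha.
Genes that pass screening enter a confirmation stage in which the component
hypotheses are tested with a Holm procedure at the screening-implied level
t = alpha * |R| / G (the stageR convention; ``t = alpha`` is available),
yielding per-model confirmed DE bits.  The legacy comparator applies BH to
each model's p-values independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def simes_combine(p_naive, p_aware):
    """Two-hypothesis Simes omnibus p-value (symmetric in its arguments)."""
    pn = np.asarray(p_naive, dtype=float)
    pa = np.asarray(p_aware, dtype=float)
    valid = np.isnan(pn) | np.isnan(pa)
    if ((pn < 0) | (pn > 1) | (pa < 0) | (pa > 1))[~valid].any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(2.0 * np.minimum(pn, pa), np.maximum(pn, pa))


def screen_bh(p_simes, alpha: float = 0.05):
    """BH step-up on the Simes p-values; returns (screened, padj, stage2 level).

    The stage-2 (confirmation) level is the BH threshold implied by the
    screening rejections, t = alpha * |R| / G; with no rejections t = 0.
    NaN entries are excluded from the family and never screened.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(p_simes, dtype=float)
    padj = np.full(p.shape, np.nan)
    screened = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return screened, padj, 0.0
    rej, adj, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    padj[ok] = adj
    screened[ok] = rej
    stage2_level = alpha * screened.sum() / ok.sum()
    return screened, padj, stage2_level


def confirm_holm(p_naive: float, p_aware: float, stage2_level: float):
    """Holm confirmation of the two component hypotheses at level t.

    The smaller p-value is rejected if <= t/2; only then is the larger tested
    at t.  Returns the (naive, aware) confirmed bits.
    """
    t = stage2_level
    pn, pa = float(p_naive), float(p_aware)
    if np.isnan(pn) or np.isnan(pa):
        first, second = (pa, "aware") if np.isnan(pn) else (pn, "naive")
        bit = int(np.isfinite(first) and first <= t / 2.0)
        return (bit, 0) if second == "naive" else (0, bit)
    lo, hi = (pn, pa) if pn <= pa else (pa, pn)
    reject_lo = lo <= t / 2.0
    reject_hi = reject_lo and hi <= t
    if pn <= pa:
        return int(reject_lo), int(reject_hi)
    return int(reject_hi), int(reject_lo)


@dataclass
class DualTestResult:
    """Per-gene two-model test summary (one row per gene)."""

    table: pd.DataFrame
    stage2_level: float
    alpha: float

    def __getitem__(self, col: str):
        return self.table[col]


def stagewise_pipeline(
    naive: pd.DataFrame, aware: pd.DataFrame, alpha: float = 0.05
) -> DualTestResult:
    """Simes screening + BH + per-gene Holm confirmation over two model runs.

    ``naive`` and ``aware`` are per-gene tables with a ``pvalue`` column and
    identical gene indexes.  Genes with a missing p-value in both models are
    excluded from the BH family and reported unscreened.
    """
    if not naive.index.equals(aware.index):
        if set(naive.index) != set(aware.index):
            raise ValueError("naive and aware tables must cover the same genes")
        aware = aware.loc[naive.index]
    pn = naive["pvalue"].to_numpy(dtype=float)
    pa = aware["pvalue"].to_numpy(dtype=float)
    # a gene with one failed fit is still testable through the other model
    p_s = np.where(
        np.isnan(pn) & np.isnan(pa), np.nan,
        simes_combine(np.nan_to_num(pn, nan=1.0), np.nan_to_num(pa, nan=1.0)),
    )
    screened, padj, t = screen_bh(p_s, alpha=alpha)
    de_n = np.zeros(len(pn), dtype=int)
    de_a = np.zeros(len(pa), dtype=int)
    for i in np.nonzero(screened)[0]:
        de_n[i], de_a[i] = confirm_holm(pn[i], pa[i], t)
    table = pd.DataFrame(
        {
            "p_naive": pn,
            "p_aware": pa,
            "p_simes": p_s,
            "padj_screen": padj,
            "screened": screened,
            "de_naive": de_n,
            "de_aware": de_a,
        },
        index=naive.index,
    )
    return DualTestResult(table=table, stage2_level=t, alpha=alpha)


def per_model_bh(
    naive: pd.DataFrame, aware: pd.DataFrame, alpha: float = 0.05
) -> DualTestResult:
    """Comparator mode: independent BH correction per model (no screening)."""
    if not naive.index.equals(aware.index):
        if set(naive.index) != set(aware.index):
            raise ValueError("naive and aware tables must cover the same genes")
        aware = aware.loc[naive.index]
    pn = naive["pvalue"].to_numpy(dtype=float)
    pa = aware["pvalue"].to_numpy(dtype=float)

    def bh_bits(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        bits = np.zeros(p.shape, dtype=int)
        padj = np.full(p.shape, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            rej, adj, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
            bits[ok] = rej.astype(int)
            padj[ok] = adj
        return bits, padj

    de_n, padj_n = bh_bits(pn)
    de_a, padj_a = bh_bits(pa)
    table = pd.DataFrame(
        {
            "p_naive": pn,
            "p_aware": pa,
            "p_simes": simes_combine(
                np.nan_to_num(pn, nan=1.0), np.nan_to_num(pa, nan=1.0)
            ),
            "padj_screen": np.fmin(padj_n, padj_a),
            "padj_naive": padj_n,
            "padj_aware": padj_a,
            "screened": (de_n | de_a).astype(bool),
            "de_naive": de_n,
            "de_aware": de_a,
        },
        index=naive.index,
    )
    return DualTestResult(table=table, stage2_level=alpha, alpha=alpha)
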
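"""Gene-dosage classification from joint CN-naive / CN-aware DE decisions.

A gene is called DE under a model when its confirmed test decision holds and
its (shrunken) |log2FC| exceeds the effect-size threshold (strictly > 1 by
default).  The joint bit pattern maps to four mechanistic classes:

    (naive, aware) = (1, 0) -> DSG   dosage-sensitive (CN-driven change)
    (1, 1) -> DIG   dosage-insensitive (regulatory change, CN-independent)
    (0, 1) -> DCG   dosage-compensated (buffered; visible only CN-aware)
    (0, 0) -> nonDEG
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stagewise import DualTestResult

_CLASS_TABLE = {(1, 0): "DSG", (1, 1): "DIG", (0, 1): "DCG", (0, 0): "nonDEG"}


def de_bit(confirmed, lfc, lfc_threshold: float = 1.0):
    """Final DE bit: confirmed decision AND |log2FC| strictly above threshold.

    A missing log2FC yields 0 (the gene cannot pass the effect-size gate).
    """
    confirmed = np.asarray(confirmed, dtype=float)
    lfc = np.asarray(lfc, dtype=float)
    with np.errstate(invalid="ignore"):
        gate = np.abs(lfc) > lfc_threshold
    gate = np.where(np.isnan(lfc), False, gate)
    return ((confirmed > 0) & gate).astype(int)


def classify_gene(de_naive: int, de_aware: int) -> str:
    """Map a (naive, aware) DE bit pair to its dosage class."""
    key = (int(de_naive), int(de_aware))
    if key not in _CLASS_TABLE:
        raise ValueError(f"DE bits must be 0/1, got {key}")
    return _CLASS_TABLE[key]


def classify_all(
    dual: DualTestResult | pd.DataFrame,
    lfc_naive,
    lfc_aware,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify every gene; returns per-gene labels with direction and bits.

    ``dual`` provides the confirmed decisions (columns de_naive / de_aware);
    the effect-size gate uses each model's own log2FC.  Direction (up/down) is
    read from the aware log2FC for DIG/DCG and from the naive log2FC for DSG.
    """
    table = dual.table if isinstance(dual, DualTestResult) else dual
    lfc_n = np.asarray(lfc_naive, dtype=float)
    lfc_a = np.asarray(lfc_aware, dtype=float)
    bit_n = de_bit(table["de_naive"].to_numpy(), lfc_n, lfc_threshold)
    bit_a = de_bit(table["de_aware"].to_numpy(), lfc_a, lfc_threshold)
    labels = np.array(
        [_CLASS_TABLE[(n, a)] for n, a in zip(bit_n, bit_a)], dtype=object
    )
    direction_lfc = np.where(labels == "DSG", lfc_n, lfc_a)
    direction = np.where(
        labels == "nonDEG", "", np.where(direction_lfc > 0, "up", "down")
    )
    return pd.DataFrame(
        {
            "dosage_class": labels,
            "direction": direction,
            "de_naive": bit_n,
            "de_aware": bit_a,
            "lfc_naive": lfc_n,
            "lfc_aware": lfc_a,
        },
        index=table.index,
    )


def class_summary(classes: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per dosage class."""
    counts = classes["dosage_class"].value_counts()
    counts = counts.reindex(["DSG", "DIG", "DCG", "nonDEG"], fill_value=0)
    return pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / max(counts.sum(), 1)}
    )
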
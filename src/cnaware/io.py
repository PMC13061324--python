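"""Input/output, validation, expression filtering and CN-state annotation.

Count and copy-number matrices are plain :class:`pandas.DataFrame` objects with
genes in rows and samples in columns; the functions here validate the domain
invariants (integral non-negative counts, non-negative copy numbers, diploid
normals) rather than wrapping the frames in bespoke containers.  The design is
a small table mapping samples to a binary condition (0 = normal/reference,
1 = tumor) plus optional numeric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOSAGE_CLASSES = ("DSG", "DIG", "DCG", "nonDEG")
CN_STATES = ("loss", "neutral", "gain", "amplification")

#: canonical column order of a results table (round-trips through TSV)
RESULT_COLUMNS = [
    "gene_id", "base_mean", "lfc_naive", "lfc_aware", "p_naive", "p_aware",
    "p_simes", "padj_screen", "de_naive", "de_aware", "dosage_class", "cn_state",
]


class MatrixParseError(ValueError):
    """A delimited matrix file could not be parsed into numbers."""


class ValidationError(ValueError):
    """Parsed input violates a domain invariant."""


@dataclass
class DesignSpec:
    """Sample-to-condition mapping plus the tested contrast.

    Parameters
    ----------
    table:
        DataFrame indexed by sample id with a binary ``condition`` column
        (0 = normal, 1 = tumor) and optional numeric covariate columns.
    contrast:
        Coefficient combination tested by the Wald test, of length
        ``1 + n_covariates + 1`` (intercept, condition, covariates).  Defaults
        to selecting the condition coefficient.
    """

    table: pd.DataFrame
    contrast: np.ndarray | None = None
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "condition" not in self.table.columns:
            raise ValidationError("design table needs a 'condition' column")
        cond = self.table["condition"]
        if not set(np.unique(cond)).issubset({0, 1}):
            raise ValidationError("condition must be coded 0 (normal) / 1 (tumor)")
        if (cond == 0).sum() == 0 or (cond == 1).sum() == 0:
            raise ValidationError("need at least one sample per condition")
        for cov in self.covariates:
            if cov not in self.table.columns:
                raise ValidationError(f"covariate {cov!r} missing from design table")
        if self.contrast is None:
            c = np.zeros(2 + len(self.covariates))
            c[1] = 1.0
            self.contrast = c
        else:
            self.contrast = np.asarray(self.contrast, dtype=float)
            if self.contrast.shape != (2 + len(self.covariates),):
                raise ValidationError(
                    f"contrast must have length {2 + len(self.covariates)}"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def condition(self) -> np.ndarray:
        return self.table["condition"].to_numpy(dtype=float)

    @property
    def normal_samples(self) -> pd.Index:
        return self.table.index[self.table["condition"] == 0]

    @property
    def tumor_samples(self) -> pd.Index:
        return self.table.index[self.table["condition"] == 1]

    def matrix(self) -> np.ndarray:
        """Design matrix X (samples x coefficients): intercept, condition, covariates."""
        cols = [np.ones(len(self.table)), self.condition]
        for cov in self.covariates:
            cols.append(self.table[cov].to_numpy(dtype=float))
        return np.column_stack(cols)

    @property
    def coef_names(self) -> list[str]:
        return ["intercept", "condition", *self.covariates]


def _read_delimited(path: str) -> pd.DataFrame:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r} in {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().sum() > df[col].isna().sum():
            bad = df.index[coerced.isna() & df[col].notna()][0]
            raise MatrixParseError(
                f"non-numeric value for gene {bad!r}, sample {col!r} in {path}"
            )
        df[col] = coerced
    return df


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a raw count matrix (genes x samples)."""
    if df.empty:
        raise ValidationError("count matrix is empty")
    values = df.to_numpy()
    if np.isnan(values).any():
        raise ValidationError("count matrix contains missing values")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count for gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if not np.allclose(values, np.round(values)):
        g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValidationError(
            f"non-integral count for gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return df.round().astype(np.int64)


def validate_cn(df: pd.DataFrame, design: DesignSpec | None = None) -> pd.DataFrame:
    """Validate a copy-number matrix; normals (if identified) must be diploid."""
    if df.empty:
        raise ValidationError("copy-number matrix is empty")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("copy-number matrix contains missing values")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative copy number for gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    df = df.astype(float)
    if design is not None:
        normals = [s for s in design.normal_samples if s in df.columns]
        if normals and not np.allclose(df[normals].to_numpy(), 2.0):
            raise ValidationError("normal (diploid) samples must have CN = 2 throughout")
    return df


def read_matrix(path: str, kind: str = "counts") -> pd.DataFrame:
    """Read a genes-x-samples matrix from TSV/CSV (extension-detected).

    ``kind='counts'`` coerces to non-negative integers; ``kind='cn'`` accepts
    non-negative reals (segmented absolute copy numbers may be fractional).
    """
    if kind not in ("counts", "cn"):
        raise ValueError("kind must be 'counts' or 'cn'")
    df = _read_delimited(path)
    return validate_counts(df) if kind == "counts" else validate_cn(df)


def read_design(path: str, covariates: list[str] | None = None) -> DesignSpec:
    """Read a design CSV/TSV with columns sample_id, condition[, covariates]."""
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValidationError("design file needs a 'sample_id' column")
    df = df.set_index("sample_id")
    return DesignSpec(df, covariates=list(covariates or []))


@dataclass
class AlignedInputs:
    counts: pd.DataFrame
    cn: pd.DataFrame
    design: DesignSpec
    dropped_genes: list = field(default_factory=list)
    dropped_samples: list = field(default_factory=list)


def align_inputs(
    counts: pd.DataFrame, cn: pd.DataFrame, design: DesignSpec
) -> AlignedInputs:
    """Restrict counts/CN/design to shared genes and samples, in counts order.

    A CN matrix covering only tumor samples is completed with CN = 2 columns
    for the design's normal samples (diploid reference).
    """
    cn = cn.copy()
    missing_normals = [
        s for s in design.normal_samples
        if s not in cn.columns and s in counts.columns
    ]
    for s in missing_normals:
        cn[s] = 2.0

    genes = counts.index.intersection(cn.index)
    samples = counts.columns.intersection(cn.columns).intersection(design.sample_ids)
    if len(genes) == 0 or len(samples) == 0:
        raise ValidationError("no shared genes/samples between counts, CN and design")

    dropped_genes = sorted(
        set(counts.index).symmetric_difference(cn.index)
    )
    dropped_samples = sorted(
        (set(counts.columns) | set(cn.columns) | set(design.sample_ids)) - set(samples)
    )

    sub_design = DesignSpec(
        design.table.loc[samples].copy(),
        contrast=design.contrast,
        covariates=design.covariates,
    )
    return AlignedInputs(
        counts=counts.loc[genes, samples],
        cn=validate_cn(cn.loc[genes, samples], sub_design),
        design=sub_design,
        dropped_genes=dropped_genes,
        dropped_samples=dropped_samples,
    )


def filter_low_expression(
    counts: pd.DataFrame,
    design: DesignSpec,
    min_mean: float = 10.0,
    sample_set: str = "normal",
) -> tuple[pd.DataFrame, list]:
    """Drop genes whose mean count over the reference samples is < ``min_mean``.

    Low expression is assessed in normal tissue by default (``sample_set`` may
    be ``'normal'``, ``'tumor'`` or ``'all'``); the comparison is strict, so a
    mean of exactly ``min_mean`` is retained.
    """
    if sample_set == "normal":
        cols = [s for s in design.normal_samples if s in counts.columns]
        if not cols:
            raise ValidationError("expression filter needs at least one normal sample")
    elif sample_set == "tumor":
        cols = [s for s in design.tumor_samples if s in counts.columns]
        if not cols:
            raise ValidationError("expression filter needs at least one tumor sample")
    elif sample_set == "all":
        cols = list(counts.columns)
    else:
        raise ValueError("sample_set must be 'normal', 'tumor' or 'all'")
    mean = counts[cols].mean(axis=1)
    keep = mean >= min_mean
    removed = list(counts.index[~keep])
    return counts.loc[keep], removed


def annotate_cn_state(
    cn: pd.DataFrame,
    design: DesignSpec | None = None,
    loss_fraction: float = 0.25,
) -> pd.Series:
    """Label each gene loss / neutral / gain / amplification from tumor CN.

    Mean-CN bins: neutral (1.7, 2.5], gain (2.5, 3.5], amplification (> 3.5);
    means <= 1.7 fall in the loss bin.  A gene with CN 0 or 1 in at least
    ``loss_fraction`` of tumor samples is labelled loss regardless of its mean
    (frequently deleted genes can have near-diploid mean CN).
    """
    if design is not None:
        cols = [s for s in design.tumor_samples if s in cn.columns]
        if not cols:
            raise ValidationError("CN-state annotation needs tumor samples")
        cn = cn[cols]
    values = cn.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    state = np.full(len(cn), "neutral", dtype=object)
    state[mean <= 1.7] = "loss"
    state[(mean > 2.5) & (mean <= 3.5)] = "gain"
    state[mean > 3.5] = "amplification"
    frac_lost = (values <= 1).mean(axis=1)
    state[frac_lost >= loss_fraction] = "loss"
    return pd.Series(state, index=cn.index, name="cn_state")


def write_matrix(df: pd.DataFrame, path: str) -> None:
    """Write a genes-x-samples matrix as TSV/CSV (extension-detected)."""
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index_label="gene_id")


def write_results(table: pd.DataFrame, path: str) -> None:
    """Write a results table as TSV with deterministic column order."""
    df = table.copy()
    if "gene_id" not in df.columns:
        df = df.reset_index(names="gene_id")
    bad = df.loc[
        df["dosage_class"].notna()
        & ~df["dosage_class"].isin(DOSAGE_CLASSES), "dosage_class"
    ]
    if len(bad):
        raise ValidationError(f"unknown dosage class {bad.iloc[0]!r}")
    cols = [c for c in RESULT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
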
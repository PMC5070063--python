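"""Two-group differential expression screen on log2 expression values.

The screen is deliberately low-stringency: a gene is called up-regulated when
its between-group fold difference exceeds 1.15 (a >15% difference in average
expression) and down-regulated when the fold falls below 1/1.15, with strict
inequalities at the boundary.  Folds come from the difference of group means
on the log2 scale, i.e. they are ratios of geometric means.  No per-gene
significance testing is done: small designs are not powered for it, and the
gene lists feed an aggregate promoter-level statistic instead.

Nuisance variables (age, sex, BMI, leukocyte subset fractions) can be removed
beforehand by per-gene least-squares residualization on the covariates alone;
the group contrast is preserved because group membership is excluded from the
regression design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.15


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with sample annotations.

    Parameters
    ----------
    values:
        DataFrame indexed by gene id with one column per sample.
    groups:
        Series mapping sample id to a two-level group label.
    covariates:
        Optional samples x variables numeric DataFrame.
    pairing:
        Optional DataFrame with columns ``subject``, ``pre``, ``post`` naming
        the two samples of each subject, for within-subject contrasts.
    """

    values: pd.DataFrame
    groups: pd.Series
    covariates: pd.DataFrame | None = None
    pairing: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ExpressionError("expression values must be finite")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ExpressionError(f"samples without group label: {missing[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        if self.groups.isna().any():
            raise ExpressionError("missing group label")
        if self.covariates is not None:
            self.covariates = self.covariates.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def group_levels(self) -> list[str]:
        return sorted(self.groups.unique())


def _split_groups(
    matrix: ExpressionMatrix, case: str | None, reference: str | None
) -> tuple[str, str]:
    levels = matrix.group_levels()
    if len(levels) != 2:
        raise ExpressionError(f"need exactly 2 group levels, got {levels}")
    if case is None and reference is None:
        case, reference = levels[0], levels[1]
    elif case is None:
        case = next(l for l in levels if l != reference)
    elif reference is None:
        reference = next(l for l in levels if l != case)
    if case not in levels or reference not in levels or case == reference:
        raise ExpressionError(f"bad group labels {case!r}/{reference!r} for {levels}")
    for lab in (case, reference):
        if (matrix.groups == lab).sum() < 2:
            raise ExpressionError(f"group {lab!r} has fewer than 2 samples")
    return case, reference


def group_fold_difference(
    matrix: ExpressionMatrix,
    case: str | None = None,
    reference: str | None = None,
) -> pd.Series:
    """Per-gene fold = 2**(mean_log2_case - mean_log2_reference).

    ``reference`` is the control/baseline level.  When neither label is given
    the alphabetically first level is treated as the case group.
    """
    case, reference = _split_groups(matrix, case, reference)
    mean_case = matrix.values.loc[:, matrix.groups == case].mean(axis=1)
    mean_ref = matrix.values.loc[:, matrix.groups == reference].mean(axis=1)
    fold = np.power(2.0, mean_case - mean_ref)
    fold.name = "fold"
    return fold


def paired_fold_difference(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene fold = 2**(mean over subjects of post_log2 - pre_log2)."""
    if matrix.pairing is None:
        raise ExpressionError("paired analysis requires a pairing table")
    diffs = []
    for row in matrix.pairing.itertuples(index=False):
        for col, label in ((row.pre, "pre"), (row.post, "post")):
            if col not in matrix.values.columns:
                raise ExpressionError(
                    f"subject {row.subject!r}: missing {label} sample {col!r}"
                )
        diffs.append(matrix.values[row.post] - matrix.values[row.pre])
    fold = np.power(2.0, pd.concat(diffs, axis=1).mean(axis=1))
    fold.name = "fold"
    return fold


@dataclass
class DifferentialResult:
    """Outcome of the fold-difference screen."""

    fold: pd.Series
    threshold: float = DEFAULT_THRESHOLD
    up_genes: list[str] = field(init=False)
    down_genes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ExpressionError(f"threshold must be > 0: {self.threshold}")
        up_cut = 1.0 + self.threshold
        self.up_genes = list(self.fold.index[self.fold > up_cut])
        self.down_genes = list(self.fold.index[self.fold < 1.0 / up_cut])

    def summary(self) -> str:
        return (
            f"{len(self.fold)} transcripts screened at >{self.threshold:.0%}: "
            f"{len(self.up_genes)} up, {len(self.down_genes)} down"
        )


def screen_differential(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    case: str | None = None,
    reference: str | None = None,
    paired: bool = False,
) -> DifferentialResult:
    """Screen genes for a >threshold fold difference between groups.

    Strict inequalities: a fold of exactly ``1 + threshold`` is excluded.
    Emits a warning when either list comes back empty, since the enrichment
    stage requires both.
    """
    if paired:
        fold = paired_fold_difference(matrix)
    else:
        fold = group_fold_difference(matrix, case=case, reference=reference)
    result = DifferentialResult(fold, threshold)
    logger.info(result.summary())
    if not result.up_genes or not result.down_genes:
        warnings.warn(
            "differential screen produced an empty up or down list; "
            "enrichment analysis will refuse these inputs",
            stacklevel=2,
        )
    return result


def residualize_covariates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove covariate effects gene-by-gene by ordinary least squares.

    Each gene's expression is regressed on the covariates plus an intercept
    (group membership excluded); the returned matrix holds residual + gene
    grand mean, so adjusted values stay on the original log2 scale.  The
    operation is idempotent up to numerical precision.
    """
    if matrix.covariates is None or matrix.covariates.shape[1] == 0:
        raise ExpressionError("no covariates to residualize")
    cov = matrix.covariates.astype(float)
    n = len(cov)
    X = np.column_stack([np.ones(n), cov.to_numpy()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [
            c
            for j, c in enumerate(cov.columns)
            if np.linalg.matrix_rank(np.delete(X, j + 1, axis=1)) == rank
        ]
        raise ExpressionError(
            f"covariate design is rank-deficient; collinear columns: {bad}"
        )
    Y = matrix.values.to_numpy().T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    adjusted = resid.T + matrix.values.to_numpy().mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        values=pd.DataFrame(
            adjusted, index=matrix.values.index, columns=matrix.values.columns
        ),
        groups=matrix.groups,
        covariates=matrix.covariates,
        pairing=matrix.pairing,
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_expression_tsv(
    expression_path,
    groups_path=None,
    covariates_path=None,
    pairing_path=None,
) -> ExpressionMatrix:
    """Read an expression matrix (genes in rows, sample ids in the header).

    The groups file is two-column TSV (sample, group) with a header; the
    covariates file is samples x variables with sample ids in column 1.
    """
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep="\t", index_col=0)
        groups = gdf.iloc[:, 0]
    else:
        raise ExpressionError("a groups file is required")
    covariates = (
        pd.read_csv(covariates_path, sep="\t", index_col=0)
        if covariates_path
        else None
    )
    pairing = pd.read_csv(pairing_path, sep="\t") if pairing_path else None
    return ExpressionMatrix(values, groups, covariates, pairing)


def write_expression_tsv(matrix: ExpressionMatrix, expression_path, groups_path=None,
                         covariates_path=None) -> None:
    matrix.values.to_csv(expression_path, sep="\t", index_label="gene")
    if groups_path is not None:
        matrix.groups.rename("group").to_csv(groups_path, sep="\t",
                                             index_label="sample")
    if covariates_path is not None and matrix.covariates is not None:
        matrix.covariates.to_csv(covariates_path, sep="\t", index_label="sample")
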
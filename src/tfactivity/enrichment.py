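"""Promoter TFBM enrichment: prevalence ratios over the scan grid.

For each transcription-factor matrix, motif prevalence (mean hits per
promoter) is computed separately in the promoters of up-regulated genes and
in the promoters of down-regulated genes.  Using the down-regulated set as
the reference controls for the fact that roughly half the genome is not
expressible in the assayed cell pool: both sets consist of genes detectably
expressed in at least one condition.

At each of the grid's stringency x window combinations the prevalence ratio

    r_k = (prev_up + c/n_up) / (prev_down + c/n_down)

is formed (c = 0.5 is a symmetric zero-count guard), the log ratios are
averaged across combinations to obtain a fold estimate robust to scan
parameter choice, and a two-tailed one-sample t-test of the log ratios
against 0 (df = grid size - 1) tests the null hypothesis of a 1.0-fold
prevalence difference.  The grid combinations share the underlying data, so
the t-test is heuristic rather than exact; its calibration is checked
empirically against null simulations rather than claimed analytically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DifferentialResult
from .scan import ScanParams

logger = logging.getLogger(__name__)

ZERO_COUNT_GUARD = 0.5


class EnrichmentError(ValueError):
    pass


def prevalence(
    table: pd.DataFrame,
    genes: list[str],
    matrix_name: str,
    params: ScanParams,
) -> float:
    """Mean motif hits per promoter over ``genes`` at one grid point."""
    if not genes:
        raise EnrichmentError("enrichment requires nonempty up and down lists")
    sub = table[
        (table["matrix"] == matrix_name)
        & (table["threshold"] == params.threshold)
        & (table["window_start"] == params.window[0])
        & (table["window_end"] == params.window[1])
    ]
    counts = sub.set_index("gene")["count"]
    missing = [g for g in genes if g not in counts.index]
    if missing:
        raise EnrichmentError(
            f"genes absent from count table for {matrix_name}: {missing[:5]}"
        )
    return float(counts.loc[genes].mean())


def combo_ratio(
    prev_up: float,
    prev_down: float,
    n_up: int,
    n_down: int,
    correction: float = ZERO_COUNT_GUARD,
) -> float:
    """Prevalence ratio with a symmetric additive zero-count guard.

    The guard ``correction / n`` vanishes for large gene lists and keeps the
    ratio finite (and equal to 1.0 when both prevalences are 0 and the lists
    have equal size).
    """
    if prev_up < 0 or prev_down < 0:
        raise EnrichmentError("prevalences must be nonnegative")
    return (prev_up + correction / n_up) / (prev_down + correction / n_down)


@dataclass
class EnrichmentResult:
    """Fold estimate and test for one transcription-factor matrix."""

    matrix_name: str
    per_combo_ratios: dict[ScanParams, float]
    mean_fold: float
    se_fold: float
    se_log: float
    p_value: float
    df: int
    degenerate: bool = False
    n_up: int = 0
    n_down: int = 0
    bonferroni_significant: bool | None = None

    @property
    def direction(self) -> str:
        return "up" if self.mean_fold > 1.0 else "down"


def telis_test(
    table: pd.DataFrame,
    de: DifferentialResult,
    matrix_name: str,
    grid: list[ScanParams],
    correction: float = ZERO_COUNT_GUARD,
) -> EnrichmentResult:
    """Estimate and test one matrix's prevalence ratio across the scan grid.

    Genes from the differential lists that are missing from the count table
    (promoter not available) are dropped from both lists with a logged count.
    Zero variance across combinations cannot support a t-test: if every log
    ratio is 0 the result is the exact null (p = 1); otherwise the result is
    flagged degenerate with p reported as 0.
    """
    if len(grid) < 2:
        raise EnrichmentError("grid must contain at least 2 combinations")
    tabled = set(table.loc[table["matrix"] == matrix_name, "gene"])
    up = [g for g in de.up_genes if g in tabled]
    down = [g for g in de.down_genes if g in tabled]
    dropped = (len(de.up_genes) - len(up)) + (len(de.down_genes) - len(down))
    if dropped:
        logger.info(
            "%s: dropped %d gene(s) without scanned promoters", matrix_name, dropped
        )
    if not up or not down:
        raise EnrichmentError("enrichment requires nonempty up and down lists")

    ratios: dict[ScanParams, float] = {}
    for params in grid:
        r = combo_ratio(
            prevalence(table, up, matrix_name, params),
            prevalence(table, down, matrix_name, params),
            n_up=len(up),
            n_down=len(down),
            correction=correction,
        )
        ratios[params] = r
    logs = np.log([ratios[p] for p in grid])
    mean_log = float(logs.mean())
    sd_log = float(logs.std(ddof=1))
    mean_fold = math.exp(mean_log)
    se_log = sd_log / math.sqrt(len(grid))
    se_fold = mean_fold * se_log  # delta method on the fold scale
    degenerate = False
    if sd_log == 0.0:
        if mean_log == 0.0:
            p_value = 1.0
        else:
            p_value = 0.0
            degenerate = True
    else:
        _, p_value = stats.ttest_1samp(logs, popmean=0.0)
        p_value = float(p_value)
    return EnrichmentResult(
        matrix_name=matrix_name,
        per_combo_ratios=ratios,
        mean_fold=mean_fold,
        se_fold=se_fold,
        se_log=se_log,
        p_value=p_value,
        df=len(grid) - 1,
        degenerate=degenerate,
        n_up=len(up),
        n_down=len(down),
    )


def bonferroni_adjust(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Flag family-wise significance at ``alpha`` over the tested matrices."""
    if not results:
        raise EnrichmentError("no results to adjust")
    cutoff = alpha / len(results)
    logger.info(
        "Bonferroni correction over %d pathways: individual P < %.4f",
        len(results),
        cutoff,
    )
    for r in results:
        r.bonferroni_significant = r.p_value < cutoff
    return results


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-comparison p-value cutoff, reported to 4 decimals."""
    if n_tests < 1:
        raise EnrichmentError("need at least one test")
    return round(alpha / n_tests, 4)


def results_table(
    results: list[EnrichmentResult], verbose: bool = False
) -> pd.DataFrame:
    """Report-shaped table: matrix, mean fold +/- s.e., p, significance flag.

    ``verbose`` adds the log-scale standard error alongside the fold-scale
    (delta method) one, plus the individual per-combination ratios.
    """
    rows = []
    for r in results:
        row: dict = {
            "matrix": r.matrix_name,
            "mean_fold": r.mean_fold,
            "se_fold": r.se_fold,
            "p_value": r.p_value,
            "bonferroni_significant": r.bonferroni_significant,
            "n_up": r.n_up,
            "n_down": r.n_down,
        }
        if verbose:
            row["se_log"] = r.se_log
            row["degenerate"] = r.degenerate
        for params, ratio in r.per_combo_ratios.items():
            row[f"ratio_{params.label()}"] = ratio
        rows.append(row)
    return pd.DataFrame(rows)
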
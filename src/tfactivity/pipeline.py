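"""End-to-end orchestration: screen -> scan -> enrich -> report.

A single config drives the full analysis either on user-supplied files
(expression TSV + groups TSV + promoter FASTA + TRANSFAC matrices) or in
synthetic demo mode where all inputs come from :mod:`tfactivity.simulate`.
Every run writes the differential gene lists, the motif count table, the
enrichment table and a log of the effective parameters, so a run can be
audited and reproduced byte-for-byte from its own output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    EnrichmentResult,
    bonferroni_adjust,
    results_table,
    telis_test,
)
from .expression import (
    DifferentialResult,
    ExpressionMatrix,
    read_expression_tsv,
    residualize_covariates,
    screen_differential,
)
from .pwm import PWM, parse_transfac
from .scan import (
    PromoterSet,
    ScanParams,
    build_count_table,
    default_grid,
    read_promoters_fasta,
    write_count_table,
    write_promoters_fasta,
)
from .simulate import SimulationConfig, simulate_dataset, simulate_null_dataset

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Inputs and parameters for one pipeline run.

    Exactly one of file mode (``expression_path`` etc.) or synthetic mode
    (``simulation``) must be active.  Defaults follow the published analysis
    conventions: 15% screen, nine-combo scan grid, family-wise alpha 0.05.
    """

    # file mode
    expression_path: str | None = None
    groups_path: str | None = None
    covariates_path: str | None = None
    promoters_path: str | None = None
    matrices_path: str | None = None
    pairing_path: str | None = None
    case_label: str | None = None
    reference_label: str | None = None
    # synthetic mode
    simulation: SimulationConfig | None = None
    null_mode: bool = False
    # shared parameters
    threshold: float = 0.15
    grid: list[ScanParams] = field(default_factory=default_grid)
    alpha: float = 0.05
    adjust: bool = False
    paired: bool = False
    binary_counts: bool = False
    seed: int = 0
    output_dir: str = "tfactivity_out"

    def __post_init__(self) -> None:
        file_mode = self.expression_path is not None
        synthetic = self.simulation is not None
        if file_mode == synthetic:
            raise PipelineError(
                "exactly one of file mode (expression_path) or synthetic mode "
                "(simulation) must be configured"
            )
        if file_mode:
            required = {
                "expression_path": self.expression_path,
                "groups_path": self.groups_path,
                "promoters_path": self.promoters_path,
                "matrices_path": self.matrices_path,
            }
            for name, value in required.items():
                if value is None:
                    raise PipelineError(f"file mode requires {name}")
                if not Path(value).exists():
                    raise PipelineError(f"{name} does not exist: {value}")

    @property
    def synthetic(self) -> bool:
        return self.simulation is not None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["grid"] = [
            {"threshold": p.threshold, "window": list(p.window)} for p in self.grid
        ]
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw:
            raw["grid"] = [
                ScanParams(g["threshold"], tuple(g["window"])) for g in raw["grid"]
            ]
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "planted_tf_effects" in sim:
                sim["planted_tf_effects"] = {
                    k: tuple(v) for k, v in sim["planted_tf_effects"].items()
                }
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)


def analyze(
    matrix: ExpressionMatrix,
    promoters: PromoterSet,
    pwms: list[PWM],
    grid: list[ScanParams] | None = None,
    threshold: float = 0.15,
    adjust: bool = False,
    paired: bool = False,
    alpha: float = 0.05,
    case: str | None = None,
    reference: str | None = None,
    binary_counts: bool = False,
) -> tuple[DifferentialResult, pd.DataFrame, list[EnrichmentResult]]:
    """Library entry point for the screen -> scan -> enrich chain.

    Only the promoters of differentially expressed genes are scanned, since
    the enrichment statistic uses nothing else.
    """
    grid = grid or default_grid()
    if adjust:
        matrix = residualize_covariates(matrix)
    de = screen_differential(
        matrix, threshold=threshold, case=case, reference=reference, paired=paired
    )
    de_genes = [
        g for g in de.up_genes + de.down_genes if g in promoters.sequences
    ]
    scanned = PromoterSet(
        {g: promoters.sequences[g] for g in de_genes}, span=promoters.span
    )
    table = build_count_table(scanned, pwms, grid, binary=binary_counts)
    results = [telis_test(table, de, pwm.name, grid) for pwm in pwms]
    bonferroni_adjust(results, alpha=alpha)
    return de, table, results


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured analysis and write the report bundle.

    Returns the output directory.  Written files: ``de_genes.tsv``,
    ``tfbm_counts.tsv``, ``enrichment.tsv``, ``run_log.yaml`` and, in
    synthetic mode, the generated inputs (FASTA, expression TSV, truth JSON).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load inputs"
    try:
        if config.synthetic:
            sim = config.simulation
            if config.null_mode:
                promoters, matrix, pwms, truth = simulate_null_dataset(sim)
            else:
                promoters, matrix, pwms, truth = simulate_dataset(sim)
            write_promoters_fasta(promoters, out / "promoters.fasta")
            matrix.values.to_csv(out / "expression.tsv", sep="\t",
                                 index_label="gene")
            matrix.groups.rename("group").to_csv(
                out / "groups.tsv", sep="\t", index_label="sample"
            )
            truth.to_json(out / "ground_truth.json")
            case, reference = "case", "control"
        else:
            matrix = read_expression_tsv(
                config.expression_path,
                config.groups_path,
                config.covariates_path,
                config.pairing_path,
            )
            promoters = read_promoters_fasta(config.promoters_path)
            with open(config.matrices_path) as fh:
                pwms = parse_transfac(fh.read())
            case, reference = config.case_label, config.reference_label

        stage = "differential screen"
        de, table, results = analyze(
            matrix,
            promoters,
            pwms,
            grid=config.grid,
            threshold=config.threshold,
            adjust=config.adjust,
            paired=config.paired,
            alpha=config.alpha,
            case=case,
            reference=reference,
            binary_counts=config.binary_counts,
        )

        stage = "write report"
        pd.DataFrame(
            {
                "gene": list(de.fold.index),
                "fold": de.fold.to_numpy(),
                "direction": [
                    "up" if g in set(de.up_genes)
                    else "down" if g in set(de.down_genes)
                    else "none"
                    for g in de.fold.index
                ],
            }
        ).to_csv(out / "de_genes.tsv", sep="\t", index=False, float_format="%.6g")
        write_count_table(table, out / "tfbm_counts.tsv")
        report = results_table(results, verbose=True)
        report.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                      float_format="%.6g")

        log = {
            "tfactivity_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": config.to_dict(),
            "n_transcripts": len(de.fold),
            "n_up": len(de.up_genes),
            "n_down": len(de.down_genes),
            "n_matrices": len(pwms),
            "bonferroni_cutoff": round(config.alpha / len(pwms), 4),
        }
        with open(out / "run_log.yaml", "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=False)
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.info("report written to %s", out)
    return out


# ---------------------------------------------------------------------------
# Replicated null calibration
# ---------------------------------------------------------------------------


def null_calibration(
    n_replicates: int,
    config: SimulationConfig | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    grid: list[ScanParams] | None = None,
) -> pd.DataFrame:
    """Screen->scan->enrich on replicate null datasets.

    Returns one row per (replicate, matrix) with the estimated fold and
    p-value; the empirical rejection rate at ``alpha`` measures the
    calibration of the grid t-test, which treats the parameter combinations
    as replicates although they share data.
    """
    base = config or SimulationConfig()
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(
            np.random.SeedSequence(seed, spawn_key=(rep,)).generate_state(1)[0] >> 1
        )
        sim = dataclasses.replace(base, seed=rep_seed)
        promoters, matrix, pwms, _ = simulate_null_dataset(sim)
        _, _, results = analyze(
            matrix, promoters, pwms, grid=grid, alpha=alpha,
            case="case", reference="control",
        )
        for r in results:
            rows.append(
                {
                    "replicate": rep,
                    "matrix": r.matrix_name,
                    "mean_fold": r.mean_fold,
                    "p_value": r.p_value,
                    "reject": r.p_value < alpha,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-run concordance
# ---------------------------------------------------------------------------

CONCORDANCE_CLASSES = (
    "consistent",
    "inconsistent",
    "additional",
    "not_detected",
    "null",
)


def compare_runs(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Classify per-matrix agreement between two enrichment reports.

    Taxonomy (two-run case): both significant in the same fold direction ->
    ``consistent``; both significant in opposite directions ->
    ``inconsistent``; significant only in B -> ``additional``; significant
    only in A -> ``not_detected``; neither significant -> ``null``.
    Significance is the Bonferroni flag of each report.
    """
    a = report_a.set_index("matrix")
    b = report_b.set_index("matrix")
    shared = [m for m in a.index if m in b.index]
    if not shared:
        raise PipelineError("reports share no matrix names")
    rows = []
    for m in shared:
        sig_a = bool(a.loc[m, "bonferroni_significant"])
        sig_b = bool(b.loc[m, "bonferroni_significant"])
        dir_a = "up" if a.loc[m, "mean_fold"] > 1.0 else "down"
        dir_b = "up" if b.loc[m, "mean_fold"] > 1.0 else "down"
        if sig_a and sig_b:
            cls = "consistent" if dir_a == dir_b else "inconsistent"
        elif sig_b:
            cls = "additional"
        elif sig_a:
            cls = "not_detected"
        else:
            cls = "null"
        rows.append(
            {
                "matrix": m,
                "direction_a": dir_a,
                "significant_a": sig_a,
                "direction_b": dir_b,
                "significant_b": sig_b,
                "concordance": cls,
            }
        )
    return pd.DataFrame(rows)
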
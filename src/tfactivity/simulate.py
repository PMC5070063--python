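"""Synthetic promoters, motif plantings, expression matrices and Ct tables.

The generator encodes the causal structure the promoter-based inference
presumes: an active transcription factor shifts the expression of the genes
whose promoters carry its binding motif.  Genes are split into an
"up-destined" and a "down-destined" set; motif instances are planted into
each set at a controlled prevalence, and the expression simulator adds the
corresponding group effect on the log2 scale.  Setting the two prevalences
equal (or zero) yields the null regime in which the expected motif
prevalence ratio is exactly 1.0 for every matrix.

Randomness is hierarchical: one global integer seed feeds per-component,
per-gene :class:`numpy.random.SeedSequence` substreams, so enlarging the gene
panel does not perturb draws for existing genes.

The shipped motif library (three synthetic matrices modelled on the length
and sharpness range of curated vertebrate TF matrices) avoids redistributing
licence-encumbered TRANSFAC originals.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .pwm import BASES, PWM, parse_transfac, reverse_complement
from .scan import PromoterSet

# Substream component tags (first element of every spawn key).
_PROMOTER, _PLANT, _EXPRESSION, _COVARIATE, _QPCR = range(5)

#: Default fraction of promoters in each destined set carrying one planted
#: motif instance under the null regime; in the range of real promoter motif
#: occupancy for broadly acting factors.
NULL_PREVALENCE = 0.4


class SimulationError(ValueError):
    pass


def default_matrix_library() -> list[PWM]:
    """The packaged synthetic TF matrices (TRANSFAC flat format)."""
    text = (
        importlib.resources.files("tfactivity.data")
        .joinpath("synthetic_motifs.transfac")
        .read_text()
    )
    return parse_transfac(text)


@dataclass
class CovariateSpec:
    """A per-sample nuisance variable: Normal(mean, sd) with a linear slope
    applied uniformly across genes (log2 units per covariate unit)."""

    name: str
    mean: float
    sd: float
    slope: float


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a small two-arm leukocyte transcriptome study: 20 samples
    per arm, promoters spanning -1000..+200 around the TSS, a 0.5 log2-unit
    group effect (~1.4-fold) against 0.3 log2 units of residual noise.
    """

    n_genes: int = 200
    n_per_group: int = 20
    promoter_length: int = 1200
    gc_content: float = 0.5
    planted_tf_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    expression_effect: float = 0.5
    noise_sd: float = 0.3
    covariate_spec: list[CovariateSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise SimulationError("need at least 2 genes")
        if self.n_per_group < 2:
            raise SimulationError("need at least 2 samples per arm")
        if self.promoter_length < 1:
            raise SimulationError(f"invalid promoter length {self.promoter_length}")
        if not 0.0 <= self.gc_content <= 1.0:
            raise SimulationError(f"GC content must be in [0, 1]: {self.gc_content}")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")
        for name, (pu, pd_) in self.planted_tf_effects.items():
            if not (0.0 <= pu <= 1.0 and 0.0 <= pd_ <= 1.0):
                raise SimulationError(
                    f"prevalences for {name!r} must be in [0, 1]: {(pu, pd_)}"
                )

    @property
    def span(self) -> tuple[int, int]:
        """TSS-relative span: the final 200 bases are transcribed sequence."""
        return (200 - self.promoter_length, 200)

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def up_destined(self) -> list[str]:
        ids = self.gene_ids()
        return ids[: self.n_genes // 2]

    def down_destined(self) -> list[str]:
        ids = self.gene_ids()
        return ids[self.n_genes // 2 :]


@dataclass
class GroundTruth:
    """Per-gene planted effects and motif counts, with expected ratios."""

    true_effect: dict[str, float] = field(default_factory=dict)
    planted_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    expected_ratio: dict[str, float] = field(default_factory=dict)
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)

    def planted(self, gene: str, matrix: str) -> int:
        return self.planted_counts.get(matrix, {}).get(gene, 0)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_effect": self.true_effect,
                    "planted_counts": self.planted_counts,
                    "expected_ratio": self.expected_ratio,
                    "up_genes": self.up_genes,
                    "down_genes": self.down_genes,
                },
                fh,
                indent=1,
            )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def expected_prevalence_ratio(
    prevalence_up: float, prevalence_down: float, n_up: int, n_down: int
) -> float:
    """Ground-truth ratio implied by the planting prevalences.

    With both prevalences zero the zero-count guard of the estimator defines
    the ratio; it equals 1.0 for equal-sized sets.
    """
    if prevalence_down > 0:
        return prevalence_up / prevalence_down
    if prevalence_up == 0:
        return (0.5 / n_up) / (0.5 / n_down)
    return math.inf


# ---------------------------------------------------------------------------
# Promoters and plantings
# ---------------------------------------------------------------------------


def generate_promoter_set(config: SimulationConfig) -> PromoterSet:
    """I.i.d. random promoters at the configured GC content, one per gene."""
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    sequences = {}
    for i, gene in enumerate(config.gene_ids()):
        rng = _rng(config.seed, _PROMOTER, i)
        draws = rng.choice(4, size=config.promoter_length, p=probs)
        sequences[gene] = "".join(BASES[b] for b in draws)
    return PromoterSet(sequences, span=config.span)


def plant_motif_instances(
    promoters: PromoterSet,
    pwm: PWM,
    gene_subset: list[str],
    prevalence: float,
    seed: int,
) -> tuple[PromoterSet, dict[str, int]]:
    """Plant one sampled motif instance into a Bernoulli(prevalence) subset.

    Each planted instance is drawn base-by-base from the matrix frequencies
    (so the consensus is the modal planting), written at a uniform random
    position on a uniform random strand, overwriting the background so that
    coordinates stay stable.  Returns the modified promoters and the per-gene
    planted-instance counts.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise SimulationError(f"prevalence must be in [0, 1]: {prevalence}")
    width = promoters.span[1] - promoters.span[0]
    if len(pwm) > width:
        raise SimulationError(
            f"motif {pwm.name!r} (length {len(pwm)}) exceeds promoter span {width}"
        )
    unknown = [g for g in gene_subset if g not in promoters.sequences]
    if unknown:
        raise SimulationError(f"unknown gene id(s): {unknown[:5]}")

    sequences = dict(promoters.sequences)
    counts: dict[str, int] = {}
    ss = np.random.SeedSequence(seed)
    for child, gene in zip(ss.spawn(len(gene_subset)), gene_subset):
        rng = np.random.default_rng(child)
        counts[gene] = 0
        if rng.random() >= prevalence:
            continue
        instance = "".join(
            BASES[rng.choice(4, p=row)] for row in pwm.frequencies
        )
        if rng.random() < 0.5:
            instance = reverse_complement(instance)
        pos = int(rng.integers(0, width - len(pwm) + 1))
        seq = sequences[gene]
        sequences[gene] = seq[:pos] + instance + seq[pos + len(pwm) :]
        counts[gene] = 1
    return PromoterSet(sequences, span=promoters.span), counts


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig, truth: GroundTruth
) -> ExpressionMatrix:
    """Log2 expression: baseline + group effect + covariate terms + noise.

    Groups are balanced ("case" vs "control", n_per_group each); the case arm
    receives each gene's true effect.  Covariates are drawn per sample and
    contribute slope * value to every gene.
    """
    genes = config.gene_ids()
    missing = [g for g in genes if g not in truth.true_effect]
    if missing:
        raise SimulationError(f"ground truth missing genes: {missing[:5]}")
    n = 2 * config.n_per_group
    samples = [f"S{j:03d}" for j in range(n)]
    group = np.array([1] * config.n_per_group + [0] * config.n_per_group)
    labels = pd.Series(
        np.where(group == 1, "case", "control"), index=samples, name="group"
    )

    cov_values = {}
    cov_term = np.zeros(n)
    for k, spec in enumerate(config.covariate_spec):
        rng = _rng(config.seed, _COVARIATE, k)
        vals = rng.normal(spec.mean, spec.sd, size=n)
        cov_values[spec.name] = vals
        cov_term = cov_term + spec.slope * vals
    covariates = (
        pd.DataFrame(cov_values, index=samples) if cov_values else None
    )

    effects = np.array([truth.true_effect[g] for g in genes])
    values = np.empty((len(genes), n))
    for i in range(len(genes)):
        rng = _rng(config.seed, _EXPRESSION, i)
        baseline = rng.uniform(6.0, 10.0)
        noise = rng.normal(0.0, config.noise_sd, size=n)
        values[i] = baseline + effects[i] * group + cov_term + noise
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=labels,
        covariates=covariates,
    )


# ---------------------------------------------------------------------------
# Full datasets
# ---------------------------------------------------------------------------


def simulate_dataset(
    config: SimulationConfig, pwms: list[PWM] | None = None
) -> tuple[PromoterSet, ExpressionMatrix, list[PWM], GroundTruth]:
    """Coupled dataset: motif prevalence differs between destined sets.

    ``config.planted_tf_effects`` maps matrix name to (prevalence_up,
    prevalence_down); matrices without an entry are left unplanted
    (background only, expected ratio 1.0).
    """
    if pwms is None:
        pwms = default_matrix_library()
    by_name = {p.name: p for p in pwms}
    for name in config.planted_tf_effects:
        if name not in by_name:
            raise SimulationError(f"no matrix named {name!r} in the library")

    up, down = config.up_destined(), config.down_destined()
    truth = GroundTruth(up_genes=up, down_genes=down)
    for g in config.gene_ids():
        truth.true_effect[g] = (
            config.expression_effect if g in set(up) else -config.expression_effect
        )

    promoters = generate_promoter_set(config)
    for m, pwm in enumerate(pwms):
        prev_up, prev_down = config.planted_tf_effects.get(pwm.name, (0.0, 0.0))
        plant_seed_up = np.random.SeedSequence(
            config.seed, spawn_key=(_PLANT, m, 0)
        ).generate_state(1)[0] >> 1
        plant_seed_down = np.random.SeedSequence(
            config.seed, spawn_key=(_PLANT, m, 1)
        ).generate_state(1)[0] >> 1
        promoters, counts_up = plant_motif_instances(
            promoters, pwm, up, prev_up, int(plant_seed_up)
        )
        promoters, counts_down = plant_motif_instances(
            promoters, pwm, down, prev_down, int(plant_seed_down)
        )
        truth.planted_counts[pwm.name] = {**counts_up, **counts_down}
        truth.expected_ratio[pwm.name] = expected_prevalence_ratio(
            prev_up, prev_down, len(up), len(down)
        )
    expression = simulate_expression(config, truth)
    return promoters, expression, pwms, truth


def simulate_null_dataset(
    config: SimulationConfig | None = None, pwms: list[PWM] | None = None
) -> tuple[PromoterSet, ExpressionMatrix, list[PWM], GroundTruth]:
    """No-signal dataset: equal planting prevalence in both destined sets.

    Expression effects still separate the destined sets (so the screen yields
    nonempty gene lists), but motif presence is independent of the direction
    of regulation; the expected prevalence ratio is 1.0 for every matrix.
    """
    if config is None:
        config = SimulationConfig()
    if pwms is None:
        pwms = default_matrix_library()
    effects = config.planted_tf_effects or {
        p.name: (NULL_PREVALENCE, NULL_PREVALENCE) for p in pwms
    }
    for name, (pu, pd_) in effects.items():
        if pu != pd_:
            raise SimulationError(
                f"null dataset requires equal prevalences; {name!r} has {(pu, pd_)}"
            )
    null_config = SimulationConfig(
        n_genes=config.n_genes,
        n_per_group=config.n_per_group,
        promoter_length=config.promoter_length,
        gc_content=config.gc_content,
        planted_tf_effects=effects,
        expression_effect=config.expression_effect,
        noise_sd=config.noise_sd,
        covariate_spec=config.covariate_spec,
        seed=config.seed,
    )
    return simulate_dataset(null_config, pwms)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    fold_changes: dict[str, float],
    n_per_group: int,
    ct_noise_sd: float,
    seed: int,
    reference_gene: str = "GAPDH",
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Ct table for target genes at configured case/control fold changes.

    The reference gene's Ct is constant in expectation across samples; each
    target gene's case-arm Ct is shifted by -log2(fold).  Technical replicate
    wells share the sample's biological draw but get independent well noise.
    """
    for gene, fold in fold_changes.items():
        if fold <= 0:
            raise SimulationError(f"fold for {gene!r} must be positive: {fold}")
    if ct_noise_sd < 0:
        raise SimulationError("ct_noise_sd must be nonnegative")
    rng = _rng(seed, _QPCR)
    samples = [f"S{j:03d}" for j in range(2 * n_per_group)]
    groups = ["case"] * n_per_group + ["control"] * n_per_group
    baselines = {reference_gene: 20.0}
    for gene in fold_changes:
        baselines[gene] = float(rng.uniform(22.0, 28.0))
    rows = []
    for sample, group in zip(samples, groups):
        for gene, base in baselines.items():
            ct = base
            if group == "case" and gene in fold_changes:
                ct -= math.log2(fold_changes[gene])
            for _ in range(n_replicates):
                rows.append(
                    (sample, group, gene, ct + rng.normal(0.0, ct_noise_sd))
                )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
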
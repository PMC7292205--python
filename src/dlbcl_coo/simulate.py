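"""Synthetic DLBCL cohorts with the statistical structure the assay assumes.

The generator emulates the four inputs of the real workflow: a two-class
Gaussian expression matrix in which each panel gene is shifted upward in its
overexpressing subtype, raw Ct triplicates obtained by inverting the −ΔCt
convention (Ct falls one cycle per unit of expression), class-correlated IHC
marker percentages, and class-dependent exponential overall survival with
independent uniform censoring.

Everything is driven by a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CtTable, ExpressionMatrix, IhcTable, SampleAnnotation
from .panel import DEFAULT_PANEL, GenePanel

#: Fixed instrument midrange; cancels exactly in ΔCt normalization.
BASE_CT = 25.0

#: Administrative censoring horizon, months (uniform censoring upper bound).
CENSOR_HORIZON = 120.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the clinical validation cohort: 89 ABC and 51 GCB samples,
    a two-standard-deviation expression shift for each marker in its
    overexpressing subtype, 0.15-cycle replicate noise, and a roughly twofold
    overall-survival hazard disadvantage for the ABC subtype.
    """

    n_abc: int = 89
    n_gcb: int = 51
    n_noise_genes: int = 0
    effect_size: float = 2.0  # mean shift of a panel gene in its subtype, SD units
    batch_shift: float | None = None  # additive offset applied to batch "B"
    replicate_sd: float = 0.15  # Ct replicate noise SD, cycles
    hazard_abc: float = 0.02  # exponential event rate, per month
    hazard_gcb: float = 0.01
    ihc_noise: float = 0.15  # probability a sample draws the other class's IHC pattern
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_abc < 0 or self.n_gcb < 0 or self.n_noise_genes < 0:
            raise ValueError("counts must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")
        if self.hazard_abc <= 0 or self.hazard_gcb <= 0:
            raise ValueError("hazards must be positive")
        if not 0 <= self.ihc_noise <= 1:
            raise ValueError("ihc_noise must lie in [0, 1]")


def _rng(spec: CohortSpec, stream: int) -> np.random.Generator:
    # Independent substreams so e.g. regenerating IHC does not perturb expression.
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def generate_expression(
    spec: CohortSpec, panel: GenePanel = DEFAULT_PANEL
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Draw a class-labelled expression matrix on the −ΔCt scale.

    Each panel gene is Normal(effect_size, 1) in its overexpressing subtype and
    Normal(0, 1) otherwise; noise genes are Normal(0, 1) everywhere. When
    ``batch_shift`` is set, the second half of each class is assigned batch "B"
    and receives a constant additive offset on every gene.
    """
    n = spec.n_abc + spec.n_gcb
    if n == 0:
        raise ValueError("cohort must contain at least one sample")
    rng = _rng(spec, 0)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    labels = np.array(["ABC"] * spec.n_abc + ["GCB"] * spec.n_gcb)

    genes = list(panel.target_genes) + [
        f"NOISE{i + 1:04d}" for i in range(spec.n_noise_genes)
    ]
    X = rng.standard_normal((len(genes), n))
    abc_mask = labels == "ABC"
    for i, g in enumerate(panel.abc_genes):
        X[i, abc_mask] += spec.effect_size
    off = len(panel.abc_genes)
    for i, g in enumerate(panel.gcb_genes):
        X[off + i, ~abc_mask] += spec.effect_size

    batches = np.array([None] * n, dtype=object)
    if spec.batch_shift is not None:
        in_b = np.zeros(n, dtype=bool)
        in_b[: spec.n_abc][spec.n_abc // 2 :] = True
        in_b[spec.n_abc :][spec.n_gcb // 2 :] = True
        X[:, in_b] += spec.batch_shift
        batches = np.where(in_b, "B", "A").astype(object)

    ann = [
        SampleAnnotation(sample_id=s, reference_label=l, batch=b)
        for s, l, b in zip(sample_ids, labels, batches)
    ]
    matrix = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=sample_ids))
    return matrix, ann


def generate_ct(
    spec: CohortSpec,
    expr: ExpressionMatrix,
    panel: GenePanel = DEFAULT_PANEL,
) -> CtTable:
    """Invert expression to raw Ct triplicates.

    For every sample, each target gene yields three replicates
    ``BASE_CT − expression + Normal(0, replicate_sd)``; the housekeeping genes
    have expression zero by construction, so their Ct sits at ``BASE_CT`` plus
    replicate noise. Running the ΔCt preprocessing on noise-free output
    recovers the planted expression exactly.
    """
    missing = [g for g in panel.target_genes if g.upper() not in
               {x.upper() for x in expr.gene_ids}]
    if missing:
        raise ValueError(f"expression matrix lacks panel genes: {missing}")
    rng = _rng(spec, 1)
    sub = expr.subset_genes(list(panel.target_genes))
    rows: list[dict] = []
    for s_idx, sample in enumerate(sub.sample_ids):
        for gene in panel.all_genes:
            e = 0.0 if gene in panel.housekeeping_genes else float(
                sub.data.at[gene, sample]
            )
            for rep in (1, 2, 3):
                noise = rng.normal(0.0, spec.replicate_sd) if spec.replicate_sd else 0.0
                rows.append(
                    {
                        "sample_id": sample,
                        "gene": gene,
                        "replicate": rep,
                        "ct": BASE_CT - e + noise,
                    }
                )
    return CtTable(pd.DataFrame(rows))


def generate_ihc_and_survival(
    spec: CohortSpec, annotations: Sequence[SampleAnnotation]
) -> tuple[IhcTable, list[SampleAnnotation]]:
    """Draw IHC marker percentages and survival follow-up from the true labels.

    GCB samples stain CD10 well above the 30% positivity cut-off and ABC
    samples well below it, each with the Hans-concordant BCL6/MUM1 pattern;
    with probability ``ihc_noise`` a sample swaps to the other class's staining
    distribution, which is what drives IHC/assay discordance. Survival times
    are Exponential(hazard of the true class) censored by an independent
    Uniform(0, 120 months) follow-up.
    """
    if not annotations:
        raise ValueError("no annotations supplied")
    for a in annotations:
        if a.reference_label not in ("ABC", "GCB"):
            raise ValueError(f"sample {a.sample_id} lacks a true ABC/GCB label")
    rng = _rng(spec, 2)
    ihc_rows = {}
    updated: list[SampleAnnotation] = []
    for a in annotations:
        pattern = a.reference_label
        if rng.uniform() < spec.ihc_noise:
            pattern = "GCB" if pattern == "ABC" else "ABC"
        if pattern == "GCB":
            # CD10-positive: first branch of the Hans tree → GCB.
            cd10 = rng.uniform(35.0, 95.0)
            bcl6 = rng.uniform(30.0, 90.0)
            mum1 = rng.uniform(0.0, 20.0)
        else:
            # CD10−, BCL6+, MUM1+ → non-GCB.
            cd10 = rng.uniform(0.0, 25.0)
            bcl6 = rng.uniform(40.0, 90.0)
            mum1 = rng.uniform(40.0, 90.0)
        ihc_rows[a.sample_id] = {
            "cd10_pct": cd10, "bcl6_pct": bcl6, "mum1_pct": mum1
        }
        hazard = spec.hazard_abc if a.reference_label == "ABC" else spec.hazard_gcb
        event_time = rng.exponential(1.0 / hazard)
        censor_time = rng.uniform(0.0, CENSOR_HORIZON)
        updated.append(
            replace(
                a,
                survival_time=float(min(event_time, censor_time)),
                event=bool(event_time <= censor_time),
            )
        )
    table = IhcTable(pd.DataFrame.from_dict(ihc_rows, orient="index"))
    return table, updated


def generate_cohort(
    spec: CohortSpec, panel: GenePanel = DEFAULT_PANEL
) -> tuple[ExpressionMatrix, CtTable, IhcTable, list[SampleAnnotation]]:
    """Convenience wrapper producing all four linked fixtures at once."""
    expr, ann = generate_expression(spec, panel)
    ct = generate_ct(spec, expr, panel)
    ihc, ann = generate_ihc_and_survival(spec, ann)
    return expr, ct, ihc, ann
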
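"""Recursive feature elimination with a linear max-margin classifier.

The marker panel was derived by SVM-RFE: fit a linear support vector machine
(C = 1) on standardized training expression, score every gene by the squared
weight it receives in the decision function, discard the lowest-scoring
fraction, and repeat until the target panel size remains. The full elimination
trace is kept so the procedure is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io import ExpressionMatrix


@dataclass(frozen=True)
class RfeConfig:
    """Elimination schedule and SVM hyperparameters.

    ``step_fraction`` of the surviving genes (at least one) is removed each
    round; ``C`` is the SVM soft-margin penalty, fixed at 1 for the assay.
    """

    target_size: int = 32
    step_fraction: float = 0.1
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.step_fraction < 1:
            raise ValueError("step_fraction must lie in (0, 1)")
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class RfeRound:
    survivors: list[str]
    scores: dict[str, float]  # squared SVM weight per surviving gene
    eliminated: list[str]  # genes dropped at the end of this round


@dataclass
class RfeTrace:
    """Ordered record of every elimination round."""

    rounds: list[RfeRound] = field(default_factory=list)
    config: RfeConfig = field(default_factory=RfeConfig)

    @property
    def selected_genes(self) -> list[str]:
        """Final surviving panel, in the input gene order."""
        last = self.rounds[-1]
        return [g for g in last.survivors if g not in last.eliminated]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.rounds):
            for g in r.survivors:
                rows.append(
                    {
                        "round": i,
                        "gene": g,
                        "score": r.scores[g],
                        "eliminated": g in r.eliminated,
                    }
                )
        return pd.DataFrame(rows)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant features stay zero after centering
    return (X - mu) / sd


def _encode_labels(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    return y


def rank_features(
    X: ExpressionMatrix, y: np.ndarray | pd.Series, C: float = 1.0
) -> pd.Series:
    """Score each gene by its squared weight in a linear SVM fit.

    Expression is standardized (per gene, mean 0 / SD 1 on the supplied data)
    before fitting, so scores compare loadings rather than raw scales. Larger
    scores mark more informative genes; an all-constant gene scores zero.
    """
    y = _encode_labels(np.asarray(y))
    M = _standardize(X.values.T)  # samples × genes
    for cls in np.unique(y):
        if (y == cls).sum() < 2:
            raise ValueError(f"need >=2 samples in class {cls!r}")
    svm = SVC(kernel="linear", C=C)
    svm.fit(M, y)
    w = np.asarray(svm.coef_).ravel()
    return pd.Series(w**2, index=X.gene_ids, name="score")


def run_rfe(
    X: ExpressionMatrix, y: np.ndarray | pd.Series, config: RfeConfig = RfeConfig()
) -> RfeTrace:
    """Iteratively eliminate the lowest-scoring genes down to ``target_size``.

    Each round refits the SVM on the survivors and removes
    ``ceil(step_fraction × n_surviving)`` genes (never dipping below the
    target size). Score ties are broken by dropping the lexicographically
    last gene ids first, which makes the procedure deterministic.
    """
    genes = X.gene_ids
    if config.target_size > len(genes):
        raise ValueError(
            f"target_size {config.target_size} exceeds {len(genes)} features"
        )
    y = np.asarray(y)
    trace = RfeTrace(config=config)
    survivors = list(genes)
    while True:
        scores = rank_features(X.subset_genes(survivors), y, C=config.C)
        if len(survivors) <= config.target_size:
            trace.rounds.append(
                RfeRound(survivors=list(survivors), scores=dict(scores), eliminated=[])
            )
            break
        n_drop = min(
            math.ceil(config.step_fraction * len(survivors)),
            len(survivors) - config.target_size,
        )
        # Ascending score; stable sort preserves the reverse-lexicographic
        # pre-order, so ties drop the lexicographically last gene ids first.
        order = sorted(sorted(survivors, reverse=True), key=lambda g: scores[g])
        dropped = order[:n_drop]
        trace.rounds.append(
            RfeRound(survivors=list(survivors), scores=dict(scores),
                     eliminated=list(dropped))
        )
        drop_set = set(dropped)
        survivors = [g for g in survivors if g not in drop_set]
    return trace
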
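"""The cell-of-origin subtype classifier.

A linear support vector machine (soft-margin penalty C = 1) is trained on
−ΔCt (or log-expression) values of the 32 panel genes with known ABC/GCB
labels. Its signed margin is mapped to a class probability by a Platt-style
sigmoid fitted on five-fold out-of-fold margins, and a sample is called ABC or
GCB only when the calibrated probability of that subtype exceeds the call
threshold (default 75%, strict inequality); otherwise it is unclassified
(UNC). For comparison against two-way immunohistochemistry surrogates, calls
collapse deterministically to GCB vs non-GCB: GCB stays GCB, ABC and UNC
become non-GCB.

The module follows the model/results idiom: build a :class:`CooSubtypeModel`
from data, call :meth:`~CooSubtypeModel.fit`, and use the returned
:class:`CooSubtypeResults` (which wraps the portable :class:`CooModel` assay
artifact) for prediction, calling and serialization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import CooCallSet, ExpressionMatrix, ValidationError

CLASSES = ("ABC", "GCB")  # sklearn's lexicographic order; positive margin = GCB
DEFAULT_THRESHOLD = 0.75


def call_subtype(p_abc: float, p_gcb: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Three-way call from the calibrated probability vector.

    GCB if p_GCB > threshold, ABC if p_ABC > threshold, otherwise UNC.
    The comparison is strict: a probability of exactly the threshold is
    unclassified.
    """
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must lie in (0.5, 1)")
    if not (np.isfinite(p_abc) and np.isfinite(p_gcb)):
        raise ValueError("probabilities must be finite")
    if abs(p_abc + p_gcb - 1.0) > 1e-9:
        raise ValueError("p_ABC + p_GCB must equal 1")
    if p_gcb > threshold:
        return "GCB"
    if p_abc > threshold:
        return "ABC"
    return "UNC"


def collapse_binary(call: str) -> str:
    """Collapse a three-way call for comparison with two-way surrogates."""
    if call == "GCB":
        return "GCB"
    if call in ("ABC", "UNC"):
        return "non-GCB"
    raise ValueError(f"unknown subtype call {call!r}")


@dataclass
class CooModel:
    """Portable assay model: everything needed to reproduce a call.

    Stores the ordered panel, per-gene standardization statistics frozen from
    the training data, the linear decision function (weights, bias) and the
    sigmoid calibration ``p_GCB = expit(calib_a · margin + calib_b)``.
    """

    panel_genes: list[str]
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bias: float
    calib_a: float
    calib_b: float
    threshold: float = DEFAULT_THRESHOLD
    calibration: str = "sigmoid-oof-5fold"

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.panel_genes)
        if not (self.means.size == self.sds.size == self.weights.size == n):
            raise ValueError("panel/standardization/weight lengths disagree")
        if self.calib_a <= 0:
            raise ValueError("calibration must be monotone increasing in the margin")
        if not 0.5 < self.threshold < 1:
            raise ValueError("threshold must lie in (0.5, 1)")

    def _design(self, X: ExpressionMatrix) -> np.ndarray:
        sub = X.subset_genes(self.panel_genes)
        M = sub.values.T  # samples × genes
        if not np.isfinite(M).all():
            raise ValidationError("non-finite expression value; no imputation is done")
        return (M - self.means) / self.sds

    def decision_function(self, X: ExpressionMatrix) -> pd.Series:
        """Signed margin per sample; positive side is GCB."""
        Z = self._design(X)
        return pd.Series(Z @ self.weights + self.bias, index=X.sample_ids,
                         name="margin")

    def predict_proba(self, X: ExpressionMatrix) -> pd.DataFrame:
        """Calibrated probabilities over {ABC, GCB}; rows sum to one."""
        m = self.decision_function(X)
        p_gcb = expit(self.calib_a * m.to_numpy() + self.calib_b)
        return pd.DataFrame(
            {"p_ABC": 1.0 - p_gcb, "p_GCB": p_gcb}, index=m.index
        )

    def call(self, X: ExpressionMatrix, threshold: float | None = None) -> CooCallSet:
        """Three-way subtype calls (with binary collapse) for every sample."""
        thr = self.threshold if threshold is None else threshold
        probs = self.predict_proba(X)
        calls = [
            call_subtype(a, g, thr)
            for a, g in zip(probs["p_ABC"], probs["p_GCB"])
        ]
        df = probs.copy()
        df["call"] = calls
        df["binary_call"] = [collapse_binary(c) for c in calls]
        return CooCallSet(df)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel_genes),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "calib_a": self.calib_a,
            "calib_b": self.calib_b,
            "threshold": self.threshold,
            "calibration": self.calibration,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CooModel":
        return cls(
            panel_genes=list(d["panel"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            weights=np.array(d["weights"]),
            bias=float(d["bias"]),
            calib_a=float(d["calib_a"]),
            calib_b=float(d["calib_b"]),
            threshold=float(d.get("threshold", DEFAULT_THRESHOLD)),
            calibration=str(d.get("calibration", "sigmoid-oof-5fold")),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CooModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


class CooSubtypeModel:
    """Linear-SVM subtype model specified by training data.

    Parameters
    ----------
    X : ExpressionMatrix
        Expression over (at least) the panel genes; genes × samples.
    y : sequence of str
        Reference label per sample, each ``"ABC"`` or ``"GCB"``.
    panel_genes : sequence of str, optional
        Ordered panel; defaults to all genes of ``X``.
    """

    def __init__(
        self,
        X: ExpressionMatrix,
        y: Sequence[str],
        panel_genes: Sequence[str] | None = None,
    ) -> None:
        panel = list(panel_genes) if panel_genes is not None else X.gene_ids
        self.X = X.subset_genes(panel)
        self.panel_genes = self.X.gene_ids
        y = np.asarray(list(y), dtype=object)
        if y.size != len(self.X.sample_ids):
            raise ValueError("label count does not match sample count")
        bad = sorted(set(y) - set(CLASSES))
        if bad:
            raise ValueError(f"labels must be ABC/GCB; got {bad}")
        if len(set(y)) < 2:
            raise ValueError("both classes must be present in the training data")
        self.y = y.astype(str)

    @classmethod
    def from_dataframe(
        cls,
        expr: pd.DataFrame,
        labels: pd.Series | dict,
        panel_genes: Sequence[str] | None = None,
    ) -> "CooSubtypeModel":
        """Build from a genes × samples DataFrame and a per-sample label map."""
        labels = pd.Series(labels)
        X = ExpressionMatrix(expr)
        y = labels.reindex(X.sample_ids)
        if y.isna().any():
            missing = list(y.index[y.isna()])
            raise ValueError(f"samples without labels: {missing}")
        return cls(X, y.to_numpy(), panel_genes=panel_genes)

    def fit(
        self,
        C: float = 1.0,
        threshold: float = DEFAULT_THRESHOLD,
        n_calibration_folds: int = 5,
        seed: int = 0,
    ) -> "CooSubtypeResults":
        """Fit the SVM, calibrate margins on out-of-fold predictions.

        Standardization statistics are computed on the training data only and
        frozen into the model, so downstream samples are scored on the
        training scale.
        """
        M = self.X.values.T  # samples × genes
        means = M.mean(axis=0)
        sds = M.std(axis=0, ddof=0)
        sds = np.where(sds == 0, 1.0, sds)
        Z = (M - means) / sds

        svm = SVC(kernel="linear", C=C)
        svm.fit(Z, self.y)
        # sklearn orders classes lexicographically: ABC then GCB, so a
        # positive decision value already points at GCB.
        weights = np.asarray(svm.coef_).ravel()
        bias = float(svm.intercept_[0])

        oof_margin = np.empty(len(self.y))
        min_class = int(min((self.y == c).sum() for c in CLASSES))
        n_splits = max(2, min(n_calibration_folds, min_class))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=seed)
        for train_idx, test_idx in skf.split(Z, self.y):
            fold_svm = SVC(kernel="linear", C=C)
            fold_svm.fit(Z[train_idx], self.y[train_idx])
            oof_margin[test_idx] = fold_svm.decision_function(Z[test_idx])

        lr = LogisticRegression(C=1.0)
        lr.fit(oof_margin.reshape(-1, 1), (self.y == "GCB").astype(int))
        calib_a = float(lr.coef_[0, 0])
        calib_b = float(lr.intercept_[0])
        if calib_a <= 0:
            # Uninformative data: out-of-fold margins carry no class signal,
            # so the sigmoid slope collapses. Clamp to an (arbitrarily) small
            # positive slope to preserve the monotone-calibration invariant;
            # probabilities then sit near 0.5 and samples fall to UNC.
            warnings.warn(
                "out-of-fold margins do not separate the classes; "
                "calibration slope clamped to a small positive value",
                stacklevel=2,
            )
            calib_a = 1e-6

        model = CooModel(
            panel_genes=list(self.panel_genes),
            means=means,
            sds=sds,
            weights=weights,
            bias=bias,
            calib_a=calib_a,
            calib_b=calib_b,
            threshold=threshold,
        )
        return CooSubtypeResults(self, model, oof_margin=oof_margin, C=C)


class CooSubtypeResults:
    """Fit results: the portable assay model plus training diagnostics."""

    def __init__(
        self,
        model_spec: CooSubtypeModel,
        model: CooModel,
        oof_margin: np.ndarray,
        C: float,
    ) -> None:
        self.model_spec = model_spec
        self.model = model
        self.oof_margin = oof_margin
        self.C = C

    @property
    def weights(self) -> pd.Series:
        return pd.Series(self.model.weights, index=self.model.panel_genes,
                         name="weight")

    @property
    def training_accuracy(self) -> float:
        calls = np.where(
            self.model.decision_function(self.model_spec.X).to_numpy() > 0,
            "GCB", "ABC",
        )
        return float((calls == self.model_spec.y).mean())

    @property
    def oof_accuracy(self) -> float:
        """Out-of-fold (cross-validated) hard-label accuracy."""
        calls = np.where(self.oof_margin > 0, "GCB", "ABC")
        return float((calls == self.model_spec.y).mean())

    def predict_proba(self, X: ExpressionMatrix) -> pd.DataFrame:
        return self.model.predict_proba(X)

    def call(self, X: ExpressionMatrix, threshold: float | None = None) -> CooCallSet:
        return self.model.call(X, threshold=threshold)

    def save(self, path: str | Path) -> None:
        self.model.to_json(path)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Cell-of-origin subtype classifier (linear SVM)",
            "=" * 47,
            f"panel genes:        {len(m.panel_genes)}",
            f"training samples:   {len(self.model_spec.y)} "
            f"(ABC {int((self.model_spec.y == 'ABC').sum())}, "
            f"GCB {int((self.model_spec.y == 'GCB').sum())})",
            f"C:                  {self.C:g}",
            f"training accuracy:  {self.training_accuracy:.3f}",
            f"out-of-fold acc.:   {self.oof_accuracy:.3f}",
            f"calibration:        p_GCB = expit({m.calib_a:.4f}*margin "
            f"{m.calib_b:+.4f})",
            f"call threshold:     {m.threshold:g} (strict >)",
            "",
            "largest |weight| genes:",
        ]
        top = self.weights.abs().sort_values(ascending=False).head(10)
        for g in top.index:
            w = self.weights[g]
            side = "GCB" if w > 0 else "ABC"
            lines.append(f"  {g:<10} {w:+.4f}  ({side})")
        return "\n".join(lines)
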
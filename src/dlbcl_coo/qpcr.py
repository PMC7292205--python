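"""Raw Ct triplicates → −ΔCt expression values.

The assay runs every target in triplicate. Replicates are first reconciled
(discordant wells dropped by a spread rule), then each target's mean Ct is
normalized against the mean of the three housekeeping genes:

    ΔCt(gene, sample) = meanCt(gene, sample) − mean(meanCt(housekeeping, sample))

and the stored expression value is −ΔCt, which increases with transcript
abundance. A per-sample plate offset adds the same constant to every Ct and
therefore cancels exactly in ΔCt.

The replicate-concordance rule (``max_spread``, default 0.5 cycles) and the
sample-acceptance rule (at most ``max_failed_genes`` failed targets, default 3)
are laboratory conventions exposed as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CtTable, ExpressionMatrix
from .panel import DEFAULT_PANEL, GenePanel

PASS = "pass"
FAIL = "fail"


def aggregate_replicates(ct: CtTable, max_spread: float = 0.5) -> pd.DataFrame:
    """Reconcile replicate wells into one mean Ct per (sample, gene).

    If the replicates span more than ``max_spread`` cycles, the replicate
    farthest from the median is dropped and the rest re-tested; two survivors
    still more than ``max_spread`` apart — or no measurable replicate at all —
    yield a ``fail`` flag rather than an exception.

    Returns a DataFrame indexed by (sample_id, gene) with columns
    ``mean_ct``, ``n_used`` and ``flag``.
    """
    records = []
    for (sample, gene), grp in ct.data.groupby(["sample_id", "gene"], sort=True):
        values = grp["ct"].dropna().to_numpy()
        mean_ct, n_used, flag = _reconcile(values, max_spread)
        records.append(
            {
                "sample_id": sample,
                "gene": gene,
                "mean_ct": mean_ct,
                "n_used": n_used,
                "flag": flag,
            }
        )
    return pd.DataFrame(records).set_index(["sample_id", "gene"])


def _reconcile(values: np.ndarray, max_spread: float) -> tuple[float, int, str]:
    if values.size == 0:
        return np.nan, 0, FAIL
    if values.size == 1 or np.ptp(values) <= max_spread:
        return float(values.mean()), int(values.size), PASS
    # Drop the well farthest from the median, then re-test the survivors.
    median = np.median(values)
    keep = np.delete(values, int(np.argmax(np.abs(values - median))))
    if np.ptp(keep) <= max_spread:
        return float(keep.mean()), int(keep.size), PASS
    return np.nan, 0, FAIL


def delta_ct(
    mean_ct: pd.DataFrame, panel: GenePanel = DEFAULT_PANEL
) -> ExpressionMatrix:
    """Normalize mean Cts into a −ΔCt expression matrix over the panel targets.

    A sample is usable only if all three housekeeping genes passed replicate
    QC; otherwise every target of that sample is flagged failed. Failed
    (sample, gene) cells are carried as QC failures, available via
    :func:`qc_flags`, and excluded from the returned matrix values by being
    set to NaN in the companion flag table — the matrix itself contains only
    samples that pass housekeeping.
    """
    wide = mean_ct["mean_ct"].unstack("sample_id")
    flags = mean_ct["flag"].unstack("sample_id")
    upper = {g.upper(): g for g in wide.index}

    hk_rows = []
    for hk in panel.housekeeping_genes:
        if hk.upper() not in upper:
            hk_rows.append(None)
        else:
            hk_rows.append(upper[hk.upper()])

    samples = list(wide.columns)
    hk_ok = pd.Series(True, index=samples)
    for hk, row in zip(panel.housekeeping_genes, hk_rows):
        if row is None:
            hk_ok[:] = False
        else:
            hk_ok &= flags.loc[row].reindex(samples).eq(PASS)

    target_rows = []
    for g in panel.target_genes:
        if g.upper() not in upper:
            raise KeyError(f"target gene {g!r} absent from Ct data")
        target_rows.append(upper[g.upper()])

    hk_mean = wide.loc[[r for r in hk_rows if r is not None]].mean(axis=0)
    neg_delta = -(wide.loc[target_rows].sub(hk_mean, axis=1))
    neg_delta.index = list(panel.target_genes)

    gene_flags = flags.loc[target_rows].eq(PASS)
    gene_flags.index = list(panel.target_genes)
    gene_flags = gene_flags & hk_ok  # housekeeping failure fails the whole sample

    qc = gene_flags.map(lambda ok: PASS if ok else FAIL)
    qc.index.name = "gene"
    qc.columns.name = "sample"

    values = neg_delta.where(gene_flags)
    result = DeltaCtMatrix(values=values, qc=qc, housekeeping_mean=hk_mean,
                           housekeeping_ok=hk_ok)
    return result


@dataclass
class DeltaCtMatrix:
    """−ΔCt values with per-cell QC flags and the per-sample housekeeping mean."""

    values: pd.DataFrame  # genes × samples, NaN where QC failed
    qc: pd.DataFrame  # genes × samples, "pass"/"fail"
    housekeeping_mean: pd.Series  # per sample
    housekeeping_ok: pd.Series  # per sample

    def passing_matrix(self, samples: list[str] | None = None) -> ExpressionMatrix:
        """Complete −ΔCt matrix over samples with every cell passing QC."""
        cols = samples if samples is not None else [
            s for s in self.values.columns if self.qc[s].eq(PASS).all()
        ]
        sub = self.values[cols]
        if sub.isna().to_numpy().any():
            bad = [c for c in cols if sub[c].isna().any()]
            raise ValueError(f"samples with failed QC cells: {bad}")
        return ExpressionMatrix(sub)


def sample_qc(delta: DeltaCtMatrix, max_failed_genes: int = 3) -> pd.Series:
    """Per-sample pass/fail: housekeeping intact and at most
    ``max_failed_genes`` failed target genes."""
    failed = delta.qc.eq(FAIL).sum(axis=0)
    ok = delta.housekeeping_ok & (failed <= max_failed_genes)
    return ok.map(lambda b: PASS if b else FAIL).rename("sample_qc")
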
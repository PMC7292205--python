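"""Tabular domain types and their readers/writers.

All on-disk formats are plain text:

* expression matrix — TSV/CSV, genes in rows, samples in columns, first column
  the gene symbol, header row the sample ids;
* Ct table — long-format CSV with columns ``sample_id,gene,replicate,ct``
  (``ct`` numeric or the qPCR sentinel ``Undetermined``);
* subtype calls — TSV with columns
  ``sample_id, p_ABC, p_GCB, call, binary_call``.

Matrix orientation is fixed (genes × samples); a transposed file is an error,
never auto-detected, because silent transposition is the classic
expression-matrix bug.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("ABC", "GCB", "UNC")
BINARY_LABELS = ("GCB", "non-GCB")

#: qPCR cycle values outside this open-closed interval are implausible.
CT_RANGE = (0.0, 45.0)


class ValidationError(ValueError):
    """Input violates a domain invariant (duplicate ids, bad range, ...)."""


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of expression values (log-like or −ΔCt scale)."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        idx = pd.Index([str(g).strip() for g in self.data.index], name="gene")
        cols = pd.Index([str(s).strip() for s in self.data.columns], name="sample")
        lowered = idx.str.upper()
        if lowered.duplicated().any():
            dups = sorted(set(idx[lowered.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        self.data = pd.DataFrame(values, index=idx, columns=cols)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (case-insensitive match), preserving order."""
        lookup = {g.upper(): g for g in self.data.index}
        missing = [g for g in genes if g.strip().upper() not in lookup]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        rows = [lookup[g.strip().upper()] for g in genes]
        return ExpressionMatrix(self.data.loc[rows])

    def to_file(self, path: str | Path, dialect: str = "tsv") -> None:
        sep = {"tsv": "\t", "csv": ","}[dialect]
        self.data.to_csv(path, sep=sep, index_label="gene")


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes × samples expression table.

    The first column holds gene symbols and the header row holds sample ids;
    every body cell must be numeric. Duplicated gene or sample ids raise
    :class:`ValidationError`, as does any non-numeric cell (named by row and
    column in the message).
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    parsed = raw.apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {raw.iat[gi, si]!r} at gene "
            f"{raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    if parsed.isna().to_numpy().any():
        gi, si = np.argwhere(parsed.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r}"
        )
    return ExpressionMatrix(parsed)


@dataclass
class CtTable:
    """Long-format raw qPCR table: one row per (sample, gene, replicate)."""

    data: pd.DataFrame  # columns: sample_id, gene, replicate, ct (NaN = missing)

    REQUIRED = ("sample_id", "gene", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"Ct table lacks columns: {missing}")
        df = self.data.loc[:, list(self.REQUIRED)].copy()
        df["sample_id"] = df["sample_id"].astype(str).str.strip()
        df["gene"] = df["gene"].astype(str).str.strip()
        df["replicate"] = df["replicate"].astype(int)
        ct = pd.to_numeric(df["ct"], errors="coerce")
        present = ct.notna()
        lo, hi = CT_RANGE
        out = present & ((ct <= lo) | (ct > hi))
        if out.any():
            row = df[out].iloc[0]
            raise ValidationError(
                f"ct value {ct[out].iloc[0]} outside plausible cycle range "
                f"({lo}, {hi}] for sample {row.sample_id!r}, gene {row.gene!r}"
            )
        dup = df.duplicated(subset=["sample_id", "gene", "replicate"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate replicate index {row.replicate} for sample "
                f"{row.sample_id!r}, gene {row.gene!r}"
            )
        df["ct"] = ct
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


#: Sentinels a qPCR instrument emits for a failed well.
_CT_SENTINELS = {"undetermined", "undet", "na", "nan", ""}


def read_ct_table(path: str | Path) -> CtTable:
    """Read a long-format Ct CSV (``sample_id,gene,replicate,ct``).

    The instrument sentinel ``Undetermined`` (and blank cells) become missing
    values; a numeric Ct outside (0, 45] cycles is a :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CtTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: Ct table lacks columns {missing}")
    raw = df["ct"].astype(str).str.strip()
    is_sentinel = raw.str.lower().isin(_CT_SENTINELS)
    ct = pd.to_numeric(raw.where(~is_sentinel), errors="coerce")
    unparsed = ct.isna() & ~is_sentinel
    if unparsed.any():
        raise ValidationError(
            f"{path}: non-numeric ct value {raw[unparsed].iloc[0]!r}"
        )
    out = df.copy()
    out["ct"] = ct
    return CtTable(out)


@dataclass
class SampleAnnotation:
    """Per-sample reference label, survival follow-up and optional batch."""

    sample_id: str
    reference_label: str = "unknown"  # ABC | GCB | UNC | unknown
    survival_time: float | None = None  # months from diagnosis
    event: bool | None = None  # True = death observed
    batch: str | None = None

    def __post_init__(self) -> None:
        if self.reference_label not in (*SUBTYPES, "unknown"):
            raise ValidationError(
                f"reference_label {self.reference_label!r} not in "
                f"{SUBTYPES + ('unknown',)}"
            )
        if self.survival_time is not None and self.survival_time < 0:
            raise ValidationError("survival_time must be non-negative")
        if self.event is not None and self.survival_time is None:
            raise ValidationError("event defined without survival_time")


def annotations_to_frame(annotations: Iterable[SampleAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": a.sample_id,
            "reference_label": a.reference_label,
            "survival_time": a.survival_time,
            "event": a.event,
            "batch": a.batch,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV (sample_id, reference_label, survival_time, event, batch)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        t = r.get("survival_time")
        t = float(t) if t not in (None, "") and not pd.isna(t) else None
        e = r.get("event")
        e = bool(int(e)) if e not in (None, "") and not pd.isna(e) else None
        out.append(
            SampleAnnotation(
                sample_id=str(r["sample_id"]),
                reference_label=str(r.get("reference_label", "unknown")),
                survival_time=t,
                event=e,
                batch=None if pd.isna(r.get("batch")) else str(r.get("batch")),
            )
        )
    return out


def write_annotations(path: str | Path, annotations: Sequence[SampleAnnotation]) -> None:
    df = annotations_to_frame(annotations).reset_index()
    df["event"] = df["event"].map(lambda e: "" if e is None else str(int(e)))
    df.to_csv(path, sep="\t", index=False)


@dataclass
class IhcTable:
    """Per-sample immunostaining percentages for CD10, BCL6 and MUM1."""

    data: pd.DataFrame  # index = sample_id; columns cd10_pct, bcl6_pct, mum1_pct

    MARKERS = ("cd10_pct", "bcl6_pct", "mum1_pct")

    def __post_init__(self) -> None:
        missing = [c for c in self.MARKERS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"IHC table lacks columns: {missing}")
        df = self.data.loc[:, list(self.MARKERS)].astype(float)
        vals = df.to_numpy()
        present = ~np.isnan(vals)
        if ((vals < 0) & present).any() or ((vals > 100) & present).any():
            raise ValidationError("IHC percentages must lie in [0, 100]")
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        self.data = df


def read_ihc_table(path: str | Path) -> IhcTable:
    df = pd.read_csv(path, index_col="sample_id")
    return IhcTable(df)


def write_ihc_table(path: str | Path, table: IhcTable) -> None:
    table.data.to_csv(path, index_label="sample_id")


@dataclass
class CooCallSet:
    """Per-sample subtype calls with calibrated class probabilities.

    Each sample carries a probability vector over {ABC, GCB} summing to one,
    a three-way call in {ABC, GCB, UNC} and its deterministic two-way collapse
    (GCB stays GCB; ABC and UNC become non-GCB).
    """

    data: pd.DataFrame  # index sample_id; columns p_ABC, p_GCB, call, binary_call

    COLUMNS = ("p_ABC", "p_GCB", "call", "binary_call")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"call set lacks columns: {missing}")
        df = self.data.loc[:, list(self.COLUMNS)].copy()
        if len(df) == 0:
            raise ValidationError("empty call set")
        p = df[["p_ABC", "p_GCB"]].astype(float)
        if ((p < 0) | (p > 1)).to_numpy().any():
            raise ValidationError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("p_ABC + p_GCB must equal 1 within 1e-9")
        if not df["call"].isin(SUBTYPES).all():
            raise ValidationError(f"calls must be one of {SUBTYPES}")
        expected_binary = df["call"].map(lambda c: "GCB" if c == "GCB" else "non-GCB")
        if not (df["binary_call"] == expected_binary).all():
            raise ValidationError("binary_call must be the collapse of call")
        df[["p_ABC", "p_GCB"]] = p
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def calls(self) -> pd.Series:
        return self.data["call"]

    def binary_calls(self) -> pd.Series:
        return self.data["binary_call"]


def write_calls(path: str | Path, calls: CooCallSet) -> None:
    """Write a call set as TSV; re-reading reproduces it exactly."""
    df = calls.data.copy()
    df[["p_ABC", "p_GCB"]] = df[["p_ABC", "p_GCB"]].map(lambda v: format(v, ".17g"))
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_calls(path: str | Path) -> CooCallSet:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CooCallSet(df)
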
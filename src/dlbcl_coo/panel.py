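"""The 32-gene cell-of-origin panel and its housekeeping genes.

The assay measures 32 subtype-marker transcripts — 16 overexpressed in the
activated B-cell-like (ABC) subtype and 16 in the germinal center B-cell-like
(GCB) subtype — normalized against three housekeeping genes (IPO8, PGK1, TFRC)
that are stably expressed in DLBCL cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

ABC_GENES: tuple[str, ...] = (
    "GPR183", "IGHM", "P2RX5", "CCL22", "FCMR", "SH3BP5", "JADE3", "BATF",
    "BLNK", "DOCK10", "AICDA", "TOX2", "MIR155HG", "NLRP7", "FAM129C", "MPEG1",
)

GCB_GENES: tuple[str, ...] = (
    "BCL6", "CR2", "LMO2", "LRMP", "MME", "MYBL1", "RGS13", "TUBB2A",
    "UCHL1", "XIST", "CILP", "CD83", "STAG3", "RGCC", "VPREB3", "HOPX",
)

HOUSEKEEPING_GENES: tuple[str, ...] = ("IPO8", "PGK1", "TFRC")


def _norm(gene: str) -> str:
    """Canonical gene key: trimmed, upper-cased (matching is case-insensitive)."""
    return gene.strip().upper()


@dataclass(frozen=True)
class GenePanel:
    """A target-gene panel with subtype directions plus housekeeping genes.

    Parameters
    ----------
    abc_genes, gcb_genes
        Target genes overexpressed in the ABC / GCB subtype respectively.
    housekeeping_genes
        Reference genes used for ΔCt normalization.
    """

    abc_genes: tuple[str, ...] = ABC_GENES
    gcb_genes: tuple[str, ...] = GCB_GENES
    housekeeping_genes: tuple[str, ...] = HOUSEKEEPING_GENES

    def __post_init__(self) -> None:
        targets = [_norm(g) for g in self.abc_genes + self.gcb_genes]
        hk = [_norm(g) for g in self.housekeeping_genes]
        if len(set(targets)) != len(targets):
            raise ValueError("duplicate gene symbols among panel targets")
        if len(set(hk)) != len(hk):
            raise ValueError("duplicate housekeeping gene symbols")
        if set(targets) & set(hk):
            raise ValueError("housekeeping genes overlap with panel targets")
        if len(self.abc_genes) != len(self.gcb_genes):
            raise ValueError(
                "panel must be balanced: %d ABC vs %d GCB markers"
                % (len(self.abc_genes), len(self.gcb_genes))
            )

    @property
    def target_genes(self) -> tuple[str, ...]:
        return self.abc_genes + self.gcb_genes

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.target_genes + self.housekeeping_genes

    def direction(self, gene: str) -> str:
        """Return 'ABC' or 'GCB' for a target gene."""
        g = _norm(gene)
        if g in {_norm(x) for x in self.abc_genes}:
            return "ABC"
        if g in {_norm(x) for x in self.gcb_genes}:
            return "GCB"
        raise KeyError(f"{gene!r} is not a target gene of this panel")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "abc_genes": list(self.abc_genes),
                    "gcb_genes": list(self.gcb_genes),
                    "housekeeping_genes": list(self.housekeeping_genes),
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GenePanel":
        d = json.loads(Path(path).read_text())
        return cls(
            abc_genes=tuple(d["abc_genes"]),
            gcb_genes=tuple(d["gcb_genes"]),
            housekeeping_genes=tuple(d["housekeeping_genes"]),
        )


#: The published 32-gene assay panel (16 ABC + 16 GCB markers, IPO8/PGK1/TFRC).
DEFAULT_PANEL = GenePanel()
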
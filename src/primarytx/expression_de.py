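"""Threshold differential expression between two conditions.

No statistical model is fitted: a gene is called up in condition A versus B
when three strict filters all hold — RPKM fold change > 2, RPKM in A > 2 and
raw reads in A > 50 — with RPKM taken from the TEX-untreated libraries.  The
down direction is obtained by swapping the arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass
class DEParams:
    min_fold: float = 2.0
    min_rpkm_a: float = 2.0
    min_raw_a: int = 50
    use_untreated_only: bool = True

    def __post_init__(self) -> None:
        if min(self.min_fold, self.min_rpkm_a, self.min_raw_a) <= 0:
            raise ValueError("DE thresholds must be > 0")


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    cond_a: str
    cond_b: str
    rpkm_a: float
    rpkm_b: float
    raw_a: int
    fold: float  # rpkm_a / rpkm_b; inf when rpkm_b == 0 and rpkm_a > 0
    passes: bool
    missing_in_b: bool = False


#: Standard comparisons mirroring the study design: growth phase within each
#: soil-extract medium, and the root-exudate effect at middle stationary phase.
STANDARD_COMPARISONS = (
    ("SE#9h", "SE#6h"),
    ("RS#9h", "RS#6h"),
    ("RS#9h", "SE#9h"),
)


def differential_genes(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    params: DEParams | None = None,
    cond_a: str = "A",
    cond_b: str = "B",
) -> list[DEResult]:
    """Genes up in A versus B under the three-filter rule.

    ``expr_a``/``expr_b`` are expression tables with columns gene_id,
    raw_reads, rpkm (one TEX- library per condition).  Genes present in A but
    absent from B get fold = inf (flagged) when expressed in A.
    """
    params = params or DEParams()
    a = expr_a.set_index("gene_id")
    b = expr_b.set_index("gene_id")
    results: list[DEResult] = []
    for gid, row in a.iterrows():
        rpkm_a = float(row["rpkm"])
        raw_a = int(row["raw_reads"])
        missing = gid not in b.index
        if missing:
            rpkm_b = 0.0
        else:
            rpkm_b = float(b.loc[gid, "rpkm"])
        if rpkm_b > 0:
            fold = rpkm_a / rpkm_b
        elif rpkm_a > 0:
            fold = math.inf
        else:
            fold = 0.0
        passes = (
            fold > params.min_fold
            and rpkm_a > params.min_rpkm_a
            and raw_a > params.min_raw_a
        )
        results.append(
            DEResult(gid, cond_a, cond_b, rpkm_a, rpkm_b, raw_a, fold, passes, missing)
        )
    return results


def passing_genes(results: list[DEResult]) -> set[str]:
    return {r.gene_id for r in results if r.passes}


def common_set(list_1, list_2) -> set[str]:
    """Exact intersection of two gene-id collections."""
    return set(list_1) & set(list_2)


def de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": r.gene_id, "cond_a": r.cond_a, "cond_b": r.cond_b,
          "rpkm_a": r.rpkm_a, "rpkm_b": r.rpkm_b, "raw_a": r.raw_a,
          "fold": r.fold, "passes": r.passes, "missing_in_b": r.missing_in_b}
         for r in results],
        columns=["gene_id", "cond_a", "cond_b", "rpkm_a", "rpkm_b", "raw_a",
                 "fold", "passes", "missing_in_b"],
    )
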
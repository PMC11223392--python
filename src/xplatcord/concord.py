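"""Cross-platform DEG overlap, quadrant, and conflict classification.

Given per-gene differential-expression results from two platforms over a
shared gene universe, each gene is categorized as DEG in both, one, or
neither platform; the overlap/union bookkeeping, direction-conflict
counts, quadrant fractions, and Spearman fold-change correlations follow.

Conventions (chosen so the summary is internally consistent): "overlap"
counts genes flagged DEG on both platforms regardless of direction;
direction-split overlap rows count only sign-agreeing genes; "conflicting"
is evaluated over the union of DEGs (opposite log2FC signs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InputError, round_half_away
from .diffexpr import DEResults


@dataclass
class ConcordanceSummary:
    """Table-2-shaped overlap and union accounting for one condition."""

    condition: str
    n_deg_A: int
    n_up_A: int
    n_down_A: int
    n_deg_B: int
    n_up_B: int
    n_down_B: int
    overlap_total: int
    overlap_up: int
    overlap_down: int
    union_total: int
    conflicting: int
    pct_overlap_of_A: float | None
    pct_overlap_of_B: float | None
    pct_overlap_of_union: float | None
    pct_concordant_quadrants: float | None
    pct_conflicting: float | None
    spearman_rho_union: float | None
    spearman_rho_overlap: float | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "A": [self.n_deg_A, self.n_up_A, self.n_down_A],
                "B": [self.n_deg_B, self.n_up_B, self.n_down_B],
                "overlap": [self.overlap_total, self.overlap_up, self.overlap_down],
                "union": [self.union_total, np.nan, np.nan],
            },
            index=["total", "up", "down"],
        )
        return df

    def summary(self) -> str:
        lines = [
            f"DEG concordance at {self.condition}",
            f"  platform A: {self.n_deg_A} DEGs ({self.n_up_A} up / {self.n_down_A} down)",
            f"  platform B: {self.n_deg_B} DEGs ({self.n_up_B} up / {self.n_down_B} down)",
            f"  overlap: {self.overlap_total} ({self.overlap_up} up / {self.overlap_down} down)"
            f"   union: {self.union_total}   conflicting: {self.conflicting}",
        ]
        if self.pct_overlap_of_union is not None:
            lines.append(
                f"  overlap share: {self.pct_overlap_of_A:.0f}% of A, "
                f"{self.pct_overlap_of_B:.0f}% of B, "
                f"{self.pct_overlap_of_union:.0f}% of union"
            )
        if self.pct_concordant_quadrants is not None:
            lines.append(
                f"  concordant quadrants: {self.pct_concordant_quadrants:.1f}%"
                f"   conflicting: {self.pct_conflicting:.2f}%"
            )
        if self.spearman_rho_union is not None:
            lines.append(f"  Spearman rho (union): {self.spearman_rho_union:.2f}")
        if self.spearman_rho_overlap is not None:
            lines.append(f"  Spearman rho (overlap): {self.spearman_rho_overlap:.2f}")
        return "\n".join(lines)


def _direction(lfc: pd.Series) -> np.ndarray:
    return np.where(lfc > 0, "up", np.where(lfc < 0, "down", "zero"))


def classify_overlap(
    de_A: DEResults, de_B: DEResults, gene_universe: list[str] | None = None
) -> tuple[pd.DataFrame, ConcordanceSummary]:
    """Per-gene concordance records plus the overlap/union summary.

    Genes present in only one result are excluded and reported in the
    records' attrs under ``"excluded"``.
    """
    ids_a = set(de_A.feature_ids)
    ids_b = set(de_B.feature_ids)
    if gene_universe is None:
        gene_universe = sorted(ids_a & ids_b)
    universe = list(gene_universe)
    excluded = [g for g in universe if g not in ids_a or g not in ids_b]
    genes = [g for g in universe if g in ids_a and g in ids_b]

    ta = de_A.table.loc[genes]
    tb = de_B.table.loc[genes]
    records = pd.DataFrame(
        {
            "log2fc_A": ta["log2fc"],
            "log2fc_B": tb["log2fc"],
            "deg_A": ta["is_deg"].astype(bool),
            "deg_B": tb["is_deg"].astype(bool),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    records["direction_A"] = _direction(records["log2fc_A"])
    records["direction_B"] = _direction(records["log2fc_B"])
    records["category"] = np.select(
        [
            records["deg_A"] & records["deg_B"],
            records["deg_A"] & ~records["deg_B"],
            ~records["deg_A"] & records["deg_B"],
        ],
        ["both", "A_only", "B_only"],
        default="neither",
    )
    records["direction_concordant"] = (
        records["direction_A"] == records["direction_B"]
    ) & (records["direction_A"] != "zero")
    records.attrs["excluded"] = excluded

    summary = _summarize(records, condition=de_A.contrast)
    return records, summary


def _summarize(records: pd.DataFrame, condition: str) -> ConcordanceSummary:
    deg_a = records["deg_A"]
    deg_b = records["deg_B"]
    both = deg_a & deg_b
    union = deg_a | deg_b

    n_a = int(deg_a.sum())
    n_b = int(deg_b.sum())
    overlap_total = int(both.sum())
    union_total = int(union.sum())
    up_a = int((deg_a & (records["log2fc_A"] > 0)).sum())
    down_a = int((deg_a & (records["log2fc_A"] < 0)).sum())
    up_b = int((deg_b & (records["log2fc_B"] > 0)).sum())
    down_b = int((deg_b & (records["log2fc_B"] < 0)).sum())
    agree = records["direction_concordant"]
    overlap_up = int((both & agree & (records["log2fc_A"] > 0)).sum())
    overlap_down = int((both & agree & (records["log2fc_A"] < 0)).sum())
    conflicting = int(
        (union & (np.sign(records["log2fc_A"]) != np.sign(records["log2fc_B"]))).sum()
    )

    def pct(num, den, nd=0):
        return round_half_away(100.0 * num / den, nd) if den else None

    concordant = int((union & agree).sum())
    rho_union = fc_spearman(records, "union_degs")
    rho_overlap = fc_spearman(records, "overlap_degs")
    return ConcordanceSummary(
        condition=condition,
        n_deg_A=n_a,
        n_up_A=up_a,
        n_down_A=down_a,
        n_deg_B=n_b,
        n_up_B=up_b,
        n_down_B=down_b,
        overlap_total=overlap_total,
        overlap_up=overlap_up,
        overlap_down=overlap_down,
        union_total=union_total,
        conflicting=conflicting,
        pct_overlap_of_A=pct(overlap_total, n_a),
        pct_overlap_of_B=pct(overlap_total, n_b),
        pct_overlap_of_union=pct(overlap_total, union_total),
        pct_concordant_quadrants=pct(concordant, union_total, nd=1),
        pct_conflicting=pct(conflicting, union_total, nd=2),
        spearman_rho_union=rho_union,
        spearman_rho_overlap=rho_overlap,
    )


def summarize_from_counts(
    condition: str,
    n_deg_A: int,
    n_up_A: int,
    n_down_A: int,
    n_deg_B: int,
    n_up_B: int,
    n_down_B: int,
    overlap_total: int,
    overlap_up: int,
    overlap_down: int,
    conflicting: int,
) -> ConcordanceSummary:
    """Build the summary arithmetic directly from printed DEG counts."""
    union_total = n_deg_A + n_deg_B - overlap_total
    concordant = union_total - conflicting

    def pct(num, den, nd=0):
        return round_half_away(100.0 * num / den, nd) if den else None

    return ConcordanceSummary(
        condition=condition,
        n_deg_A=n_deg_A,
        n_up_A=n_up_A,
        n_down_A=n_down_A,
        n_deg_B=n_deg_B,
        n_up_B=n_up_B,
        n_down_B=n_down_B,
        overlap_total=overlap_total,
        overlap_up=overlap_up,
        overlap_down=overlap_down,
        union_total=union_total,
        conflicting=conflicting,
        pct_overlap_of_A=pct(overlap_total, n_deg_A),
        pct_overlap_of_B=pct(overlap_total, n_deg_B),
        pct_overlap_of_union=pct(overlap_total, union_total),
        pct_concordant_quadrants=pct(concordant, union_total, nd=1),
        pct_conflicting=pct(conflicting, union_total, nd=2),
        spearman_rho_union=None,
        spearman_rho_overlap=None,
    )


def fc_spearman(records: pd.DataFrame, subset: str = "union_degs") -> float | None:
    """Spearman rank correlation of the two platforms' log2 fold changes.

    ``subset``: ``union_degs`` (DEG on either platform), ``overlap_degs``
    (DEG on both), or ``all``. Returns None for fewer than 3 records or a
    constant vector.
    """
    if subset == "union_degs":
        sub = records[records["deg_A"] | records["deg_B"]]
    elif subset == "overlap_degs":
        sub = records[records["deg_A"] & records["deg_B"]]
    elif subset == "all":
        sub = records
    else:
        raise InputError(f"unknown subset {subset!r}")
    if len(sub) < 3:
        return None
    x = sub["log2fc_A"].to_numpy()
    y = sub["log2fc_B"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def quadrant_table(records: pd.DataFrame) -> dict:
    """Quadrant counts of union DEGs by fold-change sign on each platform.

    Genes with a log2FC of exactly 0 on either axis are counted separately
    under ``on_axis`` and treated as non-concordant.
    """
    union = records[records["deg_A"] | records["deg_B"]]
    a = np.sign(union["log2fc_A"].to_numpy())
    b = np.sign(union["log2fc_B"].to_numpy())
    counts = {
        "up_up": int(((a > 0) & (b > 0)).sum()),
        "down_down": int(((a < 0) & (b < 0)).sum()),
        "up_down": int(((a > 0) & (b < 0)).sum()),
        "down_up": int(((a < 0) & (b > 0)).sum()),
        "on_axis": int(((a == 0) | (b == 0)).sum()),
    }
    n = len(union)
    counts["union_total"] = n
    counts["concordant_fraction"] = (
        (counts["up_up"] + counts["down_down"]) / n if n else 0.0
    )
    return counts


def write_summary_tsv(summary: ConcordanceSummary, path: str | Path) -> None:
    pd.Series(vars(summary)).to_csv(path, sep="\t", header=False)
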
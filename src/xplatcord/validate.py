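"""RT-qPCR validation taxonomy for cross-platform DEGs.

DEGs at the validated condition are stratified into genesets — I (DEG on
both platforms), II (array only), III (sequencing only), REF (non-DEG
panel genes) — and each DEG is classified against its qPCR result:

* ``not_detected`` — no amplification signal;
* ``not_confirmed`` — detected but not significant in qPCR;
* ``confirmed`` — significant with a matching fold-change direction;
* ``conflicting`` — significant but opposite in direction.

Direction matching is evaluated at two granularities, mirroring how such
validation tables are reported. The overall (union) category compares the
qPCR direction with *both* platforms' fold-change directions — a gene is
confirmed only when all three systems agree — and conflicts are subtyped
by which platform(s) the qPCR call opposes. The per-platform summary
columns compare only against their own platform's direction, so a gene
can be confirmed for the sequencing platform while conflicting overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import InputError, round_half_away
from .diffexpr import DEResults
from .qpcr import QpcrResults

GENESETS = ("I", "II", "III", "REF")
CATEGORIES = ("confirmed", "conflicting", "not_confirmed", "not_detected")
CONFLICT_SUBTYPES = ("both_vs_qpcr", "affy_vs_qpcr", "tempo_vs_qpcr")


def assign_genesets(
    de_A: DEResults, de_B: DEResults, reference_genes: list[str] = ()
) -> pd.Series:
    """Partition panel genes into validation genesets by their DEG flags.

    A supplied reference gene that turns out to be a DEG is kept in its
    DEG geneset with a warning.
    """
    genes = [g for g in de_A.feature_ids if g in set(de_B.feature_ids)]
    flags_a = de_A.table.loc[genes, "is_deg"].astype(bool)
    flags_b = de_B.table.loc[genes, "is_deg"].astype(bool)
    geneset = pd.Series("REF", index=pd.Index(genes, name="gene_id"), name="geneset")
    geneset[flags_a & flags_b] = "I"
    geneset[flags_a & ~flags_b] = "II"
    geneset[~flags_a & flags_b] = "III"
    bad_refs = [g for g in reference_genes if g in geneset.index and geneset[g] != "REF"]
    if bad_refs:
        import warnings

        warnings.warn(f"supplied reference gene(s) are DEGs: {bad_refs[:5]}")
    return geneset


def _direction(x: float) -> str:
    return "up" if x > 0 else "down" if x < 0 else "zero"


def _category(dir_q, q_sig, detected, platform_dirs) -> str:
    if not detected:
        return "not_detected"
    if not q_sig:
        return "not_confirmed"
    return "confirmed" if all(d == dir_q for d in platform_dirs) else "conflicting"


def classify_validation(
    assignment: pd.Series,
    de_A: DEResults,
    de_B: DEResults,
    qpcr: QpcrResults,
    condition: str = "HD",
) -> pd.DataFrame:
    """Classify every assigned DEG against its qPCR call at ``condition``.

    Returns one row per DEG gene with the overall ``category`` (qPCR vs
    both platforms' fold-change directions), a ``conflict_subtype`` for
    conflicting genes, and column-specific categories ``category_vs_A``,
    ``category_vs_B`` (present when the gene is in the respective column's
    genesets) and ``category_vs_both`` (geneset I only).
    """
    deg_genes = [g for g in assignment.index if assignment[g] in ("I", "II", "III")]
    q = qpcr.table[qpcr.table["condition"] == condition].set_index("gene_id")
    missing = [g for g in deg_genes if g not in q.index]
    if missing:
        raise InputError(f"qPCR result missing for DEG gene(s): {missing[:5]}")
    undetected = set(qpcr.globally_undetected)

    rows = []
    for g in deg_genes:
        gs = assignment[g]
        dir_a = _direction(float(de_A.table.loc[g, "log2fc"]))
        dir_b = _direction(float(de_B.table.loc[g, "log2fc"]))
        detected = bool(q.loc[g, "detected"]) and g not in undetected
        q_sig = bool(q.loc[g, "significant"]) and detected
        lfc_q = q.loc[g, "log2fc"]
        dir_q = _direction(float(lfc_q)) if detected and np.isfinite(lfc_q) else None

        category = _category(dir_q, q_sig, detected, (dir_a, dir_b))
        subtype = None
        if category == "conflicting":
            if dir_a == dir_b:
                subtype = "both_vs_qpcr"
            elif dir_q != dir_a:
                subtype = "affy_vs_qpcr"
            else:
                subtype = "tempo_vs_qpcr"
        rows.append(
            {
                "gene_id": g,
                "geneset": gs,
                "direction_A": dir_a if gs in ("I", "II") else None,
                "direction_B": dir_b if gs in ("I", "III") else None,
                "direction_fc_A": dir_a,
                "direction_fc_B": dir_b,
                "direction_q": dir_q,
                "q_significant": q_sig,
                "detected": detected,
                "category": category,
                "conflict_subtype": subtype,
                "category_vs_A": _category(dir_q, q_sig, detected, (dir_a,))
                if gs in ("I", "II")
                else None,
                "category_vs_B": _category(dir_q, q_sig, detected, (dir_b,))
                if gs in ("I", "III")
                else None,
                "category_vs_both": _category(dir_q, q_sig, detected, (dir_a, dir_b))
                if gs == "I"
                else None,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class ValidationSummary:
    """Four-column validation table: union / A / B / both."""

    counts: pd.DataFrame  # rows: N, confirmed, conflicting, not_confirmed, not_detected
    pct: pd.DataFrame  # percentages of column N (and of detected genes)
    subtype_counts: dict

    def summary(self) -> str:
        lines = ["qPCR validation of platform DEGs"]
        for col in self.counts.columns:
            n = self.counts.loc["N", col]
            conf = self.counts.loc["confirmed", col]
            pct = self.pct.loc["confirmed", col]
            lines.append(f"  {col}: {conf}/{n} confirmed ({pct}%)")
        st = self.subtype_counts
        lines.append(
            "  conflicts: "
            f"{st.get('both_vs_qpcr', 0)} vs both, "
            f"{st.get('affy_vs_qpcr', 0)} vs array, "
            f"{st.get('tempo_vs_qpcr', 0)} vs seq"
        )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.astype(object).copy()
        for row in ("confirmed", "not_confirmed"):
            for col in out.columns:
                out.loc[row, col] = (
                    f"{self.counts.loc[row, col]} ({self.pct.loc[row, col]}%)"
                )
        out.to_csv(path, sep="\t")


def summarize_validation(records: pd.DataFrame) -> ValidationSummary:
    """Aggregate validation records into the four-column summary.

    Column membership and category source: union = all DEG records using
    the overall ``category``; A = genesets I+II using ``category_vs_A``;
    B = genesets I+III using ``category_vs_B``; both = geneset I using
    ``category_vs_both``. Percentages are relative to the column N
    (including not-detected genes), rounded to one decimal half away from
    zero; ``pct`` also carries a ``*_of_detected`` block with
    detected-only denominators.
    """
    cols = {
        "union": records["category"],
        "A": records.loc[records["geneset"].isin(["I", "II"]), "category_vs_A"],
        "B": records.loc[records["geneset"].isin(["I", "III"]), "category_vs_B"],
        "both": records.loc[records["geneset"] == "I", "category_vs_both"],
    }
    counts = pd.DataFrame(index=["N", *CATEGORIES], columns=list(cols), dtype=int)
    pct = pd.DataFrame(
        index=[*CATEGORIES, *(f"{c}_of_detected" for c in CATEGORIES)],
        columns=list(cols),
        dtype=object,
    )
    for name, cat in cols.items():
        n = len(cat)
        counts.loc["N", name] = n
        n_detected = int((cat != "not_detected").sum())
        for c in CATEGORIES:
            k = int((cat == c).sum())
            counts.loc[c, name] = k
            pct.loc[c, name] = round_half_away(100.0 * k / n, 1) if n else None
            pct.loc[f"{c}_of_detected", name] = (
                round_half_away(100.0 * k / n_detected, 1) if n_detected else None
            )
    subtypes = {
        s: int((records["conflict_subtype"] == s).sum()) for s in CONFLICT_SUBTYPES
    }
    return ValidationSummary(counts.astype(int), pct, subtypes)


def summarize_from_counts(
    n: int, confirmed: int, conflicting: int, not_confirmed: int, not_detected: int
) -> dict:
    """Percentage arithmetic for one summary column fed printed counts."""
    if confirmed + conflicting + not_confirmed + not_detected != n:
        raise InputError("validation counts do not sum to N")
    n_detected = n - not_detected
    return {
        "N": n,
        "pct_confirmed": round_half_away(100.0 * confirmed / n, 1),
        "pct_not_confirmed": round_half_away(100.0 * not_confirmed / n, 1),
        "pct_confirmed_of_detected": round_half_away(100.0 * confirmed / n_detected, 1)
        if n_detected
        else None,
        "pct_not_confirmed_of_detected": round_half_away(
            100.0 * not_confirmed / n_detected, 1
        )
        if n_detected
        else None,
    }
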
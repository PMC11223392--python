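"""RT-qPCR processing: detection calls, reference-gene stability, and
comparative ddCT quantification with per-gene significance.

The quantification chain is the classic comparative CT method: per well,
dCT = CT(target) - mean CT(references); per condition, ddCT is the mean
dCT difference to the control condition, and log2 fold change = -ddCT
(amplification efficiency fixed at perfect doubling). Reference genes are
chosen by the model-based stability measure of Andersen et al.: per-group
intergroup deviation (variance-shrunken) plus an intragroup standard-error
term, lower is more stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InputError, SampleDesign


@dataclass
class CtTable:
    """Gene-by-sample cycle-threshold values; NaN encodes "not detected"."""

    values: pd.DataFrame
    detection_limit: float = 40.0
    reference_candidates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if (finite < 0).any():
            raise InputError("negative CT values are not valid")
        if (finite > 45).any():
            raise InputError("CT values above 45 cycles are not valid")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def undetected_genes(self) -> list[str]:
        mask = self.values.isna().all(axis=1)
        return list(self.values.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        long = self.values.stack(future_stack=True).rename("ct").reset_index()
        long.columns = ["gene_id", "sample_id", "ct"]
        long["detected"] = long["ct"].notna()
        long.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(
        cls, path: str | Path, detection_limit: float = 40.0, reference_candidates=()
    ) -> "CtTable":
        long = pd.read_csv(path, sep="\t", na_values=["NA"])
        wide = long.pivot(index="gene_id", columns="sample_id", values="ct")
        wide.columns.name = None
        return cls(wide, detection_limit, list(reference_candidates))


def detect_calls(raw_ct: CtTable, detection_limit: float | None = None) -> CtTable:
    """Flag wells above the detection limit (default 40 cycles) as n.d.

    Missing CT values stay n.d.; a gene with no detected well in any
    sample is reported through :attr:`CtTable.undetected_genes`.
    """
    limit = raw_ct.detection_limit if detection_limit is None else detection_limit
    values = raw_ct.values.where(raw_ct.values <= limit)
    return CtTable(values, limit, list(raw_ct.reference_candidates))


@dataclass
class StabilityResult:
    stability: pd.Series  # gene -> stability value, ascending = more stable
    selected_references: list

    def __repr__(self) -> str:
        return f"StabilityResult(selected={self.selected_references})"


def normfinder_stability(
    ct: CtTable,
    design: SampleDesign,
    candidates: list[str] | None = None,
    k: int = 2,
) -> StabilityResult:
    """Model-based reference-gene stability over all sample groups.

    Per group, CT values are double-centered (gene and sample effects
    removed); the per-gene group deviation d_gi is shrunken toward zero by
    its sampling variance, and stability is the group average of
    |shrunken d_gi| plus the intragroup standard error. Ties are broken
    lexicographically by gene id.
    """
    if candidates is None:
        candidates = list(ct.reference_candidates)
    candidates = list(candidates)
    if not candidates:
        raise InputError("no reference-gene candidates supplied")
    missing = set(candidates) - set(ct.gene_ids)
    if missing:
        raise InputError(f"candidates absent from CT table: {sorted(missing)[:5]}")
    sub = ct.values.loc[candidates, design.sample_ids]
    with_nd = sub.index[sub.isna().any(axis=1)]
    if len(with_nd):
        warnings.warn(
            f"dropping {len(with_nd)} candidate(s) with non-detected wells: "
            f"{list(with_nd)[:5]}"
        )
        sub = sub.drop(index=with_nd)
    genes = list(sub.index)
    G = len(genes)
    if G < k:
        raise InputError(f"only {G} eligible candidates; {k} required")
    groups = design.conditions
    I = len(groups)

    group_means = np.empty((G, I))
    samp_var = np.empty((G, I))
    for i, cond in enumerate(groups):
        cols = design.samples(cond)
        Y = sub[cols].to_numpy(dtype=float)
        n_i = Y.shape[1]
        gene_mean = Y.mean(axis=1, keepdims=True)
        sample_mean = Y.mean(axis=0, keepdims=True)
        grand = Y.mean()
        resid = Y - gene_mean - sample_mean + grand
        if n_i > 1 and G > 1:
            s2 = (resid**2).sum(axis=1) / (n_i - 1) * (G / (G - 1))
        else:
            s2 = np.zeros(G)
        group_means[:, i] = gene_mean[:, 0]
        samp_var[:, i] = s2 / n_i

    a = group_means - group_means.mean(axis=0, keepdims=True)
    d = a - a.mean(axis=1, keepdims=True)
    if G > 1 and I > 1:
        gamma2 = max(0.0, (d**2).sum() / ((G - 1) * (I - 1)) - samp_var.mean())
    else:
        gamma2 = 0.0
    denom = gamma2 + samp_var
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
    d_tilde = d * shrink
    stability_vals = (np.abs(d_tilde) + np.sqrt(samp_var)).mean(axis=1)

    stability = pd.Series(stability_vals, index=genes, name="stability")
    order = sorted(genes, key=lambda g: (stability[g], g))
    return StabilityResult(stability, order[:k])


# ---------------------------------------------------------------------------
# comparative ddCT chain


def _delta_ct(ct: CtTable, references: list[str]) -> pd.DataFrame:
    refs = list(references)
    missing = set(refs) - set(ct.gene_ids)
    if missing:
        raise InputError(f"reference genes absent from CT table: {sorted(missing)}")
    ref_block = ct.values.loc[refs]
    if ref_block.isna().any().any():
        raise InputError("reference genes must be detected in every sample")
    ref_mean = ref_block.mean(axis=0)
    return ct.values.subtract(ref_mean, axis=1)


@dataclass
class QpcrResults:
    """Per gene x condition ddCT fold changes and significance."""

    table: pd.DataFrame  # columns: gene_id, condition, delta_ct_mean, ddct,
    #          log2fc, linear_fc, p, significant, detected
    references: list
    stability: pd.Series | None = None
    control: str = "CA"

    def _at(self, condition: str) -> pd.DataFrame:
        sub = self.table[self.table["condition"] == condition]
        return sub.set_index("gene_id")

    def log2fc(self, condition: str) -> pd.Series:
        return self._at(condition)["log2fc"]

    def significant(self, condition: str) -> pd.Series:
        return self._at(condition)["significant"]

    def detected(self, condition: str) -> pd.Series:
        return self._at(condition)["detected"]

    @property
    def globally_undetected(self) -> list[str]:
        per_gene = self.table.groupby("gene_id")["detected"].any()
        return list(per_gene.index[~per_gene])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary(self) -> str:
        n_genes = self.table["gene_id"].nunique()
        lines = [
            "qPCR comparative ddCT results",
            f"  genes: {n_genes}   control: {self.control}",
            f"  references: {', '.join(self.references)}",
        ]
        for cond, sub in self.table.groupby("condition"):
            n_sig = int(sub["significant"].sum())
            lines.append(f"  {cond}: {n_sig} significant of {len(sub)}")
        return "\n".join(lines)


class QpcrModel:
    """qPCR experiment: CT table plus design; ``fit`` runs the ddCT chain.

    Parameters
    ----------
    ct
        CT table (NaN = not detected). Detection calls are applied at the
        table's detection limit.
    design
        Sample-to-condition map; the reference condition is the ddCT
        control.
    references
        ``"auto"`` selects ``k_refs`` genes by stability among
        ``candidates`` (default: the table's flagged candidates); or pass
        an explicit list of gene ids.
    """

    def __init__(
        self,
        ct: CtTable,
        design: SampleDesign,
        references: str | list = "auto",
        candidates: list | None = None,
        k_refs: int = 2,
    ):
        self.ct = detect_calls(ct)
        self.design = design
        self._references = references
        self._candidates = candidates
        self.k_refs = k_refs

    def fit(self, control: str | None = None) -> QpcrResults:
        control = control or self.design.reference_condition
        if control not in self.design.conditions:
            raise InputError(f"control condition {control!r} absent from design")
        stability = None
        if self._references == "auto":
            stab = normfinder_stability(
                self.ct, self.design, self._candidates, k=self.k_refs
            )
            references = stab.selected_references
            stability = stab.stability
        else:
            references = list(self._references)
        dct = _delta_ct(self.ct, references)

        conditions = [c for c in self.design.conditions if c != control]
        ctrl_cols = self.design.samples(control)
        rows = []
        for gene in self.ct.gene_ids:
            g_dct = dct.loc[gene]
            ctrl_vals = g_dct[ctrl_cols].dropna()
            group_vals = {
                c: g_dct[self.design.samples(c)].dropna() for c in conditions
            }
            # pooled residual variance across all groups with >= 2 wells
            all_groups = {control: ctrl_vals, **group_vals}
            ss = 0.0
            df = 0
            for vals in all_groups.values():
                if len(vals) >= 2:
                    ss += float(((vals - vals.mean()) ** 2).sum())
                    df += len(vals) - 1
            s2 = ss / df if df > 0 else np.nan

            for cond in conditions:
                vals = group_vals[cond]
                detected = len(vals) > 0 and len(ctrl_vals) > 0
                if detected:
                    ddct = float(vals.mean() - ctrl_vals.mean())
                    log2fc = -ddct
                    lin = 2.0**log2fc
                    dmean = float(vals.mean())
                else:
                    ddct = log2fc = lin = dmean = np.nan
                p = np.nan
                if len(vals) >= 2 and len(ctrl_vals) >= 2 and df > 0:
                    se = np.sqrt(s2 * (1.0 / len(vals) + 1.0 / len(ctrl_vals)))
                    diff = float(vals.mean() - ctrl_vals.mean())
                    if se < 1e-12:
                        p = 0.0 if abs(diff) > 1e-9 else 1.0
                    else:
                        t = diff / se
                        p = 2.0 * stats.t.sf(abs(t), df)
                significant = bool(detected and np.isfinite(p) and p < 0.05)
                rows.append(
                    {
                        "gene_id": gene,
                        "condition": cond,
                        "delta_ct_mean": dmean,
                        "ddct": ddct,
                        "log2fc": log2fc,
                        "linear_fc": lin,
                        "p": p,
                        "significant": significant,
                        "detected": detected,
                    }
                )
        table = pd.DataFrame(rows)
        return QpcrResults(table, references, stability, control)


# ---------------------------------------------------------------------------
# functional wrappers matching the pipeline stage names


def ddct_log2fc(
    ct: CtTable,
    refs: StabilityResult | list,
    design: SampleDesign,
    control: str = "CA",
) -> QpcrResults:
    references = (
        refs.selected_references if isinstance(refs, StabilityResult) else list(refs)
    )
    return QpcrModel(ct, design, references=references).fit(control=control)


def qpcr_significance(
    ct: CtTable,
    refs: StabilityResult | list,
    design: SampleDesign,
    contrast: str,
    control: str = "CA",
) -> pd.Series:
    """Per-gene p-value of the contrast-vs-control dCT linear model."""
    res = ddct_log2fc(ct, refs, design, control=control)
    return res._at(contrast)["p"]
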
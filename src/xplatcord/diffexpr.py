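"""Normalization and platform-specific differential expression.

Two fitted models, one per platform, each returning a :class:`DEResults`:

* :class:`CountsDEModel` — negative-binomial Wald test for targeted
  sequencing counts. Size factors are the CPM factors (library size /
  1e6); per-gene dispersion is a method-of-moments estimate (variance =
  mu + alpha * mu^2) with a floor; the Wald statistic for the log fold
  change is referred to a t distribution with n_A + n_B - 2 degrees of
  freedom as a small-sample moderation. DEG rule: FDR < 0.05 and
  |log2FC| > 0.5 (strict).
* :class:`ArrayDEModel` — per-gene two-sample t-test on log2 intensities
  (pooled variance by default, Welch optional). DEG rule: unadjusted
  p < 0.05 and |linear FC| > 2 (strict); a BH-adjusted column is computed
  alongside but does not enter the DEG call, matching standard microarray
  console output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, InputError, SampleDesign

DISPERSION_FLOOR = 1e-8


def cpm_normalize(matrix: ExpressionMatrix, log: bool = False) -> ExpressionMatrix:
    """Counts-per-million normalization, optionally log2(cpm + 1)."""
    if matrix.kind != "counts":
        raise InputError(f"CPM normalization requires counts, got {matrix.kind!r}")
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise InputError(f"sample(s) with zero total count: {list(zero)}")
    cpm = matrix.values * 1e6 / totals
    if log:
        return ExpressionMatrix(np.log2(cpm + 1.0), kind="log2_cpm")
    return ExpressionMatrix(cpm, kind="cpm")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DegCriteria:
    """Platform-specific DEG thresholds (strict inequalities)."""

    mode: str  # {"seq", "array"}
    fdr_max: float = 0.05
    p_max: float = 0.05
    min_abs_log2fc: float = 0.5
    min_abs_linear_fc: float = 2.0

    def __post_init__(self):
        if self.mode not in ("seq", "array"):
            raise InputError(f"unknown criteria mode {self.mode!r}")

    def flags(self, table: pd.DataFrame) -> pd.Series:
        if self.mode == "seq":
            if table["fdr"].isna().all():
                raise InputError("seq criteria require an FDR column")
            return (table["fdr"] < self.fdr_max) & (
                table["log2fc"].abs() > self.min_abs_log2fc
            )
        return (table["p"] < self.p_max) & (
            table["linear_fc"].abs() > self.min_abs_linear_fc
        )


SEQ_CRITERIA = DegCriteria("seq")
ARRAY_CRITERIA = DegCriteria("array")


class DEResults:
    """Differential-expression estimates for one contrast.

    ``table`` has one row per feature: base_mean, log2fc, linear_fc, p,
    fdr (NaN when not part of the platform's DEG rule), is_deg, direction.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        contrast: str,
        reference: str,
        platform: str,
        criteria: DegCriteria | None = None,
    ):
        self.table = table
        self.contrast = contrast
        self.reference = reference
        self.platform = platform
        self.criteria = criteria

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def deg_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_deg"]])

    @property
    def n_deg(self) -> int:
        return int(self.table["is_deg"].sum())

    @property
    def n_up(self) -> int:
        return int((self.table["is_deg"] & (self.table["log2fc"] > 0)).sum())

    @property
    def n_down(self) -> int:
        return int((self.table["is_deg"] & (self.table["log2fc"] < 0)).sum())

    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    def subset(self, features) -> "DEResults":
        return DEResults(
            self.table.loc[list(features)].copy(),
            self.contrast,
            self.reference,
            self.platform,
            self.criteria,
        )

    def summary(self) -> str:
        crit = ""
        if self.criteria is not None:
            if self.criteria.mode == "seq":
                crit = (
                    f"FDR < {self.criteria.fdr_max}, "
                    f"|log2FC| > {self.criteria.min_abs_log2fc}"
                )
            else:
                crit = (
                    f"p < {self.criteria.p_max}, "
                    f"|linear FC| > {self.criteria.min_abs_linear_fc}"
                )
        lines = [
            f"Differential expression ({self.platform}): "
            f"{self.contrast} vs {self.reference}",
            f"  features tested: {len(self.table)}",
            f"  DEG rule: {crit}",
            f"  DEGs: {self.n_deg} ({self.n_up} up / {self.n_down} down)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, contrast="NA", reference="CA", platform="NA") -> "DEResults":
        table = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        table["is_deg"] = table["is_deg"].astype(bool)
        return cls(table, contrast, reference, platform)


def call_degs(de: DEResults, criteria: DegCriteria) -> DEResults:
    """Apply DEG thresholds, returning results with is_deg/direction set."""
    table = de.table.copy()
    table["is_deg"] = criteria.flags(table)
    table["direction"] = np.where(
        table["log2fc"] > 0, "up", np.where(table["log2fc"] < 0, "down", "zero")
    )
    return DEResults(table, de.contrast, de.reference, de.platform, criteria)


class CountsDEModel:
    """NB Wald differential expression for a count matrix."""

    def __init__(self, counts: ExpressionMatrix, design: SampleDesign):
        if counts.kind != "counts":
            raise InputError("CountsDEModel requires a counts matrix")
        self.counts = counts
        self.design = design
        totals = counts.values.sum(axis=0)
        if (totals == 0).any():
            raise InputError("sample with zero total count")
        self.size_factors = totals / 1e6  # CPM factors

    def fit(
        self,
        contrast: str,
        criteria: DegCriteria = SEQ_CRITERIA,
        max_dispersion: float = 10.0,
    ) -> DEResults:
        design = self.design
        ref = design.reference_condition
        design.require_replicates(contrast, 2)
        design.require_replicates(ref, 2)
        cols_b = design.samples(contrast)
        cols_a = design.samples(ref)

        k = self.counts.values
        s = self.size_factors
        ka = k[cols_a].to_numpy(dtype=float)
        kb = k[cols_b].to_numpy(dtype=float)
        sa = s[cols_a].to_numpy(dtype=float)
        sb = s[cols_b].to_numpy(dtype=float)
        na, nb = len(cols_a), len(cols_b)

        sum_a = ka.sum(axis=1)
        sum_b = kb.sum(axis=1)
        all_zero = (sum_a + sum_b) == 0
        # group abundance = mean of size-factor-normalized counts (CPM
        # mean), with a half-count continuity correction for empty groups
        qa = (ka / sa[None, :]).mean(axis=1)
        qb = (kb / sb[None, :]).mean(axis=1)
        qa = np.where(qa == 0, 0.5 / sa.sum(), qa)
        qb = np.where(qb == 0, 0.5 / sb.sum(), qb)

        # method-of-moments dispersion pooled over both groups
        mu_a = sa[None, :] * qa[:, None]
        mu_b = sb[None, :] * qb[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            chi_a = ((ka - mu_a) ** 2 - mu_a) / mu_a**2
            chi_b = ((kb - mu_b) ** 2 - mu_b) / mu_b**2
        chi = np.concatenate([chi_a, chi_b], axis=1)
        dof = max(na + nb - 2, 1)
        alpha = np.nansum(np.where(np.isfinite(chi), chi, 0.0), axis=1) / dof
        alpha = np.clip(alpha, DISPERSION_FLOOR, max_dispersion)

        # delta-method variance of the mean of normalized counts:
        # Var(q) = (1/n^2) sum_j (q / s_j + alpha q^2)
        var_qa = (qa[:, None] / sa[None, :] + alpha[:, None] * qa[:, None] ** 2).sum(
            axis=1
        ) / na**2
        var_qb = (qb[:, None] / sb[None, :] + alpha[:, None] * qb[:, None] ** 2).sum(
            axis=1
        ) / nb**2
        with np.errstate(divide="ignore", invalid="ignore"):
            var_log = var_qa / qa**2 + var_qb / qb**2
            z = (np.log(qb) - np.log(qa)) / np.sqrt(var_log)
        p = 2.0 * stats.t.sf(np.abs(z), df=max(na + nb - 2, 1))
        log2fc = np.log2(qb / qa)
        p = np.where(all_zero, 1.0, p)
        log2fc = np.where(all_zero, 0.0, log2fc)

        base_mean = (k.to_numpy(dtype=float) / s.to_numpy()[None, :]).mean(axis=1)
        table = pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2fc": log2fc,
                "linear_fc": np.sign(log2fc) * np.power(2.0, np.abs(log2fc)),
                "p": p,
                "fdr": bh_adjust(p),
                "dispersion": alpha,
            },
            index=self.counts.values.index,
        )
        table.loc[table["linear_fc"] == 0, "linear_fc"] = 1.0
        res = DEResults(table, contrast, ref, platform="seq")
        return call_degs(res, criteria)


class ArrayDEModel:
    """Per-gene t-test differential expression for log2 intensities."""

    def __init__(self, intensities: ExpressionMatrix, design: SampleDesign):
        if intensities.kind not in ("log2_intensity", "log2_cpm"):
            raise InputError("ArrayDEModel requires log2-scale intensities")
        self.intensities = intensities
        self.design = design

    def fit(
        self,
        contrast: str,
        criteria: DegCriteria = ARRAY_CRITERIA,
        welch: bool = False,
    ) -> DEResults:
        design = self.design
        ref = design.reference_condition
        design.require_replicates(contrast, 2)
        design.require_replicates(ref, 2)
        xa = self.intensities.values[design.samples(ref)].to_numpy(dtype=float)
        xb = self.intensities.values[design.samples(contrast)].to_numpy(dtype=float)

        log2fc = xb.mean(axis=1) - xa.mean(axis=1)
        import warnings as _warnings

        with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
            # noise-free replicates trigger a harmless precision warning;
            # the resulting NaN p-values are mapped to 1 below
            _warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(xb, xa, axis=1, equal_var=not welch)
        p = np.where(np.isfinite(p), p, 1.0)  # constant genes -> p = 1

        table = pd.DataFrame(
            {
                "base_mean": np.concatenate([xa, xb], axis=1).mean(axis=1),
                "log2fc": log2fc,
                "linear_fc": np.where(log2fc == 0, 1.0, np.sign(log2fc) * np.power(2.0, np.abs(log2fc))),
                "p": p,
                # BH column reported for reference; the array DEG rule is
                # deliberately unadjusted
                "fdr_reference_only": bh_adjust(p),
                "fdr": np.nan,
            },
            index=self.intensities.values.index,
        )
        res = DEResults(table, contrast, ref, platform="array")
        return call_degs(res, criteria)


# ---------------------------------------------------------------------------
# functional wrappers matching the pipeline stage names


def nb_wald_de(
    counts: ExpressionMatrix,
    design: SampleDesign,
    contrast: str,
    criteria: DegCriteria = SEQ_CRITERIA,
) -> DEResults:
    return CountsDEModel(counts, design).fit(contrast, criteria=criteria)


def array_lm_de(
    intensities: ExpressionMatrix,
    design: SampleDesign,
    contrast: str,
    criteria: DegCriteria = ARRAY_CRITERIA,
    welch: bool = False,
) -> DEResults:
    return ArrayDEModel(intensities, design).fit(contrast, criteria=criteria, welch=welch)
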
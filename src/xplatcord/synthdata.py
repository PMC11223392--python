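"""Matched synthetic dual-platform datasets with known ground truth.

Emulates the study design the analysis assumes: five exposure conditions
(UT, CA, LD, MD, HD) measured on a targeted-sequencing platform (negative
binomial counts with library-size variation), a microarray platform
(dynamic-range-compressed log2 intensities with Gaussian noise), and an
RT-qPCR panel (CT values with a detection ceiling). Dose effects are shared
across platforms: a differentially expressed gene carries one sign and a
magnitude that grows monotonically with dose.

Every output object draws from its own RNG stream split off the master
seed, so e.g. regenerating counts never perturbs the intensity draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CONDITIONS,
    DOSE_CONDITIONS,
    ConfigError,
    ExpressionMatrix,
    SampleDesign,
)
from .panels import ProbeRecord, TranscriptModel, ProbeAlignment, UNMAPPABLE_LABELS
from .qpcr import CtTable

# fixed stream ids: one RNG stream per generated object
_STREAMS = {"truth": 1, "counts": 2, "intensities": 3, "ct": 4, "panels": 5}


def _stream_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: three biological replicates per
    condition, ~6.2 million counts per sequencing sample, a microarray
    dynamic range compressed to about half the sequencing log2 fold
    changes, and a CT detection ceiling of 40 cycles.
    """

    n_genes: int = 2000
    frac_de: float = 0.05
    n_reps: int = 3
    conditions: tuple = CONDITIONS
    lib_size_mean: float = 6.2e6
    lib_size_cv: float = 0.15
    nb_dispersion: float = 0.05
    array_compression: float = 0.5
    array_noise_sd: float = 0.25
    ct_intercept: float = 38.0
    ct_noise_sd: float = 0.15
    ct_detection_limit: float = 40.0
    panel_overlap_frac: float = 0.8
    flawed_probe_frac: float = 0.05
    seed: int = 0
    # dose-response profile: fraction of the full (HD) effect per dose
    dose_profile: dict = field(default_factory=lambda: {"LD": 0.3, "MD": 0.6, "HD": 1.0})
    # |HD log2FC| = min_abs_log2fc + Gamma(shape, scale)
    min_abs_log2fc: float = 0.6
    effect_gamma_shape: float = 2.0
    effect_gamma_scale: float = 0.75
    base_abundance_sdlog: float = 1.6
    n_reference_candidates: int = 8
    # residual relative signal of a flawed panel-B probe (targets an
    # unexpressed isoform, so it sees background only)
    flawed_signal_frac: float = 0.01

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        for name in ("frac_de", "panel_overlap_frac", "flawed_probe_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_reps < 2:
            raise ConfigError("n_reps must be >= 2")
        if "CA" not in self.conditions:
            raise ConfigError("conditions must contain the reference condition CA")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0.0 < self.array_compression <= 1.0:
            raise ConfigError("array_compression must be in (0, 1]")
        for name in ("lib_size_mean", "lib_size_cv"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.array_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


def _balanced_signs(base: np.ndarray, magnitude: np.ndarray) -> np.ndarray:
    """Assign +/-1 signs, near-even in count, cancelling mass change.

    Greedy: genes in decreasing order of potential mass gain pick the sign
    that keeps the running net change of expected total expression closest
    to zero, subject to an at-most-one difference between the up and down
    counts.
    """
    n = len(magnitude)
    signs = np.zeros(n)
    if n == 0:
        return signs
    gain = base * (np.power(2.0, magnitude) - 1.0)  # mass added if up
    loss = base * (np.power(2.0, -magnitude) - 1.0)  # mass removed if down
    up_left = (n + 1) // 2
    down_left = n - up_left
    running = 0.0
    for i in np.argsort(-gain, kind="stable"):
        take_up = abs(running + gain[i]) <= abs(running + loss[i])
        if take_up and up_left == 0:
            take_up = False
        if not take_up and down_left == 0:
            take_up = True
        if take_up:
            signs[i] = 1.0
            running += gain[i]
            up_left -= 1
        else:
            signs[i] = -1.0
            running += loss[i]
            down_left -= 1
    return signs


def _make_design(config: SimConfig) -> SampleDesign:
    return SampleDesign.from_conditions(config.conditions, config.n_reps)


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw the per-gene ground truth table.

    Returns a DataFrame indexed by gene_id with columns: base_abundance
    (expected counts in CA at the reference library size), base_cpm, is_de,
    direction ({up, down, none}), log2fc_LD/MD/HD, ct_detectable,
    shared_panel, flawed_probe, ref_candidate.
    """
    config.validate()
    rng = _stream_rng(config.seed, "truth")
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(1, n + 1)])

    raw = rng.lognormal(mean=0.0, sigma=config.base_abundance_sdlog, size=n)
    base_abundance = raw / raw.sum() * config.lib_size_mean
    base_abundance = np.maximum(base_abundance, 1e-9)
    base_cpm = base_abundance / config.lib_size_mean * 1e6

    n_de = int(round(config.frac_de * n))
    is_de = np.zeros(n, dtype=bool)
    de_idx = rng.choice(n, size=n_de, replace=False)
    is_de[de_idx] = True

    hd_mag = config.min_abs_log2fc + rng.gamma(
        config.effect_gamma_shape, config.effect_gamma_scale, size=n_de
    )
    # Split up/down approximately evenly, assigning signs so that the
    # abundance-weighted gain and loss of transcript mass cancel: total
    # expression is conserved under treatment, which is the assumption
    # total-count (CPM) normalization rests on.
    signs = _balanced_signs(base_abundance[de_idx], hd_mag)
    lfc = {d: np.zeros(n) for d in DOSE_CONDITIONS}
    for d in DOSE_CONDITIONS:
        lfc[d][de_idx] = signs * hd_mag * config.dose_profile[d]

    direction = np.where(is_de, np.where(lfc["HD"] > 0, "up", "down"), "none")

    ct_model_ca = config.ct_intercept - np.log2(base_cpm)
    ct_detectable = ct_model_ca <= config.ct_detection_limit

    shared = rng.random(n) < config.panel_overlap_frac
    flawed = np.zeros(n, dtype=bool)
    shared_idx = np.flatnonzero(shared)
    if len(shared_idx) and config.flawed_probe_frac > 0:
        flawed[shared_idx] = rng.random(len(shared_idx)) < config.flawed_probe_frac

    # reference-gene candidates: stable, well-detected, non-DE genes
    ref_candidate = np.zeros(n, dtype=bool)
    eligible = np.flatnonzero(~is_de & ct_detectable & ~flawed)
    if len(eligible):
        order = eligible[np.argsort(-base_cpm[eligible], kind="stable")]
        ref_candidate[order[: config.n_reference_candidates]] = True

    truth = pd.DataFrame(
        {
            "base_abundance": base_abundance,
            "base_cpm": base_cpm,
            "is_de": is_de,
            "direction": direction,
            "log2fc_LD": lfc["LD"],
            "log2fc_MD": lfc["MD"],
            "log2fc_HD": lfc["HD"],
            "ct_detectable": ct_detectable,
            "shared_panel": shared,
            "flawed_probe": flawed,
            "ref_candidate": ref_candidate,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return truth


def true_log2fc(truth: pd.DataFrame, condition: str) -> pd.Series:
    """True log2 fold change vs CA for any condition (0 for UT and CA)."""
    if condition in DOSE_CONDITIONS:
        return truth[f"log2fc_{condition}"]
    return pd.Series(0.0, index=truth.index)


def simulate_counts(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Negative-binomial counts for the sequencing platform (panel B).

    Gene means scale with a log-normally drawn library size; flawed-probe
    genes yield background-level counts with no dose effect.
    """
    config.validate()
    rng = _stream_rng(config.seed, "counts")
    design = _make_design(config)
    samples = design.sample_ids
    n_samples = len(samples)

    sigma = np.sqrt(np.log1p(config.lib_size_cv**2))
    mu = np.log(config.lib_size_mean) - sigma**2 / 2.0
    lib_sizes = rng.lognormal(mean=mu, sigma=sigma, size=n_samples)

    base = truth["base_abundance"].to_numpy()[:, None]
    flawed = truth["flawed_probe"].to_numpy()[:, None]
    lfc = np.column_stack(
        [true_log2fc(truth, design.condition_of(s)).to_numpy() for s in samples]
    )
    scale = lib_sizes[None, :] / config.lib_size_mean
    mean = base * np.power(2.0, lfc) * scale
    # flawed panel-B probes see only background, flat across doses
    mean = np.where(flawed, base * config.flawed_signal_frac * scale, mean)

    alpha = config.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / alpha
        lam = rng.gamma(shape, alpha * mean)
        counts = rng.poisson(lam)

    mat = ExpressionMatrix(
        pd.DataFrame(counts.astype(np.int64), index=truth.index, columns=samples),
        kind="counts",
    )
    return mat, design


def simulate_intensities(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Log2 microarray intensities for panel A.

    Observed condition means differ from CA by compression x true log2FC;
    Gaussian noise on the log2 scale. Baseline intensity is an affine map
    of log2 base abundance into the typical 4-15 intensity window.
    """
    config.validate()
    rng = _stream_rng(config.seed, "intensities")
    design = _make_design(config)
    samples = design.sample_ids

    base_cpm = truth["base_cpm"].to_numpy()[:, None]
    baseline = 4.0 + 0.6 * np.log2(base_cpm + 1.0)
    lfc = np.column_stack(
        [true_log2fc(truth, design.condition_of(s)).to_numpy() for s in samples]
    )
    mean = baseline + config.array_compression * lfc
    noise = (
        rng.normal(0.0, config.array_noise_sd, size=mean.shape)
        if config.array_noise_sd > 0
        else 0.0
    )
    values = pd.DataFrame(mean + noise, index=truth.index, columns=samples)
    return ExpressionMatrix(values, kind="log2_intensity"), design


def simulate_ct(
    truth: pd.DataFrame, config: SimConfig, gene_subset: list[str]
) -> CtTable:
    """CT values for a qPCR panel over ``gene_subset``.

    Model: CT = ct_intercept - log2(abundance in CPM) + noise, so doubling
    the template lowers CT by one cycle. Wells whose model CT exceeds the
    detection limit, and every well of a gene with ct_detectable = False,
    are reported as not detected (NaN). Reference-gene candidates are
    simulated with reduced noise.
    """
    config.validate()
    gene_subset = list(gene_subset)
    if not gene_subset:
        raise ConfigError("gene_subset must not be empty")
    missing = set(gene_subset) - set(truth.index)
    if missing:
        raise ConfigError(f"genes absent from truth table: {sorted(missing)[:5]}")
    rng = _stream_rng(config.seed, "ct")
    design = _make_design(config)
    samples = design.sample_ids
    sub = truth.loc[gene_subset]

    base_cpm = sub["base_cpm"].to_numpy()[:, None]
    lfc = np.column_stack(
        [true_log2fc(sub, design.condition_of(s)).to_numpy() for s in samples]
    )
    model_ct = config.ct_intercept - np.log2(base_cpm * np.power(2.0, lfc))
    sd = np.where(sub["ref_candidate"].to_numpy(), 0.3 * config.ct_noise_sd, config.ct_noise_sd)
    noise = (
        rng.normal(0.0, 1.0, size=model_ct.shape) * sd[:, None]
        if config.ct_noise_sd > 0
        else 0.0
    )
    ct = model_ct + noise
    undetectable = ~sub["ct_detectable"].to_numpy()
    ct[undetectable, :] = np.nan
    ct[ct > config.ct_detection_limit] = np.nan

    values = pd.DataFrame(ct, index=sub.index, columns=samples)
    refs = list(sub.index[sub["ref_candidate"]])
    return CtTable(values, detection_limit=config.ct_detection_limit, reference_candidates=refs)


def generate_panels(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[list[ProbeRecord], list[ProbeRecord], list[TranscriptModel], list[ProbeAlignment]]:
    """Probe panels for both platforms plus transcript models and alignments.

    Each gene gets 1-3 transcripts laid out on a toy chromosome. Genes
    flagged shared_panel carry probes on both panels that share at least
    one transcript id; other genes appear on one panel only. Panel A also
    carries unmappable probes under the non-coding label vocabulary.
    """
    config.validate()
    rng = _stream_rng(config.seed, "panels")
    panel_a: list[ProbeRecord] = []
    panel_b: list[ProbeRecord] = []
    models: list[TranscriptModel] = []
    alignments: list[ProbeAlignment] = []

    gene_span = 3000
    gap = 1000
    tx_counter = 0
    for gi, (gene_id, row) in enumerate(truth.iterrows()):
        gene_start = gi * (gene_span + gap)
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(1, 4))
        tx_ids = []
        gene_models = []
        for t in range(n_tx):
            tx_counter += 1
            tx_id = f"ENSTS{tx_counter:08d}.{int(rng.integers(1, 6))}"
            n_exons = int(rng.integers(1, 4))
            # partition the gene span into alternating exon/intron blocks
            cuts = np.sort(rng.choice(np.arange(50, gene_span - 50), size=2 * n_exons - 1, replace=False))
            exons = []
            pos = gene_start + int(rng.integers(0, 40))
            bounds = [pos] + [gene_start + int(c) for c in cuts] + [gene_start + gene_span]
            for e in range(n_exons):
                s = bounds[2 * e]
                eend = bounds[2 * e + 1]
                if eend <= s:
                    eend = s + 30
                exons.append((s, eend))
            model = TranscriptModel(tx_id, str(gene_id), "chr1", strand, exons)
            gene_models.append(model)
            tx_ids.append(tx_id)
        models.extend(gene_models)

        shared = bool(row["shared_panel"])
        on_a = shared or (gi % 2 == 0)
        on_b = shared or (gi % 2 == 1)
        anchor_tx = tx_ids[0]
        if on_a:
            targets = {anchor_tx} | set(
                np.array(tx_ids)[rng.random(len(tx_ids)) < 0.5].tolist()
            )
            panel_a.append(
                ProbeRecord(f"A_{gene_id}_1", "A", "Coding", str(gene_id), frozenset(targets))
            )
        if on_b:
            targets = {anchor_tx}
            if len(tx_ids) > 1 and rng.random() < 0.4:
                targets.add(tx_ids[1])
            probe_id = f"{gene_id}_B1"
            panel_b.append(
                ProbeRecord(probe_id, "B", "Coding", str(gene_id), frozenset(targets))
            )
            # alignment blocks for the B probe inside its anchor transcript
            anchor = gene_models[0]
            exon = anchor.exons[0]
            elen = exon[1] - exon[0]
            blk_len = min(50, max(10, elen - 2))
            start = exon[0] + min(1, elen - blk_len)
            alignments.append(
                ProbeAlignment(probe_id, "chr1", strand, [(start, start + blk_len)])
            )

    # unmappable panel-A probes, spread across the non-coding label vocabulary
    n_extra = max(len(UNMAPPABLE_LABELS), config.n_genes // 20)
    for j in range(n_extra):
        label = UNMAPPABLE_LABELS[j % len(UNMAPPABLE_LABELS)]
        panel_a.append(
            ProbeRecord(f"A_extra_{j:04d}", "A", label, None, frozenset())
        )
    return panel_a, panel_b, models, alignments


# ---------------------------------------------------------------------------
# writers


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def simulate_all(config: SimConfig) -> dict:
    """Generate the full synthetic study as one dictionary of objects."""
    truth = generate_truth(config)
    counts, design = simulate_counts(truth, config)
    intensities, _ = simulate_intensities(truth, config)
    panel_a, panel_b, models, alignments = generate_panels(truth, config)
    return {
        "truth": truth,
        "counts": counts,
        "intensities": intensities,
        "design": design,
        "panel_a": panel_a,
        "panel_b": panel_b,
        "transcript_models": models,
        "alignments": alignments,
    }
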
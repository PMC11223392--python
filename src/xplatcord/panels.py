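"""Probe-panel harmonization across platforms.

Targeted-sequencing and microarray panels measure overlapping but not
identical probe sets. The two panels are joined through shared
Ensembl-style transcript ids (probes are 1-to-N on transcripts, so the
join is N-to-N on probes), coverage is accounted per probe label, probe
signals are summarized to gene level, and probe alignment blocks are
tested for perfect exonic coverage of a transcript.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, InputError

PROBE_LABELS = (
    "Coding",
    "Multiple_Complex",
    "Non-coding",
    "Precursor_microRNA",
    "Pseudogene",
    "Ribosomal",
    "Small_RNA",
    "tRNA",
    "Unassigned",
)
#: labels that, on the array platform, have no Ensembl transcript mapping
UNMAPPABLE_LABELS = (
    "Non-coding",
    "Precursor_microRNA",
    "Pseudogene",
    "Ribosomal",
    "Small_RNA",
    "tRNA",
    "Unassigned",
)


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    platform: str  # {A, B}
    label: str
    gene_id: str | None
    transcript_ids: frozenset = frozenset()

    def __post_init__(self):
        if self.label not in PROBE_LABELS:
            raise InputError(f"unknown probe label {self.label!r} for {self.probe_id}")


@dataclass
class TranscriptModel:
    """Transcript as an ordered list of 0-based half-open exon intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list  # [(start, end), ...] sorted, non-overlapping

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InputError(f"bad strand {self.strand!r} for {self.transcript_id}")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise InputError(
                    f"malformed exon [{s}, {e}) in transcript {self.transcript_id}"
                )
            if prev_end is not None and s < prev_end:
                raise InputError(f"overlapping/unsorted exons in {self.transcript_id}")
            prev_end = e
        if self.exonic_length == 0:
            raise InputError(f"transcript {self.transcript_id} has zero exonic length")

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class ProbeAlignment:
    """Genomic alignment of a probe as sorted non-overlapping blocks."""

    probe_id: str
    chrom: str
    strand: str
    blocks: list  # [(start, end), ...] 0-based half-open

    def __post_init__(self):
        prev_end = None
        for s, e in self.blocks:
            if e <= s:
                raise InputError(f"malformed block [{s}, {e}) in probe {self.probe_id}")
            if prev_end is not None and s < prev_end:
                raise InputError(f"overlapping/unsorted blocks in probe {self.probe_id}")
            prev_end = e


@dataclass
class PanelJoin:
    """Result of the transcript-mediated probe-pair join."""

    pairs: list  # [(probe_id_a, probe_id_b, frozenset of shared transcript ids)]
    mapped_probe_count: int
    covered_transcript_count: int
    per_label_summary: pd.DataFrame | None = None

    @property
    def paired_genes_a(self) -> set:
        return {a for a, _, _ in self.pairs}

    def gene_pairs(self, panel_a, panel_b) -> set:
        """Set of (gene_a, gene_b) behind the probe pairs."""
        ga = {p.probe_id: p.gene_id for p in panel_a}
        gb = {p.probe_id: p.gene_id for p in panel_b}
        return {(ga[a], gb[b]) for a, b, _ in self.pairs}


def strip_version(tx_id: str) -> str:
    """Drop a trailing Ensembl version suffix (ENST...4 -> ENST...)."""
    head, _, tail = tx_id.rpartition(".")
    if head and tail.isdigit():
        return head
    return tx_id


def _check_unique(panel: list[ProbeRecord], name: str) -> None:
    seen = set()
    for p in panel:
        if p.probe_id in seen:
            raise InputError(f"duplicate probe_id {p.probe_id!r} in panel {name}")
        seen.add(p.probe_id)


def map_probe_pairs(
    panel_a: list[ProbeRecord],
    panel_b: list[ProbeRecord],
    strip_versions: bool = True,
    one_to_one: bool = False,
) -> PanelJoin:
    """Join two probe panels through shared transcript ids.

    Every (a, b) probe pair sharing at least one transcript id yields one
    deduplicated pair carrying the full set of shared ids (the N-to-N
    sense). ``one_to_one=True`` additionally drops pairs whose probes
    participate in more than one pair. Version suffixes on transcript ids
    are stripped before matching unless ``strip_versions`` is False.
    """
    if not panel_a or not panel_b:
        raise InputError("both panels must be non-empty")
    _check_unique(panel_a, "A")
    _check_unique(panel_b, "B")

    def key(t):
        return strip_version(t) if strip_versions else t

    tx_to_b = defaultdict(list)
    for p in panel_b:
        for t in p.transcript_ids:
            tx_to_b[key(t)].append(p.probe_id)

    shared: dict[tuple, set] = defaultdict(set)
    for p in panel_a:
        for t in p.transcript_ids:
            kt = key(t)
            for b_id in tx_to_b.get(kt, ()):
                shared[(p.probe_id, b_id)].add(kt)

    pairs = [(a, b, frozenset(ts)) for (a, b), ts in sorted(shared.items())]
    if one_to_one:
        count_a = defaultdict(int)
        count_b = defaultdict(int)
        for a, b, _ in pairs:
            count_a[a] += 1
            count_b[b] += 1
        pairs = [(a, b, ts) for a, b, ts in pairs if count_a[a] == 1 and count_b[b] == 1]

    probes_in_pairs = {a for a, _, _ in pairs} | {b for _, b, _ in pairs}
    covered = set().union(*(ts for _, _, ts in pairs)) if pairs else set()
    join = PanelJoin(pairs, len(probes_in_pairs), len(covered))
    join.per_label_summary = coverage_summary(panel_a, panel_b, join)
    return join


def coverage_summary(
    panel_a: list[ProbeRecord], panel_b: list[ProbeRecord], join: PanelJoin
) -> pd.DataFrame:
    """Per-label probe and mapping accounting, plus a Total row.

    Columns: probe counts per platform, probes carrying a transcript
    mapping, distinct transcripts referenced per label, and probes of the
    label participating in at least one cross-platform pair. The Total row
    is the column sum (a transcript referenced under two labels is counted
    under each).
    """
    for p in list(panel_a) + list(panel_b):
        if p.label not in PROBE_LABELS:  # re-validate TSV round trips
            raise InputError(f"unknown probe label {p.label!r}")
    in_pair = {a for a, _, _ in join.pairs} | {b for _, b, _ in join.pairs}

    rows = []
    for label in PROBE_LABELS:
        la = [p for p in panel_a if p.label == label]
        lb = [p for p in panel_b if p.label == label]
        tx_a = set().union(*(p.transcript_ids for p in la)) if la else set()
        tx_b = set().union(*(p.transcript_ids for p in lb)) if lb else set()
        rows.append(
            {
                "label": label,
                "probes_A": len(la),
                "probes_B": len(lb),
                "mapped_A": sum(1 for p in la if p.transcript_ids),
                "transcripts_A": len(tx_a),
                "mapped_B": sum(1 for p in lb if p.transcript_ids),
                "transcripts_B": len(tx_b),
                "overlapping": sum(1 for p in la + lb if p.probe_id in in_pair),
            }
        )
    df = pd.DataFrame(rows).set_index("label")
    df.loc["Total"] = df.sum(axis=0)
    return df


# ---------------------------------------------------------------------------
# exon-block transcript coverage


def _project_block(block: tuple, model: TranscriptModel) -> tuple | None:
    """Map a genomic block to plus-direction transcript coordinates.

    Returns None unless the block lies entirely within a single exon.
    """
    s, e = block
    offset = 0
    for es, ee in model.exons:
        if es <= s and e <= ee:
            return (offset + (s - es), offset + (e - es))
        offset += ee - es
    return None


def probe_covers_transcript(
    aln: ProbeAlignment, model: TranscriptModel, match_strand: bool = True
) -> bool:
    """True iff every alignment block matches the transcript perfectly.

    Requires chromosome (and by default strand) identity, every block fully
    inside one exon, and the blocks contiguous in spliced transcript
    coordinates — i.e. internal block boundaries coincide with exon
    junctions.
    """
    if aln.chrom != model.chrom:
        return False
    if match_strand and aln.strand != model.strand:
        return False
    projected = []
    for block in aln.blocks:
        t = _project_block(block, model)
        if t is None:
            return False
        projected.append(t)
    projected.sort()
    for (s1, e1), (s2, e2) in zip(projected, projected[1:]):
        if s2 != e1:
            return False
    return True


def transcript_coverage(
    alignments: list[ProbeAlignment],
    models: list[TranscriptModel],
    match_strand: bool = True,
) -> dict[str, set]:
    """Map each probe to the set of transcripts it perfectly covers."""
    out: dict[str, set] = {}
    for aln in alignments:
        covered = {
            m.transcript_id
            for m in models
            if probe_covers_transcript(aln, m, match_strand=match_strand)
        }
        out[aln.probe_id] = covered
    return out


# ---------------------------------------------------------------------------
# gene-level summarization


def summarize_to_genes(
    matrix: ExpressionMatrix, panel: list[ProbeRecord]
) -> tuple[ExpressionMatrix, list[str]]:
    """Aggregate probe-level signals to gene level.

    Counts are summed per gene; log2-scale values are averaged. Probes
    without a gene assignment are dropped and returned for reporting.
    """
    gene_of = {p.probe_id: p.gene_id for p in panel}
    missing = [f for f in matrix.feature_ids if f not in gene_of]
    if missing:
        raise InputError(f"features absent from panel: {missing[:5]}")
    dropped = [f for f in matrix.feature_ids if gene_of[f] is None]
    keep = [f for f in matrix.feature_ids if gene_of[f] is not None]
    sub = matrix.values.loc[keep]
    groups = pd.Series({f: gene_of[f] for f in keep}, name="gene_id")
    if matrix.kind == "counts":
        agg = sub.groupby(groups).sum()
    else:
        agg = sub.groupby(groups).mean()
    agg.index.name = "feature_id"
    return ExpressionMatrix(agg, matrix.kind), dropped


# ---------------------------------------------------------------------------
# TSV I/O


def write_panel_tsv(panel: list[ProbeRecord], path: str | Path) -> None:
    rows = [
        {
            "probe_id": p.probe_id,
            "platform": p.platform,
            "label": p.label,
            "gene_id": p.gene_id if p.gene_id is not None else "",
            "transcript_ids": ";".join(sorted(p.transcript_ids)),
        }
        for p in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> list[ProbeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        tx = frozenset(t for t in r["transcript_ids"].split(";") if t)
        out.append(
            ProbeRecord(
                r["probe_id"], r["platform"], r["label"], r["gene_id"] or None, tx
            )
        )
    return out


def write_alignments_tsv(alignments: list[ProbeAlignment], path: str | Path) -> None:
    """BED12-style blocks: chromStart plus comma-joined sizes/offsets."""
    rows = []
    for a in alignments:
        start = a.blocks[0][0]
        sizes = ",".join(str(e - s) for s, e in a.blocks)
        offsets = ",".join(str(s - start) for s, _ in a.blocks)
        rows.append(
            {
                "probe_id": a.probe_id,
                "chrom": a.chrom,
                "start": start,
                "end": a.blocks[-1][1],
                "strand": a.strand,
                "block_sizes": sizes,
                "block_offsets": offsets,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path: str | Path) -> list[ProbeAlignment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        start = int(r["start"])
        sizes = [int(x) for x in r["block_sizes"].split(",")]
        offsets = [int(x) for x in r["block_offsets"].split(",")]
        blocks = [(start + o, start + o + s) for s, o in zip(sizes, offsets)]
        out.append(ProbeAlignment(r["probe_id"], r["chrom"], r["strand"], blocks))
    return out
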
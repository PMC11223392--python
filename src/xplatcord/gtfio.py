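"""Minimal exon-level GTF reader/writer.

Covers exactly the subset the pipeline exchanges: exon features with
gene_id/transcript_id attributes. GTF coordinates are 1-based inclusive;
in memory everything is 0-based half-open.
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path

from .containers import InputError
from .panels import TranscriptModel

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(models: list[TranscriptModel], path: str | Path, source: str = "xplatcord") -> None:
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    "\t".join(
                        [m.chrom, source, "exon", str(s + 1), str(e), ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    exons: dict[str, list] = defaultdict(list)
    meta: dict[str, tuple] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise InputError(f"malformed GTF line: {line[:80]!r}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            d = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in d or "gene_id" not in d:
                raise InputError("GTF exon lacks gene_id/transcript_id attributes")
            tx = d["transcript_id"]
            exons[tx].append((int(start) - 1, int(end)))
            meta[tx] = (d["gene_id"], chrom, strand)
    models = []
    for tx, ex in exons.items():
        gene_id, chrom, strand = meta[tx]
        models.append(TranscriptModel(tx, gene_id, chrom, strand, sorted(ex)))
    return models
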
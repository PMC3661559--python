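"""Precursor classification and mature-miRNA composition statistics.

Intronic precursors fall into three categories: non-clustered precursors
producing a single mature miRNA (UMP), non-clustered precursors producing
two or more matures (MMP), and clustered precursors — neighbors within the
same host gene separated by a gap of strictly less than 3000 nt (CP).
Composition statistics summarize mature length classes (20-22 / 23 / 24 nt,
the functional split between AGO1-loaded and DNA-methylation-guiding
species in rice) and the 5' initial base preference per class.

The package ships a reference fixture of 40 published novel rice intronic
mature miRNAs (``load_reference_matures``) and the published table of seven
intronic precursor clusters (``load_reference_clusters``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from ._seq import to_rna


@dataclass(frozen=True)
class PrecursorLocus:
    """Minimal information classification needs about a called precursor."""

    precursor_id: str
    host_gene: str
    chrom: str
    genomic_start: int
    genomic_end: int
    intron_ordinal: int
    n_matures: int


@dataclass(frozen=True)
class PrecursorClass:
    precursor_id: str
    category: str  # "UMP" | "MMP" | "CP"
    cluster_id: str | None
    host_gene: str
    intron_ordinal: int


# --------------------------------------------------------------------------
# clustering & categories
# --------------------------------------------------------------------------

def assign_clusters(
    precursors: list[PrecursorLocus],
    max_gap: int = 3000,
    same_host_only: bool = True,
) -> dict[str, str]:
    """Single-linkage grouping of precursors into clusters: two precursors
    join when (by default) they share a host gene and the gap between their
    genomic spans is strictly less than ``max_gap``.  Returns a mapping
    precursor_id -> cluster_id for members of clusters of size >= 2."""
    def group_key(p: PrecursorLocus):
        return (p.chrom, p.host_gene) if same_host_only else (p.chrom,)

    assignments: dict[str, str] = {}
    by_group: dict[tuple, list[PrecursorLocus]] = {}
    for p in sorted(precursors, key=lambda p: (p.chrom, p.genomic_start, p.precursor_id)):
        by_group.setdefault(group_key(p), []).append(p)
    cluster_n = 0
    for _key, members in sorted(by_group.items()):
        current: list[PrecursorLocus] = []
        prev_end = None
        for p in members:
            if prev_end is not None and p.genomic_start - prev_end < max_gap:
                current.append(p)
                prev_end = max(prev_end, p.genomic_end)
            else:
                cluster_n = _emit(current, cluster_n, assignments)
                current = [p]
                prev_end = p.genomic_end
        cluster_n = _emit(current, cluster_n, assignments)
    return assignments


def _emit(current: list[PrecursorLocus], n: int, out: dict[str, str]) -> int:
    if len(current) >= 2:
        n += 1
        for p in current:
            out[p.precursor_id] = f"CL{n}"
    return n


def categorize(
    precursors: list[PrecursorLocus],
    clusters: dict[str, str] | None = None,
    max_gap: int = 3000,
) -> list[PrecursorClass]:
    """CP if the precursor belongs to a cluster; else MMP when it yields
    two or more matures; else UMP."""
    if clusters is None:
        clusters = assign_clusters(precursors, max_gap=max_gap)
    out = []
    for p in precursors:
        if p.n_matures < 1:
            raise ValueError(
                f"{p.precursor_id}: zero matures should not survive calling"
            )
        if p.precursor_id in clusters:
            cat = "CP"
        elif p.n_matures >= 2:
            cat = "MMP"
        else:
            cat = "UMP"
        out.append(
            PrecursorClass(
                p.precursor_id, cat, clusters.get(p.precursor_id),
                p.host_gene, p.intron_ordinal,
            )
        )
    return out


# --------------------------------------------------------------------------
# composition statistics
# --------------------------------------------------------------------------

LENGTH_CLASSES = ("20-22", "23", "24", "other")


def _length_class(n: int) -> str:
    if 20 <= n <= 22:
        return "20-22"
    if n == 23:
        return "23"
    if n == 24:
        return "24"
    return "other"


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CompositionSummary:
    total: int
    class_counts: dict[str, int] = field(default_factory=dict)
    first_base_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def class_percent(self, length_class: str) -> int:
        return round_half_up(100 * self.class_counts.get(length_class, 0) / self.total)

    def first_base_percent(self, length_class: str, base: str) -> int:
        counts = self.first_base_counts.get(length_class, {})
        denom = self.class_counts.get(length_class, 0)
        if denom == 0:
            return 0
        return round_half_up(100 * counts.get(base, 0) / denom)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "class_counts": dict(self.class_counts),
            "first_base_counts": {k: dict(v) for k, v in self.first_base_counts.items()},
        }


def composition_summary(sequences: list[str]) -> CompositionSummary:
    """Length-class histogram and per-class 5' initial base tallies.

    Percentages (via the summary accessors) are rounded half-up to
    integers."""
    class_counts = {c: 0 for c in LENGTH_CLASSES}
    first_base = {c: {b: 0 for b in "UAGC"} for c in LENGTH_CLASSES}
    for seq in sequences:
        rna = to_rna(seq)
        cls = _length_class(len(rna))
        class_counts[cls] += 1
        if rna[0] in "UAGC":
            first_base[cls][rna[0]] += 1
    class_counts = {c: n for c, n in class_counts.items() if n}
    first_base = {c: v for c, v in first_base.items() if c in class_counts}
    return CompositionSummary(len(sequences), class_counts, first_base)


# --------------------------------------------------------------------------
# packaged reference fixtures
# --------------------------------------------------------------------------

_HEADER_RE = re.compile(r">(\S+)(?:\s+precursor=(\S+))?")


def load_reference_matures() -> pd.DataFrame:
    """The 40 published novel rice intronic mature miRNAs (id, precursor,
    sequence), including the sequenced star strand miR2175.1*."""
    text = resources.files("intromir.data").joinpath("novel_matures.fa").read_text()
    rows = []
    mirna_id = precursor = None
    for line in text.splitlines():
        if line.startswith(">"):
            m = _HEADER_RE.match(line)
            mirna_id, precursor = m.group(1), m.group(2)
        elif line.strip():
            rows.append({"mirna_id": mirna_id, "precursor": precursor,
                         "sequence": line.strip()})
    return pd.DataFrame(rows)


def load_reference_clusters() -> pd.DataFrame:
    """The seven published clusters of rice intronic precursors with their
    host genes and host-intron lengths."""
    with resources.files("intromir.data").joinpath("cluster_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
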
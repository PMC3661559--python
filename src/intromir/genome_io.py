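"""Genome / annotation / small-RNA library I/O and intron extraction.

Internal coordinates are 0-based half-open throughout the package; GFF3 is
1-based inclusive on disk and converted only at the I/O boundary.  Intron
ordinals are transcript-relative: counted 5'->3' along the mRNA, which for
minus-strand genes runs against genomic order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._seq import check_alphabet, revcomp


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A transcript model: ordered, non-overlapping exons on one strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.gene_id}: empty/inverted exon ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass(frozen=True)
class Intron:
    """An intron with strand-corrected sequence and transcript-relative ordinal."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic, 0-based half-open
    end: int
    ordinal: int  # 1-based, counted from the transcript 5' end
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("intron must have length >= 1")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("intron sequence length != interval length")
        if self.ordinal < 1:
            raise ValueError("intron ordinal must be >= 1")

    @property
    def intron_id(self) -> str:
        return f"{self.gene_id}.i{self.ordinal}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SmallRnaLibrary:
    """Collapsed small-RNA library: unique sequence -> read count."""

    sample_id: str
    entries: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.entries.values())

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    def merged_with(self, other: "SmallRnaLibrary") -> "SmallRnaLibrary":
        merged = dict(self.entries)
        for seq, count in other.entries.items():
            merged[seq] = merged.get(seq, 0) + count
        return SmallRnaLibrary(f"{self.sample_id}+{other.sample_id}", merged)


def merge_libraries(libraries: Iterable[SmallRnaLibrary]) -> SmallRnaLibrary:
    """Pool collapsed libraries, summing counts of identical sequences."""
    pooled: dict[str, int] = {}
    names = []
    for lib in libraries:
        names.append(lib.sample_id)
        for seq, count in lib.entries.items():
            pooled[seq] = pooled.get(seq, 0) + count
    return SmallRnaLibrary("+".join(names) if names else "empty", pooled)


# --------------------------------------------------------------------------
# genome sequence access
# --------------------------------------------------------------------------

def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] (0-based half-open) from a dict of
    strings or a pyfaidx.Fasta-like object; bounds-checked."""
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc
    if isinstance(record, str):
        n = len(record)
    else:
        n = len(record)
    if start < 0 or end > n:
        raise IndexError(
            f"interval [{start},{end}) outside chromosome {chrom!r} (length {n})"
        )
    piece = record[start:end]
    return str(piece).upper()


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA into a dict.  For large genomes use pyfaidx.Fasta;
    both work anywhere the package expects a genome store."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def _gff_db(path: str | Path):
    import gffutils

    return gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Build gene models from the `exon` features of a GFF3 file, grouped by
    their Parent attribute (transcript/gene id)."""
    db = _gff_db(path)
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get("ID")
        if not parents:
            raise ValueError(f"{path}: exon without Parent/ID at {exon.seqid}:{exon.start}")
        # GFF3 1-based inclusive -> 0-based half-open
        exons.setdefault(parents[0], []).append(
            (exon.seqid, exon.strand, exon.start - 1, exon.end)
        )
    models = []
    for gene_id, parts in exons.items():
        chroms = {p[0] for p in parts}
        strands = {p[1] for p in parts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{gene_id}: exons on multiple chromosomes/strands")
        intervals = tuple(sorted((s, e) for _, _, s, e in parts))
        models.append(GeneModel(gene_id, chroms.pop(), strands.pop(), intervals))
    models.sort(key=lambda m: (m.chrom, m.span[0], m.gene_id))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g0, g1 = m.span
            fh.write(
                f"{m.chrom}\tintromir\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for start, end in m.exons:
                fh.write(
                    f"{m.chrom}\tintromir\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                    f"Parent={m.gene_id}\n"
                )


def write_introns_gff3(introns: Iterable[Intron], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for it in introns:
            fh.write(
                f"{it.chrom}\tintromir\tintron\t{it.start + 1}\t{it.end}\t.\t"
                f"{it.strand}\t.\tID={it.intron_id};Parent={it.gene_id};"
                f"ordinal={it.ordinal}\n"
            )


def read_introns_gff3(path: str | Path, genome) -> list[Intron]:
    db = _gff_db(path)
    introns = []
    for feat in db.features_of_type("intron"):
        s, e = feat.start - 1, feat.end
        seq = fetch(genome, feat.seqid, s, e)
        if feat.strand == "-":
            seq = revcomp(seq)
        introns.append(
            Intron(
                feat.attributes["Parent"][0],
                feat.seqid,
                feat.strand,
                s,
                e,
                int(feat.attributes["ordinal"][0]),
                seq,
            )
        )
    return introns


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def extract_introns(models: Iterable[GeneModel], genome) -> list[Intron]:
    """Introns are the gaps between consecutive exons.

    The returned sequence is strand-corrected (reverse-complemented for minus
    strand genes) and the ordinal counts introns from the transcript 5' end.
    Single-exon genes yield nothing.  Identical intervals arising from
    multiple transcript models of one gene are deduplicated.
    """
    introns: list[Intron] = []
    seen: set[tuple[str, int, int, str]] = set()
    for model in models:
        g0, g1 = model.span
        try:
            n = len(genome[model.chrom])
        except KeyError as exc:
            raise KeyError(f"chromosome {model.chrom!r} not in genome") from exc
        if g0 < 0 or g1 > n:
            raise IndexError(
                f"{model.gene_id}: exons [{g0},{g1}) outside chromosome "
                f"{model.chrom!r} (length {n})"
            )
        gaps = [
            (model.exons[i][1], model.exons[i + 1][0])
            for i in range(len(model.exons) - 1)
        ]
        if model.strand == "-":
            ordered = list(reversed(gaps))  # transcript 5' end is genomic right
        else:
            ordered = gaps
        for ordinal, (start, end) in enumerate(ordered, start=1):
            if end - start < 1:
                raise ValueError(
                    f"{model.gene_id}: zero-length intron between adjacent exons"
                )
            key = (model.chrom, start, end, model.strand)
            if key in seen:
                continue
            seen.add(key)
            seq = fetch(genome, model.chrom, start, end)
            check_alphabet(seq, f"{model.gene_id} intron {ordinal}")
            if model.strand == "-":
                seq = revcomp(seq)
            introns.append(
                Intron(model.gene_id, model.chrom, model.strand, start, end, ordinal, seq)
            )
    return introns


_COUNT_X_RE = re.compile(r"_x(\d+)$")
_COUNT_EQ_RE = re.compile(r"\bcount=(\d+)\b")


def read_collapsed_library(path: str | Path, sample_id: str | None = None) -> SmallRnaLibrary:
    """Read a collapsed small-RNA FASTA where each header encodes the read
    count: either ``>id_xCOUNT`` or ``>id count=N``.  Duplicate sequences are
    merged by summing counts."""
    sample = sample_id or Path(path).stem
    entries: dict[str, int] = {}
    name = None
    count = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"{path}: record {name!r} has no sequence")
        entries[seq] = entries.get(seq, 0) + count

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:]
                name = header.split()[0]
                m = _COUNT_X_RE.search(name) or _COUNT_EQ_RE.search(header)
                if m is None:
                    raise ValueError(
                        f"{path}: record {name!r}: no read count in header "
                        "(expected '>id_xCOUNT' or '>id count=N')"
                    )
                count = int(m.group(1))
                if count < 1:
                    raise ValueError(f"{path}: record {name!r}: count must be >= 1")
                chunks = []
            else:
                chunks.append(line)
    _flush()
    return SmallRnaLibrary(sample, entries)


def write_collapsed_library(lib: SmallRnaLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(lib.entries.items()), start=1):
            fh.write(f">{lib.sample_id}_sr{i}_x{count}\n{seq}\n")


def normalize_rpm(count: float, total_reads: int, factor: float = 2.0) -> float:
    """Reads-per-million with a configurable scaling factor (default 2)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0 for RPM normalization")
    return factor * count / total_reads * 1e6


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Gene/miRNA x sample matrix from TSV; validates rectangular finite data."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.hasnans or df.index.hasnans:
        raise ValueError(f"{path}: missing row/column labels")
    values = df.to_numpy()
    import numpy as np

    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite expression values")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
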
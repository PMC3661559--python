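"""Synthetic genomes, read libraries and expression matrices with planted
ground truth.

The generator emulates the inputs of an intronic-miRNA discovery study:
intron-containing gene models on both strands; stem-loop precursors planted
inside introns (single-mature, multi-mature, clustered pairs straddling the
3000-nt gap rule, and kilobase miRNA-like long hairpins); collapsed
small-RNA libraries whose read stacks form mature/star duplexes with 2-nt
3' overhangs at a configurable duplex-read ratio over background
degradation; siRNA decoy hairpins with smeared 5' starts and abundant
antisense reads; and miRNA/host expression matrices with configured
Spearman sign structure (Gaussian copula).  A TruthManifest records every
planted feature for recovery testing.  Everything is a pure function of
(config, seed): identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp
from .genome_io import (
    GeneModel,
    SmallRnaLibrary,
    write_collapsed_library,
    write_fasta,
    write_gene_models,
)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_SAMPLES = ("grain_0_4dap", "grain_5_10dap", "seedling_shoot", "flag_leaf")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    The defaults describe the clean configuration: 20 genes, 10 planted
    precursors (4 single-mature, 2 two-mature, one clustered pair at a
    2999-nt gap just under the 3000-nt rule, one pair at 3500 nt that must
    NOT cluster), 5 siRNA decoys, duplex read ratio 0.8 with the star
    strand present.  Detected fold-back boundaries carry a few nt of
    uncertainty, so the planted gaps straddle the cluster rule with margin
    on the far side; the exact <3000 boundary is a property of the
    clustering operation itself.
    """

    seed: int
    n_genes: int = 20
    introns_per_gene: int = 2
    exon_len: int = 200
    intron_len: int = 400
    intron_pad: int = 60  # random sequence flanking planted loci

    n_ump: int = 4
    n_mmp: int = 2
    mmp_matures: int = 2
    cluster_groups: tuple[tuple[int, ...], ...] = ((2999,), (3500,))
    n_mirna_like: int = 0
    n_decoys: int = 5

    stem_len: int = 80
    loop_len: int = 8
    stem_mismatch_rate: float = 0.05  # outside the duplex, away from stem ends
    mature_len: int = 21
    mature_offset: int = 4

    mirna_like_arm: int = 550
    mirna_like_products: int = 9
    mirna_like_spacing: int = 30

    mature_reads: int = 150
    star_reads: int = 60
    duplex_read_ratio: float = 0.8
    max_background_read_count: int = 15  # keeps degradation below the 20-read gate

    decoy_arm: int = 60
    decoy_loop: int = 8
    decoy_mismatch_rate: float = 0.15
    decoy_sense_reads: int = 150
    decoy_sense_starts: int = 50
    decoy_antisense_unique: int = 20
    decoy_antisense_reads: int = 50

    n_libraries: int = 8
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    expression_rho: float = 0.9
    expression_noise_sd: float = 0.05
    zero_inflation: float = 0.0
    cluster_host_shift: float = 3.0  # clustered hosts express higher

    def __post_init__(self) -> None:
        for name in ("stem_mismatch_rate", "duplex_read_ratio", "decoy_mismatch_rate",
                     "zero_inflation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_planted_genes > self.n_genes:
            raise ValueError(
                f"{self.n_planted_genes} planted genes exceed n_genes={self.n_genes}"
            )

    @property
    def n_planted_genes(self) -> int:
        return (
            self.n_ump + self.n_mmp + len(self.cluster_groups)
            + self.n_mirna_like + self.n_decoys
        )


@dataclass
class PlantedMature:
    mature_id: str
    sequence: str
    precursor_interval: tuple[int, int]  # on the precursor, 0-based half-open
    star_sequence: str
    star_interval: tuple[int, int]
    mature_reads: int
    star_reads: int


@dataclass
class PlantedPrecursor:
    precursor_id: str
    gene_id: str
    chrom: str
    strand: str
    intron_ordinal: int
    intron_interval: tuple[int, int]  # within the intron (transcript axis)
    genomic_interval: tuple[int, int]
    category: str  # "UMP" | "MMP" | "CP" | "mirna_like"
    cluster_id: str | None
    sequence: str
    matures: list[PlantedMature] = field(default_factory=list)


@dataclass
class PlantedDecoy:
    decoy_id: str
    gene_id: str
    chrom: str
    intron_ordinal: int
    genomic_interval: tuple[int, int]
    sequence: str


@dataclass
class ExpressionPair:
    mirna_id: str
    host_gene: str
    rho_sign: int  # +1 or -1


@dataclass
class TruthManifest:
    precursors: list[PlantedPrecursor] = field(default_factory=list)
    decoys: list[PlantedDecoy] = field(default_factory=list)
    expression_pairs: list[ExpressionPair] = field(default_factory=list)

    @property
    def mature_sequences(self) -> set[str]:
        return {
            m.sequence for p in self.precursors for m in p.matures
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)

        def _tup(x):
            return tuple(x)

        precursors = []
        for p in raw["precursors"]:
            matures = [
                PlantedMature(
                    m["mature_id"], m["sequence"], _tup(m["precursor_interval"]),
                    m["star_sequence"], _tup(m["star_interval"]),
                    m["mature_reads"], m["star_reads"],
                )
                for m in p.pop("matures")
            ]
            p["intron_interval"] = _tup(p["intron_interval"])
            p["genomic_interval"] = _tup(p["genomic_interval"])
            precursors.append(PlantedPrecursor(**p, matures=matures))
        decoys = [
            PlantedDecoy(
                d["decoy_id"], d["gene_id"], d["chrom"], d["intron_ordinal"],
                _tup(d["genomic_interval"]), d["sequence"],
            )
            for d in raw["decoys"]
        ]
        pairs = [ExpressionPair(**e) for e in raw["expression_pairs"]]
        return cls(precursors, decoys, pairs)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    models: list[GeneModel]
    truth: TruthManifest
    libraries: list[SmallRnaLibrary] = field(default_factory=list)
    mirna_rpm: pd.DataFrame | None = None
    host_log2: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# sequence construction
# --------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base and b != _COMPLEMENT[base]]
    return choices[int(rng.integers(0, len(choices)))]


def _build_hairpin(
    rng: np.random.Generator,
    arm_len: int,
    loop_len: int,
    mismatch_rate: float,
    protected: list[tuple[int, int]],
    end_margin: int = 10,
) -> str:
    """X + loop + revcomp(X), with mismatches sprinkled on the 3' arm at
    ``mismatch_rate`` but never inside ``protected`` intervals (hairpin
    coordinates) nor within ``end_margin`` of the stem ends."""
    arm = _random_seq(rng, arm_len)
    loop = _random_seq(rng, loop_len)
    arm2 = list(revcomp(arm))
    n = 2 * arm_len + loop_len
    for k in range(len(arm2)):
        pos = arm_len + loop_len + k  # hairpin coordinate
        if k < end_margin or k >= arm_len - end_margin:
            continue
        if any(lo - 2 <= pos < hi + 2 for lo, hi in protected):
            continue
        if rng.random() < mismatch_rate:
            arm2[k] = _mutate(rng, arm2[k])
    hairpin = arm + loop + "".join(arm2)
    assert len(hairpin) == n
    return hairpin


def _planted_duplex_intervals(
    hairpin_len: int, mature_start: int, mature_len: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Mature on the 5' arm at ``mature_start``; star interval under the
    canonical pairing i <-> N-1-i with 2-nt 3' overhangs on both strands."""
    s, e = mature_start, mature_start + mature_len
    star = (hairpin_len + 2 - e, hairpin_len + 2 - s)
    return (s, e), star


# --------------------------------------------------------------------------
# genome + annotation + manifest
# --------------------------------------------------------------------------

def _gene_payloads(config: SyntheticConfig) -> list[tuple[str, object]]:
    payloads: list[tuple[str, object]] = []
    payloads += [("ump", None)] * config.n_ump
    payloads += [("mmp", None)] * config.n_mmp
    payloads += [("cluster", gaps) for gaps in config.cluster_groups]
    payloads += [("mirna_like", None)] * config.n_mirna_like
    payloads += [("decoy", None)] * config.n_decoys
    payloads += [("none", None)] * (config.n_genes - len(payloads))
    return payloads


def build_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate genome, annotation, truth manifest, read libraries and
    expression matrices for one seed."""
    rng = np.random.default_rng(config.seed)
    truth = TruthManifest()
    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 0
    models: list[GeneModel] = []
    spacer = 150

    for g, (kind, payload) in enumerate(_gene_payloads(config)):
        gene_id = f"g{g + 1:03d}"
        strand = "+" if g % 2 == 0 else "-"
        payload_intron = (g % config.introns_per_gene) + 1
        segments: list[tuple[str, str]] = []  # transcript order
        gene_precursors: list[PlantedPrecursor] = []
        gene_decoys: list[PlantedDecoy] = []
        for ordinal in range(1, config.introns_per_gene + 2):
            segments.append(("exon", _random_seq(rng, config.exon_len)))
            if ordinal > config.introns_per_gene:
                break
            if ordinal == payload_intron and kind != "none":
                intron_seq, planted = _build_payload_intron(
                    rng, config, kind, payload, gene_id, ordinal
                )
                if kind == "decoy":
                    gene_decoys.extend(planted)
                else:
                    gene_precursors.extend(planted)
            else:
                intron_seq = _random_seq(rng, config.intron_len)
            segments.append(("intron", intron_seq))

        transcript = "".join(seq for _, seq in segments)
        total = len(transcript)
        gene_start = cursor + spacer
        genomic_seq = transcript if strand == "+" else revcomp(transcript)
        genome_parts.append(_random_seq(rng, spacer))
        genome_parts.append(genomic_seq)
        cursor = gene_start + total

        # map transcript-space segments to genomic exon intervals
        exons = []
        c = 0
        intron_genomic: dict[int, tuple[int, int]] = {}
        intron_no = 0
        for seg_kind, seq in segments:
            lo_t, hi_t = c, c + len(seq)
            if strand == "+":
                g_iv = (gene_start + lo_t, gene_start + hi_t)
            else:
                g_iv = (gene_start + total - hi_t, gene_start + total - lo_t)
            if seg_kind == "exon":
                exons.append(g_iv)
            else:
                intron_no += 1
                intron_genomic[intron_no] = g_iv
            c = hi_t
        models.append(GeneModel(gene_id, chrom, strand, tuple(sorted(exons))))

        for p in gene_precursors:
            p.strand = strand
            p.genomic_interval = _to_genomic(
                p.intron_interval, intron_genomic[p.intron_ordinal], strand
            )
            truth.precursors.append(p)
        for d in gene_decoys:
            d.genomic_interval = _to_genomic(
                d.genomic_interval, intron_genomic[d.intron_ordinal], strand
            )
            truth.decoys.append(d)

    genome = {chrom: "".join(genome_parts) + _random_seq(rng, spacer)}

    # expression pairs: alternate +/- signs over planted canonical precursors
    sign = 1
    for p in truth.precursors:
        if p.category == "mirna_like" or not p.matures:
            continue
        truth.expression_pairs.append(
            ExpressionPair(p.matures[0].mature_id, p.gene_id, sign)
        )
        sign = -sign

    dataset = SyntheticDataset(config, genome, models, truth)
    dataset.libraries = simulate_reads(truth, config)
    dataset.mirna_rpm, dataset.host_log2 = simulate_expression(truth, config, models)
    return dataset


def _to_genomic(
    intron_iv: tuple[int, int], intron_genomic: tuple[int, int], strand: str
) -> tuple[int, int]:
    lo, hi = intron_iv
    g0, g1 = intron_genomic
    if strand == "+":
        return (g0 + lo, g0 + hi)
    return (g1 - hi, g1 - lo)


def _build_payload_intron(
    rng: np.random.Generator,
    config: SyntheticConfig,
    kind: str,
    payload,
    gene_id: str,
    ordinal: int,
):
    """Returns (intron sequence in transcript orientation, planted records
    with intron-relative coordinates)."""
    pad = config.intron_pad
    chrom = "chr1"
    strand = "?"  # filled by the caller once the gene strand is laid out

    matures_all: list[PlantedPrecursor] = []

    if kind == "decoy":
        seq = _build_hairpin(
            rng, config.decoy_arm, config.decoy_loop, config.decoy_mismatch_rate, []
        )
        intron = _random_seq(rng, pad) + seq + _random_seq(rng, pad)
        decoy = PlantedDecoy(
            f"{gene_id}.i{ordinal}.decoy", gene_id, chrom, ordinal,
            (pad, pad + len(seq)), seq,
        )
        return intron, [decoy]

    if kind == "mirna_like":
        specs = [("mirna_like", None, config.mirna_like_products, config.mirna_like_arm)]
        gaps: list[int] = []
    elif kind == "cluster":
        gaps = list(payload)
        specs = [("cluster", None, 1, config.stem_len)] * (len(gaps) + 1)
    elif kind == "mmp":
        specs = [("MMP", None, config.mmp_matures, config.stem_len)]
        gaps = []
    else:
        specs = [("UMP", None, 1, config.stem_len)]
        gaps = []

    # resolve clustered/unclustered categories from the planted gaps
    if kind == "cluster":
        categories = _cluster_categories(gaps)
        cluster_tag = f"{gene_id}.i{ordinal}.cl"
    else:
        categories = [specs[0][0]] * len(specs)
        cluster_tag = None

    pieces = [_random_seq(rng, pad)]
    offset = pad
    for idx, ((_, _, n_matures, arm_len), category) in enumerate(zip(specs, categories)):
        loop = config.loop_len
        spacing = config.mirna_like_spacing if kind == "mirna_like" else 25
        hairpin_len = 2 * arm_len + loop
        duplexes = []
        protected = []
        for k in range(n_matures):
            start = config.mature_offset + k * spacing
            mature_iv, star_iv = _planted_duplex_intervals(
                hairpin_len, start, config.mature_len
            )
            if mature_iv[1] > arm_len or star_iv[0] < arm_len + loop:
                raise ValueError("planted duplex does not fit on the hairpin arms")
            duplexes.append((mature_iv, star_iv))
            protected.extend([mature_iv, star_iv])
        seq = _build_hairpin(
            rng, arm_len, loop, config.stem_mismatch_rate, protected
        )
        cluster_id = cluster_tag if category == "CP" else None
        precursor = PlantedPrecursor(
            f"{gene_id}.i{ordinal}.p{idx + 1}", gene_id, chrom, strand, ordinal,
            (offset, offset + hairpin_len), (0, 0),
            "mirna_like" if kind == "mirna_like" else category,
            cluster_id, seq,
        )
        for k, (mature_iv, star_iv) in enumerate(duplexes):
            precursor.matures.append(
                PlantedMature(
                    f"{precursor.precursor_id}.m{k + 1}",
                    seq[mature_iv[0] : mature_iv[1]],
                    mature_iv,
                    seq[star_iv[0] : star_iv[1]],
                    star_iv,
                    config.mature_reads, config.star_reads,
                )
            )
        matures_all.append(precursor)
        pieces.append(seq)
        offset += hairpin_len
        if idx < len(gaps):
            pieces.append(_random_seq(rng, gaps[idx]))
            offset += gaps[idx]
    pieces.append(_random_seq(rng, pad))
    return "".join(pieces), matures_all


def _cluster_categories(gaps: list[int], max_gap: int = 3000) -> list[str]:
    """Members connected by a gap < max_gap are CP; isolated ones UMP."""
    n = len(gaps) + 1
    linked = [g < max_gap for g in gaps]
    cats = []
    for i in range(n):
        left = linked[i - 1] if i > 0 else False
        right = linked[i] if i < len(linked) else False
        cats.append("CP" if (left or right) else "UMP")
    return cats


# --------------------------------------------------------------------------
# reads
# --------------------------------------------------------------------------

def simulate_reads(
    truth: TruthManifest, config: SyntheticConfig
) -> list[SmallRnaLibrary]:
    """Collapsed libraries: planted duplex reads at exact intervals,
    background degradation tuned to the configured duplex read ratio, and
    smeared sense+antisense decoy reads.  Total counts are split over
    ``n_libraries`` samples multinomially."""
    rng = np.random.default_rng(config.seed + 1)
    pooled: dict[str, int] = {}

    def add(seq: str, count: int) -> None:
        if count > 0:
            pooled[seq] = pooled.get(seq, 0) + count

    for p in truth.precursors:
        duplex_total = 0
        covered: list[tuple[int, int]] = []
        for m in p.matures:
            add(m.sequence, m.mature_reads)
            add(m.star_sequence, m.star_reads)
            duplex_total += m.mature_reads + m.star_reads
            covered.extend([m.precursor_interval, m.star_interval])
        r = config.duplex_read_ratio
        n_background = int(round(duplex_total * (1 - r) / r))
        _add_background(rng, config, p.sequence, covered, n_background, add)

    for d in truth.decoys:
        _add_decoy_reads(rng, config, d.sequence, add)

    return _split_libraries(rng, pooled, config.n_libraries)


def _add_background(rng, config, seq, covered, n_background, add) -> None:
    """Degradation reads: few distinct 5' starts (precise-looking but
    uninformative), each below the 20-read support gate, never fully inside
    a planted duplex interval."""
    if n_background <= 0:
        return
    n_unique = max(6, math.ceil(n_background / config.max_background_read_count))
    placed = 0
    attempts = 0
    chunks = _even_split(n_background, n_unique)
    while placed < n_unique and attempts < 200 * n_unique:
        attempts += 1
        length = int(rng.integers(18, 26))
        start = int(rng.integers(0, max(1, len(seq) - length)))
        iv = (start, start + length)
        if any(lo <= iv[0] and iv[1] <= hi for lo, hi in covered):
            continue
        add(seq[iv[0] : iv[1]], chunks[placed])
        placed += 1


def _add_decoy_reads(rng, config, seq, add) -> None:
    read_len = 21
    max_start = len(seq) - read_len
    starts = rng.choice(max_start + 1, size=min(config.decoy_sense_starts, max_start + 1),
                        replace=False)
    counts = _even_split(config.decoy_sense_reads, len(starts))
    for start, count in zip(sorted(int(s) for s in starts), counts):
        add(seq[start : start + read_len], count)
    # antisense reads must not also match the sense strand
    anti_counts = _even_split(config.decoy_antisense_reads, config.decoy_antisense_unique)
    placed = 0
    attempts = 0
    while placed < config.decoy_antisense_unique and attempts < 2000:
        attempts += 1
        start = int(rng.integers(0, max_start + 1))
        candidate = revcomp(seq[start : start + read_len])
        if candidate in seq:
            continue
        add(candidate, anti_counts[placed])
        placed += 1


def _even_split(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total % parts
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _split_libraries(
    rng: np.random.Generator, pooled: dict[str, int], n_libraries: int
) -> list[SmallRnaLibrary]:
    libs = [
        SmallRnaLibrary(f"lib{i + 1}", {}) for i in range(n_libraries)
    ]
    for seq in sorted(pooled):
        alloc = rng.multinomial(pooled[seq], np.full(n_libraries, 1 / n_libraries))
        for lib, count in zip(libs, alloc):
            if count > 0:
                lib.entries[seq] = int(count)
    return libs


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def correlated_latents(
    rng: np.random.Generator, n: int, rho: float, noise_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Host latent z and miRNA latent sign(rho)*(|rho| z + sigma eps)."""
    z = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    zm = np.sign(rho) * (abs(rho) * z + noise_sd * eps)
    return z, zm


def simulate_expression(
    truth: TruthManifest,
    config: SyntheticConfig,
    models: list[GeneModel] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA RPM matrix and host-gene log2 matrix over the configured
    samples, honoring the per-pair Spearman signs in the manifest."""
    rng = np.random.default_rng(config.seed + 2)
    samples = list(config.samples)
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples for expression simulation")

    paired_hosts = {e.host_gene for e in truth.expression_pairs}
    cluster_hosts = {
        p.gene_id for p in truth.precursors if p.category == "CP"
    }
    gene_ids = sorted(
        {m.gene_id for m in (models or [])}
        | {p.gene_id for p in truth.precursors}
        | paired_hosts
    )
    host_rows = {}
    host_latent = {}
    for gene in gene_ids:
        z = rng.standard_normal(n)
        host_latent[gene] = z
        shift = config.cluster_host_shift if gene in cluster_hosts else 0.0
        host_rows[gene] = np.clip(8 + 2 * z + shift, 0, 16)
    host_log2 = pd.DataFrame(host_rows, index=samples).T

    mirna_rows = {}
    all_matures = [
        m for p in truth.precursors for m in p.matures
    ]
    paired_mirnas = {e.mirna_id: e for e in truth.expression_pairs}
    for m in all_matures:
        if m.mature_id in paired_mirnas:
            e = paired_mirnas[m.mature_id]
            z = host_latent[e.host_gene]
            eps = rng.standard_normal(n)
            zm = e.rho_sign * (
                config.expression_rho * z + config.expression_noise_sd * eps
            )
        else:
            zm = rng.standard_normal(n)
        rpm = np.round(100 * np.exp(0.6 * zm), 3)
        if config.zero_inflation > 0:
            mask = rng.random(n) < config.zero_inflation
            rpm = np.where(mask, 0.0, rpm)
        mirna_rows[m.mature_id] = rpm
    mirna_rpm = pd.DataFrame(mirna_rows, index=samples).T
    return mirna_rpm, host_log2


# --------------------------------------------------------------------------
# file emission
# --------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + GFF3 + collapsed libraries + truth.json + expression
    TSVs; byte-identical for identical configs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "annotation.gff3",
        "truth": out / "truth.json",
        "mirna_rpm": out / "mirna_rpm.tsv",
        "host_log2": out / "host_log2.tsv",
    }
    write_fasta(dataset.genome, paths["genome"])
    write_gene_models(dataset.models, paths["annotation"])
    dataset.truth.to_json(paths["truth"])
    for lib in dataset.libraries:
        p = out / f"reads_{lib.sample_id}.fa"
        write_collapsed_library(lib, p)
        paths[f"reads_{lib.sample_id}"] = p
    if dataset.mirna_rpm is not None:
        dataset.mirna_rpm.to_csv(paths["mirna_rpm"], sep="\t")
    if dataset.host_log2 is not None:
        dataset.host_log2.to_csv(paths["host_log2"], sep="\t")
    return paths
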
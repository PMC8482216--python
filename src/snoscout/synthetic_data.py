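"""Synthetic genome, annotation, alignments and expression matrices.

Emulates the structure of a size-selected (50–200 nt insert) RNA-seq
experiment over a small genome: protein-coding-like multi-exon genes,
intronic and intergenic snoRNA loci of each class (C/D, H/ACA, scaRNA)
built to satisfy the canonical box/structure definitions, decoy loci kept
below the cluster-calling read threshold, unannotated two-exon transcripts
hosting a subset of the intergenic snoRNAs, and candidate/host expression
matrices with controllable Pearson correlation.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    AlignedRead,
    FeatureRecord,
    GenomicInterval,
    reverse_complement,
    write_alignments_tsv,
    write_fasta,
)
from .sno_annotate import C_BOX, D_BOX, H_BOX, DEFAULT_CAB_BOX, IUPAC

SNO_CLASSES = ("CD", "HACA", "SCA")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 200_000
    contig: str = "chrS"
    n_genes: int = 8
    exons_per_gene: int = 4
    n_cd: int = 10
    n_haca: int = 10
    n_sca: int = 10
    n_decoys: int = 10
    n_intergenic: int = 6       # of the planted snoRNAs; the rest are intronic
    n_tu_hosted: int = 4        # intergenic loci wrapped in an unannotated TU
    n_known_sncrna: int = 2
    n_repeats: int = 2
    reads_per_locus_mean: float = 60.0
    reads_per_locus_dispersion: float = 8.0
    min_planted_reads: int = 20  # planted loci are redrawn to clear this depth
    decoy_reads_max: int = 19    # decoys stay strictly below the cluster rule
    insert_size_range: tuple[int, int] = (50, 200)
    end_jitter: int = 5
    end_precision: float = 0.6  # fraction of reads capturing the exact terminus
    background_reads: int = 200
    known_sncrna_reads: int = 25
    tu_exon_reads: int = 12
    tu_junction_reads: int = 6
    n_samples: int = 12
    target_correlations: tuple[float, ...] = (0.31,)
    expression_log_mean: float = 5.0
    expression_log_sd: float = 1.0
    cab_motif: str = DEFAULT_CAB_BOX

    def validate(self) -> None:
        lo, hi = self.insert_size_range
        if not (1 <= lo < hi):
            raise ConfigError("insert_size_range must satisfy 1 <= min < max")
        counts = (self.n_genes, self.n_cd, self.n_haca, self.n_sca,
                  self.n_decoys, self.n_samples)
        if any(c < 0 for c in counts):
            raise ConfigError("counts must be non-negative")
        if self.n_intergenic > self.n_cd + self.n_haca + self.n_sca:
            raise ConfigError("n_intergenic exceeds the number of planted loci")
        if self.n_tu_hosted > self.n_intergenic:
            raise ConfigError("n_tu_hosted exceeds n_intergenic")
        for r in self.target_correlations:
            if not -1.0 <= r <= 1.0:
                raise ConfigError(f"target correlation {r} outside [-1, 1]")
        n_intronic = self.n_cd + self.n_haca + self.n_sca - self.n_intergenic
        slots = self.n_genes * (self.exons_per_gene - 1)
        if n_intronic > slots:
            raise ConfigError(
                f"{n_intronic} intronic loci but only {slots} intron slots "
                f"({self.n_genes} genes x {self.exons_per_gene - 1} introns)"
            )


@dataclass
class PlantedLocus:
    locus_id: str
    interval: GenomicInterval
    sno_class: str              # CD | HACA | SCA, or "decoy"
    context: str                # intronic | intergenic
    host_gene_id: str | None
    sequence: str               # RNA alphabet, 5'->3' on the locus strand

    def __post_init__(self) -> None:
        if self.sno_class not in SNO_CLASSES + ("decoy",):
            raise ValueError(f"bad sno_class {self.sno_class!r}")
        if self.context not in ("intronic", "intergenic"):
            raise ValueError(f"bad context {self.context!r}")


@dataclass
class PlantedTU:
    tu_id: str
    exon1: GenomicInterval
    exon2: GenomicInterval
    hosted_locus_id: str


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    features: list[FeatureRecord]
    loci: list[PlantedLocus]
    tus: list[PlantedTU]
    gene_ids: list[str]


# ---------------------------------------------------------------------------
# sequence construction

_RNA = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_RNA, size=n))


def _concretize(rng: np.random.Generator, motif: str) -> str:
    return "".join(c if c in "ACGU" else rng.choice(list(IUPAC[c])) for c in motif)


def _rna_revcomp(seq: str) -> str:
    return reverse_complement(seq).replace("T", "U")


def _has_motif(seq: str, motif: str, lo: int, hi: int, max_mm: int) -> bool:
    for pos in range(max(lo, 0), min(hi, len(seq)) - len(motif) + 1):
        mm = sum(seq[pos + k] not in IUPAC[c] for k, c in enumerate(motif))
        if mm <= max_mm:
            return True
    return False


def make_cd_sequence(rng: np.random.Generator, cab_motif: str = DEFAULT_CAB_BOX,
                     with_cab: bool = False) -> str:
    """A C/D-box snoRNA: 5 nt terminal stem, C box at position 5, random guide
    region, D box and the complementary 3' stem.  Resampled until the sequence
    carries no accidental H/ACA or (unless requested) CAB signal."""
    while True:
        term5 = _random_rna(rng, 5)
        guide_len = int(rng.integers(50, 90))
        if with_cab:
            stem = _random_rna(rng, 10)
            hairpin = stem + "A" + cab_motif + "C" + _rna_revcomp(stem)
            pad = max(0, guide_len - len(hairpin)) // 2
            guide = _random_rna(rng, pad) + hairpin + _random_rna(rng, pad)
        else:
            guide = _random_rna(rng, guide_len)
        seq = term5 + _concretize(rng, C_BOX) + guide + D_BOX + _rna_revcomp(term5)
        if seq[-6:-3] == "ACA":        # would satisfy the H/ACA 3' rule
            continue
        if not with_cab and cab_motif in seq:
            continue
        return seq


def _hairpin(rng: np.random.Generator, stem_len: int, loop: str) -> str:
    stem = _random_rna(rng, stem_len)
    return stem + loop + _rna_revcomp(stem)


def make_haca_sequence(rng: np.random.Generator, cab_motif: str = DEFAULT_CAB_BOX,
                       with_cab: bool = False) -> str:
    """An H/ACA-box snoRNA: hairpin–hinge(H box)–hairpin–ACA–3 nt tail.
    scaRNA variants place the CAB box in the 5' hairpin apical loop."""
    while True:
        if with_cab:
            loop1 = "A" + cab_motif + "C"
            hp1 = _hairpin(rng, 10, loop1)
        else:
            hp1 = _hairpin(rng, int(rng.integers(9, 12)), _random_rna(rng, int(rng.integers(4, 7))))
        hp2 = _hairpin(rng, int(rng.integers(9, 12)), _random_rna(rng, int(rng.integers(4, 7))))
        seq = (
            _random_rna(rng, int(rng.integers(3, 6)))
            + hp1
            + _concretize(rng, H_BOX)
            + hp2
            + _random_rna(rng, int(rng.integers(0, 4)))
            + "ACA"
            + _random_rna(rng, 3)
        )
        if _has_motif(seq, C_BOX, 0, 12, max_mm=1):   # avoid an accidental C/D call
            continue
        if not with_cab and cab_motif in seq:
            continue
        return seq


def make_sca_sequence(rng: np.random.Generator, cab_motif: str = DEFAULT_CAB_BOX,
                      flavor: str = "HACA") -> str:
    if flavor == "CD":
        return make_cd_sequence(rng, cab_motif, with_cab=True)
    return make_haca_sequence(rng, cab_motif, with_cab=True)


# ---------------------------------------------------------------------------
# genome assembly


def _rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def generate_genome(config: SimulationConfig) -> SyntheticDataset:
    """Lay out genes, planted loci, decoys, known sncRNAs, repeats and
    unannotated two-exon transcripts on one contig; return the dataset with
    genome sequence, annotation records and truth tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig = config.contig

    classes = (["CD"] * config.n_cd + ["HACA"] * config.n_haca + ["SCA"] * config.n_sca)
    rng.shuffle(classes)
    n_sno = len(classes)
    intergenic_idx = set(range(config.n_intergenic))  # first few after shuffle
    sno_specs = [(f"sno_{i + 1}", classes[i], i in intergenic_idx) for i in range(n_sno)]
    intronic_queue = [s for s in sno_specs if not s[2]]
    intergenic_queue = [s for s in sno_specs if s[2]]

    def make_seq(cls: str, sca_flavor: str) -> str:
        if cls == "CD":
            return make_cd_sequence(rng, config.cab_motif)
        if cls == "HACA":
            return make_haca_sequence(rng, config.cab_motif)
        return make_sca_sequence(rng, config.cab_motif, flavor=sca_flavor)

    features: list[FeatureRecord] = []
    loci: list[PlantedLocus] = []
    tus: list[PlantedTU] = []
    gene_ids: list[str] = []
    # (start_in_genome, dna) pieces to splice into the random background
    patches: list[tuple[int, str]] = []

    spacing = 1500
    cursor = spacing
    sca_flip = 0

    # -- genes with intronic snoRNA slots
    for g in range(config.n_genes):
        gene_id = f"gene_{g + 1}"
        gene_ids.append(gene_id)
        strand = "+" if rng.random() < 0.5 else "-"
        exon_starts, exon_ends = [], []
        pos = cursor
        for e in range(config.exons_per_gene):
            elen = int(rng.integers(250, 350))
            exon_starts.append(pos)
            exon_ends.append(pos + elen)
            pos += elen
            if e < config.exons_per_gene - 1:
                ilen = int(rng.integers(1200, 2000))
                intron = (exon_ends[-1], exon_ends[-1] + ilen)
                if intronic_queue:
                    locus_id, cls, _ = intronic_queue.pop(0)
                    sca_flip += 1
                    seq = make_seq(cls, "CD" if sca_flip % 2 else "HACA")
                    slack = ilen - len(seq) - 60
                    off = 30 + int(rng.integers(0, max(slack, 1)))
                    s = intron[0] + off
                    iv = GenomicInterval(contig, s, s + len(seq), strand)
                    loci.append(PlantedLocus(locus_id, iv, cls, "intronic", gene_id, seq))
                    dna = _rna_to_dna(seq)
                    patches.append((s, dna if strand == "+" else reverse_complement(dna)))
                pos += ilen
        tx_iv = GenomicInterval(contig, exon_starts[0], exon_ends[-1], strand)
        features.append(FeatureRecord(tx_iv, "ER", gene_id, f"tx_{gene_id}"))  # placeholder; replaced below
        features.pop()
        for e, (s, e_end) in enumerate(zip(exon_starts, exon_ends)):
            features.append(
                FeatureRecord(GenomicInterval(contig, s, e_end, strand), "ER",
                              gene_id, f"{gene_id}.exon{e + 1}")
            )
        for a_end, b_start in zip(exon_ends, exon_starts[1:]):
            features.append(
                FeatureRecord(GenomicInterval(contig, a_end, b_start, strand), "iR",
                              gene_id, f"{gene_id}.intron")
            )
        if strand == "+":
            pr = GenomicInterval(contig, max(0, exon_starts[0] - 1000), exon_starts[0], strand)
        else:
            pr = GenomicInterval(contig, exon_ends[-1], exon_ends[-1] + 1000, strand)
        features.append(FeatureRecord(pr, "PR", gene_id, f"{gene_id}.promoter"))
        cursor = pos + spacing

    if intronic_queue:
        raise ConfigError("not enough intron slots for the intronic loci")

    # -- intergenic snoRNAs; the first n_tu_hosted sit inside unannotated TUs
    for k, (locus_id, cls, _) in enumerate(intergenic_queue):
        sca_flip += 1
        seq = make_seq(cls, "CD" if sca_flip % 2 else "HACA")
        strand = "+" if rng.random() < 0.5 else "-"
        if k < config.n_tu_hosted:
            e1_len = e2_len = 200
            gap1 = int(rng.integers(220, 300))
            gap2 = int(rng.integers(220, 300))
            e1 = GenomicInterval(contig, cursor, cursor + e1_len, strand)
            s = e1.end + gap1
            iv = GenomicInterval(contig, s, s + len(seq), strand)
            e2s = iv.end + gap2
            e2 = GenomicInterval(contig, e2s, e2s + e2_len, strand)
            tus.append(PlantedTU(f"TU_{locus_id}", e1, e2, locus_id))
            cursor = e2.end + spacing
        else:
            iv = GenomicInterval(contig, cursor, cursor + len(seq), strand)
            cursor = iv.end + spacing
        loci.append(PlantedLocus(locus_id, iv, cls, "intergenic", None, seq))
        dna = _rna_to_dna(seq)
        patches.append((iv.start, dna if strand == "+" else reverse_complement(dna)))

    # -- decoys (intergenic space, depth < threshold downstream)
    for d in range(config.n_decoys):
        dlen = int(rng.integers(60, 150))
        iv = GenomicInterval(contig, cursor, cursor + dlen, "+")
        seq = _random_rna(rng, dlen)
        loci.append(PlantedLocus(f"decoy_{d + 1}", iv, "decoy", "intergenic", None, seq))
        patches.append((iv.start, _rna_to_dna(seq)))
        cursor = iv.end + spacing

    # -- known sncRNAs and repeats (reads here are excluded from novelty calls)
    known_seqs: dict[str, str] = {}
    for k in range(config.n_known_sncrna):
        seq = make_cd_sequence(rng, config.cab_motif)
        iv = GenomicInterval(contig, cursor, cursor + len(seq), "+")
        name = f"known_sno_{k + 1}"
        features.append(FeatureRecord(iv, "known_sncRNA", None, name))
        known_seqs[name] = seq
        patches.append((iv.start, _rna_to_dna(seq)))
        cursor = iv.end + spacing
    for k in range(config.n_repeats):
        rlen = int(rng.integers(300, 600))
        iv = GenomicInterval(contig, cursor, cursor + rlen, ".")
        features.append(FeatureRecord(iv, "repeat", None, f"repeat_{k + 1}"))
        cursor = iv.end + spacing

    if cursor + spacing > config.genome_length:
        raise ConfigError(
            f"genome_length {config.genome_length} too small: layout needs "
            f"{cursor + spacing} nt (constraint: non-overlapping loci with "
            f"{spacing} nt spacing)"
        )

    genome_arr = rng.choice(np.array(list("ACGT")), size=config.genome_length)
    genome = "".join(genome_arr)
    for start, dna in patches:
        genome = genome[:start] + dna + genome[start + len(dna):]
    ds = SyntheticDataset(config, {contig: genome}, features, loci, tus, gene_ids)
    ds.known_sncrna_seqs = known_seqs  # type: ignore[attr-defined]
    return ds


# ---------------------------------------------------------------------------
# read simulation


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with the (mean, dispersion) parametrization:
    variance = mean + mean^2 / dispersion."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _jitter(rng: np.random.Generator, j: int, precision: float) -> int:
    """Read-end offset around a processed terminus: exact with probability
    ``precision`` (mature ends dominate a pileup of a processed RNA),
    otherwise uniform over the remaining +-j positions."""
    if j <= 0 or rng.random() < precision:
        return 0
    offsets = [o for o in range(-j, j + 1) if o != 0]
    return offsets[int(rng.integers(len(offsets)))]


def _locus_reads(
    rng: np.random.Generator,
    locus: PlantedLocus,
    count: int,
    config: SimulationConfig,
    genome_len: int,
    sample_names: list[str],
    prefix: str,
) -> list[AlignedRead]:
    lo, hi = config.insert_size_range
    j = config.end_jitter
    reads = []
    for i in range(count):
        s = locus.interval.start + _jitter(rng, j, config.end_precision)
        e = locus.interval.end + _jitter(rng, j, config.end_precision)
        s = max(s, 0)
        if e - s < lo:
            e = s + lo
        elif e - s > hi:
            e = s + hi
        e = min(e, genome_len)
        sample = sample_names[int(rng.integers(len(sample_names)))]
        reads.append(
            AlignedRead(
                f"{prefix}{locus.locus_id}_{i}", sample,
                [GenomicInterval(locus.interval.contig, s, e, locus.interval.strand)],
            )
        )
    return reads


def simulate_reads(ds: SyntheticDataset, seed: int | None = None) -> tuple[list[AlignedRead], dict[str, int]]:
    """Size-selected library over the planted loci: negative-binomial depth
    (redrawn above ``min_planted_reads`` for real loci), end jitter, length
    clipping to the insert range; decoys capped below the cluster threshold;
    background reads scattered over gene exons and known sncRNAs.

    Returns the reads and the per-locus simulated depth (truth for recovery
    checks downstream).
    """
    config = ds.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    contig = config.contig
    genome_len = len(ds.genome[contig])
    samples = [f"S{i + 1}" for i in range(max(config.n_samples, 1))]
    reads: list[AlignedRead] = []
    depths: dict[str, int] = {}
    for locus in ds.loci:
        if locus.sno_class == "decoy":
            count = int(rng.integers(3, config.decoy_reads_max + 1))
        elif config.reads_per_locus_mean <= 0:
            count = 0
        else:
            count = _nb_draw(rng, config.reads_per_locus_mean, config.reads_per_locus_dispersion)
            while count < config.min_planted_reads:
                count = _nb_draw(rng, config.reads_per_locus_mean, config.reads_per_locus_dispersion)
        depths[locus.locus_id] = count
        reads.extend(_locus_reads(rng, locus, count, config, genome_len, samples, "m_"))

    # background over exons (filtered out as ER downstream)
    exons = [f for f in ds.features if f.feature_class == "ER"]
    for i in range(config.background_reads):
        ex = exons[int(rng.integers(len(exons)))]
        rlen = int(rng.integers(*config.insert_size_range))
        rlen = min(rlen, len(ex.interval))
        s = ex.interval.start + int(rng.integers(0, max(len(ex.interval) - rlen, 1)))
        sample = samples[int(rng.integers(len(samples)))]
        reads.append(AlignedRead(
            f"bg_{i}", sample,
            [GenomicInterval(contig, s, s + rlen, ex.interval.strand)],
        ))
    # pileups on already-annotated sncRNAs (excluded from novelty calling)
    for f in ds.features:
        if f.feature_class != "known_sncRNA":
            continue
        fake = PlantedLocus(f.name, f.interval, "decoy", "intergenic", None, "")
        reads.extend(_locus_reads(
            rng, fake, config.known_sncrna_reads, config, genome_len, samples, "k_"
        ))
    return reads, depths


def simulate_total_rna_reads(ds: SyntheticDataset, seed: int | None = None) -> list[AlignedRead]:
    """Total-RNA evidence for the unannotated transcripts: unspliced reads
    tiling each TU exon (outer ends jittered, inner ends flush with the
    splice sites) and spliced reads across the exon1→exon2 junction."""
    config = ds.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    j = config.end_jitter
    reads: list[AlignedRead] = []
    for tu in ds.tus:
        for ex_i, ex in enumerate((tu.exon1, tu.exon2)):
            inner_is_end = ex_i == 0  # exon1's inner edge is its end (donor)
            for r in range(config.tu_exon_reads):
                frac = r / max(config.tu_exon_reads - 1, 1)
                rlen = 80
                s = ex.start + int(round(frac * (len(ex) - rlen)))
                e = s + rlen
                if inner_is_end:
                    if r == config.tu_exon_reads - 1:
                        e = ex.end          # coverage reaches the donor exactly
                    if r == 0:
                        s = ex.start + int(rng.integers(-j, j + 1))  # soft outer edge
                        s = max(s, 0)
                else:
                    if r == 0:
                        s = ex.start        # coverage starts at the acceptor
                    if r == config.tu_exon_reads - 1:
                        e = ex.end + int(rng.integers(-j, j + 1))
                reads.append(AlignedRead(
                    f"t_{tu.tu_id}_e{ex_i}_{r}", "total",
                    [GenomicInterval(ex.contig, s, e, ex.strand)],
                ))
        for r in range(config.tu_junction_reads):
            x = int(rng.integers(30, 60))
            y = int(rng.integers(30, 60))
            reads.append(AlignedRead(
                f"t_{tu.tu_id}_j{r}", "total",
                [
                    GenomicInterval(tu.exon1.contig, tu.exon1.end - x, tu.exon1.end, tu.exon1.strand),
                    GenomicInterval(tu.exon2.contig, tu.exon2.start, tu.exon2.start + y, tu.exon2.strand),
                ],
            ))
    return reads


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    pairs: list[tuple[str, str]],
    r_target: float | Sequence[float],
    n_samples: int,
    seed: int,
    log_mean: float = 5.0,
    log_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate/host count matrices whose per-pair log-abundances follow a
    bivariate normal with correlation ``r_target`` (a scalar, or one value
    per pair); counts are exp-transformed and rounded.

    One latent vector is drawn per host gene and candidates sharing a host
    are drawn conditionally on it, so every pair carries its own target
    correlation even when several snoRNAs sit in introns of the same gene.
    Returns (candidate_counts, host_counts) indexed by id with one column
    per sample.
    """
    targets = (
        [float(r_target)] * len(pairs)
        if np.isscalar(r_target)
        else [float(r) for r in r_target]
    )
    if len(targets) != len(pairs):
        raise ValueError("r_target must be scalar or one value per pair")
    for r in targets:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"r_target {r} outside [-1, 1]")
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    cand_rows, host_rows = {}, {}
    for (cand_id, host_id), r in zip(pairs, targets):
        if host_id not in host_rows:
            host_rows[host_id] = rng.standard_normal(n_samples)
        zh = host_rows[host_id]
        eps = rng.standard_normal(n_samples)
        zc = r * zh + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        cand_rows[cand_id] = np.rint(np.exp(log_mean + log_sd * zc)).astype(int)
    host_rows = {
        h: np.rint(np.exp(log_mean + log_sd * z)).astype(int)
        for h, z in host_rows.items()
    }
    cand = pd.DataFrame.from_dict(cand_rows, orient="index", columns=samples)
    host = pd.DataFrame.from_dict(host_rows, orient="index", columns=samples)
    cand.index.name = "candidate_id"
    host.index.name = "gene_id"
    return cand, host


# ---------------------------------------------------------------------------
# dataset writer


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic dataset; returns the path map.

    Files: genome.fa, annotation.gff3, truth_loci.tsv, truth_tus.tsv,
    medium_alignments.tsv, total_alignments.tsv, candidate_counts.tsv,
    host_counts.tsv, known_sncrnas.fa (homology reference with family tags).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_genome(config)
    reads, depths = simulate_reads(ds)
    total_reads = simulate_total_rna_reads(ds)

    paths = {k: outdir / v for k, v in {
        "genome": "genome.fa", "annotation": "annotation.gff3",
        "truth_loci": "truth_loci.tsv", "truth_tus": "truth_tus.tsv",
        "medium_alignments": "medium_alignments.tsv",
        "total_alignments": "total_alignments.tsv",
        "candidate_counts": "candidate_counts.tsv", "host_counts": "host_counts.tsv",
        "reference": "known_sncrnas.fa", "config": "config_echo.tsv",
    }.items()}

    write_fasta(ds.genome, paths["genome"])
    gff_with_transcripts(ds, paths["annotation"])
    write_alignments_tsv(reads, paths["medium_alignments"])
    write_alignments_tsv(total_reads, paths["total_alignments"])

    truth = pd.DataFrame([{
        "locus_id": l.locus_id, "contig": l.interval.contig,
        "start": l.interval.start, "end": l.interval.end,
        "strand": l.interval.strand, "sno_class": l.sno_class,
        "context": l.context, "host_gene_id": l.host_gene_id or "",
        "simulated_reads": depths[l.locus_id], "sequence": l.sequence,
    } for l in ds.loci])
    truth.to_csv(paths["truth_loci"], sep="\t", index=False)

    pd.DataFrame([{
        "tu_id": t.tu_id, "contig": t.exon1.contig, "strand": t.exon1.strand,
        "exon1_start": t.exon1.start, "exon1_end": t.exon1.end,
        "exon2_start": t.exon2.start, "exon2_end": t.exon2.end,
        "hosted_locus_id": t.hosted_locus_id,
    } for t in ds.tus]).to_csv(paths["truth_tus"], sep="\t", index=False)

    # expression: intronic planted loci paired with their host genes, target
    # correlations cycled over the configured list
    pairs = [(l.locus_id, l.host_gene_id) for l in ds.loci
             if l.context == "intronic" and l.sno_class != "decoy" and l.host_gene_id]
    targets = config.target_correlations or (0.0,)
    per_pair_r = [targets[i % len(targets)] for i in range(len(pairs))]
    if pairs:
        cand, host = simulate_expression(
            pairs, per_pair_r, config.n_samples, seed=config.seed * 100_003 + 3,
            log_mean=config.expression_log_mean, log_sd=config.expression_log_sd,
        )
    else:
        cand, host = pd.DataFrame(), pd.DataFrame()
    # counts rows carry locus coordinates so candidates can be matched by overlap
    by_id = {l.locus_id: l for l in ds.loci}
    if not cand.empty:
        meta = pd.DataFrame({
            "contig": [by_id[i].interval.contig for i in cand.index],
            "start": [by_id[i].interval.start for i in cand.index],
            "end": [by_id[i].interval.end for i in cand.index],
            "strand": [by_id[i].interval.strand for i in cand.index],
        }, index=cand.index)
        cand = pd.concat([meta, cand], axis=1)
    cand.to_csv(paths["candidate_counts"], sep="\t")
    host.to_csv(paths["host_counts"], sep="\t")

    write_fasta(_reference_seqs(ds), paths["reference"])
    cfg = pd.Series({**{k: str(v) for k, v in asdict(config).items()}})
    cfg.to_csv(paths["config"], sep="\t", header=False)
    return paths


def gff_with_transcripts(ds: SyntheticDataset, path: str | Path) -> None:
    """Write the annotation as gene/transcript/exon lines plus known sncRNAs
    and repeats; introns and promoters are left for the annotation reader to
    derive from the exon chains (exercising that path)."""
    lines = ["##gff-version 3"]
    contig = ds.config.contig
    by_gene: dict[str, list[FeatureRecord]] = {}
    for f in ds.features:
        if f.feature_class == "ER" and f.gene_id:
            by_gene.setdefault(f.gene_id, []).append(f)
    for gene_id, exons in by_gene.items():
        exons = sorted(exons, key=lambda f: f.interval.start)
        g0, g1 = exons[0].interval.start, exons[-1].interval.end
        strand = exons[0].interval.strand
        lines.append(f"{contig}\t.\tgene\t{g0 + 1}\t{g1}\t.\t{strand}\t.\t"
                     f"ID={gene_id};gene_id={gene_id}")
        tx_id = f"{gene_id}.t1"
        lines.append(f"{contig}\t.\ttranscript\t{g0 + 1}\t{g1}\t.\t{strand}\t.\t"
                     f"ID={tx_id};Parent={gene_id};gene_id={gene_id}")
        for i, ex in enumerate(exons):
            lines.append(
                f"{contig}\t.\texon\t{ex.interval.start + 1}\t{ex.interval.end}\t.\t"
                f"{strand}\t.\tID={tx_id}.e{i + 1};Parent={tx_id};gene_id={gene_id}"
            )
    for f in ds.features:
        if f.feature_class == "known_sncRNA":
            lines.append(f"{contig}\t.\tncRNA\t{f.interval.start + 1}\t{f.interval.end}\t.\t"
                         f"{f.interval.strand}\t.\tID={f.name}")
        elif f.feature_class == "repeat":
            lines.append(f"{contig}\t.\trepeat_region\t{f.interval.start + 1}\t{f.interval.end}\t.\t"
                         f"{f.interval.strand if f.interval.strand != '.' else '+'}\t.\tID={f.name}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _reference_seqs(ds: SyntheticDataset) -> dict[str, str]:
    """Known-sncRNA reference for homology: the annotated known snoRNAs, exact
    copies of half the planted loci (these candidates are 'homologs of known
    snoRNAs'), and unrelated decoy families."""
    rng = np.random.default_rng(ds.config.seed + 3)
    seqs: dict[str, str] = {}
    for name, seq in getattr(ds, "known_sncrna_seqs", {}).items():
        seqs[f"{name} family=snoRNA"] = seq
    for i, l in enumerate(ds.loci):
        if l.sno_class != "decoy" and i % 2 == 0:
            seqs[f"ref_{l.locus_id} family=snoRNA"] = l.sequence
    for fam in ("miRNA", "snRNA", "tRNA"):
        seqs[f"ref_{fam}_1 family={fam}"] = _random_rna(rng, int(rng.integers(70, 120)))
    return seqs
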
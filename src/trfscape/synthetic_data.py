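"""Synthetic genomes and stage-structured small-RNA libraries with known truth.

The generator plants toy tRNA genes (70–76 nt mature length, anticodon at
mature positions 33–35) in a mitochondrial sequence and several nuclear
contigs, then fragments them into six developmental-stage libraries (egg,
four larval instars, adult) according to per-anticodon region profiles and
per-anticodon stage trends.  Every read is recorded in a truth table with
its intended parent(s), region and fate, so the whole downstream pipeline
is testable without any real sequencing data.

Planted complications mirror the hazards the pipeline must handle: decoy
loci (exact extra copies of a tRNA body in non-tRNA context), genes with
polymorphic sites, spike-in sequences for normalization, pure-noise reads,
N-containing and low-quality reads, reads outside the 25–45 nt window,
and unique sequences seen fewer than five times.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .trf_classification import (
    AC_STEM_LOOP,
    FIVE_END,
    FIVE_HALF,
    THREE_END,
    THREE_HALF,
)
from .trna_catalog import MatureTRNA, TRNAGene, reverse_complement

DEFAULT_STAGES: tuple[str, ...] = ("egg", "L1", "L2", "L3", "L4", "adult")

#: anchored fragment classes the default profiles draw from
ANCHORED_CLASSES = (FIVE_HALF, THREE_HALF, FIVE_END, THREE_END)

TREND_LABELS = ("increasing", "decreasing", "egg", "flat")

# isotype/anticodon pool (DNA alphabet); mito families are drawn from the
# front, nuclear families after them, polymorphic extras from the tail
_ANTICODON_POOL: tuple[tuple[str, str], ...] = (
    ("Ser", "GCT"), ("Val", "TAC"), ("Lys", "CTT"), ("Thr", "TGT"),
    ("Ile", "GAT"), ("Phe", "GAA"), ("Gly", "TCC"), ("Asn", "GTT"),
    ("Met", "CAT"), ("Tyr", "GTA"), ("Asp", "GTC"), ("Cys", "GCA"),
    ("Pro", "TGG"), ("Gln", "TTG"), ("Leu", "TAA"), ("Ala", "TCG"),
    ("Gly", "GCC"), ("Gly", "CCC"), ("Glu", "CTC"), ("Glu", "TTC"),
    ("His", "GTG"), ("SeC", "TCA"), ("Pro", "CGG"), ("Gln", "CTG"),
    ("Ala", "CGC"), ("Arg", "TCT"), ("Ser", "TGA"), ("Leu", "CAA"),
    ("Arg", "ACG"), ("Val", "AAC"), ("Thr", "AGT"), ("Ser", "AGA"),
    ("Ile", "AAT"), ("Ala", "AGC"), ("Arg", "CCT"), ("Trp", "CCA"),
)


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults emulate the study conditions downstream modules are built
    for: six stage libraries, ~10^4 fragment reads over 20 anticodon
    families (a deliberately scaled-down library), 5 % noise, two
    spike-ins at stage-dependent counts, one decoy locus and one
    polymorphic gene family.
    """

    seed: int = 0
    stage_names: tuple[str, ...] = DEFAULT_STAGES
    n_mito_genes: int = 6
    n_nuclear_genes: int = 14
    n_subtypes_per_anticodon: int = 2
    n_fragment_reads: int = 10_000
    read_length_min: int = 25
    read_length_max: int = 45
    noise_fraction: float = 0.05
    low_quality_fraction: float = 0.02
    n_base_fraction: float = 0.01
    below_threshold_fraction: float = 0.02
    short_fraction: float = 0.01
    long_fraction: float = 0.01
    decoy_count: int = 1
    polymorphic_gene_count: int = 1
    n_nuclear_contigs: int = 4
    mature_length_range: tuple[int, int] = (70, 76)
    anticodon_position: int = 33  # 1-based start on the mature sequence
    stem_width: int = 5
    # per-stage counts of the two spike-ins, chosen unequal so that the
    # normalization factors are nontrivial
    spike_counts: tuple[tuple[int, int], ...] = (
        (70, 50), (45, 35), (60, 40), (80, 60), (50, 40), (65, 45),
    )
    # per-anticodon region profile; None -> cycle a 70 % dominant class
    # over the anchored classes with the rest split evenly
    fragmentation_profile: Mapping[str, Mapping[str, float]] | None = None
    dominant_share: float = 0.7
    # per-anticodon stage trend; None -> cycle over TREND_LABELS
    trend_profile: Mapping[str, str] | None = None
    trend_fold: float = 2.5
    # decreasing series use a gentler fold: a 2.5-fold decreasing series
    # would put >50 % of its reads in the egg stage and thus be
    # egg-enriched by definition, making the two classes inseparable
    trend_fold_decreasing: float = 1.7
    egg_share: float = 0.6
    reads_per_polymorphic_family: int = 120
    gzip_fastq: bool = False

    def __post_init__(self) -> None:
        if len(self.stage_names) != 6:
            raise SimulationConfigError("exactly six stage names are required")
        if len(self.spike_counts) != 6:
            raise SimulationConfigError("spike_counts needs one pair per stage")
        for name in (
            "noise_fraction", "low_quality_fraction", "n_base_fraction",
            "below_threshold_fraction", "short_fraction", "long_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name}={v} outside [0, 1]")
        if self.fragmentation_profile is not None:
            for ac, props in self.fragmentation_profile.items():
                total = sum(props.values())
                if abs(total - 1.0) > 1e-9:
                    raise SimulationConfigError(
                        f"profile for {ac} sums to {total}, not 1"
                    )
                if any(p < 0 for p in props.values()):
                    raise SimulationConfigError(f"profile for {ac} has negative part")


@dataclass
class TruthRead:
    """One truth-table row: a read sequence in one stage library."""

    sequence: str
    stage: str
    count: int
    parents: tuple[str, ...]
    anticodon: str
    region: str
    fate: str  # trf | spike | noise | contains_n | low_quality |
    #            too_short | too_long | below_threshold | decoy | polymorphic
    compartment: str = ""


@dataclass
class GenomeBundle:
    """A toy genome with planted tRNA genes and, after simulation, reads."""

    config: SimulationConfig
    mito_sequence: str
    nuclear_contigs: dict[str, str]
    planted_genes: list[TRNAGene]
    planted_matures: dict[str, MatureTRNA]
    spike_sequences: tuple[str, str]
    decoy_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    truth_table: list[TruthRead] = field(default_factory=list)

    @property
    def mito_genes(self) -> list[TRNAGene]:
        return [g for g in self.planted_genes if g.contig_id == "mito"]

    @property
    def nuclear_genes(self) -> list[TRNAGene]:
        return [g for g in self.planted_genes if g.contig_id != "mito"]

    def genes_of_anticodon(self, anticodon: str) -> list[TRNAGene]:
        return [g for g in self.planted_genes if g.anticodon == anticodon]

    def compartment_of(self, anticodon: str) -> str:
        genes = self.genes_of_anticodon(anticodon)
        return "mitochondrial" if genes and genes[0].contig_id == "mito" else "nuclear"

    # ---- text outputs -------------------------------------------------
    def write_fasta(self, mito_path: str | Path, nuclear_path: str | Path) -> None:
        with open(mito_path, "w") as fh:
            fh.write(">mito\n")
            fh.write(_wrap(self.mito_sequence))
        with open(nuclear_path, "w") as fh:
            for name in sorted(self.nuclear_contigs):
                fh.write(f">{name}\n")
                fh.write(_wrap(self.nuclear_contigs[name]))

    def write_annotation(self, path: str | Path, *, compartment: str) -> None:
        """tRNAscan-SE-style tabular annotation for one compartment."""
        genes = self.mito_genes if compartment == "mitochondrial" else self.nuclear_genes
        with open(path, "w") as fh:
            fh.write("Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tCove\n")
            fh.write("Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n")
            fh.write("--------\t------\t-----\t------\t----\t-----\t-----\t----\t------\n")
            for g in genes:
                number = g.gene_id.rsplit("trna", 1)[-1]
                begin, end = (g.start, g.end) if g.strand == "+" else (g.end, g.start)
                note = "polymorphic" if g.polymorphic else ("pseudo" if g.pseudo else "")
                score = g.cove_score_euk if g.cove_score_euk is not None else 60.0
                row = (
                    f"{g.contig_id}\t{number}\t{begin}\t{end}\t{g.isotype}\t"
                    f"{g.anticodon}\t0\t0\t{score:.1f}"
                )
                fh.write(row + (f"\t{note}\n" if note else "\n"))

    def write_spikes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.spike_sequences, start=1):
                fh.write(f">spike{i}\n{seq}\n")


def _wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width)) + "\n"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _make_body(rng: np.random.Generator, mature_len: int, anticodon: str, ac_pos: int) -> str:
    """A random gene body with the anticodon planted; never CCA-terminal."""
    body_len = mature_len - 3
    body = list(_random_seq(rng, body_len))
    body[ac_pos - 1 : ac_pos + 2] = list(anticodon)
    if "".join(body[-3:]) == "CCA":
        body[-1] = "T"
    return "".join(body)


def generate_genome(config: SimulationConfig) -> GenomeBundle:
    """Build a deterministic toy genome bundle for the given config.

    Guarantees: at least one minus-strand gene; at least one anticodon
    with multiple isodecoder subtypes (when configured); gene bodies never
    end in CCA (the tail is added post-transcriptionally, not encoded);
    decoy loci are exact unannotated copies of a tRNA body; spike
    sequences occur nowhere in the genome.
    """
    rng = np.random.default_rng(config.seed)
    n_families = config.n_mito_genes + config.n_nuclear_genes + config.polymorphic_gene_count
    if n_families > len(_ANTICODON_POOL):
        raise SimulationConfigError(
            f"requested {n_families} anticodon families; pool holds "
            f"{len(_ANTICODON_POOL)}"
        )
    lo, hi = config.mature_length_range
    ac_pos = config.anticodon_position

    pool = list(_ANTICODON_POOL)
    mito_pool = pool[: config.n_mito_genes]
    nuc_pool = pool[config.n_mito_genes : config.n_mito_genes + config.n_nuclear_genes]
    poly_pool = pool[
        config.n_mito_genes + config.n_nuclear_genes : n_families
    ]

    genes: list[TRNAGene] = []
    matures: dict[str, MatureTRNA] = {}

    # --- mitochondrial compartment: one gene per anticodon ------------
    mito_parts: list[str] = []
    mito_pos = 0
    mito_counter = 0

    def _append_gap(parts: list[str], n: int) -> int:
        parts.append(_random_seq(rng, n))
        return n

    mito_pos += _append_gap(mito_parts, 60)
    for i, (isotype, anticodon) in enumerate(mito_pool):
        mature_len = int(rng.integers(lo, hi + 1))
        body = _make_body(rng, mature_len, anticodon, ac_pos)
        strand = "-" if i == 1 else "+"  # guarantee a minus-strand gene
        genomic = reverse_complement(body) if strand == "-" else body
        start = mito_pos + 1
        mito_parts.append(genomic)
        mito_pos += len(genomic)
        end = mito_pos
        mito_counter += 1
        gid = f"mito.trna{mito_counter}"
        genes.append(
            TRNAGene(
                gene_id=gid, contig_id="mito", start=start, end=end,
                strand=strand, isotype=isotype, anticodon=anticodon,
                cove_score_euk=float(np.round(40 + 30 * rng.random(), 1)),
            )
        )
        matures[gid] = MatureTRNA(
            gene_id=gid, sequence=body + "CCA", anticodon=anticodon,
            anticodon_start=ac_pos, anticodon_end=ac_pos + 2, isotype=isotype,
        )
        mito_pos += _append_gap(mito_parts, int(rng.integers(30, 60)))
    mito_pos += _append_gap(mito_parts, 40)
    mito_sequence = "".join(mito_parts)

    # --- nuclear compartment: subtype families over several contigs ---
    contig_names = [f"contig{i + 1}" for i in range(config.n_nuclear_contigs)]
    contig_parts: dict[str, list[str]] = {c: [_random_seq(rng, 80)] for c in contig_names}
    contig_pos: dict[str, int] = {c: 80 for c in contig_names}
    contig_counter: dict[str, int] = {c: 0 for c in contig_names}

    def _place_nuclear(
        body: str, isotype: str, anticodon: str, ci: int, *, polymorphic: bool = False
    ) -> TRNAGene:
        contig = contig_names[ci % len(contig_names)]
        strand = "+" if (contig_counter[contig] % 3) else "-"
        genomic = reverse_complement(body) if strand == "-" else body
        start = contig_pos[contig] + 1
        contig_parts[contig].append(genomic)
        contig_pos[contig] += len(genomic)
        end = contig_pos[contig]
        gap = _random_seq(rng, int(rng.integers(40, 80)))
        contig_parts[contig].append(gap)
        contig_pos[contig] += len(gap)
        contig_counter[contig] += 1
        gid = f"{contig}.trna{contig_counter[contig]}"
        gene = TRNAGene(
            gene_id=gid, contig_id=contig, start=start, end=end, strand=strand,
            isotype=isotype, anticodon=anticodon,
            cove_score_euk=float(np.round(45 + 30 * rng.random(), 1)),
            polymorphic=polymorphic,
        )
        genes.append(gene)
        matures[gid] = MatureTRNA(
            gene_id=gid, sequence=body + "CCA", anticodon=anticodon,
            anticodon_start=ac_pos, anticodon_end=ac_pos + 2, isotype=isotype,
        )
        return gene

    for fi, (isotype, anticodon) in enumerate(nuc_pool):
        mature_len = int(rng.integers(lo, hi + 1))
        base_body = _make_body(rng, mature_len, anticodon, ac_pos)
        for sub in range(max(1, config.n_subtypes_per_anticodon)):
            body = base_body
            if sub > 0:
                # mutate on the 3' side so subtypes share their 5' half
                # (multi-subtype reads) but differ elsewhere (>=1 nt)
                body = list(base_body)
                for k in range(sub):
                    pos = len(body) - 10 - 4 * k  # 0-based, outside anticodon
                    old = body[pos]
                    body[pos] = "ACGT"[("ACGT".index(old) + 1 + k) % 4]
                body = "".join(body)
                if body[-3:] == "CCA":
                    body = body[:-1] + "T"
            _place_nuclear(body, isotype, anticodon, fi)

    # --- polymorphic gene families -------------------------------------
    for pi, (isotype, anticodon) in enumerate(poly_pool):
        mature_len = int(rng.integers(lo, hi + 1))
        body = _make_body(rng, mature_len, anticodon, ac_pos)
        _place_nuclear(body, isotype, anticodon, pi, polymorphic=True)

    # --- decoy loci: exact unannotated copies of a tRNA body ----------
    decoy_loci: list[tuple[str, int, int, str]] = []
    nuclear_plain = [g for g in genes if g.contig_id != "mito" and not g.polymorphic]
    for d in range(config.decoy_count):
        source = nuclear_plain[(d * (1 + config.n_subtypes_per_anticodon)) % len(nuclear_plain)]
        body = matures[source.gene_id].body
        contig = contig_names[(d + 1) % len(contig_names)]
        start = contig_pos[contig] + 1
        contig_parts[contig].append(body)
        contig_pos[contig] += len(body)
        end = contig_pos[contig]
        # guard base != C so a CCA-terminated read can never match here
        tail = "G" + _random_seq(rng, int(rng.integers(30, 50)))
        contig_parts[contig].append(tail)
        contig_pos[contig] += len(tail)
        decoy_loci.append((contig, start, end, source.gene_id))

    for contig in contig_names:
        contig_parts[contig].append(_random_seq(rng, 60))
    nuclear_contigs = {c: "".join(parts) for c, parts in contig_parts.items()}

    # patch gene flanks so a CCA-terminated read can never extend past a
    # gene boundary into the intergenic gap (tails are not genome-encoded)
    mito_sequence = _patch_flanks(mito_sequence, [g for g in genes if g.contig_id == "mito"])
    for c in contig_names:
        nuclear_contigs[c] = _patch_flanks(
            nuclear_contigs[c], [g for g in genes if g.contig_id == c]
        )

    # --- spikes: never present in any contig or gene ------------------
    all_text = mito_sequence + "".join(nuclear_contigs.values())
    all_text += reverse_complement(all_text)
    spikes: list[str] = []
    while len(spikes) < 2:
        cand = _random_seq(rng, 26)
        if cand not in all_text and cand not in spikes:
            spikes.append(cand)

    bundle = GenomeBundle(
        config=config,
        mito_sequence=mito_sequence,
        nuclear_contigs=nuclear_contigs,
        planted_genes=genes,
        planted_matures=matures,
        spike_sequences=(spikes[0], spikes[1]),
        decoy_loci=decoy_loci,
    )
    _check_bundle(bundle)
    return bundle


def _patch_flanks(sequence: str, genes: Sequence[TRNAGene]) -> str:
    seq = list(sequence)
    for g in genes:
        if g.strand == "+":
            if "".join(seq[g.end : g.end + 3]) == "CCA":
                seq[g.end] = "G"
        else:
            if g.start >= 4 and "".join(seq[g.start - 4 : g.start - 1]) == "TGG":
                seq[g.start - 4] = "A"
    return "".join(seq)


def _check_bundle(bundle: GenomeBundle) -> None:
    contigs = dict(bundle.nuclear_contigs)
    contigs["mito"] = bundle.mito_sequence
    for g in bundle.planted_genes:
        genomic = contigs[g.contig_id][g.start - 1 : g.end]
        expect = bundle.planted_matures[g.gene_id].body
        if g.strand == "-":
            expect = reverse_complement(expect)
        if genomic != expect:
            raise AssertionError(f"planted gene {g.gene_id} does not match its locus")


# ----------------------------------------------------------------------
# read simulation
# ----------------------------------------------------------------------

# per-class span options on a mature tRNA of length L with loop (31, 37);
# "good" reads draw from even indices, artifact reads from odd indices, so
# their sequence sets never collide for one parent
def _span_options(cls: str, L: int, loop: tuple[int, int], cfg: SimulationConfig) -> list[tuple[int, int]]:
    loop_s, loop_e = loop
    rmin, rmax = cfg.read_length_min, cfg.read_length_max
    if cls == FIVE_HALF:
        ends = [e for e in range(loop_s, loop_e + 1) if rmin <= e <= rmax]
        return [(1, e) for e in ends]
    if cls == THREE_HALF:
        starts = [s for s in range(loop_s, loop_e + 1) if rmin <= L - s + 1 <= rmax]
        return [(s, L) for s in starts]
    if cls == FIVE_END:
        ends = [e for e in range(rmin, loop_s) if e <= rmax]
        return [(1, e) for e in ends]
    if cls == THREE_END:
        starts = [s for s in range(loop_e + 1, L - rmin + 2) if rmin <= L - s + 1 <= rmax]
        return [(s, L) for s in starts]
    if cls == AC_STEM_LOOP:
        sl_s = max(1, loop_s - cfg.stem_width)
        sl_e = min(L, loop_e + cfg.stem_width)
        spans = [
            (s, e)
            for s in range(sl_s, sl_e + 1)
            for e in range(s, sl_e + 1)
            if rmin <= e - s + 1 <= rmax and s > 1 and e < L
        ]
        if not spans:
            raise SimulationConfigError(
                "no AC stem-loop span can satisfy the read-length window; "
                "widen the stem or lower read_length_min"
            )
        return spans
    raise SimulationConfigError(f"unknown fragment class {cls!r}")


def _default_profile(cfg: SimulationConfig, anticodons: Sequence[str]) -> dict[str, dict[str, float]]:
    # minor classes get unequal shares (3:2:1) so no two classes of one
    # family ever tie exactly in planted read counts
    prof: dict[str, dict[str, float]] = {}
    rest = 1.0 - cfg.dominant_share
    minor_shares = [rest * w / 6 for w in (3, 2, 1)]
    for i, ac in enumerate(anticodons):
        dominant = ANCHORED_CLASSES[i % len(ANCHORED_CLASSES)]
        minors = [c for c in ANCHORED_CLASSES if c != dominant]
        prof[ac] = {dominant: cfg.dominant_share}
        prof[ac].update(dict(zip(minors, minor_shares)))
    return prof


def _default_trends(cfg: SimulationConfig, anticodons: Sequence[str]) -> dict[str, str]:
    return {ac: TREND_LABELS[i % len(TREND_LABELS)] for i, ac in enumerate(anticodons)}


def stage_weights(label: str, cfg: SimulationConfig) -> np.ndarray:
    """Planted per-stage expression weights (normalized-count space)."""
    if label == "increasing":
        w = cfg.trend_fold ** np.arange(6)
    elif label == "decreasing":
        w = cfg.trend_fold_decreasing ** np.arange(5, -1, -1)
    elif label == "egg":
        w = np.full(6, (1 - cfg.egg_share) / 5)
        w[0] = cfg.egg_share
    elif label == "flat":
        w = np.ones(6)
    else:
        raise SimulationConfigError(f"unknown trend label {label!r}")
    return w / w.sum()


def normalization_factors_from_config(cfg: SimulationConfig) -> np.ndarray:
    sums = np.array([a + b for a, b in cfg.spike_counts], dtype=float)
    K = float(np.exp(np.mean(np.log(sums))))
    return K / sums


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` by weights, preserving the total."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


@dataclass
class StageRead:
    read_id: str
    sequence: str
    quality: str


@dataclass
class SimulatedReads:
    """Six in-memory stage libraries plus the truth table."""

    stage_records: dict[str, list[StageRead]]
    truth_table: list[TruthRead]
    fastq_paths: dict[str, Path] = field(default_factory=dict)


def simulate_reads(
    bundle: GenomeBundle,
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
) -> SimulatedReads:
    """Fragment the planted tRNAs into six stage libraries.

    Fragment reads are exact substrings of mature tRNAs (3'-anchored
    classes therefore end in the non-genomic CCA); spikes appear at their
    configured counts; noise reads match nothing; low-quality reads carry
    mean PHRED < 20; short/long/below-threshold artifacts are planted for
    filter accounting.  When ``outdir`` is given, one FASTQ per stage and
    a truth TSV are written there.
    """
    cfg = config or bundle.config
    rng = np.random.default_rng(cfg.seed + 1)
    stages = list(cfg.stage_names)
    factors = normalization_factors_from_config(cfg)

    families = planted_families(bundle)
    profile = dict(cfg.fragmentation_profile or _default_profile(cfg, families))
    trends = dict(cfg.trend_profile or _default_trends(cfg, families))

    genes_by_ac: dict[str, list[TRNAGene]] = {}
    for g in bundle.planted_genes:
        genes_by_ac.setdefault(g.anticodon, []).append(g)

    decoy_bodies = [
        bundle.planted_matures[src].body for (_, _, _, src) in bundle.decoy_loci
    ]

    truth: list[TruthRead] = []
    used_sequences: set[str] = set()

    def parents_of(seq: str, anticodon: str) -> tuple[str, ...]:
        out = []
        for g in genes_by_ac[anticodon]:
            if seq in bundle.planted_matures[g.gene_id].sequence:
                out.append(g.gene_id)
        return tuple(out)

    def fate_of(seq: str) -> str:
        if any(seq in body for body in decoy_bodies):
            return "decoy"
        return "trf"

    # ---- good fragment reads -----------------------------------------
    per_family = _largest_remainder(cfg.n_fragment_reads, np.ones(len(families)))
    for fam_i, anticodon in enumerate(families):
        fam_genes = [g for g in genes_by_ac[anticodon] if not g.polymorphic]
        compartment = "mitochondrial" if fam_genes[0].contig_id == "mito" else "nuclear"
        trend_w = stage_weights(trends[anticodon], cfg)
        # plant the trend in normalized space: raw = target / factor
        raw_w = trend_w / factors
        per_stage = _largest_remainder(int(per_family[fam_i]), raw_w)
        class_props = profile[anticodon]
        for si, stage in enumerate(stages):
            n_stage = int(per_stage[si])
            if n_stage == 0:
                continue
            classes = sorted(class_props)
            alloc = _largest_remainder(
                n_stage, np.array([class_props[c] for c in classes])
            )
            for cls, n_cls in zip(classes, alloc):
                if n_cls == 0:
                    continue
                for sub_i, n_var in enumerate(_largest_remainder(int(n_cls), np.array([0.6, 0.4]))):
                    if n_var == 0:
                        continue
                    gene = fam_genes[sub_i % len(fam_genes)]
                    mature = bundle.planted_matures[gene.gene_id]
                    rmap_loop = (mature.anticodon_start - 2, mature.anticodon_end + 2)
                    options = _span_options(cls, mature.length, rmap_loop, cfg)
                    good = options[0::2] or options
                    span = good[(fam_i + sub_i) % len(good)]
                    seq = mature.sequence[span[0] - 1 : span[1]]
                    truth.append(
                        TruthRead(
                            sequence=seq, stage=stage, count=int(n_var),
                            parents=parents_of(seq, anticodon),
                            anticodon=anticodon,
                            region=cls,
                            fate=fate_of(seq),
                            compartment=compartment,
                        )
                    )
                    used_sequences.add(seq)

    # ---- polymorphic-family reads (dropped later by footnote b) ------
    for g in bundle.planted_genes:
        if not g.polymorphic:
            continue
        mature = bundle.planted_matures[g.gene_id]
        loop = (mature.anticodon_start - 2, mature.anticodon_end + 2)
        span = _span_options(FIVE_HALF, mature.length, loop, cfg)[0]
        seq = mature.sequence[span[0] - 1 : span[1]]
        per_stage = _largest_remainder(
            cfg.reads_per_polymorphic_family, np.ones(6)
        )
        for si, stage in enumerate(stages):
            if per_stage[si]:
                truth.append(
                    TruthRead(
                        sequence=seq, stage=stage, count=int(per_stage[si]),
                        parents=(g.gene_id,), anticodon=g.anticodon,
                        region=FIVE_HALF, fate="polymorphic", compartment="nuclear",
                    )
                )
        used_sequences.add(seq)

    # ---- below-threshold fragments (pooled count < 5) ----------------
    n_below = round(cfg.below_threshold_fraction * cfg.n_fragment_reads)
    bi = 0
    while n_below > 0 and families:
        if bi > 100 * len(families) + 1000:
            raise SimulationConfigError(
                "could not place the requested below-threshold reads on "
                "distinct fragment sequences"
            )
        anticodon = families[bi % len(families)]
        gene = genes_by_ac[anticodon][0]
        mature = bundle.planted_matures[gene.gene_id]
        loop = (mature.anticodon_start - 2, mature.anticodon_end + 2)
        cls = ANCHORED_CLASSES[bi % len(ANCHORED_CLASSES)]
        options = _span_options(cls, mature.length, loop, cfg)
        artifact = options[1::2]
        if not artifact:
            bi += 1
            continue
        span = artifact[(bi // len(families)) % len(artifact)]
        seq = mature.sequence[span[0] - 1 : span[1]]
        if seq in used_sequences:
            bi += 1
            continue
        used_sequences.add(seq)
        take = min(4, n_below)
        stage = stages[bi % 6]
        truth.append(
            TruthRead(
                sequence=seq, stage=stage, count=take,
                parents=parents_of(seq, anticodon), anticodon=anticodon,
                region=cls, fate="below_threshold",
                compartment=bundle.compartment_of(anticodon),
            )
        )
        n_below -= take
        bi += 1

    # ---- spikes -------------------------------------------------------
    for si, stage in enumerate(stages):
        for spike_i, seq in enumerate(bundle.spike_sequences):
            truth.append(
                TruthRead(
                    sequence=seq, stage=stage,
                    count=int(cfg.spike_counts[si][spike_i]),
                    parents=(), anticodon="", region="", fate="spike",
                )
            )

    # ---- noise / artifact reads --------------------------------------
    haystack = bundle.mito_sequence + "#" + "#".join(bundle.nuclear_contigs.values())
    haystack = haystack + "#" + reverse_complement(haystack)
    haystack += "#" + "#".join(
        m.sequence for m in bundle.planted_matures.values()
    )

    def fresh_random(n: int) -> str:
        while True:
            cand = _random_seq(rng, n)
            if cand not in haystack and cand not in used_sequences:
                used_sequences.add(cand)
                return cand

    def plant_artifacts(total: int, fate: str, length_sampler, count_sampler) -> None:
        remaining = total
        while remaining > 0:
            seq = fresh_random(int(length_sampler()))
            if fate == "contains_n":
                pos = int(rng.integers(0, len(seq)))
                seq = seq[:pos] + "N" + seq[pos + 1 :]
            count = int(min(count_sampler(), remaining))
            if remaining - count < 5:
                count = remaining  # avoid a trailing below-abundance chunk
            stage = stages[int(rng.integers(0, 6))]
            truth.append(
                TruthRead(
                    sequence=seq, stage=stage, count=count, parents=(),
                    anticodon="", region="", fate=fate,
                )
            )
            remaining -= count

    n = cfg.n_fragment_reads
    plant_artifacts(
        round(cfg.noise_fraction * n), "noise",
        lambda: rng.integers(cfg.read_length_min, cfg.read_length_max + 1),
        lambda: rng.integers(5, 12),
    )
    plant_artifacts(
        round(cfg.n_base_fraction * n), "contains_n",
        lambda: rng.integers(cfg.read_length_min, cfg.read_length_max + 1),
        lambda: rng.integers(5, 10),
    )
    plant_artifacts(
        round(cfg.low_quality_fraction * n), "low_quality",
        lambda: rng.integers(cfg.read_length_min, cfg.read_length_max + 1),
        lambda: rng.integers(5, 10),
    )
    plant_artifacts(
        round(cfg.short_fraction * n), "too_short",
        lambda: rng.integers(18, cfg.read_length_min),
        lambda: rng.integers(5, 10),
    )
    plant_artifacts(
        round(cfg.long_fraction * n), "too_long",
        lambda: rng.integers(cfg.read_length_max + 1, cfg.read_length_max + 8),
        lambda: rng.integers(5, 10),
    )

    bundle.truth_table = truth

    # ---- materialise per-stage FASTQ records -------------------------
    stage_records: dict[str, list[StageRead]] = {s: [] for s in stages}
    counters = {s: 0 for s in stages}
    for row in sorted(truth, key=lambda r: (r.stage, r.fate, r.sequence)):
        qual_char = "-" if row.fate == "low_quality" else "?"  # Q12 vs Q30
        qual = qual_char * len(row.sequence)
        for _ in range(row.count):
            counters[row.stage] += 1
            stage_records[row.stage].append(
                StageRead(
                    read_id=f"{row.stage}_{counters[row.stage]}",
                    sequence=row.sequence,
                    quality=qual,
                )
            )

    result = SimulatedReads(stage_records=stage_records, truth_table=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        suffix = ".fastq.gz" if cfg.gzip_fastq else ".fastq"
        for stage in stages:
            path = outdir / f"{stage}{suffix}"
            opener = gzip.open if cfg.gzip_fastq else open
            with opener(path, "wt") as fh:
                for rec in stage_records[stage]:
                    fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
            result.fastq_paths[stage] = path
        write_truth_table(truth, outdir / "truth.tsv")
    return result


def write_truth_table(truth: Iterable[TruthRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tstage\tcount\tparents\tanticodon\tregion\tfate\tcompartment\n")
        for row in truth:
            fh.write(
                f"{row.sequence}\t{row.stage}\t{row.count}\t"
                f"{','.join(row.parents)}\t{row.anticodon}\t{row.region}\t"
                f"{row.fate}\t{row.compartment}\n"
            )


def planted_families(bundle: GenomeBundle) -> list[str]:
    """Non-polymorphic anticodon families in planting order."""
    seen, families = set(), []
    for g in bundle.planted_genes:
        if g.polymorphic or g.anticodon in seen:
            continue
        seen.add(g.anticodon)
        families.append(g.anticodon)
    return families


def planted_trend_labels(bundle: GenomeBundle) -> dict[str, str]:
    """The per-anticodon stage-trend labels the simulator planted."""
    cfg = bundle.config
    families = planted_families(bundle)
    if cfg.trend_profile is not None:
        return dict(cfg.trend_profile)
    return _default_trends(cfg, families)


def expected_anticodon_totals(truth: Iterable[TruthRead]) -> dict[tuple[str, str], int]:
    """Truth-table bookkeeping: per-(compartment, anticodon) read totals
    expected to survive the pipeline (fate == 'trf' only)."""
    totals: dict[tuple[str, str], int] = {}
    for row in truth:
        if row.fate == "trf":
            key = (row.compartment, row.anticodon)
            totals[key] = totals.get(key, 0) + row.count
    return totals


def expected_dominant_regions(truth: Iterable[TruthRead]) -> dict[tuple[str, str], str]:
    """Region class with the largest surviving truth count per anticodon."""
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for row in truth:
        if row.fate == "trf":
            key = (row.compartment, row.anticodon)
            counts.setdefault(key, {}).setdefault(row.region, 0)
            counts[key][row.region] += row.count
    return {
        key: max(sorted(c), key=lambda cls: c[cls]) for key, c in counts.items()
    }
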
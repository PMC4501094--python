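"""tRNA gene catalogs: annotation parsing, curation and mature sequences.

A catalog starts from tRNAscan-SE tabular output (or the package's
equivalent annotation TSV), is optionally intersected with a bacterial-model
search to keep only genes scoring better under the eukaryotic covariance
model, and is curated by removing pseudogenes, genes at contig ends and
genes with polymorphic sites.  Each surviving gene yields a mature tRNA
sequence (strand-resolved, intron-removed, ``CCA``-appended) together with
an anticodon-anchored structural region map used downstream to classify
fragments.

All genomic and mature-sequence coordinates exposed by this module are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TRNAGene",
    "MatureTRNA",
    "RegionMap",
    "TRNACatalog",
    "parse_annotation",
    "select_eukaryotic",
    "curate",
    "mature_sequence",
    "region_map",
    "build_catalog",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation row; carries the line number."""


@dataclass(frozen=True)
class TRNAGene:
    """An annotated tRNA locus.

    ``start``/``end`` are 1-based inclusive genomic coordinates with
    ``start <= end`` regardless of strand; ``anticodon`` is stored in the
    DNA alphabet of the genome it was called on.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    cove_score_euk: float | None = None
    cove_score_bac: float | None = None
    intron_start: int | None = None
    intron_end: int | None = None
    pseudo: bool = False
    contig_end: bool = False
    polymorphic: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if len(self.anticodon) != 3:
            raise ValueError(f"{self.gene_id}: anticodon {self.anticodon!r} not 3 nt")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def locus(self) -> tuple[str, int, int, str]:
        return (self.contig_id, self.start, self.end, self.strand)

    @property
    def genomic_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegionMap:
    """Anticodon-anchored structural windows on a mature tRNA.

    The 7-nt anticodon loop is the anticodon +/- 2 nt; the anticodon
    stem-loop extends the loop by ``stem_width`` paired nucleotides on each
    side; half windows abut the loop and end windows are the proper
    prefix/suffix excluding the loop.  All coordinates 1-based inclusive on
    the mature (CCA-terminated) sequence.
    """

    length: int
    loop: tuple[int, int]
    stem_loop: tuple[int, int]
    five_end: tuple[int, int]
    five_half: tuple[int, int]
    three_half: tuple[int, int]
    three_end: tuple[int, int]


@dataclass(frozen=True)
class MatureTRNA:
    """A processed tRNA: gene body (strand-resolved, intron-removed) + CCA."""

    gene_id: str
    sequence: str
    anticodon: str
    anticodon_start: int
    anticodon_end: int
    isotype: str = ""

    def __post_init__(self) -> None:
        if not self.sequence.endswith("CCA"):
            raise ValueError(f"{self.gene_id}: mature sequence must end in CCA")
        s, e = self.anticodon_start, self.anticodon_end
        if self.sequence[s - 1 : e] != self.anticodon:
            raise ValueError(
                f"{self.gene_id}: anticodon {self.anticodon} not at mature "
                f"positions {s}-{e}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def body(self) -> str:
        """The genome-encoded part of the mature sequence (CCA removed)."""
        return self.sequence[:-3]


_HEADER_PREFIXES = ("Sequence", "Name", "--------")


def parse_annotation(path: str | Path | Iterable[str]) -> list[TRNAGene]:
    """Parse tRNAscan-SE 1.x tabular output into :class:`TRNAGene` records.

    Accepts a path or an iterable of lines.  Rows with begin > end are
    minus-strand genes and are normalized to ``start <= end``.  A row whose
    isotype is ``Pseudo`` or whose trailing note column mentions ``pseudo``
    sets the pseudo flag; a note mentioning ``polymorphic`` sets the
    polymorphic flag.
    """
    if isinstance(path, (str, Path)):
        with open(path) as handle:
            lines = handle.readlines()
    else:
        lines = list(path)

    genes: list[TRNAGene] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(_HEADER_PREFIXES):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 9:
            fields = line.split()
        if len(fields) < 9:
            raise AnnotationParseError(
                f"line {lineno}: expected >=9 tab-separated columns, got "
                f"{len(fields)}"
            )
        try:
            contig = fields[0]
            number = fields[1]
            begin, end = int(fields[2]), int(fields[3])
            isotype = fields[4]
            anticodon = fields[5].upper().replace("U", "T")
            ibegin, iend = int(fields[6]), int(fields[7])
            cove = float(fields[8])
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: {exc}") from exc
        note = " ".join(fields[9:]).lower() if len(fields) > 9 else ""

        strand = "+"
        if begin > end:
            strand = "-"
            begin, end = end, begin
            if ibegin > iend:
                ibegin, iend = iend, ibegin
        intron = (ibegin, iend) if (ibegin, iend) != (0, 0) else (None, None)
        genes.append(
            TRNAGene(
                gene_id=f"{contig}.trna{number}",
                contig_id=contig,
                start=begin,
                end=end,
                strand=strand,
                isotype=isotype,
                anticodon=anticodon,
                cove_score_euk=cove,
                intron_start=intron[0],
                intron_end=intron[1],
                pseudo=(isotype.lower() == "pseudo") or ("pseudo" in note),
                polymorphic="polymorphic" in note,
            )
        )
    return genes


def select_eukaryotic(
    euk_genes: Sequence[TRNAGene], bac_genes: Sequence[TRNAGene]
) -> list[TRNAGene]:
    """Keep loci scoring higher under the eukaryotic covariance model.

    Loci are keyed by (contig, interval, strand).  A locus present only in
    the eukaryotic search is retained; where both searches found it, the
    eukaryotic COVE bit score must strictly exceed the bacterial one.  The
    bacterial score is recorded on the retained gene.
    """
    bac_by_locus = {g.locus: g for g in bac_genes}
    kept: list[TRNAGene] = []
    for gene in euk_genes:
        bac = bac_by_locus.get(gene.locus)
        if bac is None:
            kept.append(gene)
        elif gene.cove_score_euk is not None and bac.cove_score_euk is not None:
            if gene.cove_score_euk > bac.cove_score_euk:
                kept.append(replace(gene, cove_score_bac=bac.cove_score_euk))
    return kept


def flag_polymorphic(genes: Sequence[TRNAGene], contigs: dict[str, str]) -> list[TRNAGene]:
    """Flag genes with polymorphic sites.

    A gene is polymorphic when the catalog holds two genes at overlapping
    loci (same contig) whose genomic sequences differ, or two genes with
    the same gene_id and unequal sequences, or when the annotation already
    marked it so.
    """

    def genomic(g: TRNAGene) -> str:
        contig = contigs.get(g.contig_id, "")
        return contig[g.start - 1 : g.end]

    flagged = set()
    by_contig: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_contig.setdefault(g.contig_id, []).append(i)
    by_id: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_id.setdefault(g.gene_id, []).append(i)

    for idxs in by_contig.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                a, b = genes[idxs[ai]], genes[idxs[bi]]
                if a.start <= b.end and b.start <= a.end:  # overlap
                    if genomic(a) != genomic(b) or (a.start, a.end) != (b.start, b.end):
                        flagged.update((idxs[ai], idxs[bi]))
    for idxs in by_id.values():
        if len(idxs) > 1:
            seqs = {genomic(genes[i]) for i in idxs}
            if len(seqs) > 1:
                flagged.update(idxs)

    return [
        replace(g, polymorphic=True) if (i in flagged and not g.polymorphic) else g
        for i, g in enumerate(genes)
    ]


def curate(
    genes: Sequence[TRNAGene],
    contig_lengths: dict[str, int],
    *,
    edge_margin: int = 5,
) -> list[TRNAGene]:
    """Remove pseudogenes, contig-end genes and polymorphic genes.

    A gene is at a contig end when fewer than ``edge_margin`` nucleotides
    separate its interval from either contig boundary.
    """
    kept = []
    for gene in genes:
        if gene.contig_id not in contig_lengths:
            raise KeyError(f"{gene.gene_id}: unknown contig {gene.contig_id!r}")
        if gene.pseudo or gene.polymorphic:
            continue
        clen = contig_lengths[gene.contig_id]
        if gene.start - 1 < edge_margin or clen - gene.end < edge_margin:
            continue
        kept.append(gene)
    return kept


def _locate_anticodon(sequence: str, anticodon: str, hint: int | None = None) -> int:
    """1-based start of the anticodon on the mature sequence.

    When the gene model supplies no mature-coordinate hint, the occurrence
    closest to the sequence midpoint is taken (the anticodon loop sits near
    the middle of the cloverleaf).
    """
    occurrences = []
    pos = sequence.find(anticodon)
    while pos != -1:
        occurrences.append(pos + 1)
        pos = sequence.find(anticodon, pos + 1)
    if not occurrences:
        raise ValueError(f"anticodon {anticodon} absent from mature sequence")
    anchor = hint if hint is not None else (len(sequence) - 2) // 2
    return min(occurrences, key=lambda p: (abs(p - anchor), p))


def mature_sequence(
    gene: TRNAGene,
    contigs: dict[str, str],
    *,
    anticodon_hint: int | None = None,
) -> MatureTRNA:
    """Derive the mature tRNA for a gene: revcomp minus-strand bodies,
    splice the annotated intron, append CCA, and recompute the anticodon
    position on the mature coordinate system."""
    contig = contigs[gene.contig_id]
    if gene.end > len(contig) or gene.start < 1:
        raise IndexError(
            f"{gene.gene_id}: interval {gene.start}-{gene.end} outside contig "
            f"{gene.contig_id} (length {len(contig)})"
        )
    body = contig[gene.start - 1 : gene.end]
    if gene.intron_start is not None and gene.intron_end is not None:
        rel_s = gene.intron_start - gene.start
        rel_e = gene.intron_end - gene.start + 1
        body = body[:rel_s] + body[rel_e:]
    if gene.strand == "-":
        body = reverse_complement(body)
    mature = body.upper() + "CCA"
    ac_start = _locate_anticodon(mature, gene.anticodon, anticodon_hint)
    return MatureTRNA(
        gene_id=gene.gene_id,
        sequence=mature,
        anticodon=gene.anticodon,
        anticodon_start=ac_start,
        anticodon_end=ac_start + 2,
        isotype=gene.isotype,
    )


def region_map(trna: MatureTRNA, *, stem_width: int = 5) -> RegionMap:
    """Compute the anticodon-anchored region windows for one mature tRNA.

    Raises if the 7-nt anticodon loop does not fit inside the sequence.
    """
    L = trna.length
    loop_s = trna.anticodon_start - 2
    loop_e = trna.anticodon_end + 2
    if loop_s < 1 or loop_e > L:
        raise ValueError(
            f"{trna.gene_id}: anticodon at {trna.anticodon_start}-"
            f"{trna.anticodon_end} too close to a terminus for the loop"
        )
    sl_s = max(1, loop_s - stem_width)
    sl_e = min(L, loop_e + stem_width)
    return RegionMap(
        length=L,
        loop=(loop_s, loop_e),
        stem_loop=(sl_s, sl_e),
        five_end=(1, loop_s - 1),
        five_half=(1, loop_e),
        three_half=(loop_s, L),
        three_end=(loop_e + 1, L),
    )


@dataclass
class TRNACatalog:
    """A curated gene set for one genomic compartment, ready for tRF calling.

    ``genes`` is the full annotated set (curation flags included);
    ``curated`` the calling catalog; ``matures`` holds mature sequences for
    curated genes and, separately, ``polymorphic_matures`` for
    polymorphic-flagged genes so the ambiguity filter can still recognise
    reads that map only to them.
    """

    compartment: str
    contigs: dict[str, str]
    genes: list[TRNAGene]
    curated: list[TRNAGene] = field(default_factory=list)
    matures: dict[str, MatureTRNA] = field(default_factory=dict)
    polymorphic_matures: dict[str, MatureTRNA] = field(default_factory=dict)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def gene(self, gene_id: str) -> TRNAGene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def build_catalog(
    genes: Sequence[TRNAGene],
    contigs: dict[str, str],
    *,
    compartment: str,
    edge_margin: int = 5,
    detect_polymorphic: bool = True,
    anticodon_hints: dict[str, int] | None = None,
    default_anticodon_hint: int | None = None,
) -> TRNACatalog:
    """Curate a gene set and derive mature sequences.

    ``anticodon_hints`` optionally maps gene_id to the expected 1-based
    anticodon start on the mature sequence (used when a generator or a
    manual-override table knows it exactly); ``default_anticodon_hint``
    applies to genes without an explicit hint.
    """
    contigs = {k: v.upper() for k, v in contigs.items()}
    if detect_polymorphic:
        genes = flag_polymorphic(genes, contigs)
    else:
        genes = list(genes)
    lengths = {name: len(seq) for name, seq in contigs.items()}
    curated = curate(genes, lengths, edge_margin=edge_margin)
    hints = anticodon_hints or {}

    def _hint(gid: str) -> int | None:
        return hints.get(gid, default_anticodon_hint)

    matures = {
        g.gene_id: mature_sequence(g, contigs, anticodon_hint=_hint(g.gene_id))
        for g in curated
    }
    poly = {
        g.gene_id: mature_sequence(g, contigs, anticodon_hint=_hint(g.gene_id))
        for g in genes
        if g.polymorphic and not g.pseudo
    }
    return TRNACatalog(
        compartment=compartment,
        contigs=contigs,
        genes=list(genes),
        curated=curated,
        matures=matures,
        polymorphic_matures=poly,
    )
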
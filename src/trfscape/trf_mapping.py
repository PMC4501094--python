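"""Exact, CCA-aware mapping of unique reads to mature tRNAs.

Mapping is exact substring search — no mismatches, no gaps — because a
tRF is by definition a perfect fragment of its mature parent.  Mature
sequences carry the post-transcriptional CCA tail, so a read that ends in
CCA and aligns flush to the 3' terminus matches the mature sequence even
though the tail is absent from the genome; such hits are flagged
``cca_masked``.

Compartment precedence is mitochondrial before nuclear: any occurrence of
a read in the mitochondrial genome claims it, and only mito-unmapped
reads are considered against the nuclear contigs.  Nuclear candidates
then pass three ambiguity filters: (a) reads also matching a non-tRNA
genomic locus are dropped; (b) reads whose only parents carry polymorphic
sites are dropped; (c) reads matching tRNA genes of two or more distinct
anticodons are dropped.  Reads matching several isodecoder subtypes of
one anticodon are kept with all parents and counted once per anticodon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .read_filtering import UniqueRead
from .trna_catalog import MatureTRNA, TRNACatalog, reverse_complement

__all__ = [
    "ParentHit",
    "TRFRecord",
    "TRFCallResult",
    "match_to_trna",
    "assign_compartment",
    "call_trfs",
]

MITOCHONDRIAL = "mitochondrial"
NUCLEAR = "nuclear"


@dataclass(frozen=True)
class ParentHit:
    """One exact placement of a read on one mature tRNA."""

    gene_id: str
    span: tuple[int, int]  # 1-based inclusive on the mature sequence
    cca_masked: bool


@dataclass
class TRFRecord:
    """A called tRNA-derived fragment (one unique read sequence)."""

    sequence: str
    compartment: str
    isotype: str
    anticodon: str
    hits: tuple[ParentHit, ...]
    counts: tuple[int, ...]
    region: str | None = None

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(h.gene_id for h in self.hits)

    @property
    def pooled_count(self) -> int:
        return sum(self.counts)

    @property
    def span(self) -> tuple[int, int]:
        return self.hits[0].span

    @property
    def cca_masked(self) -> bool:
        return any(h.cca_masked for h in self.hits)

    def span_on(self, gene_id: str) -> tuple[int, int] | None:
        for h in self.hits:
            if h.gene_id == gene_id:
                return h.span
        return None


def match_to_trna(sequence: str, trna: MatureTRNA) -> list[tuple[tuple[int, int], bool]]:
    """All exact occurrences of a read on one mature tRNA.

    Returns (span, cca_masked) pairs.  A hit is cca_masked when it ends
    at the mature 3' terminus, i.e. the read's CCA-terminal suffix is the
    non-genomic tail; by construction (mature = genomic body + CCA) this
    is exactly the flush-3' masked alignment.
    """
    mature = trna.sequence
    hits = []
    pos = mature.find(sequence)
    while pos != -1:
        span = (pos + 1, pos + len(sequence))
        hits.append((span, span[1] == len(mature)))
        pos = mature.find(sequence, pos + 1)
    return hits


def _genomic_occurrences(sequence: str, contigs: dict[str, str]) -> list[tuple[str, int, int, str]]:
    """All genomic occurrences of a read, both strands.

    Returns (contig, start, end, strand) with 1-based inclusive
    coordinates on the forward strand; strand '-' means the read matches
    the reverse complement at that interval.
    """
    out = []
    rc = reverse_complement(sequence)
    for name in sorted(contigs):
        contig = contigs[name]
        for probe, strand in ((sequence, "+"), (rc, "-")):
            pos = contig.find(probe)
            while pos != -1:
                out.append((name, pos + 1, pos + len(probe), strand))
                pos = contig.find(probe, pos + 1)
    return out


@dataclass
class CompartmentHits:
    """Occurrence summary for one read in one compartment."""

    trna_hits: list[ParentHit] = field(default_factory=list)
    polymorphic_hits: list[ParentHit] = field(default_factory=list)
    other_genomic: bool = False
    any_genomic: bool = False

    @property
    def any_occurrence(self) -> bool:
        return bool(self.trna_hits or self.polymorphic_hits) or self.any_genomic


def scan_compartment(sequence: str, catalog: TRNACatalog) -> CompartmentHits:
    """Match a read against one compartment's matures and contigs.

    Genomic occurrences falling sense-consistently inside ANY annotated
    tRNA gene interval (including genes removed by curation) count as
    tRNA-region occurrences; everything else is an "other genomic"
    occurrence for ambiguity filter (a).  A read antisense to a tRNA is
    an other-genomic occurrence: tRFs are fragments of the sense mature
    tRNA.
    """
    result = CompartmentHits()
    for gene_id in sorted(catalog.matures):
        for span, masked in match_to_trna(sequence, catalog.matures[gene_id]):
            result.trna_hits.append(ParentHit(gene_id, span, masked))
    for gene_id in sorted(catalog.polymorphic_matures):
        for span, masked in match_to_trna(sequence, catalog.polymorphic_matures[gene_id]):
            result.polymorphic_hits.append(ParentHit(gene_id, span, masked))

    intervals = [
        (g.contig_id, g.start, g.end, g.strand) for g in catalog.genes
    ]
    for contig, start, end, strand in _genomic_occurrences(sequence, catalog.contigs):
        result.any_genomic = True
        inside_trna = any(
            contig == c and start >= s and end <= e and strand == st
            for c, s, e, st in intervals
        )
        if not inside_trna:
            result.other_genomic = True
    return result


def assign_compartment(
    mito: CompartmentHits, nuclear: CompartmentHits
) -> tuple[str, str]:
    """Decide a read's fate given its occurrence summaries.

    Returns (compartment, status).  Statuses: 'candidate' (a tRF
    candidate in that compartment, still subject to ambiguity filters),
    'consumed' (matched the compartment's genome outside tRNAs and is not
    forwarded), 'unassigned'.
    """
    if mito.trna_hits or mito.polymorphic_hits:
        return MITOCHONDRIAL, "candidate"
    if mito.any_genomic:
        return MITOCHONDRIAL, "consumed"
    if nuclear.trna_hits or nuclear.polymorphic_hits:
        return NUCLEAR, "candidate"
    if nuclear.any_genomic:
        return NUCLEAR, "consumed"
    return "", "unassigned"


def _ambiguity_check(
    hits: CompartmentHits,
    catalog: TRNACatalog,
    *,
    apply_other_genomic: bool,
) -> tuple[list[ParentHit], str | None]:
    """Apply ambiguity filters; returns (kept parents, drop reason)."""
    if apply_other_genomic and hits.other_genomic and (
        hits.trna_hits or hits.polymorphic_hits
    ):
        return [], "maps_outside_trna"
    if not hits.trna_hits:
        return [], "polymorphic_parents_only" if hits.polymorphic_hits else "no_parent"
    anticodons = {catalog.gene(h.gene_id).anticodon for h in hits.trna_hits}
    if len(anticodons) > 1:
        return [], "multiple_anticodons"
    return list(hits.trna_hits), None


@dataclass
class TRFCallResult:
    """Called tRFs plus per-read drop accounting and a per-anticodon summary."""

    records: list[TRFRecord]
    dropped: dict[str, dict[str, int]]  # reason -> {'unique': n, 'reads': n}
    stage_order: tuple[str, ...]

    def summary(self) -> pd.DataFrame:
        """Per-(compartment, anticodon) read totals, Table-style.

        Each unique read contributes its full pooled count once per
        anticodon regardless of how many subtypes it matched.
        """
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "compartment": rec.compartment,
                    "isotype": rec.isotype,
                    "anticodon": rec.anticodon,
                    "total_reads": rec.pooled_count,
                    "n_unique_reads": 1,
                    **{
                        f"reads_{stage}": c
                        for stage, c in zip(self.stage_order, rec.counts)
                    },
                }
            )
        if not rows:
            cols = ["compartment", "isotype", "anticodon", "total_reads", "n_unique_reads"]
            return pd.DataFrame(columns=cols)
        df = pd.DataFrame(rows)
        out = (
            df.groupby(["compartment", "isotype", "anticodon"], as_index=False)
            .sum(numeric_only=True)
            .sort_values(
                ["compartment", "total_reads", "anticodon"],
                ascending=[True, False, True],
            )
            .reset_index(drop=True)
        )
        return out


def call_trfs(
    unique_reads: Iterable[UniqueRead],
    mito_catalog: TRNACatalog | None,
    nuclear_catalog: TRNACatalog | None,
    *,
    stage_order: Sequence[str],
    mito_other_genomic_filter: bool = False,
) -> TRFCallResult:
    """Map unique reads to tRNAs and apply precedence + ambiguity filters.

    ``mito_other_genomic_filter`` extends ambiguity filter (a) to
    mitochondrial candidates (off by default: the filter annotates only
    nuclear calls; within-mito multi-anticodon reads are always dropped).
    Output is independent of read order: reads are processed sorted by
    sequence.
    """
    empty_mito = TRNACatalog(compartment=MITOCHONDRIAL, contigs={}, genes=[])
    empty_nuc = TRNACatalog(compartment=NUCLEAR, contigs={}, genes=[])
    mito_catalog = mito_catalog or empty_mito
    nuclear_catalog = nuclear_catalog or empty_nuc

    records: list[TRFRecord] = []
    dropped: dict[str, dict[str, int]] = {}

    def drop(reason: str, read: UniqueRead) -> None:
        bucket = dropped.setdefault(reason, {"unique": 0, "reads": 0})
        bucket["unique"] += 1
        bucket["reads"] += read.pooled_count

    for read in sorted(unique_reads, key=lambda r: r.sequence):
        mito = scan_compartment(read.sequence, mito_catalog)
        nuclear = scan_compartment(read.sequence, nuclear_catalog)
        compartment, status = assign_compartment(mito, nuclear)
        if status == "unassigned":
            drop("unassigned", read)
            continue
        if status == "consumed":
            drop(f"{compartment}_non_trna", read)
            continue
        if compartment == MITOCHONDRIAL:
            hits, catalog = mito, mito_catalog
            apply_a = mito_other_genomic_filter
        else:
            hits, catalog = nuclear, nuclear_catalog
            apply_a = True
        parents, reason = _ambiguity_check(hits, catalog, apply_other_genomic=apply_a)
        if reason is not None:
            drop(f"{compartment}_{reason}", read)
            continue
        gene = catalog.gene(parents[0].gene_id)
        records.append(
            TRFRecord(
                sequence=read.sequence,
                compartment=compartment,
                isotype=gene.isotype,
                anticodon=gene.anticodon,
                hits=tuple(parents),
                counts=read.counts,
            )
        )
    return TRFCallResult(
        records=records, dropped=dropped, stage_order=tuple(stage_order)
    )
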
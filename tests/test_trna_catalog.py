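"""Annotation parsing, COVE-score selection, curation and mature tRNAs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trfscape.trna_catalog import (
    AnnotationParseError,
    TRNAGene,
    build_catalog,
    curate,
    mature_sequence,
    parse_annotation,
    region_map,
    reverse_complement,
    select_eukaryotic,
)

HEADER = [
    "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tCove\n",
    "Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n",
    "--------\t------\t-----\t------\t----\t-----\t-----\t----\t------\n",
]


def make_gene(**overrides):
    fields = dict(
        gene_id="c1.trna1", contig_id="c1", start=100, end=171, strand="+",
        isotype="Gly", anticodon="GCC",
    )
    fields.update(overrides)
    return TRNAGene(**fields)


class TestParseAnnotation:
    def test_field_mapping(self):
        rows = HEADER + ["contig1\t1\t1000\t1071\tGly\tGCC\t0\t0\t65.2\n"]
        (gene,) = parse_annotation(rows)
        assert gene.contig_id == "contig1"
        assert (gene.start, gene.end, gene.strand) == (1000, 1071, "+")
        assert gene.isotype == "Gly" and gene.anticodon == "GCC"
        assert gene.cove_score_euk == 65.2
        assert not gene.pseudo

    def test_reversed_bounds_become_minus_strand(self):
        rows = HEADER + ["contig1\t1\t5000\t4928\tSer\tGCT\t0\t0\t60.0\n"]
        (gene,) = parse_annotation(rows)
        assert gene.strand == "-"
        assert (gene.start, gene.end) == (4928, 5000)

    def test_pseudo_and_polymorphic_notes(self):
        rows = HEADER + [
            "c\t1\t10\t81\tPseudo\tGCC\t0\t0\t20.1\n",
            "c\t2\t200\t271\tGly\tGCC\t0\t0\t55.0\tpseudo\n",
            "c\t3\t400\t471\tGly\tGCC\t0\t0\t55.0\tpolymorphic\n",
        ]
        genes = parse_annotation(rows)
        assert genes[0].pseudo and genes[1].pseudo
        assert genes[2].polymorphic and not genes[2].pseudo

    def test_intron_bounds_recorded(self):
        rows = HEADER + ["c\t1\t100\t181\tTyr\tGTA\t140\t149\t58.0\n"]
        (gene,) = parse_annotation(rows)
        assert (gene.intron_start, gene.intron_end) == (140, 149)

    def test_malformed_row_names_line(self):
        rows = HEADER + ["c\t1\tnot_a_number\t171\tGly\tGCC\t0\t0\t65.2\n"]
        with pytest.raises(AnnotationParseError, match="line 4"):
            parse_annotation(rows)

    def test_anticodon_rna_alphabet_normalized(self):
        rows = HEADER + ["c\t1\t100\t171\tSer\tGCU\t0\t0\t60.0\n"]
        (gene,) = parse_annotation(rows)
        assert gene.anticodon == "GCT"


class TestSelectEukaryotic:
    def test_higher_eukaryotic_score_retained(self):
        euk = [make_gene(cove_score_euk=65.2)]
        bac = [make_gene(cove_score_euk=50.1)]
        kept = select_eukaryotic(euk, bac)
        assert len(kept) == 1 and kept[0].cove_score_bac == 50.1

    def test_higher_bacterial_score_excluded(self):
        euk = [make_gene(cove_score_euk=40.0)]
        bac = [make_gene(cove_score_euk=45.0)]
        assert select_eukaryotic(euk, bac) == []

    def test_equal_scores_excluded(self):
        euk = [make_gene(cove_score_euk=45.0)]
        bac = [make_gene(cove_score_euk=45.0)]
        assert select_eukaryotic(euk, bac) == []

    def test_locus_only_in_eukaryotic_search_retained(self):
        euk = [make_gene(cove_score_euk=40.0)]
        assert select_eukaryotic(euk, []) == euk


class TestCurate:
    LENGTHS = {"c1": 1000}

    def test_pseudo_removed(self):
        assert curate([make_gene(pseudo=True)], self.LENGTHS) == []

    def test_polymorphic_removed(self):
        assert curate([make_gene(polymorphic=True)], self.LENGTHS) == []

    def test_contig_end_removed(self):
        near_end = make_gene(start=926, end=998)  # 2 nt from the end
        assert curate([near_end], self.LENGTHS, edge_margin=5) == []
        near_start = make_gene(start=3, end=75)
        assert curate([near_start], self.LENGTHS, edge_margin=5) == []

    def test_clean_interior_gene_retained(self):
        gene = make_gene()
        assert curate([gene], self.LENGTHS) == [gene]

    def test_unknown_contig_raises(self):
        with pytest.raises(KeyError):
            curate([make_gene(contig_id="nope")], self.LENGTHS)


class TestMatureSequence:
    def _contig_for(self, body, start=100, strand="+"):
        import numpy as np
        rng = np.random.default_rng(3)
        background = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        insert = body if strand == "+" else reverse_complement(body)
        return background[: start - 1] + insert + background[start - 1 :]

    def _body(self, length=72, ac="GCC", pos=33):
        base = ("ACGT" * 30)[:length]
        return base[: pos - 1] + ac + base[pos + 2 :]

    def test_plus_strand_gets_cca(self):
        body = self._body()
        contig = self._contig_for(body)
        gene = make_gene(start=100, end=171)
        mature = mature_sequence(gene, {"c1": contig}, anticodon_hint=33)
        assert mature.sequence == body + "CCA"
        assert mature.length == 75

    def test_minus_strand_reverse_complemented(self):
        body = self._body()
        contig = self._contig_for(body, strand="-")
        gene = make_gene(start=100, end=171, strand="-")
        mature = mature_sequence(gene, {"c1": contig}, anticodon_hint=33)
        assert mature.sequence == body + "CCA"

    def test_intron_removed(self):
        body = self._body(length=72)
        with_intron = body[:40] + "TTTTTTTTTT" + body[40:]
        contig = self._contig_for(with_intron)
        gene = make_gene(start=100, end=100 + 82 - 1, intron_start=140, intron_end=149)
        mature = mature_sequence(gene, {"c1": contig}, anticodon_hint=33)
        assert mature.length == 82 - 10 + 3
        assert mature.sequence == body + "CCA"

    def test_out_of_bounds_raises(self):
        gene = make_gene(start=100, end=5000)
        with pytest.raises(IndexError):
            mature_sequence(gene, {"c1": "A" * 200})

    def test_anticodon_recomputed_on_mature(self, default_bundle):
        contigs = dict(default_bundle.nuclear_contigs, mito=default_bundle.mito_sequence)
        for gene in default_bundle.planted_genes:
            mature = mature_sequence(gene, contigs, anticodon_hint=33)
            s, e = mature.anticodon_start, mature.anticodon_end
            assert mature.sequence[s - 1 : e] == gene.anticodon


class TestRegionMap:
    def test_windows_anchored_on_anticodon(self, toy_trna):
        rm = region_map(toy_trna)
        assert rm.loop == (31, 37)
        assert rm.stem_loop == (26, 42)
        assert rm.five_end == (1, 30)
        assert rm.five_half == (1, 37)
        assert rm.three_half == (31, 75)
        assert rm.three_end == (38, 75)

    def test_windows_tile_consistently(self, toy_trna):
        rm = region_map(toy_trna, stem_width=5)
        assert rm.stem_loop[0] <= rm.loop[0] and rm.loop[1] <= rm.stem_loop[1]
        assert rm.five_half[1] == rm.loop[1]
        assert rm.three_half[0] == rm.loop[0]
        assert rm.five_end == (1, rm.loop[0] - 1)
        assert rm.three_end == (rm.loop[1] + 1, rm.length)

    def test_anticodon_at_terminus_raises(self):
        from trfscape.trna_catalog import MatureTRNA

        trna = MatureTRNA(
            gene_id="bad", sequence="GCC" + "A" * 40 + "CCA",
            anticodon="GCC", anticodon_start=1, anticodon_end=3,
        )
        with pytest.raises(ValueError):
            region_map(trna)


class TestCatalogRoundTrip:
    def test_bundle_annotation_roundtrip_recovers_matures(self, default_bundle, tmp_path):
        """parse -> curate -> mature reproduces every planted clean gene."""
        for compartment, contigs in (
            ("mitochondrial", {"mito": default_bundle.mito_sequence}),
            ("nuclear", default_bundle.nuclear_contigs),
        ):
            path = tmp_path / f"{compartment}.tsv"
            default_bundle.write_annotation(path, compartment=compartment)
            genes = parse_annotation(path)
            catalog = build_catalog(
                genes, contigs, compartment=compartment, default_anticodon_hint=33
            )
            planted = {
                g.gene_id: default_bundle.planted_matures[g.gene_id]
                for g in default_bundle.planted_genes
                if (g.contig_id == "mito") == (compartment == "mitochondrial")
                and not (g.pseudo or g.polymorphic)
            }
            assert set(catalog.matures) == set(planted)
            for gid, mature in catalog.matures.items():
                assert mature.sequence == planted[gid].sequence
                assert mature.anticodon_start == planted[gid].anticodon_start

    def test_polymorphic_flag_survives_roundtrip(self, default_bundle, tmp_path):
        path = tmp_path / "nuc.tsv"
        default_bundle.write_annotation(path, compartment="nuclear")
        genes = parse_annotation(path)
        planted_poly = {
            g.gene_id for g in default_bundle.planted_genes if g.polymorphic
        }
        assert planted_poly == {g.gene_id for g in genes if g.polymorphic}
        catalog = build_catalog(
            genes, default_bundle.nuclear_contigs, compartment="nuclear",
            default_anticodon_hint=33,
        )
        assert set(catalog.polymorphic_matures) == planted_poly
        assert planted_poly.isdisjoint(catalog.matures)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    strand=st.sampled_from("+-"),
    length=st.integers(min_value=70, max_value=76),
    start=st.integers(min_value=50, max_value=150),
)
def test_mature_always_carries_anticodon_and_cca(strand, length, start):
    import numpy as np

    rng = np.random.default_rng(length * 1000 + start)
    body = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length - 3))
    body = body[:32] + "GCC" + body[35:]
    if body.endswith("CCA"):
        body = body[:-1] + "T"
    insert = body if strand == "+" else reverse_complement(body)
    contig = (
        "".join("ACGT"[i] for i in rng.integers(0, 4, size=start - 1))
        + insert
        + "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
    )
    gene = make_gene(start=start, end=start + len(body) - 1, strand=strand)
    mature = mature_sequence(gene, {"c1": contig}, anticodon_hint=33)
    assert mature.sequence.endswith("CCA")
    assert mature.sequence[:-3] == body
    s, e = mature.anticodon_start, mature.anticodon_end
    assert mature.sequence[s - 1 : e] == "GCC"
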
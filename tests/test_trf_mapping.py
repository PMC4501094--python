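"""Exact CCA-aware matching, compartment precedence and ambiguity filters."""

import numpy as np
import pytest

from oracle_utils import oracle_aggregate, random_instance
from trfscape.read_filtering import UniqueRead
from trfscape.synthetic_data import expected_anticodon_totals
from trfscape.trf_mapping import (
    assign_compartment,
    call_trfs,
    match_to_trna,
    scan_compartment,
)
from trfscape.trna_catalog import TRNAGene, build_catalog


def catalog_from(genes, contigs, compartment="nuclear"):
    return build_catalog(
        genes, contigs, compartment=compartment,
        detect_polymorphic=False, default_anticodon_hint=33,
    )


class TestMatchToTRNA:
    def test_internal_fragment_single_hit(self, toy_trna):
        read = toy_trna.sequence[0:33]
        ((span, masked),) = match_to_trna(read, toy_trna)
        assert span == (1, 33) and not masked

    def test_cca_flush_hit_flagged_masked(self, toy_trna):
        read = toy_trna.body[-30:] + "CCA"
        hits = match_to_trna(read, toy_trna)
        flush = [h for h in hits if h[0][1] == toy_trna.length]
        assert len(flush) == 1
        (span, masked) = flush[0]
        assert span == (43, 75) and masked

    def test_single_substitution_no_hit(self, toy_trna):
        read = list(toy_trna.sequence[0:30])
        read[10] = "T" if read[10] != "T" else "G"
        assert match_to_trna("".join(read), toy_trna) == []

    def test_no_partial_tail_hits_by_default(self, toy_trna):
        # a read with a truncated tail is still an exact substring (CC of
        # the CCA), but never flagged as a flush masked hit
        read = toy_trna.body[-30:] + "CC"
        hits = match_to_trna(read, toy_trna)
        assert all(not masked for _, masked in hits)


class TestCompartmentPrecedence:
    def _bundle_catalogs(self, default_bundle):
        mito = catalog_from(
            default_bundle.mito_genes,
            {"mito": default_bundle.mito_sequence},
            "mitochondrial",
        )
        nuc = catalog_from(
            default_bundle.nuclear_genes, default_bundle.nuclear_contigs
        )
        return mito, nuc

    def test_mito_trna_hit_claims_read(self, default_bundle):
        mito, nuc = self._bundle_catalogs(default_bundle)
        gid = default_bundle.mito_genes[0].gene_id
        read = default_bundle.planted_matures[gid].sequence[:30]
        comp, status = assign_compartment(
            scan_compartment(read, mito), scan_compartment(read, nuc)
        )
        assert (comp, status) == ("mitochondrial", "candidate")

    def test_mito_non_trna_occurrence_consumes_read(self, default_bundle):
        mito, nuc = self._bundle_catalogs(default_bundle)
        # an intergenic mitochondrial 30-mer: outside every gene interval
        genes = default_bundle.mito_genes
        gap_start = genes[-1].end + 5
        read = default_bundle.mito_sequence[gap_start : gap_start + 30]
        comp, status = assign_compartment(
            scan_compartment(read, mito), scan_compartment(read, nuc)
        )
        assert (comp, status) == ("mitochondrial", "consumed")

    def test_no_occurrence_is_unassigned(self, default_bundle):
        mito, nuc = self._bundle_catalogs(default_bundle)
        spike = default_bundle.spike_sequences[0]
        comp, status = assign_compartment(
            scan_compartment(spike, mito), scan_compartment(spike, nuc)
        )
        assert status == "unassigned"


class TestAmbiguityFilters:
    def test_decoy_read_dropped_as_outside_trna(self, default_bundle):
        decoy_rows = [r for r in default_bundle.truth_table if r.fate == "decoy"]
        assert decoy_rows
        reads = [UniqueRead(decoy_rows[0].sequence, (9, 0, 0, 0, 0, 0))]
        mito = catalog_from(
            default_bundle.mito_genes, {"mito": default_bundle.mito_sequence},
            "mitochondrial",
        )
        nuc = catalog_from(default_bundle.nuclear_genes, default_bundle.nuclear_contigs)
        result = call_trfs(reads, mito, nuc, stage_order=list("123456"))
        assert result.records == []
        assert result.dropped["nuclear_maps_outside_trna"]["reads"] == 9

    def test_multi_anticodon_read_dropped(self):
        shared = "ACGTA" * 6  # 30-nt shared prefix
        body1 = shared + "G" * 2 + "CTC" + "A" * 37
        body2 = shared + "G" * 2 + "TTC" + "C" * 37
        contigs = {"c": "G" * 20 + body1 + "T" * 30 + body2 + "G" * 20}
        genes = [
            TRNAGene("c.g1", "c", 21, 20 + len(body1), "+", "Glu", "CTC"),
            TRNAGene("c.g2", "c", 51 + len(body1), 50 + len(body1) + len(body2), "+", "Glu", "TTC"),
        ]
        nuc = catalog_from(genes, contigs)
        result = call_trfs(
            [UniqueRead(shared[:25], (7, 0, 0, 0, 0, 0))], None, nuc,
            stage_order=list("123456"),
        )
        assert result.records == []
        assert "nuclear_multiple_anticodons" in result.dropped

    def test_same_anticodon_subtypes_kept_with_all_parents(self):
        shared = "ACGTT" * 6
        body1 = shared + "AT" + "GCC" + "A" * 37
        body2 = shared + "AT" + "GCC" + "C" * 37
        contigs = {"c": "G" * 20 + body1 + "T" * 30 + body2 + "G" * 20}
        genes = [
            TRNAGene("c.g1", "c", 21, 20 + len(body1), "+", "Gly", "GCC"),
            TRNAGene("c.g2", "c", 51 + len(body1), 50 + len(body1) + len(body2), "+", "Gly", "GCC"),
        ]
        nuc = catalog_from(genes, contigs)
        result = call_trfs(
            [UniqueRead(shared[:25], (7, 0, 0, 0, 0, 0))], None, nuc,
            stage_order=list("123456"),
        )
        (rec,) = result.records
        assert set(rec.parent_ids) == {"c.g1", "c.g2"}
        # counted once per anticodon, not once per subtype
        summary = result.summary()
        assert summary.total_reads.sum() == 7

    def test_polymorphic_only_parents_dropped(self):
        body = "A" * 30 + "AT" + "GTC" + "G" * 37
        contigs = {"c": "G" * 20 + body + "T" * 20}
        genes = [TRNAGene("c.g1", "c", 21, 20 + len(body), "+", "Asp", "GTC",
                          polymorphic=True)]
        nuc = catalog_from(genes, contigs)
        result = call_trfs(
            [UniqueRead(body[:28], (6, 0, 0, 0, 0, 0))], None, nuc,
            stage_order=list("123456"),
        )
        assert result.records == []
        assert "nuclear_polymorphic_parents_only" in result.dropped


class TestCallTRFs:
    def test_empty_catalogs_leave_all_unassigned(self):
        reads = [UniqueRead("ACGT" * 8, (6, 0, 0, 0, 0, 0))]
        result = call_trfs(reads, None, None, stage_order=list("123456"))
        assert result.records == []
        assert result.dropped["unassigned"]["reads"] == 6

    def test_read_and_catalog_order_invariance(self, default_bundle):
        mito = catalog_from(
            default_bundle.mito_genes, {"mito": default_bundle.mito_sequence},
            "mitochondrial",
        )
        nuc = catalog_from(default_bundle.nuclear_genes, default_bundle.nuclear_contigs)
        rows = {}
        for r in default_bundle.truth_table:
            if r.fate in ("trf", "decoy") and len(rows) < 40:
                rows.setdefault(r.sequence, (11, 0, 0, 0, 0, 0))
        reads = [UniqueRead(s, c) for s, c in rows.items()]
        forward = call_trfs(reads, mito, nuc, stage_order=list("123456"))
        backward = call_trfs(reads[::-1], mito, nuc, stage_order=list("123456"))
        assert [r.sequence for r in forward.records] == [
            r.sequence for r in backward.records
        ]
        assert forward.dropped == backward.dropped

    def test_decoy_bookkeeping_against_truth(self, pipeline_result):
        """Per-anticodon totals fall short of gross truth by exactly the
        planted ambiguous reads."""
        bundle = pipeline_result.bundle
        surviving = expected_anticodon_totals(bundle.truth_table)
        got = {
            (row.compartment, row.anticodon): int(row.total_reads)
            for _, row in pipeline_result.anticodon_summary.iterrows()
        }
        assert got == {k: v for k, v in surviving.items() if v > 0}
        decoy_reads = sum(r.count for r in bundle.truth_table if r.fate == "decoy")
        assert decoy_reads > 0
        assert (
            pipeline_result.calls.dropped["nuclear_maps_outside_trna"]["reads"]
            == decoy_reads
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        reads, mito_genes, mito_contigs, nuc_genes, nuc_contigs = random_instance(rng)
        kept_exp, dropped_exp = oracle_aggregate(
            reads, mito_genes, mito_contigs, nuc_genes, nuc_contigs
        )
        mito = catalog_from(mito_genes, mito_contigs, "mitochondrial")
        nuc = catalog_from(nuc_genes, nuc_contigs)
        result = call_trfs(reads, mito, nuc, stage_order=list("123456"))
        kept_got = {
            r.sequence: (r.compartment, r.anticodon, frozenset(r.parent_ids), r.counts)
            for r in result.records
        }
        assert kept_got == kept_exp
        dropped_got = {k: v["reads"] for k, v in result.dropped.items()}
        assert dropped_got == dropped_exp
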
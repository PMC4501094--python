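"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the calling rules, using naive
enumeration (scan every start position, evaluate every predicate
literally), and shares no code path with the package implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_occurrences(seq: str, contigs: dict[str, str]):
    """Every occurrence of seq (either strand) found by scanning every
    position of every contig."""
    occ = []
    for name in contigs:
        contig = contigs[name]
        for strand, probe in (("+", seq), ("-", rc(seq))):
            for i in range(len(contig) - len(probe) + 1):
                if contig[i : i + len(probe)] == probe:
                    occ.append((name, i + 1, i + len(probe), strand))
    return occ


def naive_mature(gene, contigs: dict[str, str]) -> str:
    body = contigs[gene.contig_id][gene.start - 1 : gene.end]
    if gene.intron_start is not None:
        rel_s = gene.intron_start - gene.start
        rel_e = gene.intron_end - gene.start + 1
        body = body[:rel_s] + body[rel_e:]
    if gene.strand == "-":
        body = rc(body)
    return body + "CCA"


def naive_mature_hits(seq: str, mature: str):
    hits = []
    for i in range(len(mature) - len(seq) + 1):
        if mature[i : i + len(seq)] == seq:
            hits.append((i + 1, i + len(seq)))
    return hits


@dataclass
class OracleCall:
    status: str  # kept | dropped | consumed | unassigned
    compartment: str = ""
    anticodon: str = ""
    parents: frozenset = frozenset()
    reason: str = ""


def oracle_call_one(
    seq: str,
    mito_genes,
    mito_contigs: dict[str, str],
    nuc_genes,
    nuc_contigs: dict[str, str],
    edge_margin: int = 5,
    mito_other_genomic_filter: bool = False,
) -> OracleCall:
    """Literal predicate evaluation of the calling rules for one read."""

    def curated(genes, contigs):
        out = []
        for g in genes:
            if g.pseudo or g.polymorphic:
                continue
            clen = len(contigs[g.contig_id])
            if g.start - 1 < edge_margin or clen - g.end < edge_margin:
                continue
            out.append(g)
        return out

    def polymorphic(genes):
        return [g for g in genes if g.polymorphic and not g.pseudo]

    def evaluate(genes, contigs, apply_other_filter):
        cur = curated(genes, contigs)
        parent_hits = [g for g in cur if naive_mature_hits(seq, naive_mature(g, contigs))]
        poly_hits = [
            g for g in polymorphic(genes)
            if naive_mature_hits(seq, naive_mature(g, contigs))
        ]
        occ = naive_occurrences(seq, contigs)
        inside_any_annotation = lambda o: any(
            o[0] == g.contig_id and o[1] >= g.start and o[2] <= g.end and o[3] == g.strand
            for g in genes
        )
        other_genomic = any(not inside_any_annotation(o) for o in occ)
        return parent_hits, poly_hits, bool(occ), other_genomic, apply_other_filter

    mito = evaluate(mito_genes, mito_contigs, mito_other_genomic_filter)
    nuc = evaluate(nuc_genes, nuc_contigs, True)

    for compartment, (parents, poly, any_occ, other, apply_a) in (
        ("mitochondrial", mito),
        ("nuclear", nuc),
    ):
        if parents or poly:
            if apply_a and other:
                return OracleCall("dropped", compartment, reason="maps_outside_trna")
            if not parents:
                return OracleCall("dropped", compartment, reason="polymorphic_parents_only")
            anticodons = {g.anticodon for g in parents}
            if len(anticodons) > 1:
                return OracleCall("dropped", compartment, reason="multiple_anticodons")
            return OracleCall(
                "kept",
                compartment,
                anticodon=next(iter(anticodons)),
                parents=frozenset(g.gene_id for g in parents),
            )
        if any_occ:
            return OracleCall("consumed", compartment)
    return OracleCall("unassigned")


# ---- independent region-classification predicates ---------------------

def brute_force_category(
    start: int,
    end: int,
    L: int = 75,
    loop: tuple[int, int] = (31, 37),
    stem_loop: tuple[int, int] = (26, 42),
    t5: int = 2,
    t3: int = 2,
    w: int = 3,
):
    """Evaluate every region predicate independently; return the list of
    categories whose predicate holds (decision order resolves overlaps)."""
    satisfied = []
    a5 = start <= 1 + t5
    a3 = end >= L - t3
    if a5 and loop[0] <= end <= loop[1]:
        satisfied.append("5' half")
    if a3 and loop[0] <= start <= loop[1]:
        satisfied.append("3' half")
    if a5 and end < loop[0]:
        satisfied.append("5' end")
    if a3 and start > loop[1]:
        satisfied.append("3' end")
    if (not a5) and (not a3) and start >= stem_loop[0] - w and end <= stem_loop[1] + w:
        satisfied.append("AC stem-loop")
    return satisfied


# ---- random problem instances for oracle-equivalence testing ----------
# (instances are built with the package's data containers, but all
# expected outcomes come from the naive routines above)

def random_instance(rng):
    """A small random calling problem with deliberate ambiguity features:
    isodecoder subtype pairs, a shared-prefix pair with different
    anticodons, a polymorphic gene, a pseudo gene, a decoy locus and an
    assortment of read types."""
    from trfscape.read_filtering import UniqueRead
    from trfscape.trna_catalog import TRNAGene

    def rand_seq(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    def body(anticodon, L=None):
        L = L or int(rng.integers(67, 74))
        b = list(rand_seq(L))
        b[32:35] = list(anticodon)
        if "".join(b[-3:]) == "CCA":
            b[-1] = "T"
        return "".join(b)

    genes, contigs = {}, {}

    def place(contig_name, parts, pos, seq_body, anticodon, isotype="Xxx", strand="+",
              pseudo=False, polymorphic=False):
        insert = rc(seq_body) if strand == "-" else seq_body
        start = pos + 1
        parts.append(insert)
        pos += len(insert)
        gid = f"{contig_name}.g{len(genes)}"
        genes[gid] = TRNAGene(
            gene_id=gid, contig_id=contig_name, start=start, end=pos,
            strand=strand, isotype=isotype, anticodon=anticodon,
            pseudo=pseudo, polymorphic=polymorphic,
        )
        gap = rand_seq(int(rng.integers(25, 45)))
        # keep flanks CCA-read-proof, mirroring real intergenic junk that
        # just should not complete a tail by chance in a tiny toy genome
        if strand == "+" and gap.startswith("CC"):
            gap = "GG" + gap[2:]
        parts.append(gap)
        return pos + len(gap)

    # mitochondrial compartment: two genes, one minus strand
    parts, pos = [rand_seq(50)], 50
    pos = place("mito", parts, pos, body("GCT"), "GCT", "Ser", "+")
    pos = place("mito", parts, pos, body("TAC"), "TAC", "Val", "-")
    mito_contigs = {"mito": "".join(parts) + rand_seq(40)}
    mito_genes = [g for g in genes.values() if g.contig_id == "mito"]

    # nuclear contig 1: subtype pair + polymorphic + pseudo
    parts, pos = [rand_seq(50)], 50
    b1 = body("GCC")
    b2 = b1[:-8] + ("A" if b1[-8] != "A" else "G") + b1[-7:]
    if b2.endswith("CCA"):
        b2 = b2[:-1] + "T"
    pos = place("n1", parts, pos, b1, "GCC", "Gly", "+")
    pos = place("n1", parts, pos, b2, "GCC", "Gly", "-")
    pos = place("n1", parts, pos, body("GTC"), "GTC", "Asp", "+", polymorphic=True)
    pos = place("n1", parts, pos, body("CTT"), "CTT", "Lys", "+", pseudo=True)
    n1 = "".join(parts) + rand_seq(40)

    # nuclear contig 2: shared 30-nt prefix, different anticodons + decoy
    prefix = rand_seq(30)
    b3 = prefix + body("CTC")[30:]
    b4 = prefix + body("TTC")[30:]
    parts, pos = [rand_seq(50)], 50
    pos = place("n2", parts, pos, b3, "CTC", "Glu", "+")
    pos = place("n2", parts, pos, b4, "TTC", "Glu", "+")
    decoy = b1  # unannotated copy of the subtype-1 body
    parts.append(decoy)
    pos += len(decoy)
    parts.append("G" + rand_seq(30))
    n2 = "".join(parts) + rand_seq(40)
    nuc_contigs = {"n1": n1, "n2": n2}
    nuc_genes = [g for g in genes.values() if g.contig_id != "mito"]

    matures = {gid: naive_mature(g, {**mito_contigs, **nuc_contigs})
               for gid, g in genes.items()}

    n_reads = int(rng.integers(40, 90))
    counts_of = {}
    gids = sorted(genes)
    for _ in range(n_reads):
        kind = int(rng.integers(0, 8))
        gid = gids[int(rng.integers(0, len(gids)))]
        mature = matures[gid]
        length = int(rng.integers(25, 46))
        if kind <= 2:  # mature substring (may cross into CCA)
            start = int(rng.integers(0, max(1, len(mature) - length + 1)))
            seq = mature[start : start + length]
        elif kind == 3:  # flush 3' (CCA-masked style)
            seq = mature[-length:]
        elif kind == 4:  # antisense fragment
            start = int(rng.integers(0, max(1, len(mature) - length + 1)))
            seq = rc(mature[start : start + length])
        elif kind == 5:  # one substitution
            start = int(rng.integers(0, max(1, len(mature) - length + 1)))
            s = list(mature[start : start + length])
            p = int(rng.integers(0, len(s)))
            s[p] = "ACGT"[("ACGT".index(s[p]) + 1) % 4]
            seq = "".join(s)
        elif kind == 6:  # shared-prefix read (multi-anticodon bait)
            seq = prefix[: int(rng.integers(25, 31))]
        else:  # pure random
            seq = rand_seq(length)
        if len(seq) < 25:
            continue
        counts = tuple(int(c) for c in rng.integers(0, 20, size=6))
        if sum(counts) < 5:
            counts = (5,) + counts[1:]
        prev = counts_of.get(seq, (0,) * 6)
        counts_of[seq] = tuple(a + b for a, b in zip(prev, counts))
    reads = [UniqueRead(s, c) for s, c in sorted(counts_of.items())]
    return reads, mito_genes, mito_contigs, nuc_genes, nuc_contigs


def oracle_aggregate(reads, mito_genes, mito_contigs, nuc_genes, nuc_contigs,
                     edge_margin=5):
    """Oracle outcomes for a whole instance: kept-record map and read
    totals per drop reason (implementation reason-key naming)."""
    kept, dropped = {}, {}
    for read in reads:
        res = oracle_call_one(
            read.sequence, mito_genes, mito_contigs, nuc_genes, nuc_contigs,
            edge_margin=edge_margin,
        )
        if res.status == "kept":
            kept[read.sequence] = (
                res.compartment, res.anticodon, res.parents, read.counts
            )
        elif res.status == "dropped":
            key = f"{res.compartment}_{res.reason}"
            dropped[key] = dropped.get(key, 0) + sum(read.counts)
        elif res.status == "consumed":
            key = f"{res.compartment}_non_trna"
            dropped[key] = dropped.get(key, 0) + sum(read.counts)
        else:
            dropped["unassigned"] = dropped.get("unassigned", 0) + sum(read.counts)
    return kept, dropped
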
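"""Structural classification of tRFs on their parental tRNAs.

A tRF is categorised by where its span sits relative to the anticodon
loop of the mature tRNA: halves are fragments cleaved inside the anticodon
loop that reach one terminus; end fragments are shorter than halves and
stop before the loop; anticodon stem-loop fragments sit, unanchored, on
the central hairpin.  Anything else is reported as "other" rather than
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .trna_catalog import MatureTRNA, RegionMap

FIVE_HALF = "5' half"
THREE_HALF = "3' half"
FIVE_END = "5' end"
THREE_END = "3' end"
AC_STEM_LOOP = "AC stem-loop"
OTHER = "other"

#: fixed tie-break / reporting order for region categories
CATEGORY_ORDER = (FIVE_HALF, FIVE_END, THREE_HALF, THREE_END, AC_STEM_LOOP)

__all__ = [
    "FIVE_HALF",
    "THREE_HALF",
    "FIVE_END",
    "THREE_END",
    "AC_STEM_LOOP",
    "OTHER",
    "CATEGORY_ORDER",
    "RegionCall",
    "classify_region",
    "main_region",
    "top_variants",
    "variant_alignment",
]


@dataclass(frozen=True)
class RegionCall:
    """Region category for one span, with the anchoring evidence."""

    category: str
    anchored_5p: bool
    anchored_3p: bool
    loop_overlap: bool


def classify_region(
    span: tuple[int, int],
    regions: RegionMap,
    *,
    t5: int = 2,
    t3: int = 2,
    window_slack: int = 3,
) -> RegionCall:
    """Assign a structural category to a span on a mature tRNA.

    ``t5``/``t3`` are the anchoring tolerances: a fragment still counts as
    5'- (3'-) anchored when it starts (ends) within that many nucleotides
    of the terminus.  ``window_slack`` widens the anticodon stem-loop
    window for the unanchored class.  Decision order: 5' half, 3' half,
    5' end, 3' end, AC stem-loop, other — so exactly one category results.
    """
    start, end = span
    if start < 1 or end > regions.length or start > end:
        raise ValueError(f"span {span} outside mature tRNA of length {regions.length}")
    loop_s, loop_e = regions.loop
    sl_s, sl_e = regions.stem_loop
    anchored_5p = start <= 1 + t5
    anchored_3p = end >= regions.length - t3
    loop_overlap = start <= loop_e and end >= loop_s

    if anchored_5p and loop_s <= end <= loop_e:
        category = FIVE_HALF
    elif anchored_3p and loop_s <= start <= loop_e:
        category = THREE_HALF
    elif anchored_5p and end < loop_s:
        category = FIVE_END
    elif anchored_3p and start > loop_e:
        category = THREE_END
    elif (
        not anchored_5p
        and not anchored_3p
        and start >= sl_s - window_slack
        and end <= sl_e + window_slack
    ):
        category = AC_STEM_LOOP
    else:
        category = OTHER
    return RegionCall(category, anchored_5p, anchored_3p, loop_overlap)


def main_region(
    category_counts: dict[str, float] | Iterable[tuple[str, float]],
    *,
    min_fraction: float = 0.25,
) -> str:
    """Summarise a group of tRFs into its dominant region label(s).

    Every category holding at least ``min_fraction`` of the group's read
    count is reported, most abundant first, joined with " and ".  Ties are
    broken by the fixed category order.  Scale-invariant by construction.
    """
    counts = dict(category_counts)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("main_region needs a group with positive read count")
    rank = {c: i for i, c in enumerate(CATEGORY_ORDER + (OTHER,))}
    eligible = [
        c for c, n in counts.items() if n / total >= min_fraction
    ]
    eligible.sort(key=lambda c: (-counts[c], rank.get(c, len(rank))))
    if not eligible:
        # no single category reaches the threshold; fall back to the largest
        eligible = [max(counts, key=lambda c: (counts[c], -rank.get(c, len(rank))))]
    return " and ".join(eligible)


def top_variants(trfs: Sequence, k: int = 3) -> list:
    """The ``k`` most abundant tRF records of a group.

    Sorted by pooled count descending; ties broken lexicographically by
    sequence, so the result is a deterministic prefix of the full
    abundance-sorted list.
    """
    ranked = sorted(trfs, key=lambda t: (-t.pooled_count, t.sequence))
    return ranked[: max(k, 0)]


def variant_alignment(
    trfs: Sequence,
    parent: MatureTRNA,
    *,
    min_count: int | None = None,
) -> list[str]:
    """Gapless stacked alignment of tRF variants under their parent tRNA.

    Each variant row is offset by its span start; rows carry the pooled
    read count.  ``min_count`` hides variants below a read-count threshold
    (e.g. 500 to show only highly redundant variants).  cca-masked
    variants are rendered against the CCA-terminated mature sequence like
    any other.
    """
    rows = [f"{parent.sequence}  {parent.gene_id}"]
    shown = [t for t in trfs if min_count is None or t.pooled_count >= min_count]
    shown = sorted(shown, key=lambda t: (-t.pooled_count, t.sequence))
    for t in shown:
        span = t.span_on(parent.gene_id)
        if span is None:
            raise ValueError(
                f"variant {t.sequence} is not an exact substring of {parent.gene_id}"
            )
        start, end = span
        if parent.sequence[start - 1 : end] != t.sequence:
            raise ValueError(
                f"variant {t.sequence} does not match {parent.gene_id} at {span}"
            )
        rows.append(f"{' ' * (start - 1)}{t.sequence}  ({t.pooled_count})")
    return rows
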
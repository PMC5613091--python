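"""In-silico PCR: exact primer-site search and product-length prediction.

A product is delimited by one primer annealing to the plus strand and the
other to the minus strand, 3' ends facing.  Reverse primers are often printed
3'->5' in cloning protocols; pass ``rev_is_3to5=True`` to reverse such input.
Circular templates may yield origin-spanning products.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import Replicon, reverse_complement


@dataclass
class PCRProduct:
    start: int            # 1-based start of the left primer site
    end: int              # 1-based end of the right primer site (may wrap)
    length: int           # primer-inclusive product length
    insert_length: int    # product minus both primer sites
    orientation: str      # "fwd_left" | "rev_left"


def _find_sites(seq: str, primer: str, circular: bool) -> list[int]:
    """All 1-based occurrences; on circular templates sites may span the
    sequence origin."""
    hay = seq + (seq[: len(primer) - 1] if circular else "")
    sites, i = [], hay.find(primer)
    while i != -1:
        sites.append(i + 1)
        i = hay.find(primer, i + 1)
    return sites


def in_silico_pcr(
    replicon: Replicon,
    fwd_primer: str,
    rev_primer: str,
    max_product: int = 20_000,
    rev_is_3to5: bool = False,
    max_products: int = 10,
) -> list[PCRProduct]:
    fwd = fwd_primer.upper()
    rev = rev_primer.upper()
    if rev_is_3to5:
        rev = rev[::-1]
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    seq = replicon.sequence
    n = replicon.length
    circular = replicon.topology == "circular"

    products = []
    # orientation A: fwd on plus strand, rev on minus strand (rev site =
    # reverse complement of rev primer on the plus strand, downstream)
    # orientation B: the mirror-image amplicon
    for left_primer, right_primer, tag in (
        (fwd, rev, "fwd_left"),
        (rev, fwd, "rev_left"),
    ):
        lefts = _find_sites(seq, left_primer, circular)
        rights = _find_sites(seq, reverse_complement(right_primer), circular)
        for ls in lefts:
            for rs in rights:
                r_end = rs + len(right_primer) - 1
                if r_end >= ls:
                    length = r_end - ls + 1
                elif circular:
                    length = n - ls + 1 + r_end
                else:
                    continue
                if len(left_primer) + len(right_primer) <= length <= max_product:
                    products.append(PCRProduct(
                        start=ls, end=(r_end - 1) % n + 1, length=length,
                        insert_length=length - len(left_primer) - len(right_primer),
                        orientation=tag))
    # an amplicon found in both orientations (identical primers) counts once
    seen = set()
    unique = []
    for p in sorted(products, key=lambda p: (p.start, p.end, p.orientation)):
        if (p.start, p.end) not in seen:
            seen.add((p.start, p.end))
            unique.append(p)
    if len(unique) > max_products:
        raise ValueError(
            f"unspecific primer pair: {len(unique)} products (> {max_products})")
    return unique
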
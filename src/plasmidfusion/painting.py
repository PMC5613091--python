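"""Order-level gene-origin painting and donor-block segmentation.

Each gene receives a taxonomic origin at order level (Rhizobiales,
Rhodobacterales, some other order, or none) from a pre-computed homology-hit
table: self-genome hits are excluded, hits above the E-value cutoff dropped,
and the best surviving hit's order wins.  Runs of genes sharing a focal
origin delineate donor blocks; the boundaries between blocks of different
origin localize plasmid-fusion breakpoints.  Transposases can be masked from
the block vote because their scattered origins reflect intragenomic
transposition, not the fusion architecture.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIT_TABLE_COLUMNS = ["qseqid", "sseqid", "pident", "evalue", "bitscore",
                     "staxid", "sorder"]


@dataclass
class HitRecord:
    query_locus: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    subject_taxon_order: str
    subject_taxid: int


@dataclass
class GroupConfig:
    """Self/close-group definition for origin painting (defaults follow the
    M. mediterranea analysis: self TaxID 293088, close group TaxID 356 =
    Rhizobiales, E < 1e-5, up to 500 hits per gene)."""

    self_taxids: frozenset = frozenset({293088})
    close_group_taxid: int = 356
    close_group_order: str = "Rhizobiales"
    focal_orders: tuple = ("Rhizobiales", "Rhodobacterales")
    evalue_cutoff: float = 1e-5
    max_hits: int = 500
    flag_threshold: float = 0.5

    def __post_init__(self):
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue cutoff must be > 0")


@dataclass
class OriginCall:
    locus_tag: str
    origin: str  # focal order | "other:<order>" | "none"
    best_hit: Optional[HitRecord] = None
    close_fraction: float = 0.0
    # carried along for segmentation
    start: int = 0
    end: int = 0
    product: str = ""

    @property
    def focal_origin(self) -> Optional[str]:
        return self.origin if not self.origin.startswith(("other", "none")) else None


@dataclass
class Block:
    start: int
    end: int
    dominant_origin: str
    n_genes: int


@dataclass
class BlockSegmentation:
    blocks: list
    breakpoints: list  # positions between adjacent blocks of different origin


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing required columns {sorted(missing)}")
    return df


def _hits_from_frame(df: pd.DataFrame) -> list[HitRecord]:
    return [
        HitRecord(r.qseqid, r.sseqid, float(r.pident), float(r.evalue),
                  float(r.bitscore), str(r.sorder), int(r.staxid))
        for r in df.itertuples(index=False)
    ]


def classify_gene_origin(hits_for_gene: Sequence[HitRecord],
                         cfg: Optional[GroupConfig] = None) -> OriginCall:
    """Best-hit origin call after self-exclusion and E-value filtering.

    Surviving hits are ordered by ascending E-value (ties: descending
    bitscore, then subject id) and capped at ``max_hits``; the top hit's
    order is the origin and ``close_fraction`` is the share of kept hits in
    the close group."""
    cfg = cfg or GroupConfig()
    locus = hits_for_gene[0].query_locus if hits_for_gene else ""
    kept = [
        h for h in hits_for_gene
        if h.subject_taxid not in cfg.self_taxids and h.evalue < cfg.evalue_cutoff
    ]
    kept.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    kept = kept[: cfg.max_hits]
    if not kept:
        return OriginCall(locus, "none")
    best = kept[0]
    order = best.subject_taxon_order
    origin = order if order in cfg.focal_orders else f"other:{order}"
    close = sum(1 for h in kept if h.subject_taxon_order == cfg.close_group_order)
    return OriginCall(locus, origin, best, close / len(kept))


def paint_genes(hit_table: pd.DataFrame, loci_in_order: Sequence[str],
                cfg: Optional[GroupConfig] = None) -> list[OriginCall]:
    """Origin call for every locus (gene order preserved; loci without any
    table row are called 'none')."""
    cfg = cfg or GroupConfig()
    grouped = {q: g for q, g in hit_table.groupby("qseqid", sort=False)}
    calls = []
    for locus in loci_in_order:
        if locus in grouped:
            call = classify_gene_origin(_hits_from_frame(grouped[locus]), cfg)
            call.locus_tag = locus
        else:
            call = OriginCall(locus, "none")
        calls.append(call)
    return calls


def summarize_origins(calls: Sequence[OriginCall],
                      cfg: Optional[GroupConfig] = None) -> dict:
    """Counts and fractions per category; 'other:<order>' collapses to
    'other'.  Fractions are reported against all genes and against the
    classifiable (non-'none') genes, since published percentages may use
    either denominator."""
    if not calls:
        raise ValueError("no origin calls to summarize")
    cfg = cfg or GroupConfig()
    cats = list(cfg.focal_orders) + ["other", "none"]
    counts = dict.fromkeys(cats, 0)
    for c in calls:
        key = c.origin if c.origin in cfg.focal_orders else (
            "none" if c.origin == "none" else "other")
        counts[key] += 1
    n = len(calls)
    n_classified = n - counts["none"]
    fractions = {k: v / n for k, v in counts.items()}
    fractions_classified = {
        k: (counts[k] / n_classified if n_classified else float("nan"))
        for k in cats if k != "none"
    }
    return {"counts": counts, "n": n, "n_classified": n_classified,
            "fractions": fractions, "fractions_of_classified": fractions_classified}


def _majority_smooth(labels: list, window: int) -> list:
    """Sliding-majority label per position (window clipped at the ends)."""
    half = window // 2
    out = []
    for i in range(len(labels)):
        lo, hi = max(0, i - half), min(len(labels), i + half + 1)
        votes = labels[lo:hi]
        best = max(sorted(set(votes)), key=votes.count)
        out.append(best)
    return out


def segment_origin_blocks(
    calls_in_gene_order: Sequence[OriginCall],
    min_block: int = 3,
    masked_products: str = r"transposase",
    cfg: Optional[GroupConfig] = None,
    circular: bool = False,
    replicon_length: Optional[int] = None,
) -> BlockSegmentation:
    """Segment the gene order into donor blocks of dominant focal origin.

    Genes whose product matches ``masked_products`` are excluded from voting,
    as are genes of non-focal ('other'/'none') origin — both are neutral and
    never break a block.  Voting labels are majority-smoothed over a window
    of ``min_block`` genes; runs shorter than ``min_block`` are discarded as
    noise.  If no run survives, the whole replicon is one block of the
    globally dominant origin.  Breakpoints are midpoints of the gaps between
    adjacent blocks; on circular molecules a first/last block of equal origin
    merges across the origin.
    """
    cfg = cfg or GroupConfig()
    mask_re = re.compile(masked_products, re.IGNORECASE) if masked_products else None
    voters = [
        c for c in calls_in_gene_order
        if c.focal_origin is not None and not (mask_re and mask_re.search(c.product or ""))
    ]
    if not voters:
        raise ValueError("no unmasked focal-origin genes to segment")
    labels = _majority_smooth([c.origin for c in voters], min_block)

    # runs over the smoothed voting sequence
    runs = []  # (label, first_idx, last_idx) into voters
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1][2] = i
        else:
            runs.append([lab, i, i])
    surviving = [r for r in runs if r[2] - r[1] + 1 >= min_block]
    if not surviving:
        all_labels = [c.origin for c in voters]
        dominant = max(sorted(set(all_labels)), key=all_labels.count)
        blocks = [Block(voters[0].start, voters[-1].end, dominant, len(voters))]
        return BlockSegmentation(blocks, [])

    # merge consecutive surviving runs of equal label
    merged = []
    for lab, i0, i1 in surviving:
        if merged and merged[-1][0] == lab:
            merged[-1][2] = i1
        else:
            merged.append([lab, i0, i1])

    blocks = [
        Block(voters[i0].start, voters[i1].end, lab, i1 - i0 + 1)
        for lab, i0, i1 in merged
    ]
    if circular and len(blocks) > 1 and blocks[0].dominant_origin == blocks[-1].dominant_origin:
        first, last = blocks[0], blocks[-1]
        blocks = blocks[1:-1] + [Block(last.start, first.end, first.dominant_origin,
                                       first.n_genes + last.n_genes)]
        blocks.sort(key=lambda b: b.start)
    breakpoints = []
    for a, b in zip(blocks, blocks[1:]):
        breakpoints.append((a.end + b.start) // 2)
    if circular and len(blocks) > 1 and replicon_length:
        # midpoint of the gap closing the circle (the gap itself may or may
        # not wrap through the sequence origin once a block has been merged
        # across it)
        gap = (blocks[0].start - blocks[-1].end) % replicon_length
        breakpoints.append((blocks[-1].end + gap // 2 - 1) % replicon_length + 1)
    return BlockSegmentation(blocks, breakpoints)


def close_distal_flag(call: OriginCall, cfg: Optional[GroupConfig] = None) -> str:
    """'putative_HGT' when the close-group share of a gene's hits falls below
    the flag threshold — a transparent surrogate for kernel-density HGT
    discovery tools, kept deliberately simple."""
    cfg = cfg or GroupConfig()
    return "putative_HGT" if call.close_fraction < cfg.flag_threshold else "vertical"
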
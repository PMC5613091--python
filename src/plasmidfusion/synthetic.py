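"""Synthetic multi-replicon genomes and composite fusion plasmids with known
ground truth.

The default composite-plasmid spec emulates a 259-kb fusion replicon: a
200-kb high-G+C (62%) backbone of rhodobacteral genes carrying a
roseobacter-type RepABC operon with a group-2 palindrome doublet, fused to a
60-kb low-G+C (58%) rhizobial insertion carrying its own RepABC operon plus a
solitary replicase.  Every planted property — segment bounds, per-segment
replication origin (inside repC), operon/palindrome coordinates, primer
sites, per-gene origin labels before and after noise — is recorded in a
TruthRecord so each analysis stage can be scored.

Codon archetypes are per-family codon-probability vectors jittered on a
simplex and calibrated so a gene's expected G+C matches the segment target;
two independent archetypes are separated by ~0.5 RMS per RSCU codon.  G+C
skew is injected by re-assigning a fraction of G/C bases to G on the leading
strand and C on the lagging strand, which leaves G+C content untouched and
yields a windowed skew amplitude equal to the swap rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneFeature, GenomeSet, Replicon, reverse_complement
from .codon_usage import FAMILIES, RSCU_CODONS, SENSE_CODONS

# ---------------------------------------------------------------------------
# codon archetypes
# ---------------------------------------------------------------------------

_CODON_GC = np.array([sum(b in "GC" for b in c) for c in SENSE_CODONS], dtype=float)
_AA_OF = {c: aa for aa, fam in FAMILIES.items() for c in fam}
_FAMILY_IDX = {aa: [SENSE_CODONS.index(c) for c in fam] for aa, fam in FAMILIES.items()}
_N_AA = len(FAMILIES)

#: jitter concentration for fresh archetypes (lower = stronger codon bias)
ARCHETYPE_CONCENTRATION = 8.0
#: concentration tying related (same-host-genus) archetypes together; set so
#: congeneric chromosomes sit a few-fold above within-replicon RSCU sampling
#: noise (~0.4 Euclidean at 100-kb scale) yet well inside the alien-archetype
#: separation (~3.8 Euclidean)
RELATED_CONCENTRATION = 20.0


@dataclass
class CodonArchetype:
    """A codon-usage regime: sampling distribution over the 61 sense codons
    (uniform amino-acid prior) plus the implied expected RSCU vector."""

    name: str
    codon_probs: np.ndarray      # 61, sums to 1
    expected_rscu: np.ndarray    # over RSCU_CODONS (59)
    gc_target: float

    def rms_separation(self, other: "CodonArchetype") -> float:
        d = self.expected_rscu - other.expected_rscu
        return float(np.sqrt(np.mean(d ** 2)))


def _build_archetype(name: str, gc_target: float, weights: np.ndarray) -> CodonArchetype:
    """Scale family-wise jitter weights by exp(k * codon G+C) with k solved so
    the expected per-base G+C of a sampled gene equals ``gc_target``."""

    def distribution(k: float):
        w = weights * np.exp(k * _CODON_GC)
        q = np.zeros(len(SENSE_CODONS))
        syn = np.zeros(len(SENSE_CODONS))
        for aa, idx in _FAMILY_IDX.items():
            fam_w = w[idx]
            p = fam_w / fam_w.sum()
            syn[idx] = p
            q[idx] = p / _N_AA
        return q, syn

    def expected_gc(k: float) -> float:
        q, _ = distribution(k)
        return float((q * _CODON_GC).sum() / 3.0)

    lo, hi = -10.0, 10.0
    if not (expected_gc(lo) <= gc_target <= expected_gc(hi)):
        raise ValueError(f"G+C target {gc_target} unreachable for archetype {name}")
    for _ in range(60):
        mid = (lo + hi) / 2
        if expected_gc(mid) < gc_target:
            lo = mid
        else:
            hi = mid
    q, syn = distribution((lo + hi) / 2)
    rscu = np.array([syn[SENSE_CODONS.index(c)] * len(FAMILIES[_AA_OF[c]])
                     for c in RSCU_CODONS])
    return CodonArchetype(name, q, rscu, gc_target)


def make_archetype(name: str, gc_target: float, seed: int,
                   concentration: float = ARCHETYPE_CONCENTRATION) -> CodonArchetype:
    rng = np.random.default_rng(seed)
    weights = rng.gamma(concentration, 1.0, size=len(SENSE_CODONS))
    return _build_archetype(name, gc_target, weights)


def make_related_archetype(base: CodonArchetype, name: str, gc_target: float,
                           seed: int,
                           concentration: float = RELATED_CONCENTRATION) -> CodonArchetype:
    """A mild perturbation of ``base`` — e.g. the chromosome archetypes of
    congeneric genomes."""
    rng = np.random.default_rng(seed)
    eps = rng.gamma(concentration, 1.0 / concentration, size=len(SENSE_CODONS))
    return _build_archetype(name, gc_target, base.codon_probs * eps)


def roseo_like(gc_target: float = 0.62) -> CodonArchetype:
    """Preset emulating a rhodobacteral (roseobacter) codon-usage regime."""
    return make_archetype("roseo-like", gc_target, seed=20331)


def rhizo_like(gc_target: float = 0.58) -> CodonArchetype:
    """Preset emulating a rhizobial codon-usage regime."""
    return make_archetype("rhizo-like", gc_target, seed=20333)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

#: PCR primers as printed for the two pMM259 RepABC modules; reverse primers
#: are printed 3'->5' and are reversed on use.
PRIMERS = {
    "roseo": {"fwd_name": "P1245", "fwd": "CGTCGAGCAGGTAAAGAACG",
              "rev_name": "P1246", "rev_printed_3to5": "GTTTCGACCCCTTCAGCATC",
              "product": 4415},
    "rhizo": {"fwd_name": "P1289", "fwd": "GCTCATCGTACCGTTTGTCC",
              "rev_name": "P1290", "rev_printed_3to5": "GCGAAATCCACGGTAATGCT",
              "product": 4986},
}


@dataclass
class OperonSpec:
    position: int                    # segment-relative planned repA start (1-based)
    strand: str = "+"
    palindrome_group: Optional[str] = None   # group-1 | group-2 | None
    spacer: int = 20                 # bases between the two 14-mers
    gene_lengths: tuple = (1251, 999, 1302)  # repA, repB, repC (bp, /3)
    gaps: tuple = (50, 400)          # repA-repB, repB-repC (antisense-RNA spacer)
    carries_segment_ori: bool = True  # plant the segment ori inside repC
    primer_key: Optional[str] = None  # key into PRIMERS

    @property
    def span_length(self) -> int:
        return sum(self.gene_lengths) + sum(self.gaps)


@dataclass
class SegmentSpec:
    length: int
    gc_target: float
    archetype: CodonArchetype
    origin_label: str                # Rhodobacterales | Rhizobiales | ...
    operons: list = field(default_factory=list)
    solitary_repc_at: Optional[int] = None  # segment-relative position
    ori_at: Optional[int] = None     # segment-relative; default: operon repC or length//3


@dataclass
class CompositePlasmidSpec:
    replicon_id: str = "pSYN259"
    segments: list = field(default_factory=list)
    skew_amplitude: float = 0.10
    noise_flip_rate: float = 0.10    # gene-level origin-label flip rate
    none_rate: float = 0.03          # genes whose hits all miss the cutoff
    transposase_rate: float = 0.04
    mean_gene_len: int = 900
    mean_intergenic: int = 120

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @staticmethod
    def pmm259_like(backbone_length: int = 200_000,
                    insertion_length: int = 60_000,
                    skew_amplitude: float = 0.10,
                    noise_flip_rate: float = 0.10,
                    none_rate: float = 0.03) -> "CompositePlasmidSpec":
        """The default scenario: 200-kb G+C-0.62 rhodobacteral
        backbone (roseobacter operon, group-2 doublet, 4415-bp primer pair) +
        60-kb G+C-0.58 rhizobial insertion (own operon with ori inside repC,
        4986-bp primer pair, solitary replicase)."""
        backbone = SegmentSpec(
            length=backbone_length, gc_target=0.62, archetype=roseo_like(0.62),
            origin_label="Rhodobacterales",
            operons=[OperonSpec(position=backbone_length // 2,
                                palindrome_group="group-2",
                                primer_key="roseo")],
        )
        insertion = SegmentSpec(
            length=insertion_length, gc_target=0.58, archetype=rhizo_like(0.58),
            origin_label="Rhizobiales",
            operons=[OperonSpec(position=insertion_length // 3,
                                palindrome_group="group-1",
                                gene_lengths=(1500, 1200, 1500),
                                primer_key="rhizo")],
            solitary_repc_at=int(insertion_length * 0.75),
        )
        return CompositePlasmidSpec(
            segments=[backbone, insertion], skew_amplitude=skew_amplitude,
            noise_flip_rate=noise_flip_rate, none_rate=none_rate)


@dataclass
class TruthRecord:
    replicon_id: str
    segments: list = field(default_factory=list)    # dicts: start,end,label,gc,ori,ter
    operons: list = field(default_factory=list)     # dicts incl palindrome coords
    solitary_repc: list = field(default_factory=list)
    genes: list = field(default_factory=list)       # dicts incl true/observed origin
    primers: list = field(default_factory=list)
    chromid_labels: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

_CODON_STRS = np.array(SENSE_CODONS)
_STOPS = ("TAA", "TGA", "TAG")

_MOTIF_BY_GROUP = {
    "group-1": "TTAACAG" + reverse_complement("TTAACAG"),
    "group-2": "TTCACAG" + reverse_complement("TTCACAG"),
}

_ORDER_TAXIDS = {"Rhizobiales": 356, "Rhodobacterales": 204455,
                 "Sphingomonadales": 204457, "Caulobacterales": 204458}
_OTHER_ORDERS = ("Sphingomonadales", "Caulobacterales")
SELF_TAXID = 293088


def _sample_gene(rng: np.random.Generator, archetype: CodonArchetype,
                 length: int) -> str:
    """A CDS of ``length`` bp (multiple of 3): ATG + archetype codons + stop."""
    n_body = length // 3 - 2
    idx = rng.choice(len(SENSE_CODONS), size=n_body, p=archetype.codon_probs)
    return "ATG" + "".join(_CODON_STRS[idx]) + _STOPS[rng.integers(0, 3)]


@dataclass
class _PlacedGene:
    start: int      # segment-relative 1-based
    end: int
    strand: str
    role: Optional[str]
    product: str


def _plan_segment(rng: np.random.Generator, seg: SegmentSpec,
                  spec: CompositePlasmidSpec) -> tuple[list[_PlacedGene], list[tuple[int, int]]]:
    """Place operons/solitary genes at reserved positions and fill the rest
    with ordinary genes; returns genes and reserved intervals."""
    reserved: list[tuple[int, int]] = []
    genes: list[_PlacedGene] = []
    for op in seg.operons:
        if op.position < 300 or op.position + op.span_length + 400 > seg.length:
            raise ValueError("operon does not fit inside its segment")
        product_reach = 0
        if op.primer_key:
            product_reach = PRIMERS[op.primer_key]["product"] - 170
        hi = op.position + max(op.span_length + 350, product_reach + 50)
        if hi > seg.length:
            raise ValueError("operon primer product does not fit inside segment")
        reserved.append((op.position - 250, hi))
        cursor = op.position
        lens, gaps = op.gene_lengths, op.gaps
        roles = ("repA", "repB", "repC")
        prods = ("replication protein RepA (ParA family)",
                 "replication protein RepB (ParB family)",
                 "replicase RepC")
        coords = []
        for k in range(3):
            coords.append((cursor, cursor + lens[k] - 1))
            cursor += lens[k] + (gaps[k] if k < 2 else 0)
        idx = list(range(3)) if op.strand == "+" else [2, 1, 0]
        for k in range(3):
            s, e = coords[k]
            r = idx[k]
            genes.append(_PlacedGene(s, e, op.strand, roles[r], prods[r]))
    if seg.solitary_repc_at is not None:
        pos = seg.solitary_repc_at
        if pos < 100 or pos + 1500 > seg.length:
            raise ValueError("solitary replicase does not fit inside segment")
        for lo, hi in reserved:
            if pos <= hi and pos + 1500 >= lo:
                raise ValueError("solitary replicase overlaps an operon reserve")
        reserved.append((pos - 100, pos + 1402))
        genes.append(_PlacedGene(pos, pos + 1301, "+", "repC", "replicase RepC"))
    reserved.sort()
    for (a, b), (c, d) in zip(reserved, reserved[1:]):
        if c <= b:
            raise ValueError("overlapping reserved intervals in segment spec")

    # fill unreserved gaps with ordinary genes
    bounds = [(1, seg.length)]
    for lo, hi in reserved:
        nb = []
        for a, b in bounds:
            if hi < a or lo > b:
                nb.append((a, b))
            else:
                if lo - 1 >= a:
                    nb.append((a, lo - 1))
                if hi + 1 <= b:
                    nb.append((hi + 1, b))
        bounds = nb
    for a, b in bounds:
        cursor = a
        while True:
            gap = 2 + int(rng.geometric(1.0 / spec.mean_intergenic))
            glen = int(np.exp(rng.normal(np.log(spec.mean_gene_len), 0.35)))
            glen = min(max(glen // 3 * 3, 300), 3000)
            start = cursor + gap
            if start + glen - 1 > b - 2:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            product = ("transposase" if rng.random() < spec.transposase_rate
                       else "hypothetical protein")
            genes.append(_PlacedGene(start, start + glen - 1, strand, None, product))
            cursor = start + glen - 1
    genes.sort(key=lambda g: g.start)
    return genes, reserved


def _materialize_segment(rng: np.random.Generator, seg: SegmentSpec,
                         genes: list[_PlacedGene],
                         reserved: list[tuple[int, int]],
                         skew_amplitude: float) -> tuple[np.ndarray, int, int]:
    """Emit the segment byte array with calibrated G+C and injected skew;
    returns (array, ori_rel, ter_rel)."""
    L = seg.length
    # intergenic background near the target G+C
    p_gc = seg.gc_target
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=L, p=probs)
    genic = np.zeros(L, dtype=bool)
    for g in genes:
        s = _sample_gene(rng, seg.archetype, g.end - g.start + 1)
        if g.strand == "-":
            s = reverse_complement(s)
        arr[g.start - 1 : g.end] = np.frombuffer(s.encode(), dtype=np.uint8)
        genic[g.start - 1 : g.end] = True
    in_reserve = np.zeros(L, dtype=bool)
    for lo, hi in reserved:
        in_reserve[max(lo - 1, 0) : hi] = True

    # calibrate G+C by flipping intergenic bases outside reserved zones
    G, C, A, T = (ord(x) for x in "GCAT")
    is_gc = (arr == G) | (arr == C)
    target_count = round(seg.gc_target * L)
    delta = target_count - int(is_gc.sum())
    flippable = ~genic & ~in_reserve
    if delta > 0:
        cand = np.nonzero(flippable & ~is_gc)[0]
    else:
        cand = np.nonzero(flippable & is_gc)[0]
    need = abs(delta)
    if need > len(cand):
        raise ValueError(
            f"cannot reach G+C {seg.gc_target}: {need} flips needed, "
            f"{len(cand)} intergenic bases available")
    pick = rng.choice(cand, size=need, replace=False)
    if delta > 0:
        arr[pick] = np.where(rng.random(need) < 0.5, G, C)
    else:
        arr[pick] = np.where(rng.random(need) < 0.5, A, T)

    # replication origin and skew
    if seg.ori_at is not None:
        ori = seg.ori_at
    else:
        ori = L // 3
        for op in seg.operons:
            if op.carries_segment_ori:
                repc = next(g for g in genes if g.role == "repC"
                            and op.position <= g.start <= op.position + op.span_length)
                ori = repc.start + 2 * (repc.end - repc.start + 1) // 3
                break
    ter = (ori + L // 2 - 1) % L + 1
    pos = np.arange(1, L + 1)
    if ori < ter:
        leading = (pos > ori) & (pos <= ter)
    else:
        leading = (pos > ori) | (pos <= ter)
    is_gc = (arr == G) | (arr == C)
    swap = rng.random(L) < skew_amplitude
    arr[is_gc & swap & leading] = G
    arr[is_gc & swap & ~leading] = C
    return arr, ori, ter


def generate_composite_plasmid(
    spec: Optional[CompositePlasmidSpec] = None,
    seed: int = 0,
) -> tuple[Replicon, TruthRecord, pd.DataFrame]:
    """Deterministically emit a composite plasmid, its ground truth and a
    BLAST-style per-gene hit table."""
    spec = spec or CompositePlasmidSpec.pmm259_like()
    rng = np.random.default_rng(seed)
    truth = TruthRecord(spec.replicon_id)
    arrays = []
    all_genes: list[tuple[_PlacedGene, str, int]] = []  # (gene, label, offset)
    offset = 0
    motif_writes: list[tuple[int, str]] = []  # absolute 1-based start, string
    for seg in spec.segments:
        genes, reserved = _plan_segment(rng, seg, spec)
        arr, ori, ter = _materialize_segment(rng, seg, genes, reserved,
                                             spec.skew_amplitude)
        truth.segments.append({
            "start": offset + 1, "end": offset + seg.length,
            "label": seg.origin_label, "gc_target": seg.gc_target,
            "ori": offset + ori, "ter": offset + ter,
            "ori_in_segment": ori, "ter_in_segment": ter,
        })
        for op in seg.operons:
            op_genes = [g for g in genes
                        if g.role and op.position <= g.start <= op.position + op.span_length]
            roles = {g.role: g for g in op_genes}
            repc = roles["repC"]
            pal = None
            if op.palindrome_group:
                motif = _MOTIF_BY_GROUP[op.palindrome_group]
                # doublet shortly downstream of repC in transcription order
                if op.strand == "+":
                    p1 = repc.end + 30
                else:
                    p1 = min(g.start for g in op_genes) - 30 - (2 * len(motif) + op.spacer)
                p2 = p1 + len(motif) + op.spacer
                motif_writes.append((offset + p1, motif))
                motif_writes.append((offset + p2, motif))
                pal = {"group": op.palindrome_group, "spacer": op.spacer,
                       "first": offset + p1, "second": offset + p2}
            primer_rec = None
            if op.primer_key:
                pr = PRIMERS[op.primer_key]
                fwd = pr["fwd"]
                rev = pr["rev_printed_3to5"][::-1]  # actual 5'->3'
                a_start = min(g.start for g in op_genes)
                f_start = a_start - 170
                r_site = f_start + pr["product"] - len(rev)
                motif_writes.append((offset + f_start, fwd))
                motif_writes.append((offset + r_site, reverse_complement(rev)))
                primer_rec = {
                    "pair": op.primer_key, "fwd_name": pr["fwd_name"],
                    "rev_name": pr["rev_name"], "fwd": fwd, "rev": rev,
                    "product_length": pr["product"],
                    "fwd_site_start": offset + f_start,
                    "rev_site_end": offset + r_site + len(rev) - 1,
                }
                truth.primers.append(primer_rec)
            truth.operons.append({
                "replicon": spec.replicon_id, "strand": op.strand,
                "span": [offset + min(g.start for g in op_genes),
                         offset + max(g.end for g in op_genes)],
                "group": op.palindrome_group or "untyped",
                "palindromes": pal,
                "repC": [offset + repc.start, offset + repc.end],
            })
        for g in genes:
            if g.role == "repC" and seg.solitary_repc_at is not None \
                    and g.start == seg.solitary_repc_at:
                truth.solitary_repc.append(offset + g.start)
            all_genes.append((g, seg.origin_label, offset))
        arrays.append(arr)
        offset += seg.length
    full = np.concatenate(arrays)
    for start, s in motif_writes:
        full[start - 1 : start - 1 + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
    sequence = full.tobytes().decode()

    # features + truth genes + hit table
    all_genes.sort(key=lambda t: t[0].start + t[2])
    features = []
    hit_rows = []
    for i, (g, label, off) in enumerate(all_genes):
        locus = f"{spec.replicon_id}_{(i + 1) * 5:05d}"
        features.append(GeneFeature(locus, off + g.start, off + g.end, g.strand,
                                    "CDS", g.product, g.role))
        # transposases flip to the opposing focal order (recent intragenomic
        # transposition scatters them across both donor segments); ordinary
        # misassignments scatter uniformly over wrong orders
        opposing = "Rhizobiales" if label == "Rhodobacterales" else "Rhodobacterales"
        if rng.random() < spec.none_rate:
            observed = "none"
        elif g.product == "transposase":
            observed = opposing if rng.random() < 0.5 else label
        elif rng.random() < spec.noise_flip_rate:
            wrong = [o for o in (opposing, *_OTHER_ORDERS) if o != label]
            observed = wrong[rng.integers(len(wrong))]
        else:
            observed = label
        truth.genes.append({
            "locus_tag": locus, "start": off + g.start, "end": off + g.end,
            "strand": g.strand, "segment_label": label, "product": g.product,
            "true_origin": label, "observed_origin": observed,
        })
        hit_rows.extend(_gene_hits(rng, locus, observed, label))
    hits = pd.DataFrame(hit_rows, columns=["qseqid", "sseqid", "pident", "evalue",
                                           "bitscore", "staxid", "sorder"])
    replicon = Replicon(spec.replicon_id, sequence, "circular", features)
    _check_truth(replicon, truth, spec)
    return replicon, truth, hits


def _gene_hits(rng: np.random.Generator, locus: str, observed: str,
               true_label: str) -> list[tuple]:
    """5-50 hits per gene: the best qualifying hit carries the observed order;
    decoys straddle the E-value cutoff and a couple of self-genome hits with
    excellent E-values test self-exclusion."""
    rows = []
    n = int(rng.integers(5, 51))
    if observed == "none":
        # every hit misses the E < 1e-5 cutoff
        ev = 10.0 ** rng.uniform(-4.9, -3.0, size=n)
        orders = rng.choice([true_label] + list(_OTHER_ORDERS), size=n)
        for j in range(n):
            rows.append((locus, f"WP_{rng.integers(10**8):09d}", round(rng.uniform(30, 90), 1),
                         float(ev[j]), round(rng.uniform(50, 500), 1),
                         _ORDER_TAXIDS[orders[j]], orders[j]))
        return rows
    ev = 10.0 ** rng.uniform(-180.0, -3.0, size=n)
    other = "Rhizobiales" if observed == "Rhodobacterales" else "Rhodobacterales"
    orders = rng.choice([observed, other, *_OTHER_ORDERS], size=n,
                        p=[0.55, 0.25, 0.10, 0.10])
    orders[int(np.argmin(ev))] = observed
    for j in range(n):
        rows.append((locus, f"WP_{rng.integers(10**8):09d}", round(rng.uniform(30, 90), 1),
                     float(ev[j]), round(rng.uniform(50, 500), 1),
                     _ORDER_TAXIDS[orders[j]], orders[j]))
    if rng.random() < 0.5:  # self-genome hits, always the nominal best
        for _ in range(2):
            rows.append((locus, f"SELF_{rng.integers(10**6):06d}", 100.0,
                         1e-200, 999.0, SELF_TAXID, true_label))
    return rows


def _check_truth(replicon: Replicon, truth: TruthRecord,
                 spec: CompositePlasmidSpec) -> None:
    """Generation-time consistency: planted coordinates match the sequence."""
    for op in truth.operons:
        pal = op["palindromes"]
        if pal:
            motif = _MOTIF_BY_GROUP[op["group"]]
            for key in ("first", "second"):
                s = pal[key]
                assert replicon.sequence[s - 1 : s - 1 + 14] == motif, \
                    "planted palindrome corrupted"
    for seg, sspec in zip(truth.segments, spec.segments):
        sub = replicon.sequence[seg["start"] - 1 : seg["end"]]
        gc = (sub.count("G") + sub.count("C")) / len(sub)
        assert abs(gc - sspec.gc_target) <= 0.005, \
            f"segment G+C {gc:.4f} misses target {sspec.gc_target}"


# ---------------------------------------------------------------------------
# genome sets
# ---------------------------------------------------------------------------

@dataclass
class RepliconSpec:
    replicon_id: str
    length: int
    kind: str                        # chromosome | chromid | plasmid
    gc_target: float = 0.62
    n_operons: int = 0
    palindrome_group: Optional[str] = None
    origin_label: str = "Rhizobiales"


def generate_genome_set(
    replicon_specs: Sequence[RepliconSpec],
    seed: int = 0,
    host_archetype: Optional[CodonArchetype] = None,
    alien_archetype: Optional[CodonArchetype] = None,
    skew_amplitude: float = 0.10,
    noise_flip_rate: float = 0.0,
) -> tuple[GenomeSet, TruthRecord, pd.DataFrame]:
    """A genome set whose chromids share the chromosome's codon archetype and
    whose plasmids carry an alien archetype; all truth recorded."""
    rng = np.random.default_rng(seed)
    host = host_archetype or make_archetype("host", 0.63, seed=int(rng.integers(2**31)))
    alien = alien_archetype or make_archetype("alien", 0.58, seed=int(rng.integers(2**31)))
    replicons, frames = [], []
    truth = TruthRecord("genome_set")
    for rs in replicon_specs:
        archetype = alien if rs.kind == "plasmid" else host
        gc = rs.gc_target
        operons = []
        pos = rs.length // 4
        for _ in range(rs.n_operons):
            operons.append(OperonSpec(position=pos,
                                      palindrome_group=rs.palindrome_group))
            pos += rs.length // max(rs.n_operons, 1)
        seg = SegmentSpec(rs.length, gc, archetype, rs.origin_label, operons)
        sub = CompositePlasmidSpec(replicon_id=rs.replicon_id, segments=[seg],
                                   skew_amplitude=skew_amplitude,
                                   noise_flip_rate=noise_flip_rate, none_rate=0.0)
        rep, t, hits = generate_composite_plasmid(sub, seed=int(rng.integers(2**31)))
        replicons.append(rep)
        frames.append(hits)
        truth.segments.extend(
            {**s, "replicon": rs.replicon_id} for s in t.segments)
        truth.operons.extend(t.operons)
        truth.solitary_repc.extend(t.solitary_repc)
        truth.genes.extend({**g, "replicon": rs.replicon_id} for g in t.genes)
        truth.chromid_labels[rs.replicon_id] = rs.kind
    chromosome = next(rs.replicon_id for rs in replicon_specs if rs.kind == "chromosome")
    return (GenomeSet(replicons, chromosome), truth,
            pd.concat(frames, ignore_index=True))


def martelella_like_genome(
    seed: int = 0,
    host_archetype: Optional[CodonArchetype] = None,
) -> tuple[GenomeSet, TruthRecord, pd.DataFrame]:
    """A four-replicon Martelella-like multipartite genome: chromosome, two
    chromids carrying one rhizobial RepABC module each, and the composite
    plasmid with rhodobacteral + rhizobial modules plus a solitary replicase
    (4 modules + 1 solitary genome-wide)."""
    rng = np.random.default_rng(seed)
    host = host_archetype or make_archetype("host", 0.63,
                                            seed=int(rng.integers(2**31)))
    chrom_spec = [
        RepliconSpec("chrSYN", 240_000, "chromosome", gc_target=0.63),
        RepliconSpec("pSYN593", 140_000, "chromid", gc_target=0.62, n_operons=1),
        RepliconSpec("pSYN170", 100_000, "chromid", gc_target=0.62, n_operons=1),
    ]
    genome, truth, hits = generate_genome_set(
        chrom_spec, seed=int(rng.integers(2**31)), host_archetype=host)
    plasmid_spec = CompositePlasmidSpec.pmm259_like()
    rep, t, h = generate_composite_plasmid(plasmid_spec, seed=int(rng.integers(2**31)))
    genome = GenomeSet(genome.replicons + [rep], genome.designated_chromosome)
    truth.segments.extend({**s, "replicon": rep.id} for s in t.segments)
    truth.operons.extend(t.operons)
    truth.solitary_repc.extend(t.solitary_repc)
    truth.genes.extend({**g, "replicon": rep.id} for g in t.genes)
    truth.primers.extend(t.primers)
    truth.chromid_labels[rep.id] = "plasmid"
    return genome, truth, pd.concat([hits, h], ignore_index=True)


def export_bundle(genome: GenomeSet | Replicon, truth: TruthRecord,
                  hits: pd.DataFrame, outdir: str | Path,
                  prefix: str = "synthetic") -> dict:
    """Write GenBank + FASTA + hit TSV + truth JSON; returns the paths."""
    from .genome_io import write_fasta, write_genbank

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genbank": outdir / f"{prefix}.gbk",
        "fasta": outdir / f"{prefix}.fasta",
        "hits": outdir / f"{prefix}.hits.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_genbank(genome, paths["genbank"])
    write_fasta(genome, paths["fasta"])
    hits.to_csv(paths["hits"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
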
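"""Codon counting, relative synonymous codon usage (RSCU), ordination and the
chromid/plasmid classification rule.

RSCU for codon i in a synonymous family f of size n_f is
``count_i / (sum_f counts / n_f)``: 1 means unbiased usage.  The RSCU vector
over the 59 codons in degenerate families (bacterial code 11; ATG and TGG
excluded) characterizes a replicon's long-term mutational/selectional regime.
Chromids — extrachromosomal replicons that have co-evolved with their host —
share the chromosome's codon usage, whereas genuine (recently transferred)
plasmids deviate; the classifier formalizes this as a Euclidean-distance
threshold in RSCU space.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .genome_io import Replicon, feature_sequence

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: the 61 sense codons of bacterial code 11
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: amino acid -> synonymous codon family (sorted)
FAMILIES: dict[str, tuple[str, ...]] = {}
for codon in SENSE_CODONS:
    FAMILIES.setdefault(_TABLE.forward_table[codon], tuple())
FAMILIES = {
    aa: tuple(sorted(c for c in SENSE_CODONS if _TABLE.forward_table[c] == aa))
    for aa in FAMILIES
}

#: the 59 codons carrying usage signal (single-codon families Met/Trp excluded)
RSCU_CODONS: tuple[str, ...] = tuple(
    c for aa, fam in sorted(FAMILIES.items()) for c in fam if len(fam) > 1
)


@dataclass
class CodonCounts:
    unit_id: str
    counts: Counter
    n_cds: int = 0
    n_skipped: int = 0  # N-containing codons skipped

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RSCUProfile:
    unit_id: str
    rscu: dict  # codon -> RSCU over RSCU_CODONS
    empty_families: list = field(default_factory=list)  # amino acids with zero usage

    def vector(self) -> np.ndarray:
        return np.array([self.rscu[c] for c in RSCU_CODONS])


@dataclass
class OrdinationResult:
    unit_ids: list
    coords: np.ndarray            # units x 2
    explained_variance_pct: np.ndarray  # per component, all components
    loadings: np.ndarray          # 59 x 2
    degenerate: bool = False


@dataclass
class ChromidCall:
    replicon_id: str
    call: str  # chromosome | chromid | plasmid
    distance_to_chromosome: float


def count_codons(cds_seqs: Sequence[str], unit_id: str = "") -> CodonCounts:
    """Count sense codons over in-frame CDS sequences.  Codons containing N
    are skipped, stop codons excluded, and a CDS whose length is not a
    multiple of 3 is counted up to its last full codon with a warning."""
    if not cds_seqs:
        raise ValueError("no coding sequences supplied")
    counts: Counter = Counter()
    n_skipped = 0
    for seq in cds_seqs:
        seq = seq.upper()
        if len(seq) % 3:
            logger.warning("CDS length %d not divisible by 3; truncating", len(seq))
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                n_skipped += 1
            elif codon in STOP_CODONS:
                continue
            else:
                counts[codon] += 1
    return CodonCounts(unit_id, counts, n_cds=len(cds_seqs), n_skipped=n_skipped)


def compute_rscu(counts: CodonCounts) -> RSCUProfile:
    """RSCU_i = count_i / (family total / family size); zero-usage families
    yield all-zero RSCU and are flagged."""
    rscu: dict[str, float] = {}
    empty = []
    for aa, fam in FAMILIES.items():
        if len(fam) == 1:
            continue
        tot = sum(counts.counts.get(c, 0) for c in fam)
        if tot == 0:
            empty.append(aa)
            for c in fam:
                rscu[c] = 0.0
        else:
            for c in fam:
                rscu[c] = counts.counts.get(c, 0) * len(fam) / tot
    return RSCUProfile(counts.unit_id, rscu, empty)


def replicon_rscu(replicon: Replicon) -> RSCUProfile:
    """Whole-replicon RSCU from all annotated CDSs."""
    seqs = [feature_sequence(replicon, f) for f in replicon.cds_features()]
    return compute_rscu(count_codons(seqs, unit_id=replicon.id))


def segment_rscu(replicon: Replicon, segments: Sequence[tuple[int, int]],
                 ids: Optional[Sequence[str]] = None) -> list[RSCUProfile]:
    """One RSCU profile per (start, end) segment, using only CDSs fully inside
    the segment (wrapping segments allowed on circular molecules).  Segments
    with no CDS yield an all-empty flagged profile."""
    profiles = []
    n = replicon.length
    for k, (start, end) in enumerate(segments):
        unit = ids[k] if ids else f"{replicon.id}:{start}-{end}"
        def inside(f):
            if f.wraps_origin:
                return False
            if start <= end:
                return start <= f.start and f.end <= end
            return f.start >= start or f.end <= end  # wrapping segment
        feats = [f for f in replicon.cds_features() if inside(f)]
        if not feats:
            logger.warning("segment %s contains no CDS", unit)
            profiles.append(RSCUProfile(unit, {c: 0.0 for c in RSCU_CODONS},
                                        sorted(a for a, fam in FAMILIES.items()
                                               if len(fam) > 1)))
            continue
        seqs = [feature_sequence(replicon, f) for f in feats]
        profiles.append(compute_rscu(count_codons(seqs, unit_id=unit)))
    return profiles


def rscu_matrix(profiles: Sequence[RSCUProfile]) -> np.ndarray:
    return np.vstack([p.vector() for p in profiles])


def ordinate(profiles: Sequence[RSCUProfile], n_components: int = 2,
             scale: bool = False) -> OrdinationResult:
    """Centered (optionally scaled) PCA of the RSCU matrix.  Component signs
    are fixed so the largest-magnitude loading of each is positive; explained
    variance percentages cover all components and sum to 100."""
    if len(profiles) < 3:
        raise ValueError("ordination requires at least 3 profiles")
    X = rscu_matrix(profiles)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    total_var = float((X ** 2).sum())
    unit_ids = [p.unit_id for p in profiles]
    if total_var < 1e-12:
        k = min(n_components, X.shape[0])
        return OrdinationResult(unit_ids, np.zeros((X.shape[0], n_components)),
                                np.zeros(k), np.zeros((X.shape[1], n_components)),
                                degenerate=True)
    pca = PCA(n_components=None, svd_solver="full")
    coords_all = pca.fit_transform(X)
    comps = pca.components_
    for j in range(comps.shape[0]):
        lead = np.argmax(np.abs(comps[j]))
        if comps[j, lead] < 0:
            comps[j] *= -1
            coords_all[:, j] *= -1
    expl = pca.explained_variance_ratio_ * 100.0
    return OrdinationResult(unit_ids, coords_all[:, :n_components], expl,
                            comps[:n_components].T)


def cluster_units(profiles: Sequence[RSCUProfile], method: str = "average",
                  metric: str = "euclidean") -> tuple[np.ndarray, list]:
    """Agglomerative clustering of RSCU vectors; returns (linkage matrix,
    leaf labels in input order)."""
    if len(profiles) < 2:
        raise ValueError("clustering requires at least 2 profiles")
    X = rscu_matrix(profiles)
    Z = hierarchy.linkage(X, method=method, metric=metric)
    return Z, [p.unit_id for p in profiles]


def dendrogram_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage to Newick text with merge heights as branch
    lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def classify_chromids(
    profiles: Sequence[RSCUProfile],
    chromosome_of,
    threshold_factor: float = 0.5,
    absolute_threshold: float = 1.5,
) -> list[ChromidCall]:
    """Call each non-chromosome replicon chromid or plasmid.

    ``chromosome_of`` is either a single chromosome unit id (single-genome
    set) or a mapping replicon_id -> chromosome_id covering every profile.
    With >= 2 chromosomes the rule is: chromid iff the Euclidean RSCU distance
    to the replicon's own chromosome is <= threshold_factor * median pairwise
    inter-chromosome distance.  A single-genome set has no inter-chromosome
    scale and falls back to the absolute threshold with a warning.
    """
    by_id = {p.unit_id: p for p in profiles}
    if isinstance(chromosome_of, str):
        mapping = {p.unit_id: chromosome_of for p in profiles}
    else:
        mapping = dict(chromosome_of)
    chromosomes = sorted(set(mapping.values()))
    for c in chromosomes:
        if c not in by_id:
            raise ValueError(f"chromosome profile {c!r} missing")
    if len(chromosomes) >= 2:
        dists = [
            float(np.linalg.norm(by_id[a].vector() - by_id[b].vector()))
            for i, a in enumerate(chromosomes)
            for b in chromosomes[i + 1 :]
        ]
        threshold = threshold_factor * float(np.median(dists))
    else:
        logger.warning(
            "single-genome set: no inter-chromosome distances; using absolute "
            "RSCU-distance threshold %.3g", absolute_threshold
        )
        threshold = absolute_threshold
    calls = []
    for p in profiles:
        chrom = mapping[p.unit_id]
        d = float(np.linalg.norm(p.vector() - by_id[chrom].vector()))
        if p.unit_id == chrom:
            call = "chromosome"
        else:
            call = "chromid" if d <= threshold else "plasmid"
        calls.append(ChromidCall(p.unit_id, call, d))
    return calls
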
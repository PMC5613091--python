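"""Codon counting, RSCU, ordination, clustering and chromid calls."""

import io

import numpy as np
import pytest
from Bio import Phylo
from hypothesis import given, settings, strategies as st

from plasmidfusion.codon_usage import (FAMILIES, RSCU_CODONS, ChromidCall,
                                       classify_chromids, cluster_units,
                                       compute_rscu, count_codons,
                                       dendrogram_newick, ordinate,
                                       replicon_rscu, segment_rscu)
from plasmidfusion.synthetic import make_archetype

CODING = st.lists(
    st.text(alphabet="ACGT", min_size=3, max_size=60).map(
        lambda s: s[: len(s) - len(s) % 3]
    ).filter(lambda s: len(s) >= 3),
    min_size=1, max_size=8,
)


def _archetype_profile(seed, gc=0.60, n_codons=30_000, sample_seed=0):
    arch = make_archetype(f"a{seed}", gc, seed=seed)
    rng = np.random.default_rng(sample_seed + seed)
    idx = rng.choice(61, size=n_codons, p=arch.codon_probs)
    from plasmidfusion.codon_usage import SENSE_CODONS
    seq = "".join(np.array(SENSE_CODONS)[idx])
    prof = compute_rscu(count_codons([seq], unit_id=f"u{seed}"))
    return prof


class TestCountCodons:
    def test_stops_and_start_counting(self):
        counts = count_codons(["ATGGGTTAA"])
        assert counts.counts == {"ATG": 1, "GGT": 1}

    def test_n_codons_skipped(self):
        counts = count_codons(["ATGNNNGGC"])
        assert counts.counts == {"ATG": 1, "GGC": 1}
        assert counts.n_skipped == 1

    def test_frame_truncation_warns(self, caplog):
        counts = count_codons(["ATGGG"])
        assert counts.counts == {"ATG": 1}
        assert "truncating" in caplog.text

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            count_codons([])

    @settings(max_examples=200, derandomize=True)
    @given(CODING, CODING)
    def test_additivity(self, xs, ys):
        cx, cy = count_codons(xs), count_codons(ys)
        cxy = count_codons(xs + ys)
        assert cxy.counts == cx.counts + cy.counts


class TestRSCU:
    def test_uniform_fourfold_family(self):
        counts = count_codons(["GGT" * 2 + "GGC" * 2 + "GGA" * 2 + "GGG" * 2])
        rscu = compute_rscu(counts)
        assert all(rscu.rscu[c] == 1.0 for c in FAMILIES["G"])

    def test_twofold_family_hand_formula(self):
        # Lys: AAA x3, AAG x1 -> RSCU 1.5 / 0.5
        rscu = compute_rscu(count_codons(["AAA" * 3 + "AAG"]))
        assert rscu.rscu["AAA"] == 1.5 and rscu.rscu["AAG"] == 0.5

    def test_empty_family_flagged_zero(self):
        rscu = compute_rscu(count_codons(["AAA"]))
        assert "G" in rscu.empty_families
        assert all(rscu.rscu[c] == 0.0 for c in FAMILIES["G"])

    def test_family_means_are_one(self):
        prof = _archetype_profile(1)
        for aa, fam in FAMILIES.items():
            if len(fam) < 2:
                continue
            assert np.mean([prof.rscu[c] for c in fam]) == pytest.approx(1.0)


class TestOrdination:
    def _two_group_profiles(self, n_per=4):
        return ([_archetype_profile(101, sample_seed=s) for s in range(n_per)]
                + [_archetype_profile(202, sample_seed=s) for s in range(n_per)])

    def test_variance_conservation_and_order(self):
        ordn = ordinate(self._two_group_profiles())
        assert ordn.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(ordn.explained_variance_pct) <= 1e-9).all()

    def test_component1_separates_archetypes(self):
        ordn = ordinate(self._two_group_profiles())
        pc1 = ordn.coords[:, 0]
        assert len({tuple(np.sign(pc1[:4])), tuple(np.sign(pc1[4:]))}) == 2
        # silhouette on the 1-d embedding is positive
        from sklearn.metrics import silhouette_score
        assert silhouette_score(pc1.reshape(-1, 1), [0] * 4 + [1] * 4) > 0

    def test_identical_profiles_degenerate(self):
        prof = _archetype_profile(7)
        ordn = ordinate([prof, prof, prof])
        assert ordn.degenerate
        assert np.allclose(ordn.coords, 0.0)

    def test_requires_three_profiles(self):
        prof = _archetype_profile(7)
        with pytest.raises(ValueError):
            ordinate([prof, prof])

    def test_deterministic_with_fixed_sign(self):
        profiles = self._two_group_profiles()
        a, b = ordinate(profiles), ordinate(profiles)
        assert np.array_equal(a.coords, b.coords)
        for j in range(2):
            lead = np.argmax(np.abs(a.loadings[:, j]))
            assert a.loadings[lead, j] > 0


class TestClustering:
    def test_two_units_single_merge(self):
        p1, p2 = _archetype_profile(1), _archetype_profile(2)
        Z, labels = cluster_units([p1, p2])
        d = np.linalg.norm(p1.vector() - p2.vector())
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(d)

    def test_duplicate_unit_merges_at_zero(self):
        p = _archetype_profile(1)
        Z, _ = cluster_units([p, p, _archetype_profile(2)])
        assert Z[0, 2] == pytest.approx(0.0)

    def test_first_bipartition_separates_archetypes(self):
        profiles = ([_archetype_profile(101, sample_seed=s) for s in range(3)]
                    + [_archetype_profile(202, sample_seed=s) for s in range(3)])
        Z, labels = cluster_units(profiles)
        from scipy.cluster.hierarchy import fcluster
        assign = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(assign[:3])) == 1 and len(set(assign[3:])) == 1
        assert assign[0] != assign[3]

    def test_newick_is_parseable_and_complete(self):
        profiles = [_archetype_profile(s) for s in (1, 2, 3, 4)]
        Z, labels = cluster_units(profiles)
        tree = Phylo.read(io.StringIO(dendrogram_newick(Z, labels)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)


class TestChromidCalls:
    def test_fixture_genome_recovers_labels(self, genome_bundle):
        genome, truth, _ = genome_bundle
        profiles = [replicon_rscu(r) for r in genome.replicons]
        calls = {c.replicon_id: c.call
                 for c in classify_chromids(profiles, genome.designated_chromosome)}
        assert calls == truth.chromid_labels

    def test_chromosome_called_chromosome(self):
        profiles = [_archetype_profile(s) for s in (1, 2, 3)]
        calls = classify_chromids(profiles, profiles[0].unit_id)
        assert calls[0].call == "chromosome"
        assert calls[0].distance_to_chromosome == 0.0

    def test_profile_equal_to_chromosome_is_chromid(self):
        p = _archetype_profile(1)
        import copy
        q = copy.deepcopy(p)
        q.unit_id = "twin"
        calls = classify_chromids([p, q], p.unit_id)
        assert calls[1].call == "chromid"

    def test_multi_genome_median_rule(self):
        # three related chromosomes + one alien plasmid: the plasmid exceeds
        # half the median inter-chromosome distance, a same-archetype chromid
        # does not
        base = make_archetype("host", 0.62, seed=5)
        from plasmidfusion.synthetic import make_related_archetype
        chroms = []
        for k in range(3):
            arch = make_related_archetype(base, f"c{k}", 0.62, seed=50 + k)
            rng = np.random.default_rng(k)
            idx = rng.choice(61, size=40_000, p=arch.codon_probs)
            from plasmidfusion.codon_usage import SENSE_CODONS
            seq = "".join(np.array(SENSE_CODONS)[idx])
            chroms.append(compute_rscu(count_codons([seq], unit_id=f"chr{k}")))
        chromid = _archetype_profile(50, gc=0.62)  # same seed as chr0 archetype
        chromid.unit_id = "ecr1"
        # rebuild chromid from chr0's archetype
        arch0 = make_related_archetype(base, "c0", 0.62, seed=50)
        rng = np.random.default_rng(99)
        idx = rng.choice(61, size=30_000, p=arch0.codon_probs)
        from plasmidfusion.codon_usage import SENSE_CODONS
        chromid = compute_rscu(count_codons(["".join(np.array(SENSE_CODONS)[idx])],
                                            unit_id="ecr1"))
        plasmid = _archetype_profile(777, gc=0.58)
        plasmid.unit_id = "pX"
        mapping = {"chr0": "chr0", "chr1": "chr1", "chr2": "chr2",
                   "ecr1": "chr0", "pX": "chr0"}
        calls = {c.replicon_id: c.call
                 for c in classify_chromids(chroms + [chromid, plasmid], mapping)}
        assert calls["ecr1"] == "chromid"
        assert calls["pX"] == "plasmid"


class TestSegmentRSCU:
    def test_whole_replicon_segment_equals_replicon_profile(self, small_composite):
        rep, _, _ = small_composite
        whole = replicon_rscu(rep)
        seg = segment_rscu(rep, [(1, rep.length)])[0]
        assert np.allclose(whole.vector(), seg.vector())

    def test_fusion_parts_differ_more_than_chromid_does(self, genome_bundle):
        genome, truth, _ = genome_bundle
        rep = genome["pSYN259"]
        segs = [(s["start"], s["end"]) for s in truth.segments
                if s.get("replicon") == "pSYN259"]
        part_r, part_z = segment_rscu(rep, segs)
        parts_dist = np.linalg.norm(part_r.vector() - part_z.vector())
        chrom = replicon_rscu(genome[genome.designated_chromosome])
        chromid = replicon_rscu(genome["pSYN593"])
        chromid_dist = np.linalg.norm(chrom.vector() - chromid.vector())
        assert parts_dist > chromid_dist

    def test_empty_segment_flagged(self, small_composite):
        rep, truth, _ = small_composite
        # a gene-free stretch: the gap right after a palindome doublet
        prof = segment_rscu(rep, [(5, 20)])[0]
        assert prof.empty_families
        assert np.allclose(prof.vector(), 0.0)
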
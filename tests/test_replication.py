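"""RepABC module detection, palindrome scanning and compatibility typing."""

import numpy as np
import pytest

from plasmidfusion.genome_io import GeneFeature, Replicon, reverse_complement
from plasmidfusion.replication import (DEFAULT_MOTIFS, MotifConfigError,
                                       PalindromeHit,
                                       discover_candidate_palindromes,
                                       find_doublets, find_repabc_modules,
                                       find_solitary_replicases,
                                       group_motifs_differ_at,
                                       palindrome_search_window,
                                       scan_palindromes, type_module,
                                       validate_motifs)


def _triplet_replicon(strands=("+", "+", "+"), gaps=(50, 400), length=20_000):
    feats = []
    start = 5000
    lens = (1200, 900, 1200)
    roles = ("repA", "repB", "repC")
    for k in range(3):
        feats.append(GeneFeature(f"g{k}", start, start + lens[k] - 1,
                                 strands[k], "CDS", "", roles[k]))
        start += lens[k] + (gaps[k] if k < 2 else 0)
    return Replicon("syn", "A" * length, "circular", feats)


class TestModuleDetection:
    def test_labelled_triplet_detected(self):
        rep = _triplet_replicon()
        mods = find_repabc_modules(rep)
        assert len(mods) == 1
        assert mods[0].locus_tags == ("g0", "g1", "g2")
        assert mods[0].strand == "+"

    def test_opposite_strand_repc_breaks_module(self):
        rep = _triplet_replicon(strands=("+", "+", "-"))
        assert find_repabc_modules(rep) == []

    def test_oversized_gap_breaks_module(self):
        rep = _triplet_replicon(gaps=(50, 2500))
        assert find_repabc_modules(rep) == []
        assert len(find_repabc_modules(rep, max_operon_gap=3000)) == 1

    def test_minus_strand_operon(self):
        # coordinate order repC, repB, repA on the minus strand
        feats = [
            GeneFeature("c", 5000, 6200, "-", "CDS", "", "repC"),
            GeneFeature("b", 6600, 7500, "-", "CDS", "", "repB"),
            GeneFeature("a", 7550, 8700, "-", "CDS", "", "repA"),
        ]
        rep = Replicon("syn", "A" * 20000, "circular", feats)
        mods = find_repabc_modules(rep)
        assert len(mods) == 1
        assert mods[0].strand == "-"
        assert mods[0].repA.locus_tag == "a"

    def test_product_regex_fallback(self):
        rep = _triplet_replicon()
        for f, prod in zip(rep.features, ["replication protein RepA (ParA family)",
                                          "replication protein RepB (ParB family)",
                                          "replicase RepC"]):
            f.role = None
            f.product = prod
        assert len(find_repabc_modules(rep)) == 1

    def test_genome_fixture_inventory(self, genome_bundle):
        genome, truth, _ = genome_bundle
        n_mod = sum(len(find_repabc_modules(r)) for r in genome.replicons)
        n_sol = sum(len(find_solitary_replicases(r)) for r in genome.replicons)
        assert n_mod == len(truth.operons) == 4
        assert n_sol == len(truth.solitary_repc) == 1


class TestSolitaryReplicases:
    def test_lone_repc_is_solitary(self):
        rep = Replicon("syn", "A" * 10000, "circular",
                       [GeneFeature("c", 4000, 5200, "+", "CDS", "", "repC")])
        assert [f.locus_tag for f in find_solitary_replicases(rep)] == ["c"]

    def test_module_repc_excluded(self):
        rep = _triplet_replicon()
        assert find_solitary_replicases(rep) == []


class TestSearchWindow:
    def test_pad_extends_both_sides(self):
        rep = _triplet_replicon(length=100_000)
        mod = find_repabc_modules(rep)[0]
        lo, hi = mod.span
        assert palindrome_search_window(mod, rep, pad=500) == (lo - 500, hi + 500)

    def test_pad_zero_is_span(self):
        rep = _triplet_replicon()
        mod = find_repabc_modules(rep)[0]
        assert palindrome_search_window(mod, rep, pad=0) == mod.span

    def test_window_wraps_through_origin(self):
        feats = [
            GeneFeature("a", 200, 1400, "+", "CDS", "", "repA"),
            GeneFeature("b", 1450, 2350, "+", "CDS", "", "repB"),
            GeneFeature("c", 2400, 3600, "+", "CDS", "", "repC"),
        ]
        rep = Replicon("syn", "A" * 50000, "circular", feats)
        mod = find_repabc_modules(rep)[0]
        start, end = palindrome_search_window(mod, rep, pad=500)
        assert (start, end) == (49700, 4100)

    def test_window_longer_than_replicon_errors(self):
        rep = _triplet_replicon(length=9000)
        mod = find_repabc_modules(rep)[0]
        with pytest.raises(ValueError, match="exceeds"):
            palindrome_search_window(mod, rep, pad=3000)


def brute_force_scan(seq, motifs, max_mismatch):
    """Independent oracle: all-windows Hamming comparison, char by char."""
    hits = []
    groups = list(motifs)
    k = len(next(iter(motifs.values())))
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        dists = [sum(a != b for a, b in zip(window, motifs[g])) for g in groups]
        d = min(dists)
        if d <= max_mismatch:
            hits.append((i + 1, groups[dists.index(d)], d))
    return hits


class TestScanPalindromes:
    @pytest.mark.parametrize("motif,group", [("TTAACAGCTGTTAA", "group-1"),
                                             ("TTCACAGCTGTGAA", "group-2")])
    def test_planted_motif_found(self, motif, group):
        seq = "AT" * 30 + motif + "GC" * 30
        hits = [(h.position, h.group, h.mismatches) for h in scan_palindromes(seq)]
        assert hits == [(61, group, 0)]

    @pytest.mark.parametrize("mm", [0, 1])
    def test_equals_brute_force_oracle(self, mm):
        rng = np.random.default_rng(42)
        motifs = list(DEFAULT_MOTIFS.values())
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            if rng.random() < 0.5:  # plant a motif, sometimes mutated
                m = list(motifs[rng.integers(2)])
                if rng.random() < 0.5:
                    m[rng.integers(14)] = "ACGT"[rng.integers(4)]
                pos = rng.integers(0, len(seq) - 14)
                seq = seq[:pos] + "".join(m) + seq[pos + 14 :]
            got = [(h.position, h.group, h.mismatches)
                   for h in scan_palindromes(seq, max_mismatch=mm)]
            assert got == brute_force_scan(seq, DEFAULT_MOTIFS, mm)

    def test_strand_symmetry_of_motifs(self):
        # both stated motifs are their own reverse complement, so scanning
        # the reverse complement of a window gives the same doublet count
        for motif in DEFAULT_MOTIFS.values():
            assert reverse_complement(motif) == motif
        seq = "AT" * 20 + "TTAACAGCTGTTAA" + "C" * 20 + "TTAACAGCTGTTAA" + "AT" * 20
        fwd = find_doublets(scan_palindromes(seq))
        rev = find_doublets(scan_palindromes(reverse_complement(seq)))
        assert len(fwd) == len(rev) == 1

    def test_invalid_motif_config(self):
        with pytest.raises(MotifConfigError):
            validate_motifs({"bad": "TTAACAGTTAACAG"})

    def test_group_motifs_differ_at_positions_3_and_12(self):
        assert group_motifs_differ_at(DEFAULT_MOTIFS) == [3, 12]


class TestDoublets:
    def _hits(self, positions, group="group-1"):
        return [PalindromeHit(p, "TTAACAGCTGTTAA", 0, group) for p in positions]

    @pytest.mark.parametrize("spacer,n", [(11, 1), (20, 1), (42, 1), (10, 0), (50, 0)])
    def test_spacer_bounds(self, spacer, n):
        hits = self._hits([1, 1 + 14 + spacer])
        assert len(find_doublets(hits)) == n

    def test_greedy_pairing_three_hits(self):
        # spacers 15, 15: greedy pairs the first two, third stays unpaired —
        # matches exhaustive enumeration of non-overlapping pairings
        hits = self._hits([1, 30, 59])
        doublets = find_doublets(hits)
        assert len(doublets) == 1
        assert (doublets[0].first.position, doublets[0].second.position) == (1, 30)

    def test_mixed_groups_do_not_pair(self):
        hits = self._hits([1]) + self._hits([35], group="group-2")
        assert find_doublets(hits) == []


class TestDiscovery:
    def test_known_palindrome(self):
        assert [h.position for h in discover_candidate_palindromes("TTAACAGCTGTTAA")] == [1]

    def test_homopolymer_is_not_palindromic(self):
        assert discover_candidate_palindromes("A" * 14) == []

    def test_brute_force_windows(self):
        seq = "ACGCGCGCGCGCGT"
        got = {h.position for h in discover_candidate_palindromes(seq)}
        expect = {
            i + 1 for i in range(len(seq) - 13)
            if seq[i + 7 : i + 14] == reverse_complement(seq[i : i + 7])
        }
        assert got == expect


class TestTypeModule:
    def test_generator_truth_groups(self, small_composite):
        rep, truth, _ = small_composite
        mods = find_repabc_modules(rep)
        labels = sorted(type_module(m, rep).compat_label for m in mods)
        assert labels == sorted(o["group"] for o in truth.operons)

    def test_doublet_recovery_and_spacer(self, small_composite):
        rep, truth, _ = small_composite
        mods = {m.span[0]: type_module(m, rep) for m in find_repabc_modules(rep)}
        for op in truth.operons:
            mod = mods[op["span"][0]]
            assert mod.doublet is not None
            assert mod.doublet.spacer == op["palindromes"]["spacer"]
            # window-relative position maps back to the planted coordinate
            assert mod.window[0] + mod.doublet.first.position - 1 == \
                op["palindromes"]["first"]

    def test_no_palindrome_means_untyped(self):
        rep = _triplet_replicon(length=30_000)
        assert type_module(find_repabc_modules(rep)[0], rep).compat_label == "untyped"
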
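"""k-of-n consensus rule, clustering and peptide design."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_single_linkage
from ppikit import synthetic_data as sd
from ppikit.interface_geometry import OccupancyTable
from ppikit.replica_consensus import (ConsensusConfig, consensus_pairs,
                                      design_peptides, interface_clusters,
                                      pool_alternative_partners)

RES_A = ("A", 115, "ASP")
RES_B = ("B", 940, "LYS")


def occ_table(patterns: dict[tuple, list[float]], n=4) -> OccupancyTable:
    return OccupancyTable({k: np.asarray(v, float)
                           for k, v in patterns.items()},
                          frames_analyzed=[50] * n, n_replicas=n)


def one_pair_table(occs) -> OccupancyTable:
    return occ_table({("saltbridge", RES_A, RES_B): list(occs)})


class TestConsensusRule:
    def test_exhaustive_three_of_four_truth_table(self):
        cfg = ConsensusConfig(4, 3, 0.10)
        for pattern in itertools.product([0.0, 0.5], repeat=4):
            tbl = consensus_pairs(one_pair_table(pattern), cfg)
            kept = tbl.rows[0].kept
            assert kept == (sum(p >= 0.10 for p in pattern) >= 3), pattern

    @pytest.mark.parametrize("present,kept", [
        ((1, 1, 1, 0), True),   # three of four
        ((1, 0, 0, 1), False),  # two of four
        ((1, 1, 1, 1), True),
        ((0, 0, 0, 0), False),
    ])
    def test_named_patterns(self, present, kept):
        occs = [0.6 if p else 0.0 for p in present]
        tbl = consensus_pairs(one_pair_table(occs), ConsensusConfig())
        assert tbl.rows[0].kept is kept

    def test_presence_threshold_applied_per_replica(self):
        tbl = consensus_pairs(one_pair_table([0.09, 0.10, 0.5, 1.0]),
                              ConsensusConfig())
        assert tbl.rows[0].present == (False, True, True, True)
        assert tbl.rows[0].kept

    def test_empty_table(self):
        tbl = consensus_pairs(occ_table({}), ConsensusConfig())
        assert tbl.rows == []
        assert tbl.kept_pairs() == set()

    def test_too_few_replicas_is_config_error(self):
        occ = OccupancyTable({("contact", RES_A, RES_B): np.array([1.0])},
                             [50], 1)
        with pytest.raises(ValueError, match="replicas"):
            consensus_pairs(occ, ConsensusConfig(n_replicas=4))

    def test_k_equals_one_is_union_k_equals_n_is_intersection(self):
        patterns = {
            ("contact", RES_A, ("B", 900 + i, "GLY")): occs
            for i, occs in enumerate([[0.5, 0, 0, 0], [0.5, 0.5, 0.5, 0.5],
                                      [0, 0.5, 0.5, 0], [0, 0, 0, 0]])
        }
        occ = occ_table(patterns)
        union = consensus_pairs(occ, ConsensusConfig(4, 1)).kept_pairs()
        inter = consensus_pairs(occ, ConsensusConfig(4, 4)).kept_pairs()
        assert len(union) == 3
        assert len(inter) == 1

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(occs=st.lists(st.floats(0, 1), min_size=4, max_size=4),
           k1=st.integers(1, 4), k2=st.integers(1, 4),
           t1=st.floats(0.01, 1.0), t2=st.floats(0.01, 1.0))
    def test_monotone_in_both_thresholds(self, occs, k1, k2, t1, t2):
        lo_k, hi_k = sorted((k1, k2))
        lo_t, hi_t = sorted((t1, t2))
        occ = one_pair_table(occs)
        for lo_cfg, hi_cfg in [
            (ConsensusConfig(4, lo_k, lo_t), ConsensusConfig(4, hi_k, lo_t)),
            (ConsensusConfig(4, lo_k, lo_t), ConsensusConfig(4, lo_k, hi_t)),
        ]:
            kept_lo = consensus_pairs(occ, lo_cfg).kept_pairs()
            kept_hi = consensus_pairs(occ, hi_cfg).kept_pairs()
            assert kept_hi <= kept_lo


class TestAlternativePartnerPooling:
    def test_nearby_lysines_pool_and_survive_consensus(self, default_complex):
        # Asp bridging K940 in two runs and K943 in two other runs: each
        # alone fails 3-of-4, pooled they pass
        structure, _ = default_complex
        k940 = ("B", 940, "LYS")
        k943 = ("B", 943, "LYS")
        occ = occ_table({("saltbridge", RES_A, k940): [0.8, 0.8, 0, 0],
                         ("saltbridge", RES_A, k943): [0, 0, 0.8, 0.8]})
        pooled = pool_alternative_partners(occ, structure)
        assert len(pooled.occupancy) == 1
        (key, vals), = pooled.occupancy.items()
        assert "940" in key[2][2] and "943" in key[2][2]
        tbl = consensus_pairs(pooled, ConsensusConfig())
        assert tbl.rows[0].kept
        unpooled = consensus_pairs(occ, ConsensusConfig())
        assert not any(r.kept for r in unpooled.rows)

    def test_distant_partners_not_pooled(self, default_complex):
        structure, _ = default_complex
        far = ("B", 883, "GLU")  # far from LYS 940 in space and sequence
        occ = occ_table({("saltbridge", RES_A, ("B", 940, "LYS")):
                         [0.8, 0.8, 0, 0],
                         ("saltbridge", RES_A, far): [0, 0, 0.8, 0.8]})
        pooled = pool_alternative_partners(occ, structure)
        assert len(pooled.occupancy) == 2


class TestClusters:
    def make_table(self, resids, structure):
        occ = occ_table({("contact", RES_A, ("B", r, "GLY")):
                         [0.5, 0.5, 0.5, 0.5] for r in resids})
        return consensus_pairs(occ, ConsensusConfig())

    def test_sequence_gap_linkage(self, default_complex):
        structure, _ = default_complex
        tbl = self.make_table([903, 904, 907, 911], structure)
        clusters = interface_clusters(tbl, structure, linkage_gap=4,
                                      spatial_cutoff=0.1)
        assert clusters == [[903, 904, 907, 911]]

    def test_far_apart_residues_split(self, default_complex):
        structure, _ = default_complex
        tbl = self.make_table([883, 940], structure)
        clusters = interface_clusters(tbl, structure, linkage_gap=4,
                                      spatial_cutoff=8.0)
        assert clusters == [[883], [940]]

    def test_matches_brute_force_single_linkage(self, default_complex):
        structure, _ = default_complex
        rng = np.random.default_rng(14)
        for _ in range(10):
            resids = sorted(rng.choice(np.arange(877, 948), size=8,
                                       replace=False).tolist())
            tbl = self.make_table(resids, structure)
            got = interface_clusters(tbl, structure, linkage_gap=4,
                                     spatial_cutoff=0.1)
            expect = brute_single_linkage(
                resids, lambda a, b: abs(a - b) <= 4)
            assert got == expect


class TestPeptideDesign:
    def test_two_peptide_split_for_distant_anchors(self, default_complex):
        structure, _ = default_complex
        designs = design_peptides([883, 940, 943], structure, "B",
                                  flank=4, max_len=20)
        assert len(designs) == 2
        first = [d for d in designs if 883 in d.anchors]
        second = [d for d in designs if 940 in d.anchors]
        assert len(first) == 1 and len(second) == 1
        assert set(second[0].anchors) == {940, 943}
        for d in designs:
            assert d.end_resid - d.start_resid + 1 <= 20
            assert all(d.start_resid <= a <= d.end_resid for a in d.anchors)

    def test_nearby_anchors_share_one_peptide(self, default_complex):
        structure, _ = default_complex
        designs = design_peptides([940, 943], structure, "B",
                                  flank=4, max_len=20)
        assert len(designs) == 1
        assert designs[0].anchors == (940, 943)

    def test_forced_split_when_span_exceeds_max_len(self, default_complex):
        structure, _ = default_complex
        designs = design_peptides([885, 945], structure, "B",
                                  flank=4, max_len=20)
        assert len(designs) == 2

    def test_sequence_extracted_from_topology(self, default_complex):
        structure, _ = default_complex
        designs = design_peptides([940, 943], structure, "B", flank=2,
                                  max_len=20)
        seq = designs[0].sequence
        # residues 938-945: glycine except the planted lysines 940/943
        assert seq == "GGKGGKGG"

    def test_flank_clipped_at_termini(self, default_complex):
        structure, _ = default_complex
        d = design_peptides([877], structure, "B", flank=6, max_len=20)[0]
        assert d.start_resid == 876  # chain start

    def test_missing_anchor_raises(self, default_complex):
        structure, _ = default_complex
        with pytest.raises(ValueError, match="absent"):
            design_peptides([700], structure, "B")
        with pytest.raises(ValueError, match="max_len"):
            design_peptides([883], structure, "B", flank=10, max_len=20)
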
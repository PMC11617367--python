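"""Evidence merging, tiers, group-specific selection, coverage reports."""

import pytest

from dualprot.assembly import Contig
from dualprot.config import PipelineConfig
from dualprot.errors import FormatError
from dualprot.evidence import (assign_tier, coverage_augmentation,
                               coverage_percent, filter_min_samples,
                               merge_evidence, select_group_specific,
                               strategy_overlap, summarize_length_bins)
from dualprot.io import PeptideHit, ReferenceProtein
from dualprot.matching import ContigClass, map_contig
from dualprot.pipeline import map_contigs


class TestCoveragePercent:
    @pytest.mark.parametrize("covered,length,pct", [
        (565, 609, 93),   # albumin row
        (34, 106, 32),    # IGLC7 row
        (555, 698, 80),   # serotransferrin row
        (0, 500, 0),
    ])
    def test_published_cells(self, covered, length, pct):
        assert coverage_percent(covered, length) == pct

    def test_rounding_is_half_up(self):
        assert coverage_percent(5, 1000) == 1   # 0.5 -> 1
        assert coverage_percent(4, 1000) == 0   # 0.4 -> 0


class TestTiers:
    def test_published_concentrations(self, config):
        assert assign_tier(5e-5, config) == "mid"     # SAA2, 50 μg/L
        assert assign_tier(1.1e-8, config) == "low"   # Ephrin-B3, 11 ng/L

    def test_boundaries_assigned_to_mid(self, config):
        assert assign_tier(1e-3, config) == "mid"   # exactly 1 μg/mL
        assert assign_tier(1e-5, config) == "mid"   # exactly 10 ng/mL
        assert assign_tier(1.0001e-3, config) == "high"
        assert assign_tier(0.9999e-5, config) == "low"

    def test_missing_and_negative(self, config):
        assert assign_tier(None, config) == "unknown"
        with pytest.raises(ValueError):
            assign_tier(-1.0, config)

    def test_monotone_in_concentration(self, config):
        order = {"low": 0, "mid": 1, "high": 2}
        concs = [1e-8, 5e-6, 1e-5, 5e-4, 1e-3, 5e-2]
        tiers = [order[assign_tier(c, config)] for c in concs]
        assert tiers == sorted(tiers)


def _hit(sample, group, seq, acc):
    return PeptideHit(sample, group, seq, (acc,))


class TestMergeEvidence:
    def test_library_coverage_fraction(self, config):
        prot = ReferenceProtein("P1", "G" * 10 + "WPEPTIDEKW" + "A" * 80)
        hits = [_hit("SZ001", "case", "WPEPTIDEKW", "P1")]
        (ev,) = merge_evidence(hits, [], [prot], config)
        assert len(ev.covered_library) == 10
        assert coverage_percent(ev.covered_library, prot.length_aa) == 10
        assert ev.strategies == {"library"}
        assert (ev.samples_case, ev.samples_control) == (1, 0)

    def test_both_strategies_recorded(self, config, toy_db):
        prot = toy_db[2]
        pep = prot.sequence[40:60]
        contig = Contig(prot.sequence[100:130], 3, 0.9, "SZ001")
        contig_hits = map_contigs([contig], toy_db, config)
        (ev,) = merge_evidence([_hit("SZ001", "case", pep, prot.accession)],
                               contig_hits, toy_db, config)
        assert ev.strategies == {"library", "denovo"}
        assert ev.covered_denovo == set(range(100, 130))

    def test_noncanonical_coverage_is_matched_columns_only(self, config,
                                                           toy_db):
        prot = toy_db[4]
        window = list(prot.sequence[200:230])
        window[10] = "W" if window[10] != "W" else "H"
        aln, cls = map_contig("".join(window), toy_db)
        assert cls is ContigClass.NONCANONICAL_VARIANT
        contig = Contig("".join(window), 1, 0.9, "SZ001")
        (ev,) = merge_evidence([], [(contig, aln, cls)], toy_db, config,
                               sample_groups={"SZ001": "case"})
        assert ev.covered_noncanonical == set(range(200, 230)) - {210}

    def test_unknown_accession_rejected(self, config, toy_db):
        with pytest.raises(FormatError, match="NOPE"):
            merge_evidence([_hit("SZ001", "case", "PEPTIDEK", "NOPE")],
                           [], toy_db, config)

    def test_sample_counts_split_by_group(self, config):
        prot = ReferenceProtein("P1", "GGWPEPTIDEKWGG" + "A" * 40)
        hits = [_hit(s, g, "WPEPTIDEKW", "P1") for s, g in
                [("SZ1", "case"), ("SZ2", "case"), ("SZ1", "case"),
                 ("CNT1", "control")]]
        (ev,) = merge_evidence(hits, [], [prot], config)
        assert (ev.samples_case, ev.samples_control) == (2, 1)


class TestGroupSpecific:
    def _evidence(self, config, sz, cnt, ptp=2):
        prot = ReferenceProtein("P1", "GGWPEPTIDEKWGG" + "A" * 40)
        hits = ([_hit(f"SZ{i}", "case", "WPEPTIDEKW", "P1")
                 for i in range(sz)]
                + [_hit(f"CNT{i}", "control", "WPEPTIDEKW", "P1")
                   for i in range(cnt)])
        ev = merge_evidence(hits, [], [prot], config)
        return ev

    def test_weakest_published_pattern_selected(self, config):
        # the Sz=9, Cnt=1 row shape
        ev = self._evidence(config, sz=9, cnt=1)
        assert select_group_specific(ev, config) == ["P1"]

    def test_control_threshold_edge(self, config):
        assert select_group_specific(self._evidence(config, 9, 6),
                                     config) == []
        assert select_group_specific(self._evidence(config, 8, 1),
                                     config) == []
        assert select_group_specific(self._evidence(config, 9, 5),
                                     config) == ["P1"]


class TestOverlapAndReports:
    def test_degenerate_overlaps(self, config):
        prot = ReferenceProtein("P1", "GGWPEPTIDEKWGG" + "A" * 40)
        ev = merge_evidence([_hit("SZ1", "case", "WPEPTIDEKW", "P1")],
                            [], [prot], config)
        counts = strategy_overlap(ev)["proteins"]
        assert counts == {"library_only": 1, "denovo_only": 0, "both": 0}

    def test_overlap_counts_partition_proteins(self, config, toy_db):
        hits = [_hit("SZ1", "case", toy_db[0].sequence[5:20],
                     toy_db[0].accession)]
        contig = Contig(toy_db[1].sequence[10:40], 1, 0.9, "SZ1")
        contig_hits = map_contigs([contig], toy_db, config)
        ev = merge_evidence(hits, contig_hits, toy_db, config)
        counts = strategy_overlap(ev)["proteins"]
        assert sum(counts.values()) == len(ev)
        assert counts == {"library_only": 1, "denovo_only": 1, "both": 0}

    def test_length_bins_single_protein(self, config, toy_db):
        prot = toy_db[4]  # 500 aa
        pep = prot.sequence[10:30]
        contig = Contig(prot.sequence[50:80], 1, 0.9, "SZ1")
        ev = merge_evidence([_hit("SZ1", "case", pep, prot.accession)],
                            map_contigs([contig], toy_db, config),
                            toy_db, config)
        bins = summarize_length_bins(ev, toy_db)
        assert bins["hist"]["library"] == [0, 1, 0]
        assert bins["hist"]["denovo"] == [0, 1, 0]

    def test_empty_evidence_zero_histogram(self, toy_db):
        bins = summarize_length_bins([], toy_db)
        assert bins["hist"] == {"library": [0, 0, 0], "denovo": [0, 0, 0]}

    def test_min_samples_filter_pooled_vs_per_group(self, config):
        prot = ReferenceProtein("P1", "GGWPEPTIDEKWGG" + "A" * 40)
        hits = ([_hit(f"SZ{i}", "case", "WPEPTIDEKW", "P1")
                 for i in range(9)]
                + [_hit("CNT0", "control", "WPEPTIDEKW", "P1")])
        ev = merge_evidence(hits, [], [prot], config)
        assert len(filter_min_samples(ev, config)) == 1          # 10 pooled
        assert filter_min_samples(ev, config, per_group=True) == []


class TestCoverageAugmentation:
    def _make(self, config, toy_db, nc_range, lib_range):
        prot = toy_db[5]  # 650 aa
        hits = [_hit("SZ1", "case", prot.sequence[slice(*lib_range)],
                     prot.accession)]
        window = list(prot.sequence[slice(*nc_range)])
        window[10] = "W" if window[10] != "W" else "H"
        window[15] = "W" if window[15] != "W" else "H"
        aln, cls = map_contig("".join(window), toy_db)
        assert cls is ContigClass.NONCANONICAL_VARIANT
        contig = Contig("".join(window), 1, 0.9, "SZ1")
        return merge_evidence(hits, [(contig, aln, cls)], toy_db, config)

    def test_nested_noncanonical_adds_nothing(self, config, toy_db):
        ev = self._make(config, toy_db, nc_range=(100, 130),
                        lib_range=(95, 140))
        row = coverage_augmentation(ev, toy_db).iloc[0]
        assert row["additional_aa"] == 0

    def test_disjoint_noncanonical_footprint(self, config, toy_db):
        ev = self._make(config, toy_db, nc_range=(300, 330),
                        lib_range=(10, 40))
        row = coverage_augmentation(ev, toy_db).iloc[0]
        assert row["additional_aa"] == 28  # 30 aa minus 2 mismatches
        assert row["additional_pct"] == coverage_percent(28, 650)

    def test_union_coverage_dominates_single_strategy(self, config, toy_db):
        ev = self._make(config, toy_db, nc_range=(200, 230),
                        lib_range=(10, 60))
        for e in ev:
            union = e.covered_library | e.covered_denovo
            assert len(union) >= len(e.covered_library)
            assert len(union) >= len(e.covered_denovo)
            assert len(union) <= e.length_aa
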
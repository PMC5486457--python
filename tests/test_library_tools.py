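"""Pairwise similarity, 80-80 clustering, ORF finding, intactness screening."""

import numpy as np
import pytest

from oracles import brute_force_single_linkage, dp_local_similarity, revcomp
from telandscape.library_tools import (
    cluster_80_80,
    find_orfs,
    pair_similarity,
    screen_erv,
    screen_line,
    summarize_screen,
)
from telandscape import synthetic_data as sd


class TestPairSimilarity:
    def test_identical_sequences(self):
        seq = sd.random_dna(300, 1)
        sim = pair_similarity(seq, seq)
        assert sim.identity == 1.0 and sim.coverage == 1.0

    def test_containment_covers_shorter(self):
        seq = sd.random_dna(400, 2)
        sim = pair_similarity(seq, seq[:200])
        assert sim.identity == 1.0 and sim.coverage == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        a = sd.random_dna(250, rng)
        b = sd.mutate_jc(a, 15.0, rng)
        assert pair_similarity(a, b) == pair_similarity(b, a)

    def test_reverse_complement_invariant(self):
        rng = np.random.default_rng(4)
        a = sd.random_dna(250, rng)
        b = sd.mutate_jc(a, 10.0, rng)
        sim_f = pair_similarity(a, b)
        sim_r = pair_similarity(a, revcomp(b))
        assert sim_f.identity == pytest.approx(sim_r.identity)
        assert sim_f.coverage == pytest.approx(sim_r.coverage)
        assert sim_f.score == sim_r.score

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            pair_similarity("ACGT", "ACXT")

    def test_agrees_with_dp_oracle(self):
        """Identity/coverage match an independent full-matrix Gotoh DP."""
        rng = np.random.default_rng(7)
        for trial in range(12):
            L = int(rng.integers(100, 1000))
            a = sd.random_dna(L, rng)
            kind = trial % 3
            if kind == 0:
                b = sd.random_dna(int(rng.integers(100, 1000)), rng)
            elif kind == 1:
                b = sd.mutate_jc(a, float(rng.uniform(2, 30)), rng)
            else:
                start = int(rng.integers(0, L // 2))
                b = sd.mutate_jc(a[start : start + L // 2 + 20], 8.0, rng)
            imp = pair_similarity(a, b)
            ora = dp_local_similarity(a, b)
            assert imp.score == ora.score
            assert imp.identity == pytest.approx(ora.identity, abs=0.02)
            assert imp.coverage == pytest.approx(ora.coverage_shorter, abs=0.02)


class TestCluster8080:
    def test_identical_pair_merges(self):
        seq = sd.random_dna(300, 9)
        clustering = cluster_80_80({"a": seq, "b": seq})
        assert clustering.as_sets() == {frozenset({"a", "b"})}

    def test_seventy_percent_pair_stays_split(self):
        a, b = sd.make_diverged_pair(600, 0.70, 10)
        assert dp_local_similarity(a, b).identity < 0.80  # constructed probe
        clustering = cluster_80_80({"a": a, "b": b})
        assert clustering.as_sets() == {frozenset({"a"}), frozenset({"b"})}

    def test_fragment_absorbed_into_family(self):
        rng = np.random.default_rng(12)
        founder = sd.random_dna(800, rng)
        frag = sd.mutate_jc(founder[100:500], 5.0, rng)
        clustering = cluster_80_80({"full": founder, "frag": frag})
        assert clustering.as_sets() == {frozenset({"full", "frag"})}
        assert clustering.representatives == ["full"]  # longest member

    def test_representative_tie_lexicographic(self):
        seq = sd.random_dna(200, 13)
        clustering = cluster_80_80({"zeta": seq, "alpha": seq})
        assert clustering.representatives == ["alpha"]

    def test_partition_and_order_invariance(self):
        lib = sd.simulate_library(
            [
                sd.FamilySpec("famA", 500, n_members=3, n_fragments=1),
                sd.FamilySpec("famB", 350, n_members=2),
                sd.FamilySpec("famC", 700, n_members=1),
            ],
            seed=14,
        )
        clustering = cluster_80_80(lib.library)
        members = sorted(m for f in clustering.families for m in f.members)
        assert members == sorted(lib.library)  # partition
        reordered = dict(sorted(lib.library.items(), reverse=True))
        assert cluster_80_80(reordered).as_sets() == clustering.as_sets()

    def test_reverse_complement_member_still_merges(self):
        rng = np.random.default_rng(15)
        founder = sd.random_dna(400, rng)
        member = revcomp(sd.mutate_jc(founder, 5.0, rng))
        clustering = cluster_80_80({"fwd": founder, "rc": member})
        assert clustering.as_sets() == {frozenset({"fwd", "rc"})}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(16)
        for trial in range(3):
            lib = sd.simulate_library(
                [
                    sd.FamilySpec(f"f{trial}a", 300, n_members=3, n_fragments=1),
                    sd.FamilySpec(f"f{trial}b", 200, n_members=2),
                    sd.FamilySpec(f"f{trial}c", 400, n_members=2, n_fragments=1),
                ],
                seed=rng,
            )
            assert cluster_80_80(lib.library).as_sets() == brute_force_single_linkage(
                lib.library
            )

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            cluster_80_80({})


class TestFindOrfs:
    def test_constructed_orf_length(self):
        rng = np.random.default_rng(17)
        protein = "M" + "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=600)
        )
        nt = "".join(
            {"M": "ATG"}.get(aa) or sd._CODON[aa] for aa in protein
        ) + "TAA"
        orfs = find_orfs(nt)
        assert orfs[0].length_aa == 601
        assert orfs[0].strand == "+"
        assert orfs[0].start == 1 and orfs[0].end == len(nt)

    def test_only_stops_is_empty(self):
        assert find_orfs("TAATAATAGTGA") == []

    def test_reverse_complement_flips_strand(self):
        line_specs, _ = sd.default_screen_plan()
        element = sd.simulate_elements([line_specs[0]], seed=18).elements[
            line_specs[0].name
        ]
        fwd = find_orfs(element, min_length_aa=50)
        rev = find_orfs(revcomp(element), min_length_aa=50)
        flip = {"+": "-", "-": "+"}
        assert sorted((o.length_aa, flip[o.strand]) for o in fwd) == sorted(
            (o.length_aa, o.strand) for o in rev
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("AC")

    def test_stop_to_stop_mode_drops_atg_requirement(self):
        nt = "TAA" + "GCT" * 50 + "TAA"  # no ATG anywhere
        assert find_orfs(nt) == []
        orfs = find_orfs(nt, require_atg=False)
        assert orfs and orfs[0].length_aa == 50


class TestScreenLine:
    def test_planted_full_line(self, screen_fixture):
        result = screen_line(
            screen_fixture.elements["line_full_1"],
            screen_fixture.rt_refs,
            element_id="line_full_1",
        )
        assert result.category == "full_LINE"
        assert result.has_ORF1 and result.has_intact_RT
        assert result.orf2_length_aa == 680

    def test_orf2_600_boundary_not_full(self, screen_fixture):
        result = screen_line(
            screen_fixture.elements["line_orf2_600"], screen_fixture.rt_refs
        )
        assert result.orf2_length_aa == 600
        assert result.category == "ORF1_only"
        result601 = screen_line(
            screen_fixture.elements["line_orf2_601"], screen_fixture.rt_refs
        )
        assert result601.category == "full_LINE"

    def test_no_orfs_is_defective(self, screen_fixture):
        result = screen_line(
            screen_fixture.elements["line_def_1"], screen_fixture.rt_refs
        )
        assert result.category == "defective"
        assert result.orf2_length_aa == 0

    def test_long_orfs_without_rt_are_defective(self, screen_fixture):
        result = screen_line(
            screen_fixture.elements["line_norf_rt"], screen_fixture.rt_refs
        )
        assert result.category == "defective"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            screen_line("ATGGCTTAA", {})

    def test_extending_orf2_never_demotes(self):
        """Monotonicity of the ladder in the planted ORF2 length."""
        ladder = ["defective", "intact_RT_only", "ORF1_only", "ORF2_only",
                  "full_LINE"]
        ranks = []
        for orf2_aa in (400, 601, 700):
            spec = sd.LineElementSpec("el", orf1_aa=300, orf2_aa=orf2_aa)
            fix = sd.simulate_elements([spec], seed=19)
            result = screen_line(fix.elements["el"], fix.rt_refs)
            ranks.append(ladder.index(result.category))
        assert ranks == sorted(ranks)


class TestScreenErv:
    def test_planted_full_erv(self, screen_fixture):
        result = screen_erv(
            screen_fixture.elements["erv_full_1"], screen_fixture.erv_refs
        )
        assert result.category == "full_ERV"
        assert set(result.erv_domains) == {"ENV", "GAG", "POL"}
        assert result.erv_domains == {"ENV": 500, "GAG": 520, "POL": 850}

    def test_pol_only_is_partial(self, screen_fixture):
        result = screen_erv(
            screen_fixture.elements["erv_pol_1"], screen_fixture.erv_refs
        )
        assert result.category == "partial_ERV"
        assert set(result.erv_domains) == {"POL"}

    def test_pol_800_boundary_absent(self, screen_fixture):
        result = screen_erv(
            screen_fixture.elements["erv_pol_800"], screen_fixture.erv_refs
        )
        assert result.category == "defective"
        result801 = screen_erv(
            screen_fixture.elements["erv_pol_801"], screen_fixture.erv_refs
        )
        assert result801.category == "partial_ERV"

    def test_unlabeled_reference_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            screen_erv("ATGGCTTAA", {"mystery_protein": "MA" * 50})


class TestSummarize:
    def test_empty_input_all_zero(self):
        table = summarize_screen([], mode="line")
        assert int(table.to_numpy().sum()) == 0

    def test_counts_match_planted_truth(self, screen_fixture):
        results = []
        for name, seq in screen_fixture.elements.items():
            if name.startswith("line"):
                results.append(
                    screen_line(seq, screen_fixture.rt_refs, element_id=name,
                                clade=screen_fixture.clade_of[name])
                )
        table = summarize_screen(results, mode="line")
        planted = {}
        for name, category in screen_fixture.category_of.items():
            if not name.startswith("line"):
                continue
            clade = screen_fixture.clade_of[name] or "all"
            planted[(clade, category)] = planted.get((clade, category), 0) + 1
        for (clade, category), count in planted.items():
            assert table.loc[clade, category] == count
        assert int(table["total"].sum()) == sum(planted.values())
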
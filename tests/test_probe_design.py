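"""Probe design: cleavage-site finding, arm construction, controls, screening."""

import numpy as np
import pytest

from nanoladder import (
    CircularDNAzymeProbe,
    ProbeDesignConfig,
    ProbeDesignError,
    TargetTranscript,
    design_circular_dnazyme,
    emit_padlock_linker,
    find_cleavage_sites,
    make_control_variant,
    rank_cleavage_sites,
    screen_specificity,
)
from nanoladder.probe_design import (
    PURINES,
    PYRIMIDINES,
    _kmers,
    orthogonal_sequences,
    rna_window_to_arm,
)

from conftest import random_rna


def brute_force_sites(seq, arm_len):
    """Independent nested scan over all adjacent pairs."""
    out = []
    for i in range(len(seq) - 1):
        if seq[i] in "AG" and seq[i + 1] in "UC":
            out.append((i, seq[i : i + 2], i + 1 >= arm_len and len(seq) - i - 1 >= arm_len))
    return out


def design_for(seq_rng, arm_len=20, length=200, seed=0):
    t = TargetTranscript("t", random_rna(seq_rng, length))
    sites = [s for s in find_cleavage_sites(t, arm_len) if s.flank_ok]
    cfg = ProbeDesignConfig(arm_len=arm_len, seed=seed)
    return t, design_circular_dnazyme(t, sites[0], cfg), cfg


class TestCleavageSites:
    def test_pyrimidine_only_sequence_has_no_sites(self):
        t = TargetTranscript("py", "UUUUCCCCUUCCUCUCUCCC")
        assert find_cleavage_sites(t, 1) == []

    def test_matches_brute_force_scan(self, rng):
        for _ in range(25):
            seq = random_rna(rng, 200)
            t = TargetTranscript("r", seq)
            got = [(s.position, s.dinucleotide, s.flank_ok) for s in find_cleavage_sites(t, 20)]
            assert got == brute_force_sites(seq, 20)

    def test_single_forced_gu_site_with_flanks(self):
        seq = "A" * 20 + "GU" + "A" * 20  # only R-Y junction is the GU
        t = TargetTranscript("one", seq)
        sites = [s for s in find_cleavage_sites(t, 20) if s.dinucleotide in ("GU",)]
        assert len(sites) == 1
        assert sites[0].position == 20 and sites[0].flank_ok

    def test_every_site_satisfies_purine_pyrimidine_rule(self, rng):
        for _ in range(10):
            t = TargetTranscript("r", random_rna(rng, 300))
            for s in find_cleavage_sites(t, 10):
                assert s.dinucleotide[0] in PURINES and s.dinucleotide[1] in PYRIMIDINES

    def test_sites_sorted_and_ranked_by_preference(self, rng):
        t = TargetTranscript("r", random_rna(rng, 300))
        sites = find_cleavage_sites(t, 20)
        assert [s.position for s in sites] == sorted(s.position for s in sites)
        ranked = rank_cleavage_sites(sites)
        usable = [s for s in ranked if s.flank_ok]
        prefs = ("AU", "GU", "AC", "GC")
        order = [prefs.index(s.dinucleotide) for s in usable]
        assert order == sorted(order)

    def test_t_converted_to_u_with_warning(self):
        with pytest.warns(UserWarning, match="T->U"):
            t = TargetTranscript("dna", "ACGTACGT")
        assert t.sequence == "ACGUACGU"

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            TargetTranscript("bad", "ACGUX")
        with pytest.raises(ValueError):
            TargetTranscript("empty", "")


class TestDesign:
    def test_component_lengths_default_20(self, rng):
        _, probe, _ = design_for(rng)
        assert len(probe.arm_5p) == len(probe.arm_3p) == 20
        assert len(probe.reference_region) == 20

    def test_arms_reverse_complement_target_windows(self, rng):
        t, probe, _ = design_for(rng)
        pos = probe.site.position
        up = t.sequence[pos + 1 - 20 : pos + 1]
        down = t.sequence[pos + 1 : pos + 21]
        # reverse-complementing the arm again recovers the window (involution)
        assert rna_window_to_arm(up) == probe.arm_3p
        assert rna_window_to_arm(down) == probe.arm_5p
        assert probe.recognition_rna == up + down

    def test_circle_length_is_component_sum(self, rng):
        _, probe, cfg = design_for(rng)
        expected = (
            2 * cfg.arm_len
            + len(cfg.catalytic_core)
            + cfg.reference_len
            + cfg.anchor_len
            + 3 * len(cfg.spacer)
        )
        assert len(probe.circle_sequence) == expected
        assert probe.circle_position(len(probe.circle_sequence)) == 0

    def test_flank_too_short_raises(self):
        t = TargetTranscript("short", "A" * 5 + "GU" + "A" * 30)
        site = [s for s in find_cleavage_sites(t, 20) if s.dinucleotide == "GU"][0]
        with pytest.raises(ProbeDesignError):
            design_circular_dnazyme(t, site)

    def test_design_is_deterministic(self, rng):
        seq = random_rna(rng, 200)
        t = TargetTranscript("t", seq)
        site = [s for s in find_cleavage_sites(t, 20) if s.flank_ok][0]
        cfg = ProbeDesignConfig(seed=3)
        a = design_circular_dnazyme(t, site, cfg)
        b = design_circular_dnazyme(t, site, cfg)
        assert a == b

    def test_reference_and_anchor_are_orthogonal_to_target(self, rng):
        t, probe, _ = design_for(rng)
        target_dna = t.sequence.replace("U", "T")
        for seq in (probe.reference_region, probe.barcode_anchor):
            assert not (_kmers(seq, 10) & _kmers(target_dna, 10))


class TestControls:
    def test_mm12_hamming_distance_is_12(self, rng):
        region = random_rna(rng, 40)
        t = TargetTranscript("t", region)
        var = make_control_variant(t, "MM12", seed=2)
        dist = sum(a != b for a, b in zip(t.sequence, var.sequence))
        assert dist == 12

    def test_snv_single_central_mismatch(self, rng):
        t = TargetTranscript("t", random_rna(rng, 41))
        var = make_control_variant(t, "SNV", seed=2)
        diffs = [i for i, (a, b) in enumerate(zip(t.sequence, var.sequence)) if a != b]
        assert diffs == [20]

    def test_random_variant_shares_no_10mer(self, rng):
        region = random_rna(rng, 60)
        t = TargetTranscript("t", region)
        var = make_control_variant(t, "random", seed=7)
        assert len(var.sequence) == len(t.sequence)
        # brute-force 10-mer set intersection
        orig = {t.sequence[i : i + 10] for i in range(len(t.sequence) - 9)}
        new = {var.sequence[i : i + 10] for i in range(len(var.sequence) - 9)}
        assert not (orig & new)
        gc = lambda s: sum(c in "GC" for c in s) / len(s)
        assert abs(gc(var.sequence) - gc(t.sequence)) <= 0.05 + 1e-9

    def test_mm12_requires_12nt_region(self):
        t = TargetTranscript("t", "ACGUACGUACG")  # 11 nt
        with pytest.raises(ProbeDesignError):
            make_control_variant(t, "MM12")

    def test_core_deleted_probe_keeps_length(self, rng):
        _, probe, _ = design_for(rng)
        dead = make_control_variant(probe, "core_deleted")
        assert len(dead.catalytic_core) == len(probe.catalytic_core)
        assert dead.catalytic_core != probe.catalytic_core
        assert len(dead.circle_sequence) == len(probe.circle_sequence)
        assert dead.kind == "core_deleted"


class TestSpecificity:
    def test_probe_matches_own_target_perfectly(self, rng):
        t, probe, _ = design_for(rng)
        rep = screen_specificity(probe, [t])
        row = rep.iloc[0]
        assert row.arm_5p_max_contig == 20 and row.arm_3p_max_contig == 20
        assert bool(row.cleavage_competent)

    def test_snv_probe_is_cleavage_incompetent(self, rng):
        # design -> SNV control -> screen round-trip always flags incompetence
        for seed in range(5):
            t, probe, _ = design_for(rng, seed=seed)
            snv = make_control_variant(probe, "SNV", seed=seed)
            rep = screen_specificity(snv, [t])
            assert not bool(rep.iloc[0].cleavage_competent)

    def test_contiguous_match_equals_brute_force(self, rng):
        t, probe, _ = design_for(rng)
        # dinucleotide-shuffled-ish background: draw random transcripts
        bgs = [TargetTranscript(f"bg{i}", random_rna(rng, 300)) for i in range(5)]
        rep = screen_specificity(probe, bgs)
        arm5_sense = probe.recognition_rna[20:]
        arm3_sense = probe.recognition_rna[:20]
        for row, bg in zip(rep.itertuples(index=False), bgs):
            for arm_sense, got in [(arm5_sense, row.arm_5p_max_contig), (arm3_sense, row.arm_3p_max_contig)]:
                best = 0
                for i in range(len(arm_sense)):
                    for j in range(i + 1, len(arm_sense) + 1):
                        if arm_sense[i:j] in bg.sequence:
                            best = max(best, j - i)
                assert got == best
            assert not bool(row.cleavage_competent)

    def test_empty_background_gives_empty_report(self, rng):
        _, probe, _ = design_for(rng)
        assert screen_specificity(probe, []).empty


class TestPadlock:
    def test_padlock_is_rotation_and_rejoins_to_circle(self, rng):
        _, probe, _ = design_for(rng)
        padlock, linker = emit_padlock_linker(probe)
        assert len(padlock) == len(probe.circle_sequence)
        doubled = probe.circle_sequence * 2
        assert padlock in doubled  # rotation invariance
        # rotating back reproduces the circle
        k = doubled.index(padlock)
        assert padlock[-k:] + padlock[:-k] == probe.circle_sequence if k else padlock == probe.circle_sequence

    def test_linker_reverse_complements_padlock_ends(self, rng):
        from nanoladder.probe_design import revcomp_dna

        _, probe, _ = design_for(rng)
        padlock, linker = emit_padlock_linker(probe)
        assert len(linker) == 20
        assert linker == revcomp_dna(padlock[-10:] + padlock[:10])


def test_orthogonal_pool_respects_constraints(rng):
    seqs = orthogonal_sequences(5, 20, rng=rng)
    for s in seqs:
        gc = sum(c in "GC" for c in s) / len(s)
        assert 0.4 <= gc <= 0.6
        assert all(s.count(b * 5) == 0 for b in "ACGT")
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            assert not (_kmers(a, 10) & _kmers(b, 10))
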
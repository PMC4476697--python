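"""Uniqueness screen vs brute-force oracle; Tm model; design constraints; specificity."""
import numpy as np
import pytest

from mitosignal import (
    GenomePair,
    PrimerConstraints,
    UniqueRegion,
    check_specificity,
    design_primer_pairs,
    make_genome_pair,
    melting_temperature,
    screen_unique_regions,
)
from mitosignal.primers import window_best_identities
from mitosignal.published import load_assays
from mitosignal.seq import random_sequence, revcomp

from _oracles import (
    brute_force_window_identities,
    regions_from_bools,
    tm_nearest_neighbor_oracle,
)

WINDOW, STEP, THRESH = 100, 10, 0.80


class TestScreen:
    def test_clean_nuclear_genome_gives_whole_mito_region(self, clean_genomes):
        pair, _ = clean_genomes
        regions = screen_unique_regions(pair, window=WINDOW, step=STEP, identity_threshold=THRESH)
        assert regions == [
            UniqueRegion(0, len(pair.mito), regions[0].max_nuclear_identity)
        ]
        assert regions[0].max_nuclear_identity < THRESH

    def test_empty_nuclear_genome_returns_whole_genome(self):
        pair = GenomePair(mito=random_sequence(np.random.default_rng(0), 2000), nuclear={})
        regions = screen_unique_regions(pair, window=WINDOW, step=STEP)
        assert len(regions) == 1
        assert (regions[0].mito_start, regions[0].mito_end) == (0, 2000)
        assert regions[0].max_nuclear_identity == 0.0

    def test_window_longer_than_mito_raises(self, clean_genomes):
        pair, _ = clean_genomes
        with pytest.raises(ValueError, match="window"):
            screen_unique_regions(pair, window=len(pair.mito) + 1)

    def test_regions_exclude_perfect_numt(self):
        pair, truths = make_genome_pair(3, mito_length=5000, nuclear_length=15_000, numt_specs=[(500, 0.0)])
        (t,) = truths
        regions = screen_unique_regions(pair, window=WINDOW, step=STEP, identity_threshold=THRESH)
        for r in regions:
            # no window fully inside the identical NUMT can be part of a region:
            # any overlap is confined to sub-threshold edge windows (< window bases)
            overlap = min(r.mito_end, t.mito_end) - max(r.mito_start, t.mito_start)
            assert overlap < WINDOW

    def test_regions_equal_bruteforce_oracle(self, small_genomes):
        """Returned regions are exactly the oracle's maximal runs of windows
        whose best full-scan nuclear identity stays below the threshold."""
        pair, _ = small_genomes
        oracle_ident = brute_force_window_identities(pair.mito, pair.nuclear, WINDOW, STEP)
        starts = np.arange(0, len(pair.mito), STEP)
        expected = regions_from_bools(starts, oracle_ident < THRESH, WINDOW, len(pair.mito), min_region=WINDOW)
        got = screen_unique_regions(pair, window=WINDOW, step=STEP, identity_threshold=THRESH, min_region=WINDOW)
        assert [(r.mito_start, r.mito_end) for r in got] == expected

    def test_reverse_strand_numt_detected_like_forward(self):
        """Planting the same diverged segment forward or reverse-complemented
        flags the same mito windows."""
        rng = np.random.default_rng(17)
        mito = random_sequence(rng, 3000)
        insert = mito[1000:1400]
        background = random_sequence(rng, 10_000)
        fwd = GenomePair(mito=mito, nuclear={"n": background[:4000] + insert + background[4000:]})
        rev = GenomePair(mito=mito, nuclear={"n": background[:4000] + revcomp(insert) + background[4000:]})
        _, ident_f = window_best_identities(fwd, window=WINDOW, step=STEP)
        _, ident_r = window_best_identities(rev, window=WINDOW, step=STEP)
        assert np.array_equal(ident_f >= THRESH, ident_r >= THRESH)

    def test_rotation_rotates_window_identities(self, small_genomes):
        """Circularity: rotating the mito sequence by k rotates the per-window
        identity profile by k / step."""
        pair, _ = small_genomes
        k = 500
        rotated = GenomePair(mito=pair.mito[k:] + pair.mito[:k], nuclear=pair.nuclear)
        _, ident = window_best_identities(pair, window=WINDOW, step=STEP)
        _, ident_rot = window_best_identities(rotated, window=WINDOW, step=STEP)
        assert np.allclose(np.roll(ident, -k // STEP), ident_rot)


class TestMeltingTemperature:
    def test_matches_independent_parameter_table(self):
        for seq in (
            "ATAGCCTATCCATTCCTCATGCTTT",
            "AACTGACTCGTACCGCTAATAATCG",
            "GCGCGCGCATATATATCGCG",
            "CGTTGAACGTACGTACGTACGTACGT",
        ):
            assert melting_temperature(seq) == pytest.approx(tm_nearest_neighbor_oracle(seq), abs=0.5)

    def test_duplex_symmetry(self):
        seq = "ACCGTTGATCCATGGCATTACCGAT"
        assert melting_temperature(seq) == pytest.approx(melting_temperature(revcomp(seq)), abs=1e-9)

    def test_gc_raises_tm(self):
        assert melting_temperature("G" * 12 + "C" * 13) > melting_temperature("A" * 12 + "T" * 13)

    def test_rejects_non_acgt_and_short(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTACGT")
        with pytest.raises(ValueError):
            melting_temperature("ACGT")


class TestDesign:
    def test_feasible_region_yields_valid_ranked_pairs(self):
        rng = np.random.default_rng(23)
        mito = random_sequence(rng, 2000)
        region = UniqueRegion(200, 800, 0.3)
        pairs = design_primer_pairs(mito, region)
        assert pairs, "expected at least one pair in a 600 bp random region"
        c = PrimerConstraints()
        for p in pairs:
            assert c.primer_len[0] <= len(p.forward_seq) <= c.primer_len[1]
            assert c.primer_len[0] <= len(p.reverse_seq) <= c.primer_len[1]
            assert c.amplicon[0] <= p.amplicon_length <= c.amplicon[1]
            assert p.amplicon_length == p.reverse_end - p.forward_start
            assert c.gc_range[0] <= p.gc_forward <= c.gc_range[1]
            # reverse primer is the reverse complement of the template interval
            tpl = mito[p.reverse_end - len(p.reverse_seq) : p.reverse_end]
            assert p.reverse_seq == revcomp(tpl)
            assert mito[p.forward_start : p.forward_start + len(p.forward_seq)] == p.forward_seq
            # probe strictly between primers
            probe_pos = mito.find(p.probe_seq, p.forward_start, p.reverse_end)
            assert probe_pos >= p.forward_start + len(p.forward_seq)
            assert probe_pos + len(p.probe_seq) <= p.reverse_end - len(p.reverse_seq)
        penalties = [p.penalty for p in pairs]
        assert penalties == sorted(penalties)

    def test_minimal_110bp_region_is_feasible(self):
        # balanced-GC region exactly at the precondition floor
        rng = np.random.default_rng(40)
        for attempt in range(5):  # a few random balanced sequences; at least one must work
            mito = random_sequence(rng, 400)
            region = UniqueRegion(100, 210, 0.2)
            if design_primer_pairs(mito, region):
                return
        pytest.fail("no pair found in any 110 bp balanced region")

    def test_homopolymer_region_yields_nothing(self):
        mito = "A" * 1000
        assert design_primer_pairs(mito, UniqueRegion(0, 500, 0.0)) == []

    def test_short_region_raises_naming_region(self):
        with pytest.raises(ValueError, match=r"\[0,80\)"):
            design_primer_pairs("ACGT" * 100, UniqueRegion(0, 80, 0.0))

    def test_published_primer_lengths_pass_constraint(self):
        assays = load_assays()
        primers = assays[assays["role"].isin(["forward", "reverse"])]["sequence"]
        lo, hi = PrimerConstraints().primer_len
        assert all(lo <= len(s) <= hi for s in primers)


class TestSpecificity:
    def _pair(self, fwd, rev, probe):
        from mitosignal import PrimerPair

        return PrimerPair(fwd, rev, probe, 0, len(fwd) + len(probe) + len(rev), len(fwd) + len(probe) + len(rev),
                          60.0, 60.0, 55.0, 0.5, 0.5, 0.0)

    def test_planted_primer_is_flagged(self, rng):
        fwd = random_sequence(rng, 25)
        contig = random_sequence(rng, 5000) + fwd + random_sequence(rng, 5000)
        genomes = GenomePair(mito=random_sequence(rng, 1000), nuclear={"n": contig})
        rep = {r.primer_id: r for r in check_specificity(self._pair(fwd, random_sequence(rng, 25), random_sequence(rng, 20)), genomes)}
        assert rep["forward"].best_identity == 1.0
        assert rep["forward"].perfect_3prime_match

    def test_empty_nuclear_genome(self, rng):
        genomes = GenomePair(mito=random_sequence(rng, 1000), nuclear={})
        reports = check_specificity(self._pair(random_sequence(rng, 25), random_sequence(rng, 25), random_sequence(rng, 20)), genomes)
        assert all(r.best_identity == 0.0 and not r.perfect_3prime_match for r in reports)

    def test_random_primer_vs_random_contig_below_090(self):
        """Across seeds, a random 25-mer never reaches 90% identity in 200 kb
        of random sequence (binomial tail is astronomically small)."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            genomes = GenomePair(mito=random_sequence(rng, 500), nuclear={"n": random_sequence(rng, 200_000)})
            rep = check_specificity(
                self._pair(random_sequence(rng, 25), random_sequence(rng, 25), random_sequence(rng, 20)), genomes
            )
            assert all(r.best_identity < 0.9 for r in rep)
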
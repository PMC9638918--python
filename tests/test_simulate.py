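"""Occupancy, degradation/fragmentation, and read-sampling behaviour."""

import numpy as np
import pytest

from pdupack.genome import Replicon, SampleModel, Segment
from pdupack.simulate import (
    Fragment,
    NothingToSampleError,
    ORIGIN_BACKGROUND,
    ORIGIN_PROTECTED,
    ProtectionParams,
    allocate_molecules,
    degrade_and_fragment,
    sample_read_intervals,
    simulate_occupancy,
    simulate_reads,
    stream,
)
from pdupack.stats import uniform_start_pvalue

from conftest import make_simple_model


class TestProtectionParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_occ": 1.5},
            {"survival_unprotected": -0.1},
            {"background_rate": 2.0},
            {"frag_len_min": 0},
            {"frag_len_min": 400, "frag_len_max": 300},
            {"n_reads": 0},
            {"molecule_count": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ProtectionParams(**kwargs)


class TestOccupancy:
    def test_full_occupancy_with_close_sites_merges_to_one_interval(self):
        model = make_simple_model(n_sites=8, spacing=40)
        params = ProtectionParams(p_occ=1.0, footprint=25, merge_gap=10)
        occ = simulate_occupancy(model, params, molecule_count=20)
        sites = model.factor_sites("plasmid")
        for intervals in occ["plasmid"]:
            assert len(intervals) == 1
            (s, e), = intervals
            assert s <= sites[0].start and e >= sites[-1].end

    def test_zero_occupancy_gives_empty_interval_lists(self):
        model = make_simple_model(n_sites=5)
        occ = simulate_occupancy(model, ProtectionParams(p_occ=0.0), molecule_count=50)
        assert all(iv == [] for iv in occ["plasmid"])

    def test_occupied_fraction_matches_binomial_oracle(self):
        # one site, p_occ = 0.5: the bound fraction over molecules is Binomial.
        model = make_simple_model(n_sites=1)
        n = 10_000
        occ = simulate_occupancy(model, ProtectionParams(p_occ=0.5, seed=11), molecule_count=n)
        frac = sum(bool(iv) for iv in occ["plasmid"]) / n
        se = (0.5 * 0.5 / n) ** 0.5
        assert abs(frac - 0.5) <= 3 * se

    def test_iscei_sites_never_protect(self, lacO8_model):
        params = ProtectionParams(p_occ=1.0, footprint=0, merge_gap=1)
        occ = simulate_occupancy(lacO8_model, params, molecule_count=5)
        laci = lacO8_model.factor_sites(lacO8_model.segment.replicon)
        for intervals in occ[lacO8_model.segment.replicon]:
            assert len(intervals) == len(laci)  # one per LacI site, none for I-SceI

    def test_allocation_proportional_to_copy_number(self, lacO8_model):
        alloc = allocate_molecules(lacO8_model, 1100)
        assert alloc == {"pOH": 900, "pRW-lacO8": 200}
        assert sum(alloc.values()) == 1100


class TestDegradeAndFragment:
    def test_600bp_protected_interval_cut_pattern(self):
        # enumeration of admissible cut patterns of 600 bp into [150, 300]:
        # either 2 pieces (both in range) or 3 pieces with at most one
        # flagged short remainder; nothing protected is lost.
        model = make_simple_model(n_sites=1, plasmid_length=5000)
        params = ProtectionParams(frag_len_min=150, frag_len_max=300,
                                  survival_unprotected=0.0, seed=5)
        occupancy = {"plasmid": [[(1000, 1600)]] * 200}
        rng = stream(5, "degradation")
        frags = degrade_and_fragment(model, occupancy, params, rng)
        by_molecule: dict[int, list[Fragment]] = {}
        i = 0
        # fragments come out molecule by molecule, contiguous over [1000,1600)
        groups = []
        current = []
        for f in frags:
            if f.start == 1000 and current:
                groups.append(current)
                current = []
            current.append(f)
        groups.append(current)
        assert len(groups) == 200
        for group in groups:
            assert 2 <= len(group) <= 3
            assert sum(f.length for f in group) == 600
            shorts = [f for f in group if f.short]
            assert len(shorts) <= 1
            for f in group:
                assert f.origin == ORIGIN_PROTECTED
                assert f.short or 150 <= f.length <= 300

    def test_no_protection_no_survival_yields_no_fragments(self):
        model = make_simple_model(n_sites=1)
        params = ProtectionParams(p_occ=0.0, survival_unprotected=0.0)
        occ = simulate_occupancy(model, params, molecule_count=10)
        assert degrade_and_fragment(model, occ, params) == []

    def test_full_survival_tiles_the_plasmid_without_overlap(self):
        # survival 1, occupancy 0: pieces partition the molecule except for a
        # single discarded sub-minimum remainder at the end.
        model = make_simple_model(n_sites=1, plasmid_length=5000)
        params = ProtectionParams(p_occ=0.0, survival_unprotected=1.0, seed=2)
        occ = {"plasmid": [[]]}
        frags = degrade_and_fragment(model, occ, params)
        frags = sorted(frags, key=lambda f: f.start)
        assert frags[0].start == 0
        for a, b in zip(frags, frags[1:]):
            assert a.end == b.start  # contiguous: each base covered at most once
        total = sum(f.length for f in frags)
        assert total >= 5000 - params.frag_len_min
        assert all(f.origin == ORIGIN_BACKGROUND for f in frags)

    def test_short_protected_interval_emitted_flagged(self):
        model = make_simple_model(n_sites=1)
        params = ProtectionParams(survival_unprotected=0.0)
        occ = {"plasmid": [[(100, 180)]]}  # 80 bp < frag_len_min
        frags = degrade_and_fragment(model, occ, params)
        assert len(frags) == 1 and frags[0].short and frags[0].length == 80


class TestReadSampling:
    def test_background_share_matches_multinomial_oracle(self):
        # replicons (len 10 000, cn 1) and (len 1 000, cn 9): expected
        # read-mass ratio 10 000 : 9 000.
        model = SampleModel(
            [
                Replicon("big", 10_000, 1.0, is_chromosome=True),
                Replicon("small", 1_000, 9.0),
            ],
            [],
            Segment("small", 100, 700),
        )
        n = 50_000
        params = ProtectionParams(background_rate=1.0, n_reads=n, seed=21)
        truth = sample_read_intervals(model, params)
        p = 10_000 / 19_000
        frac_big = (truth["replicon"] == "big").mean()
        se = (p * (1 - p) / n) ** 0.5
        assert abs(frac_big - p) <= 3 * se

    def test_conservation_fastq_bed_and_read_count(self, lacO8_model, tmp_path):
        params = ProtectionParams(n_reads=500, seed=3, molecule_count=100)
        sim = simulate_reads(lacO8_model, params, tmp_path / "r.fastq", tmp_path / "t.bed")
        fq = (tmp_path / "r.fastq").read_text().splitlines()
        bed = (tmp_path / "t.bed").read_text().splitlines()
        assert len(fq) == 4 * 500
        assert len(bed) == 500
        assert len(sim.truth) == 500

    def test_error_free_reads_equal_reference_substrings(self, lacO8_model, tmp_path):
        params = ProtectionParams(n_reads=200, error_rate=0.0, seed=4, molecule_count=100)
        sim = simulate_reads(lacO8_model, params, tmp_path / "r.fastq", None)
        seqs = {r.name: r.sequence for r in lacO8_model.replicons}
        lines = (tmp_path / "r.fastq").read_text().splitlines()
        for i, row in enumerate(sim.truth.itertuples()):
            assert lines[4 * i + 1] == seqs[row.replicon][row.start:row.end]

    def test_identical_seed_gives_byte_identical_outputs(self, lacO8_model, tmp_path):
        params = ProtectionParams(n_reads=300, seed=9, molecule_count=100)
        for d in ("a", "b"):
            (tmp_path / d).mkdir()
            simulate_reads(lacO8_model, params, tmp_path / d / "r.fastq", tmp_path / d / "t.bed")
        assert (tmp_path / "a/r.fastq").read_bytes() == (tmp_path / "b/r.fastq").read_bytes()
        assert (tmp_path / "a/t.bed").read_bytes() == (tmp_path / "b/t.bed").read_bytes()
        other = ProtectionParams(n_reads=300, seed=10, molecule_count=100)
        simulate_reads(lacO8_model, other, tmp_path / "c.fastq", None)
        assert (tmp_path / "c.fastq").read_bytes() != (tmp_path / "a/r.fastq").read_bytes()

    def test_nothing_to_sample_raises(self):
        model = make_simple_model(n_sites=1, with_sequence=True)
        params = ProtectionParams(p_occ=0.0, survival_unprotected=0.0,
                                  background_rate=0.0, n_reads=100)
        with pytest.raises(NothingToSampleError):
            sample_read_intervals(model, params)

    def test_full_occupancy_concentrates_reads_on_segment(self, lacO8_model):
        # With every operator bound, protected operator-cluster fragments
        # dominate the packaged pool. All protected-origin reads lie in the
        # segment; rare unprotected survivors cap the overall fraction near
        # 0.95 x protected-pool share (~0.83 under default survival).
        params = ProtectionParams(p_occ=1.0, background_rate=0.05, n_reads=50_000, seed=7)
        truth = sample_read_intervals(lacO8_model, params)
        seg = lacO8_model.segment
        protected = truth[truth["origin"] == ORIGIN_PROTECTED]
        in_seg = (protected["start"] < seg.end) & (protected["end"] > seg.start)
        assert in_seg.all()
        overall = (
            (truth["replicon"] == seg.replicon)
            & (truth["start"] < seg.end)
            & (truth["end"] > seg.start)
        ).mean()
        assert overall >= 0.80

    def test_fragment_length_support(self, lacO8_model):
        params = ProtectionParams(n_reads=20_000, seed=13)
        truth = sample_read_intervals(lacO8_model, params)
        lengths = (truth["end"] - truth["start"]).to_numpy()
        # support is [min, max] except flagged short protected remainders
        # and background reads truncated at a replicon end
        assert lengths.max() <= params.frag_len_max
        assert lengths.min() > 0

    def test_pure_background_coverage_is_flat(self, lacO8_model):
        # chi-square on 1-kb start bins; uniform starts make every bin exact.
        rejects = 0
        n_seeds = 20
        for seed in range(n_seeds):
            params = ProtectionParams(background_rate=1.0, n_reads=100_000, seed=seed)
            truth = sample_read_intervals(lacO8_model, params)
            for r in lacO8_model.replicons:
                starts = truth.loc[truth["replicon"] == r.name, "start"].to_numpy()
                if uniform_start_pvalue(starts, r.length) < 0.01:
                    rejects += 1
                    break
        assert rejects / n_seeds <= 0.05
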
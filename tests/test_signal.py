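"""Fragment extension, pileup conservation, region geometry, Poisson calls."""

import numpy as np
import pandas as pd
import pytest
import math
from scipy.stats import poisson

import histosplice as hs
from histosplice.signal import SignalError


def frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


class TestExtendFragments:
    @pytest.mark.parametrize(
        "start,end,strand,exp_start,exp_end",
        [
            (100, 136, "+", 100, 250),   # 5' anchored forward
            (100, 136, "-", -14, 136),   # 5' anchored reverse, unclamped
            (100, 250, "+", 100, 250),   # already the target length
            (100, 400, "+", 100, 250),   # long read truncated from the 3' side
            (100, 400, "-", 250, 400),
        ],
    )
    def test_anchoring(self, start, end, strand, exp_start, exp_end):
        out = hs.extend_fragments(frame([("chr1", start, end, strand)]), 150)
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (exp_start, exp_end)

    def test_clamped_at_chromosome_start(self):
        out = hs.extend_fragments(frame([("chr1", 100, 136, "-")]), 150,
                                  chrom_sizes={"chr1": 1000})
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (0, 136)

    def test_short_read_without_strand_is_an_error(self):
        with pytest.raises(SignalError, match="no strand"):
            hs.extend_fragments(frame([("chr1", 100, 136, ".")]), 150)

    def test_full_length_read_without_strand_is_fine(self):
        out = hs.extend_fragments(frame([("chr1", 100, 250, ".")]), 150)
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 250)


class TestPileup:
    def test_mass_conservation_random_fragments(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 10000, 1000)
        frags = frame([("chr1", s, s + 150, "+") for s in starts])
        track = hs.build_pileup(frags, {"chr1": 10150})
        assert track.coverage("chr1").sum() == 1000 * 150
        assert track.total_fragments == 1000

    def test_identical_fragments_add(self):
        frags = frame([("chr1", 10, 160, "+")] * 2)
        track = hs.build_pileup(frags, {"chr1": 200})
        cov = track.coverage("chr1")
        assert (cov[10:160] == 2).all()
        assert cov[:10].sum() == 0 and cov[160:].sum() == 0

    def test_fragment_beyond_chromosome_is_an_error(self):
        with pytest.raises(SignalError):
            hs.build_pileup(frame([("chr1", 100, 260, "+")]), {"chr1": 200})

    def test_midpoint_counts(self):
        frags = frame([("chr1", 0, 150, "+"), ("chr1", 100, 250, "+")])
        track = hs.build_pileup(frags, {"chr1": 300})
        assert track.count_midpoints("chr1", 0, 100) == 1   # midpoint 75
        assert track.count_midpoints("chr1", 100, 300) == 1  # midpoint 175
        assert track.count_midpoints("chr1", 0, 300) == 2


class TestDefineRegions:
    def test_plus_strand_geometry(self):
        t = hs.define_regions(1000, 1100, "+")
        assert t.preceding == (820, 980)
        assert t.exon_body == (1020, 1080)
        assert t.succeeding == (1120, 1280)

    def test_minus_strand_swaps_flank_roles(self):
        plus = hs.define_regions(1000, 1100, "+")
        minus = hs.define_regions(1000, 1100, "-")
        assert minus.preceding == plus.succeeding
        assert minus.succeeding == plus.preceding
        assert minus.exon_body == plus.exon_body

    def test_minimal_exon_gives_10bp_body(self):
        t = hs.define_regions(1000, 1050, "+")
        assert t.exon_body == (1020, 1030)

    def test_exon_too_short_to_trim(self):
        with pytest.raises(SignalError):
            hs.define_regions(1000, 1040, "+")


class TestPoissonPresent:
    def test_zero_count_always_absent(self):
        assert hs.poisson_present(0, 160, rate=0.05) is False

    @staticmethod
    def _tail(lam, count, upto=120):
        # direct summation oracle: P(X >= count) = 1 - sum_{k<count} e^-lam lam^k/k!
        term, head = math.exp(-lam), 0.0
        for k in range(count):
            head += term
            term *= lam / (k + 1)
        return 1.0 - head

    def test_matches_direct_tail_summation(self):
        # lambda * L = 5, count = 11: present iff sum_{k>=11} e^-5 5^k/k! < 0.05
        lam = 5.0
        assert abs(self._tail(lam, 11) - 0.013695) < 1e-5
        assert hs.poisson_present(11, 100, rate=0.05) is (self._tail(lam, 11) < 0.05)
        # one fragment fewer flips the call at this configuration
        assert hs.poisson_present(9, 100, rate=0.05) is (self._tail(lam, 9) < 0.05)
        assert hs.poisson_present(11, 100, rate=0.05)
        assert not hs.poisson_present(9, 100, rate=0.05)

    def test_deeper_sequencing_moves_calls_toward_absent(self):
        for count in range(0, 40):
            if hs.poisson_present(count, 160, rate=0.04):
                assert hs.poisson_present(count, 160, rate=0.02)

    def test_zero_mappable_genome_is_an_error(self):
        track = hs.build_pileup(frame([("chr1", 0, 150, "+")]), {"chr1": 200},
                                mappable_fraction=0.0)
        with pytest.raises(SignalError):
            track.background_rate()


class TestBinarize:
    def exon_frame(self):
        return pd.DataFrame(
            [{"exon_id": "e1", "chrom": "chr1", "start": 1000, "end": 1100,
              "strand": "+"}]
        )

    def test_empty_tracks_give_all_absent(self):
        empty = frame([])
        tracks = {m: hs.build_pileup(empty, {"chr1": 5000}) for m in ("A", "B")}
        attrs = hs.binarize_exons(self.exon_frame(), tracks)
        assert attrs.shape == (1, 6)
        assert attrs.to_numpy().sum() == 0

    def test_38_marks_give_114_attributes(self):
        marks = [f"H3K{i}me1" for i in range(38)]
        empty = frame([])
        tracks = {m: hs.build_pileup(empty, {"chr1": 5000}) for m in marks}
        attrs = hs.binarize_exons(self.exon_frame(), tracks)
        assert attrs.shape[1] == 114
        assert f"{marks[0]}.prec" in attrs.columns
        assert f"{marks[-1]}.succ" in attrs.columns

    def test_enriched_flank_is_called_present(self):
        # pile 30 fragment midpoints into the left flank over a thin background
        rng = np.random.default_rng(3)
        bg = [("chr1", int(s), int(s) + 150, "+")
              for s in rng.integers(0, 99850, 200)]
        peak = [("chr1", int(m) - 75, int(m) + 75, "+")
                for m in rng.integers(830, 970, 30)]
        track = hs.build_pileup(frame(bg + peak), {"chr1": 100000}, 1.0)
        attrs = hs.binarize_exons(self.exon_frame(), {"M": track})
        assert attrs.loc["e1", "M.prec"] == 1
        assert attrs.loc["e1", "M.succ"] == 0

    def test_strand_mirror_symmetry(self):
        """Mirroring the genome and flipping strand swaps prec/succ calls only."""
        size = 100000
        rng = np.random.default_rng(4)
        mids = rng.integers(75, size - 75, 300).tolist() + \
            list(rng.integers(830, 970, 30))
        frags = frame([("chr1", m - 75, m + 75, "+") for m in mids])
        mirrored = frame([("chr1", size - (m + 75), size - (m - 75), "-")
                          for m in mids])
        track = hs.build_pileup(frags, {"chr1": size}, 1.0)
        mtrack = hs.build_pileup(mirrored, {"chr1": size}, 1.0)
        fwd = hs.binarize_exons(self.exon_frame(), {"M": track})
        exon_rev = pd.DataFrame(
            [{"exon_id": "e1", "chrom": "chr1", "start": size - 1100,
              "end": size - 1000, "strand": "-"}]
        )
        rev = hs.binarize_exons(exon_rev, {"M": mtrack})
        assert fwd.loc["e1"].tolist() == rev.loc["e1"].tolist()
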
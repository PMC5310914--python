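"""Strand bias, methylation rate ratios, Fisher's exact test, deciles."""

import math

import numpy as np
import pytest
from scipy import stats

from mutspect.genomic_strata import (
    IntervalTrack,
    decile_stratify,
    fisher_2x2,
    methylation_ratio,
    strand_bias,
    strand_bias_tests,
    strand_classify,
)
from mutspect.synthetic_data import TrackSpec, generate_tracks
from mutspect.variant_spectrum import SIGNATURE_1, parse_class_label

from conftest import make_panel

#      123456789012345678901
SEQ = "TACGTTACATAGGATCCGATT"


class TestStrandClassify:
    def _track(self, ref):
        spec = TrackSpec(
            "strand", (("chr1", 2, 8, "+"), ("chr1", 5, 12, "-"))
        )
        return IntervalTrack(generate_tracks(ref, [spec])["strand"])

    def test_labels_follow_union_rule(self):
        _, ref = make_panel(SEQ, [], 1)
        track = self._track(ref)
        # 1-based positions: 3-5 only '+', 6-8 overlap, 9-12 only '-'
        labels = strand_classify([("chr1", p) for p in (3, 7, 10, 20)], track, ref)
        assert labels == ["+", "both", "-", "none"]

    def test_position_outside_reference_rejected(self):
        _, ref = make_panel(SEQ, [], 1)
        track = self._track(ref)
        with pytest.raises(ValueError):
            strand_classify([("chr1", 99)], track, ref)


def _biased_panel(n_untx=8, n_tx=4):
    """TCC>T mutations: TCC context at pos 16 region; build one variant per
    placement, alternating regions transcribed on - (untranscribed C) and +."""
    # reference with many TCC contexts: repeat "ATCCG" blocks
    seq = "ATCCG" * 40  # TCC at positions 2..4 of each block, C at pos 3 (1-based: 3, 8, ...)
    records = []
    # C of each TCC occurs at 1-based positions 4 + 5k? "ATCCG": A1 T2 C3 C4 G5 -> context T2 C3 C4 = TCC centered at 3
    cpos = [3 + 5 * k for k in range(n_untx + n_tx)]
    for p in cpos:
        records.append((p, "C", "T", "C", {0: 1, 1: 1}))
    panel, ref = make_panel(seq, records, 2)
    ivs = []
    for i, p in enumerate(cpos):
        strand = "-" if i < n_untx else "+"  # '-' transcribed => C on untranscribed
        ivs.append(("chr1", p - 1, p, strand))
    track = IntervalTrack(generate_tracks(ref, [TrackSpec("strand", tuple(ivs))])["strand"])
    return panel, ref, track


class TestStrandBias:
    def test_two_to_one_gives_log_two(self):
        panel, ref, track = _biased_panel(8, 4)
        res = strand_bias(panel, ref, track, [parse_class_label("TCC>T")], "f2")
        assert res.count_untranscribed[0] == 8 and res.count_transcribed[0] == 4
        assert res.log_ratio[0] == pytest.approx(math.log(2), abs=1e-12)

    def test_balanced_counts_give_zero(self):
        panel, ref, track = _biased_panel(4, 4)
        res = strand_bias(panel, ref, track, [parse_class_label("TCC>T")], "f2")
        assert res.log_ratio[0] == 0.0

    def test_flipping_track_negates_log_ratio_exactly(self):
        panel, ref, track = _biased_panel(7, 3)
        res = strand_bias(panel, ref, track, [parse_class_label("TCC>T")], "f2")
        flipped = IntervalTrack(
            [
                ("chr1", int(track._starts["chr1"][i]), int(track._ends["chr1"][i]),
                 {"+": "-", "-": "+"}.get(track._labels["chr1"][i], track._labels["chr1"][i]))
                for i in range(len(track._labels["chr1"]))
            ]
        )
        res2 = strand_bias(panel, ref, flipped, [parse_class_label("TCC>T")], "f2")
        assert np.array_equal(res.log_ratio, -res2.log_ratio)

    def test_purine_strand_mutation_counts_on_opposite_side(self):
        # a G>A SNP is the reverse complement of C>T: its pyrimidine sits on
        # the minus strand, so a + transcribed region puts it untranscribed
        seq = "ATGGA" * 10  # GGA blocks: G at 1-based 4 with context GGA
        records = [(4, "G", "A", "G", {0: 1, 1: 1})]
        panel, ref = make_panel(seq, records, 2)
        cls = parse_class_label("TCC>T")  # revcomp of GGA>A center
        track_plus = IntervalTrack([("chr1", 0, 50, "+")])
        res = strand_bias(panel, ref, track_plus, [cls], "f2")
        assert res.count_untranscribed.sum() == 2
        assert res.count_transcribed.sum() == 0

    def test_pseudocount_applied_only_on_zeros(self):
        panel, ref, track = _biased_panel(5, 0)
        res = strand_bias(panel, ref, track, [parse_class_label("TCC>T")], "f2")
        assert res.log_ratio[0] == pytest.approx(math.log(5.5 / 0.5), abs=1e-12)
        assert res.pseudocount_used[0]

    def test_group_summary_tests_run(self):
        panel, ref, track = _biased_panel(8, 4)
        res = strand_bias(panel, ref, track, [parse_class_label("TCC>T")], "f2")
        out = strand_bias_tests(res, {"a": [0], "b": [1]})
        assert set(out) == {"anova_p", "welch_t_p"}


class TestMethylationRatio:
    def test_worked_rate_ratio(self):
        # 100 mutations / 1000 high sites vs 20 / 2000 low sites -> 10.0
        seq = "ACG" * 2000
        # CG cytosines at 1-based positions 2, 5, 8, ...
        cs = [2 + 3 * k for k in range(4000)]
        high = [("chr1", p) for p in cs[:1000]]
        low = [("chr1", p) for p in cs[1000:3000]]
        records = [(p, "C", "T", "C", {0: 2}) for p in cs[:100]]
        records += [(p, "C", "T", "C", {0: 2}) for p in cs[1000:1020]]
        panel, ref = make_panel(seq, records, 2)
        from mutspect.variant_spectrum import SIGNATURE_2

        res = methylation_ratio(panel, ref, high, low, SIGNATURE_2, "f2")
        assert res.n_high_mutations == 100 and res.n_low_mutations == 20
        assert res.ratio == pytest.approx(10.0, abs=1e-12)

    def test_equal_rates_give_one(self):
        seq = "ACG" * 200
        cs = [2 + 3 * k for k in range(200)]
        high = [("chr1", p) for p in cs[:100]]
        low = [("chr1", p) for p in cs[100:200]]
        records = [(p, "C", "T", "C", {0: 2}) for p in cs[:10]]
        records += [(p, "C", "T", "C", {0: 2}) for p in cs[100:110]]
        panel, ref = make_panel(seq, records, 2)
        from mutspect.variant_spectrum import SIGNATURE_2

        res = methylation_ratio(panel, ref, high, low, SIGNATURE_2, "f2")
        assert res.ratio == pytest.approx(1.0, abs=1e-12)

    def test_zero_low_mutations_flagged_infinite(self):
        seq = "ACG" * 200
        cs = [2 + 3 * k for k in range(200)]
        records = [(cs[0], "C", "T", "C", {0: 2})]
        panel, ref = make_panel(seq, records, 2)
        from mutspect.variant_spectrum import SIGNATURE_2

        res = methylation_ratio(
            panel, ref, [("chr1", cs[0])], [("chr1", cs[1])], SIGNATURE_2, "f2"
        )
        assert res.infinite and math.isinf(res.ratio)

    def test_overlapping_site_lists_rejected(self):
        panel, ref = make_panel(SEQ, [], 1)
        with pytest.raises(ValueError):
            methylation_ratio(panel, ref, [("chr1", 3)], [("chr1", 3)], SIGNATURE_1)


def _enumerate_fisher(table):
    """Independent oracle: sum hypergeometric point probabilities <= P(obs)."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = rv.pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_degenerate_all_zero_table(self):
        assert fisher_2x2([[0, 0], [0, 0]]) == 1.0

    def test_identical_row_proportions(self):
        assert fisher_2x2([[2, 4], [3, 6]]) == pytest.approx(1.0, abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2([[1, -1], [0, 2]])

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(300):
            t = rng.integers(0, 31, size=(2, 2))
            assert fisher_2x2(t) == pytest.approx(_enumerate_fisher(t), abs=1e-12)


class TestDecileStratify:
    def _setup(self, n_variants=4000, seed=33):
        from mutspect.synthetic_data import (
            PopulationSpec,
            SyntheticGenomeSpec,
            decile_track_from_score,
            generate_panel,
            generate_reference,
        )

        ref, _ = generate_reference(SyntheticGenomeSpec(length=100_000, seed=seed))
        panel, _ = generate_panel(
            ref, [PopulationSpec("A", "R", 8)], n_variants, seed=seed + 1
        )
        track = IntervalTrack(decile_track_from_score(ref, 1000, seed=seed).intervals)
        return panel, ref, track

    def test_uniform_placement_spreads_over_deciles(self):
        panel, ref, track = self._setup()
        groups = {"all": np.arange(8)}
        res = decile_stratify(panel, ref, track, SIGNATURE_1, groups, "f2")
        totals = res.table.groupby("stratum")["n_total"].sum()
        frac = totals / totals.sum()
        se = np.sqrt(0.1 * 0.9 / totals.sum())
        assert (np.abs(frac - 0.1) < 4 * se).all()

    def test_empty_cells_reported_as_zero(self):
        panel, ref, track = self._setup(n_variants=5)
        res = decile_stratify(panel, ref, track, SIGNATURE_1, {"all": np.arange(8)}, "f2")
        assert len(res.table) == 10
        assert (res.table.loc[res.table["n_total"] == 0, "proportion"] == 0).all()

    def test_group_permutation_equivariance(self):
        panel, ref, track = self._setup()
        g1 = {"x": np.arange(4), "y": np.arange(4, 8)}
        g2 = {"y": np.arange(4, 8), "x": np.arange(4)}
        r1 = decile_stratify(panel, ref, track, SIGNATURE_1, g1, "f2").proportions()
        r2 = decile_stratify(panel, ref, track, SIGNATURE_1, g2, "f2").proportions()
        assert r1[["x", "y"]].equals(r2[["x", "y"]])

    def test_null_calibration_between_equal_intensity_groups(self):
        # two groups drawn from the same generative intensities: per-decile
        # proportion differences stay within ~3 SE in nearly all replicates
        from mutspect.synthetic_data import (
            PopulationSpec,
            SyntheticGenomeSpec,
            decile_track_from_score,
            generate_panel,
            generate_reference,
        )

        ref, _ = generate_reference(SyntheticGenomeSpec(length=60_000, seed=40))
        track = IntervalTrack(decile_track_from_score(ref, 1000, seed=40).intervals)
        pops = [PopulationSpec("A", "R", 6), PopulationSpec("B", "R", 6)]
        groups = {"A": np.arange(6), "B": np.arange(6, 12)}
        n_ok = n_cells = 0
        for rep in range(12):
            panel, _ = generate_panel(ref, pops, 3000, seed=100 + rep)
            res = decile_stratify(panel, ref, track, SIGNATURE_1, groups, "f2")
            tab = res.table.set_index(["stratum", "group"])
            for s in map(str, range(10)):
                pa, na = tab.loc[(s, "A"), ["proportion", "n_total"]]
                pb, nb = tab.loc[(s, "B"), ["proportion", "n_total"]]
                if na < 20 or nb < 20:
                    continue
                pool = (pa * na + pb * nb) / (na + nb)
                se = np.sqrt(pool * (1 - pool) * (1 / na + 1 / nb))
                if se == 0:
                    continue
                n_cells += 1
                n_ok += abs(pa - pb) <= 3 * se
        assert n_cells > 50
        assert n_ok / n_cells >= 0.95
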
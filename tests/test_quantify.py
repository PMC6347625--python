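"""Conversion matrices, product distributions, purity — against naive oracles."""

from collections import Counter

import pytest

from beditseq import (EditingRegionSet, EditorProfile, c_to_t_profile,
                      conversion_matrix, extract_regions, pattern_label,
                      product_distribution, purity_summary,
                      simulate_reads, single_edit_fraction)

BASES = "ACGT"


def region_set(regions, region_len=None):
    region_len = region_len if region_len is not None else len(regions[0])
    return EditingRegionSet(regions=list(regions), n_input=len(regions),
                            n_matched=len(regions), n_rejected_flank=0,
                            n_rejected_length=0, n_rejected_ambiguous=0,
                            region_len=region_len)


def naive_matrix(regions):
    """Independent per-column tally: base -> fraction, per position."""
    n = len(regions)
    out = []
    for j in range(len(regions[0])):
        c = Counter(r[j] for r in regions)
        out.append({b: c.get(b, 0) / n for b in BASES})
    return out


def naive_products(regions, ref, targets):
    """Independent per-read haplotype dictionary tally."""
    tpos = sorted(targets)
    idx = [ref.offset_to_region_index(o) for o in tpos]
    c = Counter()
    for r in regions:
        pat = tuple((o, r[i]) for o, i in zip(tpos, idx) if r[i] != "C")
        c[pat] += 1
    return dict(c)


class TestConversionMatrix:
    def test_all_reference_reads_have_zero_off_reference(self, demo_ref):
        m = conversion_matrix(region_set([demo_ref.region_seq] * 10), demo_ref)
        for off in demo_ref.target_cytidines():
            assert m.freq(off, "C") == 1.0
            assert m.freq(off, "T") == 0.0

    def test_forty_percent_conversion_arithmetic(self, demo_ref):
        region = demo_ref.region_seq
        i = demo_ref.offset_to_region_index(-18)
        edited = region[:i] + "T" + region[i + 1:]
        m = conversion_matrix(region_set([edited] * 4 + [region] * 6), demo_ref)
        assert m.freq(-18, "T") == pytest.approx(0.4)
        assert m.freq(-19, "T") == 0.0

    def test_matches_naive_tally_on_simulated_reads(self, demo_ref):
        prof = EditorProfile(0.6, {-18: 0.5, -19: 0.2, -16: 0.1},
                             purity_rho=0.1, seq_error=0.003)
        rs, _ = simulate_reads(demo_ref, prof, 200, seed=2)
        regs = extract_regions(rs, demo_ref)
        m = conversion_matrix(regs, demo_ref)
        oracle = naive_matrix(regs.regions)
        for j, col in enumerate(oracle):
            for b in BASES:
                assert m.table.iloc[j][b] == pytest.approx(col[b], abs=0)

    def test_column_sums_to_one(self, demo_ref):
        prof = EditorProfile(0.8, {-18: 0.7}, purity_rho=0.3, seq_error=0.01)
        rs, _ = simulate_reads(demo_ref, prof, 500, seed=9)
        m = conversion_matrix(extract_regions(rs, demo_ref), demo_ref)
        sums = m.table[list(BASES)].sum(axis=1)
        assert (abs(sums - 1.0) < 1e-9).all()

    def test_empty_region_set_is_an_error(self, demo_ref):
        with pytest.raises(ValueError, match="no matched reads"):
            conversion_matrix(region_set([], region_len=demo_ref.region_len), demo_ref)


class TestCToTProfile:
    def test_projection_of_matrix(self, demo_ref):
        region = demo_ref.region_seq
        i = demo_ref.offset_to_region_index(-16)
        edited = region[:i] + "T" + region[i + 1:]
        m = conversion_matrix(region_set([edited] + [region] * 3), demo_ref)
        prof = c_to_t_profile(m, demo_ref.target_cytidines())
        assert prof == {-16: pytest.approx(0.25), -18: 0.0, -19: 0.0}

    def test_unknown_target_raises(self, demo_ref):
        m = conversion_matrix(region_set([demo_ref.region_seq]), demo_ref)
        with pytest.raises(KeyError):
            c_to_t_profile(m, [-30])


class TestProductDistribution:
    def test_single_and_double_edit_fractions(self, demo_ref):
        region = demo_ref.region_seq
        i18 = demo_ref.offset_to_region_index(-18)
        i19 = demo_ref.offset_to_region_index(-19)
        single = region[:i18] + "T" + region[i18 + 1:]
        double = single[:i19] + "T" + single[i19 + 1:]
        regs = region_set([single] * 5 + [double] * 3 + [region] * 2)
        dist = product_distribution(regs, demo_ref, demo_ref.target_cytidines())
        assert dist.fraction_of_reads(((-18, "T"),)) == pytest.approx(0.5)
        assert dist.fraction_of_reads(((-19, "T"), (-18, "T"))) == pytest.approx(0.3)
        assert dist.fraction_of_reads(()) == pytest.approx(0.2)
        assert sum(dist.counts.values()) == dist.n_reads == 10

    def test_empty_target_set_single_unedited_bucket(self, demo_ref):
        dist = product_distribution(region_set([demo_ref.region_seq] * 4),
                                    demo_ref, [])
        assert dist.counts == {(): 4}

    def test_matches_brute_force_haplotype_tally(self, polyc_ref, polyc_targets):
        prof = EditorProfile(0.7, {o: 0.3 for o in polyc_targets},
                             purity_rho=0.05, seq_error=0.002)
        rs, _ = simulate_reads(polyc_ref, prof, 1000, seed=4)
        regs = extract_regions(rs, polyc_ref)
        dist = product_distribution(regs, polyc_ref, polyc_targets)
        assert dist.counts == naive_products(regs.regions, polyc_ref, polyc_targets)

    def test_pattern_labels(self):
        assert pattern_label(()) == "unedited"
        assert pattern_label(((-19, "T"), (-18, "T"))) == "T-19T-18"


class TestSingleEditFraction:
    def test_all_single_edit(self, demo_ref):
        region = demo_ref.region_seq
        i = demo_ref.offset_to_region_index(-18)
        single = region[:i] + "T" + region[i + 1:]
        dist = product_distribution(region_set([single] * 3 + [region]),
                                    demo_ref, demo_ref.target_cytidines())
        assert single_edit_fraction(dist, -18) == 1.0

    def test_six_of_ten_edited_reads(self, demo_ref):
        region = demo_ref.region_seq
        i18 = demo_ref.offset_to_region_index(-18)
        i19 = demo_ref.offset_to_region_index(-19)
        single = region[:i18] + "T" + region[i18 + 1:]
        double = single[:i19] + "T" + single[i19 + 1:]
        dist = product_distribution(region_set([single] * 6 + [double] * 4),
                                    demo_ref, demo_ref.target_cytidines())
        assert single_edit_fraction(dist, -18) == pytest.approx(0.6)

    def test_na_with_no_edited_reads(self, demo_ref):
        dist = product_distribution(region_set([demo_ref.region_seq] * 2),
                                    demo_ref, demo_ref.target_cytidines())
        assert single_edit_fraction(dist, -18) is None

    def test_higher_co_editing_lowers_single_edit_fraction(self, demo_ref):
        fracs = []
        for co in (0.05, 0.5, 0.95):
            prof = EditorProfile(0.8, {-18: 0.9, -19: co, -16: co})
            rs, _ = simulate_reads(demo_ref, prof, 3000, seed=8)
            regs = extract_regions(rs, demo_ref)
            dist = product_distribution(regs, demo_ref, demo_ref.target_cytidines())
            fracs.append(single_edit_fraction(dist, -18))
        assert fracs[0] > fracs[1] > fracs[2]


class TestPurity:
    def _dist_and_matrix(self, demo_ref, regions):
        regs = region_set(regions)
        m = conversion_matrix(regs, demo_ref)
        d = product_distribution(regs, demo_ref, demo_ref.target_cytidines())
        return m, d

    def test_pure_c_to_t_has_zero_non_t(self, demo_ref):
        region = demo_ref.region_seq
        i = demo_ref.offset_to_region_index(-18)
        single = region[:i] + "T" + region[i + 1:]
        m, d = self._dist_and_matrix(demo_ref, [single] * 5 + [region] * 5)
        out = purity_summary(m, d, demo_ref.target_cytidines())
        assert out.nonT_edited_read_fraction == 0.0

    def test_one_of_ten_edited_reads_carries_g(self, demo_ref):
        region = demo_ref.region_seq
        i = demo_ref.offset_to_region_index(-18)
        t_read = region[:i] + "T" + region[i + 1:]
        g_read = region[:i] + "G" + region[i + 1:]
        m, d = self._dist_and_matrix(demo_ref, [t_read] * 9 + [g_read])
        out = purity_summary(m, d, demo_ref.target_cytidines())
        assert out.nonT_edited_read_fraction == pytest.approx(0.1)
        row = out.per_position.set_index("offset").loc[-18]
        assert row["frac_C_to_G"] == pytest.approx(0.1)
        assert row["frac_C_to_T"] == pytest.approx(0.9)

    def test_recovers_simulated_impurity(self, demo_ref):
        rho, n = 0.1, 20_000
        prof = EditorProfile(1.0, {-18: 1.0}, purity_rho=rho)
        rs, _ = simulate_reads(demo_ref, prof, n, seed=6)
        regs = extract_regions(rs, demo_ref)
        m = conversion_matrix(regs, demo_ref)
        d = product_distribution(regs, demo_ref, demo_ref.target_cytidines())
        out = purity_summary(m, d, demo_ref.target_cytidines())
        sd = (rho * (1 - rho) / n) ** 0.5
        assert abs(out.nonT_edited_read_fraction - rho) < 3 * sd
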
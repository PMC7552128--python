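"""Mean-square Fst estimator vs direct-formula oracle; matrices and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedscan import (
    MISSING,
    FstMatrix,
    all_pairs_fst,
    breed_mean_pairwise,
    matrix_extremes,
    multilocus_fst,
    simulate_panel,
    snp_pair_fst,
    SimConfig,
)
from conftest import build_panel

# -- independent oracle: scalar evaluation of the mean-square formulas -------


def fst_oracle(genos_i, genos_j):
    """Direct evaluation of MSP, MSG, n_c and Fst from genotype counts,
    written with plain Python floats (no shared code with the package)."""
    counts = []
    for genos in (genos_i, genos_j):
        called = [g for g in genos if g != MISSING]
        m = 2 * len(called)
        p = sum(called) / m if m else float("nan")
        counts.append((m, p))
    (m1, p1), (m2, p2) = counts
    M = m1 + m2
    p_bar = (m1 * p1 + m2 * p2) / M
    msp = m1 * (p1 - p_bar) ** 2 + m2 * (p2 - p_bar) ** 2
    msg = (m1 * p1 * (1 - p1) + m2 * p2 * (1 - p2)) / (m1 - 1 + m2 - 1)
    nc = M - (m1 * m1 + m2 * m2) / M
    denom = msp + (nc - 1) * msg
    if denom == 0:
        return msg, msp, nc, None
    return msg, msp, nc, (msp - msg) / denom


def genotypes_from_counts(n0, n1, n2):
    return [0] * n0 + [1] * n1 + [2] * n2


def test_fixed_difference_gives_exactly_one():
    comp = snp_pair_fst([2] * 10, [0] * 10)
    assert comp.defined
    assert comp.fst == 1.0
    assert comp.msg == 0.0 and comp.msp > 0.0


def test_shared_monomorphism_is_undefined():
    comp = snp_pair_fst([2] * 8, [2] * 8)
    assert not comp.defined
    assert "monomorphic" in comp.reason


def test_equal_frequencies_give_negative_bound():
    """Both samples at p = 0.5 with 20 diploids each: MSP = 0 forces
    Fst = -1/(n_c - 1) with n_c = 40."""
    comp = snp_pair_fst([1] * 20, [1] * 20)
    assert comp.nc == pytest.approx(40.0)
    assert comp.fst == pytest.approx(-1 / 39)


def test_hand_worked_example():
    comp = snp_pair_fst([2, 2, 1, 0], [0, 0, 0, 1])
    assert comp.msp == pytest.approx(1.0)
    assert comp.msg == pytest.approx(2.75 / 14)
    assert comp.nc == pytest.approx(8.0)
    assert comp.fst == pytest.approx(0.3383458646616541)


def test_too_few_genotypes_is_undefined_with_reason():
    comp = snp_pair_fst([2, MISSING, MISSING, MISSING], [0, 0, 0, 0])
    assert not comp.defined
    assert "< 2 non-missing" in comp.reason


def test_exhaustive_small_instances_match_oracle():
    """All genotype-count configurations with 2-4 samples per population."""
    checked = 0
    for n_i in range(2, 5):
        for n_j in range(2, 5):
            cfgs_i = [
                (a, b, n_i - a - b)
                for a in range(n_i + 1)
                for b in range(n_i + 1 - a)
            ]
            cfgs_j = [
                (a, b, n_j - a - b)
                for a in range(n_j + 1)
                for b in range(n_j + 1 - a)
            ]
            for ci, cj in itertools.product(cfgs_i, cfgs_j):
                gi = genotypes_from_counts(*ci)
                gj = genotypes_from_counts(*cj)
                comp = snp_pair_fst(gi, gj)
                msg, msp, nc, fst = fst_oracle(gi, gj)
                assert comp.msg == pytest.approx(msg, abs=1e-12)
                assert comp.msp == pytest.approx(msp, abs=1e-12)
                assert comp.nc == pytest.approx(nc, abs=1e-12)
                if fst is None:
                    assert not comp.defined
                else:
                    assert comp.defined
                    assert comp.fst == pytest.approx(fst, abs=1e-12)
                    assert comp.fst <= 1.0
                checked += 1
    assert checked == 31 * 31  # sum over n of C(n+2, 2) configurations, squared


@settings(deadline=None, max_examples=150, derandomize=True)
@given(
    gi=st.lists(st.integers(0, 2), min_size=2, max_size=12),
    gj=st.lists(st.integers(0, 2), min_size=2, max_size=12),
    seed=st.integers(0, 10_000),
)
def test_permutation_and_relabeling_invariance(gi, gj, seed):
    base = snp_pair_fst(gi, gj)
    rng = np.random.default_rng(seed)
    perm = snp_pair_fst(rng.permutation(gi), rng.permutation(gj))
    swapped = snp_pair_fst(gj, gi)
    relabeled = snp_pair_fst([2 - g for g in gi], [2 - g for g in gj])
    for other in (perm, swapped, relabeled):
        assert other.defined == base.defined
        if base.defined:
            assert other.fst == pytest.approx(base.fst, abs=1e-12)


def test_all_pairs_has_choose_two_pairs(default_sim):
    panel, _ = default_sim
    table = all_pairs_fst(panel.subset_snps(np.arange(100)))
    assert len(table.pairs) == 6  # C(4, 2)
    assert table.pair_names == sorted(table.pairs)


def test_pair_values_independent_of_other_breeds(default_sim):
    panel, _ = default_sim
    sub = panel.subset_snps(np.arange(200))
    full = all_pairs_fst(sub)
    two = all_pairs_fst(sub.subset_breeds(["POP1", "POP2"]))
    pd.testing.assert_frame_equal(
        full.pairs[("POP1", "POP2")], two.pairs[("POP1", "POP2")]
    )


def test_all_pairs_rejects_singleton_breed():
    panel = build_panel({"B1": [[0, 1], [1, 2]], "B2": [[2, 0]]})
    with pytest.raises(ValueError, match="B2"):
        all_pairs_fst(panel)


def test_null_panel_mean_pair_fst_in_sampling_band():
    cfg = SimConfig(
        n_pops=2,
        samples_per_pop=[16, 16],
        n_snps=2000,
        n_chromosomes=2,
        chrom_length_bp=10_000_000,
        baseline_F=[0.02, 0.02],
        n_selected=0,
        missing_rate=0.0,
        seed=21,
    )
    panel, _ = simulate_panel(cfg)
    table = all_pairs_fst(panel)
    mean_fst = np.nanmean(table.fst_frame().iloc[:, 0])
    assert 0.005 <= mean_fst <= 0.04


def test_multilocus_is_ratio_of_sums():
    """5-SNP toy table: the combined estimate equals the spreadsheet ratio
    of summed numerators over summed denominators, not the mean of ratios."""
    rng = np.random.default_rng(3)
    geno_i = rng.binomial(2, 0.8, size=(6, 5))
    geno_j = rng.binomial(2, 0.2, size=(6, 5))
    panel = build_panel({"B1": geno_i, "B2": geno_j})
    table = all_pairs_fst(panel)
    matrix = multilocus_fst(table)
    num = den = 0.0
    for snp in range(5):
        msg, msp, nc, _ = fst_oracle(geno_i[:, snp], geno_j[:, snp])
        num += msp - msg
        den += msp + (nc - 1) * msg
    assert matrix.raw.loc["B1", "B2"] == pytest.approx(num / den)


def test_multilocus_single_snp_degenerates_to_that_snp():
    panel = build_panel({"B1": [[2], [2], [1], [0]], "B2": [[0], [0], [0], [1]]})
    table = all_pairs_fst(panel)
    matrix = multilocus_fst(table)
    assert matrix.raw.loc["B1", "B2"] == pytest.approx(0.3383458646616541)


def test_multilocus_identical_components_equals_per_snp_value():
    panel = build_panel({"B1": [[2, 2, 2], [1, 1, 1], [0, 0, 0]], "B2": [[0, 0, 0], [0, 0, 0], [1, 1, 1]]})
    table = all_pairs_fst(panel)
    per_snp = table.pairs[("B1", "B2")]["fst"]
    assert per_snp.nunique() == 1
    assert multilocus_fst(table).raw.loc["B1", "B2"] == pytest.approx(per_snp[0])


def test_fixed_difference_everywhere_saturates_linearization():
    panel = build_panel({"B1": [[2, 2], [2, 2]], "B2": [[0, 0], [0, 0]]})
    matrix = multilocus_fst(all_pairs_fst(panel))
    assert matrix.raw.loc["B1", "B2"] == 1.0
    assert np.isinf(matrix.linearized.loc["B1", "B2"])
    assert ("B1", "B2") in matrix.saturated_pairs


def test_matrix_symmetry_and_zero_diagonal(default_sim):
    panel, _ = default_sim
    matrix = multilocus_fst(all_pairs_fst(panel.subset_snps(np.arange(300))))
    np.testing.assert_allclose(matrix.raw.to_numpy(), matrix.raw.to_numpy().T)
    assert (np.diag(matrix.raw.to_numpy()) == 0).all()


def test_breed_mean_pairwise_mean_identity():
    matrix = FstMatrix.from_linearized(
        {("A", "B"): 0.02, ("A", "C"): 0.02, ("B", "C"): 0.02}
    )
    unrounded, rounded = breed_mean_pairwise(matrix, "A")
    assert unrounded == pytest.approx(0.02)
    assert rounded == 0.02
    with pytest.raises(KeyError):
        breed_mean_pairwise(matrix, "ZZZ")


def test_from_linearized_requires_all_pairs():
    with pytest.raises(ValueError, match="missing pairwise"):
        FstMatrix.from_linearized({("A", "B"): 0.1, ("A", "C"): 0.2})


def test_matrix_extremes_returns_min_and_max_cells():
    matrix = FstMatrix.from_linearized(
        {("A", "B"): 0.05, ("A", "C"): 0.01, ("B", "C"): 0.09}
    )
    (min_pair, min_v), (max_pair, max_v) = matrix_extremes(matrix)
    assert (min_pair, min_v) == (("A", "C"), 0.01)
    assert (max_pair, max_v) == (("B", "C"), 0.09)
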
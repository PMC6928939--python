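"""QC filters against fixtures with planted defects and exact oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtmod import (
    DefectSpec,
    QcThresholds,
    call_rates,
    hwe_exact_p,
    ibd_exclusions,
    inject_defects,
    ld_prune,
    relatedness,
    run_qc,
    sex_check,
    simulate_genotypes,
    variant_filters,
)
from qtmod.containers import GenotypeMatrix


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact big-integer enumeration of the HWE conditional distribution.

    Weights are integer multiples of the conditional probabilities
    (multinomial coefficient times 2^het), so the two-sided p-value is
    an exact rational, independent of the log-factorial route.
    """
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    rare = min(nA, 2 * n - nA)
    hets = list(range(rare % 2, rare + 1, 2))
    ws = []
    for h in hets:
        hr = (rare - h) // 2
        ws.append(math.comb(n, hr) * math.comb(n - hr, h) * (2**h))
    tot = sum(ws)
    w_obs = ws[hets.index(n_Aa)]
    return sum(w for w in ws if w <= w_obs) / tot


def make_matrix(dosages, sexes=None, chroms=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chroms = chroms or ["1"] * m
    return GenotypeMatrix(
        dosages,
        variant_meta=pd.DataFrame(
            {
                "snp": [f"v{j}" for j in range(m)],
                "chrom": chroms,
                "pos": np.arange(1, m + 1) * 1000,
                "a1": "A",
                "a2": "B",
                "is_x": [c == "X" for c in chroms],
            }
        ),
        sample_meta=pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(n)],
                "reported_sex": sexes or ["F"] * n,
            }
        ),
    )


class TestCallRates:
    def test_complete_matrix_is_all_ones(self, small_geno):
        cr_s, cr_v = call_rates(small_geno)
        assert np.all(cr_s == 1.0) and np.all(cr_v == 1.0)

    def test_boundary_rate_is_inclusive(self):
        # 10 missing of 100 variants -> rate exactly 0.90, kept at >= 0.90
        d = np.ones((4, 100))
        d[0, :10] = np.nan
        G = make_matrix(d)
        cr_s, _ = call_rates(G)
        assert cr_s[0] == pytest.approx(0.90)
        _, report = run_qc_samples_only(G)
        assert "s0" not in report

    def test_planted_missingness_removed(self, small_geno):
        sid = small_geno.sample_ids.iloc[2]
        bad = inject_defects(
            small_geno, DefectSpec(missing_rate_samples={sid: 0.25}), seed=5
        )
        _, rep = run_qc(bad)
        removed = rep.removed_samples
        assert sid in set(removed.loc[removed["reason"] == "call_rate", "sample"])


def run_qc_samples_only(G):
    """Call-rate sample filter in isolation, for boundary checks."""
    cr_s, _ = call_rates(G)
    removed = [s for s, r in zip(G.sample_ids, cr_s) if r < 0.90]
    return G, removed


class TestSexCheck:
    def test_homozygous_x_reported_male_unflagged(self):
        d = np.array([[0, 2, 0, 2]] * 3, dtype=float)
        G = make_matrix(d, sexes=["M", "M", "M"], chroms=["X"] * 4)
        assert not sex_check(G)["mismatch"].any()

    def test_homozygous_x_reported_female_flagged(self):
        d = np.array([[0, 2, 0, 2]] * 3, dtype=float)
        G = make_matrix(d, sexes=["F", "F", "F"], chroms=["X"] * 4)
        assert sex_check(G)["mismatch"].all()

    def test_flipped_samples_exactly_flagged(self, small_geno):
        flips = list(small_geno.sample_ids.iloc[[5, 17]])
        bad = inject_defects(small_geno, DefectSpec(sex_flip_samples=flips), seed=6)
        sx = sex_check(bad)
        assert set(sx.loc[sx["mismatch"], "sample"]) == set(flips)

    def test_requires_x_variants(self):
        G = make_matrix(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="X-flagged"):
            sex_check(G)


class TestHweExact:
    @given(
        st.integers(min_value=0, max_value=80),
        st.integers(min_value=0, max_value=80),
        st.integers(min_value=0, max_value=80),
    )
    @settings(max_examples=200, deadline=None)
    def test_allele_label_symmetry(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_p(a, h, b) == pytest.approx(hwe_exact_p(b, h, a), rel=1e-12)

    def test_extreme_table_fails_threshold(self):
        assert hwe_exact_p(50, 0, 50) < 5e-7

    def test_balanced_table_matches_enumeration(self):
        assert hwe_exact_p(25, 50, 25) == pytest.approx(
            hwe_enumeration_oracle(25, 50, 25), rel=1e-12
        )

    @given(
        st.integers(min_value=1, max_value=120),
        st.integers(min_value=0, max_value=240),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, n, nA):
        nA = min(nA, 2 * n)
        rare = min(nA, 2 * n - nA)
        # pick the most extreme table of the class: all-rare-homozygote
        n_Aa = rare % 2
        n_aa = (rare - n_Aa) // 2
        n_AA = n - n_Aa - n_aa
        assert hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(
            hwe_enumeration_oracle(n_AA, n_Aa, n_aa), rel=1e-9
        )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


class TestRelatedness:
    def test_duplicate_pair_near_one(self, small_geno):
        s1, s2 = small_geno.sample_ids.iloc[0], small_geno.sample_ids.iloc[1]
        dup = inject_defects(small_geno, DefectSpec(duplicate_pairs=[(s1, s2)]), seed=8)
        pairs = relatedness(dup)
        row = pairs[(pairs["sample1"] == s1) & (pairs["sample2"] == s2)]
        assert abs(float(row["pi_hat"].iloc[0]) - 1.0) < 0.05

    def test_unrelated_mean_near_zero(self):
        G = simulate_genotypes(200, 1000, (0.1, 0.5), seed=9, x_fraction=0.0)
        pairs = relatedness(G)
        assert abs(pairs["pi_hat"].mean()) < 0.05

    def test_one_member_of_duplicate_pair_removed(self, small_geno):
        s1, s2 = small_geno.sample_ids.iloc[0], small_geno.sample_ids.iloc[1]
        dup = inject_defects(small_geno, DefectSpec(duplicate_pairs=[(s1, s2)]), seed=8)
        removed = ibd_exclusions(dup, relatedness(dup))
        assert len(set(removed) & {s1, s2}) == 1

    def test_few_variants_warns(self):
        G = simulate_genotypes(10, 20, (0.2, 0.5), seed=10, x_fraction=0.0)
        with pytest.warns(UserWarning, match="unreliable"):
            relatedness(G)


class TestVariantFilters:
    def test_maf_boundary_inclusive(self):
        # 100 samples: MAF 0.09 removed, exactly 0.10 kept
        col_low = np.array([1.0] * 18 + [0.0] * 82)  # maf 0.09
        col_ok = np.array([1.0] * 20 + [0.0] * 80)  # maf 0.10
        G = make_matrix(np.column_stack([col_low, col_ok]))
        kept, removed = variant_filters(G)
        assert list(kept) == ["v1"]
        assert removed.iloc[0].tolist() == ["v0", "maf"]

    def test_clean_matrix_fully_retained(self):
        G = simulate_genotypes(500, 300, (0.15, 0.5), seed=11, x_fraction=0.0)
        kept, removed = variant_filters(G)
        assert len(removed) == 0 and len(kept) == 300

    def test_planted_defects_exactly_removed(self):
        G = simulate_genotypes(200, 120, (0.2, 0.5), seed=12, x_fraction=0.0)
        ids = list(G.variant_ids)
        d = DefectSpec(
            hwe_violation_snps=[(ids[3], (100, 0, 100))],
            low_maf_snps=[(ids[7], 0.02)],
            missing_rate_snps={ids[11]: 0.3},
        )
        bad = inject_defects(G, d, seed=13)
        kept, removed = variant_filters(bad)
        assert set(removed["snp"]) == {ids[3], ids[7], ids[11]}
        reasons = dict(zip(removed["snp"], removed["reason"]))
        assert reasons[ids[3]] == "hwe"
        assert reasons[ids[11]] == "call_rate"


def ld_prune_bruteforce(G, r2_max=0.8):
    """Single-window greedy oracle: recompute correlations pair by pair."""
    maf = G.maf()
    pos = G.variant_meta["pos"].to_numpy()
    alive = list(range(G.n_variants))
    changed = True
    while changed:
        changed = False
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                a, b = alive[ai], alive[bi]
                xa, xb = G.dosages[:, a], G.dosages[:, b]
                ok = ~np.isnan(xa) & ~np.isnan(xb)
                if ok.sum() < 2 or xa[ok].std() == 0 or xb[ok].std() == 0:
                    continue
                r = float(np.corrcoef(xa[ok], xb[ok])[0, 1])
                if r * r > r2_max:
                    if maf[a] < maf[b]:
                        drop = a
                    elif maf[b] < maf[a]:
                        drop = b
                    else:
                        drop = a if pos[a] > pos[b] else b
                    alive.remove(drop)
                    changed = True
                    break
            if changed:
                break
    return [G.variant_ids.iloc[j] for j in alive]


class TestLdPrune:
    def test_uncorrelated_variants_all_retained(self):
        G = simulate_genotypes(400, 80, (0.2, 0.5), seed=14, x_fraction=0.0)
        assert len(ld_prune(G)) == 80

    def test_duplicated_column_pruned_to_one(self):
        G = simulate_genotypes(100, 10, (0.3, 0.5), seed=15, x_fraction=0.0)
        d = np.column_stack([G.dosages, G.dosages[:, 0]])
        dup = make_matrix(d)
        kept = ld_prune(dup)
        assert ("v0" in kept) != ("v10" in kept)

    @staticmethod
    def _one_chromosome(G):
        """Collapse the variant map to a single chromosome, keeping order."""
        vm = G.variant_meta.copy()
        vm["chrom"] = "1"
        vm["pos"] = np.arange(1, len(vm) + 1) * 1000
        return GenotypeMatrix(G.dosages.copy(), vm, G.sample_meta.copy())

    def test_block_fixture_matches_bruteforce_oracle(self):
        # one chromosome of 200 variants in LD blocks; window spans all
        G = self._one_chromosome(
            simulate_genotypes(
                300, 200, (0.1, 0.5), n_ld_blocks=8, ld_block_size=25,
                ld_copy_prob=0.95, seed=16, x_fraction=0.0,
            )
        )
        mine = ld_prune(G, window=200, step=5, r2_max=0.8)
        oracle = ld_prune_bruteforce(G, r2_max=0.8)
        assert mine == oracle

    def test_no_retained_pair_exceeds_cap_within_window(self):
        G = self._one_chromosome(
            simulate_genotypes(
                300, 150, (0.1, 0.5), n_ld_blocks=5, ld_block_size=25,
                ld_copy_prob=0.95, seed=17, x_fraction=0.0,
            )
        )
        kept = ld_prune(G, window=50, step=5, r2_max=0.8)
        idx = G.variant_index(kept)
        for start in range(0, len(idx), 5):
            win = idx[start : start + 50]
            if len(win) < 2:
                continue
            r = np.corrcoef(G.dosages[:, win].T)
            np.fill_diagonal(r, 0.0)
            assert (r**2).max() <= 0.8 + 1e-12


class TestRunQc:
    def test_defect_laden_matrix_cleaned_with_reasons(self, small_geno):
        ids = list(small_geno.variant_ids)
        sids = list(small_geno.sample_ids)
        # duplicate within one reported sex, so the copy's X genotypes stay
        # concordant and the pair reaches the IBD stage
        sex = small_geno.sample_meta["reported_sex"]
        fem = [s for s, x in zip(sids, sex) if x == "F" and s not in (sids[0], sids[3])]
        dup_pair = (fem[1], fem[2])
        d = DefectSpec(
            missing_rate_samples={sids[0]: 0.3},
            duplicate_pairs=[dup_pair],
            sex_flip_samples=[sids[3]],
            hwe_violation_snps=[(ids[5], (60, 0, 60))],
            low_maf_snps=[(ids[9], 0.02)],
        )
        bad = inject_defects(small_geno, d, seed=18)
        G_qc, rep = run_qc(bad)
        reasons = dict(zip(rep.removed_samples["sample"], rep.removed_samples["reason"]))
        assert reasons[sids[0]] == "call_rate"
        assert reasons[sids[3]] == "sex_mismatch"
        assert sum(1 for s in dup_pair if reasons.get(s) == "ibd") == 1
        v_reasons = dict(zip(rep.removed_variants["snp"], rep.removed_variants["reason"]))
        assert v_reasons[ids[5]] == "hwe"
        assert v_reasons[ids[9]] == "maf"

    def test_idempotent_on_clean_output(self, small_geno):
        G1, _ = run_qc(small_geno)
        G2, rep2 = run_qc(G1)
        assert len(rep2.removed_samples) == 0
        assert len(rep2.removed_variants) == 0
        assert np.array_equal(G1.dosages, G2.dosages, equal_nan=True)

    def test_clean_simulated_data_passes_all_filters(self):
        G = simulate_genotypes(500, 1000, (0.12, 0.5), seed=19)
        G_qc, rep = run_qc(G)
        assert G_qc.n_samples == 500
        # only chance MAF drift below 0.10 may remove a handful
        assert len(rep.removed_samples) == 0
        assert len(rep.removed_variants) < 20
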
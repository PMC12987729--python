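"""Profiler unit and property tests: read-pair rules, NB quantile bounds,
abundance filtering rules, rarefaction and diversity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microgwas.profiling import (
    FLAG_MEDIAN_FALLBACK,
    AlignmentRecord,
    Read,
    alpha_diversity,
    classify_read_pairs,
    estimate_abundances,
    ko_profile,
    nb_gene_bounds,
    rarefy_counts,
)
from microgwas.synthetic_data import SimConfig, generate_catalog, generate_counts, generate_truth

from conftest import toy_catalog


# ---------------------------------------------------------------------------
# Read-pair classification
# ---------------------------------------------------------------------------

def _oracle_read_status(mapq, identity, length, unaligned, has_gene=True):
    """Direct evaluation of the stated mapping predicate."""
    aligned = identity >= 0.95 and length >= 100 and unaligned <= 10
    if not aligned:
        return "unmapped"
    return "unique" if (mapq >= 20 and has_gene) else "multi"


def _oracle_pair(s1, s2):
    if "unique" in (s1, s2):
        return "unique"
    if "multi" in (s1, s2):
        return "multi"
    return "unmapped"


class TestReadPairClassification:
    def test_single_unique_read_counts_its_gene(self):
        rec = AlignmentRecord(
            Read(mapq=30, identity=0.96, aligned_length=120, unaligned_bases=5, gene_id="gA"),
            Read(mapq=0, identity=0.5, aligned_length=50, unaligned_bases=40, gene_id=None),
        )
        labels, counts = classify_read_pairs([rec])
        assert labels == ["unique"]
        assert counts == {"gA": 1}

    def test_both_unmapped_pair_unmapped(self):
        bad = Read(mapq=60, identity=0.80, aligned_length=150, unaligned_bases=0, gene_id="gA")
        labels, counts = classify_read_pairs([AlignmentRecord(bad, bad)])
        assert labels == ["unmapped"]
        assert counts == {}

    def test_two_unique_reads_to_different_genes_count_read_one(self):
        r1 = Read(mapq=40, identity=0.99, aligned_length=140, unaligned_bases=0, gene_id="g1")
        r2 = Read(mapq=40, identity=0.99, aligned_length=140, unaligned_bases=0, gene_id="g2")
        _, counts = classify_read_pairs([AlignmentRecord(r1, r2)])
        assert counts == {"g1": 1}

    def test_exhaustive_boundary_grid_matches_predicate_oracle(self):
        """Every boundary combination of (MAPQ, identity, length, unaligned)
        for both reads classifies exactly as the brute-force predicate."""
        grid = list(itertools.product([19, 20], [0.949, 0.95], [99, 100], [10, 11]))
        reads = [Read(m, i, l, u, gene_id="g") for m, i, l, u in grid]
        statuses = [_oracle_read_status(m, i, l, u) for m, i, l, u in grid]
        records, expected = [], []
        for (ra, sa), (rb, sb) in itertools.product(zip(reads, statuses), repeat=2):
            records.append(AlignmentRecord(ra, rb))
            expected.append(_oracle_pair(sa, sb))
        labels, _ = classify_read_pairs(records)
        assert labels == expected


# ---------------------------------------------------------------------------
# NB quantile bounds
# ---------------------------------------------------------------------------

class TestNbBounds:
    def test_zero_total_gives_zero_bounds(self):
        b = nb_gene_bounds(np.array([500.0, 900.0]), 0)
        assert (b.lower == 0).all() and (b.upper == 0).all()
        assert (b.p_nonzero == 0).all()

    def test_equal_lengths_give_identical_bounds(self):
        b = nb_gene_bounds(np.full(6, 1024.0), 600)
        assert len(set(b.lower)) == 1 and len(set(b.upper)) == 1

    def test_bounds_match_cdf_summation_oracle(self):
        """mu=10, size r=10 (two equal genes of effective length 1024,
        total 20): bounds must equal brute-force pmf accumulation."""
        L = np.array([1024.0, 1024.0])  # log2 -> exactly 10
        b = nb_gene_bounds(L, 20)
        r, mu = 10.0, 10.0
        p = r / (r + mu)
        cdf, k = 0.0, 0
        lower = upper = None
        while upper is None:
            cdf += stats.nbinom.pmf(k, r, p)
            if lower is None and cdf >= 0.005:
                lower = k
            if cdf >= 0.995:
                upper = k
            k += 1
        assert b.lower[0] == lower and b.upper[0] == upper
        assert abs(b.p_nonzero[0] - (1 - stats.nbinom.pmf(0, r, p))) < 1e-12

    def test_short_gene_size_clamped(self):
        b = nb_gene_bounds(np.array([1.0]), 10)  # log2(1) = 0 -> clamp to 1
        assert b.upper[0] >= b.lower[0] >= 0


# ---------------------------------------------------------------------------
# Abundance estimation rules
# ---------------------------------------------------------------------------

class TestAbundanceRules:
    def test_all_zero_counts_give_zero_abundance(self):
        catalog = toy_catalog(10, 1024.0)
        counts = pd.DataFrame(0, index=["s1"], columns=[f"g{i}" for i in range(10)])
        prof = estimate_abundances(counts, catalog)
        assert prof.abundance.loc["s1", "spX"] == 0

    def test_fewer_than_five_nonzero_admitted_genes_zeroes_species(self):
        # 5 equal genes, 4 non-zero within bounds, 1 zero: 4/5 >= 66% passes
        # the fraction rule, then the <5 rule zeroes the species
        catalog = toy_catalog(5, 1024.0)
        counts = pd.DataFrame([[10, 10, 10, 10, 0]], index=["s1"],
                              columns=[f"g{i}" for i in range(5)])
        b = nb_gene_bounds(np.full(5, 1024.0), 40)
        assert b.lower[0] <= 10 <= b.upper[0]  # the 4 counts really are in bounds
        prof = estimate_abundances(counts, catalog)
        assert prof.abundance.loc["s1", "spX"] == 0

    def test_profile_rows_sum_to_100(self, small_world):
        catalog, _, _, counts = small_world
        prof = estimate_abundances(counts, catalog)
        sums = prof.abundance.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)

    def test_recovery_of_true_compositions(self, small_world):
        """Under its own NB model with no outliers the profiler recovers
        every cell with true abundance >= 0.5% within 10% relative error."""
        catalog, _, truth, counts = small_world
        prof = estimate_abundances(counts, catalog)
        est = prof.abundance.to_numpy() / 100.0
        true = truth.true_compositions.to_numpy()
        mask = true >= 0.005
        rel = np.abs(est[mask] - true[mask]) / true[mask]
        assert rel.max() < 0.10

    def test_quantile_filter_calibration(self, small_world):
        """With no outliers the central-99% filter admits >= 97% of genes on
        average (it removes ~1% by construction)."""
        catalog, _, _, counts = small_world
        admitted, total = 0, 0
        sig = catalog.signature_genes()
        for sp in catalog.species_ids:
            genes = sig[sig["species_id"] == sp]
            L = genes["effective_length"].to_numpy(dtype=float)
            sub = counts[genes["gene_id"].tolist()].to_numpy()
            for row in sub:
                b = nb_gene_bounds(L, row.sum())
                admitted += int(((row >= b.lower) & (row <= b.upper)).sum())
                total += len(L)
        assert admitted / total >= 0.97

    def test_outlier_inflation_is_filtered_but_breaks_naive_mean(self, small_world):
        """Inflating 5% of one species' signature-gene cells 50-fold moves the
        filtered estimate < 15% relative; the unfiltered mean does not."""
        catalog, _, truth, counts = small_world
        sp = truth.true_compositions.mean(axis=0).idxmax()
        gids = catalog.signature_genes(sp)["gene_id"].tolist()
        rng = np.random.default_rng(21)
        inflated = counts.copy()
        sub = inflated[gids].to_numpy()
        mask = rng.random(sub.shape) < 0.05
        inflated[gids] = np.where(mask, sub * 50, sub)

        clean = estimate_abundances(counts, catalog).abundance[sp].to_numpy()
        dirty = estimate_abundances(inflated, catalog).abundance[sp].to_numpy()
        assert np.abs(dirty / clean - 1).max() < 0.15

        def naive(tbl):
            out = {}
            sig = catalog.signature_genes()
            for s in catalog.species_ids:
                g = sig[sig["species_id"] == s]
                out[s] = (tbl[g["gene_id"].tolist()].to_numpy()
                          / g["effective_length"].to_numpy(dtype=float)).mean(axis=1)
            df = pd.DataFrame(out)
            return df.div(df.sum(axis=1), axis=0)[sp].to_numpy()

        assert np.abs(naive(inflated) / naive(counts) - 1).max() > 0.15

    def test_median_fallback_flagged(self):
        # a species whose bounds exclude most genes: half very high, half modest
        catalog = toy_catalog(10, 1024.0)
        row = [1000, 1000, 1000, 1000, 1000, 3, 3, 3, 3, 3]
        counts = pd.DataFrame([row], index=["s1"], columns=[f"g{i}" for i in range(10)])
        prof = estimate_abundances(counts, catalog)
        assert prof.flags.loc["s1", "spX"] == FLAG_MEDIAN_FALLBACK
        assert prof.abundance.loc["s1", "spX"] > 0


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny():
    catalog = toy_catalog(6, 1024.0)
    counts = pd.DataFrame(
        [[40, 30, 20, 10, 0, 0], [5, 5, 5, 5, 5, 5]],
        index=["s1", "s2"], columns=[f"g{i}" for i in range(6)],
    )
    return catalog, counts


class TestRarefaction:
    def test_target_equal_to_total_returns_input(self, tiny):
        catalog, counts = tiny
        res = rarefy_counts(counts.loc[["s1"]], catalog, target=100, seed=0)
        pd.testing.assert_frame_equal(res.rarefied_counts, counts.loc[["s1"]])

    def test_undersampled_samples_excluded(self, tiny):
        catalog, counts = tiny
        res = rarefy_counts(counts, catalog, target=50, seed=0)
        assert res.excluded_samples == ["s2"]
        assert list(res.rarefied_counts.index) == ["s1"]

    def test_richness_never_increases_under_rarefaction(self, small_world):
        catalog, _, _, counts = small_world
        sub = counts.iloc[:5]
        full = alpha_diversity(estimate_abundances(sub, catalog))
        res = rarefy_counts(sub, catalog, target=200_000, seed=3)
        rare = alpha_diversity(res.profile)
        for s in rare.index:
            assert rare.loc[s, "richness"] <= full.loc[s, "richness"]

    def test_expected_rarefied_count_is_hypergeometric_mean(self, tiny):
        catalog, counts = tiny
        row = counts.loc[["s1"]]
        total, target = 100, 30
        sums = np.zeros(6)
        for rep in range(1000):
            res = rarefy_counts(row, catalog, target=target, seed=rep)
            sums += res.rarefied_counts.iloc[0].to_numpy()
        mean = sums / 1000
        expect = target * row.iloc[0].to_numpy() / total
        # binomial-scale MC tolerance
        se = np.sqrt(np.maximum(expect * (1 - row.iloc[0].to_numpy() / total), 1e-9) / 1000)
        assert np.all(np.abs(mean - expect) < 4 * se + 0.2)

    def test_rarefaction_deterministic_under_seed(self, tiny):
        catalog, counts = tiny
        a = rarefy_counts(counts, catalog, target=30, seed=7).rarefied_counts
        b = rarefy_counts(counts, catalog, target=30, seed=7).rarefied_counts
        pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

class TestAlphaDiversity:
    def _profile(self, rows, species):
        from microgwas.profiling import SpeciesProfile, FLAG_OK
        ab = pd.DataFrame(rows, columns=species)
        return SpeciesProfile(ab, pd.DataFrame(FLAG_OK, index=ab.index, columns=ab.columns))

    def test_single_species_dominance(self):
        div = alpha_diversity(self._profile([[100.0, 0.0]], ["a", "b"]))
        assert div["shannon"].iloc[0] == 0
        assert div["richness"].iloc[0] == 1

    def test_uniform_eight_species(self):
        div = alpha_diversity(self._profile([[12.5] * 8], list("abcdefgh")))
        assert abs(div["shannon"].iloc[0] - np.log(8)) < 1e-12

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(40))
        div = alpha_diversity(self._profile([100 * p], [f"s{i}" for i in range(40)]))
        oracle = -sum(pi * np.log(pi) for pi in p if pi > 0)
        assert abs(div["shannon"].iloc[0] - oracle) < 1e-12
        assert div["shannon"].iloc[0] <= np.log(div["richness"].iloc[0])

    def test_empty_sample(self):
        div = alpha_diversity(self._profile([[0.0, 0.0]], ["a", "b"]))
        assert div["shannon"].iloc[0] == 0 and div["richness"].iloc[0] == 0


# ---------------------------------------------------------------------------
# KO profiles
# ---------------------------------------------------------------------------

class TestKoProfile:
    def test_three_gene_hand_example(self):
        catalog = toy_catalog(3, 1.0, kos=["KA", "KA", "KB"])
        catalog.genes.loc[:, "effective_length"] = [100.0, 200.0, 300.0]
        counts = pd.DataFrame([[10, 20, 30]], index=["s1"], columns=["g0", "g1", "g2"])
        kp = ko_profile(counts, catalog)
        assert abs(kp.loc["s1", "KA"] - 2 / 3) < 1e-12
        assert abs(kp.loc["s1", "KB"] - 1 / 3) < 1e-12

    def test_unannotated_abundance_dilutes_ko_sums(self):
        catalog = toy_catalog(2, 100.0, kos=["KA", ""])
        counts = pd.DataFrame([[10, 10]], index=["s1"], columns=["g0", "g1"])
        kp = ko_profile(counts, catalog)
        assert abs(kp.loc["s1", "KA"] - 0.5) < 1e-12

    def test_all_zero_sample_gives_zero_row(self):
        catalog = toy_catalog(2, 100.0, kos=["KA", "KB"])
        counts = pd.DataFrame([[0, 0]], index=["s1"], columns=["g0", "g1"])
        assert (ko_profile(counts, catalog).to_numpy() == 0).all()
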
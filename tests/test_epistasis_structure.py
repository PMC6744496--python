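"""Epistasis surfaces, matrices, periodicity kernels and contact maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prdscan import epistasis_structure as es


def _null_doubles(rng, n=5000, noise=0.05):
    t1 = rng.normal(0, 0.2, n)
    t2 = rng.normal(0, 0.2, n)
    return pd.DataFrame(
        {"t1_single": t1, "t2_single": t2,
         "toxicity": t1 + t2 + rng.normal(0, noise, n)}
    )


class TestExpectedSurface:
    def test_additive_doubles_give_additive_median(self):
        rng = np.random.default_rng(0)
        d = _null_doubles(rng, n=20_000, noise=0.05)
        surf = es.expected_double_surface(d, k_neighbors=300)
        dev = surf["p50"] - (surf["t1_single"] + surf["t2_single"])
        # in the well-populated centre of the (t1, t2) plane the local
        # median tracks additivity to within the noise SD; the sparse
        # tails have distant neighbourhoods and are not informative
        central = (
            surf["t1_single"].between(*np.quantile(surf["t1_single"], [0.05, 0.95]))
            & surf["t2_single"].between(*np.quantile(surf["t2_single"], [0.05, 0.95]))
        )
        assert np.abs(dev[central]).max() < 0.05
        assert np.abs(dev).median() < 0.01

    def test_symmetric_under_order_swap(self):
        rng = np.random.default_rng(1)
        d = _null_doubles(rng, n=2000)
        swapped = d.rename(
            columns={"t1_single": "t2_single", "t2_single": "t1_single"}
        )
        a = es.expected_double_surface(d, k_neighbors=100)
        b = es.expected_double_surface(swapped, k_neighbors=100)
        assert np.allclose(a["p05"], b["p05"])
        assert np.allclose(a["p95"], b["p95"])

    def test_constant_toxicity_degenerates_to_constant(self):
        rng = np.random.default_rng(2)
        d = _null_doubles(rng, n=500)
        d["toxicity"] = 0.7
        surf = es.expected_double_surface(d, k_neighbors=50)
        assert np.allclose(surf[["p05", "p50", "p95"]], 0.7)

    def test_k_larger_than_dataset_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="larger than dataset"):
            es.expected_double_surface(_null_doubles(rng, n=50), k_neighbors=500)


class TestClassification:
    def test_null_flag_rates_near_nominal(self):
        rng = np.random.default_rng(4)
        d = _null_doubles(rng, n=50_000, noise=0.05)
        surf = es.expected_double_surface(d, k_neighbors=250)
        flags = es.classify_epistasis(surf, range_limit_fraction=0.0)
        pos = (flags == "positive").mean()
        neg = (flags == "negative").mean()
        assert 0.03 < pos < 0.07
        assert 0.03 < neg < 0.07

    def test_double_at_median_is_none(self):
        surf = pd.DataFrame(
            {"toxicity": [0.5], "p05": [0.1], "p50": [0.5], "p95": [0.9]}
        )
        assert es.classify_epistasis(surf).iloc[0] == "none"

    def test_range_limit_doubles_excluded(self):
        surf = pd.DataFrame(
            {
                "toxicity": [0.0, 5.0, 10.0],
                "p05": [-1.0, 4.0, 9.0],
                "p50": [0.0, 5.0, 10.0],
                "p95": [1.0, 6.0, 11.0],
            }
        )
        flags = es.classify_epistasis(surf, range_limit_fraction=0.2)
        assert flags.iloc[0] == "excluded"
        assert flags.iloc[2] == "excluded"
        assert flags.iloc[1] == "none"

    def test_planted_couplings_enriched_among_flags(self):
        rng = np.random.default_rng(5)
        d = _null_doubles(rng, n=30_000, noise=0.05)
        coupled = np.zeros(len(d), dtype=bool)
        coupled[:1500] = True
        d.loc[coupled, "toxicity"] += 0.4
        surf = es.expected_double_surface(d, k_neighbors=250)
        flags = es.classify_epistasis(surf, range_limit_fraction=0.0)
        hit = flags.isin(["positive", "negative"]).to_numpy()
        table = [
            [int((hit & coupled).sum()), int((~hit & coupled).sum())],
            [int((hit & ~coupled).sum()), int((~hit & ~coupled).sum())],
        ]
        odds, p = stats.fisher_exact(table)
        assert odds > 1 and p < 0.01


class TestEnrichmentMatrix:
    def _doubles_with_flags(self, rng, n=4000, n_pos=10, flag_rate=0.1):
        p1 = rng.integers(0, n_pos - 1, n)
        p2 = p1 + rng.integers(1, n_pos - p1.clip(max=n_pos - 2))
        muts = [
            ((int(a) + 300, "G", "A"), (int(b) + 300, "N", "V"))
            for a, b in zip(p1, p2)
        ]
        doubles = pd.DataFrame({"mutations": muts})
        flags = pd.Series(
            np.where(rng.random(n) < flag_rate, "positive", "none")
        )
        return doubles, flags

    def test_uniform_flags_give_near_zero_enrichment(self):
        rng = np.random.default_rng(6)
        doubles, flags = self._doubles_with_flags(rng, n=40_000)
        E, counts, positions = es.pairwise_enrichment(doubles, flags)
        off = ~np.eye(len(positions), dtype=bool)
        vals = E[off & (counts > 100)]
        assert np.nanmean(np.abs(vals)) < 0.5
        assert abs(np.nanmean(vals)) < 0.1

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        doubles, flags = self._doubles_with_flags(rng)
        E, counts, _ = es.pairwise_enrichment(doubles, flags)
        assert np.allclose(E, E.T, equal_nan=True)
        assert np.allclose(counts, counts.T)

    def test_fully_flagged_pair_hits_corrected_maximum(self):
        doubles = pd.DataFrame(
            {"mutations": [((300, "G", "A"), (301, "N", "V"))] * 10
             + [((300, "G", "A"), (302, "S", "T"))] * 10}
        )
        flags = pd.Series(["positive"] * 10 + ["none"] * 10)
        E, counts, positions = es.pairwise_enrichment(doubles, flags)
        i, j = positions.index(300), positions.index(301)
        expected = np.log((10 + 0.5) / 0.5) - np.log(10.5 / 10.5)
        assert E[i, j] == pytest.approx(expected)


class TestDiagonalImputation:
    def test_column_mean_example(self):
        E = np.array(
            [[np.nan, 1.0, 2.0, 3.0],
             [1.0, np.nan, 4.0, 0.0],
             [2.0, 4.0, np.nan, 5.0],
             [3.0, 0.0, 5.0, np.nan]]
        )
        out = es.impute_diagonal(E)
        assert out[0, 0] == pytest.approx(2.0)

    def test_constant_matrix(self):
        E = np.full((4, 4), 3.0)
        np.fill_diagonal(E, np.nan)
        out = es.impute_diagonal(E)
        assert np.allclose(np.diag(out), 3.0)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(8)
        E = rng.normal(size=(6, 6))
        E = (E + E.T) / 2
        np.fill_diagonal(E, np.nan)
        out = es.impute_diagonal(E)
        assert np.allclose(out, out.T)


class TestPartialCorrelation:
    def test_three_variable_closed_form(self):
        R = np.array([[1.0, 0.8, 0.5], [0.8, 1.0, 0.5], [0.5, 0.5, 1.0]])
        C = es.partial_correlation_from_corr(R)
        assert C[0, 1] == pytest.approx((0.8 - 0.25) / 0.75, abs=1e-6)
        assert C[0, 1] == pytest.approx(0.733333, abs=1e-6)

    def test_independent_columns_give_near_zero(self):
        rng = np.random.default_rng(9)
        E = rng.normal(size=(500, 8))
        C = es.partial_correlation_matrix(E, shrinkage=None)
        off = ~np.eye(8, dtype=bool)
        assert np.abs(C[off]).max() < 0.2

    def test_transitive_chain_suppressed(self):
        """x -> z -> y with no direct link: pcorr(x,y|z) << corr(x,y)."""
        rng = np.random.default_rng(10)
        n = 2000
        z = rng.normal(size=n)
        x = z + rng.normal(0, 0.5, n)
        y = z + rng.normal(0, 0.5, n)
        E = np.column_stack([x, z, y])
        C = es.partial_correlation_matrix(E, shrinkage=None)
        marginal = np.corrcoef(x, y)[0, 1]
        assert abs(C[0, 2]) < abs(marginal) / 3

    def test_matrix_properties(self):
        rng = np.random.default_rng(11)
        E = rng.normal(size=(40, 40))
        E = (E + E.T) / 2
        C = es.partial_correlation_matrix(E)
        assert np.allclose(C, C.T, atol=1e-12)
        assert np.allclose(np.diag(C), 1.0)
        assert np.abs(C).max() <= 1.0


class TestKernels:
    def _helix_like_C(self, n=42, amp=1.0):
        """Similarity matrix carrying the helix signature: high where two
        positions share coupling partners under spacings {3, 4}."""
        C = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    C[i, j] = amp * es._spacing_autocorrelation((3, 4), i - j)
        np.fill_diagonal(C, 1.0)
        return C

    def _strand_like_C(self, n=42, amp=1.0):
        C = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    C[i, j] = amp * es._spacing_autocorrelation((2,), i - j)
        np.fill_diagonal(C, 1.0)
        return C

    def test_helix_signature_scores_helix_over_strand(self):
        C = self._helix_like_C()
        ph = np.nanmean(es.structure_propensity(C, "helix"))
        ps = np.nanmean(es.structure_propensity(C, "strand"))
        assert ph > 0
        assert ph > 2 * abs(ps)

    def test_strand_signature_scores_strand_over_helix(self):
        C = self._strand_like_C()
        ps = np.nanmean(es.structure_propensity(C, "strand"))
        ph = np.nanmean(es.structure_propensity(C, "helix"))
        assert ps > 0
        # the helix kernel anti-matches the strand signature
        assert ph < 0

    def test_random_matrix_propensities_fluctuate_around_zero(self):
        rng = np.random.default_rng(12)
        props = []
        for _ in range(30):
            C = rng.normal(size=(30, 30))
            C = (C + C.T) / 2
            props.append(np.nanmean(es.structure_propensity(C, "helix")))
        assert abs(np.mean(props)) < 3 * np.std(props) / np.sqrt(30) + 0.05

    def test_invariant_to_adding_constant(self):
        rng = np.random.default_rng(13)
        C = rng.normal(size=(25, 25))
        C = (C + C.T) / 2
        a = es.structure_propensity(C, "strand")
        b = es.structure_propensity(C + 5.0, "strand")
        assert np.allclose(a, b, atol=1e-9, equal_nan=True)

    def test_edge_positions_unavailable(self):
        C = np.eye(20)
        prop = es.structure_propensity(C, "helix", half_window=4)
        assert np.isnan(prop[:4]).all() and np.isnan(prop[-4:]).all()
        assert np.isfinite(prop[4:-4]).all()

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError):
            es.structure_propensity(np.eye(20), "coil")


class TestRandomization:
    def test_empirical_p_floor(self):
        """A propensity larger than every randomization hits 1/(N+1)."""
        C = TestKernels()._helix_like_C(amp=3.0)
        tracks = es.randomization_pvalues(
            C, list(range(C.shape[0])), kernels=("helix",), n_rand=200, seed=0
        )
        p = tracks["helix"].pvalue
        assert np.nanmin(p) == pytest.approx(1 / 201)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(14)
        pvals = []
        for i in range(4):
            C = rng.normal(size=(30, 30))
            C = (C + C.T) / 2
            np.fill_diagonal(C, 1.0)
            tracks = es.randomization_pvalues(
                C, list(range(30)), kernels=("strand",), n_rand=499,
                seed=100 + i,
            )
            p = tracks["strand"].pvalue
            pvals.extend(p[np.isfinite(p)].tolist())
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_minimum_randomizations_enforced(self):
        with pytest.raises(ValueError):
            es.randomization_pvalues(np.eye(20), range(20), n_rand=10)


def _write_pdb(path, residues):
    """Minimal synthetic PDB writer for contact-map tests."""
    lines = []
    serial = 1
    for resname, resseq, atoms in residues:
        for name, x, y, z, element in atoms:
            lines.append(
                f"ATOM  {serial:5d} {(' ' + name).ljust(4)} {resname:>3s} "
                f"A{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


class TestContactMap:
    def _structure(self, tmp_path, gap):
        """Three residues: 1-2 side chains at 4.0 A, 2-3 at ``gap`` A."""
        path = tmp_path / "synthetic.pdb"
        _write_pdb(
            path,
            [
                ("ALA", 1, [("N", 0, 0, 0, "N"), ("CA", 1, 0, 0, "C"),
                            ("C", 2, 0, 0, "C"), ("O", 3, 0, 0, "O"),
                            ("CB", 0, 1, 0, "C")]),
                ("VAL", 2, [("N", 10, 0, 0, "N"), ("CA", 11, 0, 0, "C"),
                            ("C", 12, 0, 0, "C"), ("O", 13, 0, 0, "O"),
                            ("CB", 0, 5, 0, "C")]),
                ("GLY", 3, [("N", 20, 0, 0, "N"),
                            ("CA", 0, 5 + gap, 0, "C"),
                            ("C", 22, 0, 0, "C"), ("O", 23, 0, 0, "O")]),
            ],
        )
        return path

    def test_hand_computed_contacts(self, tmp_path):
        # CB(1)-CB(2) distance 4.0 -> contact; CB(2)-CA(3) 4.0 -> contact
        # via the glycine fallback; CB(1)-CA(3) 8.0 -> none
        path = self._structure(tmp_path, gap=4.0)
        cmap = es.pdb_contact_map(path, "A", (1, 3), threshold=4.5)
        binary = (cmap.matrix > 0).astype(int)
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert np.array_equal(binary, expected)

    def test_above_threshold_is_no_contact(self, tmp_path):
        path = self._structure(tmp_path, gap=5.0)
        cmap = es.pdb_contact_map(path, "A", (1, 3), threshold=4.5)
        assert cmap.matrix[1, 2] < 0  # only the zero-sum offset remains

    def test_zero_sum_normalization_and_zero_diagonal(self, tmp_path):
        path = self._structure(tmp_path, gap=4.0)
        cmap = es.pdb_contact_map(path, "A", (1, 3))
        assert cmap.matrix.sum() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.diag(cmap.matrix), 0.0)

    def test_missing_residue_reported(self, tmp_path):
        path = self._structure(tmp_path, gap=4.0)
        with pytest.raises(ValueError, match=r"\[4\]"):
            es.pdb_contact_map(path, "A", (1, 4))


class TestLarksPropensity:
    def _contact_map(self, n=6, seed=15):
        rng = np.random.default_rng(seed)
        M = (rng.random((n, n)) < 0.3).astype(float)
        M = np.triu(M, 1)
        M = M + M.T
        off = ~np.eye(n, dtype=bool)
        M[off] -= M[off].mean()
        return es.ContactMap(
            positions=tuple(range(312, 312 + n)), matrix=M,
            threshold=4.5, source="synthetic",
        )

    def test_perfect_agreement_scores_max_with_min_p(self):
        cmap = self._contact_map()
        n_all = 20
        C = np.zeros((n_all, n_all))
        idx = [p - 300 for p in cmap.positions]
        C[np.ix_(idx, idx)] = cmap.matrix
        positions = list(range(300, 300 + n_all))
        score, p = es.larks_propensity(C, positions, cmap, n_rand=500, seed=1)
        assert score > 0
        # no within-window permutation can beat the identity arrangement
        assert p < 0.05

    def test_uncorrelated_scores_near_zero(self):
        rng = np.random.default_rng(16)
        cmap = self._contact_map()
        scores, ps = [], []
        for i in range(10):
            C = rng.normal(size=(20, 20))
            C = (C + C.T) / 2
            s, p = es.larks_propensity(
                C, list(range(300, 320)), cmap, n_rand=200, seed=i
            )
            scores.append(s)
            ps.append(p)
        assert abs(np.mean(scores)) < np.std(scores)
        assert 0.1 < np.mean(ps) < 0.9

    def test_window_outside_coverage_rejected(self):
        cmap = self._contact_map()
        with pytest.raises(ValueError):
            es.larks_propensity(np.eye(5), list(range(5)), cmap)


class TestTopContacts:
    def test_k_zero_gives_empty_list(self):
        C = np.eye(5)
        assert es.top_contacts(C, list(range(5)), (0, 4), k=0) == []

    def test_known_ordering(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.9
        C[2, 3] = C[3, 2] = 0.7
        C[0, 3] = C[3, 0] = 0.8
        top = es.top_contacts(C, [310, 311, 312, 313], (310, 313), k=2)
        assert top == [(310, 311, 0.9), (310, 313, 0.8)]

    def test_upper_triangle_only(self):
        rng = np.random.default_rng(17)
        C = rng.random((6, 6))
        C = (C + C.T) / 2
        top = es.top_contacts(C, list(range(6)), (0, 5), k=100)
        pairs = [(a, b) for a, b, _ in top]
        assert len(pairs) == len(set(pairs)) == 15
        assert all(a < b for a, b in pairs)
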
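"""Kernel constructions, scaling constants and marker design matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asvlmm import (
    DegenerateKernelError,
    GenotypeFactor,
    MarkerData,
    SaturationError,
    additive_dominance_design,
    build_interaction_factors,
    build_kasv,
    build_kasvd,
    build_km_kernel,
    center_genotypes,
    confounding_check,
    dominance_factor,
    km_constant,
    read_genotypes,
    read_kernel,
    write_kernel,
)
from asvlmm.kernels import write_genotypes


def make_markers(X, inbred=False):
    X = np.asarray(X, dtype=float)
    return MarkerData(
        entries=[f"e{i}" for i in range(X.shape[0])],
        X=X,
        locus_ids=[f"l{j}" for j in range(X.shape[1])],
        inbred=inbred,
    )


class TestCentering:
    def test_examples(self):
        md = make_markers([[1, 1, 1], [1, -1, 1], [-1, 1, -1]])
        Xc = center_genotypes(md)
        assert np.allclose(Xc.mean(axis=0), 0.0, atol=1e-14)
        # constant column centers to zero, [1,1,-1] to [2/3, 2/3, -4/3]
        np.testing.assert_allclose(Xc[:, 0], [2 / 3, 2 / 3, -4 / 3])
        np.testing.assert_allclose(Xc[:, 2], [2 / 3, 2 / 3, -4 / 3])

    def test_rejects_single_entry(self):
        with pytest.raises(ValueError):
            make_markers([[1, 0]])

    def test_rejects_missing_and_bad_codes(self):
        with pytest.raises(ValueError):
            make_markers([[1, 2], [0, 1]])
        with pytest.raises(ValueError):
            make_markers([[1, np.nan], [0, 1]])
        with pytest.raises(ValueError):
            make_markers([[1, 0], [1, -1]], inbred=True)


class TestKasv:
    def test_two_entry_example(self):
        K = build_kasv(make_markers([[1], [-1]]))
        np.testing.assert_allclose(K.values, [[0.5, -0.5], [-0.5, 0.5]])
        assert K.kind == "ASV_additive"

    def test_trace_and_sum_properties(self, small_markers, small_kasv):
        n = small_markers.n
        assert abs(np.trace(small_kasv.values) - (n - 1)) < 1e-10 * (n - 1)
        assert abs(small_kasv.values.sum()) / n**2 < 1e-10
        small_kasv.check_psd()

    def test_monomorphic_locus_is_inert(self, small_markers):
        K0 = build_kasv(small_markers)
        X2 = np.hstack([small_markers.X, np.ones((small_markers.n, 1))])
        md2 = MarkerData(
            entries=small_markers.entries,
            X=X2,
            locus_ids=small_markers.locus_ids + ["mono"],
        )
        np.testing.assert_allclose(build_kasv(md2).values, K0.values, atol=1e-12)

    def test_exclusion_removes_locus(self, small_markers):
        keep = build_kasv(small_markers, exclude_loci=[small_markers.locus_ids[0]])
        md_drop = MarkerData(
            entries=small_markers.entries,
            X=small_markers.X[:, 1:],
            locus_ids=small_markers.locus_ids[1:],
        )
        np.testing.assert_allclose(keep.values, build_kasv(md_drop).values)

    def test_permutation_conjugates(self, small_markers):
        perm = np.random.default_rng(3).permutation(small_markers.n)
        md_p = MarkerData(
            entries=[small_markers.entries[i] for i in perm],
            X=small_markers.X[perm],
            locus_ids=small_markers.locus_ids,
        )
        Kp = build_kasv(md_p)
        K = build_kasv(small_markers)
        np.testing.assert_allclose(Kp.values, K.values[np.ix_(perm, perm)], atol=1e-12)

    def test_all_monomorphic_errors(self):
        with pytest.raises(DegenerateKernelError):
            build_kasv(make_markers([[1, 1], [1, 1], [1, 1]]))


class TestKasvd:
    def test_single_locus_example(self):
        K = build_kasvd(make_markers([[0], [1], [-1]]))
        expect = np.array(
            [[4 / 3, -2 / 3, -2 / 3], [-2 / 3, 1 / 3, 1 / 3], [-2 / 3, 1 / 3, 1 / 3]]
        )
        np.testing.assert_allclose(K.values, expect)

    def test_properties(self, small_markers):
        K = build_kasvd(small_markers)
        n = small_markers.n
        assert abs(np.trace(K.values) - (n - 1)) < 1e-10 * (n - 1)
        assert abs(K.values.sum()) / n**2 < 1e-10

    def test_inbred_errors(self):
        with pytest.raises(DegenerateKernelError):
            build_kasvd(make_markers([[1, -1], [-1, 1], [1, 1]]))


class TestKm:
    def test_examples(self):
        own_level = GenotypeFactor.from_labels(list("abcd"), ["w", "x", "y", "z"])
        assert km_constant(own_level) == pytest.approx(1.0)
        const = GenotypeFactor.from_labels(list("abcd"), ["w"] * 4)
        assert km_constant(const) == pytest.approx(0.0)
        f = GenotypeFactor.from_labels(list("abcd"), ["AA", "Aa", "Aa", "aa"])
        assert km_constant(f) == pytest.approx((4 - 6 / 4) / 3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=9), min_size=2, max_size=50),
    )
    def test_matches_brute_force_trace(self, labels):
        """k_M equals (n-1)^{-1} tr(Z Z' P) computed from the indicator table."""
        fac = GenotypeFactor.from_labels(
            [f"e{i}" for i in range(len(labels))], [str(l) for l in labels]
        )
        n = fac.n
        Z = fac.incidence()
        P = np.eye(n) - np.ones((n, n)) / n
        brute = np.trace(Z @ Z.T @ P) / (n - 1)
        assert km_constant(fac) == pytest.approx(brute, abs=1e-12)
        assert 0.0 <= km_constant(fac) <= 1.0 + 1e-12

    def test_km_kernel(self):
        f = GenotypeFactor.from_labels(list("abcd"), ["AA", "Aa", "Aa", "aa"])
        K = build_km_kernel(f)
        np.testing.assert_allclose(np.diag(K.values), [1.2, 1.2, 1.2])
        assert K.kind == "marker_KM"
        const = GenotypeFactor.from_labels(list("abcd"), ["w"] * 4)
        with pytest.raises(DegenerateKernelError):
            build_km_kernel(const)


class TestDesignMatrices:
    def test_five_entry_worked_example(self):
        """The additive and dominance indicator tables for genotypes
        [AA, Aa, Aa, aa, aa] match the hand-written indicator matrices."""
        fac = GenotypeFactor.from_labels(
            list("vwxyz"), ["AA", "Aa", "Aa", "aa", "aa"]
        )
        za, zd = additive_dominance_design(fac)
        np.testing.assert_array_equal(
            za.to_numpy(),
            [[1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1], [0, 0, 1]],
        )
        np.testing.assert_array_equal(
            zd.to_numpy(), [[1, 0], [0, 1], [0, 1], [1, 0], [1, 0]]
        )
        assert list(za.columns) == ["AA", "Aa", "aa"]
        assert list(zd.columns) == ["hom", "het"]

    def test_row_sums_and_degenerate(self):
        fac = GenotypeFactor.from_labels(list("abc"), ["AA", "aa", "AA"])
        za, zd = additive_dominance_design(fac)
        assert (za.sum(axis=1) == 1).all() and (zd.sum(axis=1) == 1).all()
        assert zd["het"].sum() == 0  # degenerate: no heterozygotes

    def test_split_is_reparameterization(self, small_focal):
        """Column space of Z_mA contains the dominance split's columns."""
        za, zd = additive_dominance_design(small_focal)
        A = za.to_numpy()
        proj = A @ np.linalg.lstsq(A, zd.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(proj, zd.to_numpy(), atol=1e-10)

    def test_unknown_code_errors(self):
        fac = GenotypeFactor.from_labels(list("ab"), ["AA", "XX"])
        with pytest.raises(ValueError):
            additive_dominance_design(fac)
        with pytest.raises(ValueError):
            dominance_factor(fac)


class TestInteractions:
    def test_three_locus_set(self):
        rng = np.random.default_rng(4)
        n = 100
        entries = [f"e{i}" for i in range(n)]
        facs = [
            GenotypeFactor.from_labels(
                entries, rng.choice(["AA", "Aa", "aa"], size=n), name=f"M{k}"
            )
            for k in range(3)
        ]
        inter = build_interaction_factors(facs, max_order=3)
        # 3 two-way + 1 three-way; with the mains that is the seven-term model
        assert [f.name for f in inter] == ["M0xM1", "M0xM2", "M1xM2", "M0xM1xM2"]
        two_way = inter[0]
        assert two_way.n_levels <= 9
        assert "." in two_way.levels[0]
        assert two_way.counts().sum() == n

    def test_saturation_error(self):
        entries = [f"e{i}" for i in range(5)]
        labels = [["AA", "Aa", "aa", "AA", "Aa"], ["Aa", "AA", "aa", "aa", "AA"],
                  ["aa", "aa", "AA", "Aa", "Aa"]]
        facs = [
            GenotypeFactor.from_labels(entries, l, name=f"M{k}")
            for k, l in enumerate(labels)
        ]
        with pytest.raises(SaturationError):
            build_interaction_factors(facs, max_order=3)


class TestConfounding:
    def test_independent_factor_small_correlation(self, small_kasv, small_markers):
        rng = np.random.default_rng(9)
        fac = GenotypeFactor.from_labels(
            small_markers.entries, rng.choice(["AA", "Aa", "aa"], size=small_markers.n)
        )
        r = confounding_check(fac, small_kasv, n_eigvecs=3)
        assert (r >= 0).all() and (r <= 1).all()
        assert r.max() < 6 / np.sqrt(small_markers.n)

    def test_self_correlation_and_constant(self, small_kasv, small_markers):
        ev, U = np.linalg.eigh(small_kasv.values)
        lead = U[:, -1]
        fac = GenotypeFactor.from_labels(
            small_markers.entries, ["AA" if v > 0 else "aa" for v in lead]
        )
        r = confounding_check(fac, small_kasv, n_eigvecs=1)
        assert r[0] > 0.7
        const = GenotypeFactor.from_labels(small_markers.entries, ["AA"] * small_markers.n)
        assert confounding_check(const, small_kasv, 2).tolist() == [0.0, 0.0]

    def test_rank_guard(self, small_kasv):
        with pytest.raises(ValueError):
            confounding_check(
                GenotypeFactor.from_labels(small_kasv.labels, ["AA"] * small_kasv.dim),
                small_kasv,
                n_eigvecs=small_kasv.dim + 5,
            )


class TestIO:
    def test_delimited_round_trip(self, tmp_path, small_markers):
        p = tmp_path / "geno.tsv"
        write_genotypes(small_markers, p)
        back = read_genotypes(p, sep="\t")
        np.testing.assert_array_equal(back.X, small_markers.X)
        assert back.entries == small_markers.entries

    def test_plink_raw_dialect(self, tmp_path):
        raw = tmp_path / "geno.raw"
        raw.write_text(
            "FID IID PAT MAT SEX PHENOTYPE snp1_A snp2_A\n"
            "f1 i1 0 0 1 -9 0 1\n"
            "f2 i2 0 0 2 -9 2 1\n"
            "f3 i3 0 0 1 -9 1 0\n"
        )
        md = read_genotypes(raw)
        np.testing.assert_array_equal(md.X, [[-1, 0], [1, 0], [0, -1]])
        assert md.entries == ["i1", "i2", "i3"]

    def test_kernel_round_trip(self, tmp_path, small_kasv):
        p = tmp_path / "k.tsv"
        write_kernel(small_kasv, p)
        back = read_kernel(p)
        np.testing.assert_allclose(back.values, small_kasv.values, atol=1e-12)
        assert back.kind == small_kasv.kind
        assert back.scale_const == pytest.approx(small_kasv.scale_const)
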
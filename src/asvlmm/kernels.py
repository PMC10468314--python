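"""Genotype-derived covariance structures for average-semivariance (ASV) analysis.

The ASV convention scales a relationship matrix so that a variance component
estimated with it is directly interpretable as a share of the total phenotypic
variance on an entry-mean basis.  For an ``n x m`` dosage matrix ``X`` coded
``[-1, 0, 1]`` for ``[aa, Aa, AA]``, the additive ASV kernel is

    K = (n - 1) * Xc Xc^T / tr(Xc Xc^T),        Xc = P X,

with ``P = I - J/n`` the centering projector.  ``K`` has trace ``n - 1`` and
element sum 0, so ``tr(Z K Z^T P) / (n - 1) = 1`` when entries are the
observational units and the attached variance component is already on the ASV
scale.  The dominance kernel applies the same construction to the
heterozygosity coding ``W = 1 - |X|``.

Factor-coded marker terms (genotype classes as random-effect levels) are put
on the ASV scale through the constant ``k_M`` or, equivalently, by embedding
``K_M = k_M^{-1} I`` as the covariance of the class effects.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerData",
    "Kernel",
    "GenotypeFactor",
    "DegenerateKernelError",
    "SaturationError",
    "center_genotypes",
    "build_kasv",
    "build_kasvd",
    "km_constant",
    "build_km_kernel",
    "additive_dominance_design",
    "dominance_factor",
    "build_interaction_factors",
    "confounding_check",
    "read_genotypes",
    "write_kernel",
    "read_kernel",
]

#: relative eigenvalue tolerance for positive-semidefiniteness checks
PSD_RTOL = 1e-8

GENOTYPE_DOSAGE = {"AA": 1.0, "Aa": 0.0, "aa": -1.0}
DOSAGE_GENOTYPE = {1: "AA", 0: "Aa", -1: "aa"}


class DegenerateKernelError(ValueError):
    """Raised when a relationship kernel cannot be formed (zero trace)."""


class SaturationError(ValueError):
    """Raised when an interaction factor has as many levels as entries."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerData:
    """Entries-by-loci dosage codes in {-1, 0, 1} with locus metadata.

    Parameters
    ----------
    entries
        Unique entry identifiers, one per row of ``X``.
    X
        ``(n, m)`` dosage matrix coded ``-1/0/1`` for ``aa/Aa/AA``.
        Missing values are not supported.
    locus_ids
        Locus labels, one per column of ``X``.
    inbred
        If True the data are checked to contain no heterozygote (0) calls.
    """

    entries: list[str]
    X: np.ndarray
    locus_ids: list[str]
    inbred: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.entries = [str(e) for e in self.entries]
        self.locus_ids = [str(l) for l in self.locus_ids]
        n, m = self.X.shape
        if n < 2:
            raise ValueError("at least two entries are required")
        if len(self.entries) != n or len(self.locus_ids) != m:
            raise ValueError("entry/locus labels do not match X dimensions")
        if len(set(self.entries)) != n:
            raise ValueError("entry identifiers must be unique")
        if np.isnan(self.X).any():
            raise ValueError("missing genotypes are not supported")
        if not np.isin(self.X, (-1.0, 0.0, 1.0)).all():
            raise ValueError("genotype codes must be -1, 0 or 1")
        if self.inbred and (self.X == 0).any():
            raise ValueError("inbred marker data must not contain heterozygotes")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def heterozygosity(self) -> float:
        """Realized mean heterozygosity (fraction of 0 codes)."""
        return float((self.X == 0).mean())

    def focal_factor(self, locus: str) -> "GenotypeFactor":
        """Factor-code one locus of this table as genotype classes."""
        j = self.locus_ids.index(str(locus))
        labels = [DOSAGE_GENOTYPE[int(v)] for v in self.X[:, j]]
        return GenotypeFactor.from_labels(self.entries, labels, name=str(locus))


@dataclass
class Kernel:
    """Symmetric relationship structure with its ASV scaling constant.

    ``kind`` is one of ``ASV_additive``, ``ASV_dominance``, ``marker_KM`` or
    ``identity``.  ``scale_const`` records the trace-based constant applied
    during construction ((n-1)/tr for ASV kernels, 1/k_M for marker kernels).
    """

    labels: list[str]
    values: np.ndarray
    kind: str
    scale_const: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        q = self.values.shape[0]
        if self.values.shape != (q, q):
            raise ValueError("kernel must be square")
        if len(self.labels) != q:
            raise ValueError("labels do not match kernel dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kernel must be symmetric")

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.values)

    def check_psd(self) -> None:
        """Raise if any eigenvalue is below -PSD_RTOL * largest eigenvalue."""
        ev = self.eigenvalues()
        if ev[0] < -PSD_RTOL * max(ev[-1], 1.0):
            raise ValueError(f"kernel is not positive semidefinite (min eig {ev[0]:.3e})")

    def rank(self, rtol: float = 1e-10) -> int:
        ev = self.eigenvalues()
        return int((ev > rtol * max(ev[-1], 0.0)).sum())


@dataclass
class GenotypeFactor:
    """Per-entry categorical genotype level at one (pseudo-)locus.

    ``codes`` holds the level index of each entry; ``levels`` the level
    labels in index order.
    """

    entries: list[str]
    codes: np.ndarray
    levels: list[str]
    name: str = "M"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.min(initial=0) < 0 or (
            len(self.codes) and self.codes.max() >= len(self.levels)
        ):
            raise ValueError("factor codes outside level range")
        if len(self.entries) != len(self.codes):
            raise ValueError("entries and codes differ in length")

    @classmethod
    def from_labels(
        cls, entries: Sequence[str], labels: Sequence[str], name: str = "M"
    ) -> "GenotypeFactor":
        levels = sorted(set(map(str, labels)))
        index = {l: i for i, l in enumerate(levels)}
        codes = np.array([index[str(l)] for l in labels], dtype=int)
        return cls(list(map(str, entries)), codes, levels, name=name)

    @property
    def n(self) -> int:
        return len(self.codes)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def counts(self) -> np.ndarray:
        """Number of entries nested in each level."""
        return np.bincount(self.codes, minlength=self.n_levels)

    def incidence(self) -> np.ndarray:
        """Dense 0/1 indicator table (entries x levels)."""
        Z = np.zeros((self.n, self.n_levels))
        Z[np.arange(self.n), self.codes] = 1.0
        return Z

    def labels_per_entry(self) -> list[str]:
        return [self.levels[c] for c in self.codes]

    def dosage(self) -> np.ndarray:
        """Numeric coding of the factor (AA=1, Aa=0, aa=-1).

        Genotype-labelled levels use the dosage map; any other labelling
        falls back to the level index, which preserves the grouping.
        """
        if all(l in GENOTYPE_DOSAGE for l in self.levels):
            per_level = np.array([GENOTYPE_DOSAGE[l] for l in self.levels])
        else:
            per_level = np.arange(self.n_levels, dtype=float)
        return per_level[self.codes]


# ---------------------------------------------------------------------------
# kernel construction
# ---------------------------------------------------------------------------


def center_genotypes(markers: MarkerData, exclude_loci: Iterable[str] = ()) -> np.ndarray:
    """Column-centered score table Xc = P X, optionally dropping loci.

    Excluded loci are removed before centering; they contribute nothing to
    any kernel built from the result.
    """
    excl = set(map(str, exclude_loci))
    if excl:
        keep = [j for j, l in enumerate(markers.locus_ids) if l not in excl]
        X = markers.X[:, keep]
    else:
        X = markers.X
    if X.shape[1] == 0:
        raise DegenerateKernelError("no loci remain after exclusion")
    return X - X.mean(axis=0)


def _asv_from_scores(scores: np.ndarray, labels: list[str], kind: str, meta: dict) -> Kernel:
    n = scores.shape[0]
    raw = scores @ scores.T
    tr = float(np.trace(raw))
    if tr <= 0.0 or not np.isfinite(tr):
        raise DegenerateKernelError(
            "all loci are monomorphic after centering; kernel trace is zero"
        )
    scale = (n - 1) / tr
    return Kernel(labels=labels, values=raw * scale, kind=kind, scale_const=scale, meta=meta)


def build_kasv(markers: MarkerData, exclude_loci: Iterable[str] = ()) -> Kernel:
    """Additive ASV genomic relationship kernel.

    K = (n-1) * Xc Xc^T / tr(Xc Xc^T) over the loci not excluded.  Trace is
    exactly ``n - 1`` and the element sum is 0 (centered columns).  Focal
    loci modelled as explicit terms should be passed in ``exclude_loci`` so
    the polygenic background does not double-count them.
    """
    Xc = center_genotypes(markers, exclude_loci)
    meta = {"excluded_loci": sorted(map(str, exclude_loci))}
    return _asv_from_scores(Xc, markers.entries, "ASV_additive", meta)


def build_kasvd(markers: MarkerData) -> Kernel:
    """Dominance ASV kernel from the heterozygosity coding W = 1 - |X|.

    Undefined for fully inbred data (W is identically zero) — raises
    :class:`DegenerateKernelError` in that case.
    """
    W = 1.0 - np.abs(markers.X)
    Wc = W - W.mean(axis=0)
    return _asv_from_scores(Wc, markers.entries, "ASV_dominance", {"coding": "1-|X|"})


def km_constant(factor: GenotypeFactor) -> float:
    """ASV scaling constant k_M for a factor-coded marker.

    k_M = (n - n^{-1} sum_h n_h^2) / (n - 1), with n_h the number of entries
    in genotype class h; equals (n-1)^{-1} tr(Z Z^T P).  Lies in [0, 1]: 0
    when the factor is constant, 1 when every entry is its own level.
    """
    n = factor.n
    if n < 2:
        raise ValueError("factor must cover at least two entries")
    counts = factor.counts().astype(float)
    return float((n - (counts**2).sum() / n) / (n - 1))


def build_km_kernel(factor: GenotypeFactor) -> Kernel:
    """Diagonal marker kernel K_M = k_M^{-1} I over the genotype classes.

    Embedding K_M as the covariance of the class effects makes the REML
    component for the marker term land directly on the ASV scale, which is
    equivalent to multiplying the identity-kernel estimate by k_M post hoc.
    """
    km = km_constant(factor)
    if km <= 0.0:
        raise DegenerateKernelError(
            "k_M = 0: the marker carries no between-entry contrast"
        )
    q = factor.n_levels
    return Kernel(
        labels=list(factor.levels),
        values=np.eye(q) / km,
        kind="marker_KM",
        scale_const=1.0 / km,
        meta={"k_M": km, "factor": factor.name},
    )


# ---------------------------------------------------------------------------
# marker design matrices and interactions
# ---------------------------------------------------------------------------

_HET_LABELS = {"Aa"}


def dominance_factor(factor: GenotypeFactor) -> GenotypeFactor:
    """Two-level genetic-state factor: homozygous {AA, aa} vs heterozygous {Aa}."""
    state = ["het" if l in _HET_LABELS else "hom" for l in factor.labels_per_entry()]
    unknown = set(factor.levels) - (set(GENOTYPE_DOSAGE) | _HET_LABELS)
    if unknown:
        raise ValueError(f"unknown genotype codes: {sorted(unknown)}")
    return GenotypeFactor.from_labels(factor.entries, state, name=factor.name + "_D")


def additive_dominance_design(
    factor: GenotypeFactor,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Indicator tables (Z_mA, Z_mD) splitting a marker into additive and
    dominance class factors.

    Z_mA links entries to the (up to three) genotype classes in the fixed
    column order AA, Aa, aa; Z_mD links entries to genetic state with column
    order hom, het.  Every row of each table has exactly one 1.  All-homozygous
    input yields an empty heterozygote column (degenerate dominance split).
    """
    labels = factor.labels_per_entry()
    unknown = [l for l in labels if l not in GENOTYPE_DOSAGE]
    if unknown:
        raise ValueError(f"unknown genotype codes: {sorted(set(unknown))}")
    za = pd.DataFrame(0.0, index=factor.entries, columns=["AA", "Aa", "aa"])
    zd = pd.DataFrame(0.0, index=factor.entries, columns=["hom", "het"])
    for entry, lab in zip(factor.entries, labels):
        za.loc[entry, lab] = 1.0
        zd.loc[entry, "het" if lab in _HET_LABELS else "hom"] = 1.0
    # drop unobserved genotype classes from the additive table (design matrix
    # columns are the observed levels)
    za = za.loc[:, za.sum(axis=0) > 0]
    return za, zd


def build_interaction_factors(
    factors: Sequence[GenotypeFactor], max_order: int
) -> list[GenotypeFactor]:
    """All interaction pseudo-genotype factors up to ``max_order``.

    Level labels are parent level labels joined with ``"."`` (e.g. ``AA.Aa``),
    and only observed combinations become levels.  Raises
    :class:`SaturationError` when an interaction has at least as many observed
    levels as entries, in which case its variance component would be
    confounded with entry-level terms.
    """
    k = len(factors)
    if k < 2:
        raise ValueError("need at least two factors to build interactions")
    if not 2 <= max_order <= k:
        raise ValueError("max_order must be between 2 and the number of factors")
    n = factors[0].n
    if any(f.n != n for f in factors):
        raise ValueError("factors cover different numbers of entries")
    out: list[GenotypeFactor] = []
    for order in range(2, max_order + 1):
        for combo in itertools.combinations(range(k), order):
            parents = [factors[i] for i in combo]
            labels = [
                ".".join(f.levels[f.codes[i]] for f in parents) for i in range(n)
            ]
            name = "x".join(f.name for f in parents)
            fac = GenotypeFactor.from_labels(parents[0].entries, labels, name=name)
            if fac.n_levels >= n:
                raise SaturationError(
                    f"interaction {name} has {fac.n_levels} observed levels for "
                    f"{n} entries; the model would be saturated"
                )
            out.append(fac)
    return out


def confounding_check(
    factor: GenotypeFactor, kernel: Kernel, n_eigvecs: int
) -> np.ndarray:
    """|correlation| between leading kernel eigenvectors and the factor dosage.

    Large values warn that the mixed model will struggle to partition the
    marker term from the polygenic background.  A constant factor returns
    zeros (zero-variance convention).
    """
    if n_eigvecs < 1:
        raise ValueError("n_eigvecs must be at least 1")
    if kernel.dim != factor.n:
        raise ValueError("kernel and factor cover different entries")
    rank = kernel.rank()
    if n_eigvecs > rank:
        raise ValueError(f"n_eigvecs={n_eigvecs} exceeds kernel rank {rank}")
    ev, U = np.linalg.eigh(kernel.values)
    lead = U[:, ::-1][:, :n_eigvecs]  # descending eigenvalue order
    x = factor.dosage()
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    if sx == 0.0:
        return np.zeros(n_eigvecs)
    out = np.empty(n_eigvecs)
    for j in range(n_eigvecs):
        v = lead[:, j] - lead[:, j].mean()
        sv = np.sqrt((v**2).sum())
        out[j] = 0.0 if sv == 0.0 else abs(float(v @ xc) / (sv * sx))
    return out


# ---------------------------------------------------------------------------
# external formats
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, inbred: bool = False, sep: str | None = None) -> MarkerData:
    """Read a genotype dosage table.

    Two dialects are supported and auto-detected:

    * delimited text: header row of locus ids, first column entry id,
      values in ``{-1, 0, 1}``;
    * PLINK ``.raw``: whitespace-delimited with FID/IID/PAT/MAT/SEX/PHENOTYPE
      leaders and ``0/1/2`` allele counts, recoded internally as
      ``dosage - 1``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")
    cols = [c.upper() for c in df.columns[:6]]
    if cols[:2] == ["FID", "IID"]:
        ids = df["IID"].astype(str).tolist()
        geno = df.iloc[:, 6:]
        X = geno.to_numpy(dtype=float) - 1.0
        loci = list(geno.columns)
    else:
        ids = df.iloc[:, 0].astype(str).tolist()
        geno = df.iloc[:, 1:]
        X = geno.to_numpy(dtype=float)
        loci = list(geno.columns)
    return MarkerData(entries=ids, X=X, locus_ids=loci, inbred=inbred)


def write_genotypes(markers: MarkerData, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(markers.X, index=markers.entries, columns=markers.locus_ids)
    df.index.name = "entry"
    df.to_csv(path, sep=sep, float_format="%.0f")


def write_kernel(kernel: Kernel, path: str | Path, sep: str = "\t") -> None:
    """Write a kernel as a delimited square table plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(kernel.values, index=kernel.labels, columns=kernel.labels)
    df.index.name = "label"
    df.to_csv(path, sep=sep, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"kind": kernel.kind, "scale_const": kernel.scale_const, **kernel.meta},
            indent=2,
            sort_keys=True,
        )
    )


def read_kernel(path: str | Path, sep: str = "\t") -> Kernel:
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    kind = meta.pop("kind", "identity")
    scale = meta.pop("scale_const", 1.0)
    values = df.to_numpy(dtype=float)
    # round-trip symmetrization guard for text precision
    values = 0.5 * (values + values.T)
    return Kernel(
        labels=[str(l) for l in df.index],
        values=values,
        kind=kind,
        scale_const=scale,
        meta=meta,
    )
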
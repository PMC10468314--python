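"""Average-semivariance scaling of REML variance components.

A REML component ``s2`` attached to a random term with marginal contribution
``G = Z K Z^T`` explains, on the entry-mean scale, an average semivariance of

    theta = s2 * tr(G P) / (n - 1),        P = I - J/n.

The per-term constants are 1 for ASV-scaled kernels (K_ASV, K_ASV.D, K_M) and
identity-over-entries terms, and k_M for identity-coded genotype-class
factors.  The resulting theta values are additive: they sum to the total
phenotypic variance (n-1)^{-1} tr(V P), which is what makes heritability-type
ratios well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kernels import Kernel
from .reml import FitResult, ModelSpec

__all__ = ["ASVDecomposition", "asv_scale", "variance_ratios", "split_sum_check"]

#: roles a term can play in ratio computations
ROLES = ("marker", "genomic", "genetic_other", "gxe", "residual")


@dataclass
class ASVDecomposition:
    """Per-term ASV variances theta summing to the total phenotypic variance."""

    theta: dict[str, float]
    sigma2: dict[str, float]
    scale_const: dict[str, float]
    roles: dict[str, str]
    total: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nm in self.theta:
            rows.append(
                {
                    "term": nm,
                    "sigma2": self.sigma2[nm],
                    "scale_const": self.scale_const[nm],
                    "theta": self.theta[nm],
                    "ratio": self.theta[nm] / self.total if self.total > 0 else np.nan,
                    "role": self.roles[nm],
                }
            )
        return pd.DataFrame(rows)

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def _trace_gp(G: np.ndarray) -> float:
    """tr(G P) = tr(G) - 1'G1/n for the centering projector P."""
    n = G.shape[0]
    return float(np.trace(G) - G.sum() / n)


def _default_role(term) -> str:
    K = term.kernel
    if isinstance(K, Kernel):
        if K.kind == "marker_KM":
            return "marker"
        if K.kind in ("ASV_additive", "ASV_dominance"):
            return "genomic"
    return "genetic_other"


def asv_scale(
    fit: FitResult,
    spec: ModelSpec,
    roles: Optional[dict[str, str]] = None,
) -> ASVDecomposition:
    """Convert a fit's variance components to additive ASV-scale variances.

    ``roles`` optionally assigns each term one of ``marker``, ``genomic``,
    ``genetic_other``, ``gxe`` or ``residual`` for ratio computations; by
    default the role is inferred from the term's kernel kind (K_M -> marker,
    ASV kernels -> genomic, everything else genetic_other) and the residual
    is the model residual.  Components constrained at the zero boundary enter
    the decomposition as exactly 0.
    """
    n = fit.n_obs
    roles = dict(roles or {})
    theta: dict[str, float] = {}
    sigma2: dict[str, float] = {}
    consts: dict[str, float] = {}
    role_map: dict[str, str] = {}
    for term in spec.terms:
        G = term.build_G(n)
        c = _trace_gp(G) / (n - 1)
        s2 = fit.components[term.name]
        if fit.constraints.get(term.name) == "boundary":
            s2 = 0.0
        theta[term.name] = s2 * c
        sigma2[term.name] = s2
        consts[term.name] = c
        role_map[term.name] = roles.get(term.name, _default_role(term))
        if role_map[term.name] not in ROLES:
            raise ValueError(f"unknown role {role_map[term.name]!r} for term {term.name}")
    R0 = spec.residual.base_covariance(n)
    c = _trace_gp(R0) / (n - 1)
    s2 = fit.components["residual"]
    if fit.constraints.get("residual") == "boundary":
        s2 = 0.0
    theta["residual"] = s2 * c
    sigma2["residual"] = s2
    consts["residual"] = c
    role_map["residual"] = roles.get("residual", "residual")
    total = float(sum(theta.values()))
    return ASVDecomposition(
        theta=theta, sigma2=sigma2, scale_const=consts, roles=role_map, total=total
    )


def variance_ratios(decomp: ASVDecomposition) -> dict[str, float]:
    """Heritability-type ratios from an ASV decomposition.

    * ``marker``: summed marker-term share of the total variance;
    * ``genomic``: polygenic (genomic-kernel) share, the genomic heritability;
    * ``broad_sense``: all genetic terms (marker + genomic + residual genetic)
      over the total.  G-by-E and residual terms count in the denominator
      only, which keeps the ratio on an across-environment entry-mean basis.
    """
    if decomp.total <= 0:
        raise ValueError("total ASV variance must be positive")
    by_role: dict[str, float] = {r: 0.0 for r in ROLES}
    for nm, th in decomp.theta.items():
        by_role[decomp.roles[nm]] += th
    marker = by_role["marker"] / decomp.total
    genomic = by_role["genomic"] / decomp.total
    genetic = by_role["marker"] + by_role["genomic"] + by_role["genetic_other"]
    return {
        "marker": marker,
        "genomic": genomic,
        "broad_sense": genetic / decomp.total,
    }


def split_sum_check(
    decomp_split: ASVDecomposition,
    decomp_total: ASVDecomposition,
    additive: str = "mA",
    dominance: str = "mD",
    marker: str = "m",
) -> float:
    """(theta_mA + theta_mD) - theta_m between a split and a total-marker fit.

    The additive/dominance split of a genotype-class factor is a
    reparameterization of the total marker term, so the difference should be
    numerically negligible when both models are fitted to the same data.
    """
    return (
        decomp_split.theta[additive]
        + decomp_split.theta[dominance]
        - decomp_total.theta[marker]
    )
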
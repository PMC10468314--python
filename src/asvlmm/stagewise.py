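"""Stagewise and single-stage analysis of multi-environment trials (METs).

Stage one fits each environment separately with entries as fixed effects
(cell-means coding, so the estimates are directly adjusted entry means) and
design elements such as blocks as random, returning the BLUEs and their full
variance-covariance matrix Sigma_e.  The Sigma_e blocks are bound
corner-to-corner into the block-diagonal Omega, whose inverse is carried to
stage two as a fixed residual weight structure:

* naive        — identity residual with a free scalar variance (no stage-one
                 information; confounds G-by-E with the residual);
* weighted     — fixed unit residual, diagonal weights = diag(Omega^{-1});
* fully_efficient — fixed unit residual, full Omega^{-1} weight matrix.

The single-stage fit of the plot data is the reference analysis.  For
balanced complete block designs with clonal replicates it is computed through
an exact orthogonal stratum decomposition (within-cell contrasts identify the
block and plot-residual variances by ANOVA, which equals REML under balance;
the cell-mean stratum carries all genetic information with the residual fixed
at sigma_eps^2 / r); otherwise a generic plot-level REML is used.  The two
routes agree on balanced data, which is checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .kernels import GenotypeFactor, Kernel, build_km_kernel
from .reml import FitResult, ModelSpec, RandomTerm, ResidualSpec, fit_reml

__all__ = [
    "StageOneResult",
    "OmegaBlocks",
    "stage1_fit",
    "stage1_all",
    "assemble_omega",
    "build_met_model",
    "stage2_fit",
    "single_stage_fit",
]

REQUIRED_PLOT_COLUMNS = ("entry", "env", "block", "y")


def _check_plot_data(plot_data: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_PLOT_COLUMNS if c not in plot_data.columns]
    if missing:
        raise ValueError(f"plot data lacks required columns: {missing}")


# ---------------------------------------------------------------------------
# stage one
# ---------------------------------------------------------------------------


@dataclass
class StageOneResult:
    """Per-environment adjusted entry means and their covariance blocks."""

    environments: list[str]
    entries: dict[str, list[str]]  # env -> entry order of the BLUE vector
    blues: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]  # env -> VarBeta block
    resid_var: dict[str, float]  # env -> plot residual variance
    block_var: dict[str, float]
    fits: dict[str, FitResult] = field(default_factory=dict)

    def means_table(self) -> pd.DataFrame:
        rows = []
        for env in self.environments:
            for ent, b in zip(self.entries[env], self.blues[env]):
                rows.append({"entry": ent, "env": env, "blue": b})
        return pd.DataFrame(rows)

    def pooled_resid_var(self) -> float:
        return float(np.mean([self.resid_var[e] for e in self.environments]))


def stage1_fit(
    plot_data: pd.DataFrame, environment: str, method: str = "auto", **fit_kw
) -> StageOneResult:
    """Stage-one fit of one environment: entries fixed, blocks random.

    Entries are coded as cell means (no intercept), so the fixed-effect
    estimates are the adjusted entry means and their variance-covariance is
    the Sigma_e block directly.  Entries without observations are dropped
    with a warning; an environment with fewer than two observed entries is an
    error.

    For a complete randomized block design (every entry once in each of >=2
    blocks) the REML solution is available in closed form (balanced-design
    ANOVA estimators; BLUEs are entry means and Sigma_e is compound
    symmetric), which ``method="auto"`` uses; ``method="generic"`` forces the
    iterative fit.  The two routes agree, which the test suite checks.
    """
    _check_plot_data(plot_data)
    sub = plot_data[plot_data["env"].astype(str) == str(environment)]
    sub = sub.dropna(subset=["y"])
    entries = sorted(sub["entry"].astype(str).unique())
    if len(entries) < 2:
        raise ValueError(f"environment {environment!r} has fewer than two observed entries")
    all_entries = sorted(plot_data["entry"].astype(str).unique())
    dropped = sorted(set(all_entries) - set(entries))
    if dropped:
        import warnings

        warnings.warn(
            f"environment {environment!r}: entries without observations dropped: {dropped[:5]}..."
        )
    env = str(environment)
    blocks = sorted(sub["block"].astype(str).unique())
    if method == "auto" and len(blocks) >= 2:
        wide = sub.pivot_table(index=sub["entry"].astype(str),
                               columns=sub["block"].astype(str), values="y",
                               aggfunc="mean")
        counts = sub.groupby([sub["entry"].astype(str), sub["block"].astype(str)]).size()
        balanced = (
            not wide.isna().any().any()
            and len(counts) == len(entries) * len(blocks)
            and (counts == 1).all()
        )
        if balanced:
            A = wide.loc[entries].to_numpy()
            q, r = A.shape
            resid = A - A.mean(1, keepdims=True) - A.mean(0, keepdims=True) + A.mean()
            ms_res = float((resid**2).sum()) / ((q - 1) * (r - 1))
            ms_blk = float(q * ((A.mean(0) - A.mean()) ** 2).sum()) / (r - 1)
            sigma_blk = max((ms_blk - ms_res) / q, 0.0)
            sigma_e = (sigma_blk / r) * np.ones((q, q)) + (ms_res / r) * np.eye(q)
            return StageOneResult(
                environments=[env],
                entries={env: entries},
                blues={env: A.mean(axis=1)},
                sigma={env: sigma_e},
                resid_var={env: ms_res},
                block_var={env: sigma_blk},
            )

    ent_idx = {e: i for i, e in enumerate(entries)}
    codes_entry = sub["entry"].astype(str).map(ent_idx).to_numpy()
    X = np.zeros((len(sub), len(entries)))
    X[np.arange(len(sub)), codes_entry] = 1.0

    terms = []
    if len(blocks) > 1:
        blk_idx = {b: i for i, b in enumerate(blocks)}
        codes_block = sub["block"].astype(str).map(blk_idx).to_numpy()
        terms.append(RandomTerm("block", codes=codes_block, levels=blocks))
    spec = ModelSpec(terms=terms, fixed=X, residual=ResidualSpec("identity"))
    fit = fit_reml(spec, sub["y"].to_numpy(dtype=float), **fit_kw)
    env = str(environment)
    return StageOneResult(
        environments=[env],
        entries={env: entries},
        blues={env: fit.beta.copy()},
        sigma={env: 0.5 * (fit.var_beta + fit.var_beta.T)},
        resid_var={env: fit.components["residual"]},
        block_var={env: fit.components.get("block", 0.0)},
        fits={env: fit},
    )


def stage1_all(plot_data: pd.DataFrame, **fit_kw) -> StageOneResult:
    """Run stage one in every environment and merge the results."""
    _check_plot_data(plot_data)
    envs = sorted(plot_data["env"].astype(str).unique())
    merged: Optional[StageOneResult] = None
    for env in envs:
        one = stage1_fit(plot_data, env, **fit_kw)
        if merged is None:
            merged = one
        else:
            merged.environments.append(env)
            merged.entries.update(one.entries)
            merged.blues.update(one.blues)
            merged.sigma.update(one.sigma)
            merged.resid_var.update(one.resid_var)
            merged.block_var.update(one.block_var)
            merged.fits.update(one.fits)
    assert merged is not None
    return merged


# ---------------------------------------------------------------------------
# Omega
# ---------------------------------------------------------------------------


@dataclass
class OmegaBlocks:
    """Block-diagonal variance-covariance of stage-one entry means."""

    environments: list[str]
    labels: list[tuple[str, str]]  # (env, entry) per row of Omega
    blocks: dict[str, np.ndarray]
    omega: np.ndarray
    omega_inv: np.ndarray

    @property
    def dim(self) -> int:
        return self.omega.shape[0]

    def write_triplets(self, path, sep: str = "\t") -> None:
        rows = []
        for i in range(self.dim):
            for j in range(i, self.dim):
                v = self.omega[i, j]
                if v != 0.0:
                    rows.append({"i": i, "j": j, "omega": v})
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")


def assemble_omega(stage1: StageOneResult) -> OmegaBlocks:
    """Bind the Sigma_e blocks corner-to-corner and invert blockwise."""
    envs = list(stage1.environments)
    if not envs:
        raise ValueError("no environments in stage-one result")
    sizes = [len(stage1.entries[e]) for e in envs]
    dim = int(sum(sizes))
    omega = np.zeros((dim, dim))
    omega_inv = np.zeros((dim, dim))
    labels: list[tuple[str, str]] = []
    pos = 0
    for env, q in zip(envs, sizes):
        S = stage1.sigma[env]
        try:
            c, low = sla.cho_factor(S)
            Sinv = sla.cho_solve((c, low), np.eye(q))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"Sigma block for environment {env!r} is not positive definite") from exc
        except ValueError as exc:
            raise ValueError(f"Sigma block for environment {env!r} is not positive definite") from exc
        omega[pos : pos + q, pos : pos + q] = S
        omega_inv[pos : pos + q, pos : pos + q] = 0.5 * (Sinv + Sinv.T)
        labels.extend((env, ent) for ent in stage1.entries[env])
        pos += q
    return OmegaBlocks(
        environments=envs, labels=labels, blocks=dict(stage1.sigma), omega=omega, omega_inv=omega_inv
    )


# ---------------------------------------------------------------------------
# stage two and single stage
# ---------------------------------------------------------------------------


def _met_terms(
    entry_codes: np.ndarray,
    n_means: int,
    marker_codes: np.ndarray,
    km_kernel: Kernel,
    kasv: Kernel,
) -> list[RandomTerm]:
    return [
        RandomTerm("m", codes=marker_codes, kernel=km_kernel),
        RandomTerm("g", codes=entry_codes, kernel=kasv),
        RandomTerm("gR", codes=entry_codes),
        RandomTerm("ge", codes=np.arange(n_means)),
    ]


def build_met_model(
    means: pd.DataFrame,
    marker_factor: GenotypeFactor,
    kasv: Kernel,
) -> tuple[ModelSpec, np.ndarray]:
    """Stage-two model over entry-in-environment means.

    Fixed environment cell means; random marker (K_M embedding), polygene
    (K_ASV), residual genetic (identity over entries) and G-by-E (identity
    over entry-environment cells).  Returns the spec (residual to be set by
    the caller/mode) and the response vector in the means-table row order.
    """
    required = {"entry", "env", "blue"}
    if not required <= set(means.columns):
        raise ValueError(f"means table must have columns {sorted(required)}")
    envs = sorted(means["env"].astype(str).unique())
    env_idx = {e: i for i, e in enumerate(envs)}
    n_means = len(means)
    Xenv = np.zeros((n_means, len(envs)))
    Xenv[np.arange(n_means), means["env"].astype(str).map(env_idx).to_numpy()] = 1.0

    entry_order = {e: i for i, e in enumerate(marker_factor.entries)}
    try:
        entry_codes = means["entry"].astype(str).map(entry_order).to_numpy(dtype=int)
    except (ValueError, TypeError) as exc:
        raise ValueError("means table contains entries unknown to the genotype data") from exc
    marker_codes = marker_factor.codes[entry_codes]
    terms = _met_terms(entry_codes, n_means, marker_codes, build_km_kernel(marker_factor), kasv)
    spec = ModelSpec(terms=terms, fixed=Xenv, residual=ResidualSpec("identity"))
    return spec, means["blue"].to_numpy(dtype=float)


def stage2_fit(
    means: pd.DataFrame,
    omega: Optional[OmegaBlocks],
    mode: str,
    model: ModelSpec,
    **fit_kw,
) -> FitResult:
    """Stage-two fit of entry means under one of the three weighting modes.

    ``means`` rows must follow the Omega row order for the weighted and
    fully-efficient modes (env-major, entries in stage-one order); this is
    checked against the Omega labels.
    """
    if mode not in ("naive", "weighted", "fully_efficient"):
        raise ValueError(f"unknown stage-two mode {mode!r}")
    y = means["blue"].to_numpy(dtype=float)
    if mode == "naive":
        residual = ResidualSpec("identity")
    else:
        if omega is None:
            raise ValueError(f"mode {mode!r} requires the stage-one Omega blocks")
        got = list(zip(means["env"].astype(str), means["entry"].astype(str)))
        if got != [(str(e), str(t)) for e, t in omega.labels]:
            raise ValueError("means table rows are not in Omega row order")
        if mode == "weighted":
            residual = ResidualSpec(
                "diagonal", weights=np.diag(omega.omega_inv).copy(), fixed_value=1.0
            )
        else:
            residual = ResidualSpec(
                "full", omega=omega.omega, weight_matrix=omega.omega_inv, fixed_value=1.0
            )
    spec = ModelSpec(terms=model.terms, fixed=model.fixed, residual=residual)
    return fit_reml(spec, y, **fit_kw)


def _is_balanced_rcbd(plot_data: pd.DataFrame) -> bool:
    """True when every environment is a complete block design over the same
    entries with at least two blocks (clonal replicates)."""
    entries = sorted(plot_data["entry"].astype(str).unique())
    r_seen: set[int] = set()
    for env, sub in plot_data.groupby(plot_data["env"].astype(str)):
        blocks = sub["block"].astype(str).unique()
        r_seen.add(len(blocks))
        if len(blocks) < 2 or len(r_seen) > 1:
            return False
        counts = sub.groupby([sub["entry"].astype(str), sub["block"].astype(str)]).size()
        if len(counts) != len(entries) * len(blocks) or (counts != 1).any():
            return False
        if sorted(sub["entry"].astype(str).unique()) != entries:
            return False
    return True


def _plot_level_spec(
    plot_data: pd.DataFrame,
    marker_factor: GenotypeFactor,
    kasv: Kernel,
) -> tuple[ModelSpec, np.ndarray]:
    envs = sorted(plot_data["env"].astype(str).unique())
    env_idx = {e: i for i, e in enumerate(envs)}
    n = len(plot_data)
    Xenv = np.zeros((n, len(envs)))
    Xenv[np.arange(n), plot_data["env"].astype(str).map(env_idx).to_numpy()] = 1.0

    entry_order = {e: i for i, e in enumerate(marker_factor.entries)}
    entry_codes = plot_data["entry"].astype(str).map(entry_order).to_numpy(dtype=int)
    marker_codes = marker_factor.codes[entry_codes]

    cell_labels = plot_data["entry"].astype(str) + "\x1f" + plot_data["env"].astype(str)
    cell_codes = pd.factorize(cell_labels, sort=True)[0]
    blk_labels = plot_data["env"].astype(str) + "\x1f" + plot_data["block"].astype(str)
    blk_codes = pd.factorize(blk_labels, sort=True)[0]

    terms = [
        RandomTerm("block", codes=blk_codes),
        RandomTerm("m", codes=marker_codes, kernel=build_km_kernel(marker_factor)),
        RandomTerm("g", codes=entry_codes, kernel=kasv),
        RandomTerm("gR", codes=entry_codes),
        RandomTerm("ge", codes=cell_codes),
    ]
    spec = ModelSpec(terms=terms, fixed=Xenv, residual=ResidualSpec("identity"))
    return spec, plot_data["y"].to_numpy(dtype=float)


def single_stage_fit(
    plot_data: pd.DataFrame,
    marker_factor: GenotypeFactor,
    kasv: Kernel,
    *,
    method: str = "auto",
    **fit_kw,
) -> FitResult:
    """Single-stage REML of the plot data (the reference MET analysis).

    Model: fixed environments; random blocks-within-environments, marker
    (K_M), polygene (K_ASV), residual genetic, G-by-E; free plot residual.

    ``method="auto"`` uses an exact stratum decomposition for balanced
    complete clonal block designs (within-cell contrasts -> ANOVA estimates
    of block and plot-residual variance; cell means -> REML with the residual
    fixed at sigma_eps^2/r) and falls back to a generic plot-level fit
    otherwise; ``method="plot"`` forces the generic fit.
    """
    _check_plot_data(plot_data)
    if method not in ("auto", "plot", "collapsed"):
        raise ValueError(f"unknown method {method!r}")
    balanced = _is_balanced_rcbd(plot_data)
    if method == "collapsed" and not balanced:
        raise ValueError("collapsed single-stage fit requires a balanced complete design")
    if method == "plot" or (method == "auto" and not balanced):
        spec, y = _plot_level_spec(plot_data, marker_factor, kasv)
        return fit_reml(spec, y, **fit_kw)

    # --- exact stratum decomposition -------------------------------------
    df = plot_data.copy()
    df["entry"] = df["entry"].astype(str)
    df["env"] = df["env"].astype(str)
    df["block"] = df["block"].astype(str)
    envs = sorted(df["env"].unique())
    entries = sorted(df["entry"].unique())
    n_ent = len(entries)

    # within-cell stratum: pooled RCBD ANOVA per environment (= REML under
    # balance) for block and plot-residual variances
    ss_res = 0.0
    df_res = 0
    ss_blk = 0.0
    df_blk = 0
    r = None
    for env in envs:
        sub = df[df["env"] == env]
        wide = sub.pivot_table(index="entry", columns="block", values="y")
        r_e = wide.shape[1]
        r = r_e if r is None else r
        A = wide.to_numpy()
        resid = A - A.mean(axis=1, keepdims=True) - A.mean(axis=0, keepdims=True) + A.mean()
        ss_res += float((resid**2).sum())
        df_res += (n_ent - 1) * (r_e - 1)
        ss_blk += float(n_ent * ((A.mean(axis=0) - A.mean()) ** 2).sum())
        df_blk += r_e - 1
    ms_res = ss_res / df_res
    ms_blk = ss_blk / df_blk
    sigma_eps = ms_res
    sigma_blk = max((ms_blk - ms_res) / n_ent, 0.0)

    # cell-mean stratum: all genetic terms, residual fixed at sigma_eps/r
    cells = (
        df.groupby(["env", "entry"], sort=True)["y"].mean().reset_index().rename(columns={"y": "blue"})
    )
    spec, y = build_met_model(cells, marker_factor, kasv)
    spec.residual = ResidualSpec("identity", fixed_value=sigma_eps / r)
    fit = fit_reml(spec, y, **fit_kw)

    components = dict(fit.components)
    components["block"] = sigma_blk
    components["residual"] = sigma_eps  # plot-level residual, as in the plot fit
    constraints = dict(fit.constraints)
    constraints["block"] = "free"
    constraints["residual"] = "free"
    return FitResult(
        components=components,
        constraints=constraints,
        beta=fit.beta,
        var_beta=fit.var_beta,
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
        trace=fit.trace,
        n_obs=fit.n_obs,
        blups=fit.blups,
        fixed_signature=fit.fixed_signature,
        py=fit.py,
    )
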
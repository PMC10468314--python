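"""Synthetic populations and phenotypes for ASV bias experiments.

The generator emulates a structured outbred (or fully inbred) population:
correlated SNP dosages are produced by thresholding a latent Gaussian field
with AR(1) correlation along the genome (a stand-in for realized linkage
disequilibrium) at quantiles chosen to hit a target mean heterozygosity
(H = 0.38 outbred, H = 0 inbred).  A focal large-effect locus segregates
approximately 1:2:1 (outbred) or 1:0:1 (inbred).  Phenotypes are assembled
from an additive polygene built from the simulated markers, an optional
dominance polygene from the heterozygosity coding, focal-locus class effects
(total, or split into additive and dominance parts), a residual genetic term,
optional genotype-by-environment and block effects, and plot residuals whose
variance is r times the entry-mean target so the entry-mean residual variance
equals its target.

By default every component is rescaled so its realized average semivariance
equals its target exactly ("exact scaling"), which makes the per-population
truth sharp for bias computations; expectation scaling (components drawn at
the target variance without rescaling) is available as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import (
    GenotypeFactor,
    Kernel,
    MarkerData,
    build_kasv,
    build_kasvd,
    build_km_kernel,
    dominance_factor,
    km_constant,
)
from .reml import ModelSpec, RandomTerm, ResidualSpec, fit_reml, lr_test
from .stagewise import (
    assemble_omega,
    build_met_model,
    single_stage_fit,
    stage1_all,
    stage2_fit,
)

__all__ = [
    "SimDesign",
    "SimTruth",
    "ExperimentConfig",
    "EXPERIMENTS",
    "simulate_genotypes",
    "simulate_focal_locus",
    "simulate_trait",
    "run_bias_experiment",
    "BiasResult",
]

#: default block-effect variance used in multi-environment simulations
DEFAULT_BLOCK_VAR = 20.0
#: standard deviation of the fixed environment main effects
ENV_EFFECT_SD = 10.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SimDesign:
    """Experimental layout of one simulated trial."""

    n_entries: int = 500
    m_loci: int = 5000
    heterozygosity: float = 0.38
    ld_rho: float = 0.9
    population: str = "outbred"  # outbred | inbred
    reps: int = 1  # clonal replicates (blocks) per entry per environment
    n_env: int = 1
    block_effects: bool = False


@dataclass
class SimTruth:
    """Generating parameters paired with their realized per-population values.

    ``targets`` uses the keys ``g`` (additive polygene), ``gD`` (dominance
    polygene), ``m`` (focal-marker theta) or ``m_sigma2`` (focal marker on
    the sigma^2 scale, realized theta = k_M * sigma^2), ``mA``/``mD``
    (additive/dominance marker split), ``gR`` (residual genetic), ``ge``
    (G-by-E) and ``eps`` (residual on the entry-mean basis); ``block`` sets
    the block-effect variance.
    """

    targets: dict[str, float]
    design: SimDesign
    seed: Optional[int] = None
    exact_scaling: bool = True
    realized: dict[str, float] = field(default_factory=dict)


def _rng(seed: Optional[int], rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int,
    m: int,
    H_target: float,
    ld_rho: float = 0.9,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> MarkerData:
    """Correlated SNP dosages at a target mean heterozygosity.

    A latent ``n x m`` Gaussian field with AR(1) correlation ``ld_rho`` along
    the genome is thresholded per locus at the symmetric quantiles of the
    heterozygote band ``(1-H)/2 < Phi(z) < (1+H)/2``, giving genotype
    frequencies ((1-H)/2, H, (1-H)/2).  ``H_target = 0`` yields dosages in
    {-1, 1} only (inbred lines).
    """
    if n < 2 or m < 2:
        raise ValueError("need n >= 2 entries and m >= 2 loci")
    if not 0.0 <= H_target <= 0.5:
        raise ValueError("target heterozygosity must be in [0, 0.5]")
    gen = _rng(seed, rng)
    Z = gen.standard_normal((n, m))
    if ld_rho != 0.0:
        if not -1.0 < ld_rho < 1.0:
            raise ValueError("ld_rho must be in (-1, 1)")
        carry = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, m):  # stationary AR(1): marginals stay N(0,1)
            Z[:, j] = ld_rho * Z[:, j - 1] + carry * Z[:, j]
    t = stats.norm.ppf((1.0 - H_target) / 2.0)
    X = np.where(Z < t, -1.0, np.where(Z < -t, 0.0, 1.0))
    entries = [f"E{i:05d}" for i in range(n)]
    loci = [f"L{j:05d}" for j in range(m)]
    return MarkerData(entries=entries, X=X, locus_ids=loci, inbred=(H_target == 0.0))


def simulate_focal_locus(
    n: int,
    population: str = "outbred",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    entries: Optional[list[str]] = None,
) -> GenotypeFactor:
    """Focal-locus genotype classes segregating ~1:2:1 (outbred) or 1:0:1.

    Classes with positive probability are guaranteed non-empty (redrawn
    otherwise), so the factor always carries a between-entry contrast.
    """
    if n < 4:
        raise ValueError("need at least four entries for a segregating locus")
    if population == "outbred":
        labels, probs = ["AA", "Aa", "aa"], np.array([0.25, 0.5, 0.25])
    elif population == "inbred":
        labels, probs = ["AA", "aa"], np.array([0.5, 0.5])
    else:
        raise ValueError(f"unknown population type {population!r}")
    gen = _rng(seed, rng)
    for _ in range(1000):
        codes = gen.choice(len(labels), size=n, p=probs)
        if len(np.unique(codes)) == len(labels):
            break
    ents = entries if entries is not None else [f"E{i:05d}" for i in range(n)]
    return GenotypeFactor(entries=list(ents), codes=codes, levels=labels, name="focal")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _scale_component(u: np.ndarray, target: float, exact: bool) -> np.ndarray:
    """Scale a simulated component so its realized ASV equals the target."""
    if target == 0.0:
        return np.zeros_like(u)
    if not exact:
        return u
    s = float(np.var(u, ddof=1))
    if s <= 0.0:
        raise ValueError("component carries no variance; cannot scale to target")
    return u * np.sqrt(target / s)


def _realized_asv(u: np.ndarray) -> float:
    return float(np.var(u, ddof=1))


def simulate_trait(
    markers: MarkerData,
    focal: Optional[GenotypeFactor],
    truth: SimTruth,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate plot records for the design and targets in ``truth``.

    Returns the plot table (entry, env, block, rep, y) and the truth record
    with realized per-component ASV values filled in.  With exact scaling the
    realized value of every component equals its target to floating
    precision.
    """
    gen = _rng(seed if seed is not None else truth.seed, rng)
    d = truth.design
    n = markers.n
    t = dict(truth.targets)
    exact = truth.exact_scaling
    realized: dict[str, float] = {}

    entry_value = np.zeros(n)

    # additive polygene from the simulated markers
    if t.get("g", 0.0) > 0.0:
        Xc = markers.X - markers.X.mean(axis=0)
        beta = gen.standard_normal(markers.m)
        g = Xc @ beta
        if not exact:
            tr = float((Xc * Xc).sum())
            g *= np.sqrt(t["g"] * (n - 1) / tr)
        g = _scale_component(g, t["g"], exact)
        realized["g"] = _realized_asv(g)
        entry_value += g

    # dominance polygene from the heterozygosity coding
    if t.get("gD", 0.0) > 0.0:
        W = 1.0 - np.abs(markers.X)
        if not (W > 0).any():
            raise ValueError("dominance polygene requested on fully inbred markers")
        Wc = W - W.mean(axis=0)
        delta = gen.standard_normal(markers.m)
        gd = Wc @ delta
        if not exact:
            tr = float((Wc * Wc).sum())
            gd *= np.sqrt(t["gD"] * (n - 1) / tr)
        gd = _scale_component(gd, t["gD"], exact)
        realized["gD"] = _realized_asv(gd)
        entry_value += gd

    # focal-locus effects
    if focal is not None:
        km = km_constant(focal)
        realized["k_M"] = km
        if "m_sigma2" in t or "m" in t:
            theta_target = t.get("m", km * t.get("m_sigma2", 0.0))
            cls = gen.standard_normal(focal.n_levels)
            u = cls[focal.codes]
            if not exact:
                u *= np.sqrt(t.get("m_sigma2", theta_target / km))
            u = _scale_component(u, theta_target, exact)
            realized["m"] = _realized_asv(u)
            realized["m_sigma2"] = realized["m"] / km
            entry_value += u
        if t.get("mA", 0.0) > 0.0 or t.get("mD", 0.0) > 0.0:
            # class effects drawn from the split model's own prior: iid over
            # the genotype classes (additive factor) and iid over the two
            # genetic states (dominance factor)
            dom = dominance_factor(focal)
            if t.get("mD", 0.0) > 0.0 and dom.n_levels < 2:
                raise ValueError("dominance marker effect requested without heterozygotes")
            ca = gen.standard_normal(focal.n_levels)
            cd = gen.standard_normal(dom.n_levels)
            ua = ca[focal.codes]
            ud = cd[dom.codes]
            if not exact:
                if t.get("mA", 0.0) > 0.0:
                    ua *= np.sqrt(t["mA"] / km_constant(focal))
                if t.get("mD", 0.0) > 0.0:
                    ud *= np.sqrt(t["mD"] / km_constant(dom))
            ua = _scale_component(ua, t.get("mA", 0.0), exact)
            ud = _scale_component(ud, t.get("mD", 0.0), exact)
            realized["mA"] = _realized_asv(ua)
            realized["mD"] = _realized_asv(ud)
            entry_value += ua + ud

    # residual genetic term
    if t.get("gR", 0.0) > 0.0:
        gr = gen.standard_normal(n)
        if not exact:
            gr *= np.sqrt(t["gR"])
        gr = _scale_component(gr, t["gR"], exact)
        realized["gR"] = _realized_asv(gr)
        entry_value += gr

    # design expansion -----------------------------------------------------
    envs = [f"env{j + 1}" for j in range(d.n_env)]
    env_eff = gen.normal(0.0, ENV_EFFECT_SD, size=d.n_env) if d.n_env > 1 else np.zeros(1)

    ge = np.zeros((n, d.n_env))
    if t.get("ge", 0.0) > 0.0:
        ge = gen.standard_normal((n, d.n_env))
        if not exact:
            ge *= np.sqrt(t["ge"])
        ge = _scale_component(ge.ravel(), t["ge"], exact).reshape(n, d.n_env)
        realized["ge"] = _realized_asv(ge.ravel())

    block_var = t.get("block", DEFAULT_BLOCK_VAR if d.block_effects else 0.0)
    blk = np.zeros((d.n_env, d.reps))
    if d.block_effects and block_var > 0.0 and d.n_env * d.reps > 1:
        blk = gen.standard_normal((d.n_env, d.reps))
        if not exact:
            blk *= np.sqrt(block_var)
        blk = _scale_component(blk.ravel(), block_var, exact).reshape(d.n_env, d.reps)
        realized["block"] = _realized_asv(blk.ravel())

    # plot residuals: plot variance r * eps so the cell-mean variance is eps
    theta_eps = t.get("eps", 0.0)
    n_plots = n * d.n_env * d.reps
    eps = gen.standard_normal(n_plots).reshape(n, d.n_env, d.reps)
    if not exact:
        eps *= np.sqrt(d.reps * theta_eps)
    if theta_eps > 0.0 and exact:
        cell_means = eps.mean(axis=2)
        f = np.sqrt(theta_eps / np.var(cell_means.ravel(), ddof=1))
        eps *= f
    elif theta_eps == 0.0:
        eps[:] = 0.0
    realized["eps"] = _realized_asv(eps.mean(axis=2).ravel())
    realized["eps_plot"] = _realized_asv(eps.ravel())

    rows = {
        "entry": np.repeat(markers.entries, d.n_env * d.reps),
        "env": np.tile(np.repeat(envs, d.reps), n),
        "block": np.tile([f"b{k + 1}" for k in range(d.reps)], n * d.n_env),
        "rep": np.tile(np.arange(1, d.reps + 1), n * d.n_env),
    }
    i_ent = np.repeat(np.arange(n), d.n_env * d.reps)
    i_env = np.tile(np.repeat(np.arange(d.n_env), d.reps), n)
    i_rep = np.tile(np.arange(d.reps), n * d.n_env)
    y = (
        entry_value[i_ent]
        + env_eff[i_env]
        + ge[i_ent, i_env]
        + blk[i_env, i_rep]
        + eps[i_ent, i_env, i_rep]
    )
    plot_df = pd.DataFrame({**rows, "y": y})
    out_truth = SimTruth(
        targets=dict(truth.targets),
        design=d,
        seed=truth.seed if truth.seed is not None else seed,
        exact_scaling=exact,
        realized=realized,
    )
    return plot_df, out_truth


# ---------------------------------------------------------------------------
# bias experiments
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    experiment: str
    n_populations: int = 100
    seed: int = 1
    n_entries: Optional[int] = None
    m_loci: Optional[int] = None
    reps: Optional[int] = None
    exact_scaling: bool = True
    stage2_mode: str = "fully_efficient"
    fit_kw: dict = field(default_factory=dict)


#: the five simulation experiment presets
EXPERIMENTS: dict[str, dict] = {
    "exp1_outbred": {
        "design": SimDesign(population="outbred", heterozygosity=0.38, reps=1),
        "targets": {"m_sigma2": 66.0, "g": 66.0, "gR": 50.0, "eps": 40.0},
        "model": "eq1",
    },
    "exp1_inbred": {
        "design": SimDesign(population="inbred", heterozygosity=0.0, reps=1),
        "targets": {"m_sigma2": 66.0, "g": 66.0, "gR": 50.0, "eps": 40.0},
        "model": "eq1",
    },
    "exp2_markerAD": {
        "design": SimDesign(population="outbred", heterozygosity=0.38, reps=1),
        "targets": {"mA": 20.0, "mD": 20.0, "g": 66.0, "gR": 50.0, "eps": 40.0},
        "model": "eq9",
    },
    "exp3_domGRM": {
        "design": SimDesign(population="outbred", heterozygosity=0.38, reps=1),
        "targets": {"m_sigma2": 66.0, "g": 33.0, "gD": 33.0, "gR": 50.0, "eps": 40.0},
        "model": "eq13",
    },
    "exp4_stagewise": {
        "design": SimDesign(
            population="outbred", heterozygosity=0.38, reps=2, n_env=4, block_effects=True
        ),
        "targets": {
            "m": 40.0,
            "g": 66.0,
            "gR": 50.0,
            "ge": 90.0,
            "eps": 40.0,
            "block": DEFAULT_BLOCK_VAR,
        },
        "model": "met",
    },
}


@dataclass
class BiasResult:
    """Per-quantity mean relative biases with Monte-Carlo standard errors."""

    experiment: str
    summary: pd.DataFrame
    per_population: pd.DataFrame
    n_populations: int
    n_excluded: int

    def write(self, path, sep: str = "\t") -> None:
        self.summary.to_csv(path, sep=sep, index=False, float_format="%.17g")


def _entry_means_and_resid(
    plot_df: pd.DataFrame, markers: MarkerData, truth: SimTruth
) -> tuple[np.ndarray, float, Optional[float]]:
    """Entry means plus the known/estimated entry-mean residual variance.

    With replication the plot residual is estimated from the pooled
    within-entry variance (the stage-one estimate for a design without
    blocks); with a single replicate it is taken as known, following the
    framework where the residual variance of entry means is carried into the
    analysis rather than re-estimated.
    """
    r = truth.design.reps
    piv = plot_df.pivot_table(index="entry", columns="rep", values="y").loc[markers.entries]
    means = piv.mean(axis=1).to_numpy()
    if r > 1:
        within = piv.to_numpy()
        ss = float(((within - within.mean(axis=1, keepdims=True)) ** 2).sum())
        sigma_plot = ss / (markers.n * (r - 1))
        return means, sigma_plot / r, sigma_plot
    known = truth.realized["eps"] if truth.exact_scaling else truth.targets["eps"]
    return means, float(known), None


def _single_env_spec(
    model: str,
    markers: MarkerData,
    focal: GenotypeFactor,
    kasv: Kernel,
    resid_value: float,
    kasvd: Optional[Kernel] = None,
) -> ModelSpec:
    n = markers.n
    idx = np.arange(n)
    residual = ResidualSpec("identity", fixed_value=resid_value)
    if model == "eq1":
        terms = [
            RandomTerm("m", codes=focal.codes, kernel=build_km_kernel(focal)),
            RandomTerm("g", codes=idx, kernel=kasv),
            RandomTerm("gR", codes=idx),
        ]
    elif model == "eq9":
        dom = dominance_factor(focal)
        terms = [
            RandomTerm("mA", codes=focal.codes, kernel=build_km_kernel(focal)),
            RandomTerm("mD", codes=dom.codes, kernel=build_km_kernel(dom)),
            RandomTerm("g", codes=idx, kernel=kasv),
            RandomTerm("gR", codes=idx),
        ]
    elif model == "eq13":
        terms = [
            RandomTerm("m", codes=focal.codes, kernel=build_km_kernel(focal)),
            RandomTerm("gA", codes=idx, kernel=kasv),
            RandomTerm("gD", codes=idx, kernel=kasvd),
            RandomTerm("gR", codes=idx),
        ]
    else:
        raise ValueError(f"unknown single-environment model {model!r}")
    return ModelSpec(terms=terms, fixed="intercept", residual=residual)


def _population_run(
    name: str,
    preset: dict,
    design: SimDesign,
    pop_seed: int,
    cfg: ExperimentConfig,
    warm: Optional[dict] = None,
) -> dict[str, float]:
    """Simulate one population, fit the experiment's models, return records."""
    gen = np.random.default_rng(pop_seed)
    markers = simulate_genotypes(
        design.n_entries, design.m_loci, design.heterozygosity, design.ld_rho, rng=gen
    )
    focal = simulate_focal_locus(
        design.n_entries, design.population, rng=gen, entries=markers.entries
    )
    truth = SimTruth(
        targets=dict(preset["targets"]),
        design=design,
        seed=pop_seed,
        exact_scaling=cfg.exact_scaling,
    )
    plot_df, truth = simulate_trait(markers, focal, truth, rng=gen)
    kasv = build_kasv(markers)
    rec: dict[str, float] = {"seed": pop_seed, "k_M": truth.realized.get("k_M", np.nan)}

    model = preset["model"]
    warm = warm if warm is not None else {}

    def _warm_kw(key: str) -> dict:
        kw = dict(cfg.fit_kw)
        kw.setdefault("compute_blups_flag", False)
        if key in warm:  # previous population's estimates speed convergence
            kw.setdefault("init", warm[key])
            kw.setdefault("em_warmup", 1)
        return kw

    if model in ("eq1", "eq9", "eq13"):
        means, resid_value, sigma_plot = _entry_means_and_resid(plot_df, markers, truth)
        kasvd = build_kasvd(markers) if model == "eq13" else None
        spec = _single_env_spec(model, markers, focal, kasv, resid_value, kasvd)
        fit = fit_reml(spec, means, **_warm_kw(model))
        warm[model] = {
            t.name: max(fit.components[t.name], 2.0) for t in spec.terms
        }
        rec["converged"] = float(fit.converged)
        for nm in [t.name for t in spec.terms]:
            rec[f"theta_{nm}"] = fit.components[nm]  # K_M / ASV kernels: already theta
        rec["theta_eps"] = resid_value
        # truths on the theta scale for this population
        tr = {}
        tr["g"] = truth.realized.get("g", truth.targets.get("g", 0.0))
        if model == "eq13":
            tr["gA"] = tr.pop("g")
            tr["gD"] = truth.realized.get("gD", truth.targets.get("gD", 0.0))
        tr["gR"] = truth.realized.get("gR", truth.targets.get("gR", 0.0))
        tr["eps"] = truth.realized["eps"] if cfg.exact_scaling else truth.targets["eps"]
        if "m" in truth.realized:
            tr["m"] = (
                truth.realized["m"]
                if cfg.exact_scaling
                else truth.realized["k_M"] * truth.targets["m_sigma2"]
            )
        if "mA" in truth.realized:
            tr["mA"], tr["mD"] = truth.targets["mA"], truth.targets["mD"]
        for nm, tv in tr.items():
            rec[f"true_{nm}"] = tv
        # heritability-type ratios against per-population truth
        total_true = sum(tr.values())
        total_est = sum(rec[f"theta_{nm}"] for nm in tr)
        marker_terms = [nm for nm in tr if nm.startswith("m")]
        genomic_terms = [nm for nm in tr if nm in ("g", "gA", "gD")]
        rec["ratio_marker"] = sum(rec[f"theta_{nm}"] for nm in marker_terms) / total_est
        rec["true_ratio_marker"] = sum(tr[nm] for nm in marker_terms) / total_true
        rec["ratio_genomic"] = sum(rec[f"theta_{nm}"] for nm in genomic_terms) / total_est
        rec["true_ratio_genomic"] = sum(tr[nm] for nm in genomic_terms) / total_true
        gen_terms = marker_terms + genomic_terms + ["gR"]
        rec["ratio_H2"] = sum(rec[f"theta_{nm}"] for nm in gen_terms) / total_est
        rec["true_ratio_H2"] = sum(tr[nm] for nm in gen_terms) / total_true

        if model == "eq9":
            # paired total-marker fit for the split-sum and LR checks
            spec1 = _single_env_spec("eq1", markers, focal, kasv, resid_value)
            fit1 = fit_reml(spec1, means, **_warm_kw("eq1"))
            warm["eq1"] = {
                t.name: max(fit1.components[t.name], 2.0) for t in spec1.terms
            }
            rec["theta_m_total"] = fit1.components["m"]
            rec["split_diff"] = rec["theta_mA"] + rec["theta_mD"] - rec["theta_m_total"]
            lr, p = lr_test(fit1, fit, df_boundary=1)
            rec["lr"] = lr
            rec["lr_p"] = p
            rec["converged"] = float(fit.converged and fit1.converged)
    elif model == "met":
        tr = {
            "m": truth.realized["m"] if cfg.exact_scaling else truth.targets["m"],
            "g": truth.realized.get("g", 0.0),
            "gR": truth.realized.get("gR", 0.0),
            "ge": truth.realized.get("ge", 0.0),
            "eps": truth.realized["eps"] if cfg.exact_scaling else truth.targets["eps"],
        }
        for nm, tv in tr.items():
            rec[f"true_{nm}"] = tv
        r = design.reps
        free_names = ("m", "g", "gR", "ge")
        # single stage (exact stratum decomposition on this balanced design)
        fit_ss = single_stage_fit(plot_df, focal, kasv, **_warm_kw("single"))
        for nm in free_names:
            rec[f"single_{nm}"] = fit_ss.components[nm]
        rec["single_eps"] = fit_ss.components["residual"] / r
        warm["single"] = {nm: max(fit_ss.components[nm], 2.0) for nm in free_names}
        # stagewise
        s1 = stage1_all(plot_df, compute_blups_flag=False)
        omega = assemble_omega(s1)
        means_df = s1.means_table()
        spec2, _ = build_met_model(means_df, focal, kasv)
        fit_s2 = stage2_fit(means_df, omega, cfg.stage2_mode, spec2, **_warm_kw("stage2"))
        warm["stage2"] = {nm: max(fit_s2.components[nm], 2.0) for nm in free_names}
        for nm in ("m", "g", "gR", "ge"):
            rec[f"twostage_{nm}"] = fit_s2.components[nm]
        rec["twostage_eps"] = s1.pooled_resid_var() / r
        if cfg.stage2_mode == "naive":
            rec["twostage_resid_sigma"] = fit_s2.components["residual"]
        rec["converged"] = float(fit_ss.converged and fit_s2.converged)
        diffs = [
            abs(rec[f"single_{nm}"] - rec[f"twostage_{nm}"])
            / max(abs(rec[f"single_{nm}"]), 1e-12)
            for nm in ("m", "g", "gR", "ge")
        ]
        rec["max_component_rel_diff"] = max(diffs)
    else:
        raise ValueError(f"unknown model {model!r}")
    return rec


def run_bias_experiment(cfg: ExperimentConfig) -> BiasResult:
    """Replicate a simulation experiment and summarize per-term biases.

    Returns mean relative biases ``100 * mean((theta_hat - theta_true) /
    theta_true)`` and their Monte-Carlo standard errors per quantity, plus
    the per-population records.  Non-converged replicates are excluded from
    the summary and counted.
    """
    if cfg.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {cfg.experiment!r}; choose from {sorted(EXPERIMENTS)}"
        )
    preset = EXPERIMENTS[cfg.experiment]
    design: SimDesign = preset["design"]
    design = SimDesign(**{**asdict(design)})
    if cfg.n_entries is not None:
        design.n_entries = cfg.n_entries
    if cfg.m_loci is not None:
        design.m_loci = cfg.m_loci
    if cfg.reps is not None:
        design.reps = cfg.reps

    master = np.random.default_rng(cfg.seed)
    pop_seeds = master.integers(0, 2**31 - 1, size=cfg.n_populations)
    warm: dict = {}
    records = [
        _population_run(cfg.experiment, preset, design, int(s), cfg, warm)
        for s in pop_seeds
    ]
    per_pop = pd.DataFrame(records)
    ok = per_pop[per_pop["converged"] > 0.0]
    n_excluded = len(per_pop) - len(ok)

    rows = []
    est_cols = [
        c
        for c in per_pop.columns
        if c.startswith(("theta_", "single_", "twostage_", "ratio_"))
        and not c.endswith("_total")
    ]
    for col in est_cols:
        base = col.split("_", 1)[1]
        tcol = f"true_{base}" if not col.startswith("ratio_") else f"true_{col}"
        if tcol not in per_pop.columns:
            continue
        bias = 100.0 * (ok[col] - ok[tcol]) / ok[tcol]
        rows.append(
            {
                "quantity": col,
                "true_mean": float(ok[tcol].mean()),
                "mean_rel_bias_pct": float(bias.mean()),
                "mc_se_pct": float(bias.std(ddof=1) / np.sqrt(len(bias))),
                "n": int(len(bias)),
            }
        )
    for extra in ("split_diff", "lr_p", "max_component_rel_diff"):
        if extra in per_pop.columns:
            rows.append(
                {
                    "quantity": extra,
                    "true_mean": 0.0,
                    "mean_rel_bias_pct": float(ok[extra].mean()),
                    "mc_se_pct": float(ok[extra].std(ddof=1) / np.sqrt(len(ok))),
                    "n": int(len(ok)),
                }
            )
    summary = pd.DataFrame(rows)
    return BiasResult(
        experiment=cfg.experiment,
        summary=summary,
        per_population=per_pop,
        n_populations=cfg.n_populations,
        n_excluded=n_excluded,
    )
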
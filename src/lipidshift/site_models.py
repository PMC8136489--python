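"""Site-class dN/dS models (M0, M1a, M2a, M7, M8), LRTs and NEB posteriors.

The beta mixtures of M7/M8 are discretized into ``k`` equal-probability
categories with the category omega at the category median, following the
usual codeml convention.  Model pairs M1/M2 and M7/M8 are compared by a
likelihood ratio test against chi-square with 2 degrees of freedom.
Empirical-Bayes site posteriors for the positive-selection class use the
fitted mixture as prior (NEB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats

from .alignment import CodonAlignment
from .codon_model import build_f3x4
from .likelihood import PruningEngine

MODELS = ("M0", "M1", "M2", "M7", "M8")


@dataclass
class SiteModelFit:
    """A fitted site-class model: mixture, parameters and log-likelihood."""

    model_id: str
    lnL: float
    mixture: list[tuple[float, float]]  # (omega, proportion)
    params: dict[str, float]
    kappa: float
    branch_scale: float
    converged: bool = True
    n_starts: int = 1
    degenerate: bool = False  # mixture unidentifiable (e.g. invariant data)

    @property
    def omegas(self) -> np.ndarray:
        return np.array([w for w, _ in self.mixture])

    @property
    def props(self) -> np.ndarray:
        return np.array([p for _, p in self.mixture])

    @property
    def positive_class_mask(self) -> np.ndarray:
        return self.omegas > 1.0


@dataclass
class LRTResult:
    """2*(lnL_alt - lnL_null) against chi-square."""

    statistic: float
    df: int
    p_value: float


@dataclass
class SiteScanRecord:
    """Per-site selection evidence from one scan method."""

    site: int                      # 1-based codon column
    method: str                    # "NEB" or "SLAC"
    posterior_pos: float | None = None
    dn: float | None = None
    ds: float | None = None
    dnds: float | None = None
    p_value: float | None = None


def beta_category_omegas(p: float, q: float, k: int) -> np.ndarray:
    """Medians of k equal-probability categories of Beta(p, q)."""
    quantiles = (np.arange(k) + 0.5) / k
    return stats.beta.ppf(quantiles, p, q)


def _mixture_for(model_id: str, theta: dict[str, float], k: int):
    """(omegas, proportions) of a site model at parameter values theta."""
    if model_id == "M0":
        return np.array([theta["omega"]]), np.array([1.0])
    if model_id == "M1":
        return (
            np.array([theta["omega0"], 1.0]),
            np.array([theta["p0"], 1.0 - theta["p0"]]),
        )
    if model_id == "M2":
        p0, p1 = theta["p0"], theta["p1"]
        return (
            np.array([theta["omega0"], 1.0, theta["omega_s"]]),
            np.array([p0, p1, 1.0 - p0 - p1]),
        )
    if model_id == "M7":
        return (
            beta_category_omegas(theta["p"], theta["q"], k),
            np.full(k, 1.0 / k),
        )
    if model_id == "M8":
        p0 = theta["p0"]
        omegas = np.append(
            beta_category_omegas(theta["p"], theta["q"], k), theta["omega_s"]
        )
        props = np.append(np.full(k, p0 / k), 1.0 - p0)
        return omegas, props
    raise ValueError(f"unknown model {model_id!r}")


# free parameters and L-BFGS-B bounds per model
_PARAM_SPACE: dict[str, list[tuple[str, float, float]]] = {
    "M0": [("omega", 1e-4, 20.0)],
    "M1": [("p0", 1e-6, 1.0 - 1e-6), ("omega0", 1e-4, 1.0)],
    "M2": [
        ("p0", 1e-6, 1.0 - 1e-6),
        ("p1", 1e-6, 1.0 - 1e-6),
        ("omega0", 1e-4, 1.0),
        ("omega_s", 1.0, 50.0),
    ],
    "M7": [("p", 0.02, 99.0), ("q", 0.02, 99.0)],
    "M8": [
        ("p0", 1e-6, 1.0 - 1e-6),
        ("p", 0.02, 99.0),
        ("q", 0.02, 99.0),
        ("omega_s", 1.0, 50.0),
    ],
}

_DEFAULT_STARTS: dict[str, list[dict[str, float]]] = {
    "M0": [{"omega": w} for w in (0.05, 0.2, 0.5, 1.0, 2.0)],
    "M1": [
        {"p0": 0.8, "omega0": 0.1},
        {"p0": 0.5, "omega0": 0.3},
        {"p0": 0.9, "omega0": 0.05},
        {"p0": 0.3, "omega0": 0.5},
        {"p0": 0.6, "omega0": 0.8},
    ],
    "M2": [
        {"p0": 0.7, "p1": 0.2, "omega0": 0.1, "omega_s": 2.0},
        {"p0": 0.5, "p1": 0.4, "omega0": 0.3, "omega_s": 4.0},
        {"p0": 0.85, "p1": 0.1, "omega0": 0.05, "omega_s": 1.5},
        {"p0": 0.4, "p1": 0.3, "omega0": 0.5, "omega_s": 3.0},
        {"p0": 0.6, "p1": 0.3, "omega0": 0.2, "omega_s": 8.0},
    ],
    "M7": [
        {"p": 0.5, "q": 1.5},
        {"p": 1.0, "q": 1.0},
        {"p": 0.2, "q": 2.0},
        {"p": 2.0, "q": 5.0},
        {"p": 5.0, "q": 2.0},
    ],
    "M8": [
        {"p0": 0.9, "p": 0.5, "q": 1.5, "omega_s": 2.0},
        {"p0": 0.95, "p": 1.0, "q": 1.0, "omega_s": 4.0},
        {"p0": 0.8, "p": 0.2, "q": 2.0, "omega_s": 1.5},
        {"p0": 0.99, "p": 2.0, "q": 5.0, "omega_s": 3.0},
        {"p0": 0.7, "p": 0.5, "q": 0.5, "omega_s": 8.0},
    ],
}


def _theta_valid(model_id: str, theta: dict[str, float]) -> bool:
    if model_id == "M2":
        return theta["p0"] + theta["p1"] < 1.0 - 1e-9
    return True


def fit_m0(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    pi: np.ndarray | None = None,
    engine: PruningEngine | None = None,
) -> SiteModelFit:
    """Fit the single-omega M0 model with a global branch-length scale.

    Returns kappa, omega and the fitted branch multiplier; site models
    reuse kappa and the scaled branch lengths (per-branch lengths are not
    re-optimized).  The stored ``branch_scale`` is the absolute
    multiplier on the raw (unnormalized) GY94 generator — i.e. the
    fitted tree stretch divided by the expected M0 substitution rate —
    so downstream mixture fits can treat each class's likelihood as a
    function of its own omega only.
    """
    if pi is None:
        pi = build_f3x4(aln)
    if engine is None:
        engine = PruningEngine(aln, tree)

    def negloglik(x: np.ndarray) -> float:
        kappa, omega, scale = np.exp(x)
        lnL, _ = engine.mixture_log_likelihood(
            pi, kappa, np.array([omega]), np.array([1.0]), scale
        )
        return -lnL

    best = None
    for kappa0, omega0, scale0 in [(2.0, 0.3, 1.0), (1.0, 1.0, 0.5)]:
        res = optimize.minimize(
            negloglik,
            np.log([kappa0, omega0, scale0]),
            method="L-BFGS-B",
            bounds=[(np.log(0.05), np.log(50))] * 2
            + [(np.log(1e-3), np.log(100))],
            options={"maxiter": 200, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    kappa, omega, scale = np.exp(best.x)
    from .codon_model import expected_rate, gy94_unscaled

    rate0 = expected_rate(gy94_unscaled(kappa, omega, pi), pi)
    return SiteModelFit(
        model_id="M0",
        lnL=-best.fun,
        mixture=[(float(omega), 1.0)],
        params={"omega": float(omega), "tree_scale": float(scale)},
        kappa=float(kappa),
        branch_scale=float(scale / rate0),
        converged=bool(best.success),
        n_starts=2,
    )


def fit_site_model(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    model_id: str,
    k_categories: int = 10,
    n_starts: int = 5,
    seed: int = 0,
    kappa: float | None = None,
    branch_scale: float | None = None,
    pi: np.ndarray | None = None,
    engine: PruningEngine | None = None,
    m0: SiteModelFit | None = None,
    extra_starts: list[dict[str, float]] | None = None,
) -> SiteModelFit:
    """Maximum-likelihood fit of a site-class model on a fixed tree.

    kappa and the global branch-length scale default to an M0 pre-fit and
    are held fixed while the mixture parameters are optimized (multi-start
    L-BFGS-B; starts are a fixed list plus seed-derived perturbations).
    An alignment with no variable patterns yields a degenerate fit flag.
    """
    if model_id not in MODELS:
        raise ValueError(f"model_id must be one of {MODELS}")
    if pi is None:
        pi = build_f3x4(aln)
    if engine is None:
        engine = PruningEngine(aln, tree)
    if kappa is None or branch_scale is None:
        if m0 is None:
            m0 = fit_m0(aln, tree, pi=pi, engine=engine)
        kappa = m0.kappa if kappa is None else kappa
        branch_scale = m0.branch_scale if branch_scale is None else branch_scale
    if model_id == "M0":
        return fit_m0(aln, tree, pi=pi, engine=engine)

    space = _PARAM_SPACE[model_id]
    names = [n for n, _, _ in space]
    bounds = [(lo, hi) for _, lo, hi in space]
    k = k_categories

    def negloglik(x: np.ndarray) -> float:
        theta = dict(zip(names, x))
        if not _theta_valid(model_id, theta):
            return 1e12
        omegas, props = _mixture_for(model_id, theta, k)
        lnL, _ = engine.mixture_log_likelihood(
            pi, kappa, omegas, props, branch_scale,
            normalize_mixture=False,
        )
        return -lnL

    rng = np.random.default_rng(seed)
    starts = [dict(s) for s in (extra_starts or [])]
    starts += [dict(s) for s in _DEFAULT_STARTS[model_id]]
    starts = starts[:n_starts]
    while len(starts) < n_starts:  # extra seed-derived starts if requested
        base = dict(_DEFAULT_STARTS[model_id][0])
        for n, lo, hi in space:
            base[n] = float(np.clip(base[n] * rng.uniform(0.5, 2.0), lo, hi))
        starts.append(base)

    best = None
    for s in starts:
        x0 = np.array([s[n] for n in names])
        res = optimize.minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta = dict(zip(names, best.x))
    omegas, props = _mixture_for(model_id, theta, k)
    degenerate = not getattr(engine, "has_variation", True)
    if not best.success and not np.isfinite(best.fun):
        raise RuntimeError(
            f"{model_id} optimization failed to converge; best lnL "
            f"{-best.fun}"
        )
    return SiteModelFit(
        model_id=model_id,
        lnL=-best.fun,
        mixture=[(float(w), float(p)) for w, p in zip(omegas, props)],
        params={n: float(v) for n, v in theta.items()},
        kappa=float(kappa),
        branch_scale=float(branch_scale),
        converged=bool(best.success),
        n_starts=len(starts),
        degenerate=degenerate,
    )


def lrt(null: SiteModelFit, alt: SiteModelFit, df: int = 2) -> LRTResult:
    """Likelihood ratio test of nested site models.

    The statistic is clamped at zero; when the alternative's optimum falls
    below the null's by more than optimizer tolerance a warning is issued
    (the models are nested, so this indicates incomplete convergence).
    """
    stat = 2.0 * (alt.lnL - null.lnL)
    if stat < -1e-4:
        warnings.warn(
            f"lnL({alt.model_id}) < lnL({null.model_id}) by {-stat / 2:.4g}; "
            "clamping LRT statistic at 0 (optimizer tolerance exceeded)"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=stat, df=df, p_value=p)


def neb_site_posteriors(
    fit: SiteModelFit,
    aln: CodonAlignment,
    tree: dendropy.Tree,
    pi: np.ndarray | None = None,
    engine: PruningEngine | None = None,
) -> list[SiteScanRecord]:
    """Naive empirical-Bayes posterior P(omega > 1 class | data) per site."""
    if not fit.positive_class_mask.any():
        raise ValueError(
            f"model {fit.model_id} has no omega>1 class; "
            "NEB posteriors need an M2 or M8 fit"
        )
    if pi is None:
        pi = build_f3x4(aln)
    if engine is None:
        engine = PruningEngine(aln, tree)
    per_class = engine.site_class_log_likelihoods(
        pi, fit.kappa, fit.omegas, fit.props, fit.branch_scale,
        normalize_mixture=False,
    )
    props = fit.props
    m = per_class.max(axis=0)
    weighted = props[:, None] * np.exp(per_class - m)
    total = weighted.sum(axis=0)
    post_pos = weighted[fit.positive_class_mask].sum(axis=0) / total
    return [
        SiteScanRecord(site=s + 1, method="NEB", posterior_pos=float(pp))
        for s, pp in enumerate(post_pos)
    ]


def classify_selected_sites(
    ml: list[SiteScanRecord],
    counting: list[SiteScanRecord],
    posterior_cut: float = 0.9,
    p_cut: float = 0.1,
) -> set[int]:
    """Sites passing both the NEB posterior and counting-test thresholds.

    Mirrors the stringent intersection rule: posterior >= posterior_cut
    AND counting p-value <= p_cut.
    """
    ml_sites = {r.site: r for r in ml}
    ct_sites = {r.site: r for r in counting}
    if set(ml_sites) != set(ct_sites):
        raise ValueError("ML and counting scans cover different site sets")
    selected = set()
    for site, r in ml_sites.items():
        c = ct_sites[site]
        if (
            r.posterior_pos is not None
            and r.posterior_pos >= posterior_cut
            and c.p_value is not None
            and c.p_value <= p_cut
        ):
            selected.add(site)
    return selected


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0.0, 1.0)
    return out
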
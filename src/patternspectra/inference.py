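"""Statistical layer: classical tests and the Bayesian phylogenetic LMM.

The centrepiece is :func:`fit_mcmc_lmm`, a Gibbs sampler for the Gaussian
mixed model

    y = X b + Z_phylo u_phylo + Z_site u_site + e

with ``u_phylo ~ N(0, sigma2_p * C)`` where ``C`` is the Brownian-motion
species covariance implied by a phylogeny (shared root-to-tip branch
length, scaled to unit diagonal for ultrametric trees), ``u_site ~ N(0,
sigma2_s * I)`` for capture site nested within species, and ``e ~ N(0,
sigma2_e * I)``.  Fixed effects get a vague zero-mean normal prior;
each variance component gets the scalar inverse-Wishart prior IW(V, nu),
equivalent to an inverse-gamma(nu/2, nu*V/2), with the conventional
weakly-informative defaults V = 1 and nu = 0.02.

Sampling alternates a joint multivariate-normal draw of all location
effects (fixed + random) given the variances with conjugate scalar
inverse-gamma draws of each variance given the effects.  Summaries follow
the conventions of Bayesian mixed-model software: posterior mean, 95%
highest-posterior-density interval, pMCMC (twice the smaller tail
probability of the parameter's sign, floored at 2/n_draws), and DIC based
on the conditional Gaussian deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .errors import ConfigurationError, DataError

__all__ = [
    "Phylogeny",
    "ModelSpec",
    "Posterior",
    "AnovaResult",
    "TTestResult",
    "read_newick",
    "phylo_covariance",
    "one_way_anova",
    "two_sample_t",
    "fit_mcmc_lmm",
    "sex_deviation_model",
    "pmcmc",
    "hpd_interval",
    "dic",
]


# ---------------------------------------------------------------------------
# Phylogeny handling


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, wrapping a dendropy Tree."""

    newick: str
    taxa: tuple[str, ...]
    tree: dendropy.Tree

    def write_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Raises :class:`DataError` on malformed input (unbalanced parentheses,
    duplicate taxon labels, missing branch lengths on non-root edges).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several reader error types
        raise DataError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({t for t in labels if labels.count(t) > 1})
        raise DataError(f"duplicate taxa in tree: {dupes}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise DataError(
                f"missing branch length on edge above node {node.taxon.label if node.taxon else '<internal>'}"
            )
    return Phylogeny(newick=text, taxa=tuple(labels), tree=tree)


def _node_depths(tree: dendropy.Tree) -> dict[int, float]:
    depths: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = depths[id(parent)] if parent is not None else 0.0
        depths[id(node)] = base + (node.edge.length or 0.0)
    return depths


def phylo_covariance(
    phylo: Phylogeny,
    taxa_order: Sequence[str] | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Brownian-motion species covariance from shared branch lengths.

    ``C[i, j]`` is the root-to-tip path length shared by taxa ``i`` and
    ``j`` (the depth of their most recent common ancestor); the diagonal
    holds each tip's depth.  This is the expected covariance of tip values
    under Brownian motion on the tree.  With ``normalize=True`` the matrix
    is scaled to unit diagonal (correlation form).
    """
    if taxa_order is None:
        taxa_order = list(phylo.taxa)
    unknown = [t for t in taxa_order if t not in phylo.taxa]
    if unknown:
        raise DataError(f"taxa not present in tree: {unknown}")
    depths = _node_depths(phylo.tree)
    leaves = {leaf.taxon.label: leaf for leaf in phylo.tree.leaf_node_iter()}
    pdm = phylo.tree.phylogenetic_distance_matrix()
    k = len(taxa_order)
    cov = np.zeros((k, k))
    for i, ti in enumerate(taxa_order):
        di = depths[id(leaves[ti])]
        cov[i, i] = di
        for j in range(i + 1, k):
            tj = taxa_order[j]
            dj = depths[id(leaves[tj])]
            dist = pdm.patristic_distance(leaves[ti].taxon, leaves[tj].taxon)
            shared = 0.5 * (di + dj - dist)
            cov[i, j] = cov[j, i] = shared
    if normalize:
        d = np.sqrt(np.diag(cov))
        if np.any(d <= 0):
            raise DataError("zero tip depth; cannot scale covariance to unit diagonal")
        cov = cov / np.outer(d, d)
    return cov


# ---------------------------------------------------------------------------
# Classical tests


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class TTestResult:
    t_stat: float
    df: int
    p_value: float


def _as_groups(values) -> list[np.ndarray]:
    if isinstance(values, Mapping):
        groups = [np.asarray(v, dtype=float) for _, v in sorted(values.items())]
    else:
        groups = [np.asarray(v, dtype=float) for v in values]
    return groups


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA: between/within decomposition, F test.

    ``groups`` is a mapping label -> values or a sequence of value arrays.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ConfigurationError(f"need >= 2 groups, got {len(gs)}")
    for g in gs:
        if g.size < 2:
            raise ConfigurationError("every group needs >= 2 values")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_between = len(gs) - 1
    df_within = all_vals.size - len(gs)
    if ss_within <= 0:
        raise DataError("zero within-group variance; F statistic undefined")
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(float(f_stat), df_between, df_within, p)


def two_sample_t(values_a, values_b) -> TTestResult:
    """Pooled-variance Student t test, two-tailed."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each sample needs >= 2 values")
    df = a.size + b.size - 2
    pooled = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if pooled <= 0:
        raise DataError("zero pooled variance; t statistic undefined")
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1 / a.size + 1 / b.size))
    p = float(2 * stats.t.sf(abs(t), df))
    return TTestResult(float(t), int(df), p)


# ---------------------------------------------------------------------------
# Posterior summaries


def pmcmc(draws) -> float:
    """Twice the smaller posterior tail probability of the sign.

    Zeros are split evenly between the two signs; the result is floored at
    ``2 / n_draws`` (a chain of finite length cannot certify a smaller
    two-tailed probability).
    """
    d = np.asarray(draws, dtype=float)
    if d.size < 2:
        raise ConfigurationError("need >= 2 draws")
    half_zero = 0.5 * np.mean(d == 0)
    frac_pos = np.mean(d > 0) + half_zero
    frac_neg = np.mean(d < 0) + half_zero
    return float(max(2 * min(frac_pos, frac_neg), 2 / d.size))


def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` draws."""
    d = np.sort(np.asarray(draws, dtype=float))
    n = d.size
    if n < 20:
        raise ConfigurationError(f"need >= 20 draws for an HPD interval, got {n}")
    if not 0 < mass < 1:
        raise ConfigurationError(f"mass must be in (0, 1), got {mass}")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(d[0]), float(d[-1])
    widths = d[k - 1 :] - d[: n - k + 1]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + k - 1])


# ---------------------------------------------------------------------------
# The phylogenetic mixed model


@dataclass(frozen=True)
class ModelSpec:
    """Model formula and sampler settings.

    ``random`` entries: ``"phylo"`` (species effect with Brownian tree
    covariance), ``"species"`` (unstructured iid species effect),
    ``"site"`` (iid site effect; sites must nest within species).
    Chain defaults are the production scale (1,000,000 / 10,000 / 50);
    pass shorter chains for desk-scale work.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ("phylo", "site")
    prior_V: float = 1.0
    prior_nu: float = 0.02
    fixed_prior_variance: float = 1e10
    iterations: int = 1_000_000
    burn_in: int = 10_000
    thin: int = 50
    seed: int = 0
    scale_phylo: bool = True

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ConfigurationError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        known = {"phylo", "species", "site"}
        bad = set(self.random) - known
        if bad:
            raise ConfigurationError(f"unknown random terms: {sorted(bad)}")


@dataclass
class Posterior:
    """Retained MCMC draws plus per-parameter summaries and DIC."""

    draws: dict[str, np.ndarray]
    summaries: pd.DataFrame
    dic: float
    fixed_names: list[str]
    theta_draws: np.ndarray = field(repr=False)
    sigma_e_draws: np.ndarray = field(repr=False)
    _design: np.ndarray = field(repr=False)
    _y: np.ndarray = field(repr=False)


def _encode_fixed(table: pd.DataFrame, fixed: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["(Intercept)"]
    for col in fixed:
        if col not in table.columns:
            raise DataError(f"fixed-effect column {col!r} not in table")
        s = table[col]
        if s.dtype.kind in "ifu":
            cols.append(s.to_numpy(dtype=float))
            names.append(col)
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:  # first level is the reference
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{col}[{lev}]")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DataError("singular fixed-effect design matrix")
    return x, names


def _indicator(labels: pd.Series, levels: list[str]) -> np.ndarray:
    index = {lev: i for i, lev in enumerate(levels)}
    z = np.zeros((len(labels), len(levels)))
    for row, lab in enumerate(labels.astype(str)):
        z[row, index[lab]] = 1.0
    return z


def _random_blocks(
    table: pd.DataFrame, spec: ModelSpec, tree: Phylogeny | None
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Return (name, Z, Kinv) per random term; Kinv is the prior precision shape."""
    blocks: list[tuple[str, np.ndarray, np.ndarray]] = []
    for term in spec.random:
        if term in ("phylo", "species"):
            species = sorted(table["species"].astype(str).unique())
            z = _indicator(table["species"], species)
            if term == "phylo":
                if tree is None:
                    raise ConfigurationError("a tree is required for the phylo term")
                missing = [s for s in species if s not in tree.taxa]
                if missing:
                    raise DataError(f"species absent from tree: {missing}")
                cov = phylo_covariance(tree, species, normalize=False)
                if spec.scale_phylo:
                    d = np.diag(cov)
                    if not np.allclose(d, d[0], rtol=1e-6):
                        raise DataError(
                            "tree is not ultrametric; unit-diagonal scaling of the "
                            "phylogenetic covariance requires equal tip depths "
                            "(set scale_phylo=False to use raw shared branch lengths)"
                        )
                    cov = cov / np.outer(np.sqrt(d), np.sqrt(d))
                try:
                    kinv = np.linalg.inv(cov)
                    np.linalg.cholesky(cov)
                except np.linalg.LinAlgError as exc:
                    raise DataError(f"phylogenetic covariance not positive definite: {exc}")
            else:
                kinv = np.eye(len(species))
            blocks.append((term, z, kinv))
        elif term == "site":
            per_site = table.groupby("site")["species"].nunique()
            bad = per_site[per_site > 1]
            if len(bad):
                raise DataError(f"sites spanning multiple species: {list(bad.index)}")
            sites = sorted(table["site"].astype(str).unique())
            blocks.append(("site", _indicator(table["site"], sites), np.eye(len(sites))))
    return blocks


def fit_mcmc_lmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    tree: Phylogeny | None = None,
) -> Posterior:
    """Gibbs sampler for the Gaussian phylogenetic mixed model.

    Alternates (i) a joint multivariate-normal draw of all fixed and
    random effects given the variance components, and (ii) conjugate
    inverse-gamma draws of each variance component given the effects.
    Fully seeded: identical ``spec.seed`` gives identical chains.
    """
    if spec.response not in table.columns:
        raise DataError(f"response column {spec.response!r} not in table")
    y = table[spec.response].to_numpy(dtype=float)
    n = y.size
    x, fixed_names = _encode_fixed(table, spec.fixed)
    p = x.shape[1]
    blocks = _random_blocks(table, spec, tree)
    w = np.hstack([x] + [z for _, z, _ in blocks]) if blocks else x
    d = w.shape[1]
    slices = []
    start = p
    for name, z, _ in blocks:
        q = z.shape[1]
        slices.append(slice(start, start + q))
        start += q

    wtw = w.T @ w
    wty = w.T @ y
    rng = np.random.default_rng(spec.seed)
    nu, v0 = spec.prior_nu, spec.prior_V

    var_y = float(np.var(y)) or 1.0
    sigma2 = {name: var_y for name, _, _ in blocks}
    sigma2_e = var_y

    n_draws = (spec.iterations - spec.burn_in) // spec.thin
    theta_draws = np.empty((n_draws, d))
    var_draws = {name: np.empty(n_draws) for name, _, _ in blocks}
    sig_e_draws = np.empty(n_draws)
    deviances = np.empty(n_draws)

    prior_fixed = np.full(p, 1.0 / spec.fixed_prior_variance)
    kept = 0
    for it in range(1, spec.iterations + 1):
        lam = wtw / sigma2_e
        lam[np.diag_indices(p)] += prior_fixed
        for (name, _, kinv), sl in zip(blocks, slices):
            lam[sl, sl] += kinv / sigma2[name]
        try:
            chol, lower = sla.cho_factor(lam, lower=False, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise DataError(f"singular precision matrix in Gibbs update: {exc}")
        mean = sla.cho_solve((chol, lower), wty / sigma2_e, check_finite=False)
        noise = sla.solve_triangular(
            chol, rng.standard_normal(d), lower=False, check_finite=False
        )
        theta = mean + noise

        for (name, _, kinv), sl in zip(blocks, slices):
            u = theta[sl]
            quad = float(u @ kinv @ u)
            shape = (nu + u.size) / 2.0
            scale = (nu * v0 + quad) / 2.0
            sigma2[name] = scale / rng.gamma(shape)
        resid = y - w @ theta
        rss = float(resid @ resid)
        sigma2_e = (nu * v0 + rss) / 2.0 / rng.gamma((nu + n) / 2.0)

        if it > spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            theta_draws[kept] = theta
            for name in sigma2:
                var_draws[name][kept] = sigma2[name]
            sig_e_draws[kept] = sigma2_e
            deviances[kept] = n * np.log(2 * np.pi * sigma2_e) + rss / sigma2_e
            kept += 1

    theta_draws = theta_draws[:kept]
    sig_e_draws = sig_e_draws[:kept]
    deviances = deviances[:kept]
    var_draws = {k: a[:kept] for k, a in var_draws.items()}

    draws: dict[str, np.ndarray] = {
        name: theta_draws[:, i] for i, name in enumerate(fixed_names)
    }
    for name in var_draws:
        draws[f"sigma2_{name}"] = var_draws[name]
    draws["sigma2_resid"] = sig_e_draws

    rows = []
    for name in fixed_names:
        dd = draws[name]
        lo, hi = hpd_interval(dd)
        rows.append((name, float(dd.mean()), lo, hi, pmcmc(dd)))
    for name in list(var_draws) + ["resid"]:
        dd = draws[f"sigma2_{name}"]
        lo, hi = hpd_interval(dd)
        rows.append((f"sigma2_{name}", float(dd.mean()), lo, hi, np.nan))
    summaries = pd.DataFrame(
        rows, columns=["parameter", "mean", "hpd_lo", "hpd_hi", "pmcmc"]
    )

    dbar = float(deviances.mean())
    theta_bar = theta_draws.mean(axis=0)
    sig_e_bar = float(sig_e_draws.mean())
    resid_bar = y - w @ theta_bar
    d_hat = n * np.log(2 * np.pi * sig_e_bar) + float(resid_bar @ resid_bar) / sig_e_bar
    dic_value = 2 * dbar - d_hat

    return Posterior(
        draws=draws,
        summaries=summaries,
        dic=float(dic_value),
        fixed_names=fixed_names,
        theta_draws=theta_draws,
        sigma_e_draws=sig_e_draws,
        _design=w,
        _y=y,
    )


def dic(posterior: Posterior) -> float:
    """Recompute DIC from retained draws (conditional Gaussian deviance).

    ``DIC = mean deviance + (mean deviance - deviance at posterior means)``,
    with deviance evaluated conditionally on the drawn location effects.
    """
    w, y = posterior._design, posterior._y
    n = y.size
    resid = y[None, :] - posterior.theta_draws @ w.T
    rss = np.einsum("ij,ij->i", resid, resid)
    devs = n * np.log(2 * np.pi * posterior.sigma_e_draws) + rss / posterior.sigma_e_draws
    theta_bar = posterior.theta_draws.mean(axis=0)
    sig_bar = float(posterior.sigma_e_draws.mean())
    rb = y - w @ theta_bar
    d_hat = n * np.log(2 * np.pi * sig_bar) + float(rb @ rb) / sig_bar
    return float(2 * devs.mean() - d_hat)


def sex_deviation_model(
    table: pd.DataFrame,
    tree: Phylogeny | None = None,
    spec: ModelSpec | None = None,
) -> Posterior:
    """Model per-fish habitat deviation as a function of sex.

    Adds an explicit female indicator (``is_female``) so the reported
    coefficient is the female-minus-male contrast, and delegates to
    :func:`fit_mcmc_lmm` with phylogeny and site-in-species random terms.
    """
    if "deviation" not in table.columns or table["deviation"].isna().any():
        raise DataError("every fish needs a deviation value")
    t = table.copy()
    t["is_female"] = (t["sex"].astype(str) == "female").astype(float)
    if spec is None:
        spec = ModelSpec(response="deviation", fixed=("is_female",))
    else:
        spec = ModelSpec(
            response="deviation",
            fixed=("is_female",),
            random=spec.random,
            prior_V=spec.prior_V,
            prior_nu=spec.prior_nu,
            fixed_prior_variance=spec.fixed_prior_variance,
            iterations=spec.iterations,
            burn_in=spec.burn_in,
            thin=spec.thin,
            seed=spec.seed,
            scale_phylo=spec.scale_phylo,
        )
    return fit_mcmc_lmm(t, spec, tree)
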
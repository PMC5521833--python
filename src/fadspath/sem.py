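"""Recursive linear path models on observed variables, fitted by maximum
likelihood on the covariance structure.

The model is the classic RAM-style simultaneous-equation system

    y = A y + e,        Cov(e) = S_mat,

with ``A`` strictly lower-triangular under a topological order (the directed
edge graph must be acyclic) and ``S_mat`` holding exogenous variances and
covariances plus residual variances (residual covariances are fixed to zero
unless explicitly freed).  The implied covariance matrix is

    Sigma(theta) = (I - A)^-1 S_mat (I - A)^-T

and estimation minimizes the ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over the free parameters by quasi-Newton (BFGS) iteration from per-equation
OLS start values.  ``chi2 = (n - 1) * F`` at the optimum; standard errors
come from the observed information, i.e. the inverse Hessian of
``(n - 1)/2 * F``.  Data are centered internally; no mean structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "PathModelSpec",
    "FittedPathModel",
    "FitIndices",
    "build_model",
    "implied_covariance",
    "ml_discrepancy",
    "fit",
    "fit_indices",
]

_PD_PENALTY = 1e10


class ModelNotRecursiveError(ValueError):
    """The directed-edge graph contains a cycle."""


class SpecError(ValueError):
    """Malformed model specification (duplicate slots, unknown names...)."""


@dataclass(frozen=True)
class PathModelSpec:
    """Variables, directed edges and covariance structure of a path model.

    Parameters
    ----------
    variables
        Ordered observed-variable names.
    edges
        Directed ``(source, target)`` regression parameters.
    covariances
        Extra free covariance slots, e.g. residual covariances that the
        analyst frees deliberately.  Exogenous-exogenous covariances are
        free by default and need not be listed.
    fixed_zero
        Covariance slots constrained to zero (overrides the free-by-default
        exogenous block; listing a residual covariance here is a no-op
        since residual covariances default to zero).
    labels
        Optional parameter labels keyed by ``(source, target)`` for edges
        or the sorted pair for covariances.
    """

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    covariances: tuple[tuple[str, str], ...] = ()
    fixed_zero: tuple[tuple[str, str], ...] = ()
    labels: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        seen = set()
        for e in self.edges:
            if e in seen:
                raise SpecError(f"duplicate edge parameter slot {e}")
            seen.add(e)
        names = set(self.variables)
        for s, t in self.edges:
            if s not in names or t not in names:
                raise SpecError(f"edge {s}->{t} uses undeclared variable")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ModelNotRecursiveError(
                "directed-edge graph contains a cycle; model is not recursive"
            )
        covset = set()
        for a, b in self.covariances:
            key = tuple(sorted((a, b)))
            if a == b or key in covset:
                raise SpecError(f"bad covariance slot ({a},{b})")
            covset.add(key)
        fz = {tuple(sorted(p)) for p in self.fixed_zero}
        if fz & covset:
            raise SpecError("a covariance slot is both free and fixed to zero")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    @property
    def endogenous(self) -> tuple[str, ...]:
        tgt = {t for _, t in self.edges}
        return tuple(v for v in self.variables if v in tgt)

    @property
    def exogenous(self) -> tuple[str, ...]:
        tgt = {t for _, t in self.edges}
        return tuple(v for v in self.variables if v not in tgt)

    def free_covariance_pairs(self) -> tuple[tuple[str, str], ...]:
        """All free off-diagonal covariance slots, in deterministic order."""
        exo = set(self.exogenous)
        fz = {tuple(sorted(p)) for p in self.fixed_zero}
        freed = {tuple(sorted(p)) for p in self.covariances}
        pairs = []
        for a, b in itertools.combinations(self.variables, 2):
            key = tuple(sorted((a, b)))
            if key in fz:
                continue
            if (a in exo and b in exo) or key in freed:
                pairs.append((a, b))
        return tuple(pairs)

    def parameter_names(self) -> list[str]:
        names = [self.labels.get((s, t), f"b[{s}->{t}]") for s, t in self.edges]
        names += [f"v[{v}]" for v in self.variables]
        names += [f"c[{a},{b}]" for a, b in self.free_covariance_pairs()]
        return names

    @property
    def n_free(self) -> int:
        return len(self.edges) + len(self.variables) + len(self.free_covariance_pairs())

    def degrees_of_freedom(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free


def build_model(source) -> PathModelSpec:
    """Build a validated :class:`PathModelSpec` from a mapping or YAML file.

    The mapping has keys ``variables`` (list of names), ``edges`` (list of
    ``[source, target]``), optional ``covariances``, ``fixed_zero``,
    ``labels`` and ``categorical`` (``{name: [levels]}``).  A categorical
    variable is expanded to reference-coded indicators (first level is the
    reference), duplicating every edge and covariance slot that mentions it:
    six countries become five indicators, three education levels two.
    """
    if isinstance(source, PathModelSpec):
        return source
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict):
        raise SpecError("model spec must be a mapping or a YAML file path")

    variables = list(source.get("variables", []))
    edges = [tuple(e) for e in source.get("edges", [])]
    covariances = [tuple(c) for c in source.get("covariances", [])]
    fixed_zero = [tuple(c) for c in source.get("fixed_zero", [])]
    labels = {tuple(k.split("->")): v for k, v in source.get("labels", {}).items()}
    categorical = source.get("categorical", {}) or {}

    for name, levels in categorical.items():
        if name not in variables:
            raise SpecError(f"categorical {name!r} not among variables")
        indicators = [f"{name}_{lv}" for lv in levels[1:]]  # first level = reference
        i = variables.index(name)
        variables[i : i + 1] = indicators

        def _expand(pairs):
            out = []
            for a, b in pairs:
                if a == name:
                    out.extend((ind, b) for ind in indicators)
                elif b == name:
                    out.extend((a, ind) for ind in indicators)
                else:
                    out.append((a, b))
            return out

        edges = _expand(edges)
        covariances = _expand(covariances)
        fixed_zero = _expand(fixed_zero)

    return PathModelSpec(
        variables=tuple(variables),
        edges=tuple(edges),
        covariances=tuple(covariances),
        fixed_zero=tuple(fixed_zero),
        labels=labels,
    )


def expand_categorical(data: pd.DataFrame, categorical: dict[str, list]) -> pd.DataFrame:
    """Reference-code categorical columns to match :func:`build_model`."""
    out = data.copy()
    for name, levels in categorical.items():
        for lv in levels[1:]:
            out[f"{name}_{lv}"] = (out[name] == lv).astype(float)
        out = out.drop(columns=[name])
    return out


# ---------------------------------------------------------------------------
# covariance-structure algebra


def _unpack(spec: PathModelSpec, theta: np.ndarray):
    """theta -> (A, S_mat) in the spec's variable order."""
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    ne = len(spec.edges)
    A = np.zeros((p, p))
    for k, (s, t) in enumerate(spec.edges):
        A[idx[t], idx[s]] = theta[k]
    S_mat = np.zeros((p, p))
    S_mat[np.diag_indices(p)] = theta[ne : ne + p]
    for k, (a, b) in enumerate(spec.free_covariance_pairs()):
        S_mat[idx[a], idx[b]] = S_mat[idx[b], idx[a]] = theta[ne + p + k]
    return A, S_mat


def implied_covariance(spec: PathModelSpec, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance ``(I-A)^-1 S_mat (I-A)^-T``."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free,):
        raise ValueError(
            f"theta has length {theta.size}, model has {spec.n_free} free parameters"
        )
    A, S_mat = _unpack(spec, theta)
    p = len(spec.variables)
    B = np.linalg.solve(np.eye(p) - A, np.eye(p))
    return B @ S_mat @ B.T


def ml_discrepancy(sigma: np.ndarray, s_sample: np.ndarray, p: int | None = None) -> float:
    """ML fit function ``ln|Sigma| + tr(S Sigma^-1) - ln|S| - p`` (>= 0)."""
    sigma = np.asarray(sigma, float)
    s_sample = np.asarray(s_sample, float)
    if p is None:
        p = sigma.shape[0]
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    sign_s, logdet_s = np.linalg.slogdet(s_sample)
    if sign_m <= 0 or sign_s <= 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    return float(logdet_m + np.trace(np.linalg.solve(sigma, s_sample)) - logdet_s - p)


@dataclass
class FittedPathModel:
    spec: PathModelSpec
    theta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    implied_sigma: np.ndarray
    sample_sigma: np.ndarray
    n: int
    f_min: float
    converged: bool
    n_iter: int
    grad_norm: float

    @property
    def chi2(self) -> float:
        return (self.n - 1) * self.f_min

    @property
    def df(self) -> int:
        return self.spec.degrees_of_freedom()

    def _index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.spec.variables)}

    def implied_sd(self) -> dict[str, float]:
        idx = self._index()
        return {v: float(np.sqrt(self.implied_sigma[i, i])) for v, i in idx.items()}

    def coefficient(self, source: str, target: str) -> float:
        """Raw (unstandardized) estimate of a directed edge."""
        k = self.spec.edges.index((source, target))
        return float(self.theta[k])

    def standardized_from_theta(self, theta: np.ndarray) -> dict[tuple[str, str], float]:
        """Standardized edge coefficients implied by an arbitrary theta.

        Exposed as a pure function of theta so delta-method gradients can
        be taken through it.
        """
        sigma = implied_covariance(self.spec, theta)
        sd = np.sqrt(np.diag(sigma))
        idx = self._index()
        ne = len(self.spec.edges)
        return {
            (s, t): float(theta[k] * sd[idx[s]] / sd[idx[t]])
            for k, (s, t) in enumerate(self.spec.edges)
        }

    @property
    def std_solution(self) -> dict[tuple[str, str], float]:
        """Standardized edge coefficients at the optimum."""
        return self.standardized_from_theta(self.theta)

    def std_residual_variances(self) -> dict[str, float]:
        idx = self._index()
        ne = len(self.spec.edges)
        out = {}
        for v in self.spec.endogenous:
            i = idx[v]
            out[v] = float(self.theta[ne + i] / self.implied_sigma[i, i])
        return out

    def parameter_table(self) -> pd.DataFrame:
        std = self.std_solution
        ne = len(self.spec.edges)
        rows = []
        for k, (s, t) in enumerate(self.spec.edges):
            est, se = self.theta[k], self.se[k]
            z = est / se if se > 0 else np.nan
            rows.append(
                {
                    "parameter": f"{s}->{t}",
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    "standardized": std[(s, t)],
                }
            )
        return pd.DataFrame(rows)


def _start_values(spec: PathModelSpec, s_sample: np.ndarray) -> np.ndarray:
    """Per-equation OLS coefficients + residual variances + sample moments.

    For a recursive model with uncorrelated residuals these are already the
    ML optimum, so the quasi-Newton step mostly just certifies convergence.
    """
    idx = {v: i for i, v in enumerate(spec.variables)}
    p = len(spec.variables)
    ne = len(spec.edges)
    theta = np.empty(spec.n_free)
    parents: dict[str, list[str]] = {v: [] for v in spec.variables}
    for s, t in spec.edges:
        parents[t].append(s)
    variances = np.diag(s_sample).copy()
    for v in spec.variables:
        pa = parents[v]
        if not pa:
            continue
        ii = [idx[q] for q in pa]
        i = idx[v]
        sxx = s_sample[np.ix_(ii, ii)]
        sxy = s_sample[ii, i]
        beta = np.linalg.solve(sxx, sxy)
        for q, b in zip(pa, beta):
            theta[spec.edges.index((q, v))] = b
        variances[i] = s_sample[i, i] - sxy @ beta
    theta[ne : ne + p] = np.maximum(variances, 1e-8)
    for k, (a, b) in enumerate(spec.free_covariance_pairs()):
        theta[ne + p + k] = s_sample[idx[a], idx[b]]
    return theta


def fit(
    spec,
    data: pd.DataFrame,
    *,
    gtol: float = 1e-8,
    maxiter: int = 500,
) -> FittedPathModel:
    """Fit a path model by ML from OLS start values.

    ``data`` must be listwise-complete on the model variables with
    ``n > p``.  The sample covariance uses the n-1 denominator so that
    ``chi2 = (n - 1) * F`` follows the usual convention.
    """
    spec = build_model(spec)
    cols = list(spec.variables)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"cohort lacks model variables: {missing}")
    X = data[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("data contain missing values; apply listwise deletion first")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} subjects is not greater than p={p} variables")
    s_sample = np.cov(X, rowvar=False, ddof=1)
    sign, _ = np.linalg.slogdet(s_sample)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample covariance is not positive definite")

    # optimize on the unit-variance scale for conditioning: F and the
    # standardized solution are invariant to per-variable rescaling, and
    # the raw-scale parameters are a linear (diagonal) map of the scaled
    # ones, so estimates and their covariance transform back exactly.
    sd = np.sqrt(np.diag(s_sample))
    s_scaled = s_sample / np.outer(sd, sd)
    idx = {v: i for i, v in enumerate(spec.variables)}
    jac_diag = np.empty(spec.n_free)
    for k, (a, b) in enumerate(spec.edges):
        jac_diag[k] = sd[idx[b]] / sd[idx[a]]
    ne = len(spec.edges)
    jac_diag[ne : ne + p] = sd**2
    for k, (a, b) in enumerate(spec.free_covariance_pairs()):
        jac_diag[ne + p + k] = sd[idx[a]] * sd[idx[b]]

    def objective(theta):
        try:
            sigma = implied_covariance(spec, theta)
            return ml_discrepancy(sigma, s_scaled, p)
        except np.linalg.LinAlgError:
            return _PD_PENALTY

    theta0 = _start_values(spec, s_scaled)
    res = optimize.minimize(
        objective,
        theta0,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 1e-5)

    hess = approx_hess(res.x, lambda th: (n - 1) / 2.0 * objective(th))
    try:
        vcov_scaled = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov_scaled = np.full_like(hess, np.nan)
    theta = res.x * jac_diag
    vcov = vcov_scaled * np.outer(jac_diag, jac_diag)
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))

    return FittedPathModel(
        spec=spec,
        theta=theta,
        se=se,
        vcov=vcov,
        implied_sigma=implied_covariance(spec, theta),
        sample_sigma=s_sample,
        n=n,
        f_min=max(float(res.fun), 0.0),
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
    )


# ---------------------------------------------------------------------------
# fit indices


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    p_chi2: float
    cfi: float
    rmsea: float
    baseline_chi2: float
    baseline_df: int
    saturated: bool
    chi2_pass: bool
    cfi_pass: bool
    rmsea_pass: bool

    @property
    def all_pass(self) -> bool:
        return self.chi2_pass and self.cfi_pass and self.rmsea_pass


def fit_indices(
    fitted: FittedPathModel,
    *,
    chi2_alpha: float = 0.05,
    cfi_threshold: float = 0.97,
    rmsea_threshold: float = 0.03,
) -> FitIndices:
    """Chi-square test, CFI against the independence baseline, and RMSEA.

    The baseline is the independence model (diagonal covariance matrix),
    whose ML solution is the sample variances, giving
    ``F_B = sum(ln s_ii) - ln|S|`` in closed form.  A saturated model
    (df = 0) reports chi2 = 0, CFI = 1, RMSEA = 0 with ``saturated=True``.
    """
    if not fitted.converged:
        raise ValueError("fit did not converge; fit indices would be meaningless")
    n = fitted.n
    p = fitted.sample_sigma.shape[0]
    chi2 = fitted.chi2
    df = fitted.df
    if df < 0:
        raise ValueError("negative degrees of freedom: model is over-parameterized")

    s = fitted.sample_sigma
    f_base = float(np.sum(np.log(np.diag(s))) - np.linalg.slogdet(s)[1])
    chi2_base = (n - 1) * f_base
    df_base = p * (p - 1) // 2

    saturated = df == 0
    if saturated:
        p_chi2, cfi, rmsea = 1.0, 1.0, 0.0
    else:
        p_chi2 = float(stats.chi2.sf(chi2, df))
        num = max(chi2 - df, 0.0)
        den = max(chi2_base - df_base, chi2 - df, 0.0)
        cfi = 1.0 - (num / den if den > 0 else 0.0)
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))

    return FitIndices(
        chi2=chi2,
        df=df,
        p_chi2=p_chi2,
        cfi=cfi,
        rmsea=rmsea,
        baseline_chi2=chi2_base,
        baseline_df=df_base,
        saturated=saturated,
        chi2_pass=p_chi2 > chi2_alpha,
        cfi_pass=cfi >= cfi_threshold,
        rmsea_pass=rmsea <= rmsea_threshold,
    )
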
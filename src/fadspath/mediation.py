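"""Effect decomposition and multiplicity control for fitted path models.

A directed acyclic path model decomposes the association between any two
variables into a direct effect (the edge coefficient, zero if absent) and
one product-of-coefficients term per directed path through at least one
mediator.  The total indirect effect is the sum over all such paths and
the total effect is direct + total indirect — an exact arithmetic identity
on the coefficients, whether they come from a fitted model or a printed
coefficient table.

Inference for indirect effects uses the multivariate delta method on the
standardized solution by default, with a nonparametric bootstrap as the
small-sample alternative.  Families of p-values are adjusted by the
Benjamini-Hochberg step-up rule at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tools.numdiff import approx_fprime

from .sem import FittedPathModel, PathModelSpec, fit

__all__ = [
    "EffectDecomposition",
    "FDRFamily",
    "enumerate_paths",
    "decompose",
    "indirect_se",
    "bh_fdr",
]


def _as_graph(model) -> nx.DiGraph:
    if isinstance(model, nx.DiGraph):
        return model
    if isinstance(model, PathModelSpec):
        return model.graph()
    if isinstance(model, FittedPathModel):
        return model.spec.graph()
    if isinstance(model, dict):  # coefficient table {(s, t): coef}
        g = nx.DiGraph()
        g.add_edges_from(model.keys())
        return g
    raise TypeError(f"cannot interpret {type(model).__name__} as a path model")


def enumerate_paths(model, source: str, target: str) -> list[tuple[str, ...]]:
    """All directed paths from source to target, as node tuples.

    The two-node path (if the edge exists) is the direct effect; every
    longer path is a mediated effect.  Raises ``KeyError`` for unknown
    variables.  The graph must be acyclic.
    """
    g = _as_graph(model)
    for v in (source, target):
        if v not in g:
            raise KeyError(f"unknown variable {v!r}")
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("path enumeration requires an acyclic model")
    return [tuple(p) for p in nx.all_simple_paths(g, source, target)]


@dataclass
class EffectDecomposition:
    source: str
    target: str
    direct: float
    paths: list[tuple[tuple[str, ...], float]]  # mediated chains only
    total_indirect: float
    total: float
    se: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    fdr_significant: dict = field(default_factory=dict)

    def as_rows(self, model_id: str = "", digits: int | None = None) -> list[dict]:
        """Flatten to report rows (effect_type in the standard vocabulary)."""

        def _r(x):
            return round(x, digits) if digits is not None else x

        rows = [
            {
                "model": model_id,
                "source": self.source,
                "target": self.target,
                "effect_type": "direct",
                "path": f"{self.source}->{self.target}",
                "estimate": _r(self.direct),
            }
        ]
        for chain, prod in self.paths:
            rows.append(
                {
                    "model": model_id,
                    "source": self.source,
                    "target": self.target,
                    "effect_type": "indirect_path",
                    "path": "->".join(chain),
                    "estimate": _r(prod),
                }
            )
        rows.append(
            {
                "model": model_id,
                "source": self.source,
                "target": self.target,
                "effect_type": "indirect_total",
                "path": "(all mediated)",
                "estimate": _r(self.total_indirect),
            }
        )
        rows.append(
            {
                "model": model_id,
                "source": self.source,
                "target": self.target,
                "effect_type": "total",
                "path": "(direct + mediated)",
                "estimate": _r(self.total),
            }
        )
        return rows


def _coefficients(model) -> dict[tuple[str, str], float]:
    if isinstance(model, FittedPathModel):
        return model.std_solution
    if isinstance(model, dict):
        return dict(model)
    raise TypeError("decompose needs a FittedPathModel or a {(source, target): coef} table")


def decompose(model, source: str, target: str, *, graph=None) -> EffectDecomposition:
    """Direct, per-path, total-indirect and total effects of source on target.

    ``model`` may be a fitted model (standardized solution is used) or a
    plain coefficient table, which makes printed published tables usable
    directly.  ``graph`` overrides the path diagram to enumerate over
    (defaults to the model's own edges); every edge on an enumerated path
    must carry a coefficient.
    """
    coefs = _coefficients(model)
    chains = enumerate_paths(graph if graph is not None else model, source, target)
    direct = 0.0
    mediated: list[tuple[tuple[str, ...], float]] = []
    for chain in chains:
        prod = 1.0
        for s, t in zip(chain[:-1], chain[1:]):
            if (s, t) not in coefs:
                raise KeyError(f"no coefficient for edge {s}->{t} on path {chain}")
            prod *= coefs[(s, t)]
        if len(chain) == 2:
            direct = prod
        else:
            mediated.append((chain, prod))
    total_indirect = float(sum(prod for _, prod in mediated))
    return EffectDecomposition(
        source=source,
        target=target,
        direct=float(direct),
        paths=mediated,
        total_indirect=total_indirect,
        total=float(direct + total_indirect),
    )


# ---------------------------------------------------------------------------
# inference for indirect effects


def _effect_fn(
    fitted: FittedPathModel, source: str, target: str, which: str,
    standardized: bool = True,
):
    """Effect of interest as a pure function of the free-parameter vector."""
    chains = enumerate_paths(fitted.spec, source, target)
    edge_index = {e: k for k, e in enumerate(fitted.spec.edges)}

    def effect(theta):
        theta = np.asarray(theta, float)
        if standardized:
            std = fitted.standardized_from_theta(theta)
        else:
            std = {e: theta[k] for e, k in edge_index.items()}
        direct = 0.0
        indirect = 0.0
        for chain in chains:
            prod = 1.0
            for s, t in zip(chain[:-1], chain[1:]):
                prod *= std[(s, t)]
            if len(chain) == 2:
                direct = prod
            else:
                indirect += prod
        if which == "total_indirect":
            return indirect
        if which == "total":
            return direct + indirect
        if which == "direct":
            return direct
        raise ValueError(f"unknown effect kind {which!r}")

    return effect


def indirect_se(
    fitted: FittedPathModel,
    source: str,
    target: str,
    *,
    which: str = "total_indirect",
    method: str = "delta",
    standardized: bool = True,
    data: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Standard error and p-value for an indirect (or total) effect.

    delta
        Gradient of the standardized effect through the parameter
        covariance (the two-edge, zero-covariance special case reduces to
        the Sobel formula ``a^2 se_b^2 + b^2 se_a^2``).
    bootstrap
        Nonparametric resampling of subjects with refitting; reports the
        bootstrap SE, a percentile interval and a symmetric sign-crossing
        p-value.  Requires the original data and ``n_boot >= 100``.
    """
    effect = _effect_fn(fitted, source, target, which, standardized)
    est = float(effect(fitted.theta))

    if method == "delta":
        grad = approx_fprime(fitted.theta, effect, centered=True).ravel()
        var = float(grad @ fitted.vcov @ grad)
        se = float(np.sqrt(max(var, 0.0)))
        z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
        return {"estimate": est, "se": se, "p": p, "method": "delta"}

    if method == "bootstrap":
        if n_boot < 100:
            raise ValueError("bootstrap with fewer than 100 resamples is refused")
        if data is None:
            raise ValueError("bootstrap requires the subject-level data")
        rng = np.random.default_rng(seed)
        n = len(data)
        draws = np.empty(n_boot)
        cols = list(fitted.spec.variables)
        arr = data[cols].to_numpy(dtype=float)
        frame = pd.DataFrame(arr, columns=cols)
        for b in range(n_boot):
            take = rng.integers(0, n, size=n)
            refit = fit(fitted.spec, frame.iloc[take])
            draws[b] = _effect_fn(refit, source, target, which, standardized)(refit.theta)
        se = float(np.std(draws, ddof=1))
        lo, hi = np.percentile(draws, [2.5, 97.5])
        p = float(2 * min((draws <= 0).mean(), (draws >= 0).mean()))
        return {
            "estimate": est,
            "se": se,
            "p": min(p, 1.0),
            "ci": (float(lo), float(hi)),
            "method": "bootstrap",
            "n_boot": n_boot,
        }

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR


@dataclass(frozen=True)
class FDRFamily:
    labels: tuple[str, ...]
    pvalues: tuple[float, ...]
    q: float
    rejected: frozenset[str]
    alpha_adj: float

    def is_rejected(self, label: str) -> bool:
        return label in self.rejected


def bh_fdr(pvalues, q: float = 0.05) -> FDRFamily:
    """Benjamini-Hochberg step-up control of the FDR at level ``q``.

    ``pvalues`` is a mapping label -> p or a sequence (labels default to
    indices).  Rejects all hypotheses with p <= p(k*) where k* is the
    largest k with p(k) <= k q / m; ``alpha_adj`` is that largest rejected
    p-value (0 when nothing is rejected), matching the convention of
    quoting an "FDR adjusted significance value" alongside result tables.
    """
    if isinstance(pvalues, dict):
        labels = tuple(pvalues.keys())
        pvals = np.asarray(list(pvalues.values()), dtype=float)
    else:
        pvals = np.asarray(list(pvalues), dtype=float)
        labels = tuple(str(i) for i in range(pvals.size))
    if pvals.size == 0:
        raise ValueError("empty p-value family")
    if np.any((pvals < 0) | (pvals > 1)) or np.isnan(pvals).any():
        raise ValueError("p-values must lie in [0, 1]")

    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    sorted_p = pvals[order]
    thresholds = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(sorted_p <= thresholds)[0]
    if passing.size == 0:
        alpha_adj = 0.0
        rejected: frozenset[str] = frozenset()
    else:
        k_star = passing[-1]
        alpha_adj = float(sorted_p[k_star])
        rejected = frozenset(labels[i] for i in order[: k_star + 1])
    return FDRFamily(
        labels=labels,
        pvalues=tuple(float(x) for x in pvals),
        q=q,
        rejected=rejected,
        alpha_adj=alpha_adj,
    )
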
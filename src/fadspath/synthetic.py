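"""Seeded synthetic cohorts with the statistical structure of the child
fatty-acid / blood-pressure analysis.

The generator works on the standardized scale: endogenous variables are
built recursively in topological order as

    z_i = sum_j beta_ij z_j + eps_i,   eps_i ~ N(0, 1 - R2_i)

with the residual variance chosen so every endogenous variable has unit
population variance — the configured standardized coefficients are then
the exact generating truth.  The genotype is drawn as binomial(2, maf)
per subject (Hardy-Weinberg by construction) and standardized by its
binomial moments (G - 2p)/sqrt(2p(1-p)), not empirically, so the
generating coefficient on the genotype is exact as well.  Variables are
finally rescaled to configured raw-scale means/SDs.

Every cohort ships with a :class:`GroundTruthLedger` listing the
generating direct effects, all implied path products and their totals, so
parameter-recovery and decomposition tests need no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import mediation

__all__ = [
    "SyntheticConfig",
    "GroundTruthLedger",
    "generate_genotypes",
    "generate_cohort",
    "generate_stratified_cohort",
    "generate_reference_table",
    "default_config",
]

GENOTYPE_VAR = "SNP"


@dataclass
class SyntheticConfig:
    """Generating parameters for one synthetic cohort.

    ``std_paths`` maps directed edges to standardized coefficients;
    ``marginals`` maps variables to raw-scale (mean, sd); ``covariate_spec``
    lists extra independent covariates as (name, kind, params) with kind in
    {binary, categorical, continuous}; ``stratum_paths`` optionally
    overrides edges per stratum for two-group cohorts.
    """

    n_subjects: int = 520
    maf: float = 0.29
    std_paths: dict[tuple[str, str], float] = field(default_factory=dict)
    marginals: dict[str, tuple[float, float]] = field(default_factory=dict)
    covariate_spec: list[tuple[str, str, dict]] = field(default_factory=list)
    stratum_paths: dict[str, dict[tuple[str, str], float]] | None = None
    stratum_prevalence: float = 204 / 520
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.maf < 1:
            raise ValueError(f"maf must lie in (0, 1), got {self.maf}")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("std_paths define a cyclic system; model must be recursive")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables())
        g.add_edges_from(self.std_paths.keys())
        return g

    def variables(self) -> list[str]:
        names: list[str] = []
        for s, t in self.std_paths:
            for v in (s, t):
                if v not in names:
                    names.append(v)
        for v in self.marginals:
            if v not in names:
                names.append(v)
        return names


@dataclass(frozen=True)
class GroundTruthLedger:
    """Generating direct effects and all implied path products."""

    direct: dict[tuple[str, str], float]
    indirect: dict[tuple[str, str], list[tuple[tuple[str, ...], float]]]
    total_indirect: dict[tuple[str, str], float]
    total: dict[tuple[str, str], float]

    @classmethod
    def from_paths(cls, std_paths: dict[tuple[str, str], float]) -> "GroundTruthLedger":
        g = nx.DiGraph()
        g.add_edges_from(std_paths.keys())
        direct: dict[tuple[str, str], float] = {}
        indirect: dict[tuple[str, str], list] = {}
        total_indirect: dict[tuple[str, str], float] = {}
        total: dict[tuple[str, str], float] = {}
        nodes = list(nx.topological_sort(g))
        for i, s in enumerate(nodes):
            for t in nodes[i + 1 :]:
                if not nx.has_path(g, s, t):
                    continue
                dec = mediation.decompose(std_paths, s, t)
                direct[(s, t)] = dec.direct
                indirect[(s, t)] = dec.paths
                total_indirect[(s, t)] = dec.total_indirect
                total[(s, t)] = dec.total
        return cls(direct, indirect, total_indirect, total)

    def to_json(self, path) -> None:
        def key(k):
            return "->".join(k)

        payload = {
            "direct": {key(k): v for k, v in self.direct.items()},
            "indirect": {
                key(k): [["->".join(chain), prod] for chain, prod in v]
                for k, v in self.indirect.items()
            },
            "total_indirect": {key(k): v for k, v in self.total_indirect.items()},
            "total": {key(k): v for k, v in self.total.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def generate_genotypes(n: int, maf: float, seed=None) -> np.ndarray:
    """Additive genotype codes 0/1/2 drawn binomial(2, maf) per subject."""
    if not 0 < maf < 1:
        raise ValueError(f"maf must lie in (0, 1), got {maf}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, maf, size=n)


def _standardized_system(
    config: SyntheticConfig,
    std_paths: dict[tuple[str, str], float],
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the standardized system; returns standardized columns plus the
    raw genotype column when the genotype participates."""
    g = nx.DiGraph()
    variables = config.variables()
    g.add_nodes_from(variables)
    g.add_edges_from(std_paths.keys())
    order = list(nx.topological_sort(g))

    cols: dict[str, np.ndarray] = {}
    corr = pd.DataFrame(np.eye(len(order)), index=order, columns=order)
    raw_genotype = None

    for v in order:
        parents = list(g.predecessors(v))
        if not parents:
            if v == GENOTYPE_VAR:
                p = config.maf
                raw_genotype = generate_genotypes(n, p, rng)
                z = (raw_genotype - 2 * p) / np.sqrt(2 * p * (1 - p))
            else:
                z = rng.standard_normal(n)
            cols[v] = z
            continue
        beta = np.array([std_paths[(q, v)] for q in parents])
        r_pp = corr.loc[parents, parents].to_numpy()
        sys_var = float(beta @ r_pp @ beta)
        if sys_var >= 1:
            raise ValueError(
                f"implied R^2 for {v!r} is {sys_var:.3f} >= 1; "
                "standardized coefficients leave no residual variance"
            )
        X = np.column_stack([cols[q] for q in parents])
        z = X @ beta + rng.standard_normal(n) * np.sqrt(1.0 - sys_var)
        cols[v] = z
        # population correlations of the new node with everything drawn so far
        for w in order:
            if w == v:
                break
            corr.loc[v, w] = corr.loc[w, v] = float(
                beta @ corr.loc[parents, w].to_numpy()
            )

    frame = pd.DataFrame({v: cols[v] for v in variables})
    if raw_genotype is not None:
        frame[GENOTYPE_VAR + "_raw"] = raw_genotype
    return frame


def _rescale(frame: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    out = frame.copy()
    for v, (mean, sd) in config.marginals.items():
        if v == GENOTYPE_VAR:
            continue
        if v in out:
            out[v] = mean + sd * out[v]
    if GENOTYPE_VAR + "_raw" in out:
        out[GENOTYPE_VAR] = out.pop(GENOTYPE_VAR + "_raw")
    return out


def _add_covariates(
    frame: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(frame)
    for name, kind, params in config.covariate_spec:
        if name in frame.columns:
            continue
        if kind == "binary":
            frame[name] = rng.binomial(1, params.get("p", 0.5), size=n)
        elif kind == "categorical":
            levels = params["levels"]
            probs = params.get("probs")
            frame[name] = rng.choice(levels, size=n, p=probs)
        elif kind == "continuous":
            frame[name] = rng.normal(
                params.get("mean", 0.0), params.get("sd", 1.0), size=n
            )
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")
    return frame


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """One cohort table plus its ground-truth effect ledger."""
    rng = np.random.default_rng(config.seed)
    frame = _standardized_system(config, config.std_paths, config.n_subjects, rng)
    frame = _rescale(frame, config)
    frame = _add_covariates(frame, config, rng)
    ledger = GroundTruthLedger.from_paths(config.std_paths)
    return frame, ledger


def generate_stratified_cohort(
    config: SyntheticConfig, stratum_var: str = "weight_status"
) -> tuple[pd.DataFrame, dict[str, GroundTruthLedger]]:
    """Two-group cohort whose configured edges differ by stratum.

    The stratum label is drawn first (Bernoulli at the configured
    prevalence of the second-listed stratum), then each group is generated
    with its own coefficients.  Edges not overridden in ``stratum_paths``
    fall back to ``std_paths``.
    """
    if not config.stratum_paths or len(config.stratum_paths) != 2:
        raise ValueError("stratum_paths must configure exactly two strata")
    rng = np.random.default_rng(config.seed)
    strata = list(config.stratum_paths.keys())
    labels = np.where(
        rng.random(config.n_subjects) < config.stratum_prevalence, strata[1], strata[0]
    )
    frames = []
    ledgers: dict[str, GroundTruthLedger] = {}
    for stratum in strata:
        n_s = int((labels == stratum).sum())
        if n_s == 0:
            raise ValueError(f"stratum {stratum!r} has zero subjects")
        paths = dict(config.std_paths)
        paths.update(config.stratum_paths[stratum])
        sub = _standardized_system(config, paths, n_s, rng)
        sub = _rescale(sub, config)
        sub[stratum_var] = stratum
        frames.append(sub)
        ledgers[stratum] = GroundTruthLedger.from_paths(paths)
    cohort = pd.concat(frames, ignore_index=True)
    cohort = _add_covariates(cohort, config, rng)
    return cohort, ledgers


# ---------------------------------------------------------------------------
# reference-table fixtures


def generate_reference_table(kind: str, seed=None, *, with_height: bool | None = None):
    """Toy growth/BP reference table in the phenotype module's file format.

    ``lms`` tables carry (L, M, S) per (sex, age bin); ``mean_sd`` tables
    carry (mu, sigma) per (sex, age bin, height bin).  Medians increase
    monotonically with age; S/sigma are positive everywhere; coverage is
    ages 2-10 years, both sexes, heights 80-160 cm for the BP kind.
    These are synthetic stand-ins for the licensed pediatric references.
    """
    from .phenotypes import ReferenceTable

    if kind not in ("lms", "mean_sd"):
        raise ValueError(f"kind must be 'lms' or 'mean_sd', got {kind!r}")
    rng = np.random.default_rng(seed)
    if with_height is None:
        with_height = kind == "mean_sd"
    rows = []
    ages = np.arange(2.0, 10.0, 1.0)
    heights = np.arange(80.0, 160.0, 20.0) if with_height else [None]
    for sex in ("female", "male"):
        base = 15.0 + rng.uniform(0, 0.5) if kind == "lms" else 95.0 + rng.uniform(0, 2)
        for i, age in enumerate(ages):
            for j, h in enumerate(heights):
                median = base + 0.6 * i + (0.8 * j if h is not None else 0.0)
                if kind == "lms":
                    rows.append(
                        {
                            "kind": kind,
                            "sex": sex,
                            "age_lo": age,
                            "age_hi": age + 1.0,
                            "height_lo": "",
                            "height_hi": "",
                            "L": round(float(rng.uniform(-2.0, 1.0)), 3),
                            "M": round(median, 3),
                            "S": round(float(rng.uniform(0.08, 0.15)), 3),
                            "mu": "",
                            "sigma": "",
                        }
                    )
                else:
                    rows.append(
                        {
                            "kind": kind,
                            "sex": sex,
                            "age_lo": age,
                            "age_hi": age + 1.0,
                            "height_lo": h,
                            "height_hi": h + 20.0,
                            "L": "",
                            "M": "",
                            "S": "",
                            "mu": round(median, 3),
                            "sigma": round(float(rng.uniform(8.0, 12.0)), 3),
                        }
                    )
    return ReferenceTable(pd.DataFrame(rows), kind=kind, cutpoints=(90.0, 95.0))


# ---------------------------------------------------------------------------
# study-calibrated default configuration


def default_config(
    model: str = "2a", n_subjects: int = 520, seed: int = 0
) -> SyntheticConfig:
    """Config calibrated to the published study conditions for one model.

    Generating coefficients are that model's published standardized direct
    effects; marginals and MAF come from the published descriptive tables.
    The focal-exposure placeholder is renamed to the actual fatty acid.
    """
    from . import published

    fa = published.EXPOSURE[model]
    paths = {
        (s.replace("FA", fa), t.replace("FA", fa)): v
        for (s, t), v in published.MODEL_DIRECT_EFFECTS[model].items()
    }
    return SyntheticConfig(
        n_subjects=n_subjects,
        maf=published.MAF,
        std_paths=paths,
        marginals={k: v for k, v in published.MARGINALS.items()},
        seed=seed,
    )


def stratified_config(n_subjects: int = 520, seed: int = 0) -> SyntheticConfig:
    """Two-group EPA/weight-status config matching the stratified analysis."""
    from . import published

    return SyntheticConfig(
        n_subjects=n_subjects,
        maf=published.MAF,
        std_paths=dict(published.STRATIFIED_EPA["thin_normal"]),
        stratum_paths={k: dict(v) for k, v in published.STRATIFIED_EPA.items()},
        stratum_prevalence=published.STRATUM_SIZES[1] / sum(published.STRATUM_SIZES),
        marginals={k: v for k, v in published.MARGINALS.items()},
        seed=seed,
    )
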
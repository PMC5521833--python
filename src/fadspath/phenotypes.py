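"""Genotype QC and derived phenotypes.

Additive SNP coding, minor-allele frequency, Hardy-Weinberg testing
(1-df chi-square by default, exact test available), call-rate filtering,
blood-pressure reading consolidation, LMS / mean-SD z-scoring against
pluggable reference tables, blood-pressure classification, BMI and the
delta-5 desaturase (D5D) activity index.

Reference tables are delimited-text files, never hard-coded: the licensed
pediatric BP and BMI references can be supplied by the user in the same
format as the synthetic fixtures used in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeSummary",
    "ReferenceTable",
    "encode_additive",
    "call_rate_filter",
    "genotype_summary",
    "hwe_exact_test",
    "consolidate_bp",
    "classify_bp",
    "d5d_index",
    "bmi",
    "percentile_from_z",
]

_VALID_ALLELES = {"C", "T"}


def encode_additive(calls) -> pd.Series:
    """Count minor (T) alleles per call: CC -> 0, CT/TC -> 1, TT -> 2.

    Missing calls (None/NaN/empty string) propagate as missing; any allele
    outside {C, T} raises ``ValueError``.
    """
    def _one(call):
        if call is None or (isinstance(call, float) and math.isnan(call)) or call == "":
            return np.nan
        call = str(call).strip().upper()
        if len(call) != 2 or not set(call) <= _VALID_ALLELES:
            raise ValueError(f"invalid genotype call {call!r}; expected two of C/T")
        return float(call.count("T"))

    if isinstance(call := calls, str):
        return _one(call)
    return pd.Series([_one(c) for c in calls], dtype=float)


def call_rate_filter(calls: pd.DataFrame, threshold: float = 0.98) -> pd.Index:
    """Subjects (rows) whose non-missing call fraction strictly exceeds the
    threshold; a subject at exactly the threshold is excluded."""
    if calls.shape[0] == 0 or calls.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    rate = calls.notna().mean(axis=1)
    return calls.index[rate > threshold]


@dataclass(frozen=True)
class GenotypeSummary:
    counts: tuple[int, int, int]  # (n_CC, n_CT, n_TT)
    n: int
    maf: float
    major_freq: float
    hwe_chi2: float
    hwe_p: float
    hwe_exact_p: float


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int, *, midp: bool = False) -> float:
    """Exact Hardy-Weinberg test (sum of probabilities of heterozygote
    counts no more likely than the observed one, conditional on allele
    counts), with an optional mid-p variant."""
    n = n_het + n_hom_minor + n_hom_major
    n_rare = 2 * n_hom_minor + n_het
    if n_rare > n:  # make "rare" the actual minor allele
        n_rare = 2 * n - n_rare
    # log-probability of each compatible heterozygote count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.empty(hets.size)
    from scipy.special import gammaln

    for i, h in enumerate(hets):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp[i] = (
            h * math.log(2)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    mask = prob <= obs * (1 + 1e-12)
    p = prob[mask].sum()
    if midp:
        p -= 0.5 * obs
    return float(min(p, 1.0))


def genotype_summary(codes) -> GenotypeSummary:
    """Counts, minor-allele frequency and Hardy-Weinberg tests.

    The chi-square variant compares observed genotype counts with
    HWE-expected counts ``(q^2, 2pq, p^2) * N`` on 1 df; the exact-test
    p-value is reported alongside.
    """
    arr = pd.Series(codes, dtype=float).dropna().to_numpy()
    if arr.size == 0:
        raise ValueError("no non-missing genotype codes")
    if not np.isin(arr, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype codes must be 0, 1 or 2")
    n0 = int((arr == 0).sum())
    n1 = int((arr == 1).sum())
    n2 = int((arr == 2).sum())
    n = n0 + n1 + n2
    p = (n1 + 2 * n2) / (2 * n)  # frequency of the allele counted by the code
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    hwe_p = float(stats.chi2.sf(chi2, df=1))
    exact_p = hwe_exact_test(n1, n2, n0)
    return GenotypeSummary(
        counts=(n0, n1, n2),
        n=n,
        maf=float(min(p, 1 - p)),
        major_freq=float(max(p, 1 - p)),
        hwe_chi2=chi2,
        hwe_p=hwe_p,
        hwe_exact_p=exact_p,
    )


# ---------------------------------------------------------------------------
# blood-pressure consolidation and classification


def consolidate_bp(readings, *, max_rel_diff: float = 0.05) -> float:
    """Consolidate 1-3 pressure readings into one value (or NaN).

    With three readings, the mean of the pair with the smallest absolute
    difference.  With two, their mean if the relative difference (of the
    first reading) is within 5%, else missing.  A single reading is
    insufficient and yields missing.
    """
    vals = [float(r) for r in readings if r is not None and not math.isnan(float(r))]
    if len(vals) == 0:
        raise ValueError("at least one reading required")
    if any(v <= 0 for v in vals):
        raise ValueError("pressure readings must be positive")
    if len(vals) == 1:
        return float("nan")
    if len(vals) == 2:
        a, b = vals
        if abs(a - b) / a <= max_rel_diff:
            return (a + b) / 2.0
        return float("nan")
    best = None
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            d = abs(vals[i] - vals[j])
            if best is None or d < best[0]:
                best = (d, (vals[i] + vals[j]) / 2.0)
    return best[1]


def classify_bp(
    sbp_pct: float | None,
    dbp_pct: float | None,
    cutpoints: tuple[float, float] = (90.0, 95.0),
) -> str | float:
    """Normal / prehypertension / hypertension from the worse of the SBP
    and DBP percentiles against the (90th, 95th) cutpoints."""
    lo, hi = cutpoints
    if not lo < hi:
        raise ValueError("cutpoints must be increasing")
    pcts = [x for x in (sbp_pct, dbp_pct) if x is not None and not math.isnan(x)]
    if not pcts:
        return float("nan")
    worst = max(pcts)
    if any(not 0 < x < 100 for x in pcts):
        raise ValueError("percentiles must lie in (0, 100)")
    if worst >= hi:
        return "hypertension"
    if worst >= lo:
        return "prehypertension"
    return "normal"


def percentile_from_z(z: float) -> float:
    return float(stats.norm.cdf(z) * 100.0)


# ---------------------------------------------------------------------------
# reference tables and z-scores


_COLUMNS = [
    "kind", "sex", "age_lo", "age_hi", "height_lo", "height_hi",
    "L", "M", "S", "mu", "sigma",
]


class ReferenceTable:
    """Age/sex(/height)-binned reference for z-scoring, LMS or mean-SD kind.

    File format: comma-delimited with the header
    ``kind,sex,age_lo,age_hi,height_lo,height_hi,L,M,S,mu,sigma`` (unused
    fields empty), half-open bins [lo, hi), ages in years, heights in cm.
    An optional first line ``#cutpoints=90,95`` stores the BP
    classification percentile cutpoints.
    """

    def __init__(self, rows: pd.DataFrame, kind: str, cutpoints=(90.0, 95.0)):
        if kind not in ("lms", "mean_sd"):
            raise ValueError(f"unknown reference-table kind {kind!r}")
        self.kind = kind
        self.cutpoints = tuple(float(c) for c in cutpoints)
        rows = rows.copy()
        for c in _COLUMNS:
            if c not in rows.columns:
                rows[c] = ""
        self.rows = rows[_COLUMNS].reset_index(drop=True)
        value_col = "M" if kind == "lms" else "mu"
        scale_col = "S" if kind == "lms" else "sigma"
        vals = pd.to_numeric(self.rows[value_col])
        scales = pd.to_numeric(self.rows[scale_col])
        if (vals <= 0).any() and kind == "lms":
            raise ValueError("LMS medians must be positive")
        if (scales <= 0).any():
            raise ValueError("reference scale parameters must be positive")

    @property
    def uses_height(self) -> bool:
        return pd.to_numeric(self.rows["height_lo"], errors="coerce").notna().any()

    def _lookup(self, sex: str, age: float, height: float | None = None) -> pd.Series:
        rows = self.rows
        m = (
            (rows["sex"] == sex)
            & (pd.to_numeric(rows["age_lo"]) <= age)
            & (age < pd.to_numeric(rows["age_hi"]))
        )
        if self.uses_height:
            if height is None:
                raise ValueError("this reference table is height-specific")
            m &= (pd.to_numeric(rows["height_lo"]) <= height) & (
                height < pd.to_numeric(rows["height_hi"])
            )
        hit = rows[m]
        if len(hit) == 0:
            raise KeyError(
                f"no reference row covers sex={sex!r}, age={age}"
                + (f", height={height}" if height is not None else "")
            )
        return hit.iloc[0]

    def zscore(self, value: float, sex: str, age: float, height: float | None = None) -> float:
        """LMS: ``((x/M)^L - 1)/(L S)`` with the L->0 limit ``ln(x/M)/S``;
        mean-SD: ``(x - mu)/sigma``.  No extrapolation outside coverage."""
        row = self._lookup(sex, age, height)
        if self.kind == "lms":
            L = float(row["L"]); M = float(row["M"]); S = float(row["S"])
            if value <= 0:
                raise ValueError("LMS z-score needs a positive measurement")
            if abs(L) < 1e-12:
                return math.log(value / M) / S
            return ((value / M) ** L - 1.0) / (L * S)
        mu = float(row["mu"]); sigma = float(row["sigma"])
        return (value - mu) / sigma

    # --- I/O -------------------------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#cutpoints={self.cutpoints[0]:g},{self.cutpoints[1]:g}\n")
            self.rows.to_csv(fh, index=False)

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        cutpoints = (90.0, 95.0)
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#cutpoints="):
                cutpoints = tuple(float(x) for x in first.strip().split("=")[1].split(","))
                rows = pd.read_csv(fh, keep_default_na=False)
            else:
                fh.seek(0)
                rows = pd.read_csv(fh, keep_default_na=False)
        kind = str(rows["kind"].iloc[0])
        return cls(rows, kind=kind, cutpoints=cutpoints)


# ---------------------------------------------------------------------------
# simple derived quantities


def d5d_index(ara: float, dgla: float) -> float:
    """Estimated delta-5 desaturase activity: ARA / DGLA (product/precursor)."""
    if dgla <= 0:
        raise ValueError("DGLA must be positive")
    if ara < 0:
        raise ValueError("ARA cannot be negative")
    return ara / dgla


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight [kg] / height [m] squared."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2
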
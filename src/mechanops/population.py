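"""Population-level analysis of wCDI distributions.

Covers: per-population summaries with single-pass outlier removal, the
overlap coefficient of two fitted normal densities (computed analytically
from the density crossing points plus normal CDF tails), two-component
univariate Gaussian expectation-maximization to decompose a mixed
population into its lineage fractions, and thin wrappers for the χ² test
on recovery-type proportions and the t-test on wCDI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    ParameterError,
)
from .physics import RECOVERY_CLASSES


@dataclass(frozen=True)
class PopulationSummary:
    """Summary of one screened population after outlier removal."""

    label: str
    n: int  # cells before outlier removal
    n_accepted: int
    wcdi_mean: float
    wcdi_sd: float
    strain_mean: float
    recovery_proportions: dict
    recovery_counts: dict
    outlier_count: int

    def __post_init__(self) -> None:
        total = sum(self.recovery_proportions.values())
        if self.n_accepted and abs(total - 1.0) > 1e-12:
            raise ParameterError("recovery proportions must sum to 1")


@dataclass(frozen=True)
class MixtureDecomposition:
    """Two-component univariate Gaussian EM fit."""

    alpha: float  # weight of the component initialized as comp1
    comp1: dict  # {"mean": .., "sd": ..}
    comp2: dict
    log_likelihood: np.ndarray  # per-iteration trajectory
    n_iter: int
    converged: bool
    init_source: str
    flag: str | None = None  # e.g. "identifiability", "variance-floor"


# --------------------------------------------------------------------------


def summarize_population(
    phenotypes, label: str = "", outlier_sd: float = 3.0
) -> PopulationSummary:
    """Summarize wCDI, strain and recovery proportions for one population.

    Values beyond ``outlier_sd`` standard deviations from the mean wCDI are
    removed in a single pass before the statistics are computed.
    ``phenotypes`` may be a list of CellPhenotype objects or a DataFrame
    with ``wCDI``, ``strain`` and ``recovery_class`` columns.
    """
    if isinstance(phenotypes, pd.DataFrame):
        wcdi = phenotypes["wCDI"].to_numpy(dtype=float)
        eps = phenotypes["strain"].to_numpy(dtype=float)
        classes = phenotypes["recovery_class"].to_numpy()
    else:
        wcdi = np.asarray([p.wCDI for p in phenotypes], dtype=float)
        eps = np.asarray([p.strain for p in phenotypes], dtype=float)
        classes = np.asarray([p.recovery_class for p in phenotypes])
    n = len(wcdi)
    if n < 2:
        raise InsufficientDataError("population summary requires at least 2 cells")

    mean, sd = float(wcdi.mean()), float(wcdi.std(ddof=1))
    if sd > 0:
        keep = np.abs(wcdi - mean) <= outlier_sd * sd
    else:
        keep = np.ones(n, dtype=bool)
    wcdi_k, eps_k, classes_k = wcdi[keep], eps[keep], classes[keep]
    counts = {c: int(np.sum(classes_k == c)) for c in RECOVERY_CLASSES}
    n_acc = int(keep.sum())
    props = {c: counts[c] / n_acc for c in RECOVERY_CLASSES}
    return PopulationSummary(
        label=label,
        n=n,
        n_accepted=n_acc,
        wcdi_mean=float(wcdi_k.mean()),
        wcdi_sd=float(wcdi_k.std(ddof=1)) if n_acc >= 2 else 0.0,
        strain_mean=float(eps_k.mean()),
        recovery_proportions=props,
        recovery_counts=counts,
        outlier_count=int(n - n_acc),
    )


# --------------------------------------------------------------------------
# overlap coefficient of two normal densities


def overlap_coefficient(m1: float, s1: float, m2: float, s2: float) -> float:
    """∫ min(f1, f2) dx for two normal densities, computed analytically.

    The crossing points solve the quadratic equation of the log-density
    difference (at most two roots; a single root when the sds are equal);
    on each interval the smaller density's CDF mass is accumulated.
    Symmetric in its arguments and always in [0, 1].
    """
    if not (s1 > 0 and s2 > 0):
        raise ParameterError("standard deviations must be > 0")
    if m1 == m2 and s1 == s2:
        return 1.0

    # log f1 − log f2 = A x² + B x + C
    A = 0.5 / s2**2 - 0.5 / s1**2
    B = m1 / s1**2 - m2 / s2**2
    C = 0.5 * (m2**2 / s2**2 - m1**2 / s1**2) + math.log(s2 / s1)

    if abs(A) < 1e-300:  # equal sds: single crossing
        roots = [-C / B]
    else:
        disc = B**2 - 4 * A * C
        if disc <= 0:
            # Numerically degenerate near-identical densities.
            roots = [-B / (2 * A)]
        else:
            sq = math.sqrt(disc)
            roots = sorted([(-B - sq) / (2 * A), (-B + sq) / (2 * A)])

    edges = [-math.inf] + roots + [math.inf]
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        if math.isinf(lo) and math.isinf(hi):
            mid = 0.5 * (m1 + m2)
        elif math.isinf(lo):
            mid = hi - 1.0
        elif math.isinf(hi):
            mid = lo + 1.0
        else:
            mid = 0.5 * (lo + hi)
        # Compare log densities: far tails underflow in linear space.
        lf1 = stats.norm.logpdf(mid, m1, s1)
        lf2 = stats.norm.logpdf(mid, m2, s2)
        m, s = (m1, s1) if lf1 <= lf2 else (m2, s2)
        total += stats.norm.cdf(hi, m, s) - stats.norm.cdf(lo, m, s)
    return float(min(max(total, 0.0), 1.0))


# --------------------------------------------------------------------------
# two-component Gaussian EM


def em_mixture_fraction(
    values,
    init1: dict,
    init2: dict,
    *,
    freeze_components: bool = False,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureDecomposition:
    """Estimate the fraction α of component 1 in a two-normal mixture by EM.

    ``init1``/``init2`` are ``{"mean": .., "sd": ..}`` reference fits (for
    example the two lineages' sorted-population distributions) used as
    initial values.  By default all parameters are re-estimated; with
    ``freeze_components=True`` only the weights are updated.  The
    log-likelihood trajectory is monotone non-decreasing; convergence is
    declared when the improvement falls below ``tol`` (or at ``max_iter``).
    A component whose sd collapses below 1e-6 of the data sd is reset to a
    floor and the fit flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise InsufficientDataError("EM decomposition requires at least 10 values")
    for init in (init1, init2):
        if not init.get("sd", 0.0) > 0:
            raise ParameterError("initial sds must be > 0")
    if init1["mean"] == init2["mean"] and init1["sd"] == init2["sd"]:
        return MixtureDecomposition(
            alpha=0.5,
            comp1=dict(init1),
            comp2=dict(init2),
            log_likelihood=np.asarray([]),
            n_iter=0,
            converged=False,
            init_source="reference",
            flag="identifiability",
        )

    data_sd = float(x.std(ddof=1)) or 1.0
    sd_floor_trigger = 1e-6 * data_sd
    sd_floor = 1e-3 * data_sd
    mu = np.array([init1["mean"], init2["mean"]], dtype=float)
    sd = np.array([init1["sd"], init2["sd"]], dtype=float)
    w = np.array([0.5, 0.5])

    ll_traj: list[float] = []
    flag = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for numerical safety.
        logp = np.stack(
            [np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)]
        )
        log_norm = logsumexp(logp, axis=0)
        ll = float(log_norm.sum())
        ll_traj.append(ll)
        resp = np.exp(logp - log_norm)

        # M-step.
        nk = resp.sum(axis=1)
        w = nk / x.size
        if not freeze_components:
            mu = (resp @ x) / nk
            var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)])
            sd = np.sqrt(var)
            if np.any(sd < sd_floor_trigger):
                sd = np.maximum(sd, sd_floor)
                flag = "variance-floor"

        if len(ll_traj) >= 2 and ll_traj[-1] - ll_traj[-2] < tol:
            converged = True
            break

    return MixtureDecomposition(
        alpha=float(w[0]),
        comp1={"mean": float(mu[0]), "sd": float(sd[0])},
        comp2={"mean": float(mu[1]), "sd": float(sd[1])},
        log_likelihood=np.asarray(ll_traj),
        n_iter=it,
        converged=converged,
        init_source="reference",
        flag=flag,
    )


# --------------------------------------------------------------------------
# hypothesis-test wrappers


@dataclass(frozen=True)
class TestResult:
    statistic: float
    dof: float
    pvalue: float
    method: str


def _counts_vector(summary) -> np.ndarray:
    if isinstance(summary, PopulationSummary):
        counts = summary.recovery_counts
    elif isinstance(summary, dict):
        counts = summary
    else:
        counts = dict(zip(RECOVERY_CLASSES, summary))
    return np.asarray([counts[c] for c in RECOVERY_CLASSES], dtype=float)


def compare_recovery_profiles(summary_a, summary_b) -> TestResult:
    """χ² test on the 2×3 contingency table of recovery-class counts."""
    a = _counts_vector(summary_a)
    b = _counts_vector(summary_b)
    table = np.vstack([a, b])
    if table.sum(axis=1).min() == 0 or np.any(table.sum(axis=0) == 0):
        raise DegenerateTableError("contingency table has an empty margin")
    if np.array_equal(a, b):
        return TestResult(statistic=0.0, dof=2, pvalue=1.0, method="chi2")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(res.statistic), dof=float(res.dof), pvalue=float(res.pvalue), method="chi2"
    )


def compare_wcdi(values_a, values_b) -> TestResult:
    """t-test on two wCDI samples.

    Equal-length samples are compared pairwise (matching the screening
    protocol of equal-n populations); unequal lengths fall back to Welch's
    unpaired test, declared in the ``method`` field.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("t-test requires at least 2 values per sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and np.allclose(a.mean(), b.mean()):
        return TestResult(statistic=0.0, dof=a.size - 1, pvalue=1.0, method="degenerate")
    if a.size == b.size:
        diffs = a - b
        if np.all(diffs == 0):
            return TestResult(statistic=0.0, dof=a.size - 1, pvalue=1.0, method="paired")
        res = stats.ttest_rel(a, b)
        return TestResult(
            statistic=float(res.statistic),
            dof=float(a.size - 1),
            pvalue=float(res.pvalue),
            method="paired",
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        dof=float(res.df),
        pvalue=float(res.pvalue),
        method="welch",
    )
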
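"""Hit-set intersection, dose-response confirmation, and ANOVA follow-up.

The two phenotype screens are crossed by plain set intersection.  Lead
compounds are confirmed by a four-parameter logistic (4PL) dose-response
fit

    y(x) = d + (a - d) / (1 + (x / c)^b)

with bottom d, top a, EC50 c (> 0) and Hill slope b, and by one-way
ANOVA with Bonferroni-adjusted pairwise comparisons against control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "cross_screens",
    "fit_4pl",
    "four_pl",
    "confirm_by_anova",
    "DoseResponseFit",
    "AnovaResult",
]


def cross_screens(cystine_hits: Iterable[str], apoptosis_hits: Iterable[str]) -> set[str]:
    """Compounds active in both phenotypes (commutative, idempotent)."""
    return set(cystine_hits) & set(apoptosis_hits)


def four_pl(x: np.ndarray, a: float, d: float, c: float, b: float) -> np.ndarray:
    """Evaluate the 4PL curve; y(c) = (a + d) / 2 for any slope."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class DoseResponseFit:
    compound_id: str
    top: float        # a: response as dose -> 0 (for b > 0)
    bottom: float     # d: response as dose -> inf (for b > 0)
    ec50: float       # c, same units as the doses
    hill: float       # b, dimensionless
    rss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        if not self.converged:
            raise RuntimeError("fit did not converge; parameters withheld")
        return four_pl(x, self.top, self.bottom, self.ec50, self.hill)


def _fit_once(x, y, a0, d0, c0, b0):
    def resid(theta):
        a, d, logc, b = theta
        return four_pl(x, a, d, np.exp(logc), b) - y

    sol = optimize.least_squares(
        resid,
        x0=[a0, d0, np.log(c0), b0],
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=5000,
    )
    a, d, logc, b = sol.x
    return a, d, float(np.exp(logc)), b, float(np.sum(sol.fun**2)), bool(sol.success)


def fit_4pl(
    doses: Sequence[float],
    responses: Sequence[float],
    compound_id: str = "",
    n_restarts: int = 5,
    seed: int = 0,
) -> DoseResponseFit:
    """Least-squares 4PL fit with data-driven starts and bounded restarts.

    Initialization: a from the response at the lowest dose, d at the
    highest, c from the dose grid midpoint (log scale), b = 1; on
    failure up to ``n_restarts`` perturbed restarts (both slope signs).
    Near-constant responses make the EC50 unidentifiable and are
    reported with ``converged=False``.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses must have equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("doses and responses must be finite")
    if (x <= 0).any():
        raise ValueError("doses must be positive")
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct doses for a 4-parameter fit")

    span = float(y.max() - y.min())
    if span < 1e-8 * max(1.0, abs(float(y.mean()))):
        # flat data: a ~= d, EC50 unidentifiable
        return DoseResponseFit(compound_id, float(y.mean()), float(y.mean()),
                               float("nan"), float("nan"), float(np.var(y) * y.size), False)

    order = np.argsort(x)
    a0 = float(y[order[0]])   # low-dose asymptote
    d0 = float(y[order[-1]])  # high-dose asymptote
    c0 = float(np.exp(0.5 * (np.log(x.min()) + np.log(x.max()))))

    rng = np.random.default_rng(seed)
    starts = [(a0, d0, c0, 1.0), (d0, a0, c0, 1.0)]
    for _ in range(n_restarts):
        starts.append(
            (
                a0 + span * rng.normal(0, 0.2),
                d0 + span * rng.normal(0, 0.2),
                float(np.exp(rng.uniform(np.log(x.min()), np.log(x.max())))),
                float(rng.choice([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])),
            )
        )

    best = None
    for a_s, d_s, c_s, b_s in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a, d, c, b, rss, ok = _fit_once(x, y, a_s, d_s, c_s, b_s)
        except Exception:
            continue
        if not np.isfinite([a, d, c, b, rss]).all() or c <= 0:
            continue
        if best is None or rss < best[4]:
            best = (a, d, c, b, rss, ok)
        if rss <= 1e-20 * max(1.0, float(np.sum(y**2))):
            break

    if best is None:
        return DoseResponseFit(compound_id, float("nan"), float("nan"),
                               float("nan"), float("nan"), float("inf"), False)
    a, d, c, b, rss, ok = best
    degenerate = abs(a - d) < 1e-6 * max(1.0, span)
    return DoseResponseFit(compound_id, float(a), float(d), float(c), float(b),
                           rss, bool(ok and not degenerate))


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    pairwise: dict[tuple[int, int], float]  # Bonferroni-adjusted p per group pair
    warning: str | None = None


def confirm_by_anova(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA; if significant, Bonferroni-adjusted pairwise t tests.

    Pairwise comparisons use the classical multiple-comparison posttest:
    t statistics with the pooled within-group mean square and its
    degrees of freedom, raw p multiplied by the number of pairs and
    capped at 1.  They are computed only when the overall p < ``alpha``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 replicates")

    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        warnings.warn("all observations identical; ANOVA F undefined (no evidence)")
        return AnovaResult(float("nan"), 1.0, {}, warning="all observations identical")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    f, p = float(f), float(p)
    if not np.isfinite(f):
        warnings.warn("ANOVA F undefined for these groups (no evidence)")
        return AnovaResult(float("nan"), 1.0, {}, warning="F undefined")

    pairwise: dict[tuple[int, int], float] = {}
    if p < alpha:
        n_tot = sum(a.size for a in arrays)
        k = len(arrays)
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (n_tot - k)
        df = n_tot - k
        n_pairs = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse * (1 / arrays[i].size + 1 / arrays[j].size))
                if se == 0:
                    p_raw = 0.0 if arrays[i].mean() != arrays[j].mean() else 1.0
                else:
                    t = (arrays[i].mean() - arrays[j].mean()) / se
                    p_raw = 2.0 * float(stats.t.sf(abs(t), df))
                pairwise[(i, j)] = min(1.0, p_raw * n_pairs)
    return AnovaResult(f, p, pairwise)


def bonferroni(p_values: Sequence[float], n_comparisons: int | None = None) -> np.ndarray:
    """Multiply raw p values by the number of comparisons, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = n_comparisons if n_comparisons is not None else p.size
    return np.minimum(1.0, p * m)
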
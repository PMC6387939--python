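"""Right-truncated Zipf–Mandelbrot and Hyper-Pascal models with chi-square fitting.

Two discrete families cover the two spectra an F-motif analysis produces:

* **Zipf–Mandelbrot (ZM)** over ranks x = 1..n:
  ``P(x) = (b + x)^(-a) / F(n)`` with ``F(n) = sum_{i=1..n} (b + i)^(-a)``,
  a > 0 the decay exponent, b > -1 the low-rank shift, and n the right
  truncation point, fixed here at the number of observed types.

* **Hyper-Pascal (HP)** over x = 0, 1, 2, ...:
  ``y(x) = [C(k+x-1, x) / C(m+x-1, x)] * q^x * p0`` with
  ``p0 = [2F1(k, 1; m; q)]^(-1)``; motif lengths L >= 1 sit on the shifted
  support x = L - 1.

Both are fitted by minimizing the Pearson chi-square between observed and
expected counts with a derivative-free simplex search — the convention of
the word-frequency fitting tradition — with maximum likelihood available
behind a flag.  Model objects follow the statsmodels idiom: construct from
data, ``fit()`` returns a Results object carrying parameters, goodness of
fit and a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .corpus_io import ConsistencyError
from .motif import LengthSpectrum, MotifSpectrum

__all__ = [
    "ZMParams",
    "HPParams",
    "FitReport",
    "InsufficientDataError",
    "zm_pmf",
    "hyp2f1_k1m",
    "hp_pmf",
    "goodness_of_fit",
    "ZipfMandelbrot",
    "ZipfMandelbrotResults",
    "HyperPascal",
    "HyperPascalResults",
    "fit_zm",
    "fit_hyperpascal",
]

_B_FLOOR = -1.0 + 1e-6  # b is clipped away from the pole at -1
_Q_EPS = 1e-6  # q clipped into (0, 1) during search
_SERIES_RTOL = 1e-14
_SERIES_MAX_TERMS = 100_000


class InsufficientDataError(ValueError):
    """Too few spectrum classes to identify the model parameters."""


# ---------------------------------------------------------------------------
# probability mass functions


def zm_pmf(a: float, b: float, n: int) -> np.ndarray:
    """Right-truncated Zipf–Mandelbrot pmf over ranks 1..n.

    Component x equals ``(b+x)^(-a) / sum_{i=1..n} (b+i)^(-a)``.  a = 0 is
    the uniform limit; b must exceed -1.
    """
    if b <= -1:
        raise ValueError(f"parameter b must exceed -1, got {b}")
    if a < 0:
        raise ValueError(f"parameter a must be >= 0, got {a}")
    if n < 1:
        raise ValueError(f"truncation point n must be >= 1, got {n}")
    x = np.arange(1, n + 1, dtype=float)
    w = (b + x) ** (-a)
    return w / w.sum()


def hyp2f1_k1m(k: float, m: float, q: float) -> float:
    """Gauss hypergeometric 2F1(k, 1; m; q) by direct series summation.

    With the middle parameter equal to 1 the series collapses to
    ``sum_j [(k)_j / (m)_j] q^j`` (rising factorials); it is summed until
    the relative term falls below 1e-14 or 100,000 terms.  Requires
    0 <= q < 1 (the series diverges at q >= 1) and k, m > 0.
    """
    if not (0 <= q < 1):
        raise ValueError(f"q must lie in [0, 1), got {q}")
    if k <= 0 or m <= 0:
        raise ValueError(f"k and m must be positive, got k={k}, m={m}")
    total = term = 1.0
    for j in range(_SERIES_MAX_TERMS):
        term *= q * (k + j) / (m + j)
        total += term
        if term < _SERIES_RTOL * total:
            return total
    warnings.warn("2F1 series did not reach tolerance within 100000 terms", stacklevel=2)
    return total


def _hp_p0(k: float, m: float, q: float) -> float:
    return 1.0 / hyp2f1_k1m(k, m, q)


def hp_pmf(k: float, m: float, q: float, x_max: int) -> np.ndarray:
    """Hyper-Pascal pmf over x = 0..x_max.

    Uses the stable recurrence ``y(x+1) = y(x) * q * (k+x) / (m+x)`` seeded
    at ``y(0) = p0``.  Warns if the truncated vector leaves more than 1e-9
    of tail mass beyond x_max.
    """
    if x_max < 0:
        raise ValueError("x_max must be >= 0")
    p0 = _hp_p0(k, m, q)
    y = np.empty(x_max + 1)
    y[0] = p0
    for x in range(x_max):
        y[x + 1] = y[x] * q * (k + x) / (m + x)
    tail = 1.0 - y.sum()
    if tail > 1e-9:
        warnings.warn(
            f"hp_pmf truncated at x_max={x_max} leaves tail mass {tail:.3e}",
            stacklevel=2,
        )
    return y


def _hp_expected_probs(k: float, m: float, q: float, n_classes: int) -> np.ndarray:
    """HP class probabilities over x = 0..n_classes-1 with the tail folded
    into the last class, so the vector sums to 1 exactly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y = hp_pmf(k, m, q, n_classes - 1)
    y = y.copy()
    y[-1] = max(1.0 - y[:-1].sum(), 1e-300)
    return y


# ---------------------------------------------------------------------------
# parameters and goodness of fit


@dataclass(frozen=True)
class ZMParams:
    a: float
    b: float
    n: int

    def pmf(self) -> np.ndarray:
        return zm_pmf(self.a, self.b, self.n)


@dataclass(frozen=True)
class HPParams:
    k: float
    m: float
    q: float
    p0: float

    @classmethod
    def create(cls, k: float, m: float, q: float) -> "HPParams":
        return cls(k=k, m=m, q=q, p0=_hp_p0(k, m, q))

    def pmf(self, x_max: int) -> np.ndarray:
        return hp_pmf(self.k, self.m, self.q, x_max)


@dataclass
class FitReport:
    """Pearson chi-square goodness of fit, Altmann-Fitter style.

    ``C = X2 / N`` is the discrepancy coefficient; ``R2`` is computed on
    the unpooled observed-vs-expected count vectors; ``df`` is the pooled
    class count minus free parameters minus one, floored at zero.
    """

    X2: float
    df: int
    p_X2: float
    C: float
    R2: float
    converged: bool = True
    pooled_classes: int = 0


def _pool_tail(obs: np.ndarray, exp_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pool adjacent tail classes until every pooled expected count >= 1."""
    po: list[float] = []
    pe: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(obs[::-1], exp_counts[::-1]):
        acc_o += o
        acc_e += e
        if acc_e >= 1.0:
            po.append(acc_o)
            pe.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0.0:
        if po:
            po[-1] += acc_o
            pe[-1] += acc_e
        else:
            po.append(acc_o)
            pe.append(acc_e)
    return np.array(po[::-1]), np.array(pe[::-1])


def goodness_of_fit(
    observed: np.ndarray, expected: np.ndarray, N: int, n_params: int
) -> FitReport:
    """Pearson X2 with tail pooling, discrepancy coefficient and R2.

    ``observed`` are counts summing to N; ``expected`` are class
    probabilities summing to 1.  Tail classes are pooled until every
    expected count is at least 1; R2 is computed on the unpooled vectors.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ConsistencyError(
            f"observed ({obs.shape}) and expected ({exp.shape}) lengths differ"
        )
    exp_counts = N * exp
    ss_res = float(((obs - exp_counts) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else -math.inf
    po, pe = _pool_tail(obs, exp_counts)
    x2 = float(((po - pe) ** 2 / pe).sum())
    pooled = len(po)
    df = max(pooled - n_params - 1, 0)
    p = float(stats.chi2.sf(x2, df)) if df > 0 else math.nan
    return FitReport(
        X2=x2, df=df, p_X2=p, C=x2 / N, R2=r2, converged=True, pooled_classes=pooled
    )


# ---------------------------------------------------------------------------
# model objects


def _simplex(fun, x0, maxfev):
    """Two-stage Nelder-Mead: polish by restarting from the first optimum."""
    f0 = abs(fun(np.asarray(x0, dtype=float)))
    opts = {"xatol": 1e-8, "fatol": 1e-8 * (1.0 + f0), "maxfev": maxfev}
    res = optimize.minimize(fun, x0, method="Nelder-Mead", options=opts)
    res2 = optimize.minimize(fun, res.x, method="Nelder-Mead", options=opts)
    if res2.fun <= res.fun:
        res2.nfev += res.nfev
        return res2
    res.nfev += res2.nfev
    return res


class ZipfMandelbrot:
    """Right-truncated Zipf–Mandelbrot model for a rank-frequency spectrum.

    Parameters
    ----------
    counts : array-like of int
        Observed frequencies at ranks 1..n, descending.  The truncation
        point n is fixed at the number of classes.
    """

    n_free_params = 2

    def __init__(self, counts):
        self.counts = np.asarray(counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) < 4:
            raise InsufficientDataError(
                f"ZM fitting needs at least 4 rank classes, got {self.counts.size}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.N = float(self.counts.sum())
        self.n = len(self.counts)

    @classmethod
    def from_spectrum(cls, spectrum: MotifSpectrum) -> "ZipfMandelbrot":
        return cls(spectrum.frequencies)

    def _clip(self, theta) -> tuple[float, float]:
        return max(float(theta[0]), 0.0), max(float(theta[1]), _B_FLOOR)

    def chisquare(self, a: float, b: float) -> float:
        exp = self.N * zm_pmf(max(a, 0.0), max(b, _B_FLOOR), self.n)
        return float(((self.counts - exp) ** 2 / exp).sum())

    def loglike(self, a: float, b: float) -> float:
        p = zm_pmf(max(a, 0.0), max(b, _B_FLOOR), self.n)
        return float((self.counts * np.log(p)).sum())

    def start_params(self) -> np.ndarray:
        # slope of the log-log rank-frequency regression seeds the exponent
        ranks = np.arange(1, self.n + 1, dtype=float)
        pos = self.counts > 0
        slope = np.polyfit(np.log(ranks[pos]), np.log(self.counts[pos]), 1)[0]
        return np.array([max(-slope, 0.1), 1.0])

    def fit(self, method: str = "chisq", maxfev: int = 10_000) -> "ZipfMandelbrotResults":
        if method == "chisq":
            fun = lambda t: self.chisquare(*t)
        elif method == "ml":
            fun = lambda t: -self.loglike(*t)
        else:
            raise ValueError(f"unknown method {method!r}")
        res = _simplex(fun, self.start_params(), maxfev)
        a, b = self._clip(res.x)
        params = ZMParams(a=a, b=b, n=self.n)
        report = goodness_of_fit(self.counts, params.pmf(), int(self.N), self.n_free_params)
        report.converged = bool(res.success)
        return ZipfMandelbrotResults(self, params, report, nfev=res.nfev, method=method)


@dataclass
class ZipfMandelbrotResults:
    model: ZipfMandelbrot
    params: ZMParams
    report: FitReport
    nfev: int = 0
    method: str = "chisq"

    def expected(self) -> np.ndarray:
        return self.model.N * self.params.pmf()

    def summary(self) -> str:
        p, r = self.params, self.report
        lines = [
            "Zipf-Mandelbrot fit (right-truncated)",
            "=" * 45,
            f"criterion            {'Pearson X2' if self.method == 'chisq' else 'max. likelihood'}",
            f"a (decay exponent)   {p.a:12.4f}",
            f"b (rank shift)       {p.b:12.4f}",
            f"n (truncation)       {p.n:12d}",
            f"N (motif tokens)     {int(self.model.N):12d}",
            f"X2                   {r.X2:12.4f}",
            f"df                   {r.df:12d}",
            f"P(X2)                {r.p_X2:12.4f}",
            f"C = X2/N             {r.C:12.4f}",
            f"R2                   {r.R2:12.4f}",
            f"pooled classes       {r.pooled_classes:12d}",
            f"converged            {str(r.converged):>12s}",
        ]
        return "\n".join(lines)


class HyperPascal:
    """Hyper-Pascal model for a motif length spectrum.

    Parameters
    ----------
    counts : array-like of int
        Observed counts at x = 0, 1, 2, ... — i.e. length L maps to the
        shifted support point x = L - 1, with zero-count intermediate
        classes filled in.
    """

    n_free_params = 3

    def __init__(self, counts):
        self.counts = np.asarray(counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) < 2:
            raise InsufficientDataError(
                f"HP fitting needs at least 2 length classes, got {self.counts.size}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.N = float(self.counts.sum())
        self.n_classes = len(self.counts)

    @classmethod
    def from_lengths(cls, lengths: LengthSpectrum) -> "HyperPascal":
        if len(lengths.counts) < 2:
            raise InsufficientDataError(
                "HP fitting needs at least 2 distinct length classes"
            )
        x_max = lengths.max_length - 1
        counts = [lengths.counts.get(x + 1, 0) for x in range(x_max + 1)]
        return cls(counts)

    @staticmethod
    def _clip(theta) -> tuple[float, float, float]:
        k = max(float(theta[0]), 1e-6)
        m = max(float(theta[1]), 1e-6)
        q = min(max(float(theta[2]), _Q_EPS), 1.0 - _Q_EPS)
        return k, m, q

    def chisquare(self, k: float, m: float, q: float) -> float:
        k, m, q = self._clip((k, m, q))
        exp = self.N * _hp_expected_probs(k, m, q, self.n_classes)
        return float(((self.counts - exp) ** 2 / exp).sum())

    def start_params(self) -> np.ndarray:
        x = np.arange(self.n_classes, dtype=float)
        mean_len = float((self.counts * (x + 1)).sum() / self.N)
        q0 = min(max(1.0 - 1.0 / mean_len, 0.05), 0.9)
        return np.array([1.0, 1.0, q0])

    def fit(self, maxfev: int = 10_000) -> "HyperPascalResults":
        fun = lambda t: self.chisquare(*t)
        res = _simplex(fun, self.start_params(), maxfev)
        k, m, q = self._clip(res.x)
        params = HPParams.create(k, m, q)
        exp = _hp_expected_probs(k, m, q, self.n_classes)
        report = goodness_of_fit(self.counts, exp, int(self.N), self.n_free_params)
        report.converged = bool(res.success)
        return HyperPascalResults(self, params, report, nfev=res.nfev)


@dataclass
class HyperPascalResults:
    model: HyperPascal
    params: HPParams
    report: FitReport
    nfev: int = 0

    def expected(self) -> np.ndarray:
        return self.model.N * _hp_expected_probs(
            self.params.k, self.params.m, self.params.q, self.model.n_classes
        )

    def summary(self) -> str:
        p, r = self.params, self.report
        lines = [
            "Hyper-Pascal fit (length spectrum, support x = L - 1)",
            "=" * 53,
            f"k                    {p.k:12.4f}",
            f"m                    {p.m:12.4f}",
            f"q                    {p.q:12.4f}",
            f"p0 = 1/2F1(k,1;m;q)  {p.p0:12.4f}",
            f"N (motifs)           {int(self.model.N):12d}",
            f"X2                   {r.X2:12.4f}",
            f"df                   {r.df:12d}",
            f"P(X2)                {r.p_X2:12.4f}",
            f"C = X2/N             {r.C:12.4f}",
            f"R2                   {r.R2:12.4f}",
            f"pooled classes       {r.pooled_classes:12d}",
            f"converged            {str(r.converged):>12s}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_zm(spectrum: MotifSpectrum, method: str = "chisq") -> tuple[ZMParams, FitReport]:
    """Fit the ZM model to a motif rank-frequency spectrum (n fixed at V)."""
    res = ZipfMandelbrot.from_spectrum(spectrum).fit(method=method)
    return res.params, res.report


def fit_hyperpascal(lengths: LengthSpectrum) -> tuple[HPParams, FitReport]:
    """Fit the Hyper-Pascal model to a motif length spectrum."""
    res = HyperPascal.from_lengths(lengths).fit()
    return res.params, res.report
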
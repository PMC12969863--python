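"""Price-determinants model: gamma GLM with log link, fitted by IRLS.

The response is the inflation-adjusted unit price of a net.  Fixed effects
follow the market analysis this package implements: net type (reference
pyrethroid-only), net area (m²), annual market size (millions of nets
shipped, a demand proxy), market concentration (HHI in thousands), a binary
regime indicator for the Global Fund market shaping strategy (GFMSS, pooled
procurement + reference pricing from 2016), and oil price (tens of USD per
barrel, a raw-materials proxy) and destination region (reference
sub-Saharan Africa) entered within GFMSS strata — i.e. separate slopes
before and after the strategy.

Product brand is a grouping factor rather than a covariate of interest; it
can be omitted, absorbed as fixed effects, or shrunk with a ridge penalty
whose strength derives from a configured brand-variance ratio (the default,
a light-weight stand-in for a random intercept).

The fit itself is iteratively reweighted least squares on the gamma
log-likelihood.  For the log link the working weights are identically 1
(variance function μ² cancels the link derivative), so each IRLS step is an
ordinary least-squares solve on the working response z = η + (y − μ)/μ.
Inference is Wald: covariance = Pearson-dispersion × (XᵀX + D)⁻¹.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concentration import UnknownPolicy, compute_hhi, compute_shares
from .records import FibreType, NetType, Region, TransactionRecord

logger = logging.getLogger("itnvalue")

__all__ = [
    "ModelSpec",
    "Design",
    "GlmFit",
    "CollinearityError",
    "build_design",
    "fit_gamma_glm",
    "fit_design",
    "backward_eliminate",
    "rate_ratio",
    "ItnPriceModel",
    "ItnPriceResults",
]

# Term vocabulary.  Order fixes design-matrix column order.
TERM_INTERCEPT = "intercept"
TERM_NET_TYPE = "net_type"
TERM_FIBRE = "fibre_type"
TERM_AREA = "area_m2"
TERM_SHIPPED = "nets_shipped_millions"
TERM_HHI = "hhi_thousands"
TERM_GFMSS = "gfmss"
TERM_OIL_GFMSS = "oil_tens:gfmss"
TERM_REGION_GFMSS = "region:gfmss"
TERM_SHIPPED_GFMSS = "nets_shipped_millions:gfmss"

FINAL_TERMS = (
    TERM_INTERCEPT,
    TERM_NET_TYPE,
    TERM_AREA,
    TERM_SHIPPED,
    TERM_HHI,
    TERM_GFMSS,
    TERM_OIL_GFMSS,
    TERM_REGION_GFMSS,
    TERM_SHIPPED_GFMSS,
)
INITIAL_TERMS = (
    TERM_INTERCEPT,
    TERM_NET_TYPE,
    TERM_FIBRE,
    TERM_AREA,
    TERM_SHIPPED,
    TERM_HHI,
    TERM_GFMSS,
    TERM_OIL_GFMSS,
    TERM_REGION_GFMSS,
    TERM_SHIPPED_GFMSS,
)

#: A term cannot be eliminated while any of these dependent terms remain.
_DEPENDENTS = {
    TERM_SHIPPED: (TERM_SHIPPED_GFMSS,),
    TERM_GFMSS: (TERM_OIL_GFMSS, TERM_REGION_GFMSS, TERM_SHIPPED_GFMSS),
}

_NON_REF_REGIONS = (Region.ASIA_PACIFIC, Region.EECA, Region.LAC, Region.MENA)


class CollinearityError(ValueError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns):
        self.columns = tuple(columns)
        super().__init__(f"design matrix rank deficient; collinear terms: {self.columns}")


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the design and how brand is adjusted for.

    ``brand_mode``: ``"omit"`` | ``"fixed"`` | ``"ridge"`` (default).
    ``brand_prior_var`` is the assumed brand-intercept variance on the
    log-price scale; the ridge penalty is dispersion / brand_prior_var, the
    usual variance-ratio shrinkage.  ``hhi_lag`` selects which year's
    realized HHI drives a given year's prices (default: previous year).
    """

    terms: tuple[str, ...] = FINAL_TERMS
    gfmss_start_year: int = 2016
    brand_mode: str = "ridge"
    brand_prior_var: float = 0.01
    hhi_lag: int = 1

    def __post_init__(self) -> None:
        unknown = [t for t in self.terms if t not in INITIAL_TERMS]
        if unknown:
            raise ValueError(f"unknown model terms: {unknown}")
        if self.brand_mode not in ("omit", "fixed", "ridge"):
            raise ValueError(f"unknown brand_mode {self.brand_mode!r}")

    @classmethod
    def default(cls, **kw) -> "ModelSpec":
        return cls(terms=FINAL_TERMS, **kw)

    @classmethod
    def initial(cls, **kw) -> "ModelSpec":
        """Starting model for stepwise selection (includes fibre type)."""
        return cls(terms=INITIAL_TERMS, **kw)

    def drop(self, term: str) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t != term))


@dataclass(frozen=True)
class Design:
    """Design matrix, response and term bookkeeping for one fit."""

    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]
    term_blocks: Mapping[str, tuple[int, ...]]
    spec: ModelSpec
    penalized: tuple[int, ...] = ()  # column indices under the brand ridge


def _year_covariates(records, spec: ModelSpec, market_size_by_year, hhi_by_year):
    years = sorted({r.year for r in records})
    if market_size_by_year is None:
        market_size_by_year = {}
        for y in years:
            total = sum(r.quantity for r in records if r.year == y)
            market_size_by_year[y] = total / 1e6
    if hhi_by_year is None:
        hhi_by_year = {
            y: compute_hhi(compute_shares(records, y), UnknownPolicy.EXCLUDE_RENORMALIZE)
            for y in years
        }
    # lag-1 convention: a year's prices respond to the previous year's
    # realized concentration; the first observed year falls back on itself.
    design_hhi = {}
    for y in years:
        src = y - spec.hhi_lag
        design_hhi[y] = hhi_by_year.get(src, hhi_by_year[y])
    return market_size_by_year, design_hhi


def build_design(
    records: Sequence[TransactionRecord],
    spec: ModelSpec | None = None,
    market_size_by_year: Mapping[int, float] | None = None,
    hhi_by_year: Mapping[int, float] | None = None,
) -> Design:
    """Assemble the design matrix and response for the price model.

    Continuous covariates use the conventional scalings: HHI in thousands,
    market size in millions of nets, oil price in tens of USD/bbl.  Year-level
    covariates (market size, HHI) are computed from the records themselves
    unless supplied.  The response is ``unit_price_real``.
    """
    spec = spec or ModelSpec.default()
    records = list(records)
    if not records:
        raise ValueError("no records to build a design from")
    for r in records:
        if r.net_type is NetType.UNTREATED:
            raise ValueError(
                "unsupported categorical level NetType.UNTREATED in model data; "
                "filter transactions first"
            )
        if r.unit_price_real is None:
            raise ValueError("unit_price_real missing; deflate transactions first")
        if TERM_OIL_GFMSS in spec.terms and r.oil_price_real is None:
            raise ValueError("oil_price_real missing; deflate transactions first")

    market_size, design_hhi = _year_covariates(
        records, spec, market_size_by_year, hhi_by_year
    )

    n = len(records)
    cols: list[str] = []
    data: list[np.ndarray] = []
    blocks: dict[str, list[int]] = {}

    year = np.array([r.year for r in records])
    g = (year >= spec.gfmss_start_year).astype(float)

    def add(term: str, name: str, values: np.ndarray) -> None:
        blocks.setdefault(term, []).append(len(cols))
        cols.append(name)
        data.append(np.asarray(values, dtype=float))

    for term in spec.terms:
        if term == TERM_INTERCEPT:
            add(term, "intercept", np.ones(n))
        elif term == TERM_NET_TYPE:
            for level in (NetType.DUAL_AI, NetType.PBO):
                add(term, f"net_type[{level.value}]",
                    np.array([1.0 if r.net_type is level else 0.0 for r in records]))
        elif term == TERM_FIBRE:
            add(term, "fibre_type[POLYETHYLENE]",
                np.array([1.0 if r.fibre_type is FibreType.POLYETHYLENE else 0.0 for r in records]))
        elif term == TERM_AREA:
            add(term, "area_m2", np.array([r.area_m2 for r in records]))
        elif term == TERM_SHIPPED:
            add(term, "nets_shipped_millions",
                np.array([market_size[r.year] for r in records]))
        elif term == TERM_HHI:
            add(term, "hhi_thousands",
                np.array([design_hhi[r.year] / 1000.0 for r in records]))
        elif term == TERM_GFMSS:
            add(term, "gfmss", g)
        elif term == TERM_OIL_GFMSS:
            oil_tens = np.array([r.oil_price_real / 10.0 for r in records])
            add(term, "oil_tens:gfmss[present]", oil_tens * g)
            add(term, "oil_tens:gfmss[absent]", oil_tens * (1.0 - g))
        elif term == TERM_REGION_GFMSS:
            for level in _NON_REF_REGIONS:
                ind = np.array([1.0 if r.region is level else 0.0 for r in records])
                add(term, f"region[{level.value}]:gfmss[present]", ind * g)
                add(term, f"region[{level.value}]:gfmss[absent]", ind * (1.0 - g))
        elif term == TERM_SHIPPED_GFMSS:
            shipped = np.array([market_size[r.year] for r in records])
            add(term, "nets_shipped_millions:gfmss[present]", shipped * g)

    penalized: list[int] = []
    if spec.brand_mode != "omit":
        brands = sorted({r.brand for r in records})
        # fixed effects need a reference level; ridge keeps all (penalty
        # resolves the aliasing with the intercept)
        levels = brands[1:] if spec.brand_mode == "fixed" else brands
        for b in levels:
            idx = len(cols)
            add("brand", f"brand[{b}]",
                np.array([1.0 if r.brand == b else 0.0 for r in records]))
            if spec.brand_mode == "ridge":
                penalized.append(idx)

    X = np.column_stack(data)
    y = np.array([r.unit_price_real for r in records], dtype=float)
    return Design(
        X=X,
        y=y,
        columns=tuple(cols),
        term_blocks={t: tuple(ix) for t, ix in blocks.items()},
        spec=spec,
        penalized=tuple(penalized),
    )


# ---------------------------------------------------------------------------
# IRLS fit


@dataclass(frozen=True)
class GlmFit:
    """Fitted gamma GLM: point estimates, Wald inference, diagnostics."""

    columns: tuple[str, ...]
    beta: np.ndarray
    cov: np.ndarray
    dispersion: float
    deviance: float
    n_obs: int
    converged: bool
    iterations: int
    deviance_trace: tuple[float, ...]
    term_blocks: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def _index(self, term: str) -> int:
        try:
            return self.columns.index(term)
        except ValueError:
            raise KeyError(f"unknown term {term!r}; have {self.columns}") from None

    @property
    def coefficients(self) -> dict:
        return dict(zip(self.columns, self.beta))

    @property
    def std_errors(self) -> dict:
        se = np.sqrt(np.diag(self.cov))
        return dict(zip(self.columns, se))

    @property
    def ci95(self) -> dict:
        se = np.sqrt(np.diag(self.cov))
        return {
            c: (b - 1.96 * s, b + 1.96 * s)
            for c, b, s in zip(self.columns, self.beta, se)
        }

    @property
    def p_values(self) -> dict:
        """Two-sided Wald p-values per coefficient."""
        se = np.sqrt(np.diag(self.cov))
        z = self.beta / se
        return dict(zip(self.columns, 2.0 * stats.norm.sf(np.abs(z))))

    def term_pvalue(self, term: str) -> float:
        """Wald block test (chi²) for all columns of a model term."""
        idx = list(self.term_blocks.get(term, ()))
        if not idx:
            raise KeyError(f"term {term!r} not in fit")
        b = self.beta[idx]
        V = self.cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(V, b))
        return float(stats.chi2.sf(chi2, df=len(idx)))


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))


def _check_rank(X: np.ndarray, columns) -> None:
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        tol = s.max() * max(n, p) * np.finfo(float).eps
        null = vt[s < tol]
        involved = sorted(
            {columns[j] for v in null for j in np.flatnonzero(np.abs(v) > 1e-8)}
        )
        raise CollinearityError(involved)


def fit_gamma_glm(
    X: np.ndarray,
    y: np.ndarray,
    columns: Sequence[str] | None = None,
    term_blocks: Mapping[str, tuple[int, ...]] | None = None,
    penalized: Sequence[int] = (),
    brand_prior_var: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Maximize the gamma log-likelihood under a log link by IRLS.

    ``penalized`` columns (brand intercepts) receive a ridge penalty
    dispersion/``brand_prior_var``, re-evaluated each iteration from the
    current Pearson dispersion.  Convergence is a relative deviance change
    below ``tol``; a fit hitting ``max_iter`` is returned flagged, never
    silently.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.any(y <= 0):
        raise ValueError("response must be strictly positive for a gamma GLM")
    columns = tuple(columns) if columns is not None else tuple(f"x{i}" for i in range(p))
    penalized = tuple(penalized)
    if not penalized:
        _check_rank(X, columns)

    # start: null model on the intercept (or flat zero without one)
    beta = np.zeros(p)
    if "intercept" in columns:
        beta[columns.index("intercept")] = math.log(float(np.mean(y)))
    eta = X @ beta
    mu = np.exp(np.clip(eta, -500, 500))
    dev = _gamma_deviance(y, mu)
    trace = [dev]
    xtx = X.T @ X
    converged = False
    iterations = 0
    dof = max(n - (p - len(penalized)), 1)
    phi = float(np.sum(((y - mu) / mu) ** 2) / dof)

    for it in range(1, max_iter + 1):
        iterations = it
        z = eta + (y - mu) / mu
        A = xtx.copy()
        if penalized:
            lam = max(phi, 1e-8) / brand_prior_var
            A[penalized, penalized] += lam
        beta = np.linalg.solve(A, X.T @ z)
        eta = X @ beta
        mu = np.exp(np.clip(eta, -500, 500))
        phi = float(np.sum(((y - mu) / mu) ** 2) / dof)
        dev_new = _gamma_deviance(y, mu)
        trace.append(dev_new)
        if abs(dev_new - dev) <= tol * (abs(dev) + 1e-10):
            converged = True
            dev = dev_new
            break
        dev = dev_new

    if not converged:
        logger.warning("gamma GLM did not converge in %d iterations", max_iter)

    A = xtx.copy()
    if penalized:
        A[penalized, penalized] += max(phi, 1e-8) / brand_prior_var
    cov = phi * np.linalg.inv(A)
    return GlmFit(
        columns=columns,
        beta=beta,
        cov=cov,
        dispersion=phi,
        deviance=dev,
        n_obs=n,
        converged=converged,
        iterations=iterations,
        deviance_trace=tuple(trace),
        term_blocks=dict(term_blocks or {}),
    )


def fit_design(design: Design, tol: float = 1e-8, max_iter: int = 100) -> GlmFit:
    return fit_gamma_glm(
        design.X,
        design.y,
        columns=design.columns,
        term_blocks=design.term_blocks,
        penalized=design.penalized,
        brand_prior_var=design.spec.brand_prior_var,
        tol=tol,
        max_iter=max_iter,
    )


# ---------------------------------------------------------------------------
# stepwise selection and reporting


def backward_eliminate(
    records: Sequence[TransactionRecord],
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
    market_size_by_year=None,
    hhi_by_year=None,
):
    """Backward stepwise elimination by Wald block tests.

    Repeatedly refits and drops the least significant droppable term (whole
    categorical/interaction block) with p > ``alpha``.  Interaction terms
    are dropped before the main effects they reference; the intercept and
    the brand adjustment are never dropped.  Returns ``(final_spec, trace)``
    where trace lists ``(dropped_term, p_value)`` in order.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    spec = spec or ModelSpec.initial()
    trace: list[tuple[str, float]] = []
    while True:
        design = build_design(
            records, spec, market_size_by_year=market_size_by_year, hhi_by_year=hhi_by_year
        )
        fit = fit_design(design)
        droppable = [
            t
            for t in spec.terms
            if t != TERM_INTERCEPT
            and not any(d in spec.terms for d in _DEPENDENTS.get(t, ()))
        ]
        if not droppable:
            break
        pvals = {t: fit.term_pvalue(t) for t in droppable}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            break
        spec = spec.drop(worst)
        trace.append((worst, pvals[worst]))
        logger.info("backward_eliminate: dropped %s (p=%.4g)", worst, pvals[worst])
        if spec.terms == (TERM_INTERCEPT,):
            logger.warning("backward_eliminate: all covariates removed; intercept-only model")
            break
    return spec, trace


def rate_ratio(fit: GlmFit, term: str) -> tuple[float, float, float]:
    """Back-transform a log-scale coefficient to a price ratio with 95% CI."""
    i = fit._index(term)
    lo, hi = fit.ci95[term]
    return (math.exp(fit.beta[i]), math.exp(lo), math.exp(hi))


# ---------------------------------------------------------------------------
# model/results objects


class ItnPriceModel:
    """Gamma/log-link price model over a set of ITN transactions.

    Parameters
    ----------
    records : sequence of TransactionRecord
        Filtered, deflated transactions.
    spec : ModelSpec, optional
        Term structure; defaults to the full interaction structure.
    market_size_by_year, hhi_by_year : mapping, optional
        Year-level covariate overrides; computed from the records otherwise.
    """

    def __init__(self, records, spec=None, market_size_by_year=None, hhi_by_year=None):
        self.records = list(records)
        self.spec = spec or ModelSpec.default()
        self.market_size_by_year = market_size_by_year
        self.hhi_by_year = hhi_by_year

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec=None, **kw) -> "ItnPriceModel":
        from .io import records_from_frame

        return cls(records_from_frame(df), spec=spec, **kw)

    def design(self, spec: ModelSpec | None = None) -> Design:
        return build_design(
            self.records,
            spec or self.spec,
            market_size_by_year=self.market_size_by_year,
            hhi_by_year=self.hhi_by_year,
        )

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "ItnPriceResults":
        glm = fit_design(self.design(), tol=tol, max_iter=max_iter)
        return ItnPriceResults(self, glm)

    def select(self, alpha: float = 0.05, start: ModelSpec | None = None) -> "ItnPriceResults":
        """Backward-eliminate from the initial spec, then fit the winner."""
        start = start or replace(
            ModelSpec.initial(),
            gfmss_start_year=self.spec.gfmss_start_year,
            brand_mode=self.spec.brand_mode,
            brand_prior_var=self.spec.brand_prior_var,
            hhi_lag=self.spec.hhi_lag,
        )
        final_spec, trace = backward_eliminate(
            self.records,
            spec=start,
            alpha=alpha,
            market_size_by_year=self.market_size_by_year,
            hhi_by_year=self.hhi_by_year,
        )
        glm = fit_design(self.design(final_spec))
        res = ItnPriceResults(self, glm, spec=final_spec)
        res.elimination_trace = trace
        return res


class ItnPriceResults:
    """Estimates, uncertainties and diagnostics of a fitted price model."""

    def __init__(self, model: ItnPriceModel, glm: GlmFit, spec: ModelSpec | None = None):
        self.model = model
        self.glm = glm
        self.spec = spec or model.spec
        self.elimination_trace: list = []

    # statsmodels-flavoured accessors -----------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.glm.beta, index=list(self.glm.columns), name="coef")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.glm.cov)), index=list(self.glm.columns), name="se"
        )

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.glm.p_values, name="p")

    def conf_int(self) -> pd.DataFrame:
        ci = self.glm.ci95
        return pd.DataFrame(
            [ci[c] for c in self.glm.columns],
            index=list(self.glm.columns),
            columns=["lower", "upper"],
        )

    @property
    def dispersion(self) -> float:
        return self.glm.dispersion

    @property
    def deviance(self) -> float:
        return self.glm.deviance

    @property
    def converged(self) -> bool:
        return self.glm.converged

    def _report_columns(self):
        return [c for c in self.glm.columns if not c.startswith("brand[")]

    def rate_ratios(self) -> pd.DataFrame:
        """exp(β) with exponentiated 95% CI, per non-brand coefficient."""
        rows = {c: rate_ratio(self.glm, c) for c in self._report_columns()}
        return pd.DataFrame(rows, index=["ratio", "ci_low", "ci_high"]).T

    def summary(self) -> str:
        """Plain-text coefficient table in the conventional layout."""
        lines = [
            "Gamma GLM (log link) — ITN real unit price",
            f"n = {self.glm.n_obs}   deviance = {self.glm.deviance:.4f}   "
            f"dispersion = {self.glm.dispersion:.5f}",
            f"converged = {self.glm.converged} in {self.glm.iterations} iterations",
            "",
            f"{'term':<42}{'coef':>10}{'se':>9}{'p':>8}{'[0.025':>9}{'0.975]':>9}",
        ]
        se = self.bse
        pv = self.pvalues
        ci = self.conf_int()
        for c in self._report_columns():
            lines.append(
                f"{c:<42}{self.params[c]:>10.4f}{se[c]:>9.4f}{pv[c]:>8.3f}"
                f"{ci.loc[c, 'lower']:>9.4f}{ci.loc[c, 'upper']:>9.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable export (coefficients, inference, trace)."""
        rr = self.rate_ratios()
        return {
            "terms": list(self.spec.terms),
            "coefficients": {c: float(v) for c, v in self.params.items()},
            "std_errors": {c: float(v) for c, v in self.bse.items()},
            "ci95": {c: [float(lo), float(hi)] for c, (lo, hi) in self.glm.ci95.items()},
            "p_values": {c: float(v) for c, v in self.pvalues.items()},
            "rate_ratios": {
                c: [float(x) for x in row] for c, row in rr.iterrows()
            },
            "dispersion": self.glm.dispersion,
            "deviance": self.glm.deviance,
            "n_obs": self.glm.n_obs,
            "converged": self.glm.converged,
            "elimination_trace": [[t, float(p)] for t, p in self.elimination_trace],
        }
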
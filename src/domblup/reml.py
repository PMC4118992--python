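"""Variance-component estimation by average-information REML.

Models
------
MA    : y = 1 u + a + e                       (additive only)
MAD   : y = 1 u + a + d + e, d with D1        (dominance values, H coding)
MAD2  : y = 1 u + a + d + e, d with D2        (dominance deviations, M coding)
MAD3  : MAD extended to ungenotyped animals entering through expected
        codings, with separate intercepts for the SD and SMGS groups and
        three group-specific residual variances; SMGS group means carry a
        1/N residual multiplier.

The covariance of y is V = sigma2_a G + sigma2_d D + sum_g sigma2_e,g R_g
with R_g the diagonal residual design of group g.  Estimation is Newton-type
on the restricted likelihood using the average-information matrix, with
step-halving and an EM fallback when an AI step misbehaves; variances are
kept in the parameter space by projection, so exact-zero boundary estimates
are representable.

The restricted log-likelihood convention used throughout (constant terms
dropped) is

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy import stats

from .coding import RelationshipMatrix, ResidualStructure

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "REMLFit",
    "LRTResult",
    "reml_loglik",
    "fit_reml",
    "heritabilities",
    "likelihood_ratio_test",
    "mixture_lrt_pvalue",
]

_MODELS = ("MA", "MAD", "MAD2", "MAD3")


@dataclass
class ModelSpec:
    """Which random terms, intercepts and residual groups a model carries."""

    model: str = "MAD"

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")

    @property
    def dominance_kind(self) -> str | None:
        """Relationship matrix of the dominance term (None for MA)."""
        return {"MA": None, "MAD": "D1", "MAD2": "D2", "MAD3": "D1"}[self.model]

    @property
    def has_dominance(self) -> bool:
        return self.model != "MA"

    @property
    def residual_groups(self) -> list[str]:
        return ["C", "SD", "SMGS"] if self.model == "MAD3" else ["C"]

    @property
    def uses_descendants(self) -> bool:
        return self.model == "MAD3"


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_d: float = 0.0
    sigma2_e_by_group: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma2_a < 0 or self.sigma2_d < 0:
            raise ValueError("variance components must be nonnegative")
        for g, v in self.sigma2_e_by_group.items():
            if v < 0:
                raise ValueError(f"residual variance for group {g} is negative")

    @property
    def sigma2_e(self) -> float:
        """Residual variance of genotyped cows (group C)."""
        return self.sigma2_e_by_group.get("C", 0.0)


@dataclass
class REMLFit:
    estimates: VarianceComponents
    minus2_loglik: float
    iterations: int
    converged: bool
    ai_matrix: np.ndarray
    standard_errors: np.ndarray
    spec: ModelSpec | None = None
    history: list = field(default_factory=list, repr=False)


@dataclass
class LRTResult:
    delta: float
    p_value: float
    flagged: bool = False  # delta < 0 beyond tolerance: non-nested or unconverged


# --------------------------------------------------------------------------
# generic AI-REML engine over dense + diagonal covariance components
# --------------------------------------------------------------------------


def _component_arrays(G, D, resid_struct, n):
    """Return (dense components, diagonal components, parameter names)."""
    dense, names = [], []
    if G is not None:
        g = G.values if isinstance(G, RelationshipMatrix) else np.asarray(G)
        dense.append(g)
        names.append("a")
    if D is not None:
        d = D.values if isinstance(D, RelationshipMatrix) else np.asarray(D)
        dense.append(d)
        names.append("d")
    diags = []
    if resid_struct is None:
        diags.append(("C", np.ones(n)))
    else:
        for grp, dvec in resid_struct.design().items():
            diags.append((grp, dvec))
    names.extend(f"e_{grp}" for grp, _ in diags)
    return dense, diags, names


def _build_V(theta, dense, diags, n):
    V = np.zeros((n, n))
    idx = 0
    for K in dense:
        if theta[idx] != 0.0:
            V += theta[idx] * K
        idx += 1
    dsum = np.zeros(n)
    for _, dvec in diags:
        dsum += theta[idx] * dvec
        idx += 1
    V[np.diag_indices(n)] += dsum
    return V


def _loglik_pieces(theta, y, X, dense, diags):
    """Restricted log-likelihood plus P and Py (None on singular V)."""
    n = y.shape[0]
    V = _build_V(theta, dense, diags, n)
    try:
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
    except sla.LinAlgError:
        return None
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = sla.cho_solve((c, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdet_X = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return None
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    Py = P @ y
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    return ll, P, Py


def reml_loglik(theta, y, X=None, G=None, D=None, resid_struct=None) -> float:
    """Restricted log-likelihood at the given variance components.

    ``theta`` is a :class:`VarianceComponents`; raises on singular V naming
    no component can rescue.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    dense, diags, names = _component_arrays(G, D, resid_struct, n)
    vec = []
    if G is not None:
        vec.append(theta.sigma2_a)
    if D is not None:
        vec.append(theta.sigma2_d)
    for grp, _ in diags:
        vec.append(theta.sigma2_e_by_group.get(grp, theta.sigma2_e))
    pieces = _loglik_pieces(np.asarray(vec, dtype=float), y, X, dense, diags)
    if pieces is None:
        raise np.linalg.LinAlgError(
            f"V is singular at components {dict(zip(names, vec))}"
        )
    return pieces[0]


def _scores_and_ai(theta, y, X, dense, diags):
    """Scores, AI matrix, quadratic/trace pieces and -2 log-likelihood."""
    pieces = _loglik_pieces(theta, y, X, dense, diags)
    if pieces is None:
        return None
    ll, P, Py = pieces
    n_par = len(dense) + len(diags)
    traces = np.empty(n_par)
    quads = np.empty(n_par)
    W = np.empty((y.shape[0], n_par))
    idx = 0
    for K in dense:
        traces[idx] = float(np.vdot(P, K))  # tr(PK) for symmetric P, K
        w = K @ Py
        quads[idx] = float(Py @ w)
        W[:, idx] = w
        idx += 1
    diagP = np.diag(P)
    for _, dvec in diags:
        traces[idx] = float(diagP @ dvec)
        w = dvec * Py
        quads[idx] = float(Py @ w)
        W[:, idx] = w
        idx += 1
    scores = -0.5 * (traces - quads)
    PW = P @ W
    ai = 0.5 * (W.T @ PW)
    return ll, scores, ai, traces, quads


def fit_reml(
    spec: ModelSpec,
    y,
    X=None,
    G=None,
    D=None,
    resid_struct: ResidualStructure | None = None,
    init: VarianceComponents | None = None,
    max_iter: int = 100,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
) -> REMLFit:
    """AI-REML fit of the model's variance components.

    Newton updates use the average-information matrix; a step is halved
    (factor 0.5, up to 20 times) while it worsens -2logL or leaves the
    parameter space, with an EM update as last resort.  Genetic variances
    may hit the zero boundary and stay there; residual variances are kept
    strictly positive.  Convergence requires |change in -2logL| < tol_loglik
    and max relative parameter change < tol_param.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if spec.has_dominance and D is None:
        raise ValueError(f"model {spec.model} requires a dominance matrix")
    if not spec.has_dominance:
        D = None
    dense, diags, names = _component_arrays(G, D, resid_struct, n)
    n_par = len(names)
    n_dense = len(dense)

    vary = float(np.var(y, ddof=1))
    eps = 1e-8 * vary
    lower = np.array([0.0] * n_dense + [eps] * len(diags))

    if init is not None:
        theta = []
        if G is not None:
            theta.append(init.sigma2_a)
        if D is not None:
            theta.append(init.sigma2_d)
        for grp, _ in diags:
            theta.append(init.sigma2_e_by_group.get(grp, vary / 3.0))
        theta = np.asarray(theta, dtype=float)
    else:
        theta = np.full(n_par, vary / 3.0)
    theta = np.maximum(theta, lower)

    # group sizes for the EM fallback denominator
    em_dim = np.array([float(n)] * n_dense + [float((d > 0).sum()) for _, d in diags])

    state = _scores_and_ai(theta, y, X, dense, diags)
    if state is None:
        raise np.linalg.LinAlgError("V singular at the starting values")
    ll, scores, ai, traces, quads = state
    m2ll = -2.0 * ll
    history = [m2ll]
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        # hold parameters that sit on the zero boundary and want to leave it
        active = ~((theta <= lower) & (scores <= 0.0))
        delta = np.zeros(n_par)
        if active.any():
            ai_act = ai[np.ix_(active, active)]
            try:
                delta[active] = np.linalg.solve(ai_act, scores[active])
            except np.linalg.LinAlgError:
                delta[active] = np.linalg.lstsq(ai_act, scores[active], rcond=None)[0]

        step = 1.0
        accepted = None
        for _ in range(20):
            cand = np.maximum(theta + step * delta, lower)
            cand[:n_dense] = np.maximum(cand[:n_dense], 0.0)
            new_state = _scores_and_ai(cand, y, X, dense, diags)
            if new_state is not None and -2.0 * new_state[0] <= m2ll + 1e-10:
                accepted = (cand, new_state)
                break
            step *= 0.5
        if accepted is None:
            # EM fallback: guaranteed-ascent style update
            cand = theta + theta**2 * (quads - traces) / np.maximum(em_dim, 1.0)
            cand = np.maximum(cand, lower)
            new_state = _scores_and_ai(cand, y, X, dense, diags)
            if new_state is None:
                break
            accepted = (cand, new_state)

        new_theta, (ll, scores, ai, traces, quads) = accepted
        new_m2ll = -2.0 * ll
        rel_change = np.max(np.abs(new_theta - theta) / np.maximum(theta, 1e-3 * vary))
        dll = abs(new_m2ll - m2ll)
        theta, m2ll = new_theta, new_m2ll
        history.append(m2ll)
        if dll < tol_loglik and rel_change < tol_param:
            converged = True
            break

    with np.errstate(invalid="ignore"):
        try:
            se = np.sqrt(np.maximum(np.diag(np.linalg.inv(ai)), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(n_par, np.nan)

    idx = 0
    sigma2_a = 0.0
    sigma2_d = 0.0
    if G is not None:
        sigma2_a = float(theta[idx])
        idx += 1
    if D is not None:
        sigma2_d = float(theta[idx])
        idx += 1
    e_by_group = {grp: float(theta[idx + j]) for j, (grp, _) in enumerate(diags)}

    est = VarianceComponents(
        sigma2_a=sigma2_a, sigma2_d=sigma2_d, sigma2_e_by_group=e_by_group
    )
    return REMLFit(
        estimates=est,
        minus2_loglik=float(m2ll),
        iterations=it,
        converged=converged,
        ai_matrix=ai,
        standard_errors=se,
        spec=spec,
        history=history,
    )


def heritabilities(est: VarianceComponents, spec: ModelSpec) -> tuple[float, float]:
    """Additive and dominance heritability.

    h2a = sigma2_a / (sigma2_a + sigma2_d + sigma2_e); the residual in the
    denominator is the genotyped-cow variance except under MAD3, where the
    SMGS cow-level residual variance is used.
    """
    if spec.model == "MAD3":
        sigma2_e = est.sigma2_e_by_group.get("SMGS", 0.0)
    else:
        sigma2_e = est.sigma2_e
    denom = est.sigma2_a + est.sigma2_d + sigma2_e
    if denom <= 0:
        raise ValueError("all variance components are zero")
    return est.sigma2_a / denom, est.sigma2_d / denom


def mixture_lrt_pvalue(delta: float) -> float:
    """Boundary-corrected LRT p-value for one variance tested at zero.

    Under the null the statistic is a 50:50 mixture of a point mass at 0
    and chi-square with 1 df, so p = 0.5 * P(chi2_1 > delta) for delta > 0
    and p = 1 otherwise.
    """
    if delta <= 0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(delta, df=1))


_NESTED_PAIRS = {("MA", "MAD"), ("MA", "MAD2")}


def likelihood_ratio_test(fit_null: REMLFit, fit_alt: REMLFit) -> LRTResult:
    """Test the dominance variance via the boundary-mixture LRT."""
    if fit_null.spec is not None and fit_alt.spec is not None:
        pair = (fit_null.spec.model, fit_alt.spec.model)
        if pair not in _NESTED_PAIRS:
            raise ValueError(f"model pair {pair} is not nested")
    delta = fit_null.minus2_loglik - fit_alt.minus2_loglik
    flagged = delta < -1e-6
    return LRTResult(delta=float(delta), p_value=mixture_lrt_pvalue(delta), flagged=flagged)
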
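"""Bayesian animal model for heritability of colour-pattern metrics.

The animal model is a mixed-effects model in which each individual's
additive genetic value is a random effect whose covariance is
proportional to the pedigree-derived additive relationship matrix A:

    y = X beta + Z_a u_a + Z_dam u_dam + Z_pcage u_pcage + Z_ocage u_ocage + e

    u_a ~ N(0, A sigma2_A),   u_dam ~ N(0, I sigma2_dam),
    u_pcage ~ N(0, I sigma2_pcage), u_ocage ~ N(0, I sigma2_ocage),
    e ~ N(0, I sigma2_R)

with fixed effects for sampling year, age at photograph (days), sex,
offspring and parental thermal treatment, and the sex x offspring x
parental interaction with all lower-order terms.  Narrow-sense
heritability is the variance ratio

    h2 = sigma2_A / (sigma2_A + sigma2_dam + sigma2_pcage
                     + sigma2_ocage + sigma2_R)

computed draw-by-draw from the retained MCMC samples.

Sampling is by a Gibbs sweep: all location effects (beta and the four
random-effect vectors) are drawn jointly from their Gaussian full
conditional via the mixed-model equations (with A^-1 on the animal
block), then each variance component is drawn from its scaled
inverse-chi-square full conditional under a (V, nu) prior.  A direct
REML maximiser over the same five components serves as an independent
numerical cross-check of the sampler.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import gaussian_kde
from statsmodels.regression.linear_model import yule_walker

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "HeritabilityEstimate",
    "read_pedigree",
    "topological_order",
    "build_A",
    "build_A_inverse",
    "fixed_effects_matrix",
    "build_design",
    "gibbs_sample",
    "reml_fit",
    "reml_oracle",
    "posterior_mode",
    "hpd_interval",
    "pmcmc",
    "diagnostics",
    "heritability",
]

#: variance-component names, in reporting order
VARIANCE_COMPONENTS = ("sigma2_A", "sigma2_dam", "sigma2_pcage", "sigma2_ocage", "sigma2_R")

#: fixed-effect columns, in reporting order (treatment coding; reference
#: levels are the alphabetically/numerically first: 2015, female, long-bask)
FIXED_EFFECTS = (
    "intercept",
    "year",
    "age_days",
    "sex_male",
    "offspring_short",
    "parental_short",
    "sex_male:offspring_short",
    "sex_male:parental_short",
    "offspring_short:parental_short",
    "sex_male:offspring_short:parental_short",
)

#: covariate columns every phenotype record must carry
COVARIATE_COLUMNS = (
    "sex",
    "year",
    "age_days",
    "offspring_treatment",
    "parental_treatment",
    "dam",
    "parental_cage",
    "offspring_cage",
)


# ---------------------------------------------------------------------------
# pedigree and relationship matrix
# ---------------------------------------------------------------------------

def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree CSV with columns id, sire, dam (empty = unknown)."""
    ped = pd.read_csv(path, dtype=str).loc[:, ["id", "sire", "dam"]]
    return ped


def _parent_indices(pedigree: pd.DataFrame) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Map ids to 0-based indices; unknown parent -> -1."""
    ped = pedigree.reset_index(drop=True)
    ids = ped["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = ped["id"][ped["id"].duplicated()].tolist()
        raise ValueError(f"duplicate individual ids in pedigree: {dupes}")
    pos = {ind: i for i, ind in enumerate(ids)}

    def lookup(col):
        out = np.full(len(ids), -1, dtype=int)
        for i, v in enumerate(ped[col]):
            if pd.isna(v) or v == "" or v is None:
                continue
            if str(v) not in pos:
                raise ValueError(f"parent {v!r} of {ids[i]!r} not in pedigree")
            out[i] = pos[str(v)]
        return out

    return ids, lookup("sire"), lookup("dam")


def topological_order(pedigree: pd.DataFrame) -> list[int]:
    """Indices ordering parents before offspring; errors on a cycle."""
    ids, sire, dam = _parent_indices(pedigree)
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    order: list[int] = []
    while queue:
        i = queue.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) < n:
        stuck = [ids[i] for i in range(n) if indeg[i] > 0]
        raise ValueError(f"pedigree contains a cycle involving: {stuck[:5]}")
    return order


def inbreeding_coefficients(pedigree: pd.DataFrame) -> pd.Series:
    """Inbreeding coefficients by recursive kinship, without dense A.

    ``F_i`` is the kinship between i's parents; kinship follows the
    classic recursion ``phi(i, j) = (phi(sire_i, j) + phi(dam_i, j))/2``
    for i later in the pedigree than j, with ``phi(i, i) =
    (1 + F_i)/2`` and unknown parents contributing zero.  Memoised, so
    cost scales with the ancestry actually visited rather than n^2.
    """
    ids, sire, dam = _parent_indices(pedigree)
    depth: dict[int, int] = {}
    for i in topological_order(pedigree):
        depth[i] = 1 + max(
            (depth[p] for p in (sire[i], dam[i]) if p >= 0), default=-1
        )
    memo: dict[tuple[int, int], float] = {}

    def phi(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        key = (i, j) if i <= j else (j, i)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5 * (1.0 + phi(sire[i], dam[i]))
        else:
            # recurse on the individual further from the founders
            a, b = (i, j) if depth[i] >= depth[j] else (j, i)
            val = 0.5 * (phi(sire[a], b) + phi(dam[a], b))
        memo[key] = val
        return val

    F = np.array([phi(sire[i], dam[i]) for i in range(len(ids))])
    return pd.Series(F, index=ids, name="F")


def build_A(pedigree: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Additive relationship matrix by the tabular method.

    Returns (A, ids) with A in the pedigree's row order.  Unknown
    parents are treated as unrelated, non-inbred founders; the diagonal
    is ``1 + F_i`` with F_i the inbreeding coefficient.
    """
    ids, sire, dam = _parent_indices(pedigree)
    order = topological_order(pedigree)
    n = len(ids)
    A = np.zeros((n, n))
    done: list[int] = []
    for i in order:
        s, d = sire[i], dam[i]
        if done:
            prev = np.asarray(done)
            row = np.zeros(len(prev))
            if s >= 0:
                row += A[s, prev]
            if d >= 0:
                row += A[d, prev]
            A[i, prev] = A[prev, i] = 0.5 * row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        done.append(i)
    return A, ids


def build_A_inverse(pedigree: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Inverse relationship matrix from pedigree structure.

    Uses the parent-offspring update rules with inbreeding: each
    individual contributes 1/d_i on a (self, -1/2 parent) contrast,
    where d_i is its Mendelian-sampling variance.  Inbreeding
    coefficients come from the tabular A (pedigrees here are small).
    """
    ids, sire, dam = _parent_indices(pedigree)
    A, _ = build_A(pedigree)
    F = np.diag(A) - 1.0
    n = len(ids)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        known = [p for p in (s, d) if p >= 0]
        di = 1.0 - sum(0.25 * (1.0 + F[p]) for p in known)
        alpha = 1.0 / di
        Ainv[i, i] += alpha
        for p in known:
            Ainv[i, p] -= alpha / 2.0
            Ainv[p, i] -= alpha / 2.0
        for p in known:
            for q in known:
                Ainv[p, q] += alpha / 4.0
    return Ainv, ids


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Animal-model configuration.

    ``prior_V`` and ``prior_nu`` parameterise the scaled
    inverse-chi-square prior on every variance component (default
    V = 1, nu = 0.002, a very weak prior).  The default MCMC schedule
    is 1,500,000 iterations, thinning 1,000, burn-in 1,000; tests and
    the bundled benchmark use much shorter, explicitly configured
    chains.
    """

    response: str = "brightness"
    prior_V: float = 1.0
    prior_nu: float = 0.002
    n_iter: int = 1_500_000
    thin: int = 1_000
    burnin: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prior_V <= 0 or self.prior_nu <= 0:
            raise ValueError("prior V and nu must be positive")
        if self.thin > self.n_iter or self.burnin >= self.n_iter:
            raise ValueError("require thin <= n_iter and burnin < n_iter")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burnin) // self.thin


@dataclass
class DesignMatrices:
    """Fixed and random design matrices for one response."""

    y: np.ndarray
    X: np.ndarray
    Z_animal: np.ndarray
    Z_dam: np.ndarray
    Z_pcage: np.ndarray
    Z_ocage: np.ndarray
    record_ids: list[str]
    animal_ids: list[str]  # pedigree order; columns of Z_animal
    dam_levels: list[str]
    pcage_levels: list[str]
    ocage_levels: list[str]
    n_dropped: int


def _indicator(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(values.astype(str).unique())
    idx = values.astype(str).map({v: i for i, v in enumerate(levels)}).to_numpy()
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), idx] = 1.0
    return Z, levels


def fixed_effects_matrix(df: pd.DataFrame, ref_year: int | None = None) -> np.ndarray:
    """Treatment-coded fixed-effect matrix with the ``FIXED_EFFECTS`` columns.

    Reference levels are the earliest year, female sex and the
    long-bask treatment; age enters in days, uncentred.
    """
    if ref_year is None:
        ref_year = int(min(df["year"].astype(int)))
    yr = (df["year"].astype(int) != ref_year).astype(float).to_numpy()
    sex = df["sex"].astype(str).str.lower().map({"female": 0.0, "male": 1.0})
    if sex.isna().any():
        bad = df.loc[sex.isna(), "id"].tolist()
        raise ValueError(f"unrecognised sex for records {bad[:5]} (expect female/male)")

    def short(col):
        v = df[col].astype(str).str.lower().map(
            {"long-bask": 0.0, "short-bask": 1.0, "long": 0.0, "short": 1.0}
        )
        if v.isna().any():
            bad = df.loc[v.isna(), "id"].tolist()
            raise ValueError(f"unrecognised {col} for records {bad[:5]}")
        return v.to_numpy()

    sx = sex.to_numpy()
    off = short("offspring_treatment")
    par = short("parental_treatment")
    age = df["age_days"].astype(float).to_numpy()
    return np.column_stack(
        [
            np.ones(len(df)), yr, age, sx, off, par,
            sx * off, sx * par, off * par, sx * off * par,
        ]
    )


def build_design(
    records: pd.DataFrame, pedigree: pd.DataFrame, spec: ModelSpec
) -> DesignMatrices:
    """Build fixed-effect and random-incidence matrices for one trait.

    Treatment coding with reference levels 2015 / female / long-bask:
    the fixed-effect matrix has the 10 columns of ``FIXED_EFFECTS``.
    Records with any missing covariate or response are excluded
    (complete-case analysis) with a logged count.
    """
    if spec.response not in records.columns:
        raise KeyError(f"response column {spec.response!r} not in records")
    needed = list(COVARIATE_COLUMNS) + [spec.response]
    missing_cols = [c for c in needed if c not in records.columns]
    if missing_cols:
        raise KeyError(f"records are missing columns: {missing_cols}")
    df = records.copy()
    keep = df[needed].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropping %d of %d records with missing covariates (complete-case)",
            n_dropped, len(df),
        )
    # canonical record order: results are invariant to input row order
    df = df.loc[keep].sort_values("id", kind="stable").reset_index(drop=True)
    if df.empty:
        raise ValueError("no complete-case records remain")

    X = fixed_effects_matrix(df)

    ped_ids = pedigree["id"].astype(str).tolist()
    pos = {v: i for i, v in enumerate(ped_ids)}
    rec_ids = df["id"].astype(str).tolist()
    unknown = [r for r in rec_ids if r not in pos]
    if unknown:
        raise ValueError(f"records not present in pedigree: {unknown[:5]}")
    Z_animal = np.zeros((len(df), len(ped_ids)))
    Z_animal[np.arange(len(df)), [pos[r] for r in rec_ids]] = 1.0

    Z_dam, dam_levels = _indicator(df["dam"])
    Z_pc, pc_levels = _indicator(df["parental_cage"])
    Z_oc, oc_levels = _indicator(df["offspring_cage"])

    return DesignMatrices(
        y=df[spec.response].astype(float).to_numpy(),
        X=X,
        Z_animal=Z_animal,
        Z_dam=Z_dam,
        Z_pcage=Z_pc,
        Z_ocage=Z_oc,
        record_ids=rec_ids,
        animal_ids=ped_ids,
        dam_levels=dam_levels,
        pcage_levels=pc_levels,
        ocage_levels=oc_levels,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Retained MCMC draws of fixed effects and variance components."""

    beta: pd.DataFrame       # draws x FIXED_EFFECTS
    variances: pd.DataFrame  # draws x VARIANCE_COMPONENTS
    n_floored: int = 0
    spec: ModelSpec | None = None


# near-flat Gaussian prior on fixed effects (variance 1e10)
_BETA_PRECISION = 1e-10


def gibbs_sample(design: DesignMatrices, A_inv: np.ndarray, spec: ModelSpec) -> PosteriorSamples:
    """Gibbs sampler for the five-variance-component animal model.

    Each sweep draws all location effects jointly from their Gaussian
    full conditional via the mixed-model equations (A^-1 enters the
    animal block), then each variance from its scaled inverse
    chi-square full conditional: for a term with q levels and scaled
    sum of squares SS, ``sigma2 = (nu V + SS) / chi2(nu + q)``.
    Variance draws that underflow are floored at a tiny positive value
    and counted.  Fixed seed gives an identical chain.
    """
    y = design.y
    n = len(y)
    blocks = [design.X, design.Z_animal, design.Z_dam, design.Z_pcage, design.Z_ocage]
    sizes = [b.shape[1] for b in blocks]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    m = offs[-1]
    W = np.concatenate(blocks, axis=1)
    WtW = W.T @ W
    Wty = W.T @ y
    a0, a1 = offs[1], offs[2]  # animal block
    if A_inv.shape != (sizes[1], sizes[1]):
        raise ValueError("A_inv does not match the animal design")

    rng = np.random.default_rng(spec.seed)
    nu, V = spec.prior_nu, spec.prior_V
    vy = float(np.var(y)) or 1.0
    floor = max(vy * 1e-12, np.finfo(float).tiny)
    # deterministic start: equal split of the phenotypic variance
    sig = {name: vy / 5.0 for name in VARIANCE_COMPONENTS}

    rand_slices = {
        "sigma2_A": slice(offs[1], offs[2]),
        "sigma2_dam": slice(offs[2], offs[3]),
        "sigma2_pcage": slice(offs[3], offs[4]),
        "sigma2_ocage": slice(offs[4], offs[5]),
    }
    q_term = {k: s.stop - s.start for k, s in rand_slices.items()}

    out_beta = np.empty((spec.n_retained, sizes[0]))
    out_var = np.empty((spec.n_retained, len(VARIANCE_COMPONENTS)))
    kept = 0
    n_floored = 0

    for it in range(1, spec.n_iter + 1):
        s_r = sig["sigma2_R"]
        C = WtW.copy()
        C[: offs[1], : offs[1]][np.diag_indices(sizes[0])] += _BETA_PRECISION * s_r
        C[a0:a1, a0:a1] += (s_r / sig["sigma2_A"]) * A_inv
        for name in ("sigma2_dam", "sigma2_pcage", "sigma2_ocage"):
            sl = rand_slices[name]
            C[sl, sl][np.diag_indices(q_term[name])] += s_r / sig[name]
        L, low = linalg.cho_factor(C, lower=True, check_finite=False)
        mean = linalg.cho_solve((L, low), Wty, check_finite=False)
        z = rng.standard_normal(m)
        theta = mean + math.sqrt(s_r) * linalg.solve_triangular(
            L, z, lower=True, trans="T", check_finite=False
        )

        e = y - W @ theta
        ss = {"sigma2_R": float(e @ e)}
        u_a = theta[a0:a1]
        ss["sigma2_A"] = float(u_a @ (A_inv @ u_a))
        for name in ("sigma2_dam", "sigma2_pcage", "sigma2_ocage"):
            u = theta[rand_slices[name]]
            ss[name] = float(u @ u)

        for name in VARIANCE_COMPONENTS:
            q = n if name == "sigma2_R" else q_term[name]
            draw = (nu * V + ss[name]) / rng.chisquare(nu + q)
            if not np.isfinite(draw):
                raise RuntimeError(f"non-finite draw for {name} at iteration {it}")
            if draw < floor:
                draw = floor
                n_floored += 1
            sig[name] = draw

        if it > spec.burnin and (it - spec.burnin) % spec.thin == 0:
            out_beta[kept] = theta[: sizes[0]]
            out_var[kept] = [sig[k] for k in VARIANCE_COMPONENTS]
            kept += 1

    if n_floored:
        logger.info("floored %d underflowing variance draws", n_floored)
    return PosteriorSamples(
        beta=pd.DataFrame(out_beta[:kept], columns=list(FIXED_EFFECTS)),
        variances=pd.DataFrame(out_var[:kept], columns=list(VARIANCE_COMPONENTS)),
        n_floored=n_floored,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# REML cross-check
# ---------------------------------------------------------------------------

@dataclass
class RemlResult:
    estimates: dict[str, float]
    std_errors: dict[str, float]
    loglik: float
    converged: bool


def reml_restricted_loglik(
    sigma2: np.ndarray, y: np.ndarray, X: np.ndarray, covs: list[np.ndarray]
) -> float:
    """Restricted log-likelihood at the given variance components.

    ``covs`` holds the n x n covariance contribution of each random
    term per unit variance (Z A Z' for the animal term, Z Z' for iid
    terms, I for the residual).
    """
    n, p = X.shape
    Vmat = sum(s * M for s, M in zip(sigma2, covs))
    cf = linalg.cho_factor(Vmat, lower=True)
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    Vinv_X = linalg.cho_solve(cf, X)
    Vinv_y = linalg.cho_solve(cf, y)
    XtVinvX = X.T @ Vinv_X
    cfx = linalg.cho_factor(XtVinvX, lower=True)
    logdetXVX = 2.0 * np.log(np.diag(cfx[0])).sum()
    beta = linalg.cho_solve(cfx, X.T @ Vinv_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(cf, r))
    return -0.5 * (logdetV + logdetXVX + quad + (n - p) * np.log(2 * np.pi))


def reml_fit(
    y: np.ndarray, X: np.ndarray, covs: list[np.ndarray]
) -> tuple[np.ndarray, float, bool]:
    """Maximise the restricted log-likelihood over the given components.

    ``covs`` lists the per-unit-variance covariance contribution of each
    component (the residual's identity must be included explicitly).
    Optimises over log-variances with L-BFGS-B.  Returns
    (estimates, maximised restricted log-likelihood, converged).
    """

    def negll(log_s):
        try:
            return -reml_restricted_loglik(np.exp(log_s), y, X, covs)
        except linalg.LinAlgError:
            return 1e12

    vy = float(np.var(y)) or 1.0
    k = len(covs)
    x0 = np.log(np.full(k, vy / k))
    res = optimize.minimize(
        negll, x0, method="L-BFGS-B",
        bounds=[(np.log(vy * 1e-8), np.log(vy * 1e4))] * k,
        options={"maxiter": 500},
    )
    if not res.success:
        # finite-difference line searches occasionally abort near the
        # optimum; polish with a derivative-free simplex
        polish = optimize.minimize(
            negll, res.x, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if polish.fun <= res.fun:
            res = polish
    if not res.success:
        logger.warning("REML optimiser did not report convergence: %s", res.message)
    return np.exp(res.x), float(-res.fun), bool(res.success)


def reml_oracle(design: DesignMatrices, A: np.ndarray) -> RemlResult:
    """Direct REML fit of the five-component model (dense algebra).

    Maximises the restricted log-likelihood over log-variances with a
    quasi-Newton optimiser; standard errors come from the numerical
    Hessian on the log scale (delta method back to the variance scale).
    Independent of the Gibbs sampler; intended for n up to ~2,000.
    """
    y, X = design.y, design.X
    covs = [
        design.Z_animal @ A @ design.Z_animal.T,
        design.Z_dam @ design.Z_dam.T,
        design.Z_pcage @ design.Z_pcage.T,
        design.Z_ocage @ design.Z_ocage.T,
        np.eye(len(y)),
    ]
    est, loglik, converged = reml_fit(y, X, covs)
    log_est = np.log(est)

    def negll(log_s):
        try:
            return -reml_restricted_loglik(np.exp(log_s), y, X, covs)
        except linalg.LinAlgError:
            return 1e12

    # numerical Hessian on the log scale; the step must keep second
    # differences well above the likelihood's evaluation noise
    h = 0.05
    k = 5
    H = np.zeros((k, k))
    f0 = negll(log_est)
    fp = np.array([negll(log_est + h * np.eye(k)[i]) for i in range(k)])
    fm = np.array([negll(log_est - h * np.eye(k)[i]) for i in range(k)])
    for i in range(k):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
        for j in range(i + 1, k):
            fpp = negll(log_est + h * (np.eye(k)[i] + np.eye(k)[j]))
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / h**2
    try:
        cov_log = linalg.inv(H)
        se = est * np.sqrt(np.clip(np.diag(cov_log), 0, None))
    except linalg.LinAlgError:
        se = np.full(k, np.nan)

    names = list(VARIANCE_COMPONENTS)
    return RemlResult(
        estimates=dict(zip(names, est.tolist())),
        std_errors=dict(zip(names, se.tolist())),
        loglik=loglik,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# posterior summaries and diagnostics
# ---------------------------------------------------------------------------

def posterior_mode(chain: np.ndarray) -> float:
    """Mode of a Gaussian-kernel density estimate of the chain.

    Silverman bandwidth, evaluated on a 512-point grid spanning the
    chain's range.  A constant chain returns that constant.
    """
    x = np.asarray(chain, dtype=float)
    if x.size == 0:
        raise ValueError("empty chain")
    if np.ptp(x) == 0:
        return float(x[0])
    # Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    bw = 0.9 * min(sd, iqr / 1.34 if iqr > 0 else sd) * x.size ** (-0.2)
    kde = gaussian_kde(x, bw_method=bw / sd)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(chain: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``ceil(level * n)`` sorted draws."""
    x = np.sort(np.asarray(chain, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 draws for an HPD interval, got {n}")
    m = int(math.ceil(level * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def pmcmc(chain: np.ndarray) -> float:
    """MCMC sign probability: ``2 min(#draws > 0, #draws < 0) / n``.

    Floored at 1/n so a chain entirely on one side of zero reports the
    smallest resolvable value rather than 0.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty chain")
    p = 2.0 * min((x > 0).sum(), (x < 0).sum()) / n
    return float(max(p, 1.0 / n))


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit."""
    x = np.asarray(x, dtype=float)
    n = x.size
    v = float(np.var(x))
    if v == 0:
        return 0.0
    best = (n * np.log(v), v)  # order 0
    max_order = min(10, n // 10)
    for p in range(1, max_order + 1):
        rho, sigma = yule_walker(x, order=p, method="mle")
        aic = n * np.log(sigma**2) + 2.0 * p
        if aic < best[0]:
            best = (aic, sigma**2 / (1.0 - rho.sum()) ** 2)
    return best[1]


def diagnostics(chain: np.ndarray) -> dict[str, float]:
    """Lag-1 autocorrelation and Geweke convergence z-score.

    The Geweke statistic compares the means of the first 10% and last
    50% of the chain, standardised by spectral-density-at-zero variance
    estimates of each segment.  For a stationary, well-mixed chain
    |z| should behave like a standard normal draw.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError(f"chain too short for diagnostics (n={n} < 100)")
    if np.ptp(x) == 0:
        return {"lag1_autocorr": 0.0, "geweke_z": 0.0}
    lag1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
    n1 = max(int(0.1 * n), 10)
    n2 = max(int(0.5 * n), 10)
    first, last = x[:n1], x[-n2:]
    var = _spectrum0_ar(first) / n1 + _spectrum0_ar(last) / n2
    z = (first.mean() - last.mean()) / math.sqrt(var) if var > 0 else 0.0
    return {"lag1_autocorr": lag1, "geweke_z": float(z)}


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeritabilityEstimate:
    """Posterior of h2 = sigma2_A / total phenotypic variance."""

    chain: np.ndarray
    mode: float
    lower95: float
    upper95: float


def heritability(samples: PosteriorSamples) -> HeritabilityEstimate:
    """Per-draw h2 ratio with its posterior mode and 95% HPD interval."""
    v = samples.variances
    missing = [c for c in VARIANCE_COMPONENTS if c not in v.columns]
    if missing:
        raise ValueError(f"missing variance chains: {missing}")
    lengths = {c: len(v[c].dropna()) for c in VARIANCE_COMPONENTS}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"variance chains have mismatched lengths: {lengths}")
    total = v[list(VARIANCE_COMPONENTS)].sum(axis=1).to_numpy()
    h2 = v["sigma2_A"].to_numpy() / total
    lo, hi = hpd_interval(h2)
    return HeritabilityEstimate(chain=h2, mode=posterior_mode(h2), lower95=lo, upper95=hi)
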
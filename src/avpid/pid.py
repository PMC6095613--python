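"""Partial information decomposition for two predictors and one target.

Decomposes the joint mutual information that two continuous predictors
(auditory envelope A and lip area V, each represented by a 2D phase
point) carry about a target M (a neural signal) into four terms:

* redundancy  I_red — shared by both predictors,
* unique      I_uni(A), I_uni(V) — carried by one predictor only,
* synergy     I_syn — available only from joint observation.

Redundancy is measured as the expectation of the pointwise common
change in surprisal (Iccs): the local co-information c(m,a,v) is
accumulated only where the signs of i(m;a), i(m;v), i(m;a,v) and c all
agree, so only unambiguously redundant points contribute.  The
expectation is taken under the maximum-entropy surrogate distribution
that preserves the (M,A) and (M,V) pairwise marginals but is otherwise
unconstrained — for Gaussians this is exactly the model in which A and
V are conditionally independent given M, available in closed form.
There is no closed form for Iccs itself, so the expectation uses
Monte-Carlo integration with all densities evaluated in log space.

By construction the decomposition satisfies, to machine precision:
red + uni_a = I(M;A); red + uni_v = I(M;V); the four terms sum to
I(M;[A,V]); and syn - red equals the interaction information.  Terms
may be negative (Iccs is not guaranteed non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcmi import LN2, gauss_entropy_bits

__all__ = [
    "JointGaussModel",
    "MaxEntModel",
    "PIDResult",
    "fit_joint_gauss",
    "interaction_information",
    "maxent_surrogate",
    "iccs_redundancy",
    "pid_decompose",
    "pid_regions_to_stimulus",
    "local_pid_map",
]


@dataclass
class JointGaussModel:
    """Gaussian model over ordered blocks M, A, V.

    ``cov`` is the joint correlation matrix of the copula-standardized
    variables; ``dims`` gives the dimensionality of each block (2, 2, 2
    for the phase pipeline; 1, 1, 1 for local visualisation maps).
    """

    cov: np.ndarray
    n_samples: int
    dims: tuple[int, int, int] = (2, 2, 2)

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        d = sum(self.dims)
        if self.cov.shape != (d, d):
            raise ValueError(f"covariance must be {d}x{d} for block dims {self.dims}")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov)[0] <= 1e-10:
            raise np.linalg.LinAlgError("joint covariance is not positive definite")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        dm, da, dv = self.dims
        return slice(0, dm), slice(dm, dm + da), slice(dm + da, dm + da + dv)


@dataclass
class MaxEntModel:
    """Entropy-maximizing surrogate with (M,A) and (M,V) marginals fixed."""

    cov_tilde: np.ndarray
    entropy_gain: float
    dims: tuple[int, int, int]


@dataclass
class PIDResult:
    red: float
    uni_a: float
    uni_v: float
    syn: float
    mi_a: float
    mi_v: float
    mi_av: float
    mc_samples: int
    mc_se: float
    rng_seed: int | None = None

    def terms(self) -> dict[str, float]:
        return {"red": self.red, "uni_a": self.uni_a, "uni_v": self.uni_v, "syn": self.syn}


def interaction_information(mi_a: float, mi_v: float, mi_av: float) -> float:
    """I(M;[A,V]) - I(M;A) - I(M;V): negative = net redundancy, positive = net synergy."""
    return mi_av - mi_a - mi_v


def fit_joint_gauss(m: np.ndarray, a: np.ndarray, v: np.ndarray) -> JointGaussModel:
    """Fit the joint Gaussian-copula model from copula-normalized blocks.

    The empirical covariance (1/(n-1) normalization) is standardized to
    a correlation matrix; MI quantities are invariant to this scaling.
    """
    m, a, v = (np.atleast_2d(x.T).T if np.asarray(x).ndim == 1 else np.asarray(x) for x in (m, a, v))
    if not (m.shape[0] == a.shape[0] == v.shape[0]):
        raise ValueError("blocks must share the number of samples")
    if m.shape[0] < 100:
        raise ValueError("need at least 100 samples to fit the joint model")
    joint = np.concatenate([m, a, v], axis=1)
    c = np.cov(joint, rowvar=False, ddof=1)
    sd = np.sqrt(np.diag(c))
    corr = c / np.outer(sd, sd)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return JointGaussModel(corr, n_samples=m.shape[0], dims=(m.shape[1], a.shape[1], v.shape[1]))


def maxent_surrogate(model: JointGaussModel) -> MaxEntModel:
    """Closed-form maximum-entropy surrogate covariance.

    Among all Gaussians sharing the model's (M,A) and (M,V) blocks, the
    entropy maximizer is the one with A and V conditionally independent
    given M; its A-V cross block is Sigma_AM Sigma_MM^-1 Sigma_MV.  The
    result does not depend on the original A-V dependence, and its
    determinant (hence entropy) never falls below the source model's.
    """
    sm, sa, sv = model.slices
    c = model.cov
    cmm_inv = np.linalg.inv(c[sm, sm])
    cav = c[sa, sm] @ cmm_inv @ c[sm, sv]
    ct = c.copy()
    ct[sa, sv] = cav
    ct[sv, sa] = cav.T
    sign, logdet_t = np.linalg.slogdet(ct)
    if sign <= 0:
        raise np.linalg.LinAlgError("max-ent surrogate covariance is not positive definite")
    _, logdet = np.linalg.slogdet(c)
    gain = 0.5 * (logdet_t - logdet) / LN2
    return MaxEntModel(ct, entropy_gain=float(gain), dims=model.dims)


class _GaussLogPdf:
    """Log-density of a centred Gaussian, precomputed via Cholesky."""

    def __init__(self, cov: np.ndarray) -> None:
        cov = np.atleast_2d(cov)
        self.chol = np.linalg.cholesky(cov)
        self.d = cov.shape[0]
        self.logz = -0.5 * self.d * np.log(2 * np.pi) - np.sum(np.log(np.diag(self.chol)))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = np.linalg.solve(self.chol, x.T)
        return self.logz - 0.5 * np.sum(z * z, axis=0)


def _local_terms(
    samples: np.ndarray, model: JointGaussModel, maxent: MaxEntModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise i(m;a), i(m;v), i(m;a,v) and c in bits at each sample.

    i(m;a) and i(m;v) use the source model's pairwise densities; the
    joint local term uses the max-ent surrogate: log2 of
    p~(m,a,v) / (p(m) p~(a,v)).
    """
    sm, sa, sv = model.slices
    c, ct = model.cov, maxent.cov_tilde
    idx = np.arange(c.shape[0])
    ma = np.concatenate([idx[sm], idx[sa]])
    mv = np.concatenate([idx[sm], idx[sv]])
    av = np.concatenate([idx[sa], idx[sv]])

    lp_m = _GaussLogPdf(c[sm, sm])
    lp_a = _GaussLogPdf(c[np.ix_(idx[sa], idx[sa])])
    lp_v = _GaussLogPdf(c[np.ix_(idx[sv], idx[sv])])
    lp_ma = _GaussLogPdf(c[np.ix_(ma, ma)])
    lp_mv = _GaussLogPdf(c[np.ix_(mv, mv)])
    lp_av_t = _GaussLogPdf(ct[np.ix_(av, av)])
    lp_mav_t = _GaussLogPdf(ct)

    xm, xa, xv = samples[:, sm], samples[:, sa], samples[:, sv]
    i_ma = (lp_ma(samples[:, ma]) - lp_m(xm) - lp_a(xa)) / LN2
    i_mv = (lp_mv(samples[:, mv]) - lp_m(xm) - lp_v(xv)) / LN2
    i_mav = (lp_mav_t(samples) - lp_m(xm) - lp_av_t(samples[:, av])) / LN2
    c_loc = i_ma + i_mv - i_mav
    return i_ma, i_mv, i_mav, c_loc


def iccs_redundancy(
    model: JointGaussModel,
    maxent: MaxEntModel | None = None,
    n_mc: int = 100_000,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte-Carlo Iccs redundancy (bits) and its standard error.

    Samples (m, a, v) from the max-ent surrogate and averages the local
    co-information c = i(m;a) + i(m;v) - i(m;a,v), including a point
    only when all four sign conditions agree (else it contributes 0).
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10,000 for a stable estimate")
    if maxent is None:
        maxent = maxent_surrogate(model)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    chol = np.linalg.cholesky(maxent.cov_tilde)
    samples = rng.standard_normal((n_mc, chol.shape[0])) @ chol.T
    i_ma, i_mv, i_mav, c_loc = _local_terms(samples, model, maxent)
    s = np.sign(i_ma)
    include = (s == np.sign(i_mv)) & (s == np.sign(i_mav)) & (s == np.sign(c_loc))
    contrib = np.where(include, c_loc, 0.0)
    return float(contrib.mean()), float(contrib.std(ddof=1) / np.sqrt(n_mc))


def _model_mis(model: JointGaussModel, biascorrect: bool) -> tuple[float, float, float]:
    sm, sa, sv = model.slices
    c = model.cov
    idx = np.arange(c.shape[0])
    n = model.n_samples if biascorrect else None
    h = lambda ix: gauss_entropy_bits(c[np.ix_(ix, ix)], n)
    hm, ha, hv = h(idx[sm]), h(idx[sa]), h(idx[sv])
    hma = h(np.concatenate([idx[sm], idx[sa]]))
    hmv = h(np.concatenate([idx[sm], idx[sv]]))
    hav = h(np.concatenate([idx[sa], idx[sv]]))
    hmav = gauss_entropy_bits(c, n)
    mi_a = hm + ha - hma
    mi_v = hm + hv - hmv
    mi_av = hm + hav - hmav
    return mi_a, mi_v, mi_av


def pid_decompose(
    m: np.ndarray,
    a: np.ndarray,
    v: np.ndarray,
    n_mc: int = 100_000,
    rng_seed: int = 0,
    biascorrect: bool = True,
) -> PIDResult:
    """Full PID of the information (a, v) carry about target m.

    Fits the 6-dimensional (or generally block-structured) Gaussian
    copula model, computes the three MIs from its covariance with the
    same bias-correction setting as the MI estimators, estimates
    redundancy by Monte-Carlo Iccs, and derives the remaining terms so
    that the decomposition identities hold exactly.
    """
    model = fit_joint_gauss(m, a, v)
    return pid_from_model(model, n_mc=n_mc, rng_seed=rng_seed, biascorrect=biascorrect)


def pid_from_model(
    model: JointGaussModel, n_mc: int = 100_000, rng_seed: int = 0, biascorrect: bool = True
) -> PIDResult:
    """PID from an already-fitted joint Gaussian model."""
    mi_a, mi_v, mi_av = _model_mis(model, biascorrect)
    maxent = maxent_surrogate(model)
    red, mc_se = iccs_redundancy(model, maxent, n_mc=n_mc, rng_seed=rng_seed)
    return PIDResult(
        red=red,
        uni_a=mi_a - red,
        uni_v=mi_v - red,
        syn=mi_av - mi_a - mi_v + red,
        mi_a=mi_a,
        mi_v=mi_v,
        mi_av=mi_av,
        mc_samples=n_mc,
        mc_se=mc_se,
        rng_seed=rng_seed if isinstance(rng_seed, int) else None,
    )


def pid_regions_to_stimulus(
    node1: np.ndarray,
    node2: np.ndarray,
    stimulus: np.ndarray,
    n_mc: int = 100_000,
    rng_seed: int = 0,
) -> PIDResult:
    """PID with two neural signals as predictors and a stimulus as target.

    Identical machinery to :func:`pid_decompose` with roles swapped:
    ``uni_a``/``uni_v`` refer to node1/node2 respectively.
    """
    return pid_decompose(stimulus, node1, node2, n_mc=n_mc, rng_seed=rng_seed)


def local_pid_map(
    model: JointGaussModel,
    maxent: MaxEntModel | None = None,
    n_mc: int = 100_000,
    rng_seed: int = 0,
) -> dict:
    """Probability-weighted local information (p*i) by median-split cell.

    Intended for 1-dimensional blocks (the band-passed real signals):
    after copula normalization, 0 is the median, so cells are indexed by
    the sign (0 = below median, 1 = above) of m, a and v.  Returns
    2x2x2 arrays of cellwise p*i values for the local joint information
    (``mi``, sampled under the source model; cells sum to the joint MI
    within Monte-Carlo error) and for the local co-information and its
    sign-masked Iccs contribution (``coinfo``, ``iccs``, sampled under
    the max-ent surrogate).  Positive co-information cells mark
    redundant regions of the (a, v) space; negative cells synergistic
    ones.
    """
    if maxent is None:
        maxent = maxent_surrogate(model)
    rng = np.random.default_rng(rng_seed)
    d = model.cov.shape[0]
    sm, sa, sv = model.slices

    def cell_index(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # sign of the first coordinate of each block defines the cell
        return (
            (samples[:, sm.start] > 0).astype(int),
            (samples[:, sa.start] > 0).astype(int),
            (samples[:, sv.start] > 0).astype(int),
        )

    def accumulate(values: np.ndarray, cells: tuple[np.ndarray, ...]) -> np.ndarray:
        out = np.zeros((2, 2, 2))
        np.add.at(out, cells, values)
        return out / values.shape[0]

    # local joint MI under the source model
    chol = np.linalg.cholesky(model.cov)
    xs = rng.standard_normal((n_mc, d)) @ chol.T
    idx = np.arange(d)
    av = np.concatenate([idx[sa], idx[sv]])
    lp_m = _GaussLogPdf(model.cov[sm, sm])
    lp_av = _GaussLogPdf(model.cov[np.ix_(av, av)])
    lp_mav = _GaussLogPdf(model.cov)
    i_joint = (lp_mav(xs) - lp_m(xs[:, sm]) - lp_av(xs[:, av])) / LN2
    mi_map = accumulate(i_joint, cell_index(xs))
    mi_se = float(i_joint.std(ddof=1) / np.sqrt(n_mc))

    # local co-information under the max-ent surrogate
    chol_t = np.linalg.cholesky(maxent.cov_tilde)
    xt = rng.standard_normal((n_mc, d)) @ chol_t.T
    i_ma, i_mv, i_mav, c_loc = _local_terms(xt, model, maxent)
    s = np.sign(i_ma)
    include = (s == np.sign(i_mv)) & (s == np.sign(i_mav)) & (s == np.sign(c_loc))
    cells_t = cell_index(xt)
    return {
        "mi": mi_map,
        "mi_se": mi_se,
        "coinfo": accumulate(c_loc, cells_t),
        "iccs": accumulate(np.where(include, c_loc, 0.0), cells_t),
        "n_mc": n_mc,
    }
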
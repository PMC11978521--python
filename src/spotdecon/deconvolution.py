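"""Multinomial generative model for spot deconvolution.

Each spot's marker-gene counts are modeled as a multinomial draw whose
probabilities mix per-type gene-proportion signatures through a spot-level
contribution simplex ``Q`` and gene-wise log2 batch-effect factors ``r``.
Inference maximizes the posterior (MAP) or fits a mean-field Gaussian
variational approximation, both with analytic gradients and an Adam
optimizer — no autodiff dependency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from spotdecon.io import PipelineConfig, ValidationError
from spotdecon.reference import SignatureMatrix

logger = logging.getLogger("spotdecon")

_LN2 = np.log(2.0)


@dataclass
class DeconvolutionResult:
    Q: np.ndarray  # (S, T) contribution scores, rows simplex
    r: np.ndarray  # (G_m,) centered log2 batch effects
    P: np.ndarray  # (S, T) cell-number proportions, rows simplex
    loss_trace: np.ndarray
    seed: int
    n_iterations: int
    type_ids: list[str] = field(default_factory=list)
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, mat in (("Q", self.Q), ("P", self.P)):
            if np.any(mat < 0) or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
                raise ValidationError(f"{name} rows must be simplexes")
        if not np.all(np.isfinite(self.loss_trace)):
            raise ValidationError("non-finite loss trace")


def compute_rho(Q: np.ndarray, phi_m: np.ndarray) -> np.ndarray:
    """Mixture gene proportions per spot: rho = Q @ phi (rows sum to 1)."""
    Q = np.asarray(Q, dtype=float)
    phi_m = np.asarray(phi_m, dtype=float)
    if Q.ndim != 2 or phi_m.ndim != 2 or Q.shape[1] != phi_m.shape[0]:
        raise ValidationError(
            f"shape mismatch: Q {Q.shape} vs phi {phi_m.shape}"
        )
    return Q @ phi_m


def apply_batch_effect(rho: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Tilt gene proportions by 2**r per gene and renormalize each row."""
    rho = np.asarray(rho, dtype=float)
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValidationError("batch effects must be finite")
    if rho.shape[-1] != r.shape[0]:
        raise ValidationError("rho/r shape mismatch")
    tilted = rho * np.exp2(r)
    totals = tilted.sum(axis=-1, keepdims=True)
    if np.any(totals == 0):
        raise ValidationError("a row of rho is entirely zero")
    return tilted / totals


def _softmax(a: np.ndarray) -> np.ndarray:
    z = a - a.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _neg_log_posterior_and_grads(A, r, X, phi, m, col_sums, sigma_r, lam_a):
    """Negative log posterior and its gradients wrt logits A and r.

    Log-likelihood: sum_s sum_g x_sg log(rho~_sg) with
    rho~ = (Q phi) * 2^r row-normalized, Q = softmax(A).
    Priors: r ~ N(0, sigma_r^2); weak L2 on A (flat-prior substitute).
    """
    Q = _softmax(A)
    rho = Q @ phi
    w = np.exp2(r)
    tilted = rho * w
    Z = tilted.sum(axis=1)
    rho_t = tilted / Z[:, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        log_rho = np.where(rho > 0, np.log(np.maximum(rho, 1e-300)), 0.0)
    ll = float(
        np.sum(X * log_rho)
        + _LN2 * np.sum(X * r[None, :])
        - np.sum(m * np.log(Z))
    )
    nlp = -(ll - 0.5 * np.sum(r**2) / sigma_r**2 - 0.5 * lam_a * np.sum(A**2))

    inv_rho = np.where(X > 0, X / np.maximum(rho, 1e-300), 0.0)
    g_rho = inv_rho - (m / Z)[:, None] * w[None, :]
    g_q = g_rho @ phi.T
    g_a = Q * (g_q - (Q * g_q).sum(axis=1, keepdims=True)) - lam_a * A
    g_r = _LN2 * (col_sums - (m[:, None] * rho_t).sum(axis=0)) - r / sigma_r**2
    return nlp, -g_a, -g_r, Q


class _Adam:
    def __init__(self, shape, lr):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.lr = lr
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, theta, grad):
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def fit_deconvolution(
    X_m: np.ndarray,
    signature: SignatureMatrix,
    config: PipelineConfig | None = None,
    spot_ids: list[str] | None = None,
) -> DeconvolutionResult:
    """Fit the generative model on marker-gene counts.

    ``X_m`` is the raw integer spot x marker-gene matrix; columns must
    align with ``signature.gene_ids``. Returns posterior-mean (VI) or MAP
    estimates of the contribution matrix ``Q`` and centered batch effects
    ``r``, plus cell-number proportions ``P`` (see
    :func:`contribution_to_proportion`).
    """
    config = config or PipelineConfig()
    X = np.asarray(X_m, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X_m must be 2-D")
    if np.any(X < 0) or not np.allclose(X, np.round(X)):
        raise ValidationError("X_m must contain nonnegative integer counts")
    if X.shape[1] != len(signature.gene_ids):
        raise ValidationError("X_m columns do not match signature genes")
    phi = signature.phi
    S, G = X.shape
    T = signature.n_types

    m = X.sum(axis=1)
    degenerate = m == 0
    if degenerate.any():
        logger.warning(
            "fit_deconvolution: %d spots with zero marker counts get uniform "
            "proportions", int(degenerate.sum())
        )
    fit_rows = ~degenerate
    Xf = X[fit_rows]
    mf = m[fit_rows]
    col_sums = Xf.sum(axis=0)

    rng = np.random.default_rng(config.seed)
    sigma_r, lam_a = 1.0, 1e-6
    n_iter = config.n_iterations
    trace = np.empty(n_iter)

    # r is frozen during a warm-up so Q converges before the gene-wise batch
    # effects start absorbing signature differences (Q and r are partially
    # confounded when spots share a composition)
    warmup = n_iter // 4

    if config.inference_mode == "map":
        A = np.zeros((Xf.shape[0], T))
        r = np.zeros(G)
        opt_a = _Adam(A.shape, config.learning_rate)
        opt_r = _Adam(r.shape, config.learning_rate)
        Q_fit = None
        for it in range(n_iter):
            nlp, ga, gr, Q_fit = _neg_log_posterior_and_grads(
                A, r, Xf, phi, mf, col_sums, sigma_r, lam_a
            )
            if not np.isfinite(nlp):
                raise ValidationError(
                    f"divergent loss at iteration {it}; trace: {trace[:it].tolist()[-5:]}"
                )
            trace[it] = nlp
            A = opt_a.step(A, ga)
            if it >= warmup:
                r = opt_r.step(r, gr)
        Q_fit = _softmax(A)
        r_hat = r
    else:  # mean-field Gaussian VI with reparameterized one-sample gradients
        mu_a = np.zeros((Xf.shape[0], T))
        ls_a = np.full((Xf.shape[0], T), -2.0)  # log sigma
        mu_r = np.zeros(G)
        ls_r = np.full(G, -2.0)
        opts = [
            _Adam(mu_a.shape, config.learning_rate),
            _Adam(ls_a.shape, config.learning_rate),
            _Adam(mu_r.shape, config.learning_rate),
            _Adam(ls_r.shape, config.learning_rate),
        ]
        for it in range(n_iter):
            ea = rng.standard_normal(mu_a.shape)
            er = rng.standard_normal(mu_r.shape)
            sa, sr = np.exp(ls_a), np.exp(ls_r)
            A = mu_a + sa * ea
            r = mu_r + sr * er
            nlp, ga, gr, _ = _neg_log_posterior_and_grads(
                A, r, Xf, phi, mf, col_sums, sigma_r, lam_a
            )
            if not np.isfinite(nlp):
                raise ValidationError(f"divergent loss at iteration {it}")
            # negative ELBO estimate = nlp - entropy
            trace[it] = nlp - float(np.sum(ls_a) + np.sum(ls_r))
            g_ls_a = ga * sa * ea - 1.0  # -1 from entropy term
            g_ls_r = gr * sr * er - 1.0
            mu_a = opts[0].step(mu_a, ga)
            ls_a = opts[1].step(ls_a, np.clip(g_ls_a, -1e3, 1e3))
            if it >= warmup:
                mu_r = opts[2].step(mu_r, gr)
                ls_r = opts[3].step(ls_r, np.clip(g_ls_r, -1e3, 1e3))
        # posterior means via Monte Carlo over guide samples
        n_mc = 100
        Q_acc = np.zeros((Xf.shape[0], T))
        for _ in range(n_mc):
            Q_acc += _softmax(mu_a + np.exp(ls_a) * rng.standard_normal(mu_a.shape))
        Q_fit = Q_acc / n_mc
        r_hat = mu_r

    Q = np.full((S, T), 1.0 / T)
    Q[fit_rows] = Q_fit
    r_hat = r_hat - r_hat.mean()  # shift-invariant likelihood: center for identifiability

    P = contribution_to_proportion(Q, signature.nu, mode=config.qp_mode)
    P[degenerate] = 1.0 / T  # no data: report uniform proportions
    return DeconvolutionResult(
        Q=Q,
        r=r_hat,
        P=P,
        loss_trace=trace,
        seed=config.seed,
        n_iterations=n_iter,
        type_ids=list(signature.type_ids),
        spot_ids=list(spot_ids) if spot_ids is not None else [],
    )


def contribution_to_proportion(
    Q: np.ndarray, nu: np.ndarray, mode: str = "mrna"
) -> np.ndarray:
    """Convert transcript-contribution scores to cell-number proportions.

    Mode ``"mrna"`` divides each type's score by its mean library size
    ``nu_t`` (types with more mRNA contribute more transcripts per cell)
    and renormalizes; ``"identity"`` returns ``Q`` unchanged.
    """
    Q = np.asarray(Q, dtype=float)
    if mode == "identity":
        return Q.copy()
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValidationError("nu must be positive")
    P = Q / nu[None, :]
    return P / P.sum(axis=1, keepdims=True)
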
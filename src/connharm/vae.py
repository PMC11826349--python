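"""Site-conditional variational autoencoder for connectome disentanglement.

The model learns a latent code ``z`` of the vectorized connectome that is
maximally informative of biology (age, sex, the 12 network measures) and
minimally informative of acquisition site. Site information is squeezed out
of ``z`` by two cooperating terms: the *site-conditional* reconstruction
(the decoder receives the site label, so ``z`` need not carry it) and the
KL penalty toward a standard normal prior, which bounds the mutual
information between ``z`` and the site variable.

Architecture (all-linear with ReLU):

* encoder: ``x -> Linear -> ReLU -> Linear -> ReLU -> (mu, log_var)``
* reparameterization: ``z = mu + exp(log_var/2) * eps``
* decoder: ``[z, onehot(c)] -> Linear -> ReLU -> Linear -> x_hat(c)``
* heads: age and sex are affine in ``z`` alone (biology must be
  site-invariant); the measures head is affine in ``[z, onehot(c)]``
  because the training targets are themselves site-biased.

The total loss is the unweighted (by default) sum of reconstruction MSE,
KL divergence, age MSE (standardized ages), sex binary cross-entropy, and
masked measure MSE (standardized measures; undefined targets masked out).

Everything is plain NumPy with hand-derived gradients and an Adam
optimizer; training is bitwise deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from connharm.io import Cohort, vectorize
from connharm.measures import MEASURE_NAMES

_STD_FLOOR = 1e-6
#: cap on the log-scale weight a decoded connectome entry may take; e^32
#: streamlines is far beyond any plausible count, so this only guards
#: against numerical overflow on degenerate features
_LOG_WEIGHT_CAP = 32.0


def _safe_std(std: np.ndarray | float) -> np.ndarray | float:
    """Constant features are left unscaled rather than divided by ~0."""
    return np.where(np.asarray(std) < _STD_FLOOR, 1.0, std)


class SchemeError(ValueError):
    """Unknown learning-scheme token."""


@dataclass(frozen=True)
class SiteCode:
    """A site label as categorical index + one-hot indicator."""

    index: int
    n_sites: int

    def __post_init__(self) -> None:
        if not (0 <= self.index < self.n_sites):
            raise ValueError(f"site index {self.index} outside [0, {self.n_sites})")

    @property
    def one_hot(self) -> np.ndarray:
        v = np.zeros(self.n_sites)
        v[self.index] = 1.0
        return v


@dataclass(frozen=True)
class LatentCode:
    """Posterior mean and log-variance (and optionally a sampled code)."""

    mu: np.ndarray
    log_var: np.ndarray
    z: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.mu.shape[-1]


@dataclass(frozen=True)
class LossBreakdown:
    """The five loss components and their weighted total."""

    recon: float
    kl: float
    age: float
    sex: float
    measures: float
    total: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the conditional VAE.

    ``n_measures`` is 12 under co-learning and 1 under individual learning.
    The five loss weights default to 1.0 (a plain unweighted sum).
    """

    input_dim: int
    n_sites: int
    hidden_dim: int = 256
    latent_dim: int = 32
    n_measures: int = len(MEASURE_NAMES)
    w_recon: float = 1.0
    w_kl: float = 1.0
    w_age: float = 1.0
    w_sex: float = 4.0
    w_measures: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 400
    batch_size: int = 32
    #: epochs over which the KL weight ramps linearly from 0 to w_kl
    #: (a standard VAE warm-up: biological signal is encoded before the
    #: prior squeezes latent capacity); 0 disables annealing
    kl_anneal_epochs: int = 0
    #: linearly decay the learning rate to this fraction of its initial
    #: value over training (1.0 = constant)
    lr_final_fraction: float = 1.0
    #: SD of Gaussian corruption added to the (standardized) encoder input
    #: during training while the reconstruction target stays clean — a
    #: denoising criterion that makes the latent code invariant to
    #: edge-level measurement noise; 0 disables
    input_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "n_sites", "hidden_dim", "latent_dim", "n_measures"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("w_recon", "w_kl", "w_age", "w_sex", "w_measures"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Standardizer:
    """Training-set statistics used to scale inputs and targets.

    Connectome features are transformed ``log(1 + w)`` then z-scored per
    feature (streamline counts span orders of magnitude); ages and measure
    targets are z-scored. All inverse transforms live here too.
    """

    x_mean: np.ndarray
    x_std: np.ndarray
    age_mean: float
    age_std: float
    m_mean: np.ndarray
    m_std: np.ndarray

    def encode_x(self, x_raw: np.ndarray) -> np.ndarray:
        return (np.log1p(x_raw) - self.x_mean) / self.x_std

    def decode_x(self, x_std: np.ndarray) -> np.ndarray:
        log_w = np.minimum(x_std * self.x_std + self.x_mean, _LOG_WEIGHT_CAP)
        return np.maximum(np.expm1(log_w), 0.0)

    def encode_age(self, age: np.ndarray) -> np.ndarray:
        return (age - self.age_mean) / self.age_std

    def decode_age(self, age_std: np.ndarray) -> np.ndarray:
        return age_std * self.age_std + self.age_mean

    def encode_m(self, m: np.ndarray) -> np.ndarray:
        return (m - self.m_mean) / self.m_std

    def decode_m(self, m_std: np.ndarray) -> np.ndarray:
        return m_std * self.m_std + self.m_mean


Params = dict[str, np.ndarray]

_PARAM_SHAPES = (
    # encoder
    ("enc_w1", lambda c: (c.input_dim, c.hidden_dim)),
    ("enc_b1", lambda c: (c.hidden_dim,)),
    ("enc_w2", lambda c: (c.hidden_dim, c.hidden_dim)),
    ("enc_b2", lambda c: (c.hidden_dim,)),
    ("enc_wmu", lambda c: (c.hidden_dim, c.latent_dim)),
    ("enc_bmu", lambda c: (c.latent_dim,)),
    ("enc_wlv", lambda c: (c.hidden_dim, c.latent_dim)),
    ("enc_blv", lambda c: (c.latent_dim,)),
    # decoder (input: z ++ one-hot site)
    ("dec_w1", lambda c: (c.latent_dim + c.n_sites, c.hidden_dim)),
    ("dec_b1", lambda c: (c.hidden_dim,)),
    ("dec_w2", lambda c: (c.hidden_dim, c.input_dim)),
    ("dec_b2", lambda c: (c.input_dim,)),
    # heads
    ("age_w", lambda c: (c.latent_dim, 1)),
    ("age_b", lambda c: (1,)),
    ("sex_w", lambda c: (c.latent_dim, 1)),
    ("sex_b", lambda c: (1,)),
    ("mea_w", lambda c: (c.latent_dim + c.n_sites, c.n_measures)),
    ("mea_b", lambda c: (c.n_measures,)),
)


def init_params(config: ModelConfig, rng: np.random.Generator) -> Params:
    """He-style initialization: N(0, 2/fan_in) weights, zero biases."""
    params: Params = {}
    for name, shape_fn in _PARAM_SHAPES:
        shape = shape_fn(config)
        if len(shape) == 1:
            params[name] = np.zeros(shape)
        else:
            params[name] = rng.standard_normal(shape) * np.sqrt(2.0 / shape[0])
    return params


# ---------------------------------------------------------------------------
# forward pieces (public, single- or batch-input)
# ---------------------------------------------------------------------------


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def encode(x: np.ndarray, params: Params) -> LatentCode:
    """Deterministic encoder pass producing the posterior (mu, log_var)."""
    xb, squeeze = _as_batch(x)
    if xb.shape[1] != params["enc_w1"].shape[0]:
        raise ValueError(
            f"input dim {xb.shape[1]} != model input dim {params['enc_w1'].shape[0]}"
        )
    h1 = _relu(xb @ params["enc_w1"] + params["enc_b1"])
    h2 = _relu(h1 @ params["enc_w2"] + params["enc_b2"])
    mu = h2 @ params["enc_wmu"] + params["enc_bmu"]
    lv = h2 @ params["enc_wlv"] + params["enc_blv"]
    if squeeze:
        mu, lv = mu[0], lv[0]
    return LatentCode(mu=mu, log_var=lv)


def reparameterize(code: LatentCode, noise: np.ndarray) -> np.ndarray:
    """``z = mu + exp(log_var / 2) * eps`` — with ``eps = 0``, z = mu."""
    return code.mu + np.exp(code.log_var / 2.0) * np.asarray(noise, dtype=float)


def _site_onehot(site: SiteCode | np.ndarray, n: int) -> np.ndarray:
    if isinstance(site, SiteCode):
        return np.tile(site.one_hot, (n, 1))
    site = np.asarray(site, dtype=float)
    if site.ndim == 1:
        return np.tile(site, (n, 1))
    return site


def decode(z: np.ndarray, site: SiteCode | np.ndarray, params: Params) -> np.ndarray:
    """Reconstruct the (standardized) connectome vector in the site's domain."""
    zb, squeeze = _as_batch(z)
    c = _site_onehot(site, zb.shape[0])
    din = np.concatenate([zb, c], axis=1)
    h = _relu(din @ params["dec_w1"] + params["dec_b1"])
    xhat = h @ params["dec_w2"] + params["dec_b2"]
    return xhat[0] if squeeze else xhat


def predict_heads(
    z: np.ndarray, site: SiteCode | np.ndarray, params: Params
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (age_hat, sex_logit, measures_hat), all on standardized scales.

    Age and sex depend on ``z`` only; the measures head is site-conditional.
    """
    zb, squeeze = _as_batch(z)
    c = _site_onehot(site, zb.shape[0])
    din = np.concatenate([zb, c], axis=1)
    age = (zb @ params["age_w"] + params["age_b"])[:, 0]
    sexl = (zb @ params["sex_w"] + params["sex_b"])[:, 0]
    mh = din @ params["mea_w"] + params["mea_b"]
    if squeeze:
        return age[0], sexl[0], mh[0]
    return age, sexl, mh


def kl_divergence(code: LatentCode) -> float:
    """KL[N(mu, diag exp(log_var)) || N(0, I)], summed over latent dims.

    Closed form ``0.5 * sum(exp(lv) + mu^2 - 1 - lv)``; for a batch, the
    mean over samples of the per-sample KL.
    """
    mu, lv = np.atleast_2d(code.mu), np.atleast_2d(code.log_var)
    # expm1 keeps exp(lv) - 1 - lv accurate (and non-negative) for tiny lv
    per_sample = 0.5 * np.sum(np.expm1(lv) - lv + mu**2, axis=1)
    return float(np.maximum(per_sample, 0.0).mean())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bce_with_logits(logit: np.ndarray, target: np.ndarray) -> np.ndarray:
    # max(x,0) - x*t + log(1 + exp(-|x|)): numerically stable BCE
    return np.maximum(logit, 0.0) - logit * target + np.log1p(np.exp(-np.abs(logit)))


# ---------------------------------------------------------------------------
# loss + gradients
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Batch:
    """One training minibatch, already standardized.

    ``measures`` may contain NaN where a target measure is undefined; those
    entries are masked out of the measure loss.
    """

    x: np.ndarray  # (N, input_dim) standardized features (recon target)
    age: np.ndarray  # (N,) standardized ages
    sex: np.ndarray  # (N,) {0, 1}
    site_onehot: np.ndarray  # (N, n_sites)
    measures: np.ndarray  # (N, n_measures) standardized, NaN = undefined
    x_in: np.ndarray | None = None  # corrupted encoder input; None -> x


def _loss_and_grads(
    batch: Batch,
    params: Params,
    config: ModelConfig,
    eps: np.ndarray,
    want_grads: bool = True,
) -> tuple[LossBreakdown, Params | None]:
    x, c = batch.x, batch.site_onehot
    x_in = batch.x_in if batch.x_in is not None else x
    n, d = x.shape
    l = config.latent_dim

    # ---- forward ----
    a1 = x_in @ params["enc_w1"] + params["enc_b1"]
    h1 = _relu(a1)
    a2 = h1 @ params["enc_w2"] + params["enc_b2"]
    h2 = _relu(a2)
    mu = h2 @ params["enc_wmu"] + params["enc_bmu"]
    lv = h2 @ params["enc_wlv"] + params["enc_blv"]
    sig = np.exp(lv / 2.0)
    z = mu + sig * eps
    din = np.concatenate([z, c], axis=1)
    a3 = din @ params["dec_w1"] + params["dec_b1"]
    h3 = _relu(a3)
    xhat = h3 @ params["dec_w2"] + params["dec_b2"]
    age_hat = (z @ params["age_w"] + params["age_b"])[:, 0]
    sex_logit = (z @ params["sex_w"] + params["sex_b"])[:, 0]
    mh = din @ params["mea_w"] + params["mea_b"]

    mask = np.isfinite(batch.measures)
    m_tgt = np.where(mask, batch.measures, 0.0)
    n_m = max(int(mask.sum()), 1)

    l_recon = float(np.mean((xhat - x) ** 2))
    l_kl = float(np.mean(0.5 * np.sum(np.expm1(lv) - lv + mu**2, axis=1)))
    l_age = float(np.mean((age_hat - batch.age) ** 2))
    l_sex = float(np.mean(_bce_with_logits(sex_logit, batch.sex)))
    l_mea = float(np.sum(mask * (mh - m_tgt) ** 2) / n_m)
    total = (
        config.w_recon * l_recon
        + config.w_kl * l_kl
        + config.w_age * l_age
        + config.w_sex * l_sex
        + config.w_measures * l_mea
    )
    breakdown = LossBreakdown(
        recon=l_recon, kl=l_kl, age=l_age, sex=l_sex, measures=l_mea, total=total
    )
    if not want_grads:
        return breakdown, None

    # ---- backward ----
    g: Params = {}
    g_xhat = config.w_recon * 2.0 * (xhat - x) / (n * d)
    g["dec_w2"] = h3.T @ g_xhat
    g["dec_b2"] = g_xhat.sum(axis=0)
    g_a3 = (g_xhat @ params["dec_w2"].T) * (a3 > 0)
    g["dec_w1"] = din.T @ g_a3
    g["dec_b1"] = g_a3.sum(axis=0)
    g_din = g_a3 @ params["dec_w1"].T

    g_mh = config.w_measures * 2.0 * mask * (mh - m_tgt) / n_m
    g["mea_w"] = din.T @ g_mh
    g["mea_b"] = g_mh.sum(axis=0)
    g_din = g_din + g_mh @ params["mea_w"].T

    g_z = g_din[:, :l]

    g_age = (config.w_age * 2.0 * (age_hat - batch.age) / n)[:, None]
    g["age_w"] = z.T @ g_age
    g["age_b"] = g_age.sum(axis=0)
    g_z = g_z + g_age @ params["age_w"].T

    g_sexl = (config.w_sex * (_sigmoid(sex_logit) - batch.sex) / n)[:, None]
    g["sex_w"] = z.T @ g_sexl
    g["sex_b"] = g_sexl.sum(axis=0)
    g_z = g_z + g_sexl @ params["sex_w"].T

    g_mu = g_z + config.w_kl * mu / n
    g_lv = g_z * eps * 0.5 * sig + config.w_kl * 0.5 * (np.exp(lv) - 1.0) / n

    g["enc_wmu"] = h2.T @ g_mu
    g["enc_bmu"] = g_mu.sum(axis=0)
    g["enc_wlv"] = h2.T @ g_lv
    g["enc_blv"] = g_lv.sum(axis=0)
    g_h2 = g_mu @ params["enc_wmu"].T + g_lv @ params["enc_wlv"].T
    g_a2 = g_h2 * (a2 > 0)
    g["enc_w2"] = h1.T @ g_a2
    g["enc_b2"] = g_a2.sum(axis=0)
    g_a1 = (g_a2 @ params["enc_w2"].T) * (a1 > 0)
    g["enc_w1"] = x_in.T @ g_a1
    g["enc_b1"] = g_a1.sum(axis=0)
    return breakdown, g


def total_loss(
    batch: Batch,
    params: Params,
    config: ModelConfig,
    eps: np.ndarray | None = None,
) -> LossBreakdown:
    """Evaluate the composite loss on a batch (``eps=None`` means z = mu)."""
    if eps is None:
        eps = np.zeros((batch.x.shape[0], config.latent_dim))
    breakdown, _ = _loss_and_grads(batch, params, config, eps, want_grads=False)
    return breakdown


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class _Adam:
    lr: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        self.m: Params = {}
        self.v: Params = {}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, grad in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(grad)
                self.v[key] = np.zeros_like(grad)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad**2
            params[key] -= (
                self.lr * (self.m[key] / b1t) / (np.sqrt(self.v[key] / b2t) + self.eps)
            )


@dataclass(frozen=True)
class TrainedModel:
    """A trained conditional VAE plus everything needed to reuse it."""

    params: Params
    config: ModelConfig
    standardizer: Standardizer
    site_vocabulary: tuple[str, ...]
    measure_names: tuple[str, ...]
    history: tuple[LossBreakdown, ...]

    def site_code(self, site: str) -> SiteCode:
        if site not in self.site_vocabulary:
            raise ValueError(
                f"site {site!r} not in model vocabulary {self.site_vocabulary}"
            )
        return SiteCode(index=self.site_vocabulary.index(site), n_sites=len(self.site_vocabulary))

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([h.to_dict() for h in self.history])


def _prepare_training_arrays(
    cohort: Cohort,
    measures: pd.DataFrame,
    measure_names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw (un-standardized) X, age, sex, site-index, measure-target arrays."""
    m_indexed = measures.set_index("subject_id")
    missing = [r.subject_id for r in cohort if r.subject_id not in m_indexed.index]
    if missing:
        raise LookupError(f"no measure rows for subjects: {missing}")
    x = np.stack([vectorize(r.connectome) for r in cohort])
    age = np.array([r.age for r in cohort], dtype=float)
    sex = np.array([r.sex_code for r in cohort], dtype=float)
    site_idx = np.array(
        [cohort.site_vocabulary.index(r.site) for r in cohort], dtype=int
    )
    b = m_indexed.loc[[r.subject_id for r in cohort], list(measure_names)].to_numpy(
        dtype=float
    )
    return x, age, sex, site_idx, b


def train(
    cohort: Cohort,
    measures: pd.DataFrame,
    config: ModelConfig,
    measure_names: Sequence[str] = MEASURE_NAMES,
) -> TrainedModel:
    """Train the conditional VAE by minibatch Adam on the composite loss.

    Targets (ages, measures) are standardized with training-set statistics
    only, which are persisted with the model. Bitwise deterministic given
    ``config.seed``. Refuses single-site cohorts: with one site the
    conditional decoder cannot separate site from biology.
    """
    if len(cohort.site_vocabulary) < 2:
        raise ValueError(
            "training cohort spans a single site; site disentanglement is "
            "undefined — provide records from at least two sites"
        )
    if len(measure_names) != config.n_measures:
        raise ValueError(
            f"config.n_measures={config.n_measures} but {len(measure_names)} "
            "measure names given"
        )
    if len(cohort.site_vocabulary) != config.n_sites:
        raise ValueError(
            f"config.n_sites={config.n_sites} but cohort has "
            f"{len(cohort.site_vocabulary)} sites"
        )
    x_raw, age, sex, site_idx, b_raw = _prepare_training_arrays(
        cohort, measures, measure_names
    )
    if x_raw.shape[1] != config.input_dim:
        raise ValueError(
            f"config.input_dim={config.input_dim} but connectomes vectorize to "
            f"{x_raw.shape[1]}"
        )

    x_log = np.log1p(x_raw)
    import warnings

    with warnings.catch_warnings():  # all-NaN measure columns are legal
        warnings.simplefilter("ignore", RuntimeWarning)
        m_mean = np.nan_to_num(np.nanmean(b_raw, axis=0))
        m_std = np.nan_to_num(np.nanstd(b_raw, axis=0))
    std = Standardizer(
        x_mean=x_log.mean(axis=0),
        x_std=np.asarray(_safe_std(x_log.std(axis=0))),
        age_mean=float(age.mean()),
        age_std=float(_safe_std(age.std())),
        m_mean=m_mean,
        m_std=np.asarray(_safe_std(m_std)),
    )
    x_std = (x_log - std.x_mean) / std.x_std
    age_std = std.encode_age(age)
    b_std = (b_raw - std.m_mean) / std.m_std  # NaN propagates -> masked in loss

    n = x_std.shape[0]
    n_sites = config.n_sites
    onehot = np.eye(n_sites)[site_idx]

    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)
    opt = _Adam(lr=config.learning_rate)
    history: list[LossBreakdown] = []

    for epoch in range(config.epochs):
        if config.kl_anneal_epochs > 0:
            ramp = min(1.0, (epoch + 1) / config.kl_anneal_epochs)
            epoch_config = replace(config, w_kl=config.w_kl * ramp)
        else:
            epoch_config = config
        if config.lr_final_fraction < 1.0 and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            opt.lr = config.learning_rate * (
                1.0 - frac * (1.0 - config.lr_final_fraction)
            )
        order = rng.permutation(n)
        sums = np.zeros(6)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            eps = rng.standard_normal((idx.size, config.latent_dim))
            xb = x_std[idx]
            x_in = (
                xb + config.input_noise_sd
                * rng.standard_normal((idx.size, x_std.shape[1]))
                if config.input_noise_sd > 0
                else None
            )
            batch = Batch(
                x=xb,
                age=age_std[idx],
                sex=sex[idx],
                site_onehot=onehot[idx],
                measures=b_std[idx],
                x_in=x_in,
            )
            breakdown, grads = _loss_and_grads(batch, params, epoch_config, eps)
            opt.step(params, grads)
            sums += np.array(
                [
                    breakdown.recon,
                    breakdown.kl,
                    breakdown.age,
                    breakdown.sex,
                    breakdown.measures,
                    breakdown.total,
                ]
            )
            n_batches += 1
        mean = sums / n_batches
        history.append(
            LossBreakdown(
                recon=mean[0], kl=mean[1], age=mean[2], sex=mean[3],
                measures=mean[4], total=mean[5],
            )
        )

    return TrainedModel(
        params=params,
        config=config,
        standardizer=std,
        site_vocabulary=cohort.site_vocabulary,
        measure_names=tuple(measure_names),
        history=tuple(history),
    )


def train_scheme(
    cohort: Cohort,
    measures: pd.DataFrame,
    config: ModelConfig,
    scheme: str,
) -> TrainedModel | dict[str, TrainedModel]:
    """Train under one of the two learning schemes.

    ``colearn``
        One model whose measures head predicts all 12 network measures
        simultaneously from the shared latent space.
    ``individual``
        Twelve separate models, each predicting a single measure
        (measures whose target is undefined for every training subject
        are skipped).
    """
    if scheme == "colearn":
        return train(
            cohort,
            measures,
            replace(config, n_measures=len(MEASURE_NAMES)),
            measure_names=MEASURE_NAMES,
        )
    if scheme == "individual":
        models: dict[str, TrainedModel] = {}
        for name in MEASURE_NAMES:
            if not np.isfinite(measures[name].to_numpy(dtype=float)).any():
                continue
            models[name] = train(
                cohort,
                measures,
                replace(config, n_measures=1),
                measure_names=(name,),
            )
        return models
    raise SchemeError(f"scheme must be 'colearn' or 'individual', got {scheme!r}")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, out_dir: str | Path) -> Path:
    """Persist parameters (npz) plus a JSON sidecar of everything else."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "params.npz", **model.params)
    sidecar = {
        "config": asdict(model.config),
        "standardizer": {
            "x_mean": model.standardizer.x_mean.tolist(),
            "x_std": model.standardizer.x_std.tolist(),
            "age_mean": model.standardizer.age_mean,
            "age_std": model.standardizer.age_std,
            "m_mean": model.standardizer.m_mean.tolist(),
            "m_std": model.standardizer.m_std.tolist(),
        },
        "site_vocabulary": list(model.site_vocabulary),
        "measure_names": list(model.measure_names),
        "history": [h.to_dict() for h in model.history],
    }
    (out_dir / "model.json").write_text(json.dumps(sidecar))
    return out_dir


def load_model(model_dir: str | Path) -> TrainedModel:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    with np.load(model_dir / "params.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    sc = sidecar["standardizer"]
    return TrainedModel(
        params=params,
        config=ModelConfig(**sidecar["config"]),
        standardizer=Standardizer(
            x_mean=np.array(sc["x_mean"]),
            x_std=np.array(sc["x_std"]),
            age_mean=sc["age_mean"],
            age_std=sc["age_std"],
            m_mean=np.array(sc["m_mean"]),
            m_std=np.array(sc["m_std"]),
        ),
        site_vocabulary=tuple(sidecar["site_vocabulary"]),
        measure_names=tuple(sidecar["measure_names"]),
        history=tuple(LossBreakdown(**h) for h in sidecar["history"]),
    )
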
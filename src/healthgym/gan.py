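"""Sequence Wasserstein GAN with gradient penalty and correlation alignment.

The generative core: a recurrent generator maps latent Gaussian sequences to
encoded mixed-type clinical sequences, and a recurrent critic scores their
realisticness.  Training minimises

* critic:     ``L_D = E[D(G(z))] - E[D(x_real)] + lambda_GP * E[(||grad_xhat D(xhat)||_2 - 1)^2]``
* generator:  ``L_G = -E[D(G(z))] + lambda_corr * sum_{i>j} | r_syn(i,j) - r_real(i,j) |``

where ``r`` are Pearson correlation matrices over the encoded channels,
pooled across batch and time.  With ``lambda_corr = 0`` the generator loss
reduces exactly to the vanilla Wasserstein objective.  The penalty point
``xhat`` defaults to a per-sequence uniform interpolation between paired
real and synthetic sequences (the standard gradient-penalty construction);
``gp_mode="at_synthetic"`` differentiates at the synthetic batch instead.

The public surface is the model/results pair: :class:`HealthGymGAN` is
built from a :class:`~healthgym.schema.LongitudinalDataset`, ``fit`` runs
the alternating optimisation, and the returned :class:`HealthGymGANResults`
carries the trained networks, the per-step training log and ``sample``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._nn import Adam, BiLSTM, Dense, Embedding
from .preprocessing import (
    ChannelMap,
    EncodedBatch,
    TransformSpec,
    decode,
    encode,
    fit_transforms,
)
from .schema import NUMERIC, CohortSchema, LongitudinalDataset, SchemaError


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """Generator architecture: biLSTM then three dense layers.

    The first two dense widths are free; the third layer's width is the
    encoded channel count, with a bounded (sigmoid) head per numeric channel
    and a softmax head per categorical block.
    """

    latent_dim: int = 16
    hidden_size: int = 24
    dense_widths: tuple = (48, 48)


@dataclass
class CriticSpec:
    """Critic architecture: soft embeddings, two dense layers, biLSTM, score.

    ``time_pooling`` controls how per-timestep scores collapse to one scalar
    realisticness score per sequence ("mean" or "last").
    """

    embedding_dim: int = 4
    dense_widths: tuple = (48, 48)
    hidden_size: int = 24
    time_pooling: str = "mean"


@dataclass
class TrainingConfig:
    lambda_gp: float = 10.0
    lambda_corr: float = 10.0
    critic_steps_per_generator_step: int = 5
    lr_generator: float = 1e-3
    lr_critic: float = 1e-3
    batch_size: int = 64
    epochs: Optional[int] = None
    total_steps: Optional[int] = None
    seed: int = 0
    gp_mode: str = "interpolate"  # or "at_synthetic"
    global_r: bool = False  # r_real per minibatch (False) or once globally

    def __post_init__(self):
        if self.lambda_gp < 0 or self.lambda_corr < 0:
            raise SchemaError("penalty weights must be non-negative")
        if self.batch_size < 2:
            raise SchemaError("batch size must be >= 2 (correlation needs it)")
        if self.gp_mode not in ("interpolate", "at_synthetic"):
            raise SchemaError(f"unknown gp_mode {self.gp_mode!r}")
        if self.epochs is None and self.total_steps is None:
            raise SchemaError("set epochs or total_steps")


@dataclass
class CorrelationMatrix:
    """Symmetric channel-correlation matrix with channel labels."""

    r: np.ndarray
    labels: list
    constant_channels: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _col(x: ad.Tensor, start: int, stop: int) -> ad.Tensor:
    return x[:, start:stop]


class Generator:
    """z (B, T, latent) -> encoded batch values (B, T, channels)."""

    def __init__(self, spec: GeneratorSpec, channel_map: ChannelMap, rng):
        self.spec = spec
        self.channel_map = channel_map
        w1, w2 = spec.dense_widths
        self.bilstm = BiLSTM(rng, spec.latent_dim, spec.hidden_size)
        self.d1 = Dense(rng, 2 * spec.hidden_size, w1)
        self.d2 = Dense(rng, w1, w2)
        self.d3 = Dense(rng, w2, channel_map.n_channels)

    @property
    def params(self):
        return self.bilstm.params + self.d1.params + self.d2.params + self.d3.params

    def forward(self, z: np.ndarray) -> ad.Tensor:
        if not np.all(np.isfinite(z)):
            raise SchemaError("latent input contains non-finite values")
        B, T, Z = z.shape
        xs = [ad.constant(z[:, t, :]) for t in range(T)]
        hs = self.bilstm(xs)
        h = ad.concat(hs, axis=0)  # (T*B, 2H), time-major
        h = ad.relu(self.d1(h))
        h = ad.relu(self.d2(h))
        raw = self.d3(h)  # (T*B, C)
        parts = []
        for ch in self.channel_map.channels:
            block = _col(raw, ch.start, ch.stop)
            if ch.kind == NUMERIC:
                parts.append(ad.sigmoid(block))
            else:
                parts.append(ad.softmax(block, axis=1))
        out = ad.concat(parts, axis=1)  # (T*B, C)
        out = ad.reshape(out, (T, B, self.channel_map.n_channels))
        return _tb_to_bt(out)  # (B, T, C)

    def sample_encoded(
        self, n: int, T: int, rng: np.random.Generator, chunk: int = 512
    ) -> np.ndarray:
        """Draw latent sequences and return generator output as an array."""
        z = rng.standard_normal((n, T, self.spec.latent_dim))
        outs = []
        for lo in range(0, n, chunk):
            outs.append(self.forward(z[lo: lo + chunk]).data)
        if not outs:
            return np.zeros((0, T, self.channel_map.n_channels))
        return np.concatenate(outs, axis=0)


def _tb_to_bt(x: ad.Tensor) -> ad.Tensor:
    """(T, B, C) -> (B, T, C) using a transpose-style gather."""
    T, B, C = x.shape
    idx = (np.arange(T)[None, :].repeat(B, 0), np.arange(B)[:, None].repeat(T, 1))
    return x[idx]


def _bt_slices(x: ad.Tensor) -> List[ad.Tensor]:
    """(B, T, F) tensor -> list of T (B, F) tensors."""
    B, T, F = x.shape
    return [x[:, t, :] for t in range(T)]


class Critic:
    """Encoded batch (B, T, channels) -> one realisticness score per sequence."""

    def __init__(self, spec: CriticSpec, channel_map: ChannelMap, rng):
        self.spec = spec
        self.channel_map = channel_map
        self.embeddings = {}
        width_in = 0
        for ch in channel_map.channels:
            if ch.kind == NUMERIC:
                width_in += 1
            else:
                self.embeddings[ch.name] = Embedding(
                    rng, ch.stop - ch.start, spec.embedding_dim
                )
                width_in += spec.embedding_dim
        w1, w2 = spec.dense_widths
        self.d1 = Dense(rng, width_in, w1)
        self.d2 = Dense(rng, w1, w2)
        self.bilstm = BiLSTM(rng, w2, spec.hidden_size)
        self.d3 = Dense(rng, 2 * spec.hidden_size, 1)

    @property
    def params(self):
        ps = []
        for emb in self.embeddings.values():
            ps.extend(emb.params)
        return ps + self.d1.params + self.d2.params + self.bilstm.params + self.d3.params

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        B, T, C = x.shape
        flat = ad.reshape(x, (B * T, C))
        parts = []
        for ch in self.channel_map.channels:
            block = _col(flat, ch.start, ch.stop)
            if ch.kind == NUMERIC:
                parts.append(block)
            else:
                parts.append(self.embeddings[ch.name](block))
        h = ad.concat(parts, axis=1)
        h = ad.relu(self.d1(h))
        h = ad.relu(self.d2(h))
        h = ad.reshape(h, (B, T, -1))
        hs = self.bilstm(_bt_slices(h))
        scores = [self.d3(ht) for ht in hs]  # T tensors of (B, 1)
        if self.spec.time_pooling == "last":
            pooled = scores[-1]
        else:
            pooled = ad.concat(scores, axis=1).mean(axis=1, keepdims=True)
        return ad.reshape(pooled, (B,))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_EPS_STD = 1e-8


def pearson_matrix(batch) -> CorrelationMatrix:
    """Pearson r over all encoded channel pairs, pooled across batch and time.

    Constant channels are flagged and given r = 0 against every other
    channel; the diagonal is 1.
    """
    if isinstance(batch, EncodedBatch):
        X = batch.pooled()
        labels = batch.channel_map.channel_labels()
    else:
        X = np.asarray(batch, dtype=float)
        if X.ndim == 3:
            X = X.reshape(-1, X.shape[2])
        labels = [f"ch{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise SchemaError("pearson_matrix needs at least 2 pooled samples")
    sd = X.std(axis=0)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, labels, [labels[i] for i in np.flatnonzero(const)])


def _pearson_tensor(X: ad.Tensor) -> ad.Tensor:
    """Differentiable channel correlation of a pooled (N, C) tensor.

    Standard deviations carry a small epsilon so near-constant channels do
    not produce infinite gradients; the numpy-level :func:`pearson_matrix`
    applies the exact constant-channel convention instead.
    """
    N, C = X.shape
    mu = X.mean(axis=0, keepdims=True)
    Xc = X - mu
    cov = (Xc.T @ Xc) / float(N - 1)
    diag = cov[(np.arange(C), np.arange(C))]
    s = ad.sqrt(diag + _EPS_STD)
    denom = s.reshape((C, 1)) * s.reshape((1, C))
    return cov / denom


def _tril_mask(C: int) -> np.ndarray:
    return np.tril(np.ones((C, C)), k=-1)


def alignment_loss(r_syn, r_real, lambda_corr: float) -> float:
    """L1 gap between correlation matrices over unique (i > j) pairs."""
    rs = r_syn.r if isinstance(r_syn, CorrelationMatrix) else np.asarray(r_syn)
    rr = r_real.r if isinstance(r_real, CorrelationMatrix) else np.asarray(r_real)
    mask = _tril_mask(rs.shape[0])
    return float(lambda_corr * (np.abs(rs - rr) * mask).sum())


def _alignment_tensor(r_syn: ad.Tensor, r_real: np.ndarray, lam: float) -> ad.Tensor:
    mask = ad.constant(_tril_mask(r_syn.shape[0]))
    return ad.constant(lam) * (ad.absolute(r_syn - ad.constant(r_real)) * mask).sum()


def critic_loss(
    critic: Critic,
    generator: Generator,
    x_real: np.ndarray,
    z: np.ndarray,
    lambda_gp: float,
    gp_mode: str = "interpolate",
    u: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Critic objective; returns (loss tensor, diagnostics dict).

    The synthetic batch is treated as fixed data for the critic update.  The
    penalty point is a per-sequence uniform interpolation between paired
    real and synthetic sequences ("interpolate") or the synthetic batch
    itself ("at_synthetic").
    """
    x_syn = generator.forward(z).data
    d_real = critic.forward(ad.constant(x_real))
    d_syn = critic.forward(ad.constant(x_syn))
    wasserstein = d_syn.mean() - d_real.mean()
    if lambda_gp == 0:
        parts = {"wasserstein": wasserstein.item(), "gradient_penalty": 0.0}
        return wasserstein, parts
    penalty = gradient_penalty(critic, x_real, x_syn, gp_mode=gp_mode, u=u, rng=rng)
    loss = wasserstein + ad.constant(lambda_gp) * penalty
    parts = {"wasserstein": wasserstein.item(), "gradient_penalty": penalty.item()}
    return loss, parts


def gradient_penalty(
    critic: Critic,
    x_real: np.ndarray,
    x_syn: np.ndarray,
    gp_mode: str = "interpolate",
    u: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> ad.Tensor:
    """``E[(||grad_xhat D(xhat)||_2 - 1)^2]`` as a differentiable tensor."""
    if gp_mode == "interpolate":
        if u is None:
            rng = rng or np.random.default_rng()
            u = rng.random((x_real.shape[0], 1, 1))
        xhat_data = u * x_real + (1.0 - u) * x_syn
    elif gp_mode == "at_synthetic":
        xhat_data = np.array(x_syn)
    else:
        raise SchemaError(f"unknown gp_mode {gp_mode!r}")
    xhat = ad.Tensor(xhat_data, requires_grad=True)
    score_sum = critic.forward(xhat).sum()
    g = ad.grad(score_sum, [xhat])[0]
    gnorm = ad.sqrt((g * g).sum(axis=(1, 2)) + 1e-12)
    return ((gnorm - ad.constant(1.0)) ** 2).mean()


def generator_loss(
    critic: Critic,
    generator: Generator,
    z: np.ndarray,
    r_real: Optional[np.ndarray],
    lambda_corr: float,
):
    """Generator objective; with ``lambda_corr = 0`` exactly the vanilla loss."""
    x = generator.forward(z)
    score = critic.forward(x).mean()
    loss = -score
    align_val = 0.0
    if lambda_corr != 0:
        B, T, C = x.shape
        pooled = ad.reshape(x, (B * T, C))
        r_syn = _pearson_tensor(pooled)
        align = _alignment_tensor(r_syn, np.asarray(r_real), lambda_corr)
        loss = loss + align
        align_val = align.item()
    parts = {"generator_score": score.item(), "alignment": align_val}
    return loss, parts


def _pearson_np_eps(X: np.ndarray) -> np.ndarray:
    """Numpy mirror of the epsilon-guarded correlation used in the loss."""
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    s = np.sqrt(np.diag(cov) + _EPS_STD)
    return cov / np.outer(s, s)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class HealthGymGAN:
    """Generative model of a longitudinal cohort.

    Parameters
    ----------
    real : LongitudinalDataset
        Training cohort; transforms are fitted on it unless supplied.
    generator_spec, critic_spec : optional architecture overrides.
    transform_spec : optional pre-fitted numeric transforms.
    """

    def __init__(
        self,
        real: LongitudinalDataset,
        generator_spec: Optional[GeneratorSpec] = None,
        critic_spec: Optional[CriticSpec] = None,
        transform_spec: Optional[TransformSpec] = None,
    ):
        self.real = real
        self.schema = real.schema
        self.generator_spec = generator_spec or GeneratorSpec()
        self.critic_spec = critic_spec or CriticSpec()
        self.transform_spec = transform_spec or fit_transforms(real)
        self.encoded = encode(real, self.transform_spec)
        self.channel_map = self.encoded.channel_map

    def fit(self, config: TrainingConfig) -> "HealthGymGANResults":
        """Run the alternating critic/generator optimisation."""
        rng = np.random.default_rng(config.seed)
        init_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )
        generator = Generator(self.generator_spec, self.channel_map, init_rng)
        critic = Critic(self.critic_spec, self.channel_map, init_rng)
        X = self.encoded.values
        n = X.shape[0]
        T = self.schema.timesteps_per_patient
        B = min(config.batch_size, n)

        steps_per_epoch = max(1, math.ceil(n / B))
        total = (
            config.total_steps
            if config.total_steps is not None
            else config.epochs * steps_per_epoch
        )

        order: list = []

        def next_batch() -> np.ndarray:
            nonlocal order
            if len(order) < B:
                order = list(rng.permutation(n))
            idx = [order.pop() for _ in range(B)]
            return X[idx]

        r_global = (
            _pearson_np_eps(X.reshape(-1, X.shape[2])) if config.global_r else None
        )

        opt_c = Adam(critic.params, lr=config.lr_critic)
        opt_g = Adam(generator.params, lr=config.lr_generator)
        rows = []
        last_finite = None
        for step in range(total):
            c_parts = {"wasserstein": 0.0, "gradient_penalty": 0.0}
            c_loss_val = 0.0
            for _ in range(config.critic_steps_per_generator_step):
                xr = next_batch()
                z = rng.standard_normal((B, T, self.generator_spec.latent_dim))
                u = rng.random((B, 1, 1))
                loss, c_parts = critic_loss(
                    critic, generator, xr, z, config.lambda_gp,
                    gp_mode=config.gp_mode, u=u,
                )
                grads = ad.grad(loss, critic.params)
                opt_c.step(grads)
                c_loss_val = loss.item()

            xr = next_batch()
            r_real = (
                r_global
                if r_global is not None
                else _pearson_np_eps(xr.reshape(-1, xr.shape[2]))
            )
            z = rng.standard_normal((B, T, self.generator_spec.latent_dim))
            g_loss, g_parts = generator_loss(
                critic, generator, z, r_real, config.lambda_corr
            )
            grads = ad.grad(g_loss, generator.params)
            opt_g.step(grads)

            row = {
                "step": step,
                "critic_loss": c_loss_val,
                "wasserstein": c_parts["wasserstein"],
                "gradient_penalty": c_parts["gradient_penalty"],
                "generator_loss": g_loss.item(),
                "generator_score": g_parts["generator_score"],
                "alignment": g_parts["alignment"],
            }
            vals = [v for v in row.values() if isinstance(v, float)]
            if not np.all(np.isfinite(vals)):
                raise RuntimeError(
                    f"non-finite loss at step {step}; last finite losses: "
                    f"{last_finite}"
                )
            last_finite = row
            rows.append(row)

        log = pd.DataFrame(
            rows,
            columns=[
                "step", "critic_loss", "wasserstein", "gradient_penalty",
                "generator_loss", "generator_score", "alignment",
            ],
        )
        return HealthGymGANResults(
            generator=generator,
            critic=critic,
            log=log,
            model=self,
            config=config,
        )


@dataclass
class HealthGymGANResults:
    """Trained generator plus training diagnostics."""

    generator: Generator
    critic: Critic
    log: pd.DataFrame
    model: HealthGymGAN
    config: TrainingConfig

    def sample(self, n_patients: int, seed: int = 0) -> LongitudinalDataset:
        """Generate a synthetic cohort with fresh patient IDs."""
        rng = np.random.default_rng(seed)
        T = self.model.schema.timesteps_per_patient
        values = self.generator.sample_encoded(n_patients, T, rng)
        batch = EncodedBatch(
            values, self.model.channel_map,
            [f"syn_{i:05d}" for i in range(n_patients)],
        )
        batch.validate()
        return decode(batch, self.model.transform_spec, self.model.schema)

    def summary(self) -> str:
        lines = [
            "Health Gym sequence GAN",
            f"  schema:            {self.model.schema.name} "
            f"({len(self.model.schema.variables)} variables, "
            f"{self.model.schema.timesteps_per_patient} timesteps)",
            f"  encoded channels:  {self.model.channel_map.n_channels}",
            f"  training patients: {self.model.real.n_patients}",
            f"  generator steps:   {len(self.log)}",
            f"  lambda_GP:         {self.config.lambda_gp}",
            f"  lambda_corr:       {self.config.lambda_corr}",
        ]
        if len(self.log):
            k = max(1, len(self.log) // 10)
            first = self.log["alignment"].head(k).mean()
            last = self.log["alignment"].tail(k).mean()
            lines += [
                f"  alignment term, first decile of steps: {first:.4f}",
                f"  alignment term, last decile of steps:  {last:.4f}",
                f"  final Wasserstein estimate:            "
                f"{-self.log['wasserstein'].iloc[-1]:.4f}",
            ]
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------
    def save(self, directory) -> None:
        """Write weights + specs so sampling is bit-reproducible."""
        import pathlib

        import yaml

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        gen = self.generator
        arrays = {f"g{i}": p.data for i, p in enumerate(gen.params)}
        arrays.update({f"c{i}": p.data for i, p in enumerate(self.critic.params)})
        np.savez(d / "weights.npz", **arrays)
        doc = {
            "schema": self.model.schema.name,
            "generator_spec": vars(self.model.generator_spec),
            "critic_spec": vars(self.model.critic_spec),
            "config": {k: v for k, v in vars(self.config).items()},
            "transforms": self.model.transform_spec.transforms,
            "skew_threshold": self.model.transform_spec.skew_threshold,
        }
        doc["generator_spec"]["dense_widths"] = list(
            doc["generator_spec"]["dense_widths"]
        )
        doc["critic_spec"]["dense_widths"] = list(doc["critic_spec"]["dense_widths"])
        with open(d / "model.yaml", "w") as fh:
            yaml.safe_dump(doc, fh)

    @staticmethod
    def load(directory, real: LongitudinalDataset) -> "HealthGymGANResults":
        """Rebuild a results object from a model directory and the cohort."""
        import pathlib

        import yaml

        d = pathlib.Path(directory)
        with open(d / "model.yaml") as fh:
            doc = yaml.safe_load(fh)
        gspec = GeneratorSpec(**{**doc["generator_spec"],
                                 "dense_widths": tuple(doc["generator_spec"]["dense_widths"])})
        cspec = CriticSpec(**{**doc["critic_spec"],
                              "dense_widths": tuple(doc["critic_spec"]["dense_widths"])})
        tspec = TransformSpec(doc["transforms"], doc["skew_threshold"])
        model = HealthGymGAN(real, gspec, cspec, tspec)
        cfg = TrainingConfig(**doc["config"])
        rng = np.random.default_rng(0)
        generator = Generator(gspec, model.channel_map, rng)
        critic = Critic(cspec, model.channel_map, rng)
        with np.load(d / "weights.npz") as npz:
            for i, p in enumerate(generator.params):
                p.data = npz[f"g{i}"]
            for i, p in enumerate(critic.params):
                p.data = npz[f"c{i}"]
        return HealthGymGANResults(generator, critic, pd.DataFrame(), model, cfg)
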
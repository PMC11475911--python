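"""Conditional variational autoencoder for platform-effect removal.

The measuring platform (scRNA-seq vs spatial barcoding) is encoded as a
scalar condition appended to both encoder and decoder inputs. After
training on reference cells, pseudo-spots (both under the scRNA-seq
condition) and real ST spots (ST condition), a spot profile is translated
across platforms by encoding it under the ST condition and decoding it
under the scRNA-seq condition.

The model is a compact NumPy implementation: single-hidden-layer (tanh)
encoder and decoder, diagonal-Gaussian posterior, standard-normal prior,
Gaussian unit-variance decoder likelihood (reconstruction term = squared
error), optimized with Adam and seeded reparameterization sampling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingFactors",
    "TrainConfig",
    "CVAEModel",
    "minmax_scale",
    "inverse_minmax",
    "cvae_loss",
    "train_cvae",
    "transform_st",
    "denoise_reference",
]

SCALE_TOP = 10.0  # target of the per-gene min-max rescaling


@dataclass
class ScalingFactors:
    """Per-gene (min, max) recorded for one condition's training data."""

    genes: list[str]
    vmin: np.ndarray
    vmax: np.ndarray

    @classmethod
    def fit(cls, df: pd.DataFrame) -> "ScalingFactors":
        """Fit from a genes x samples matrix."""
        values = df.to_numpy()
        return cls(list(df.index), values.min(axis=1), values.max(axis=1))


def minmax_scale(df: pd.DataFrame, factors: ScalingFactors | None = None):
    """Per-gene min-max rescale of a genes x samples matrix to [0, 10].

    Genes with max == min (degenerate) map to 0. When ``factors`` is None
    they are fitted and returned alongside the scaled matrix.
    """
    fitted = factors is None
    if factors is None:
        factors = ScalingFactors.fit(df)
    elif list(df.index) != factors.genes:
        raise ValueError("gene panel does not match scaling factors")
    span = factors.vmax - factors.vmin
    safe = np.where(span > 0, span, 1.0)
    scaled = (df.sub(factors.vmin, axis=0)).div(safe, axis=0) * SCALE_TOP
    scaled[span == 0] = 0.0
    return (scaled, factors) if fitted else scaled


def inverse_minmax(df: pd.DataFrame, factors: ScalingFactors) -> pd.DataFrame:
    """Invert :func:`minmax_scale`; degenerate genes return their min."""
    if list(df.index) != factors.genes:
        raise ValueError("gene panel does not match scaling factors")
    span = factors.vmax - factors.vmin
    out = df.div(SCALE_TOP).mul(span, axis=0).add(factors.vmin, axis=0)
    out[span == 0] = np.broadcast_to(
        factors.vmin[span == 0][:, None], out[span == 0].shape
    )
    return out


@dataclass
class TrainConfig:
    learning_rate: float = 0.003
    epochs: int = 1000
    batch_size: int = 128
    val_fraction: float = 0.2
    decay_patience: int = 5  # halve the learning rate after this many epochs without val improvement
    stop_patience: int = 10  # stop after this many epochs without val improvement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class CVAEModel:
    """Encoder/decoder pair with latent dimension 3*K.

    Hidden width for both maps is floor(sqrt(input_width * latent_width)).
    Condition codes default to 0 (scRNA-seq) and 10 (ST) appended as one
    scalar input feature.
    """

    def __init__(
        self,
        n_genes: int,
        n_types: int,
        seed: int = 0,
        code_sc: float = 0.0,
        code_st: float = 10.0,
    ):
        self.n_genes = n_genes
        self.n_types = n_types
        self.latent = 3 * n_types
        self.code_sc = code_sc
        self.code_st = code_st
        d_in = n_genes + 1
        self.hidden = max(2, int(np.sqrt(d_in * self.latent)))
        rng = np.random.default_rng(seed)

        def glorot(n_in, n_out):
            lim = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-lim, lim, size=(n_in, n_out))

        h, L = self.hidden, self.latent
        self.params = {
            "W1": glorot(d_in, h), "b1": np.zeros(h),
            "Wm": glorot(h, L), "bm": np.zeros(L),
            "Wv": glorot(h, L), "bv": np.zeros(L),
            "W2": glorot(L + 1, h), "b2": np.zeros(h),
            "W3": glorot(h, n_genes), "b3": np.zeros(n_genes),
        }

    # ---- forward passes -------------------------------------------------
    def encode(self, X: np.ndarray, c: np.ndarray):
        """Posterior parameters (mu, logvar) given data and condition codes."""
        # inputs live on [0, 10]; normalize to unit scale so the tanh
        # hidden layer does not saturate at initialization
        inp = np.hstack([X, c[:, None]]) / SCALE_TOP
        h1 = np.tanh(inp @ self.params["W1"] + self.params["b1"])
        mu = h1 @ self.params["Wm"] + self.params["bm"]
        lv = np.clip(h1 @ self.params["Wv"] + self.params["bv"], -10.0, 10.0)
        return mu, lv

    def decode(self, z: np.ndarray, c: np.ndarray) -> np.ndarray:
        inp = np.hstack([z, c[:, None] / SCALE_TOP])
        h2 = np.tanh(inp @ self.params["W2"] + self.params["b2"])
        return h2 @ self.params["W3"] + self.params["b3"]

    def loss_and_grads(self, X: np.ndarray, c: np.ndarray, rng: np.random.Generator | None):
        """Negative ELBO (KL + 0.5*SSE reconstruction, averaged over the batch)
        and its gradients. ``rng=None`` uses the posterior mean (no sampling)."""
        P = self.params
        B = X.shape[0]
        inp = np.hstack([X, c[:, None]]) / SCALE_TOP
        h1 = np.tanh(inp @ P["W1"] + P["b1"])
        mu = h1 @ P["Wm"] + P["bm"]
        lv = np.clip(h1 @ P["Wv"] + P["bv"], -10.0, 10.0)
        noise = rng.standard_normal(mu.shape) if rng is not None else np.zeros_like(mu)
        std = np.exp(0.5 * lv)
        z = mu + std * noise
        dinp = np.hstack([z, c[:, None] / SCALE_TOP])
        h2 = np.tanh(dinp @ P["W2"] + P["b2"])
        xh = h2 @ P["W3"] + P["b3"]
        if not np.isfinite(xh).all():
            raise FloatingPointError("non-finite activations in CVAE forward pass")
        recon = 0.5 * np.sum((xh - X) ** 2) / B
        kl = 0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv) / B
        loss = recon + kl

        dxh = (xh - X) / B
        g = {}
        g["W3"] = h2.T @ dxh
        g["b3"] = dxh.sum(axis=0)
        dh2 = (dxh @ P["W3"].T) * (1.0 - h2**2)
        g["W2"] = dinp.T @ dh2
        g["b2"] = dh2.sum(axis=0)
        dz = (dh2 @ P["W2"].T)[:, : self.latent]
        dmu = dz + mu / B
        dlv = dz * noise * 0.5 * std + 0.5 * (np.exp(lv) - 1.0) / B
        g["Wm"] = h1.T @ dmu
        g["bm"] = dmu.sum(axis=0)
        g["Wv"] = h1.T @ dlv
        g["bv"] = dlv.sum(axis=0)
        dh1 = (dmu @ P["Wm"].T + dlv @ P["Wv"].T) * (1.0 - h1**2)
        g["W1"] = inp.T @ dh1
        g["b1"] = dh1.sum(axis=0)
        return loss, g

    def loss(self, X: np.ndarray, c: np.ndarray) -> float:
        """Deterministic (posterior-mean) negative ELBO of a batch."""
        return self.loss_and_grads(X, c, rng=None)[0]

    # ---- persistence ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params)
        meta = {
            "n_genes": self.n_genes,
            "n_types": self.n_types,
            "code_sc": self.code_sc,
            "code_st": self.code_st,
        }
        (directory / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "CVAEModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = cls(meta["n_genes"], meta["n_types"],
                    code_sc=meta["code_sc"], code_st=meta["code_st"])
        with np.load(directory / "weights.npz") as data:
            model.params = {k: data[k] for k in data.files}
        return model


def cvae_loss(model: CVAEModel, X: np.ndarray, c: np.ndarray) -> float:
    """Negative ELBO to minimize: KL(q(z|x,c) || N(0,I)) + reconstruction error."""
    return model.loss(X, c)


def kl_diag_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mu, diag(exp(logvar))) || N(0, I) ) = 0.5*sum(var + mu^2 - 1 - logvar)."""
    return 0.5 * float(np.sum(np.exp(logvar) + mu**2 - 1.0 - logvar))


@dataclass
class TrainedCVAE:
    """Trained model plus the per-condition scaling factors and gene panel."""

    model: CVAEModel
    factors_sc: ScalingFactors
    factors_st: ScalingFactors
    genes: list[str]
    config: TrainConfig
    history: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.model.save(directory)
        payload = {
            "genes": self.genes,
            "factors_sc": {"vmin": self.factors_sc.vmin.tolist(),
                           "vmax": self.factors_sc.vmax.tolist()},
            "factors_st": {"vmin": self.factors_st.vmin.tolist(),
                           "vmax": self.factors_st.vmax.tolist()},
            "config": asdict(self.config),
        }
        (directory / "trained.json").write_text(json.dumps(payload))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedCVAE":
        directory = Path(directory)
        payload = json.loads((directory / "trained.json").read_text())
        genes = payload["genes"]
        fs = ScalingFactors(genes, np.array(payload["factors_sc"]["vmin"]),
                            np.array(payload["factors_sc"]["vmax"]))
        ft = ScalingFactors(genes, np.array(payload["factors_st"]["vmin"]),
                            np.array(payload["factors_st"]["vmax"]))
        return cls(CVAEModel.load(directory), fs, ft, genes,
                   TrainConfig(**payload["config"]))


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train_cvae(
    st_scaled: pd.DataFrame,
    ref_scaled: pd.DataFrame,
    pseudo_train_scaled: pd.DataFrame | None,
    pseudo_val_scaled: pd.DataFrame | None,
    factors_sc: ScalingFactors,
    factors_st: ScalingFactors,
    n_types: int,
    config: TrainConfig = TrainConfig(),
) -> TrainedCVAE:
    """Train on ST spots (ST condition), reference cells and pseudo-spots
    (scRNA-seq condition); pseudo-spot hold-outs drive learning-rate decay
    and early stopping.

    All matrices are genes x samples, already min-max scaled with their
    condition's factors and sharing one gene panel. When pseudo-spots are
    withheld (ablation), a random fifth of the reference cells serves as the
    validation set instead.
    """
    genes = list(st_scaled.index)
    for other in (ref_scaled, pseudo_train_scaled, pseudo_val_scaled):
        if other is not None and list(other.index) != genes:
            raise ValueError("gene panel mismatch between CVAE training inputs")
    rng = np.random.default_rng(config.seed)
    model = CVAEModel(len(genes), n_types, seed=config.seed)

    blocks = [(st_scaled.T.to_numpy(), model.code_st),
              (ref_scaled.T.to_numpy(), model.code_sc)]
    if pseudo_train_scaled is not None:
        blocks.append((pseudo_train_scaled.T.to_numpy(), model.code_sc))
        Xval = pseudo_val_scaled.T.to_numpy()
    else:
        refX = ref_scaled.T.to_numpy()
        perm = rng.permutation(refX.shape[0])
        n_val = max(1, refX.shape[0] // 5)
        Xval = refX[perm[:n_val]]
    if Xval.shape[0] == 0:
        raise ValueError("empty validation set")
    cval = np.full(Xval.shape[0], model.code_sc)
    Xtr = np.vstack([b[0] for b in blocks])
    ctr = np.concatenate([np.full(b[0].shape[0], b[1]) for b in blocks])

    adam = _Adam(model.params, config.learning_rate)
    best_loss = model.loss(Xval, cval)
    best_params = {k: v.copy() for k, v in model.params.items()}
    history = {"val_loss": [best_loss], "lr": [config.learning_rate]}
    since_best = 0
    n = Xtr.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            _, grads = model.loss_and_grads(Xtr[idx], ctr[idx], rng)
            adam.step(model.params, grads)
        val = model.loss(Xval, cval)
        history["val_loss"].append(val)
        history["lr"].append(adam.lr)
        if val < best_loss - 1e-9:
            best_loss = val
            best_params = {k: v.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best % config.decay_patience == 0:
                adam.lr *= 0.5
            if since_best >= config.stop_patience:
                logger.info("early stop at epoch %d (val loss %.4f)", epoch, best_loss)
                break
    model.params = best_params
    return TrainedCVAE(model, factors_sc, factors_st, genes, config, history)


def _translate(trained: TrainedCVAE, scaled: pd.DataFrame, code_in: float, code_out: float) -> pd.DataFrame:
    model = trained.model
    X = scaled.T.to_numpy()
    mu, _ = model.encode(X, np.full(X.shape[0], code_in))  # posterior mean, no sampling
    out = model.decode(mu, np.full(X.shape[0], code_out))
    out = np.clip(out, 0.0, SCALE_TOP)
    return pd.DataFrame(out.T, index=scaled.index, columns=scaled.columns)


def transform_st(trained: TrainedCVAE, st_scaled: pd.DataFrame) -> pd.DataFrame:
    """Translate ST spots into the scRNA-seq space.

    Encode under the ST condition, decode under the scRNA-seq condition,
    invert the scRNA-seq min-max scaling, multiply by 10,000, round and
    clamp at zero, yielding a nonnegative-integer count matrix.
    """
    decoded = _translate(trained, st_scaled, trained.model.code_st, trained.model.code_sc)
    expr = inverse_minmax(decoded, trained.factors_sc)
    counts = np.maximum(np.rint(expr.to_numpy() * 10_000.0), 0.0).astype(np.int64)
    return pd.DataFrame(counts, index=st_scaled.index, columns=st_scaled.columns)


def denoise_reference(trained: TrainedCVAE, ref_scaled: pd.DataFrame) -> pd.DataFrame:
    """Encode and decode reference cells under the scRNA-seq condition;
    returns continuous (inverse-scaled) expression for profile averaging."""
    decoded = _translate(trained, ref_scaled, trained.model.code_sc, trained.model.code_sc)
    return inverse_minmax(decoded, trained.factors_sc)
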
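"""Semi-supervised adversarial autoencoders for 2-D latent embedding.

Two model variants embed standardized ``(192, n)`` repetition matrices into a
2-D latent space shaped by a mixture-of-Gaussians prior with one isotropic
mode per activity class:

* ``Res-SSAAE`` — residual convolutional encoder/decoder (3 blocks of 16, 32
  and 64 channels, kernel 5, max-pool 2 between blocks, dense 128, linear 2)
  with a dense discriminator (2 x 512 sigmoid units) acting on latent codes.
* ``Cond-SSAAE`` — the same network with the activity label embedded and
  concatenated to both encoder and decoder inputs; it requires the label at
  inference and acts as a cluster-analysis rather than predictive model.

The semi-supervised mechanism is label-conditioned adversarial
regularization: for each labelled batch item, "real" samples are drawn from
that item's class mode, and the discriminator receives the latent point
together with the one-hot label.  At the adversarial equilibrium each
activity therefore forms one Gaussian cluster at its mode.

Training alternates reconstruction (MSE), discriminator, and generator
updates per batch (Adam, learning rate 1e-4).  After every epoch the KL
divergence between a Gaussian fitted to the validation encodings of each
activity and that activity's prior mode is computed; the weights with the
lowest mean validation KL are kept (early stopping by KL).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .synthio import EXERCISES, child_seed

N_CLASSES = 4
LATENT_DIM = 2


@dataclass
class PriorLayout:
    """Mixture-of-Gaussians prior: one isotropic mode per activity class.

    Modes are equally spaced on a circle of radius ``radius``; every mode
    shares the isotropic standard deviation ``sd``.
    """

    radius: float = 4.0
    sd: float = 1.0
    n_classes: int = N_CLASSES
    class_names: tuple[str, ...] = EXERCISES

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("prior sd must be > 0")

    @property
    def modes(self) -> np.ndarray:
        ang = 2 * np.pi * np.arange(self.n_classes) / self.n_classes
        return self.radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    def mode(self, c: int) -> np.ndarray:
        if not 0 <= c < self.n_classes:
            raise ValueError(f"unknown class {c}")
        return self.modes[c]

    def sample(self, c: int | np.ndarray, count: int | None = None,
               rng: np.random.Generator | None = None,
               seed: int | None = None) -> np.ndarray:
        """Draw latent points from the mode(s) of class ``c``.

        ``c`` may be a scalar class (with ``count`` draws) or an array of
        per-item classes (one draw each).
        """
        rng = rng if rng is not None else np.random.default_rng(seed)
        if np.isscalar(c):
            centers = np.repeat(self.mode(int(c))[None, :], count, axis=0)
        else:
            c = np.asarray(c, dtype=int)
            if c.min() < 0 or c.max() >= self.n_classes:
                raise ValueError("unknown class in label array")
            centers = self.modes[c]
        return centers + self.sd * rng.standard_normal(centers.shape)

    def nearest_mode(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points[:, None, :] - self.modes[None, :, :], axis=2)
        return d.argmin(axis=1)


def sample_prior(layout: PriorLayout, c: int, count: int, seed: int) -> np.ndarray:
    """Seeded draws from class ``c``'s prior mode."""
    return layout.sample(c, count=count, seed=seed)


def kl_to_prior(points: np.ndarray, c: int, layout: PriorLayout,
                reg: float = 1e-9) -> float:
    """KL divergence of a Gaussian fitted to ``points`` from the class prior.

    Fits ``N(m, S)`` by sample mean/covariance and returns the closed-form
    ``KL(N(m, S) || N(mu_c, sd^2 I))`` in nats.  The sample covariance is
    regularized by ``reg * I`` if it is near-singular.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != LATENT_DIM:
        raise ValueError("points must be (N, 2)")
    if len(pts) < 3:
        raise ValueError("kl_to_prior requires at least 3 points")
    mu = layout.mode(c)
    s2 = layout.sd ** 2
    m = pts.mean(axis=0)
    S = np.cov(pts, rowvar=False, bias=False)
    det = np.linalg.det(S)
    if det <= reg:
        S = S + reg * np.eye(LATENT_DIM)
        det = np.linalg.det(S)
    diff = m - mu
    return float(0.5 * (np.trace(S) / s2 + diff @ diff / s2 - LATENT_DIM
                        + np.log(s2 ** LATENT_DIM / det)))


def latent_accuracy(points: np.ndarray, labels: np.ndarray,
                    layout: PriorLayout) -> float:
    """Fraction of points whose nearest prior mode matches the true class."""
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("latent_accuracy requires at least one point")
    return float(np.mean(layout.nearest_mode(points) == np.asarray(labels)))


def _one_hot(y: np.ndarray, n: int = N_CLASSES) -> np.ndarray:
    out = np.zeros((len(y), n))
    out[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return out


class AdversarialAutoencoder(BaseEstimator, TransformerMixin):
    """Res-SSAAE / Cond-SSAAE estimator with a scikit-learn interface.

    Parameters
    ----------
    conditional : bool
        False for Res-SSAAE, True for Cond-SSAAE (label required at
        inference).
    prior_radius, prior_sd : float
        Geometry of the circular mixture-of-Gaussians prior.
    lr : float
        Adam learning rate for all three phases.
    batch_size, max_epochs : int
        Optimization budget; the returned weights are those of the epoch
        with minimum mean validation KL.
    dropout : float
        Dropout rate applied throughout encoder/decoder/discriminator.
    embed_dim : int
        Width of the label embedding (conditional variant only).
    random_state : int
        Seed for initialization, shuffling, dropout and prior draws.

    Attributes
    ----------
    history_ : list of dict
        Per-epoch reconstruction/discriminator/generator losses and
        per-activity validation KL (phase "train" or "fine_tune").
    selected_epoch_ : int
        Epoch whose weights were restored (argmin mean validation KL).
    prior_ : PriorLayout
    """

    def __init__(self, conditional: bool = False, prior_radius: float = 4.0,
                 prior_sd: float = 1.0, lr: float = 1e-4, batch_size: int = 64,
                 max_epochs: int = 300, dropout: float = 0.1,
                 embed_dim: int = 8, disc_warmup_steps: int = 300,
                 n_restarts: int = 1, kl_accept: float = 6.0,
                 random_state: int = 0):
        self.conditional = conditional
        self.prior_radius = prior_radius
        self.prior_sd = prior_sd
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.dropout = dropout
        self.embed_dim = embed_dim
        self.disc_warmup_steps = disc_warmup_steps
        self.n_restarts = n_restarts
        self.kl_accept = kl_accept
        self.random_state = random_state

    # -- network construction --------------------------------------------

    def _build(self, n_channels: int, n_frames: int) -> None:
        rng = np.random.default_rng(self.random_state)
        self.n_channels_ = n_channels
        self.n_frames_ = n_frames
        if n_frames % 8 != 0:
            raise ValueError("input length must be divisible by 2^3")
        c_in = n_channels + (self.embed_dim if self.conditional else 0)
        l3 = n_frames // 8
        dz = LATENT_DIM + (self.embed_dim if self.conditional else 0)
        self._enc = nn.Sequential(
            nn.ResBlock1d(c_in, 16, 5, rng, self.dropout), nn.MaxPool1d(),
            nn.ResBlock1d(16, 32, 5, rng, self.dropout), nn.MaxPool1d(),
            nn.ResBlock1d(32, 64, 5, rng, self.dropout), nn.MaxPool1d(),
            nn.Flatten(),
            nn.Dense(64 * l3, 128, rng), nn.BatchNorm(128), nn.ReLU(),
            nn.Dropout(self.dropout, rng),
            nn.Dense(128, LATENT_DIM, rng, gain="linear"),
        )
        self._dec = nn.Sequential(
            nn.Dense(dz, 128, rng), nn.BatchNorm(128), nn.ReLU(),
            nn.Dropout(self.dropout, rng),
            nn.Dense(128, 64 * l3, rng), nn.BatchNorm(64 * l3), nn.ReLU(),
            nn.Reshape(64, l3),
            nn.Upsample1d(), nn.ResBlock1d(64, 32, 5, rng, self.dropout),
            nn.Upsample1d(), nn.ResBlock1d(32, 16, 5, rng, self.dropout),
            nn.Upsample1d(), nn.ResBlock1d(16, 16, 5, rng, self.dropout),
            nn.Conv1d(16, n_channels, 5, rng, gain="linear"),
        )
        # no batch norm in the discriminator: normalizing mixed real/fake
        # batches makes the critic blind to the global shift the encoder
        # must learn, stalling the adversarial game
        self._disc = nn.Sequential(
            nn.Dense(LATENT_DIM + N_CLASSES, 512, rng, gain="linear"),
            nn.Sigmoid(), nn.Dropout(self.dropout, rng),
            nn.Dense(512, 512, rng, gain="linear"),
            nn.Sigmoid(), nn.Dropout(self.dropout, rng),
            nn.Dense(512, 1, rng, gain="linear"),
        )
        if self.conditional:
            self._embed = nn.Param(rng.normal(0.0, 0.5, size=(N_CLASSES, self.embed_dim)))
        else:
            self._embed = None
        self.prior_ = PriorLayout(radius=self.prior_radius, sd=self.prior_sd)
        self._rng = rng

    def _params_ae(self) -> list[nn.Param]:
        ps = self._enc.params() + self._dec.params()
        if self._embed is not None:
            ps.append(self._embed)
        return ps

    def _params_gen(self) -> list[nn.Param]:
        ps = self._enc.params()
        if self._embed is not None:
            ps.append(self._embed)
        return ps

    # -- forward helpers ---------------------------------------------------

    def _enc_input(self, X: np.ndarray, y: np.ndarray | None) -> np.ndarray:
        # X: (B, C, L)
        if not self.conditional:
            return X
        if y is None:
            raise ValueError("Cond-SSAAE requires the activity label")
        emb = self._embed.value[np.asarray(y, dtype=int)]  # (B, E)
        tiled = np.repeat(emb[:, :, None], X.shape[2], axis=2)
        return np.concatenate([X, tiled], axis=1)

    def _dec_input(self, z: np.ndarray, y: np.ndarray | None) -> np.ndarray:
        if not self.conditional:
            return z
        emb = self._embed.value[np.asarray(y, dtype=int)]
        return np.concatenate([z, emb], axis=1)

    def _embed_backward_enc(self, d_in: np.ndarray, y: np.ndarray) -> None:
        # d_in: (B, C+E, L); accumulate the embedding-channel gradient
        dE = d_in[:, self.n_channels_:, :].sum(axis=2)  # (B, E)
        np.add.at(self._embed.grad, np.asarray(y, dtype=int), dE)

    def _embed_backward_dec(self, d_in: np.ndarray, y: np.ndarray) -> None:
        dE = d_in[:, LATENT_DIM:]
        np.add.at(self._embed.grad, np.asarray(y, dtype=int), dE)

    def _encode_batch(self, X: np.ndarray, y: np.ndarray | None,
                      train: bool) -> np.ndarray:
        return self._enc.forward(self._enc_input(X, y), train)

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
            max_epochs: int | None = None, lr: float | None = None,
            phase: str = "train") -> "AdversarialAutoencoder":
        """Train on standardized matrices ``X`` (R, frames, channels).

        ``X_val``/``y_val`` drive per-epoch KL tracking and weight selection;
        without a validation set the training set itself is used (with a
        warning), which weakens the early-stopping rationale.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if not hasattr(self, "_enc") and phase == "train" and self.n_restarts > 1:
            # adversarial training on small folds occasionally commits a
            # cluster to the wrong mode; retry from derived seeds and keep
            # the run with the best (lowest) validation KL -- the same
            # signal used for epoch selection, so no extra data is touched
            best = None
            for r in range(self.n_restarts):
                params = {**self.get_params(), "n_restarts": 1,
                          "random_state": child_seed(self.random_state, "restart", r)}
                sub = AdversarialAutoencoder(**params)
                sub.fit(X, y, X_val=X_val, y_val=y_val,
                        max_epochs=max_epochs, lr=lr, phase=phase)
                kl = sub.history_[sub.selected_epoch_]["val_kl_mean"]
                if best is None or kl < best[0]:
                    best = (kl, sub)
                if kl <= self.kl_accept:
                    break
            for attr in ("_enc", "_dec", "_disc", "_embed", "prior_", "_rng",
                         "history_", "selected_epoch_", "n_channels_",
                         "n_frames_"):
                setattr(self, attr, getattr(best[1], attr))
            return self
        if not hasattr(self, "_enc"):
            self._build(X.shape[2], X.shape[1])
            self.history_ = []
        if X_val is None:
            warnings.warn("no validation set; using training data for KL selection")
            X_val, y_val = X, y
        Xb = np.ascontiguousarray(X.transpose(0, 2, 1), dtype=nn.DTYPE)  # (B, C, L)
        n_epochs = self.max_epochs if max_epochs is None else max_epochs
        lr_eff = self.lr if lr is None else lr
        opt_ae = nn.Adam(self._params_ae(), lr=lr_eff)
        opt_disc = nn.Adam(self._disc.params(), lr=lr_eff)
        opt_gen = nn.Adam(self._params_gen(), lr=lr_eff)
        rng = self._rng
        track_best = phase == "train"
        best_kl = np.inf
        best_state = None
        best_epoch = -1
        start_epoch = len(self.history_)

        # warm up the discriminator before the first encoder update so its
        # label-conditional decision surface exists from the start; without
        # it, early encoder updates chase an unconditional critic and can
        # commit activity clusters to the wrong prior modes
        if phase == "train" and start_epoch == 0:
            for _ in range(self.disc_warmup_steps):
                idx = rng.integers(0, len(Xb), min(self.batch_size, len(Xb)))
                xb, yb = Xb[idx], y[idx]
                onehot = _one_hot(yb).astype(nn.DTYPE)
                z_fake = self._encode_batch(xb, yb, False)
                z_real = self.prior_.sample(yb, rng=rng).astype(nn.DTYPE)
                d_in = np.concatenate([
                    np.concatenate([z_real, onehot], axis=1),
                    np.concatenate([z_fake, onehot], axis=1),
                ], axis=0)
                targets = np.concatenate([np.ones(len(yb)), np.zeros(len(yb))])
                opt_disc.zero_grad()
                logits = self._disc.forward(d_in, True)
                _, dlog = nn.bce_with_logits(logits, targets)
                self._disc.backward(dlog)
                opt_disc.step()

        for epoch in range(n_epochs):
            order = rng.permutation(len(Xb))
            losses = np.zeros(3)
            n_batches = 0
            for i in range(0, len(order), self.batch_size):
                idx = order[i : i + self.batch_size]
                xb, yb = Xb[idx], y[idx]
                onehot = _one_hot(yb).astype(nn.DTYPE)

                # (1) reconstruction
                opt_ae.zero_grad()
                x_in = self._enc_input(xb, yb)
                z = self._enc.forward(x_in, True)
                xp = self._dec.forward(self._dec_input(z, yb), True)
                l_rec, dxp = nn.mse(xp, xb)
                d_dec_in = self._dec.backward(dxp)
                if self.conditional:
                    self._embed_backward_dec(d_dec_in, yb)
                d_enc_in = self._enc.backward(d_dec_in[:, :LATENT_DIM])
                if self.conditional:
                    self._embed_backward_enc(d_enc_in, yb)
                opt_ae.step()

                # (2) discriminator: prior draws (real) vs encodings (fake)
                opt_disc.zero_grad()
                z_fake = self._encode_batch(xb, yb, True)
                z_real = self.prior_.sample(yb, rng=rng).astype(nn.DTYPE)
                d_in = np.concatenate([
                    np.concatenate([z_real, onehot], axis=1),
                    np.concatenate([z_fake, onehot], axis=1),
                ], axis=0)
                targets = np.concatenate([np.ones(len(yb)), np.zeros(len(yb))])
                logits = self._disc.forward(d_in, True)
                l_disc, dlog = nn.bce_with_logits(logits, targets)
                self._disc.backward(dlog)
                opt_disc.step()

                # (3) generator: encoder updated to fool the discriminator
                opt_gen.zero_grad()
                x_in = self._enc_input(xb, yb)
                z = self._enc.forward(x_in, True)
                logits = self._disc.forward(
                    np.concatenate([z, onehot], axis=1), True)
                l_gen, dlog = nn.bce_with_logits(logits, np.ones(len(yb)))
                d_d_in = self._disc.backward(dlog)
                d_enc_in = self._enc.backward(d_d_in[:, :LATENT_DIM])
                if self.conditional:
                    self._embed_backward_enc(d_enc_in, yb)
                opt_gen.step()

                if not np.isfinite([l_rec, l_disc, l_gen]).all():
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: "
                        f"recon={l_rec} disc={l_disc} gen={l_gen}")
                losses += (l_rec, l_disc, l_gen)
                n_batches += 1

            kl_per_class, kl_mean = self._validation_kl(X_val, y_val)
            rec = {
                "epoch": start_epoch + epoch, "phase": phase,
                "recon_loss": losses[0] / n_batches,
                "disc_loss": losses[1] / n_batches,
                "gen_loss": losses[2] / n_batches,
                "val_kl_per_class": kl_per_class, "val_kl_mean": kl_mean,
            }
            self.history_.append(rec)
            if track_best and kl_mean < best_kl:
                best_kl = kl_mean
                best_epoch = start_epoch + epoch
                best_state = self._get_state()

        if track_best and best_state is not None:
            self._set_state(best_state)
            self.selected_epoch_ = best_epoch
        return self

    def _validation_kl(self, X_val, y_val) -> tuple[dict, float]:
        z = self.transform(X_val, y_val)
        y_val = np.asarray(y_val)
        per_class: dict[str, float] = {}
        vals = []
        for c in range(N_CLASSES):
            pts = z[y_val == c]
            if len(pts) < 3:
                warnings.warn(f"class {EXERCISES[c]} missing from validation; "
                              "excluded from mean KL")
                continue
            k = kl_to_prior(pts, c, self.prior_)
            per_class[EXERCISES[c]] = k
            vals.append(k)
        return per_class, float(np.mean(vals)) if vals else float("inf")

    def fine_tune(self, X: np.ndarray, y: np.ndarray, epochs: int = 10,
                  lr_factor: float = 0.1,
                  X_val: np.ndarray | None = None,
                  y_val: np.ndarray | None = None) -> "AdversarialAutoencoder":
        """Continue training (e.g., on Group B) at a reduced learning rate.

        Runs exactly ``epochs`` epochs of the same alternating loop at
        ``lr * lr_factor``; history entries are flagged ``fine_tune`` and the
        final (not KL-selected) weights are kept.
        """
        if not hasattr(self, "_enc"):
            raise ValueError("fine_tune requires a fitted model")
        if epochs == 0:
            return self
        return self.fit(X, y, X_val=X_val if X_val is not None else X,
                        y_val=y_val if y_val is not None else y,
                        max_epochs=epochs, lr=self.lr * lr_factor,
                        phase="fine_tune")

    # -- inference ----------------------------------------------------------

    def transform(self, X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        """Encode matrices to 2-D latent points (deterministic eval mode)."""
        if not hasattr(self, "_enc"):
            raise ValueError("model is not fitted")
        X = np.ascontiguousarray(np.asarray(X).transpose(0, 2, 1), dtype=nn.DTYPE)
        out = []
        for i in range(0, len(X), 256):
            yb = None if y is None else np.asarray(y)[i : i + 256]
            out.append(self._encode_batch(X[i : i + 256], yb, train=False))
        return np.concatenate(out, axis=0)

    encode = transform

    def reconstruct(self, X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        z = self.transform(X, y)
        xp = self._dec.forward(self._dec_input(z, y), False)
        return xp.transpose(0, 2, 1)

    def reconstruction_error(self, X: np.ndarray, y: np.ndarray | None = None) -> float:
        xp = self.reconstruct(X, y)
        return float(np.mean((xp - np.asarray(X, dtype=float)) ** 2))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Latent-space accuracy (nearest-prior-mode classification)."""
        return latent_accuracy(self.transform(X, y), y, self.prior_)

    # -- persistence --------------------------------------------------------

    def _get_state(self) -> dict:
        state = {"enc": nn.get_state(self._enc), "dec": nn.get_state(self._dec),
                 "disc": nn.get_state(self._disc)}
        if self._embed is not None:
            state["embed"] = [self._embed.value.copy()]
        return state

    def _set_state(self, state: dict) -> None:
        nn.set_state(self._enc, state["enc"])
        nn.set_state(self._dec, state["dec"])
        nn.set_state(self._disc, state["disc"])
        if self._embed is not None:
            self._embed.value[...] = state["embed"][0]

    def save(self, path: str | Path) -> None:
        """Single-file .npz checkpoint with a JSON sidecar for metadata."""
        path = Path(path)
        state = self._get_state()
        arrays = {}
        for part, arrs in state.items():
            for i, a in enumerate(arrs):
                arrays[f"{part}__{i}"] = a
        np.savez(path, **arrays)
        meta = {
            "params": self.get_params(),
            "n_channels": self.n_channels_, "n_frames": self.n_frames_,
            "history": self.history_,
            "selected_epoch": getattr(self, "selected_epoch_", None),
            "stats_provenance": getattr(self, "stats_provenance_", None),
            "val_accuracy_pre_ft": getattr(self, "val_accuracy_pre_ft_", None),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AdversarialAutoencoder":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        model = cls(**meta["params"])
        model._build(meta["n_channels"], meta["n_frames"])
        data = np.load(path)
        state: dict[str, list] = {}
        for key in data.files:
            part, i = key.split("__")
            state.setdefault(part, []).append((int(i), data[key]))
        state = {p: [a for _, a in sorted(v)] for p, v in state.items()}
        model._set_state(state)
        model.history_ = meta["history"]
        if meta["selected_epoch"] is not None:
            model.selected_epoch_ = meta["selected_epoch"]
        model.stats_provenance_ = meta.get("stats_provenance")
        if meta.get("val_accuracy_pre_ft") is not None:
            model.val_accuracy_pre_ft_ = meta["val_accuracy_pre_ft"]
        return model


def train(X_train: np.ndarray, y_train: np.ndarray, X_val: np.ndarray,
          y_val: np.ndarray, conditional: bool = False,
          **params) -> AdversarialAutoencoder:
    """Thin functional wrapper over :class:`AdversarialAutoencoder.fit`."""
    model = AdversarialAutoencoder(conditional=conditional, **params)
    return model.fit(X_train, y_train, X_val=X_val, y_val=y_val)


def fine_tune(model: AdversarialAutoencoder, X: np.ndarray, y: np.ndarray,
              epochs: int = 10, **kw) -> AdversarialAutoencoder:
    return model.fine_tune(X, y, epochs=epochs, **kw)


def encode(model: AdversarialAutoencoder, X: np.ndarray,
           y: np.ndarray | None = None) -> np.ndarray:
    return model.transform(X, y)
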
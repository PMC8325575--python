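"""CasRedSCAN: alternating de-aliasing network and data-fidelity layers.

The cascade unrolls Z blocks.  Block k applies the RedSCAN backbone to the
current image estimate and then the projection data fidelity layer, which
re-projects the prediction onto the full view grid, fuses it row-wise with
the acquired sinogram, and filtered back-projects.  All backbones share
one set of weights by default, so the cascade's parameter count equals the
single network's regardless of depth.  Training minimizes the L2 loss
between the final cascade output and the full-view reconstruction ground
truth with Adam (first-moment decay 0.99, learning rate 5e-4, batch 4).

Network conditioning: images enter the backbone linearly rescaled to
[0, 1] over a configured HU window; the tomographic layers operate on
attenuation, and metrics are computed after mapping back to HU.  The
fidelity layers use the surrogate derivatives the method prescribes (FBP
as the derivative of projection and vice versa), wired in through the
autodiff custom-op hook.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .errors import ContractError
from .fbp import fbp_reconstruct_batch
from .geometry import FanGeometry, Image, hu_to_mu
from .metrics import DEFAULT_HU_WINDOW, evaluate, image_metrics  # noqa: F401
from .pdfl import FidelityParams, ViewMask
from .projector import FanSinogram, forward_project_batch
from .redscan import RedSCAN, RedSCANConfig, build_redscan


@dataclass
class CascadeConfig:
    """Depth, weight sharing, fidelity and backbone settings."""

    z_blocks: int = 4
    share_weights: bool = True
    fidelity: FidelityParams = field(default_factory=FidelityParams)
    backbone: RedSCANConfig = field(default_factory=RedSCANConfig)
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW

    def __post_init__(self) -> None:
        if self.z_blocks < 1:
            raise ContractError("cascade depth must be >= 1")


@dataclass
class TrainConfig:
    """Optimization settings.

    ``adam_momentum`` is the first-moment decay (beta1); the second moment
    uses the conventional 0.999.
    """

    learning_rate: float = 5e-4
    adam_momentum: float = 0.99
    batch_size: int = 4
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ContractError("training settings must be positive")


# ---------------------------------------------------------------------------
# tomographic autodiff ops with prescribed surrogate derivatives

def _fp_op(x: Tensor, geometry: FanGeometry) -> Tensor:
    """Forward projection (N,1,H,W) -> (N,M,bins); backward is FBP."""
    out = forward_project_batch(x.data[:, 0], geometry)

    def bw(g):
        return (fbp_reconstruct_batch(g, geometry)[:, None],)

    return ad.custom_op(out, (x,), bw)


def _fbp_op(s: Tensor, geometry: FanGeometry) -> Tensor:
    """FBP (N,M,bins) -> (N,1,H,W); backward is forward projection."""
    out = fbp_reconstruct_batch(s.data, geometry)[:, None]

    def bw(g):
        return (forward_project_batch(g[:, 0], geometry),)

    return ad.custom_op(out, (s,), bw)


def _fuse_op(
    s_cnn: Tensor, s_u: np.ndarray, mask: ViewMask, lam: float
) -> Tensor:
    """Row-wise sinogram fusion; backward scales acquired rows by e_i."""
    ind = mask.indicator()
    out = s_cnn.data.copy()
    out[:, ind] = (lam * s_cnn.data[:, ind] + s_u[:, ind]) / (lam + 1.0)
    e = mask.row_weights(lam)[None, :, None]

    def bw(g):
        return (g * e,)

    return ad.custom_op(out, (s_cnn,), bw)


class CasRedSCAN:
    """The unrolled cascade, operating on batches in scaled image units."""

    def __init__(self, config: CascadeConfig | None = None):
        self.config = config or CascadeConfig()
        if self.config.share_weights:
            net = build_redscan(self.config.backbone)
            self.nets = [net] * self.config.z_blocks
        else:
            self.nets = [
                build_redscan(self.config.backbone)
                for _ in range(self.config.z_blocks)
            ]
        lo, hi = self.config.hu_window
        self._mu_lo = float(hu_to_mu(lo))
        self._mu_scale = float(hu_to_mu(hi) - hu_to_mu(lo))

    # -- unit conversions --------------------------------------------------
    def scale_mu(self, mu: np.ndarray) -> np.ndarray:
        return (np.asarray(mu, float) - self._mu_lo) / self._mu_scale

    def unscale_mu(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float) * self._mu_scale + self._mu_lo

    def parameters(self):
        seen, out = set(), []
        for net in self.nets:
            for p in net.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward -----------------------------------------------------------
    def forward(
        self,
        i_u_scaled: Tensor,
        s_u: np.ndarray,
        mask: ViewMask,
        geometry: FanGeometry,
    ) -> tuple[Tensor, list[np.ndarray], list[np.ndarray]]:
        """Run the cascade; returns (x_Z, intermediate images, fused sinograms)."""
        lam = self.config.fidelity.lam
        x = i_u_scaled
        images, sinos = [], []
        for net in self.nets:
            y = net(x)                                   # de-aliasing step
            mu = ad.shift(ad.scale(y, self._mu_scale), self._mu_lo)
            s_cnn = _fp_op(mu, geometry)
            s_rec = _fuse_op(s_cnn, s_u, mask, lam)      # data fidelity
            mu_out = _fbp_op(s_rec, geometry)
            x = ad.scale(ad.shift(mu_out, -self._mu_lo), 1.0 / self._mu_scale)
            images.append(x.data[:, 0].copy())
            sinos.append(s_rec.data.copy())
        return x, images, sinos

    def reconstruct(
        self, i_u: Image, s_u: FanSinogram, mask: ViewMask
    ) -> tuple[Image, list[np.ndarray], list[np.ndarray]]:
        """Inference on one scan; input and output are attenuation images."""
        geometry = s_u.geometry
        x0 = Tensor(self.scale_mu(i_u.values)[None, None])
        xz, images, sinos = self.forward(
            x0, s_u.values[None], mask, geometry
        )
        return Image(self.unscale_mu(xz.data[0, 0])), images, sinos


def casredscan_forward(
    i_u: Image,
    s_u: FanSinogram,
    mask: ViewMask,
    config: CascadeConfig | None = None,
    model: CasRedSCAN | None = None,
):
    """Functional cascade forward pass.

    Returns the final image plus the per-block intermediate images and
    fused sinograms (for sinogram-evolution analysis).
    """
    model = model or CasRedSCAN(config)
    return model.reconstruct(i_u, s_u, mask)


def train_cascade(
    dataset,
    train_config: TrainConfig,
    cascade_config: CascadeConfig,
    model: CasRedSCAN | None = None,
) -> tuple[CasRedSCAN, list[dict]]:
    """Fit the cascade to (i_u, s_u, mask, i_gt) samples with Adam.

    Deterministic for fixed seeds.  Returns the trained model and a log of
    per-epoch mean training loss (scaled-image MSE).
    """
    dataset = list(dataset)
    if not dataset:
        raise ContractError("training dataset is empty")
    model = model or CasRedSCAN(cascade_config)
    geometry = dataset[0].s_u.geometry
    i_u = np.stack([model.scale_mu(s.i_u.values) for s in dataset])
    i_gt = np.stack([model.scale_mu(s.i_gt.values) for s in dataset])
    s_u = np.stack([s.s_u.values for s in dataset])
    mask = dataset[0].mask

    opt = Adam(
        model.parameters(),
        lr=train_config.learning_rate,
        beta1=train_config.adam_momentum,
    )
    rng = np.random.default_rng(train_config.seed)
    log: list[dict] = []
    step = 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(dataset), train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            x0 = Tensor(i_u[idx][:, None])
            out, _, _ = model.forward(x0, s_u[idx], mask, geometry)
            loss = ad.mse_loss(out, i_gt[idx][:, None])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step}: "
                    f"{loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
        log.append({"epoch": epoch, "loss": float(np.mean(losses)), "steps": step})
    return model, log


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(path, model: CasRedSCAN) -> None:
    import json
    from dataclasses import asdict

    cfg = asdict(model.config)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> CasRedSCAN:
    import json

    with np.load(path, allow_pickle=False) as f:
        cfg = json.loads(str(f["config"]))
        cfg["fidelity"] = FidelityParams(**cfg["fidelity"])
        cfg["backbone"] = RedSCANConfig(**cfg["backbone"])
        cfg["hu_window"] = tuple(cfg["hu_window"])
        model = CasRedSCAN(CascadeConfig(**cfg))
        arrays = [f[f"param_{i}"] for i in range(len(model.parameters()))]
    for p, a in zip(model.parameters(), arrays):
        if p.data.shape != a.shape:
            raise ContractError("checkpoint parameter shape mismatch")
        p.data[...] = a
    return model
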
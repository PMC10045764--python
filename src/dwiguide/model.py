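"""Model/Results interface over the guided denoiser.

:class:`GuidedDenoiser` bundles a dataset with network, loss, and schedule
configurations; ``fit()`` runs patch-based training and returns a
:class:`DenoiserResults` carrying the trained network, the loss history,
denoising and evaluation methods, and a text ``summary()``.

Typical use::

    from dwiguide import phantom, model

    pairs = phantom.make_dataset(phantom.PhantomSpec(seed=1), n_subjects=6, seed=1)
    m = model.GuidedDenoiser.from_pairs(pairs, n_val=2)
    res = m.fit()
    print(res.summary())
    out = res.denoise_series(pairs[0][0], nex=1)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import nn as _nn
from . import training as _training
from .containers import DWISeries
from .nn import NetConfig, ResidualDenoiser
from .pipeline import normalize_for_inference, normalize_series
from .training import LossConfig, SplitDataset, TrainConfig, TrainHistory

__all__ = ["GuidedDenoiser", "DenoiserResults", "lambda_sweep"]


class GuidedDenoiser:
    """Guided residual-CNN denoising model for high b-value DWI.

    Parameters
    ----------
    dataset
        :class:`~dwiguide.training.SplitDataset` of normalized
        (series, ground-truth) pairs.
    net_config, loss_config, train_config
        Architecture, loss, and schedule; defaults are the desk-scale network
        with the joint L1-L2 loss at lambda = 4.
    """

    def __init__(
        self,
        dataset: SplitDataset,
        net_config: NetConfig | None = None,
        loss_config: LossConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.dataset = dataset
        self.net_config = net_config or NetConfig()
        self.loss_config = loss_config or LossConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_pairs(cls, pairs, n_val: int, **kwargs) -> "GuidedDenoiser":
        """Build from raw (series, ground-truth) pairs; normalizes and splits."""
        return cls(_training.prepare_dataset(pairs, n_val), **kwargs)

    def fit(self, log=None) -> "DenoiserResults":
        net, history = _training.train(
            self.dataset, self.net_config, self.loss_config, self.train_config, log=log
        )
        return DenoiserResults(self, net, history)


class DenoiserResults:
    """Fitted denoiser: trained network + training history + evaluation."""

    def __init__(self, model: GuidedDenoiser, network: ResidualDenoiser, history: TrainHistory):
        self.model = model
        self.network = network
        self.history = history

    # -- inference -------------------------------------------------------

    def denoise(self, noisy: np.ndarray, guide: np.ndarray, normalized: bool = True) -> _nn.DenoisedResult:
        """Denoise a volume (or slice); inputs in normalized units by default.

        With ``normalized=False`` the pair is normalized by its own maxima
        (deployment convention, no reference available) and the output is
        rescaled back to input units.
        """
        if not normalized:
            noisy_n, guide_n, sn, _sg = normalize_for_inference(noisy, guide)
            res = _nn.denoise(self.network, noisy_n, guide_n, scale=sn)
            return _nn.DenoisedResult(
                denoised=res.denoised * sn,
                residual=res.residual * sn,
                denoised_raw=res.denoised_raw * sn,
                scale=sn,
            )
        return _nn.denoise(self.network, noisy, guide)

    def denoise_series(self, series: DWISeries, nex: int) -> _nn.DenoisedResult:
        """Denoise one NEX level of a normalized series."""
        return self.denoise(series.noisy[nex], series.guide)

    # -- evaluation ------------------------------------------------------

    def evaluate(self, pairs, nex_levels=(1, 2, 4), roi_dilation: int = 3, normalized: bool = False):
        """Score noisy vs denoised against the reference on held-out subjects.

        Returns a list of :class:`~dwiguide.metrics.QualityReport`, one per
        subject, using each phantom's rectal mask dilated by ``roi_dilation``
        pixels as the region of interest.
        """
        reports = []
        for series, gt in pairs:
            s = series if normalized else normalize_series(series)
            den = {n: self.denoise_series(s, n).denoised for n in nex_levels}
            roi = _metrics.dilate_mask(gt.roi_mask, roi_dilation)
            reports.append(_metrics.evaluate_series(s, den, roi, nex_levels=nex_levels))
        return reports

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "Guided DWI Denoiser Results",
            "=" * 44,
            f"architecture      depth {m.net_config.depth}, width {m.net_config.width}, "
            f"kernel {m.net_config.kernel}x{m.net_config.kernel}",
            f"conv weights      {self.network.count_conv_weights():,}",
            f"total parameters  {self.network.count_parameters():,}",
            f"loss              {m.loss_config.mode}"
            + (f" (lambda = {m.loss_config.lambda_l1:g})" if m.loss_config.mode == "joint" else ""),
            f"schedule          {m.train_config.epochs} epochs, batch {m.train_config.batch_size}, "
            f"Adam lr {m.train_config.learning_rate:g}",
            f"training subjects {len(m.dataset.train)}  validation subjects {len(m.dataset.val)}",
            "-" * 44,
        ]
        for e, l in self.history.train_loss:
            entry = f"epoch {e:3d}  train loss {l:10.5f}"
            vl = dict(self.history.val_loss).get(e)
            if vl is not None:
                entry += f"   val loss {vl:10.5f}"
            lines.append(entry)
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss curves (training per epoch, validation at its period)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        te, tl = zip(*self.history.train_loss)
        ax.plot(te, tl, label="train")
        if self.history.val_loss:
            ve, vl = zip(*self.history.val_loss)
            ax.plot(ve, vl, "o-", label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss (per patch)")
        ax.legend()
        return ax

    def save(self, path) -> None:
        _nn.save_checkpoint(
            path,
            self.network,
            extra={
                "loss": {"mode": self.model.loss_config.mode, "lambda_l1": self.model.loss_config.lambda_l1},
                "train": self.model.train_config.to_dict(),
            },
        )


def lambda_sweep(
    dataset: SplitDataset,
    net_config: NetConfig,
    train_config: TrainConfig,
    lambdas,
    eval_pairs=None,
    eval_nex: int = 1,
) -> pd.DataFrame:
    """Train one joint-loss network per lambda with shared seeds and data.

    Returns a table with one row per lambda: final validation loss and
    held-out global/ROI PSNR and SSIM of denoised NEX=``eval_nex`` volumes.
    Selection among the rows is left to the user (in the source study a
    radiologist chose lambda = 4).
    """
    lambdas = list(lambdas)
    if len(lambdas) < 2:
        raise ValueError("lambda_sweep needs >= 2 lambda values")
    eval_pairs = eval_pairs if eval_pairs is not None else dataset.val
    rows = []
    for lam in lambdas:
        mode = "l2_only" if lam == 0 else "joint"
        model = GuidedDenoiser(dataset, net_config, LossConfig(mode=mode, lambda_l1=float(lam)), train_config)
        res = model.fit()
        reports = res.evaluate(eval_pairs, nex_levels=(eval_nex,), normalized=True)
        agg = pd.concat([r.table for r in reports])
        den = agg[agg["image"] == "denoised"]
        rows.append(
            {
                "lambda": lam,
                "val_loss": res.history.final_val_loss,
                "psnr_global": den["psnr_global"].mean(),
                "ssim_global": den["ssim_global"].mean(),
                "psnr_roi": den["psnr_roi"].mean(),
                "ssim_roi": den["ssim_roi"].mean(),
            }
        )
    return pd.DataFrame(rows)
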
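"""Artifact rejection.

Cleaning rules: channels with extensive ±100 μV excursions or low
correlation with their spatial neighbors are flagged and interpolated;
independent components correlated with a frontal ocular proxy are
subtracted; epochs with any sample beyond ±100 μV or more than 7 per-channel
SDs from the per-channel mean are rejected. Stage order is
bad-electrode detection → blink ICA → epoch rejection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import EpochedEEG

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleaningConfig:
    amp_limit: float = 100.0          # μV
    epoch_sd_limit: float = 7.0       # SD multiples
    # permissive: single-trial EEG is noise-dominated, so even healthy
    # channels correlate only weakly with their neighbor average; the
    # criterion is meant to catch channels that share *nothing*
    neighbor_sim_threshold: float = 0.05
    max_blink_components: int = 2
    bad_sample_fraction: float = 0.05  # "extensive" out-of-range samples
    n_neighbors: int = 4
    ocular_corr_cutoff: float = 0.7
    ica_seed: int = 97

    def validate(self) -> None:
        if self.amp_limit <= 0 or self.epoch_sd_limit <= 0:
            raise ValueError("amp_limit and epoch_sd_limit must be positive")


@dataclass
class CleaningReport:
    bad_channels: set[str] = field(default_factory=set)
    rejected_epochs: dict[str, list[int]] = field(default_factory=dict)
    removed_components: int = 0
    fraction_retained: float = 1.0


class UnusableRecordingError(RuntimeError):
    """Every channel or every epoch failed the artifact criteria."""


def detect_bad_electrodes(raw: EpochedEEG, cfg: CleaningConfig | None = None
                          ) -> set[str]:
    """Channels with extensive out-of-range samples or low neighbor similarity.

    A channel is flagged when more than ``bad_sample_fraction`` of its samples
    (pooled over epochs) exceed ±``amp_limit``, or when its correlation with
    the mean of its ``n_neighbors`` nearest channels falls below
    ``neighbor_sim_threshold``. Flagging every channel raises
    :class:`UnusableRecordingError`.
    """
    cfg = cfg or CleaningConfig()
    cfg.validate()
    if raw.n_channels < 4:
        raise ValueError("need at least 4 channels for neighbor statistics")

    flat = raw.data.transpose(1, 0, 2).reshape(raw.n_channels, -1)
    bad: set[str] = set()

    frac_out = np.mean(np.abs(flat) > cfg.amp_limit, axis=1)
    for i in np.nonzero(frac_out > cfg.bad_sample_fraction)[0]:
        bad.add(raw.ch_names[i])

    neigh = raw.montage.neighbors(cfg.n_neighbors)
    centered = flat - flat.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    for i, name in enumerate(raw.ch_names):
        idx = [raw.montage.index(n) for n in neigh[name]]
        ref = centered[idx].mean(axis=0)
        denom = sd[i] * ref.std()
        if denom == 0:  # constant channels carry no dissimilarity evidence
            continue
        r = float(centered[i] @ ref / (flat.shape[1] * denom))
        if r < cfg.neighbor_sim_threshold:
            bad.add(name)

    if len(bad) == raw.n_channels:
        raise UnusableRecordingError("all channels flagged as bad")
    return bad


def interpolate_channels(raw: EpochedEEG, bad: set[str],
                         n_neighbors: int = 4) -> EpochedEEG:
    """Replace flagged channels by the inverse-distance-weighted mean of
    their nearest good neighbors."""
    if not bad:
        return raw
    out = raw.copy()
    good = [i for i, n in enumerate(raw.ch_names) if n not in bad]
    if not good:
        raise UnusableRecordingError("no good channels left to interpolate from")
    pos = raw.montage.positions
    for name in bad:
        i = raw.montage.index(name)
        d = np.linalg.norm(pos[good] - pos[i], axis=1)
        order = np.argsort(d)[:n_neighbors]
        w = 1.0 / np.maximum(d[order], 1e-6)
        w /= w.sum()
        src = [good[j] for j in order]
        out.data[:, i, :] = np.einsum("j,ejt->et", w, raw.data[:, src, :])
    return out


def reject_noisy_epochs(epochs: EpochedEEG, cfg: CleaningConfig | None = None
                        ) -> tuple[EpochedEEG, dict[str, list[int]]]:
    """Drop epochs with absolute or statistical amplitude outliers.

    An epoch is removed iff any sample exceeds ±``amp_limit`` or deviates
    more than ``epoch_sd_limit`` per-channel SDs from the per-channel mean,
    with mean/SD pooled over all epochs of the same condition (an epoch is
    judged on its worst channel). Returns the surviving epochs and the
    rejected indices per condition (indices into the input epoch order).
    """
    cfg = cfg or CleaningConfig()
    cfg.validate()
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to screen")

    keep = np.ones(epochs.n_epochs, dtype=bool)
    rejected: dict[str, list[int]] = {}
    for cond in np.unique(epochs.conditions):
        idx = np.nonzero(epochs.conditions == cond)[0]
        x = epochs.data[idx]  # (k, ch, t)
        mu = x.mean(axis=(0, 2), keepdims=True)
        sd = x.std(axis=(0, 2), keepdims=True)
        hard = np.abs(x) > cfg.amp_limit
        with np.errstate(invalid="ignore"):
            soft = np.abs(x - mu) > cfg.epoch_sd_limit * sd
        viol = (hard | (soft & (sd > 0))).any(axis=(1, 2))
        out = idx[viol]
        if out.size:
            rejected[str(cond)] = out.tolist()
            keep[out] = False

    if not keep.any():
        raise UnusableRecordingError("all epochs rejected")
    logger.info("epoch rejection: kept %d/%d", int(keep.sum()), epochs.n_epochs)
    return epochs.subset(np.nonzero(keep)[0]), rejected


def remove_blink_components(epochs: EpochedEEG, cfg: CleaningConfig | None = None
                            ) -> tuple[EpochedEEG, int]:
    """Subtract independent components that track a frontal ocular proxy.

    Concatenated epochs are decomposed with FastICA; components whose time
    course correlates (|r| > ``ocular_corr_cutoff``) with the mean of the two
    most anterior channels are zeroed (strongest correlations first, at most
    ``max_blink_components``) and the data reconstructed. On decomposition
    failure the input is passed through unchanged with a logged warning.
    Returns (cleaned epochs, number of removed components).
    """
    cfg = cfg or CleaningConfig()
    if cfg.max_blink_components == 0:
        return epochs, 0
    if epochs.n_channels < 8 or epochs.n_epochs < 30:
        raise ValueError("need ≥ 8 channels and ≥ 30 epochs for a stable unmixing")

    x = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)  # ch × t
    frontal = [epochs.montage.index(n) for n in epochs.montage.most_anterior(2)]
    proxy = x[frontal].mean(axis=0)
    proxy = proxy - proxy.mean()
    if proxy.std() == 0:
        return epochs, 0

    n_comp = min(epochs.n_channels, 20)
    try:
        with warnings.catch_warnings():
            # an unconverged unmixing is still usable for blink rejection
            warnings.simplefilter("ignore", ConvergenceWarning)
            ica = FastICA(
                n_components=n_comp, random_state=cfg.ica_seed, max_iter=500
            )
            sources = ica.fit_transform(x.T).T  # (n_comp, samples)
    except Exception as exc:  # pragma: no cover - rare numerical failure
        logger.warning("ICA decomposition failed (%s); passing data through", exc)
        return epochs, 0

    r = np.array(
        [
            abs(np.corrcoef(s, proxy)[0, 1]) if s.std() > 0 else 0.0
            for s in sources
        ]
    )
    order = np.argsort(-r)
    blink = [k for k in order[: cfg.max_blink_components] if r[k] > cfg.ocular_corr_cutoff]
    if not blink:
        return epochs, 0

    contribution = ica.mixing_[:, blink] @ sources[blink]  # ch × samples
    cleaned = x - contribution
    out = epochs.copy()
    out.data = cleaned.reshape(
        epochs.n_channels, epochs.n_epochs, epochs.n_times
    ).transpose(1, 0, 2)
    logger.info("blink ICA: removed %d component(s)", len(blink))
    return out, len(blink)


def clean_epochs(raw: EpochedEEG, cfg: CleaningConfig | None = None
                 ) -> tuple[EpochedEEG, CleaningReport]:
    """Full cleaning chain: bad electrodes → blink ICA → epoch rejection."""
    cfg = cfg or CleaningConfig()
    report = CleaningReport()
    report.bad_channels = detect_bad_electrodes(raw, cfg)
    data = interpolate_channels(raw, report.bad_channels)
    try:
        data, report.removed_components = remove_blink_components(data, cfg)
    except ValueError:
        logger.info("skipping blink ICA (too few channels/epochs)")
    data, report.rejected_epochs = reject_noisy_epochs(data, cfg)
    report.fraction_retained = data.n_epochs / raw.n_epochs
    return data, report
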
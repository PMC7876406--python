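"""Trial-to-trial ERP variability (ERPv) and neural consistency.

ERPv is the trial-by-trial standard error of the amplitude at every
post-stimulus time point and electrode, averaged over all of them — one
scalar per subject × condition. Low ERPv means the single-trial responses
to the same stimulus are consistent; high ERPv means the neural response is
perturbed. Neural consistency is 1 − normalized ERPv.

The raw score is in μV and depends on signal scale; the normalized variant
divides by the RMS of the condition-average post-stimulus ERP, giving a
dimensionless score on roughly the 0–1 scale. ERPv is computed on broadband
cleaned epochs, outside the band-filtered STEP flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochedEEG


@dataclass
class ERPvScore:
    subject: str
    visit: int | None
    condition: str
    raw_erpv: float          # μV
    normalized_erpv: float | None
    n_trials_used: int
    window_ms: tuple[float, float]


def compute_erpv(
    epochs: EpochedEEG,
    condition: str,
    normalize: bool = True,
    valid_mask: np.ndarray | None = None,
) -> ERPvScore:
    """Mean trial-by-trial standard error over post-stimulus samples.

    ``valid_mask`` restricts the computation to valid trials of the
    condition (correct responses surviving artifact rejection); by default
    all epochs of the condition are used. SE uses the n−1 sample SD.
    """
    sel = epochs.select(condition)
    if valid_mask is not None:
        sel = sel.subset(np.nonzero(np.asarray(valid_mask))[0])
    n = sel.n_epochs
    if n < 2:
        raise ValueError(f"need ≥ 2 valid trials for {condition!r}, got {n}")

    post = sel.times_ms >= 0
    if not post.any():
        raise ValueError("epochs contain no post-stimulus samples")
    x = sel.data[:, :, post]  # (trials, ch, t_post)
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    raw = float(se.mean())

    normalized = None
    if normalize:
        rms = float(np.sqrt((x.mean(axis=0) ** 2).mean()))
        if rms == 0:
            raise ValueError("zero-RMS average ERP; cannot normalize")
        normalized = raw / rms

    return ERPvScore(
        subject=str(epochs.meta.get("subject", "")),
        visit=epochs.meta.get("visit"),
        condition=condition,
        raw_erpv=raw,
        normalized_erpv=normalized,
        n_trials_used=n,
        window_ms=(0.0, float(sel.times_ms[-1]) + 1000.0 / sel.sfreq),
    )


def neural_consistency(score: ERPvScore) -> float:
    """1 − normalized ERPv: higher means a more reproducible response."""
    if score.normalized_erpv is None:
        raise ValueError("neural consistency requires the normalized score")
    return 1.0 - score.normalized_erpv


def erpv_valid_mask(epochs: EpochedEEG, condition: str,
                    behavior: "pd.DataFrame | None" = None) -> np.ndarray:
    """Validity mask for the epochs of one condition.

    Valid = correct response (for response conditions), correct inhibition
    (NoGo), or simply artifact-free (Frequent/Novel, which require none).
    ``behavior`` rows must align with the epoch order of the recording.
    """
    sel = epochs.conditions == condition
    if behavior is None:
        return np.ones(int(sel.sum()), dtype=bool)
    rows = behavior.loc[np.asarray(sel), "correct"]
    return np.array([bool(c) if c is not None else True for c in rows])
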
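"""Formats, configuration and fixtures.

EEG interchange uses EDF (European Data Format): reading goes through mne's
EDF reader; writing uses the small EDF+ writer below (16-bit samples, one
data record per second). Events and behavior travel as UTF-8 tab-separated
tables with a header row. The full study configuration round-trips through
YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bna import BandSpec, BNAConfig, ClusterConfig, DEFAULT_BANDS, MainSTEP, \
    ReferenceEntry, ReferenceGroup
from .containers import EpochedEEG
from .montage import ChannelGeometry, standard_montage
from .preprocess import CleaningConfig
from .synth import TaskSpec, aob_task, gng_task

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["onset_ms", "condition", "tone_hz"]
BEHAVIOR_COLUMNS = ["trial", "condition", "responded", "correct", "rt_ms"]


# ---------------------------------------------------------------------------
# EDF writing / epoch loading
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    return text[:width].ljust(width).encode("ascii")


def write_edf(
    path: "Path | str",
    data: np.ndarray,
    sfreq: float,
    ch_names: "list[str] | tuple[str, ...]",
    physical_dim: str = "uV",
) -> None:
    """Write a continuous multichannel recording as EDF.

    ``data`` is ``(n_channels, n_samples)`` in μV. Samples are quantized to
    16 bits over a symmetric physical range covering the data; the recording
    is padded with zeros to a whole number of 1-second records.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    spr = int(round(sfreq))  # samples per 1 s record
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    phys_max = max(1.0, float(np.abs(padded).max()) * 1.0001)
    dig_max = 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(padded * scale), -dig_max, dig_max).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    sig = b"".join(_pad(n, 16) for n in ch_names)
    sig += b"".join(_pad("", 80) for _ in range(n_ch))
    sig += b"".join(_pad(physical_dim, 8) for _ in range(n_ch))
    sig += b"".join(_pad(f"{-phys_max:.6g}"[:8], 8) for _ in range(n_ch))
    sig += b"".join(_pad(f"{phys_max:.6g}"[:8], 8) for _ in range(n_ch))
    sig += b"".join(_pad(str(-dig_max), 8) for _ in range(n_ch))
    sig += b"".join(_pad(str(dig_max), 8) for _ in range(n_ch))
    sig += b"".join(_pad("", 80) for _ in range(n_ch))
    sig += b"".join(_pad(str(spr), 8) for _ in range(n_ch))
    sig += b"".join(_pad("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: "Path | str") -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF recording; returns (μV data, sfreq, channel names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def load_epochs(
    edf_path: "Path | str",
    events_tsv: "Path | str",
    window_ms: tuple[float, float],
    montage: ChannelGeometry | None = None,
) -> EpochedEEG:
    """Cut epochs from an EDF recording at the event onsets.

    The half-open window ``[pre, post)`` is sampled at the recording rate
    with the onset mapping to t = 0 ms. Events whose window runs past the
    end of the recording are skipped with a warning; an empty event table is
    an error.
    """
    data, sfreq, ch_names = read_edf(edf_path)
    events = pd.read_csv(events_tsv, sep="\t")
    if events.empty:
        raise ValueError(f"no events in {events_tsv}")
    if montage is None:
        montage = standard_montage(len(ch_names))

    pre, post = window_ms
    n_times = int(round((post - pre) * sfreq / 1000.0))
    epochs, conditions = [], []
    for _, ev in events.iterrows():
        start = int(round((ev["onset_ms"] + pre) * sfreq / 1000.0))
        if start < 0 or start + n_times > data.shape[1]:
            logger.warning("event at %.0f ms outside recording; skipped",
                           ev["onset_ms"])
            continue
        epochs.append(data[:, start : start + n_times])
        conditions.append(ev["condition"])
    if not epochs:
        raise ValueError("no usable events inside the recording")
    return EpochedEEG(
        data=np.stack(epochs), sfreq=sfreq, tmin_ms=pre, montage=montage,
        conditions=np.asarray(conditions),
    )


def write_subject_recording(
    epochs: EpochedEEG, edf_path: "Path | str", events_tsv: "Path | str",
    sequence: pd.DataFrame | None = None,
) -> None:
    """Write epochs as a continuous EDF plus its events table.

    Epochs are laid back-to-back; each stimulus onset lands at the sample
    where its epoch's t = 0 ms falls, so :func:`load_epochs` with the same
    window reproduces the arrays (up to 16-bit quantization).
    """
    cont = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    write_edf(edf_path, cont, epochs.sfreq, epochs.ch_names)
    offset = -epochs.tmin_ms
    onset_ms = np.arange(epochs.n_epochs) * epochs.n_times * 1000.0 / epochs.sfreq + offset
    tone = (
        sequence["tone_hz"].to_numpy()
        if sequence is not None and "tone_hz" in sequence
        else np.zeros(epochs.n_epochs)
    )
    pd.DataFrame(
        {"onset_ms": onset_ms, "condition": epochs.conditions, "tone_hz": tone}
    ).to_csv(events_tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """All pipeline constants in one serializable bundle."""

    tasks: tuple[TaskSpec, ...] = field(default_factory=lambda: (aob_task(), gng_task()))
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    grid_resolution: tuple[int, int] = (32, 32)
    min_abs_amplitude: float = 1.0
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    reference_size: int = 120
    seed: int = 0

    def bna_config(self) -> BNAConfig:
        return BNAConfig(
            bands=self.bands,
            grid_resolution=self.grid_resolution,
            min_abs_amplitude=self.min_abs_amplitude,
            cluster=self.cluster,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples → lists

    def to_yaml(self, path: "Path | str | None" = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        tasks = tuple(
            TaskSpec(
                name=t["name"],
                n_trials=t["n_trials"],
                condition_probs=dict(t["condition_probs"]),
                tone_freqs=dict(t["tone_freqs"]),
                isi_ms=tuple(t["isi_ms"]),
                epoch_window_ms=tuple(t["epoch_window_ms"]),
                min_correct=t["min_correct"],
            )
            for t in d["tasks"]
        )
        cl = d["cluster"]
        return cls(
            tasks=tasks,
            cleaning=CleaningConfig(**d["cleaning"]),
            bands=tuple(BandSpec(**b) for b in d["bands"]),
            grid_resolution=tuple(d["grid_resolution"]),
            min_abs_amplitude=d["min_abs_amplitude"],
            cluster=ClusterConfig(
                t_cap_ms=cl["t_cap_ms"], s_cap=cl["s_cap"],
                prevalence_min=cl["prevalence_min"],
                sigma_floor=tuple(cl["sigma_floor"]),
            ),
            reference_size=d["reference_size"],
            seed=d["seed"],
        )

    @classmethod
    def from_yaml(cls, src: "Path | str") -> "StudyConfig":
        p = Path(src)
        text = p.read_text() if p.exists() else str(src)
        return cls.from_dict(yaml.safe_load(text))

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# reference-group serialization
# ---------------------------------------------------------------------------

REFERENCE_FORMAT_VERSION = 1


def reference_to_dict(ref: ReferenceGroup) -> dict:
    return {
        "format_version": REFERENCE_FORMAT_VERSION,
        "n_members": ref.n_members,
        "entries": {
            f"{cond}::{band}": [
                {
                    "main_step": dataclasses.asdict(e.main_step),
                    "values": {a: v.tolist() for a, v in e.values.items()},
                    "n_matched": e.n_matched,
                }
                for e in entries
            ]
            for (cond, band), entries in ref.entries.items()
        },
    }


def reference_from_dict(d: dict) -> ReferenceGroup:
    if d.get("format_version") != REFERENCE_FORMAT_VERSION:
        raise ValueError("unsupported reference bundle version")
    ref = ReferenceGroup(n_members=d["n_members"])
    for key, entries in d["entries"].items():
        cond, band = key.split("::")
        ref.entries[(cond, band)] = [
            ReferenceEntry(
                main_step=MainSTEP(**{
                    **e["main_step"],
                    "centroid_location": tuple(e["main_step"]["centroid_location"]),
                }),
                values={a: np.asarray(v) for a, v in e["values"].items()},
                n_matched=e["n_matched"],
            )
            for e in entries
        ]
    return ref


def save_reference(ref: ReferenceGroup, path: "Path | str") -> None:
    Path(path).write_text(json.dumps(reference_to_dict(ref)))


def load_reference(path: "Path | str") -> ReferenceGroup:
    return reference_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# score export and fixtures
# ---------------------------------------------------------------------------

def export_scores(
    scores: pd.DataFrame,
    out_dir: "Path | str",
    results: pd.DataFrame | None = None,
    config: StudyConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write tidy score (and result) tables with a JSON run-metadata sidecar.

    Column order is fixed and rows are sorted, so identical runs produce
    byte-identical files.
    """
    if scores.empty:
        raise ValueError("scores table is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        df = df.reindex(sorted(df.columns), axis=1)
        df = df.sort_values(by=list(df.columns), kind="mergesort",
                            na_position="last").reset_index(drop=True)
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)

    _write(scores, "scores.tsv")
    if results is not None and not results.empty:
        _write(results, "results.tsv")

    from . import __version__

    meta = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config.content_hash() if config else None,
    }
    sidecar = out / "run_meta.json"
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    written.append(sidecar)
    return written


def load_patient_demographics() -> pd.DataFrame:
    """Packaged demographics of the ten-patient 15q13.3 microdeletion cohort
    (subject, sex, age in years + months, clinical notes)."""
    with resources.files("stepnet.data").joinpath(
        "patient_demographics.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
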
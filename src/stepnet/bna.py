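"""Spatiotemporal ERP peak (STEP) analysis.

The core normative-scoring pipeline, in five stages:

1. zero-phase band filtering of the condition-average ERP into overlapping
   physiological bands (delta 0.5–4 Hz, theta 3–8 Hz, alpha 7–13 Hz);
2. interpolation of each time slice onto a high-resolution 2-D scalp grid,
   giving a (x, y, time) amplitude volume;
3. extraction of STEPs — strict local extrema of the volume in space and
   time, each with its same-sign connected half-amplitude surround;
4. clustering of STEPs across a reference cohort into *main STEPs* (clusters
   present in ≥ 70% of subjects), whose member amplitude/latency values form
   the normative distributions;
5. matching a single subject's STEPs to the main STEPs and converting the
   matched amplitude and latency to percentile ranks within the reference.

Amplitudes are kept signed throughout (a deeper negativity scores *lower*,
not larger). Latencies are ms from stimulus onset.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage, signal
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import RBFInterpolator
from scipy.spatial.distance import squareform

from .containers import EpochedEEG
from .montage import ChannelGeometry

logger = logging.getLogger(__name__)

_FAR = 10.0  # linkage distance for incompatible STEP pairs (≫ cut threshold)


# ---------------------------------------------------------------------------
# bands and filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band lo must be < hi")


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 3.0, 8.0),
    BandSpec("alpha", 7.0, 13.0),
)


@lru_cache(maxsize=32)
def _design_fir(lo: float, hi: float, fs: float, numtaps: int) -> np.ndarray:
    """Least-squares linear-phase FIR bandpass taps."""
    nyq = fs / 2.0
    trans = 2.5  # Hz transition band
    lo_stop = max(lo / 2.0, lo - trans)
    hi_stop = min(nyq * 0.99, hi + trans)
    bands = [0.0, lo_stop, lo, hi, hi_stop, nyq]
    desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    return signal.firls(numtaps, bands, desired, fs=fs)


def bandpass_filter(
    x: np.ndarray, band: BandSpec, fs: float, numtaps: int = 101
) -> np.ndarray:
    """Zero-phase bandpass along the last axis.

    A least-squares linear-phase FIR applied forward and reverse
    (``filtfilt``), so the net phase is zero and planted peak times are not
    shifted. Output length equals input length.
    """
    if fs <= 2.0 * band.hi:
        raise ValueError(f"sampling rate {fs} too low for band {band.name}")
    if numtaps % 2 == 0:
        numtaps += 1
    if x.shape[-1] <= 3 * numtaps:
        raise ValueError(
            f"signal length {x.shape[-1]} too short for a {numtaps}-tap filter"
        )
    taps = _design_fir(band.lo, band.hi, fs, numtaps)
    return signal.filtfilt(taps, [1.0], x, axis=-1)


# ---------------------------------------------------------------------------
# averaging and gridding
# ---------------------------------------------------------------------------

def compute_condition_erp(epochs: EpochedEEG, condition: str) -> np.ndarray:
    """Baseline-corrected condition average, ``(n_channels, n_times)`` μV.

    The per-channel mean of the pre-stimulus window is subtracted.
    """
    sel = epochs.select(condition)
    if sel.n_epochs == 0:
        raise ValueError(f"no epochs for condition {condition!r}")
    erp = sel.data.mean(axis=0)
    baseline = erp[:, sel.times_ms < 0].mean(axis=1, keepdims=True)
    return erp - baseline


@dataclass
class ERPGrid:
    """Scalp-interpolated ERP volume: ``values[x, y, t]`` in μV.

    Nodes outside the unit-disc head outline are NaN.
    """

    values: np.ndarray          # (W, H, T)
    xs: np.ndarray              # (W,)
    ys: np.ndarray              # (H,)
    times_ms: np.ndarray        # (T,)
    band: str = ""
    condition: str = ""


def interpolate_grid(
    erp: np.ndarray,
    montage: ChannelGeometry,
    times_ms: np.ndarray,
    resolution: tuple[int, int] = (32, 32),
    band: str = "",
    condition: str = "",
) -> ERPGrid:
    """Thin-plate-spline interpolation of every time slice onto a W×H grid.

    The interpolant is exact: a grid node coinciding with an electrode
    position takes that electrode's value. Nodes outside the unit disc are
    masked with NaN.
    """
    pos = np.asarray(montage.positions, dtype=float)
    if pos.shape[0] < 4:
        raise ValueError("need at least 4 electrodes to interpolate")
    if np.linalg.matrix_rank(pos - pos.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) montage")

    W, H = resolution
    xs = np.linspace(-1.0, 1.0, W)
    ys = np.linspace(-1.0, 1.0, H)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.c_[gx.ravel(), gy.ravel()]

    interp = RBFInterpolator(pos, np.asarray(erp, dtype=float),
                             kernel="thin_plate_spline")
    vals = interp(nodes).reshape(W, H, -1)
    vals[np.hypot(gx, gy) > 1.0 + 1e-9] = np.nan
    return ERPGrid(values=vals, xs=xs, ys=ys, times_ms=np.asarray(times_ms),
                   band=band, condition=condition)


# ---------------------------------------------------------------------------
# STEP extraction
# ---------------------------------------------------------------------------

@dataclass
class STEP:
    """One spatiotemporal ERP peak with its half-amplitude surround."""

    amplitude: float            # signed, μV
    time_ms: float
    location: tuple[float, float]
    polarity: int
    idx: tuple[int, int, int]   # (ix, iy, it) in the source grid
    surround: np.ndarray | None  # (k, 3) grid indices, 26-connected, incl. peak
    band: str = ""
    condition: str = ""


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dt)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dt in (-1, 0, 1)
        if (dx, dy, dt) != (0, 0, 0)
    ]
)


def _half_amplitude_surround(
    v: np.ndarray, peak: tuple[int, int, int], polarity: int, half: float
) -> np.ndarray:
    """Connected component (26-connectivity) of same-sign cells with
    |amplitude| ≥ half, grown from the peak by flood fill."""
    shape = v.shape
    ok = (
        lambda p: 0 <= p[0] < shape[0]
        and 0 <= p[1] < shape[1]
        and 0 <= p[2] < shape[2]
    )
    member = (
        lambda p: np.isfinite(v[p]) and polarity * v[p] >= half
    )
    seen = {peak}
    queue = deque([peak])
    while queue:
        p = queue.popleft()
        for off in _NEIGHBOR_OFFSETS:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if q not in seen and ok(q) and member(q):
                seen.add(q)
                queue.append(q)
    return np.array(sorted(seen), dtype=int)


def extract_steps(
    grid: ERPGrid,
    min_abs_amplitude: float = 1.0,
    with_surround: bool = True,
    max_steps: int | None = None,
) -> list[STEP]:
    """All post-stimulus strict local extrema of the (x, y, t) volume.

    A grid point is a peak iff it is finite, lies at t ≥ 0, has
    |amplitude| ≥ ``min_abs_amplitude`` and is strictly larger (for maxima;
    smaller for minima) than every finite point of its 3×3×3 neighborhood.
    Exact ties (plateaus, e.g. a noiseless bump centered between two grid
    nodes) yield one STEP per connected equal-valued plateau. The surround
    is the 26-connected same-sign region with amplitude of at least half
    the peak's. Returned sorted by |amplitude| descending; ``max_steps``
    keeps only the most salient peaks.
    """
    v = grid.values
    fp = np.ones((3, 3, 3), dtype=bool)
    fp[1, 1, 1] = False
    post = grid.times_ms >= 0

    steps: list[STEP] = []
    for polarity in (+1, -1):
        s = polarity * v
        filled = np.where(np.isfinite(s), s, -np.inf)
        neigh_max = ndimage.maximum_filter(
            filled, footprint=fp, mode="constant", cval=-np.inf
        )
        cand = (
            np.isfinite(s)
            & (filled >= neigh_max)
            & (s >= min_abs_amplitude)
            & post[None, None, :]
        )
        # two adjacent candidates necessarily share the same value (else the
        # smaller would see a larger neighbor), so each connected candidate
        # component is one plateau: emit its first cell only
        if cand.any():
            labels, n_lab = ndimage.label(cand, structure=np.ones((3, 3, 3)))
            keep = np.zeros_like(cand)
            flat_idx = np.argsort(labels, axis=None, kind="stable")
            first = np.searchsorted(np.sort(labels, axis=None), np.arange(1, n_lab + 1))
            keep.ravel()[flat_idx[first]] = True
            cand = keep
        for ix, iy, it in zip(*np.nonzero(cand)):
            amp = float(v[ix, iy, it])
            steps.append(
                STEP(
                    amplitude=amp,
                    time_ms=float(grid.times_ms[it]),
                    location=(float(grid.xs[ix]), float(grid.ys[iy])),
                    polarity=polarity,
                    idx=(int(ix), int(iy), int(it)),
                    surround=None,
                    band=grid.band,
                    condition=grid.condition,
                )
            )
    steps.sort(key=lambda s: -abs(s.amplitude))
    if max_steps is not None:
        steps = steps[:max_steps]
    if with_surround:
        for st in steps:
            st.surround = _half_amplitude_surround(
                v, st.idx, st.polarity, abs(st.amplitude) / 2.0
            )
    return steps


# ---------------------------------------------------------------------------
# clustering into main STEPs
# ---------------------------------------------------------------------------

@dataclass
class MainSTEP:
    """A STEP cluster shared by most of a reference cohort."""

    label: str
    centroid_time: float
    centroid_location: tuple[float, float]
    time_dispersion: float
    spatial_dispersion: float
    prevalence: float
    polarity: int
    band: str = ""
    condition: str = ""


@dataclass(frozen=True)
class ClusterConfig:
    t_cap_ms: float = 100.0     # max within-cluster time separation
    s_cap: float = 0.5          # max within-cluster spatial separation (radii)
    prevalence_min: float = 0.7
    sigma_floor: tuple[float, float] = (25.0, 0.1)  # (ms, radii)


def _step_distance_matrix(steps: list[STEP], cfg: ClusterConfig) -> np.ndarray:
    """Pairwise capped time/space distance; incompatible pairs get ``_FAR``."""
    times = np.array([s.time_ms for s in steps])
    locs = np.array([s.location for s in steps])
    pols = np.array([s.polarity for s in steps])
    dt = np.abs(times[:, None] - times[None, :]) / cfg.t_cap_ms
    ds = np.linalg.norm(locs[:, None, :] - locs[None, :, :], axis=-1) / cfg.s_cap
    d = np.maximum(dt, ds)
    d[(d > 1.0) | (pols[:, None] != pols[None, :])] = _FAR
    np.fill_diagonal(d, 0.0)
    return d


def cluster_steps(
    per_subject_steps: dict[str, list[STEP]],
    prevalence_min: float | None = None,
    cfg: ClusterConfig | None = None,
) -> list[MainSTEP]:
    """Group one band×condition's STEPs across subjects into main STEPs.

    Average-linkage agglomeration under a capped time/space metric
    (incompatible pairs — opposite polarity or beyond the caps — get a large
    fixed distance, so a merge needs most cross-pairs compatible), then a
    prevalence filter: a cluster survives iff at least ``prevalence_min`` of
    the subjects contribute a STEP to it. Within a cluster a subject counts
    once (its STEP nearest the centroid).
    """
    cfg = cfg or ClusterConfig()
    if prevalence_min is not None:
        cfg = ClusterConfig(cfg.t_cap_ms, cfg.s_cap, prevalence_min, cfg.sigma_floor)
    n_subjects = len(per_subject_steps)
    if n_subjects < 2:
        raise ValueError("clustering needs at least 2 subjects")

    flat: list[tuple[str, STEP]] = [
        (subj, st) for subj, steps in per_subject_steps.items() for st in steps
    ]
    if not flat:
        return []

    if len(flat) == 1:
        assignments = np.array([1])
    else:
        dm = _step_distance_matrix([st for _, st in flat], cfg)
        assignments = fcluster(
            linkage(squareform(dm, checks=False), method="average"),
            t=1.0,
            criterion="distance",
        )

    main: list[MainSTEP] = []
    for cl in np.unique(assignments):
        members = [flat[i] for i in np.nonzero(assignments == cl)[0]]
        times = np.array([st.time_ms for _, st in members])
        locs = np.array([st.location for _, st in members])
        ct, cloc = times.mean(), locs.mean(axis=0)
        # one STEP per subject: nearest to the provisional centroid
        best: dict[str, STEP] = {}
        for subj, st in members:
            d = np.hypot(
                (st.time_ms - ct) / cfg.t_cap_ms,
                np.hypot(st.location[0] - cloc[0], st.location[1] - cloc[1])
                / cfg.s_cap,
            )
            if subj not in best or d < best[subj][0]:
                best[subj] = (d, st)  # type: ignore[assignment]
        chosen = [st for _, st in best.values()]
        prevalence = len(chosen) / n_subjects
        if prevalence < cfg.prevalence_min:
            continue
        times = np.array([s.time_ms for s in chosen])
        locs = np.array([s.location for s in chosen])
        pol = chosen[0].polarity
        label = (
            f"{chosen[0].condition or 'cond'}-{chosen[0].band or 'band'}-"
            f"{'P' if pol > 0 else 'N'}{int(round(times.mean()))}ms"
        )
        main.append(
            MainSTEP(
                label=label,
                centroid_time=float(times.mean()),
                centroid_location=(float(locs[:, 0].mean()), float(locs[:, 1].mean())),
                time_dispersion=float(times.std(ddof=0)),
                spatial_dispersion=float(
                    np.hypot(*(locs - locs.mean(axis=0)).T).mean()
                ),
                prevalence=float(prevalence),
                polarity=pol,
                band=chosen[0].band,
                condition=chosen[0].condition,
            )
        )
    main.sort(key=lambda m: m.centroid_time)
    return main


# ---------------------------------------------------------------------------
# matching and scoring
# ---------------------------------------------------------------------------

def match_steps(
    subject_steps: list[STEP],
    main_steps: list[MainSTEP],
    windows: tuple[float, float] | None = None,
    sigma_floor: tuple[float, float] = (25.0, 0.1),
    window_floor: tuple[float, float] = (100.0, 0.3),
) -> dict[str, STEP | None]:
    """Assign subject STEPs to main STEPs by time/space similarity.

    A candidate must share the template's polarity and fall within the
    matching windows (default: 2× the cluster dispersion, floored). Among
    candidates the smallest dispersion-normalized distance
    √((Δt/σt)² + (Δs/σs)²) wins; assignment is greedy by ascending distance
    with every subject STEP and every template used at most once.
    """
    pairs: list[tuple[float, int, int]] = []
    for mi, ms in enumerate(main_steps):
        st_floor = max(ms.time_dispersion, sigma_floor[0])
        ss_floor = max(ms.spatial_dispersion, sigma_floor[1])
        if windows is not None:
            wt, ws = windows
        else:
            wt = max(2.0 * ms.time_dispersion, window_floor[0])
            ws = max(2.0 * ms.spatial_dispersion, window_floor[1])
        if wt <= 0 or ws <= 0:
            raise ValueError("matching windows must be positive")
        for si, st in enumerate(subject_steps):
            if st.polarity != ms.polarity:
                continue
            dt = abs(st.time_ms - ms.centroid_time)
            ds = np.hypot(
                st.location[0] - ms.centroid_location[0],
                st.location[1] - ms.centroid_location[1],
            )
            if dt <= wt and ds <= ws:
                pairs.append(
                    (float(np.hypot(dt / st_floor, ds / ss_floor)), mi, si)
                )

    result: dict[str, STEP | None] = {ms.label: None for ms in main_steps}
    used_main: set[int] = set()
    used_step: set[int] = set()
    for d, mi, si in sorted(pairs):
        if mi in used_main or si in used_step:
            continue
        result[main_steps[mi].label] = subject_steps[si]
        used_main.add(mi)
        used_step.add(si)
    return result


def percentile_score(value: float, reference: np.ndarray) -> float:
    """Mid-rank percentile of ``value`` within a sorted reference sample:
    ``100 × (#{ref < value} + 0.5 × #{ref = value}) / n``."""
    ref = np.asarray(reference)
    if ref.size == 0:
        raise ValueError("empty reference")
    less = int(np.searchsorted(ref, value, side="left"))
    equal = int(np.searchsorted(ref, value, side="right")) - less
    return 100.0 * (less + 0.5 * equal) / ref.size


# ---------------------------------------------------------------------------
# reference group
# ---------------------------------------------------------------------------

ATTRIBUTES = ("amplitude", "latency")


@dataclass
class ReferenceEntry:
    main_step: MainSTEP
    values: dict[str, np.ndarray]  # attribute → sorted member values
    n_matched: int = 0


@dataclass
class ReferenceGroup:
    """Main-STEP registry plus normative attribute distributions."""

    n_members: int
    entries: dict[tuple[str, str], list[ReferenceEntry]] = field(
        default_factory=dict
    )  # (condition, band) → entries

    def all_entries(self) -> list[ReferenceEntry]:
        return [e for group in self.entries.values() for e in group]


def build_reference_group(
    cohort_steps: dict[str, list[STEP]],
    main_steps: list[MainSTEP],
    **match_kw,
) -> list[ReferenceEntry]:
    """Match every reference member against the main STEPs and store the
    matched amplitude/latency values, sorted ascending.

    A main STEP matched by fewer than half of the members is dropped.
    """
    if not main_steps:
        raise ValueError("main_steps must be non-empty")
    n = len(cohort_steps)
    collected: dict[str, dict[str, list[float]]] = {
        ms.label: {a: [] for a in ATTRIBUTES} for ms in main_steps
    }
    for steps in cohort_steps.values():
        matched = match_steps(steps, main_steps, **match_kw)
        for label, st in matched.items():
            if st is not None:
                collected[label]["amplitude"].append(st.amplitude)
                collected[label]["latency"].append(st.time_ms)

    entries: list[ReferenceEntry] = []
    for ms in main_steps:
        k = len(collected[ms.label]["amplitude"])
        if k < 0.5 * n:
            logger.warning(
                "dropping %s: matched by %d/%d reference members", ms.label, k, n
            )
            continue
        entries.append(
            ReferenceEntry(
                main_step=ms,
                values={
                    a: np.sort(np.asarray(collected[ms.label][a]))
                    for a in ATTRIBUTES
                },
                n_matched=k,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# end-to-end subject processing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BNAConfig:
    """Knobs of the STEP pipeline (defaults used throughout the package)."""

    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    grid_resolution: tuple[int, int] = (32, 32)
    min_abs_amplitude: float = 1.0  # μV, post-filter
    numtaps: int = 101
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    with_surround: bool = False  # surrounds are not needed for scoring
    max_steps: int | None = 15   # most salient peaks per condition × band


def subject_steps(
    epochs: EpochedEEG,
    cfg: BNAConfig | None = None,
    conditions: tuple[str, ...] | None = None,
) -> dict[tuple[str, str], list[STEP]]:
    """Filter → average → grid → extract, per condition × band.

    Band filtering is applied to the condition average; for a linear
    zero-phase filter this equals averaging band-filtered epochs.
    """
    cfg = cfg or BNAConfig()
    conditions = conditions or tuple(np.unique(epochs.conditions))
    out: dict[tuple[str, str], list[STEP]] = {}
    for cond in conditions:
        erp = compute_condition_erp(epochs, cond)
        for band in cfg.bands:
            filt = bandpass_filter(erp, band, epochs.sfreq, cfg.numtaps)
            grid = interpolate_grid(
                filt,
                epochs.montage,
                epochs.times_ms,
                cfg.grid_resolution,
                band=band.name,
                condition=cond,
            )
            out[(cond, band.name)] = extract_steps(
                grid,
                cfg.min_abs_amplitude,
                with_surround=cfg.with_surround,
                max_steps=cfg.max_steps,
            )
    return out


def build_reference(
    per_subject_steps: dict[str, dict[tuple[str, str], list[STEP]]],
    cfg: BNAConfig | None = None,
) -> ReferenceGroup:
    """Cluster a reference cohort's STEPs and collect normative values."""
    cfg = cfg or BNAConfig()
    subjects = list(per_subject_steps)
    keys = sorted({k for d in per_subject_steps.values() for k in d})
    ref = ReferenceGroup(n_members=len(subjects))
    for key in keys:
        per_subj = {s: per_subject_steps[s].get(key, []) for s in subjects}
        main = cluster_steps(per_subj, cfg=cfg.cluster)
        if not main:
            continue
        entries = build_reference_group(per_subj, main)
        if entries:
            ref.entries[key] = entries
    return ref


@dataclass
class BNAScore:
    subject: str
    main_step: str
    condition: str
    band: str
    attribute: str
    raw_value: float | None
    percentile: float | None
    matched: bool


def score_subject(
    epochs: EpochedEEG,
    reference: ReferenceGroup,
    cfg: BNAConfig | None = None,
    subject: str = "",
) -> list[BNAScore]:
    """Percentile-score one subject against a reference group.

    Applies the identical extraction pipeline used for the reference
    members, matches against each main STEP, and converts the matched
    amplitude and latency to percentile ranks. Unmatched templates yield
    ``matched=False`` and no percentile.
    """
    cfg = cfg or BNAConfig()
    subject = subject or str(epochs.meta.get("subject", ""))
    conditions = tuple(np.unique(epochs.conditions))
    steps = subject_steps(epochs, cfg, conditions)
    scores: list[BNAScore] = []
    for key, entries in reference.entries.items():
        cond, band = key
        if cond not in conditions:
            continue
        matched = match_steps(
            steps.get(key, []), [e.main_step for e in entries]
        )
        for entry in entries:
            st = matched[entry.main_step.label]
            for attr in ATTRIBUTES:
                if st is None:
                    scores.append(
                        BNAScore(subject, entry.main_step.label, cond, band,
                                 attr, None, None, False)
                    )
                else:
                    raw = st.amplitude if attr == "amplitude" else st.time_ms
                    scores.append(
                        BNAScore(
                            subject,
                            entry.main_step.label,
                            cond,
                            band,
                            attr,
                            float(raw),
                            percentile_score(raw, entry.values[attr]),
                            True,
                        )
                    )
    return scores


def scores_to_frame(scores: list[BNAScore]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame([vars(s) for s in scores])
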
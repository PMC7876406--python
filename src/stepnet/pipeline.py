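"""End-to-end study flows.

Composes the stage modules into the study design: build a normative
reference group from simulated healthy subjects, percentile-score a
two-visit cohort against it, and assemble the tidy ERPv and behavioral
tables that feed the statistics layer.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import behavior as beh
from . import bna, erpv, preprocess, synth
from .containers import EpochedEEG
from .montage import standard_montage

logger = logging.getLogger(__name__)


def _maybe_clean(eeg: EpochedEEG, cleaning: preprocess.CleaningConfig | None
                 ) -> EpochedEEG:
    if cleaning is None:
        return eeg
    cleaned, _ = preprocess.clean_epochs(eeg, cleaning)
    return cleaned


def simulate_condition_epochs(
    condition_counts: dict[str, int],
    window_ms: tuple[float, float],
    params: synth.SubjectParams,
    montage,
    seed,
    isi_ms: float = 1500.0,
) -> "EpochedEEG":
    """Simulate exactly the requested number of epochs per condition.

    Epochs are statistically independent in the generator, so simulating a
    condition subset is distributionally identical to subsetting a full task
    run — and proportionally cheaper when only rare conditions are needed.
    """
    conds = [c for c, n in condition_counts.items() for _ in range(n)]
    seq = pd.DataFrame(
        {
            "condition": conds,
            "onset_ms": np.arange(len(conds)) * isi_ms,
            "tone_hz": np.full(len(conds), 1000.0),
        }
    )
    return synth.simulate_subject_eeg(
        seq, params, montage=montage, seed=seed, epoch_window_ms=window_ms
    )


def simulate_reference_group(
    task: synth.TaskSpec,
    conditions: tuple[str, ...],
    n_members: int = 120,
    seed: int = 0,
    cfg: bna.BNAConfig | None = None,
    cleaning: preprocess.CleaningConfig | None = None,
    n_channels: int = 64,
    condition_counts: dict[str, int] | None = None,
) -> bna.ReferenceGroup:
    """Simulate ``n_members`` healthy subjects and build their reference.

    Each member gets independently drawn healthy parameters, one simulated
    recording of ``task``, the STEP extraction pipeline, and contributes to
    the cluster discovery and the normative amplitude/latency distributions.
    ``condition_counts`` simulates only the listed conditions (at the given
    per-subject trial counts) instead of the full task sequence.
    """
    cfg = cfg or bna.BNAConfig()
    montage = standard_montage(n_channels)
    per_subject: dict[str, dict[tuple[str, str], list[bna.STEP]]] = {}
    for i in range(n_members):
        ss = np.random.SeedSequence(seed, spawn_key=(100, i))
        rng = np.random.default_rng(ss)
        params = synth.draw_subject_params("healthy", rng)
        sim_seed = np.random.SeedSequence(seed, spawn_key=(101, i))
        if condition_counts is None:
            seq_seed = int(ss.generate_state(2)[1] % (2**31))
            seq = synth.generate_task_sequence(task, seq_seed)
            eeg = synth.simulate_subject_eeg(
                seq, params, montage=montage, seed=sim_seed,
                epoch_window_ms=task.epoch_window_ms,
            )
        else:
            eeg = simulate_condition_epochs(
                condition_counts, task.epoch_window_ms, params, montage, sim_seed
            )
        eeg = _maybe_clean(eeg, cleaning)
        per_subject[f"R{i:03d}"] = bna.subject_steps(eeg, cfg, conditions)
        if (i + 1) % 20 == 0:
            logger.info("reference build: %d/%d members", i + 1, n_members)
    return bna.build_reference(per_subject, cfg)


def score_cohort(
    cohort: synth.Cohort,
    reference: bna.ReferenceGroup,
    task_name: str,
    cfg: bna.BNAConfig | None = None,
    cleaning: preprocess.CleaningConfig | None = None,
) -> pd.DataFrame:
    """Percentile-score every subject × visit of a cohort against a
    reference; returns the tidy long-format score table."""
    cfg = cfg or bna.BNAConfig()
    rows = []
    for s in cohort.subjects:
        for visit in range(1, cohort.config.visits + 1):
            eeg = _maybe_clean(cohort.epochs(s.subject_id, visit, task_name),
                               cleaning)
            for sc in bna.score_subject(eeg, reference, cfg, subject=s.subject_id):
                rows.append(
                    {
                        "subject": s.subject_id,
                        "visit": visit,
                        "group": s.group,
                        "task": task_name,
                        "condition": sc.condition,
                        "band": sc.band,
                        "main_step": sc.main_step,
                        "attribute": sc.attribute,
                        "raw": sc.raw_value,
                        "percentile": sc.percentile,
                        "matched": sc.matched,
                    }
                )
    return pd.DataFrame(rows)


def erpv_cohort(
    cohort: synth.Cohort,
    task_name: str,
    conditions: tuple[str, ...] | None = None,
    cleaning: preprocess.CleaningConfig | None = None,
    use_behavior_validity: bool = True,
) -> pd.DataFrame:
    """ERPv scores for every subject × visit × condition of a task.

    Validity follows the scoring rule: correct-response trials for response
    conditions, correct inhibitions for NoGo, all artifact-free trials for
    conditions without a response requirement.
    """
    rows = []
    for s in cohort.subjects:
        for visit in range(1, cohort.config.visits + 1):
            eeg = cohort.epochs(s.subject_id, visit, task_name)
            rec = cohort.behavior(s.subject_id, visit, task_name)
            eeg = _maybe_clean(eeg, cleaning)
            conds = conditions or tuple(np.unique(eeg.conditions))
            for cond in conds:
                mask = None
                if use_behavior_validity and cleaning is None:
                    mask = erpv.erpv_valid_mask(eeg, cond, rec)
                try:
                    score = erpv.compute_erpv(eeg, cond, normalize=True,
                                              valid_mask=mask)
                except ValueError:
                    continue
                rows.append(
                    {
                        "subject": s.subject_id,
                        "visit": visit,
                        "group": s.group,
                        "task": task_name,
                        "condition": cond,
                        "raw_erpv": score.raw_erpv,
                        "normalized_erpv": score.normalized_erpv,
                        "neural_consistency": erpv.neural_consistency(score),
                        "n_trials_used": score.n_trials_used,
                    }
                )
    return pd.DataFrame(rows)


def find_main_step(
    reference: bna.ReferenceGroup,
    condition: str,
    band: str,
    polarity: int,
    near_time_ms: float,
) -> bna.ReferenceEntry | None:
    """The reference entry of given polarity closest in time to a target
    latency — e.g. the positive delta-band Novel cluster near 300 ms is the
    P3a template."""
    entries = [
        e
        for e in reference.entries.get((condition, band), [])
        if e.main_step.polarity == polarity
    ]
    if not entries:
        return None
    return min(entries, key=lambda e: abs(e.main_step.centroid_time - near_time_ms))


def replicate_tables(
    reference: bna.ReferenceGroup,
    seed: int,
    n_healthy: int = 30,
    n_patient: int = 9,
    novel_trials: int = 60,
    erpv_counts_aob: dict[str, int] | None = None,
    erpv_counts_gng: dict[str, int] | None = None,
    cfg: bna.BNAConfig | None = None,
    group_effect: synth.GroupEffect | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One cohort replicate: STEP percentile scores plus ERPv per condition.

    Simulates a fresh two-visit 30 + 9 cohort, scores each subject's Novel
    oddball epochs (60, the per-session Novel count of the default task)
    against the
    shared, pre-built reference group, and computes ERPv for every condition
    of both tasks from condition-subset recordings. Returns
    (score table, ERPv table).
    """
    cfg = cfg or bna.BNAConfig()
    erpv_counts_aob = erpv_counts_aob or {"Frequent": 48, "Target": 12}
    erpv_counts_gng = erpv_counts_gng or {"Go": 48, "NoGo": 12}
    effect = group_effect if group_effect is not None else synth.default_group_effect()
    montage = standard_montage()
    aob_win = synth.aob_task().epoch_window_ms
    gng_win = synth.gng_task().epoch_window_ms

    score_rows, erpv_rows = [], []
    for i in range(n_healthy + n_patient):
        group = "healthy" if i < n_healthy else "patient"
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, i)))
        params = synth.draw_subject_params(group, rng, effect)
        for visit in (1, 2):
            novel = simulate_condition_epochs(
                {"Novel": novel_trials}, aob_win, params, montage,
                np.random.SeedSequence(seed, spawn_key=(1, i, visit)),
            )
            for sc in bna.score_subject(novel, reference, cfg, subject=f"S{i:03d}"):
                score_rows.append(
                    {
                        "subject": f"S{i:03d}",
                        "visit": visit,
                        "group": group,
                        "condition": sc.condition,
                        "band": sc.band,
                        "main_step": sc.main_step,
                        "attribute": sc.attribute,
                        "percentile": sc.percentile,
                        "matched": sc.matched,
                    }
                )
            aob_rest = simulate_condition_epochs(
                erpv_counts_aob, aob_win, params, montage,
                np.random.SeedSequence(seed, spawn_key=(2, i, visit)),
            )
            gng = simulate_condition_epochs(
                erpv_counts_gng, gng_win, params, montage,
                np.random.SeedSequence(seed, spawn_key=(3, i, visit)),
            )
            for task_name, eeg, conds in (
                ("AOB", novel, ("Novel",)),
                ("AOB", aob_rest, tuple(erpv_counts_aob)),
                ("GNG", gng, tuple(erpv_counts_gng)),
            ):
                for cond in conds:
                    try:
                        e = erpv.compute_erpv(eeg, cond, normalize=True)
                    except ValueError:
                        continue
                    erpv_rows.append(
                        {
                            "subject": f"S{i:03d}",
                            "visit": visit,
                            "group": group,
                            "task": task_name,
                            "condition": cond,
                            "normalized_erpv": e.normalized_erpv,
                            "raw_erpv": e.raw_erpv,
                        }
                    )
    return pd.DataFrame(score_rows), pd.DataFrame(erpv_rows)


def behavior_cohort(cohort: synth.Cohort, task_name: str, k: float = 2.5
                    ) -> pd.DataFrame:
    """Tidy behavioral summary for every subject × visit of a task."""
    records = [
        cohort.behavior(s.subject_id, visit, task_name)
        for s in cohort.subjects
        for visit in range(1, cohort.config.visits + 1)
    ]
    table = beh.behavior_table(records, k)
    groups = {s.subject_id: s.group for s in cohort.subjects}
    table["group"] = table["subject"].map(groups)
    return table
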
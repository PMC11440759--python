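"""Per-subject HSMM training, resting-heart-rate bias adjustment, state
labelling, and majority-vote ensemble prediction.

Two model variants are supported: STEPHEN uses both step counts and heart
rate as conditionally independent NB emissions; STEPCODE is the steps-only
ablation.  One model is fitted per training subject; to predict a new
subject, each member model's heart-rate means are shifted by the difference
in resting heart rate (mean HR over zero-step minutes) between the target
and the member's training subject, the member decodes the target with
Viterbi, its states are mapped to activity labels by increasing step/HR
means, and the per-minute modal label across members is the prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np
import pandas as pd

from .errors import DegenerateModelError, InsufficientDataError
from .hsmm import MEAN_FLOOR, HsmmModel, NbParams, ObservationSegments, fit_em, viterbi
from .io import MinuteSeries


class ActivityLabel(IntEnum):
    """Activity intensity classes in increasing order."""

    SEDENTARY = 0
    STANDING_LPA = 1
    MPA = 2
    VPA = 3


class Mode(str, Enum):
    STEPHEN = "stephen"
    STEPCODE = "stepcode"


#: bijection from 1-based model state indices to activity labels
LabelMap = dict


@dataclass
class EnsembleMember:
    model: HsmmModel
    label_map: LabelMap
    reference_resting_hr: float
    subject_id: str = ""


@dataclass
class TrainedEnsemble:
    mode: Mode
    members: list[EnsembleMember]
    K: int
    seed: int | None = None

    def __post_init__(self) -> None:
        for m in self.members:
            if m.model.K != self.K:
                raise ValueError("all members must share K")
            if (self.mode is Mode.STEPCODE) == m.model.use_hr:
                raise ValueError(f"member use_hr inconsistent with mode {self.mode}")

    def __len__(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "K": self.K,
            "seed": self.seed,
            "members": [
                {
                    "subject_id": m.subject_id,
                    "model": m.model.to_dict(),
                    "label_map": {str(k): v.name for k, v in m.label_map.items()},
                    "reference_resting_hr": m.reference_resting_hr,
                }
                for m in self.members
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedEnsemble":
        members = [
            EnsembleMember(
                model=HsmmModel.from_dict(m["model"]),
                label_map={int(k): ActivityLabel[v] for k, v in m["label_map"].items()},
                reference_resting_hr=m["reference_resting_hr"],
                subject_id=m.get("subject_id", ""),
            )
            for m in d["members"]
        ]
        return cls(mode=Mode(d["mode"]), members=members, K=d["K"], seed=d.get("seed"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrainedEnsemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class LabeledPrediction:
    """Per-minute ensemble prediction: modal label plus vote counts."""

    subject_id: str
    timestamps: pd.DatetimeIndex
    labels: np.ndarray  # ActivityLabel values, int
    votes: np.ndarray  # (n_minutes, 4) counts per label

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.timestamps,
                "label": [ActivityLabel(v).name for v in self.labels],
            }
        )
        for lab in ActivityLabel:
            df[f"votes_{lab.name.lower()}"] = self.votes[:, lab.value]
        return df


def resting_hr(series: MinuteSeries) -> float:
    """Resting heart rate: mean HR over zero-step worn minutes.

    Subjects with no zero-step minutes fall back to the minutes in the lowest
    decile of step counts (with a warning).
    """
    if len(series) == 0:
        raise InsufficientDataError("cannot compute resting HR of an empty series")
    steps = series.steps
    hr = series.heart_rate
    ok = np.isfinite(hr)
    zero = (steps == 0) & ok
    if zero.any():
        return float(np.mean(hr[zero]))
    warnings.warn(
        f"subject {series.subject_id} has no zero-step minutes; "
        "using the lowest step-count decile for resting HR",
        stacklevel=2,
    )
    cut = np.quantile(steps[ok], 0.1)
    low = ok & (steps <= cut)
    return float(np.mean(hr[low]))


def hr_bias(target: MinuteSeries, member_reference_resting_hr: float) -> float:
    """Target resting HR minus the training subject's resting HR (bpm)."""
    return resting_hr(target) - member_reference_resting_hr


def apply_bias(model: HsmmModel, bias: float) -> HsmmModel:
    """Shift every state's HR mean by ``bias`` bpm (floored at a small epsilon).

    Aligns a member model's heart-rate scale with the target subject; all
    other parameters are untouched.  Returns a new model.
    """
    if not model.use_hr:
        warnings.warn("apply_bias is a no-op on a steps-only model", stacklevel=2)
        return model
    new_hr = []
    for p in model.hr_params:
        m = p.mean + bias
        if m < MEAN_FLOOR:
            warnings.warn(f"HR mean floored at {MEAN_FLOOR} after bias {bias:+.2f}", stacklevel=2)
            m = MEAN_FLOOR
        new_hr.append(NbParams(mean=m, dispersion=p.dispersion))
    return HsmmModel(
        K=model.K,
        step_params=model.step_params,
        hr_params=new_hr,
        sojourn=model.sojourn,
        init_probs=model.init_probs,
        trans=model.trans,
    )


def label_states(model: HsmmModel, rank_only: bool = False) -> LabelMap:
    """Map 1-based state indices to activity labels by increasing intensity.

    States are sorted by (mean step count, then mean HR when present); the
    lowest becomes SEDENTARY and the rest follow the intensity order.  Exact
    ties in both keys indicate a degenerate fit and raise an error.
    """
    if model.K != 4 and not rank_only:
        raise ValueError(f"labelling expects K=4 (got K={model.K}); pass rank_only=True")
    if model.K > len(ActivityLabel):
        raise ValueError(f"cannot label K={model.K} > {len(ActivityLabel)} states")
    keys = [
        (model.step_params[k].mean, model.hr_params[k].mean if model.use_hr else 0.0)
        for k in range(model.K)
    ]
    if len(set(keys)) != len(keys):
        raise DegenerateModelError("exactly tied (step mean, HR mean) pairs; re-fit the model")
    order = sorted(range(model.K), key=lambda k: keys[k])
    return {state + 1: ActivityLabel(rank) for rank, state in enumerate(order)}


def train_ensemble(
    training: list[MinuteSeries],
    mode: Mode | str,
    K: int = 4,
    seed: int = 0,
    **em_options,
) -> TrainedEnsemble:
    """Fit one labelled HSMM per training subject.

    Each member stores its training subject's resting HR so predictions can
    be bias-adjusted.  Member fits that fail are dropped with a warning;
    if all fail an error is raised.  Deterministic given ``seed``.
    """
    mode = Mode(mode)
    use_hr = mode is Mode.STEPHEN
    members: list[EnsembleMember] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(len(training)) % (2**31)
    for series, sub_seed in zip(training, child_seeds):
        try:
            segments = ObservationSegments.from_minute_series(series, use_hr=use_hr)
            model, _ = fit_em(segments, K=K, use_hr=use_hr, seed=int(sub_seed), **em_options)
            label_map = label_states(model, rank_only=(K != 4))
            ref = resting_hr(series)
        except Exception as exc:  # noqa: BLE001 - member failures are recorded, not fatal
            warnings.warn(
                f"dropping training subject {series.subject_id}: {exc}", stacklevel=2
            )
            continue
        members.append(
            EnsembleMember(
                model=model,
                label_map=label_map,
                reference_resting_hr=ref,
                subject_id=series.subject_id,
            )
        )
    if not members:
        raise InsufficientDataError("every training subject failed to fit")
    return TrainedEnsemble(mode=mode, members=members, K=K, seed=seed)


def predict_subject(ensemble: TrainedEnsemble, target: MinuteSeries) -> LabeledPrediction:
    """Majority-vote ensemble prediction of per-minute activity labels.

    STEPHEN members are bias-adjusted to the target's resting HR before
    decoding; STEPCODE members decode on steps alone.  Per minute the modal
    label across members wins; ties go to the lowest-intensity label.
    """
    if len(target) == 0:
        return LabeledPrediction(
            target.subject_id,
            pd.DatetimeIndex([]),
            np.empty(0, dtype=np.int64),
            np.zeros((0, len(ActivityLabel)), dtype=np.int64),
        )
    use_hr = ensemble.mode is Mode.STEPHEN
    segments = ObservationSegments.from_minute_series(target, use_hr=use_hr)
    n = segments.n_obs
    votes = np.zeros((n, len(ActivityLabel)), dtype=np.int64)
    bias = hr_bias(target, 0.0) if use_hr else 0.0  # target resting HR, reused per member
    for member in ensemble.members:
        model = member.model
        if use_hr:
            model = apply_bias(model, bias - member.reference_resting_hr)
        states = viterbi(model, segments)
        labels = np.array([member.label_map[s].value for s in states])
        votes[np.arange(n), labels] += 1
    winners = np.argmax(votes, axis=1)  # first max -> lowest-intensity tie-break
    return LabeledPrediction(
        subject_id=target.subject_id,
        timestamps=target.timestamps,
        labels=winners.astype(np.int64),
        votes=votes,
    )
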
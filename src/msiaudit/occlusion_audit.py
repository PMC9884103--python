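"""Spectral channel occlusion sensitivity and its correlation with SNR.

Occluding a channel replaces it, in the model's input space, by the scalar
average of that channel over every pixel of every training patch — exactly
the mean value the network saw during training.  The change in the mean
correct-class probability on test patches, per tissue class and channel,
measures how much the model relies on that channel.  Ranking channels by
this sensitivity and by their photon-limited SNR and correlating the two
rank lists (Spearman) tests whether SNR predicts a channel's contribution
to classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import TrainedModel, predict_proba
from .patchwork import PatchDataset
from .radiometry import all_channel_ids

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChannelMeans:
    """Per-channel scalar grand mean over all training-patch pixels.

    Carries the split it was computed from so downstream occlusion can
    enforce its train-only precondition.
    """

    values: np.ndarray
    source_split: str
    channel_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("channel means must be a 1-d vector")


def compute_channel_means(dataset: PatchDataset, split: str = "train",
                          normalized: bool = True) -> ChannelMeans:
    """Grand mean per channel over (patches x 32 x 32) of the given split.

    The audit contract requires training-split means; requesting another
    split raises immediately rather than silently producing a leaky audit.
    """
    if split != "train":
        raise ValueError("channel means must be computed from the train split")
    s = dataset.splits[split]
    if len(s) == 0:
        raise ValueError("empty train split")
    x = dataset.normalize(s.patches) if normalized else s.patches.astype(np.float64)
    means = np.asarray(x, dtype=np.float64).mean(axis=(0, 1, 2))
    ids = tuple(all_channel_ids()[i] for i in dataset.channel_indices)
    return ChannelMeans(values=means, source_split=split, channel_ids=ids)


def occlude_channel(patches: np.ndarray, channel: int, means: ChannelMeans) -> np.ndarray:
    """Replace channel ``channel`` of every patch by its training mean.

    Returns a new array; the input is never mutated.  Idempotent by
    construction.
    """
    c = patches.shape[-1]
    if not 0 <= channel < c:
        raise IndexError(f"channel {channel} out of range [0, {c})")
    if means.values.size != c:
        raise ValueError("channel means length does not match patch channels")
    out = patches.copy()
    out[..., channel] = means.values[channel]
    return out


@dataclass
class OcclusionMap:
    """K x C matrix of signed change in correct-class probability.

    ``delta[k, c]`` = mean correct-class probability of class-k test patches
    before occlusion minus after occluding channel c (positive = the channel
    helps).  Classes absent from the test set carry NaN rows.  The absolute
    map and the class-averaged per-channel sensitivity are derived views.
    """

    delta: np.ndarray
    class_names: tuple[str, ...]
    channel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != (len(self.class_names), len(self.channel_ids)):
            raise ValueError("delta must be (K, C)")

    @property
    def abs_delta(self) -> np.ndarray:
        return np.abs(self.delta)

    def channel_sensitivity(self, signed: bool = False) -> pd.Series:
        """Class-averaged sensitivity per channel (NaN classes excluded)."""
        m = self.delta if signed else self.abs_delta
        with np.errstate(invalid="ignore"):
            avg = np.nanmean(m, axis=0)
        return pd.Series(avg, index=list(self.channel_ids),
                         name="occlusion_sensitivity")

    def to_frame(self, signed: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.delta if signed else self.abs_delta,
                          index=list(self.class_names), columns=list(self.channel_ids))
        df.loc["average"] = self.channel_sensitivity(signed=signed).to_numpy()
        return df

    def to_csv(self, path: str | Path, signed: bool = True) -> None:
        self.to_frame(signed=signed).to_csv(path, na_rep="NA")


def occlusion_map(trained: TrainedModel, patches: np.ndarray, labels: np.ndarray,
                  means: ChannelMeans, class_names: Sequence[str],
                  channel_ids: Sequence[str] | None = None) -> OcclusionMap:
    """Occlude each channel in turn and measure the probability change.

    ``patches`` must already be in the model's input space (normalized), and
    ``means`` must come from the training split — the substituted scalar is
    then exactly the average the network sees.
    """
    if means.source_split != "train":
        raise ValueError("occlusion requires train-split channel means")
    n, _, _, C = patches.shape
    K = len(class_names)
    if channel_ids is None:
        channel_ids = means.channel_ids or tuple(f"ch{c}" for c in range(C))
    if len(channel_ids) != C:
        raise ValueError("channel_ids length must match patch channels")
    base = predict_proba(trained, patches, labels=labels, class_names=class_names)
    base_correct = base.correct_probs()
    delta = np.full((K, C), np.nan)
    class_masks = [labels == k for k in range(K)]
    present = [m.any() for m in class_masks]
    for k in range(K):
        if not present[k]:
            logger.warning("class %s absent from evaluation patches; row flagged NA",
                           class_names[k])
    for c in range(C):
        occ = predict_proba(trained, occlude_channel(patches, c, means),
                            labels=labels, class_names=class_names)
        occ_correct = occ.correct_probs()
        for k in range(K):
            if present[k]:
                delta[k, c] = float(base_correct[class_masks[k]].mean()
                                    - occ_correct[class_masks[k]].mean())
    return OcclusionMap(delta=delta, class_names=tuple(class_names),
                        channel_ids=tuple(channel_ids))


def spearman_rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho: product-moment correlation of average-tie ranks.

    Returns NaN (flagged undefined) when either input has zero rank
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass
class SnrOcclusionReport:
    """Per-channel SNR vs occlusion sensitivity with ranks, rho and flags."""

    table: pd.DataFrame  # channel_id, snr_db, sensitivity, snr_rank, occ_rank, below_threshold
    rho: float
    threshold_db: float
    nullity_bound: float
    flagged_channels: tuple[str, ...]
    flagged_null: bool  # True if every below-threshold channel has mean |dP| < bound

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rho": self.rho,
            "threshold_db": self.threshold_db,
            "nullity_bound": self.nullity_bound,
            "flagged_channels": list(self.flagged_channels),
            "flagged_null": bool(self.flagged_null),
            "channels": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def snr_threshold_report(snr_db: pd.Series, occ_map: OcclusionMap,
                         threshold_db: float = 20.0,
                         nullity_bound: float = 0.01) -> SnrOcclusionReport:
    """Pair channel SNR with occlusion sensitivity and audit the threshold.

    ``snr_db`` is indexed by channel_id and must cover exactly the channels
    of the occlusion map.  Channels below ``threshold_db`` are flagged, and
    ``flagged_null`` records whether all of them have class-averaged |dP|
    below ``nullity_bound`` (i.e. removing them does not affect the model).
    """
    sens = occ_map.channel_sensitivity(signed=False)
    if set(snr_db.index) != set(sens.index):
        raise ValueError("SNR table and occlusion map cover different channel sets")
    snr = snr_db.reindex(sens.index)
    order = np.arange(len(sens))  # roster order for tie-breaks
    snr_rank = pd.Series(_dense_rank(-snr.to_numpy(), order), index=sens.index)
    occ_rank = pd.Series(_dense_rank(-sens.to_numpy(), order), index=sens.index)
    below = snr < threshold_db
    table = pd.DataFrame({
        "channel_id": sens.index,
        "snr_db": snr.to_numpy(),
        "occlusion_sensitivity": sens.to_numpy(),
        "signed_sensitivity": occ_map.channel_sensitivity(signed=True).to_numpy(),
        "snr_rank": snr_rank.to_numpy(),
        "occlusion_rank": occ_rank.to_numpy(),
        "below_threshold": below.to_numpy(),
    })
    rho = spearman_rank_correlation(snr.to_numpy(), sens.to_numpy())
    flagged = tuple(sens.index[below])
    flagged_null = bool(np.all(sens[below] < nullity_bound)) if below.any() else True
    return SnrOcclusionReport(table=table, rho=rho, threshold_db=threshold_db,
                              nullity_bound=nullity_bound,
                              flagged_channels=flagged, flagged_null=flagged_null)


def _dense_rank(keys: np.ndarray, tiebreak: np.ndarray) -> np.ndarray:
    """1-based ranks by ascending key; NaN keys last; ties by ``tiebreak``."""
    keys = np.where(np.isfinite(keys), keys, np.inf)
    order = np.lexsort((tiebreak, keys))
    ranks = np.empty(len(keys), dtype=int)
    ranks[order] = np.arange(1, len(keys) + 1)
    return ranks
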
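"""Grand averages, signed-r2 discriminability maps, bootstrap CIs.

The class contrast is quantified per channel and time point by the
point-biserial correlation r between single-epoch voltage and the class
label (1 target, 0 distractor), reported as signed r2 = sign(r) * r^2.
Participant maps are averaged after Fisher z-transforming the underlying
correlations (atanh, averaged, tanh back, re-squared with sign), which
makes the coefficients approximately Gaussian for averaging.  No
significance threshold is applied anywhere: the full spatio-temporal
pattern is kept, including subtle differences that only the multivariate
classifier can exploit.

Unlike classification, these analyses operate on artifact-free epochs only
(max-min rejection at 100 uV EEG / 200 uV EOG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class GrandAverage:
    """Two-stage class means: epochs -> participant average -> grand
    average with equal participant weights."""

    #: (condition, class label) -> channels x time grand mean (uV)
    mean: dict[tuple[str, int], np.ndarray]
    #: (condition, class label) -> participants x channels x time
    participant_means: dict[tuple[str, int], np.ndarray]
    #: (condition, class label) -> per-participant epoch counts
    epoch_counts: dict[tuple[str, int], np.ndarray]
    channel_names: list[str]
    times_ms: np.ndarray
    participants: list[str]


def grand_average(epoch_sets: list[EpochSet]) -> GrandAverage:
    """Grand-average ERPs per condition and class over a cohort.

    Each entry of ``epoch_sets`` is one participant-condition; the artifact
    mask is applied.  Participants contribute with equal weight regardless
    of their epoch counts.
    """
    if not epoch_sets:
        raise ValueError("no epoch sets given")
    channel_names = epoch_sets[0].channel_names
    times = epoch_sets[0].times_ms
    participants = sorted({es.participant for es in epoch_sets})
    per: dict[tuple[str, int], dict[str, tuple[np.ndarray, int]]] = {}
    for es in epoch_sets:
        if es.channel_names != channel_names:
            raise ValueError("channel sets differ between epoch sets")
        kept = es.kept_only()
        for label in (0, 1):
            sel = kept.data[kept.labels == label]
            if sel.shape[0] == 0:
                logger.warning("no class-%d epochs for %s/%s", label,
                               es.participant, es.condition)
                continue
            per.setdefault((es.condition, label), {})[es.participant] = (
                sel.mean(axis=0), sel.shape[0])

    mean, pmeans, counts = {}, {}, {}
    for key, by_part in per.items():
        parts = [p for p in participants if p in by_part]
        stack = np.stack([by_part[p][0] for p in parts])
        pmeans[key] = stack
        counts[key] = np.array([by_part[p][1] for p in parts])
        mean[key] = stack.mean(axis=0)
    return GrandAverage(mean=mean, participant_means=pmeans, epoch_counts=counts,
                        channel_names=list(channel_names), times_ms=times.copy(),
                        participants=participants)


@dataclass
class DiscriminabilityMap:
    """Channels x time signed-r2 values for one participant-condition."""

    values: np.ndarray
    channel_names: list[str]
    times_ms: np.ndarray
    participant: str = ""
    condition: str = ""


def signed_r2(epochs: EpochSet, use_mask: bool = True) -> DiscriminabilityMap:
    """Signed squared point-biserial correlation per (channel, time).

    r is the Pearson correlation between single-epoch voltage and the 0/1
    class label; the map holds sign(r) * r^2.  Cells with zero voltage
    variance are set to 0 with a warning.
    """
    src = epochs.kept_only() if use_mask else epochs
    y = src.labels.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present after rejection")
    n = y.size
    yc = y - y.mean()
    Xc = src.data - src.data.mean(axis=0, keepdims=True)
    cov = np.tensordot(yc, Xc, axes=(0, 0)) / n  # channels x time
    vx = np.mean(Xc**2, axis=0)
    vy = np.mean(yc**2)
    denom = np.sqrt(vx * vy)
    zero = denom == 0
    if zero.any():
        logger.warning("%d zero-variance cells set to 0", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(zero, 0.0, cov / np.where(zero, 1.0, denom))
    return DiscriminabilityMap(values=np.sign(r) * r**2,
                               channel_names=list(src.channel_names),
                               times_ms=src.times_ms.copy(),
                               participant=src.participant,
                               condition=src.condition)


def fisher_average(maps: list[DiscriminabilityMap],
                   operand: str = "r") -> DiscriminabilityMap:
    """Average signed-r2 maps across participants via the Fisher
    z-transform.

    With ``operand='r'`` (default, and the reading we consider correct
    since atanh is defined for correlations): per cell
    r = sign(v) sqrt(|v|); z = atanh(r); z averaged across participants;
    back-transformed with tanh and re-squared with sign.  The alternative
    reading ``operand='signed_r2'`` applies atanh to the signed square
    itself.  |.| is clipped to 1 - 1e-10 before atanh.
    """
    if not maps:
        raise ValueError("no maps given")
    if operand not in ("r", "signed_r2"):
        raise ValueError("operand must be 'r' or 'signed_r2'")
    stack = np.stack([m.values for m in maps])
    if operand == "r":
        r = np.sign(stack) * np.sqrt(np.abs(stack))
    else:
        r = stack
    clip = np.abs(r) >= 1.0
    if clip.any():
        logger.warning("clipping %d |r|=1 cells before atanh", int(clip.sum()))
        r = np.clip(r, -1.0 + 1e-10, 1.0 - 1e-10)
    z = np.arctanh(r).mean(axis=0)
    r_avg = np.tanh(z)
    if operand == "signed_r2":
        return DiscriminabilityMap(values=r_avg,
                                   channel_names=list(maps[0].channel_names),
                                   times_ms=maps[0].times_ms.copy(),
                                   participant="average",
                                   condition=maps[0].condition)
    return DiscriminabilityMap(values=np.sign(r_avg) * r_avg**2,
                               channel_names=list(maps[0].channel_names),
                               times_ms=maps[0].times_ms.copy(),
                               participant="average",
                               condition=maps[0].condition)


def bootstrap_ci(values: np.ndarray, n_boot: int = 1000, level: float = 0.68,
                 seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean over participants.

    Resamples participants with replacement; the default 68% interval
    (16th-84th percentile) is equivalent to +-1 SD of the mean in the
    Gaussian case.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo = float(np.percentile(means, 100 * (0.5 - level / 2)))
    hi = float(np.percentile(means, 100 * (0.5 + level / 2)))
    return lo, hi


def peak_cell(map_: DiscriminabilityMap, tmin_ms: float | None = None,
              tmax_ms: float | None = None) -> tuple[str, float, float]:
    """(channel, time_ms, value) of the maximum signed-r2 cell, optionally
    restricted to a time window."""
    v = map_.values
    t = map_.times_ms
    mask = np.ones_like(t, dtype=bool)
    if tmin_ms is not None:
        mask &= t >= tmin_ms
    if tmax_ms is not None:
        mask &= t <= tmax_ms
    sub = v[:, mask]
    ci, ti = np.unravel_index(np.argmax(sub), sub.shape)
    return map_.channel_names[ci], float(t[mask][ti]), float(sub[ci, ti])
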
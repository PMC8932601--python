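"""Statistical channel selection on per-channel broadband power.

Two classes: classical pooled-variance two-sample t-test. More classes:
one-way ANOVA F-test. A channel is retained when its p-value is at most
alpha (0.05 by default). No multiple-testing correction is applied by
default, matching the source analysis, which reports raw per-channel
p-values; a Bonferroni option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .preprocessing import EpochMatrix
from .spectral import welch_psd_array


@dataclass
class ChannelTestResult:
    channel: str
    statistic: float
    p_value: float
    significant: bool


def channel_power_summary(epochs: EpochMatrix, low_hz: float = 4.0,
                          high_hz: float = 45.0, seg_len: int = 64,
                          overlap: float = 0.5,
                          taper: str = "hamming") -> np.ndarray:
    """Per-epoch, per-channel mean PSD over [low_hz, high_hz] -> (n_epochs, n_channels)."""
    freqs, pxx = welch_psd_array(epochs.epochs, epochs.fs, seg_len=seg_len,
                                 overlap=overlap, taper=taper)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    if not mask.any():
        raise ValueError("no PSD bins inside the summary band")
    return pxx[..., mask].mean(axis=-1)


def select_channels(power: np.ndarray, labels, channels,
                    alpha: float = 0.05, equal_var: bool = True,
                    bonferroni: bool = False) -> list[ChannelTestResult]:
    """Per-channel significance test of class differences in power.

    ``power`` is (n_epochs, n_channels); ``labels`` one class per epoch.
    Results are returned in headset channel order.
    """
    power = np.asarray(power, dtype=float)
    labels = np.asarray(labels)
    if power.shape != (len(labels), len(channels)):
        raise ValueError("power must be (n_epochs, n_channels) aligned with labels")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    groups_idx = [np.flatnonzero(labels == c) for c in classes]
    for c, idx in zip(classes, groups_idx):
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 epochs")
    thresh = alpha / len(channels) if bonferroni else alpha
    results = []
    for j, ch in enumerate(channels):
        groups = [power[idx, j] for idx in groups_idx]
        if len(classes) == 2:
            stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        else:
            stat, p = stats.f_oneway(*groups)
        results.append(ChannelTestResult(channel=ch, statistic=float(stat),
                                         p_value=float(p),
                                         significant=bool(p <= thresh)))
    return results


class StatisticalChannelSelector(BaseEstimator, TransformerMixin):
    """sklearn-style selector keeping channels whose class effect is significant.

    Parameters
    ----------
    channels : sequence of str
        Column names of X (headset order).
    alpha : float
        Significance level on the raw p-value.
    equal_var : bool
        Pooled-variance (classical Student) t-test when True; Welch otherwise.
    bonferroni : bool
        Divide alpha by the number of channels.

    Attributes
    ----------
    results_ : list of ChannelTestResult
    support_ : boolean array over channels
    selected_channels_ : tuple of retained channel names
    """

    def __init__(self, channels=None, alpha: float = 0.05,
                 equal_var: bool = True, bonferroni: bool = False):
        self.channels = channels
        self.alpha = alpha
        self.equal_var = equal_var
        self.bonferroni = bonferroni

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        channels = (tuple(self.channels) if self.channels is not None
                    else tuple(f"ch{i}" for i in range(X.shape[1])))
        self.results_ = select_channels(X, y, channels, alpha=self.alpha,
                                        equal_var=self.equal_var,
                                        bonferroni=self.bonferroni)
        self.support_ = np.array([r.significant for r in self.results_])
        self.selected_channels_ = tuple(
            r.channel for r in self.results_ if r.significant)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of channels than fit")
        return X[:, self.support_]
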
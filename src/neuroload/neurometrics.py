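"""IAF-anchored band power and the workload / approach-withdrawal indices.

Band edges are anchored to the Individual Alpha Frequency (IAF) estimated
from an eyes-closed rest segment: theta spans [IAF - 6, IAF - 2] Hz and
alpha spans [IAF - 2, IAF + 2] Hz, adjacent by construction.  Per 1-s clean
epoch the Global Field Power (GFP) of a band over a channel subset is, by
default, the mean across the subset of each channel's periodogram power
integrated over the band; the classical spatial-variance GFP is available as
an alternative mode.

Two scalar neurometrics summarise each subject x condition recording:

* ``WL`` (workload, dimensionless): epoch-mean frontal theta GFP divided by
  epoch-mean parietal alpha GFP.  Higher values indicate higher cognitive
  load (frontal theta rises and parietal alpha falls with load).
* ``AW`` (approach-withdrawal, uV^2): epoch-mean right-frontal alpha GFP
  minus the left-frontal value.  Relatively greater right-hemisphere alpha
  (i.e. less right activation) is read as approach / acceptance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .montage import ChannelMontage
from .recording import EpochSet, Recording

logger = logging.getLogger(__name__)

IAF_SEARCH_RANGE = (7.0, 13.0)
IAF_FALLBACK = 10.0
#: a spectral peak must exceed this multiple of the median in-range PSD to
#: count as an alpha peak (rejects spurious local maxima of flat spectra)
PEAK_PROMINENCE_FACTOR = 1.5


@dataclass(frozen=True)
class BandScheme:
    """IAF-anchored theta/alpha band edges."""

    iaf: float

    def __post_init__(self) -> None:
        if not 7.0 <= self.iaf <= 13.0:
            raise ValueError("iaf must lie in [7, 13] Hz")

    @property
    def theta_band(self) -> tuple[float, float]:
        return (self.iaf - 6.0, self.iaf - 2.0)

    @property
    def alpha_band(self) -> tuple[float, float]:
        return (self.iaf - 2.0, self.iaf + 2.0)


def band_edges(iaf: float) -> BandScheme:
    """Validate ``iaf`` and return the anchored band scheme."""
    return BandScheme(float(iaf))


def estimate_iaf(rest: Recording,
                 search_range: tuple[float, float] = IAF_SEARCH_RANGE,
                 subset: tuple[str, ...] | None = None,
                 return_found: bool = False):
    """IAF from an eyes-closed rest segment.

    Welch periodogram (2-s Hann windows, 50% overlap, 0.5 Hz resolution)
    averaged over the parietal subset; the IAF is the frequency of the
    largest sufficiently prominent local maximum inside ``search_range``.
    Returns the 10 Hz fallback with a logged warning when no peak exists
    (e.g. featureless noise); with ``return_found=True`` a
    ``(iaf, peak_found)`` pair is returned so callers can distinguish a
    genuine 10 Hz peak from the fallback.
    """
    if rest.duration < 30.0:
        raise ValueError("rest segment must be at least 30 s")
    subset = subset if subset is not None else rest.montage.parietal
    if not subset:
        raise ValueError("channel subset must be non-empty")
    idx = rest.montage.indices(subset)
    nperseg = int(round(2.0 * rest.fs))
    freqs, psd = signal.welch(rest.samples[idx], fs=rest.fs, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2,
                              axis=-1)
    mean_psd = psd.mean(axis=0)
    in_range = (freqs >= search_range[0]) & (freqs <= search_range[1])
    floor = np.median(mean_psd[in_range]) * PEAK_PROMINENCE_FACTOR
    # local maxima against immediate neighbours, evaluated on the full grid
    candidates = []
    for k in np.flatnonzero(in_range):
        if 0 < k < len(freqs) - 1 and \
                mean_psd[k] > mean_psd[k - 1] and \
                mean_psd[k] >= mean_psd[k + 1] and mean_psd[k] > floor:
            candidates.append(k)
    if not candidates:
        logger.warning("no alpha peak in [%g, %g] Hz; falling back to "
                       "IAF = %g Hz", *search_range, IAF_FALLBACK)
        return (IAF_FALLBACK, False) if return_found else IAF_FALLBACK
    best = max(candidates, key=lambda k: mean_psd[k])
    iaf = float(freqs[best])
    return (iaf, True) if return_found else iaf


@dataclass
class BandPower:
    """Per-epoch band power (uV^2); NaN marks rejected epochs."""

    values: np.ndarray
    band: tuple[float, float]
    subset: tuple[str, ...]

    @property
    def clean_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def mean(self) -> float:
        clean = self.clean_values
        if clean.size == 0:
            raise ValueError("no clean epochs")
        return float(clean.mean())


def _epoch_psd(epochs: np.ndarray, fs: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Single Hann-windowed periodogram per epoch and channel (density)."""
    n = epochs.shape[-1]
    freqs, psd = signal.periodogram(epochs, fs=fs, window="hann",
                                    axis=-1, scaling="density")
    return freqs, psd


def band_gfp(epochs: EpochSet, band: tuple[float, float],
             subset: tuple[str, ...], mode: str = "subset-mean") -> BandPower:
    """GFP band power per clean epoch over a channel subset.

    ``subset-mean`` (default): integral of each channel's periodogram over
    ``[low, high)`` then the mean across the subset.  ``spatial-variance``:
    classical GFP -- the per-sample across-channel variance of the
    band-limited signal, averaged over the epoch.
    """
    if not subset:
        raise ValueError("channel subset must be non-empty")
    low, high = band
    if not 0 < low < high:
        raise ValueError("band edges must satisfy 0 < low < high")
    idx = epochs.montage.indices(subset)
    data = epochs.epochs[:, idx, :]
    values = np.full(epochs.n_epochs, np.nan)
    clean = ~epochs.artifact_mask
    if not clean.any():
        return BandPower(values, (low, high), tuple(subset))
    if mode == "subset-mean":
        freqs, psd = _epoch_psd(data[clean], epochs.fs)
        sel = (freqs >= low) & (freqs < high)
        df = freqs[1] - freqs[0]
        values[clean] = psd[..., sel].sum(axis=-1).mean(axis=-1) * df
    elif mode == "spatial-variance":
        n = data.shape[-1]
        spec = np.fft.rfft(data[clean], axis=-1)
        freqs = np.fft.rfftfreq(n, 1.0 / epochs.fs)
        spec[..., ~((freqs >= low) & (freqs < high))] = 0.0
        narrow = np.fft.irfft(spec, n=n, axis=-1)
        gfp_t = narrow.var(axis=1)          # across-channel variance per sample
        values[clean] = gfp_t.mean(axis=-1)
    else:
        raise ValueError(f"unknown GFP mode {mode!r}")
    return BandPower(values, (low, high), tuple(subset))


def workload_index(epochs: EpochSet, scheme: BandScheme,
                   montage: ChannelMontage | None = None,
                   gfp_mode: str = "subset-mean",
                   aggregate: str = "ratio-of-means") -> float:
    """WL = frontal theta GFP / parietal alpha GFP.

    ``ratio-of-means`` (default) divides the epoch-mean powers, which is
    stable for 1-s epochs; ``mean-of-ratios`` averages per-epoch ratios.
    """
    montage = montage or epochs.montage
    if epochs.n_clean < 1:
        raise ValueError("no clean epochs")
    theta = band_gfp(epochs, scheme.theta_band, montage.frontal, gfp_mode)
    alpha = band_gfp(epochs, scheme.alpha_band, montage.parietal, gfp_mode)
    if aggregate == "ratio-of-means":
        denom = alpha.mean()
        if denom == 0:
            raise ZeroDivisionError("zero parietal alpha power")
        return theta.mean() / denom
    if aggregate == "mean-of-ratios":
        num, den = theta.clean_values, alpha.clean_values
        if np.any(den == 0):
            raise ZeroDivisionError("zero parietal alpha power in an epoch")
        return float((num / den).mean())
    raise ValueError(f"unknown aggregate mode {aggregate!r}")


def approach_withdrawal_index(epochs: EpochSet, scheme: BandScheme,
                              montage: ChannelMontage | None = None,
                              gfp_mode: str = "subset-mean",
                              scale: str = "power") -> float:
    """AW = right-frontal alpha GFP minus left-frontal alpha GFP.

    ``scale='power'`` (default) differences raw band powers in uV^2;
    ``scale='log'`` differences natural-log powers (the common asymmetry
    transform), offered for sensitivity analyses.
    """
    montage = montage or epochs.montage
    if not montage.frontal_right or not montage.frontal_left:
        raise ValueError("hemispheric subsets must be non-empty")
    right = band_gfp(epochs, scheme.alpha_band, montage.frontal_right,
                     gfp_mode).mean()
    left = band_gfp(epochs, scheme.alpha_band, montage.frontal_left,
                    gfp_mode).mean()
    if scale == "power":
        return right - left
    if scale == "log":
        if right <= 0 or left <= 0:
            raise ValueError("log scale requires positive band powers")
        return float(np.log(right) - np.log(left))
    raise ValueError(f"unknown AW scale {scale!r}")


def aggregate_study(epoch_sets: dict, schemes: dict,
                    montage: ChannelMontage | None = None,
                    gfp_mode: str = "subset-mean") -> pd.DataFrame:
    """One neurometric record per subject x condition.

    ``epoch_sets`` maps ``(subject_id, condition)`` to an EpochSet and
    ``schemes`` maps ``subject_id`` to a BandScheme.  Records with zero
    clean epochs are excluded with a logged warning.
    """
    rows = []
    for (subject_id, condition), epochs in sorted(epoch_sets.items()):
        scheme = schemes[subject_id]
        if epochs.n_clean < 1:
            logger.warning("no clean epochs for %s/%s; record excluded",
                           subject_id, condition)
            continue
        m = montage or epochs.montage
        rows.append({
            "subject_id": subject_id,
            "group": epochs.meta.get("group"),
            "condition": condition,
            "wl": workload_index(epochs, scheme, m, gfp_mode),
            "aw": approach_withdrawal_index(epochs, scheme, m, gfp_mode),
            "n_clean_epochs": epochs.n_clean,
            "iaf_hz": scheme.iaf,
        })
    return pd.DataFrame(rows)
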
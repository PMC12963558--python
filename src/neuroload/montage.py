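"""Electrode montage and channel-role bookkeeping.

The headset modelled here carries eight wet electrodes placed by the
International 10-20 system: five prefrontal sites (AFz, AF3, AF4, AF7, AF8)
and three posterior-parietal sites (Pz, P3, P4).  Downstream neurometrics
address channels by *role* rather than by index: the workload index contrasts
frontal theta against parietal alpha, and the approach-withdrawal index
contrasts right-frontal against left-frontal alpha.
"""

from __future__ import annotations

from dataclasses import dataclass


DEFAULT_LABELS = ("AFz", "AF3", "AF4", "AF7", "AF8", "Pz", "P3", "P4")


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered channel labels plus the role subsets used by the neurometrics.

    Parameters
    ----------
    ordered_labels
        Canonical channel order; recordings are stored row-per-channel in
        this order.
    frontal, parietal
        Subsets used by the workload index (theta numerator / alpha
        denominator).
    frontal_left, frontal_right
        Hemispheric subsets used by the approach-withdrawal index.  The
        midline site AFz belongs to neither.
    """

    ordered_labels: tuple[str, ...] = DEFAULT_LABELS
    frontal: tuple[str, ...] = ("AFz", "AF3", "AF4", "AF7", "AF8")
    parietal: tuple[str, ...] = ("Pz", "P3", "P4")
    frontal_left: tuple[str, ...] = ("AF3", "AF7")
    frontal_right: tuple[str, ...] = ("AF4", "AF8")

    def __post_init__(self) -> None:
        labels = set(self.ordered_labels)
        if len(labels) != len(self.ordered_labels):
            raise ValueError("duplicate channel labels in montage")
        for name in ("frontal", "parietal", "frontal_left", "frontal_right"):
            subset = getattr(self, name)
            unknown = [ch for ch in subset if ch not in labels]
            if unknown:
                raise ValueError(f"{name} contains unknown labels: {unknown}")
        if set(self.frontal_left) & set(self.frontal_right):
            raise ValueError("frontal_left and frontal_right must be disjoint")

    @property
    def n_channels(self) -> int:
        return len(self.ordered_labels)

    def index(self, label: str) -> int:
        try:
            return self.ordered_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels) -> list[int]:
        return [self.index(ch) for ch in labels]

    def role(self, name: str) -> tuple[str, ...]:
        """Return the label subset for a role name.

        Accepted roles: ``frontal``, ``parietal``, ``frontal_left``,
        ``frontal_right`` and ``all``.
        """
        if name == "all":
            return self.ordered_labels
        if name in ("frontal", "parietal", "frontal_left", "frontal_right"):
            return getattr(self, name)
        raise KeyError(f"unknown montage role {name!r}")


def default_montage() -> ChannelMontage:
    return ChannelMontage()
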